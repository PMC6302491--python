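"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: naive substring
scans, explicit projection matrices, plain-python arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_chi_square(disease: float, control: float) -> float:
    """Plain-python pseudocount chi-square evaluation."""
    return (disease - control) ** 2 / (control + 1)


def naive_tryptic_peptides(sequence: str, min_len: int, max_len: int) -> set[str]:
    """All fully tryptic peptides by exhaustive substring enumeration."""
    out = set()
    n = len(sequence)
    for start in range(n):
        if start != 0 and sequence[start - 1] not in "KR":
            continue
        for end in range(start + min_len, min(start + max_len, n) + 1):
            if end != n and sequence[end - 1] not in "KR":
                continue
            out.add(sequence[start:end])
    return out


def projection_sequential_ss(obs: pd.DataFrame) -> dict:
    """Sequential (type-I) sums of squares via explicit projection matrices.

    P_k = X_k pinv(X_k); SS of term k = y' (P_k - P_{k-1}) y.  Term df are
    projection-rank increments.  Independent of the package's incremental
    least-squares route.
    """
    y = obs["log10_intensity"].to_numpy(dtype=float)
    n = y.size
    pep = pd.get_dummies(obs["peptide"]).to_numpy(dtype=float)
    trt = pd.get_dummies(obs["treatment_id"]).to_numpy(dtype=float)
    inter = pd.get_dummies(
        obs["peptide"].astype(str) + "|" + obs["treatment_id"].astype(str)
    ).to_numpy(dtype=float)
    designs = [np.ones((n, 1))]
    names = []
    if pep.shape[1] > 1:
        designs.append(np.hstack([designs[-1], pep]))
        names.append("Peptide_Sequence")
    designs.append(np.hstack([designs[-1], trt]))
    names.append("Treatment_ID")
    if pep.shape[1] > 1:
        designs.append(np.hstack([designs[-1], inter]))
        names.append("Peptide_Sequence:Treatment_ID")
    projections = [X @ np.linalg.pinv(X) for X in designs]
    fitted_ss = [float(y @ P @ y) for P in projections]
    ranks = [int(np.round(np.trace(P))) for P in projections]
    out = {}
    for k, name in enumerate(names, start=1):
        out[name] = {
            "sum_sq": fitted_ss[k] - fitted_ss[k - 1],
            "df": ranks[k] - ranks[k - 1],
        }
    out["Residuals"] = {
        "sum_sq": float(y @ y) - fitted_ss[-1],
        "df": n - ranks[-1],
    }
    return out


def bh_step_up(pvalues: list[float]) -> list[float]:
    """Hand-rolled BH step-up for cross-checking."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvalues[i] * m / rank_from_end)
        q[i] = val
        prev = val
    return q
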