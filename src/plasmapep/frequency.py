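"""Observation-frequency correction and the pseudocount chi-square screen.

Spectral counting treats the number of accepted PSMs per gene symbol and
treatment as a semi-quantitative abundance proxy.  Because treatments
contribute unequal total numbers of accepted spectra, raw control counts are
rescaled by the ratio of treatment totals before comparison; the corrected
difference distribution is then centred at zero by construction, which is
the quantile diagnostic this module reproduces.

The per-symbol statistic is the pseudocount-protected goodness-of-fit value

    chi2 = (Disease - Control)^2 / (Control + 1)

with Control the corrected control count.  Following the field convention
it is referred to the chi-square distribution with one degree of freedom;
the pseudocount statistic is not exactly chi-square distributed under the
null, so a simulation-based exceedance rate is reported alongside rather
than asserting either calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CHI2_DF = 1

#: selection used for network export: frequency difference > 15 and chi2 > 15
RULE_CHI2_15: "SelectionRule"
#: headline-table selection: chi2 >= 60 (delta rule unchanged)
RULE_CHI2_60: "SelectionRule"


@dataclass(frozen=True)
class SelectionRule:
    """Candidate-selection thresholds on the chi-square statistic and delta."""

    chi2_min: float = 15.0
    delta_min: float = 15.0
    chi2_strict: bool = True  # strict > for the 15-rule, >= for the 60-rule

    def __post_init__(self) -> None:
        if self.chi2_min < 0 or self.delta_min < 0:
            raise ValueError("selection thresholds must be non-negative")


RULE_CHI2_15 = SelectionRule(15.0, 15.0, chi2_strict=True)
RULE_CHI2_60 = SelectionRule(60.0, 15.0, chi2_strict=False)


@dataclass
class FrequencyMatrix:
    """Gene-symbol x treatment table of accepted-PSM counts for one pool."""

    pool: str
    counts: pd.DataFrame  # index gene_symbol, columns treatment_id (int)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_symbol"
        out.to_csv(path, sep="\t")


def count_frequencies(
    accepted: pd.DataFrame,
    pool: str,
    treatments: list[int] | None = None,
) -> FrequencyMatrix:
    """Tally accepted PSMs of ``pool`` per gene symbol and treatment.

    A degenerate PSM whose peptide maps to several gene symbols contributes
    one count to each symbol.
    """
    sub = accepted[accepted["pool"] == pool]
    if len(sub):
        exploded = sub.assign(gene_symbol=sub["gene_symbols"].str.split(";")).explode(
            "gene_symbol"
        )
        counts = (
            exploded.groupby(["gene_symbol", "treatment_id"])
            .size()
            .unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame(dtype=int)
        counts.index.name = "gene_symbol"
        counts.columns.name = "treatment_id"
    if treatments is not None:
        counts = counts.reindex(columns=treatments, fill_value=0)
    counts = counts.astype(int).sort_index()
    return FrequencyMatrix(pool=pool, counts=counts)


def correct_control(
    freq: FrequencyMatrix, disease_t: int, control_t: int
) -> pd.Series:
    """Scale the control column to the disease total.

    corrected(g) = raw_control(g) * totals[disease] / totals[control];
    the disease counts the tables report stay unscaled.
    """
    totals = freq.totals
    if control_t not in freq.counts.columns or disease_t not in freq.counts.columns:
        raise KeyError("contrast treatment absent from frequency matrix")
    if totals[control_t] == 0:
        raise ZeroDivisionError(
            f"control treatment {control_t} has zero total accepted PSMs; "
            "frequency correction is undefined"
        )
    ratio = totals[disease_t] / totals[control_t]
    return freq.counts[control_t] * ratio


def chi_square(disease, control):
    """Pseudocount chi-square: (disease - control)^2 / (control + 1).

    Accepts scalars or arrays; ``control`` is normally the corrected control
    count.  Negative inputs are a domain error.
    """
    d = np.asarray(disease, dtype=float)
    c = np.asarray(control, dtype=float)
    if np.any(d < 0) or np.any(c < 0):
        raise ValueError("counts must be non-negative")
    out = (d - c) ** 2 / (c + 1.0)
    if np.isscalar(disease) and np.isscalar(control):
        return float(out)
    return out


def chi2_pvalue(chi2):
    """Upper-tail probability of the chi-square distribution, df = 1."""
    x = np.asarray(chi2, dtype=float)
    if np.any(x < 0):
        raise ValueError("chi2 must be non-negative")
    p = stats.chi2.sf(x, CHI2_DF)
    return float(p) if np.isscalar(chi2) else p


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combine_peptide_pvalues(pvalues, method: str = "fisher") -> float:
    """Cumulative protein p-value from per-peptide p-values.

    ``fisher``: -2 sum(ln p) referred to chi-square with 2k df.
    ``stouffer``: unweighted inverse-normal combination.
    Zero p-values are clamped to the smallest positive float with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("p = 0 clamped to the smallest positive float", RuntimeWarning)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    if method == "fisher":
        stat = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(stat, 2 * p.size))
    if method == "stouffer":
        z = stats.norm.isf(p).sum() / np.sqrt(p.size)
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown combination method {method!r}")


def analyze_contrast(
    freq: FrequencyMatrix, disease_t: int, control_t: int
) -> pd.DataFrame:
    """Per-gene-symbol chi-square contrast table.

    Columns: disease_count, control_count, control_corrected, delta, chi2,
    p (df = 1 upper tail), q (BH within the pool), selected_15, selected_60.
    """
    corrected = correct_control(freq, disease_t, control_t)
    d = freq.counts[disease_t].astype(float)
    table = pd.DataFrame(
        {
            "disease_count": d,
            "control_count": freq.counts[control_t].astype(float),
            "control_corrected": corrected,
        }
    )
    table["delta"] = table["disease_count"] - table["control_corrected"]
    table["chi2"] = chi_square(
        table["disease_count"].to_numpy(), table["control_corrected"].to_numpy()
    )
    table["p"] = chi2_pvalue(table["chi2"].to_numpy())
    table["q"] = bh_qvalues(table["p"].to_numpy())
    table["selected_15"] = _selected_mask(table, RULE_CHI2_15)
    table["selected_60"] = _selected_mask(table, RULE_CHI2_60)
    return table.sort_values("chi2", ascending=False)


def _selected_mask(table: pd.DataFrame, rule: SelectionRule) -> pd.Series:
    chi2_ok = (
        table["chi2"] > rule.chi2_min
        if rule.chi2_strict
        else table["chi2"] >= rule.chi2_min
    )
    return (table["delta"] > rule.delta_min) & chi2_ok


def select_candidates(table: pd.DataFrame, rule: SelectionRule) -> list[str]:
    """Gene symbols passing ``rule``, sorted by chi2 descending.

    The returned newline-joinable list is the export format for external
    network/enrichment submission.
    """
    mask = _selected_mask(table, rule)
    return list(table[mask].sort_values("chi2", ascending=False).index)


@dataclass
class DeltaDiagnostic:
    """Sorted corrected-delta distribution on a standardized quantile axis."""

    table: pd.DataFrame  # columns: quantile, delta
    mean: float
    sd: float

    @property
    def standardized_mean(self) -> float:
        """|mean| / SD of the delta distribution (0 when centred)."""
        if self.sd == 0:
            return 0.0
        return abs(self.mean) / self.sd


def delta_quantile_diagnostic(deltas: pd.Series | np.ndarray) -> DeltaDiagnostic:
    """Quantile plot data for the corrected frequency differences.

    The quantile axis is the standard normal quantile of each order
    statistic, so a correctly corrected null cohort crosses delta = 0 at the
    0 quantile point (the mean of the difference distribution).
    """
    d = np.sort(np.asarray(deltas, dtype=float))
    n = d.size
    if n == 0:
        return DeltaDiagnostic(
            table=pd.DataFrame(columns=["quantile", "delta"]), mean=0.0, sd=0.0
        )
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    return DeltaDiagnostic(
        table=pd.DataFrame({"quantile": q, "delta": d}),
        mean=float(d.mean()),
        sd=sd,
    )


def cumulative_protein_pvalues(
    accepted: pd.DataFrame,
    pool: str,
    disease_t: int,
    control_t: int,
    method: str = "fisher",
) -> pd.DataFrame:
    """Combined per-gene-symbol p-values from peptide-level chi-square tests.

    Each peptide of a symbol gets its own corrected chi-square p-value; a
    symbol's cumulative p combines them (Fisher by default), and q is the BH
    adjustment across symbols within the pool.
    """
    sub = accepted[
        (accepted["pool"] == pool)
        & accepted["treatment_id"].isin([disease_t, control_t])
    ]
    exploded = sub.assign(gene_symbol=sub["gene_symbols"].str.split(";")).explode(
        "gene_symbol"
    )
    counts = (
        exploded.groupby(["gene_symbol", "peptide", "treatment_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[disease_t, control_t], fill_value=0)
    )
    totals = counts.sum(axis=0)
    if totals[control_t] == 0:
        raise ZeroDivisionError("control treatment has zero accepted PSMs")
    ratio = totals[disease_t] / totals[control_t]
    chi2 = chi_square(
        counts[disease_t].to_numpy(dtype=float),
        counts[control_t].to_numpy(dtype=float) * ratio,
    )
    pep_p = chi2_pvalue(chi2)
    per_pep = pd.DataFrame(
        {"gene_symbol": counts.index.get_level_values(0), "p": pep_p}
    )
    combined = (
        per_pep.groupby("gene_symbol")["p"]
        .apply(lambda ps: combine_peptide_pvalues(ps.to_numpy(), method=method))
        .rename("p_cumulative")
        .to_frame()
    )
    combined["n_peptides"] = per_pep.groupby("gene_symbol").size()
    combined["q"] = bh_qvalues(combined["p_cumulative"].to_numpy())
    return combined.sort_values("p_cumulative")


def average_chi2_per_symbol(
    accepted: pd.DataFrame,
    pool: str,
    disease_t: int,
    control_t: int,
    library,
) -> pd.DataFrame:
    """Accession-level chi-square statistics averaged per gene symbol.

    Counts are tallied per accession (a PSM listing several accessions
    contributes to each), corrected with accession-level totals, scored
    with the pseudocount statistic, and the per-symbol mean is reported —
    the accession-aware view of the headline table.  Also returns the
    number of accessions per symbol.
    """
    sub = accepted[
        (accepted["pool"] == pool)
        & accepted["treatment_id"].isin([disease_t, control_t])
    ]
    exploded = sub.assign(accession=sub["accessions"].str.split(";")).explode(
        "accession"
    )
    counts = (
        exploded.groupby(["accession", "treatment_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[disease_t, control_t], fill_value=0)
    )
    totals = counts.sum(axis=0)
    if totals[control_t] == 0:
        raise ZeroDivisionError("control treatment has zero accepted PSMs")
    ratio = totals[disease_t] / totals[control_t]
    per_acc = pd.DataFrame(
        {
            "gene_symbol": [library.symbol_of(a) for a in counts.index],
            "chi2": chi_square(
                counts[disease_t].to_numpy(dtype=float),
                counts[control_t].to_numpy(dtype=float) * ratio,
            ),
        },
        index=counts.index,
    )
    out = per_acc.groupby("gene_symbol")["chi2"].agg(
        mean_chi2="mean", accessions_per_symbol="size"
    )
    return out.sort_values("mean_chi2", ascending=False)


def null_exceedance_rate(table: pd.DataFrame, chi2_min: float = 15.0) -> float:
    """Fraction of symbols whose chi2 exceeds ``chi2_min`` (reported, not asserted)."""
    if len(table) == 0:
        return 0.0
    return float((table["chi2"] >= chi2_min).mean())
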