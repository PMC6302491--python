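"""Per-gene-symbol analysis of log10 precursor intensities.

For every gene symbol that survived the frequency screen, the accepted-PSM
log10 intensities are modelled by a two-way fixed-effects ANOVA with
sequential (type-I) sums of squares in the order

    Peptide_Sequence, Treatment_ID, Peptide_Sequence:Treatment_ID

matching the R convention of the per-gene report tables.  Designs are
expected to be unbalanced with missing cells (not every peptide is observed
in every treatment); term degrees of freedom come from design-matrix rank
increments, so aliased interaction cells drop out with the df adjusted
accordingly.  All-pairs treatment comparisons use the Tukey-Kramer
studentized-range test on the model residual mean square, summarized as a
compact letter display: two treatments share a letter iff their difference
is not significant.
"""

from __future__ import annotations

import functools
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ANOVA_TERMS = ("Peptide_Sequence", "Treatment_ID", "Peptide_Sequence:Treatment_ID")


class InsufficientDataError(ValueError):
    """Too few observations for the requested analysis."""


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


@dataclass
class QQResult:
    theoretical: np.ndarray
    sample: np.ndarray  # sorted, standardized observations
    correlation: float
    degenerate: bool = False  # zero-variance input


def qq_normality(values) -> QQResult:
    """Normal quantile-quantile data plus the QQ correlation coefficient."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        raise InsufficientDataError("qq_normality requires at least 3 observations")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    sd = x.std(ddof=1)
    if sd == 0:
        return QQResult(theo, np.zeros(n), correlation=float("nan"), degenerate=True)
    std = (x - x.mean()) / sd
    r = float(np.corrcoef(theo, std)[0, 1])
    return QQResult(theo, std, correlation=r)


def standard_error(sd: float, n: int) -> float:
    """SE of the mean from the sample SD: SD / sqrt(n); NaN when n < 2."""
    if n < 2 or np.isnan(sd):
        return float("nan")
    return sd / np.sqrt(n)


@dataclass
class TreatmentSummary:
    """Per-treatment mean/SD/SE/n row with an optional letter-display string."""

    treatment_id: int
    mean: float
    sd: float  # sample SD, n-1 denominator; NaN at n = 1
    se: float  # SD / sqrt(n); NaN at n = 1
    n: int
    letters: str = ""


def summarize_treatment(values, treatment_id: int = -1) -> TreatmentSummary:
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise InsufficientDataError("no observations to summarize")
    sd = float(x.std(ddof=1)) if n >= 2 else float("nan")
    return TreatmentSummary(
        treatment_id=treatment_id,
        mean=float(x.mean()),
        sd=sd,
        se=standard_error(sd, n),
        n=n,
    )


# ---------------------------------------------------------------------------
# sequential two-way ANOVA
# ---------------------------------------------------------------------------


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_two_way_anova(observations: pd.DataFrame) -> pd.DataFrame:
    """Sequential-SS ANOVA table for one gene symbol.

    ``observations`` needs columns ``peptide``, ``treatment_id`` and
    ``log10_intensity``.  Returns a table indexed by term (the model terms
    followed by ``Residuals``) with columns ``sum_sq``, ``df``, ``F``, ``p``.
    Terms that are inestimable (a single peptide) are dropped; with zero
    residual df the F and p columns are NaN and a warning is issued.
    """
    obs = observations
    y = obs["log10_intensity"].to_numpy(dtype=float)
    n = y.size
    pep_codes, pep_levels = pd.factorize(obs["peptide"], sort=True)
    trt_codes, trt_levels = pd.factorize(obs["treatment_id"], sort=True)
    if len(trt_levels) < 2:
        raise InsufficientDataError("two-way ANOVA requires >= 2 treatments")

    blocks = [np.ones((n, 1))]
    terms: list[str] = []
    if len(pep_levels) > 1:
        blocks.append(_dummies(pep_codes, len(pep_levels)))
        terms.append("Peptide_Sequence")
    blocks.append(_dummies(trt_codes, len(trt_levels)))
    terms.append("Treatment_ID")
    if len(pep_levels) > 1:
        inter = pep_codes * len(trt_levels) + trt_codes
        inter_codes, inter_levels = pd.factorize(inter, sort=True)
        blocks.append(_dummies(inter_codes, len(inter_levels)))
        terms.append("Peptide_Sequence:Treatment_ID")

    rss = []
    rank = []
    X = np.empty((n, 0))
    for b in blocks:
        X = np.hstack([X, b])
        r, k = _rss_rank(X, y)
        rss.append(r)
        rank.append(k)

    sum_sq = [max(rss[i - 1] - rss[i], 0.0) for i in range(1, len(rss))]
    df = [rank[i] - rank[i - 1] for i in range(1, len(rank))]
    resid_ss = rss[-1]
    resid_df = n - rank[-1]

    rows = {}
    if resid_df > 0:
        ms_resid = resid_ss / resid_df
    else:
        ms_resid = float("nan")
        warnings.warn(
            "zero residual degrees of freedom: F and p are undefined", RuntimeWarning
        )
    for name, ss, d in zip(terms, sum_sq, df):
        if d > 0 and resid_df > 0 and ms_resid > 0:
            F = (ss / d) / ms_resid
            p = float(stats.f.sf(F, d, resid_df))
        else:
            F, p = float("nan"), float("nan")
        rows[name] = {"sum_sq": ss, "df": d, "F": F, "p": p}
    rows["Residuals"] = {
        "sum_sq": resid_ss,
        "df": resid_df,
        "F": float("nan"),
        "p": float("nan"),
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "term"
    return table


# ---------------------------------------------------------------------------
# Tukey-Kramer HSD and compact letter display
# ---------------------------------------------------------------------------


def compact_letter_display(
    levels: list, significant: set[frozenset]
) -> dict:
    """Insert-and-absorb letter assignment.

    ``levels`` are ordered (conventionally by descending mean); two levels
    share a letter iff their pair is not in ``significant``.
    """
    columns: list[set] = [set(levels)]
    for pair in significant:
        i, j = tuple(pair)
        new_columns: list[set] = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorb columns contained in another
        absorbed: list[set] = []
        for col in new_columns:
            if any(col < other for other in new_columns) or col in absorbed:
                continue
            absorbed.append(col)
        columns = absorbed
    # stable letter order: by first (highest-ranked) member
    order = {lvl: k for k, lvl in enumerate(levels)}
    columns.sort(key=lambda col: min(order[l] for l in col) if col else len(order))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lvl: "" for lvl in levels}
    for idx, col in enumerate(columns):
        for lvl in col:
            letters[lvl] += alphabet[idx % len(alphabet)]
    return {lvl: "".join(sorted(s)) for lvl, s in letters.items()}


@functools.lru_cache(maxsize=4096)
def _studentized_range_critical(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


@dataclass
class TukeyResult:
    pairs: pd.DataFrame  # treatment_i, treatment_j, diff, q_stat, significant
    letters: dict
    q_critical: float
    alpha: float


def tukey_kramer_hsd(
    means: dict | pd.Series,
    ns: dict | pd.Series,
    ms_resid: float,
    df_resid: int,
    alpha: float = 0.05,
) -> TukeyResult:
    """All-pairs Tukey-Kramer comparison of treatment means.

    Pair (i, j) is significant iff
    |mean_i - mean_j| / sqrt((MS_resid / 2) (1/n_i + 1/n_j)) exceeds the
    studentized-range critical value q(alpha, k, df_resid).  Unequal group
    sizes enter through the Kramer harmonic form, so n = 1 treatments remain
    testable against the shared residual error.
    """
    means = pd.Series(means, dtype=float)
    ns = pd.Series(ns).reindex(means.index)
    if len(means) < 2:
        raise InsufficientDataError("Tukey-Kramer requires >= 2 treatments")
    if df_resid < 1:
        raise InsufficientDataError("Tukey-Kramer requires residual df >= 1")
    k = len(means)
    q_crit = _studentized_range_critical(alpha, k, df_resid)
    rows = []
    significant: set[frozenset] = set()
    for i, j in itertools.combinations(means.index, 2):
        diff = means[i] - means[j]
        se = np.sqrt((ms_resid / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
        q_stat = abs(diff) / se if se > 0 else np.inf
        sig = bool(q_stat > q_crit)
        if sig:
            significant.add(frozenset((i, j)))
        rows.append(
            {
                "treatment_i": i,
                "treatment_j": j,
                "diff": diff,
                "q_stat": q_stat,
                "significant": sig,
            }
        )
    ranked = list(means.sort_values(ascending=False).index)
    letters = compact_letter_display(ranked, significant)
    return TukeyResult(
        pairs=pd.DataFrame(rows),
        letters=letters,
        q_critical=q_crit,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# per-gene driver
# ---------------------------------------------------------------------------


@dataclass
class GeneAnovaResult:
    """Table-style report for one gene symbol: summaries + ANOVA + Tukey."""

    gene_symbol: str
    summaries: pd.DataFrame  # treatment_id, mean, sd, se, n, letters
    anova: pd.DataFrame
    tukey: TukeyResult | None


def observations_from_psms(accepted: pd.DataFrame, gene_symbol: str) -> pd.DataFrame:
    """Extract (peptide, treatment, log10 intensity) rows for one symbol."""
    mask = accepted["gene_symbols"].str.split(";").map(lambda s: gene_symbol in s)
    sub = accepted[mask]
    return pd.DataFrame(
        {
            "peptide": sub["peptide"].to_numpy(),
            "treatment_id": sub["treatment_id"].to_numpy(),
            "log10_intensity": np.log10(sub["precursor_intensity"].to_numpy(dtype=float)),
        }
    )


def analyze_gene(
    observations: pd.DataFrame,
    gene_symbol: str = "",
    alpha: float = 0.05,
    *,
    one_way_letters: bool = False,
) -> GeneAnovaResult:
    """Fit the two-way model and the Tukey-Kramer letters for one gene.

    Letters are computed on the raw per-treatment means using the two-way
    model's residual mean square (or a one-way model's with
    ``one_way_letters``).
    """
    anova = fit_two_way_anova(observations)
    if one_way_letters:
        one_way = observations.assign(peptide="_pooled_")
        err = fit_two_way_anova(one_way).loc["Residuals"]
    else:
        err = anova.loc["Residuals"]
    grouped = observations.groupby("treatment_id")["log10_intensity"]
    summaries = pd.DataFrame(
        [
            vars(summarize_treatment(vals.to_numpy(), treatment_id=tid))
            for tid, vals in grouped
        ]
    ).set_index("treatment_id")
    tukey = None
    if err["df"] >= 1 and err["sum_sq"] > 0:
        tukey = tukey_kramer_hsd(
            means=summaries["mean"],
            ns=summaries["n"],
            ms_resid=err["sum_sq"] / err["df"],
            df_resid=int(err["df"]),
            alpha=alpha,
        )
        summaries["letters"] = pd.Series(tukey.letters)
    return GeneAnovaResult(
        gene_symbol=gene_symbol,
        summaries=summaries.reset_index(),
        anova=anova,
        tukey=tukey,
    )


def run_all_genes(
    accepted: pd.DataFrame,
    genes: list[str],
    *,
    min_observations: int = 3,
    alpha: float = 0.05,
    one_way_letters: bool = False,
) -> tuple[dict[str, GeneAnovaResult], pd.DataFrame]:
    """Per-gene ANOVA over a gene list (typically the chi-square selection).

    Returns results keyed by gene symbol and a skip report (gene, reason)
    for symbols with too few observations or a single treatment.
    """
    results: dict[str, GeneAnovaResult] = {}
    skipped = []
    for gene in genes:
        obs = observations_from_psms(accepted, gene)
        if len(obs) < min_observations:
            skipped.append({"gene_symbol": gene, "reason": "too few observations"})
            continue
        if obs["treatment_id"].nunique() < 2:
            skipped.append({"gene_symbol": gene, "reason": "single treatment"})
            continue
        results[gene] = analyze_gene(
            obs, gene_symbol=gene, alpha=alpha, one_way_letters=one_way_letters
        )
    return results, pd.DataFrame(skipped, columns=["gene_symbol", "reason"])
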