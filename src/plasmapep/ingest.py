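"""Reading and filtering of PSM tables.

Acceptance rules applied to raw candidate correlations, in order:

1. precursor intensity strictly greater than the working threshold
   (1e4 counts by default — the 99th percentile of the noise distribution);
2. one best fit per spectrum, by score with a deterministic tie-break
   (higher score, then charge +2 over +3, then lexicographically smaller
   peptide), so no MS/MS spectrum is re-used;
3. the peptide must be fully tryptic in at least one listed accession;
4. pool classification: STYP iff the match carries a phospho-S/T/Y
   modification, TRYP otherwise;
5. accessions collapse to distinct gene symbols (the aggregation key).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .library import ProteinLibrary
from .simulate import PSM_COLUMNS

logger = logging.getLogger(__name__)

INTENSITY_THRESHOLD = 1e4
CHARGE_STATES = (2, 3)

MODIFICATION_TYPES = (
    "Phospho-S",
    "Phospho-T",
    "Phospho-Y",
    "Acetyl",
    "Oxidation-M",
    "Loss-water",
    "Loss-ammonia",
)


class PsmFormatError(ValueError):
    """The PSM table does not match the expected TSV dialect."""


class NonTrypticError(ValueError):
    """A peptide has no fully tryptic context in any mapped protein."""


class PsmReadResult(NamedTuple):
    psms: pd.DataFrame
    rejected: pd.DataFrame  # columns: line, spectrum_id, reason


class AnnotateResult(NamedTuple):
    accepted: pd.DataFrame
    rejected: pd.DataFrame  # columns: spectrum_id, reason


def parse_modifications(spec: str) -> list[tuple[int, str]]:
    """Parse a semicolon-joined ``position:type`` modification string."""
    if not spec or (isinstance(spec, float) and np.isnan(spec)):
        return []
    out = []
    for item in str(spec).split(";"):
        pos, _, kind = item.partition(":")
        out.append((int(pos), kind))
    return out


def has_phospho(spec: str) -> bool:
    return any(kind.startswith("Phospho") for _, kind in parse_modifications(spec))


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False, columns=PSM_COLUMNS)


def read_psm_table(path: str | Path) -> PsmReadResult:
    """Read a PSM TSV, validating the dialect row by row.

    Malformed rows (non-numeric intensity, out-of-domain charge, empty
    peptide or accession list) are dropped and reported with their 1-based
    file line numbers; a missing required column raises
    :class:`PsmFormatError`.
    """
    df = pd.read_csv(
        str(path),
        sep="\t",
        dtype={
            "spectrum_id": str,
            "sample_id": str,
            "engine": str,
            "peptide": str,
            "modifications": str,
            "accessions": str,
        },
        keep_default_na=False,
    )
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise PsmFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[PSM_COLUMNS]
    if df.empty:
        rejected = pd.DataFrame(columns=["line", "spectrum_id", "reason"])
        return PsmReadResult(df, rejected)

    intensity = pd.to_numeric(df["precursor_intensity"], errors="coerce")
    mz = pd.to_numeric(df["precursor_mz"], errors="coerce")
    score = pd.to_numeric(df["score"], errors="coerce")
    charge = pd.to_numeric(df["charge"], errors="coerce")
    treatment = pd.to_numeric(df["treatment_id"], errors="coerce")
    fraction = pd.to_numeric(df["fraction_id"], errors="coerce")

    reasons = pd.Series("", index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    flag(intensity.isna() | (intensity <= 0), "non-positive or non-numeric intensity")
    flag(~charge.isin(CHARGE_STATES), "charge outside accepted states +2/+3")
    flag(mz.isna() | score.isna(), "non-numeric m/z or score")
    flag(treatment.isna() | fraction.isna(), "non-numeric treatment or fraction id")
    flag(df["peptide"].str.len() == 0, "empty peptide")
    flag(df["accessions"].str.len() == 0, "empty accession list")

    bad = reasons != ""
    rejected = pd.DataFrame(
        {
            "line": df.index[bad] + 2,  # header is line 1
            "spectrum_id": df.loc[bad, "spectrum_id"].to_numpy(),
            "reason": reasons[bad].to_numpy(),
        }
    )
    for _, row in rejected.iterrows():
        logger.warning("line %d (%s): %s", row["line"], row["spectrum_id"], row["reason"])

    good = df[~bad].copy()
    good["precursor_intensity"] = intensity[~bad]
    good["precursor_mz"] = mz[~bad]
    good["score"] = score[~bad]
    good["charge"] = charge[~bad].astype(int)
    good["treatment_id"] = treatment[~bad].astype(int)
    good["fraction_id"] = fraction[~bad].astype(int)
    return PsmReadResult(good.reset_index(drop=True), rejected.reset_index(drop=True))


def apply_intensity_threshold(
    psms: pd.DataFrame, threshold: float = INTENSITY_THRESHOLD
) -> pd.DataFrame:
    """Keep rows with precursor intensity strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return psms[psms["precursor_intensity"] > threshold].copy()


def select_best_fit(psms: pd.DataFrame, *, within_engine: bool = False) -> pd.DataFrame:
    """Retain one candidate per spectrum: the best fit by score.

    Ties break toward charge +2 over +3, then the lexicographically smaller
    peptide, giving a deterministic total order.  With ``within_engine`` the
    selection key is (engine, spectrum_id) instead of spectrum_id alone.
    Input row order is preserved among survivors.
    """
    keys = ["engine", "spectrum_id"] if within_engine else ["spectrum_id"]
    ordered = psms.sort_values(
        ["score", "charge", "peptide"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ordered.drop_duplicates(subset=keys, keep="first")
    return best.sort_index()


def map_to_gene_symbols(accessions: str | list[str], library: ProteinLibrary) -> list[str]:
    """Collapse an accession list to the distinct gene symbols owning them."""
    if isinstance(accessions, str):
        accessions = [a for a in accessions.split(";") if a]
    if not accessions:
        raise ValueError("empty accession list")
    return sorted({library.symbol_of(a) for a in accessions})


def classify_pool(
    peptide: str,
    modifications: str,
    accessions: str | list[str],
    library: ProteinLibrary,
) -> str:
    """Return TRYP or STYP after validating the tryptic context.

    Raises :class:`NonTrypticError` when the peptide is not fully tryptic in
    any of its mapped proteins.
    """
    if isinstance(accessions, str):
        accessions = [a for a in accessions.split(";") if a]
    if not any(library.is_fully_tryptic(peptide, a) for a in accessions):
        raise NonTrypticError(
            f"peptide {peptide!r} is not fully tryptic in any mapped accession"
        )
    return "STYP" if has_phospho(modifications) else "TRYP"


def annotate_psms(psms: pd.DataFrame, library: ProteinLibrary) -> AnnotateResult:
    """Validate tryptic context, assign pool and gene symbols.

    Returns the accepted table with ``pool``, ``gene_symbols``
    (semicolon-joined) and ``degenerate`` (peptide maps to more than one
    gene symbol) columns, plus a rejection report of spectra whose peptide
    has no tryptic context.  Unknown accessions raise.
    """
    index = library.peptide_index()
    pep_cache: dict[tuple[str, str], bool] = {}

    def valid(peptide: str, accs: str) -> bool:
        key = (peptide, accs)
        if key not in pep_cache:
            acc_list = [a for a in accs.split(";") if a]
            in_index = index.get(peptide)
            if in_index is not None and any(a in in_index for a in acc_list):
                ok = True
            else:
                ok = any(library.is_fully_tryptic(peptide, a) for a in acc_list)
            pep_cache[key] = ok
        return pep_cache[key]

    sym_cache: dict[str, tuple[str, bool]] = {}

    def symbols(accs: str) -> tuple[str, bool]:
        if accs not in sym_cache:
            syms = map_to_gene_symbols(accs, library)
            sym_cache[accs] = (";".join(syms), len(syms) > 1)
        return sym_cache[accs]

    ok_mask = np.array(
        [valid(p, a) for p, a in zip(psms["peptide"], psms["accessions"])]
    )
    rejected = pd.DataFrame(
        {
            "spectrum_id": psms.loc[~ok_mask, "spectrum_id"].to_numpy(),
            "reason": "non-tryptic in all mapped proteins",
        }
    )
    accepted = psms[ok_mask].copy()
    if len(accepted):
        sym_deg = [symbols(a) for a in accepted["accessions"]]
        accepted["gene_symbols"] = [s for s, _ in sym_deg]
        accepted["degenerate"] = [d for _, d in sym_deg]
        accepted["pool"] = np.where(
            accepted["modifications"].map(has_phospho), "STYP", "TRYP"
        )
    else:
        accepted["gene_symbols"] = pd.Series(dtype=str)
        accepted["degenerate"] = pd.Series(dtype=bool)
        accepted["pool"] = pd.Series(dtype=str)
    return AnnotateResult(accepted.reset_index(drop=True), rejected)


def accept_psms(
    psms: pd.DataFrame,
    library: ProteinLibrary,
    *,
    threshold: float = INTENSITY_THRESHOLD,
    within_engine: bool = False,
    engine: str | None = None,
) -> AnnotateResult:
    """Full acceptance chain: threshold, best fit, tryptic/pool annotation."""
    stage = psms if engine is None else psms[psms["engine"] == engine]
    stage = apply_intensity_threshold(stage, threshold)
    stage = select_best_fit(stage, within_engine=within_engine)
    return annotate_psms(stage, library)
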