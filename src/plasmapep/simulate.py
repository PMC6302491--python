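"""Synthetic multi-treatment PSM cohorts with known ground truth.

The generator emulates the statistical structure of redundant search-engine
output from randomly and independently sampled LC-ESI-MS/MS recordings of
plasma peptide extracts:

* per (sample, fraction) recording, spectra either carry a true peptide
  (drawn without replacement from the library's tryptic peptide pool with
  per-gene-symbol weights) or are unassignable noise;
* noise precursor intensities are log-normal and calibrated so their 99th
  percentile sits at the working acceptance threshold (1e4 counts by
  default), with the signal median about 100-fold above the noise median;
* planted effects multiply a gene symbol's sampling weight in a target
  treatment and/or shift its log10 precursor intensity, and are written to a
  truth log for recovery testing;
* acute-phase symbols are elevated in every disease-class treatment, and
  ice-cold treatments see a global detection-probability scale;
* a fraction of spectra carry a second, lower-scoring candidate peptide at
  the other charge state, to exercise best-fit filtering downstream.

One global integer seed fans out through ``numpy.random.SeedSequence``
substreams per treatment/sample/fraction; the substream used for peptide
selection is separate from the one used for intensities and scores, so
selection uses common random numbers across effect-size settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass
from scipy import stats

from .library import ProteinLibrary, ProteinLibraryEntry

#: Fixed column order of the PSM TSV dialect.
PSM_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "treatment_id",
    "fraction_id",
    "engine",
    "peptide",
    "modifications",
    "charge",
    "precursor_mz",
    "precursor_intensity",
    "score",
    "accessions",
]

_PROTON = 1.00727646688
_PHOSPHO = 79.96633
# residues that never create a tryptic cut site inside a generated peptide
_NONCLEAVE = np.array(list("ACDEFGHILMNPQSTVWY"))

TREATMENT_CLASSES = ("disease", "matched_normal", "ice_cold")


@dataclass(frozen=True)
class Treatment:
    """One treatment column of the study design (Table-3-style id convention)."""

    treatment_id: int
    label: str
    condition: str  # disease | matched_normal | ice_cold
    pool: str = "TRYP"  # TRYP | STYP
    spectra_scale: float = 1.0  # per-treatment multiplier on spectra budget

    def __post_init__(self) -> None:
        if self.condition not in TREATMENT_CLASSES:
            raise ValueError(f"unknown treatment class {self.condition!r}")
        if self.pool not in ("TRYP", "STYP"):
            raise ValueError(f"unknown pool {self.pool!r}")
        if self.spectra_scale <= 0:
            raise ValueError("spectra_scale must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """Treatments and per-sample recording budget."""

    treatments: tuple[Treatment, ...]
    samples_per_treatment: int = 10
    fractions_per_sample: int = 10  # 10-step organic extraction
    spectra_per_fraction: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        ids = [t.treatment_id for t in self.treatments]
        if len(ids) != len(set(ids)):
            raise ValueError("treatment ids must be unique")
        if self.samples_per_treatment < 1:
            raise ValueError("samples_per_treatment must be >= 1")
        if self.fractions_per_sample < 1 or self.spectra_per_fraction < 1:
            raise ValueError("fractions and spectra budgets must be >= 1")
        has_disease = any(t.condition == "disease" for t in self.treatments)
        has_normal = any(t.condition == "matched_normal" for t in self.treatments)
        if has_disease and not has_normal:
            raise ValueError("a disease treatment requires a matched_normal control")

    def treatment(self, treatment_id: int) -> Treatment:
        for t in self.treatments:
            if t.treatment_id == treatment_id:
                return t
        raise KeyError(f"treatment id {treatment_id} not in design")


@dataclass(frozen=True)
class PlantedEffect:
    """A known enrichment of one gene symbol in one treatment."""

    gene_symbol: str
    treatment_id: int
    frequency_multiplier: float = 1.0
    intensity_log10_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_multiplier < 1:
            raise ValueError("frequency multipliers must be >= 1")


@dataclass(frozen=True)
class EffectSpec:
    """Planted differential effects plus cohort-wide backgrounds."""

    enriched: tuple[PlantedEffect, ...] = ()
    acute_phase: tuple[str, ...] = ()
    acute_phase_multiplier: float = 2.0
    ice_cold_detection_scale: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "enriched", tuple(self.enriched))
        object.__setattr__(self, "acute_phase", tuple(self.acute_phase))
        if self.acute_phase_multiplier < 1:
            raise ValueError("acute_phase_multiplier must be >= 1")
        if not 0 < self.ice_cold_detection_scale <= 1:
            raise ValueError("ice_cold_detection_scale must be in (0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal noise/signal intensity geometry.

    The noise location is derived, not set: its log10 mean is anchored so
    the 99th percentile of the noise intensity distribution equals
    ``noise_p99`` (the working acceptance threshold).  The signal location
    sits ``log10(signal_to_noise_median)`` above the noise location.
    """

    noise_p99: float = 1e4
    noise_sigma_log10: float = 0.30
    signal_to_noise_median: float = 100.0
    signal_sigma_log10: float = 0.35
    peptide_sigma_log10: float = 0.25  # static per-peptide response spread
    noise_fraction: float = 0.88  # fraction of spectra that are unassignable

    def __post_init__(self) -> None:
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.noise_p99 <= 0 or self.noise_sigma_log10 <= 0:
            raise ValueError("noise distribution parameters must be positive")

    @property
    def noise_mu_log10(self) -> float:
        z99 = stats.norm.ppf(0.99)
        return math.log10(self.noise_p99) - z99 * self.noise_sigma_log10

    @property
    def signal_mu_log10(self) -> float:
        return self.noise_mu_log10 + math.log10(self.signal_to_noise_median)

    def sample_noise_log10(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.noise_mu_log10, self.noise_sigma_log10, n)


@dataclass
class TruthLog:
    """Record of the effects actually planted in a simulated cohort."""

    effects: pd.DataFrame  # gene_symbol, treatment_id, multiplier, shift, expected_count
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        self.effects.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = -1) -> "TruthLog":
        return cls(effects=pd.read_csv(path, sep="\t"), seed=seed)


# ---------------------------------------------------------------------------
# protein library generation
# ---------------------------------------------------------------------------


def _random_tryptic_peptide(rng: np.random.Generator) -> str:
    """A fully tryptic peptide of length 6-30 with no internal cut site."""
    length = int(rng.integers(6, 31))
    body = rng.choice(_NONCLEAVE, size=length - 1)
    last = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + last


def generate_protein_library(
    n_symbols: int,
    accessions_per_symbol: int = 1,
    seed: int = 0,
    *,
    mean_peptides_per_symbol: float = 4.0,
    peptide_count_distribution: str = "geometric",
) -> ProteinLibrary:
    """Generate a small non-redundant library analogue.

    Each gene symbol owns a core set of tryptic peptides (count drawn from a
    geometric distribution by default, or fixed); every accession of the
    symbol concatenates those peptides in a shuffled order, and accessions
    beyond the first append one private peptide so sequences differ.
    """
    if n_symbols < 2:
        raise ValueError(
            "n_symbols must be >= 2: a single symbol admits no disease/control contrast"
        )
    if accessions_per_symbol < 1:
        raise ValueError("accessions_per_symbol must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[ProteinLibraryEntry] = []
    for i in range(n_symbols):
        symbol = f"GS{i:04d}"
        if peptide_count_distribution == "geometric":
            n_pep = int(rng.geometric(1.0 / mean_peptides_per_symbol))
        elif peptide_count_distribution == "fixed":
            n_pep = max(1, round(mean_peptides_per_symbol))
        else:
            raise ValueError(
                f"unknown peptide_count_distribution {peptide_count_distribution!r}"
            )
        peptides = [_random_tryptic_peptide(rng) for _ in range(n_pep)]
        for j in range(accessions_per_symbol):
            order = rng.permutation(n_pep)
            parts = [peptides[k] for k in order]
            if j > 0:
                parts.append(_random_tryptic_peptide(rng))
            entries.append(
                ProteinLibraryEntry(
                    accession=f"{symbol}.{j + 1}",
                    gene_symbol=symbol,
                    sequence="".join(parts),
                )
            )
    return ProteinLibrary(entries)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _peptide_pool(library: ProteinLibrary) -> pd.DataFrame:
    """Flat table of the unique tryptic peptide pool (0 missed cleavages)."""
    index = library.peptide_index(missed_cleavages=0)
    symbol_accessions: dict[str, dict[str, list[str]]] = {}
    for pep, accs in index.items():
        for acc in accs:
            sym = library.symbol_of(acc)
            symbol_accessions.setdefault(pep, {}).setdefault(sym, []).append(acc)
    rows = []
    for pep in sorted(index):
        for sym, accs in sorted(symbol_accessions[pep].items()):
            rows.append(
                {
                    "peptide": pep,
                    "gene_symbol": sym,
                    "accessions": ";".join(sorted(accs)),
                }
            )
    pool = pd.DataFrame(rows)
    # peptides shared by several symbols stay once per symbol; sampling is
    # symbol-weighted so each (peptide, symbol) pair is a pool member
    return pool


def _symbol_weights(
    symbols: np.ndarray,
    unique_symbols: list[str],
    treatment: Treatment,
    effects: EffectSpec,
) -> np.ndarray:
    w = {s: 1.0 for s in unique_symbols}
    if treatment.condition == "disease":
        for s in effects.acute_phase:
            if s in w:
                w[s] *= effects.acute_phase_multiplier
    for eff in effects.enriched:
        if eff.treatment_id == treatment.treatment_id:
            w[eff.gene_symbol] *= eff.frequency_multiplier
    return np.array([w[s] for s in symbols])


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Gumbel top-k: exact weighted sampling without replacement.

    The Gumbel noise is drawn with a fixed call pattern (one array per
    fraction), so increasing one item's weight can only add it to the
    selected set under common random numbers.
    """
    gumbel = rng.gumbel(size=weights.size)
    if k >= weights.size:
        return np.arange(weights.size)
    keys = np.log(weights) + gumbel
    return np.argpartition(-keys, k - 1)[:k]


def simulate_cohort(
    library: ProteinLibrary,
    design: StudyDesign,
    effects: EffectSpec = EffectSpec(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    *,
    redundant_fraction: float = 0.3,
    phospho_fraction: float = 0.9,
    engines: tuple[str, ...] = ("XTANDEM", "SEQUEST"),
) -> tuple[pd.DataFrame, TruthLog]:
    """Simulate one multi-treatment cohort of candidate PSM rows.

    Returns the PSM table (one row per candidate peptide-to-spectrum
    correlation, redundant on purpose) and the :class:`TruthLog` of planted
    effects.  Fully reproducible for a fixed seed.
    """
    known = set(library.gene_symbols())
    for eff in effects.enriched:
        if eff.gene_symbol not in known:
            raise ValueError(f"effect references unknown gene symbol {eff.gene_symbol!r}")
    for s in effects.acute_phase:
        if s not in known:
            raise ValueError(f"acute-phase list references unknown gene symbol {s!r}")
    for eff in effects.enriched:
        design.treatment(eff.treatment_id)  # raises KeyError if absent

    pool = _peptide_pool(library)
    peptides = pool["peptide"].to_numpy()
    symbols = pool["gene_symbol"].to_numpy()
    accession_str = pool["accessions"].to_numpy()
    n_pool = len(pool)
    # within a symbol, weight splits evenly over its peptides so the symbol
    # weight is independent of its peptide count
    pep_per_symbol = pool.groupby("gene_symbol")["peptide"].transform("size").to_numpy()
    base_w = 1.0 / pep_per_symbol
    neutral_mass = np.array([_pt_mass.fast_mass(p) for p in peptides])
    sty_positions = [
        [i for i, aa in enumerate(p) if aa in "STY"] for p in peptides
    ]
    has_sty = np.array([len(x) > 0 for x in sty_positions])

    root = np.random.SeedSequence(seed)
    pool_ss, *treatment_ss = root.spawn(1 + len(design.treatments))
    rng_pool = np.random.default_rng(pool_ss)
    pep_offset = rng_pool.normal(0.0, noise.peptide_sigma_log10, n_pool)

    columns: dict[str, list] = {c: [] for c in PSM_COLUMNS}

    def emit(**kw) -> None:
        for c in PSM_COLUMNS:
            columns[c].extend(kw[c])

    for t, t_ss in zip(design.treatments, treatment_ss):
        w = base_w * _symbol_weights(symbols, library.gene_symbols(), t, effects)
        shift = np.zeros(n_pool)
        for eff in effects.enriched:
            if eff.treatment_id == t.treatment_id and eff.intensity_log10_shift:
                shift[symbols == eff.gene_symbol] += eff.intensity_log10_shift
        n_spec = max(1, round(design.spectra_per_fraction * t.spectra_scale))
        sample_ss = t_ss.spawn(design.samples_per_treatment)
        for s_idx, s_ss in enumerate(sample_ss):
            sample_id = f"T{t.treatment_id}S{s_idx + 1:02d}"
            fraction_ss = s_ss.spawn(design.fractions_per_sample)
            for f_idx, f_ss in enumerate(fraction_ss):
                sel_ss, obs_ss = f_ss.spawn(2)
                rng_sel = np.random.default_rng(sel_ss)
                rng_obs = np.random.default_rng(obs_ss)
                n_noise = int(rng_sel.binomial(n_spec, noise.noise_fraction))
                n_signal = n_spec - n_noise
                if t.condition == "ice_cold":
                    n_signal = int(
                        rng_sel.binomial(n_signal, effects.ice_cold_detection_scale)
                    )
                idx = _weighted_sample_without_replacement(rng_sel, w, n_signal)
                k = idx.size
                prefix = f"{sample_id}F{f_idx + 1:02d}"
                # --- signal spectra ------------------------------------
                if k:
                    log10_i = (
                        noise.signal_mu_log10
                        + pep_offset[idx]
                        + shift[idx]
                        + rng_obs.normal(0.0, noise.signal_sigma_log10, k)
                    )
                    charge = rng_obs.choice([2, 3], size=k, p=[0.6, 0.4])
                    score = rng_obs.uniform(2.0, 6.0, k)
                    engine = rng_obs.choice(np.asarray(engines), size=k)
                    phospho = np.zeros(k, dtype=bool)
                    if t.pool == "STYP":
                        phospho = (rng_obs.random(k) < phospho_fraction) & has_sty[idx]
                    mods = []
                    mod_mass = np.zeros(k)
                    for row, pi in enumerate(idx):
                        if phospho[row]:
                            pos_list = sty_positions[pi]
                            pos = pos_list[int(rng_obs.integers(len(pos_list)))]
                            mods.append(f"{pos + 1}:Phospho-{peptides[pi][pos]}")
                            mod_mass[row] = _PHOSPHO
                        else:
                            mods.append("")
                    mz = (neutral_mass[idx] + mod_mass + charge * _PROTON) / charge
                    spectrum_ids = [f"{prefix}N{j + 1:04d}" for j in range(k)]
                    emit(
                        spectrum_id=spectrum_ids,
                        sample_id=[sample_id] * k,
                        treatment_id=[t.treatment_id] * k,
                        fraction_id=[f_idx + 1] * k,
                        engine=list(engine),
                        peptide=list(peptides[idx]),
                        modifications=mods,
                        charge=list(charge),
                        precursor_mz=list(np.round(mz, 4)),
                        precursor_intensity=list(np.round(10.0 ** log10_i, 1)),
                        score=list(np.round(score, 3)),
                        accessions=list(accession_str[idx]),
                    )
                    # second, lower-scoring candidate at the other charge
                    dup = np.flatnonzero(rng_obs.random(k) < redundant_fraction)
                    if dup.size:
                        alt_idx = rng_obs.integers(0, n_pool, dup.size)
                        alt_charge = 5 - charge[dup]
                        alt_score = score[dup] - rng_obs.uniform(0.1, 1.0, dup.size)
                        alt_mz = (
                            neutral_mass[alt_idx] + alt_charge * _PROTON
                        ) / alt_charge
                        emit(
                            spectrum_id=[spectrum_ids[j] for j in dup],
                            sample_id=[sample_id] * dup.size,
                            treatment_id=[t.treatment_id] * dup.size,
                            fraction_id=[f_idx + 1] * dup.size,
                            engine=[engine[j] for j in dup],
                            peptide=list(peptides[alt_idx]),
                            modifications=[""] * dup.size,
                            charge=list(alt_charge),
                            precursor_mz=list(np.round(alt_mz, 4)),
                            # both candidates of a spectrum share one precursor
                            precursor_intensity=[
                                round(10.0 ** log10_i[j], 1) for j in dup
                            ],
                            score=list(np.round(alt_score, 3)),
                            accessions=list(accession_str[alt_idx]),
                        )
                # --- noise spectra -------------------------------------
                if n_noise:
                    log10_n = noise.sample_noise_log10(rng_obs, n_noise)
                    n_charge = rng_obs.choice([2, 3], size=n_noise, p=[0.6, 0.4])
                    n_len = rng_obs.integers(8, 21, n_noise)
                    n_acc = rng_obs.integers(0, len(library), n_noise)
                    all_accs = [e.accession for e in library]
                    noise_peps = []
                    for L in n_len:
                        body = rng_obs.choice(_NONCLEAVE, size=int(L))
                        noise_peps.append("".join(body))  # non-K/R terminus
                    emit(
                        spectrum_id=[
                            f"{prefix}X{j + 1:04d}" for j in range(n_noise)
                        ],
                        sample_id=[sample_id] * n_noise,
                        treatment_id=[t.treatment_id] * n_noise,
                        fraction_id=[f_idx + 1] * n_noise,
                        engine=list(rng_obs.choice(np.asarray(engines), size=n_noise)),
                        peptide=noise_peps,
                        modifications=[""] * n_noise,
                        charge=list(n_charge),
                        precursor_mz=list(np.round(rng_obs.uniform(300, 2000, n_noise), 4)),
                        precursor_intensity=list(np.round(10.0 ** log10_n, 1)),
                        score=list(np.round(rng_obs.uniform(0.5, 2.0, n_noise), 3)),
                        accessions=[all_accs[j] for j in n_acc],
                    )

    psms = pd.DataFrame(columns)
    psms["treatment_id"] = psms["treatment_id"].astype(int)
    psms["fraction_id"] = psms["fraction_id"].astype(int)
    psms["charge"] = psms["charge"].astype(int)

    truth_rows = []
    sig_per_treatment = {
        t.treatment_id: design.samples_per_treatment
        * design.fractions_per_sample
        * max(1, round(design.spectra_per_fraction * t.spectra_scale))
        * (1 - noise.noise_fraction)
        * (
            effects.ice_cold_detection_scale
            if t.condition == "ice_cold"
            else 1.0
        )
        for t in design.treatments
    }
    for eff in effects.enriched:
        t = design.treatment(eff.treatment_id)
        w_t = _symbol_weights(
            np.array(library.gene_symbols()), library.gene_symbols(), t, effects
        )
        total_w = w_t.sum()
        w_g = w_t[library.gene_symbols().index(eff.gene_symbol)]
        truth_rows.append(
            {
                "gene_symbol": eff.gene_symbol,
                "treatment_id": eff.treatment_id,
                "frequency_multiplier": eff.frequency_multiplier,
                "intensity_log10_shift": eff.intensity_log10_shift,
                "expected_count": sig_per_treatment[eff.treatment_id] * w_g / total_w,
            }
        )
    truth = TruthLog(
        effects=pd.DataFrame(
            truth_rows,
            columns=[
                "gene_symbol",
                "treatment_id",
                "frequency_multiplier",
                "intensity_log10_shift",
                "expected_count",
            ],
        ),
        seed=seed,
    )
    return psms, truth
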