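"""Reference validation studies run against the synthetic-data generator.

These functions define the fixed simulation scenarios used to characterize
the pipeline: a null cohort with a realistic total-spectra imbalance (the
frequency-correction diagnostic) and a replicated planted-effect recovery
study for the chi-square selection rule.  They are plain library code so the
test suite and the reproduction script exercise the exact same conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frequency import (
    RULE_CHI2_15,
    analyze_contrast,
    count_frequencies,
    delta_quantile_diagnostic,
    select_candidates,
)
from .ingest import accept_psms
from .simulate import (
    EffectSpec,
    PlantedEffect,
    StudyDesign,
    Treatment,
    generate_protein_library,
    simulate_cohort,
)

#: ratio of the printed whole-cohort accepted-spectra totals
#: (disease 660,251 vs control 269,371 for the unmodified pool)
DEFAULT_TOTAL_IMBALANCE = 2.45


@dataclass
class CorrectionStudy:
    """Centredness of the delta distribution with and without correction."""

    corrected_stat: float  # |mean delta| / SD after total correction
    uncorrected_stat: float  # same statistic on raw count differences
    n_symbols: int


def correction_balance_study(
    seed: int,
    *,
    n_symbols: int = 500,
    imbalance: float = DEFAULT_TOTAL_IMBALANCE,
    samples: int = 5,
    fractions: int = 10,
    spectra_per_fraction: int = 420,
) -> CorrectionStudy:
    """Null cohort, one treatment recorded ``imbalance``-fold deeper.

    With no planted effects the corrected difference distribution must pass
    through zero at its mean, while the uncorrected one is shifted by the
    sampling-depth imbalance alone.
    """
    library = generate_protein_library(n_symbols, 1, seed=seed)
    design = StudyDesign(
        treatments=(
            Treatment(1, "deep", "matched_normal", spectra_scale=imbalance),
            Treatment(2, "shallow", "matched_normal"),
        ),
        samples_per_treatment=samples,
        fractions_per_sample=fractions,
        spectra_per_fraction=spectra_per_fraction,
    )
    psms, _ = simulate_cohort(library, design, seed=seed)
    accepted = accept_psms(psms, library).accepted
    fm = count_frequencies(accepted, "TRYP", treatments=[1, 2])
    table = analyze_contrast(fm, 1, 2)
    corrected = delta_quantile_diagnostic(table["delta"]).standardized_mean
    raw_delta = (fm.counts[1] - fm.counts[2]).to_numpy(dtype=float)
    uncorrected = delta_quantile_diagnostic(raw_delta).standardized_mean
    return CorrectionStudy(
        corrected_stat=corrected,
        uncorrected_stat=uncorrected,
        n_symbols=len(table),
    )


@dataclass
class RecoveryStudy:
    """Planted-effect recovery of the (chi2 > 15, delta > 15) rule."""

    recovery_rate: float  # fraction of (planted symbol, replicate) selected
    null_selection_rate: float  # fraction of (null symbol, replicate) selected
    mean_planted_disease_count: float
    n_replicates: int
    n_planted: int


def recovery_study(
    seed: int,
    *,
    n_replicates: int = 100,
    n_symbols: int = 50,
    multiplier: float = 5.0,
    planted: tuple[str, ...] = ("GS0003", "GS0017", "GS0031"),
    samples: int = 5,
    fractions: int = 10,
    spectra_per_fraction: int = 260,
) -> RecoveryStudy:
    """Replicate cohorts with a few strongly enriched symbols.

    Every replicate regenerates the library, cohort and full acceptance +
    contrast chain from its own substream of ``seed``, then applies the
    selection rule; rates aggregate over replicates.
    """
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    hits = 0
    null_hits = 0
    null_total = 0
    planted_counts: list[float] = []
    for rep_seed in rep_seeds:
        rep_seed = int(rep_seed)
        library = generate_protein_library(n_symbols, 2, seed=rep_seed)
        design = StudyDesign(
            treatments=(
                Treatment(9, "cancer ovarian", "disease"),
                Treatment(7, "cancer control", "matched_normal"),
            ),
            samples_per_treatment=samples,
            fractions_per_sample=fractions,
            spectra_per_fraction=spectra_per_fraction,
        )
        effects = EffectSpec(
            enriched=tuple(
                PlantedEffect(g, 9, frequency_multiplier=multiplier) for g in planted
            )
        )
        psms, _ = simulate_cohort(library, design, effects, seed=rep_seed)
        accepted = accept_psms(psms, library).accepted
        table = analyze_contrast(count_frequencies(accepted, "TRYP"), 9, 7)
        selected = set(select_candidates(table, RULE_CHI2_15))
        hits += sum(g in selected for g in planted)
        nulls = set(table.index) - set(planted)
        null_hits += len(selected & nulls)
        null_total += len(nulls)
        planted_counts.extend(
            float(table.loc[g, "disease_count"]) for g in planted if g in table.index
        )
    return RecoveryStudy(
        recovery_rate=hits / (n_replicates * len(planted)),
        null_selection_rate=null_hits / null_total if null_total else 0.0,
        mean_planted_disease_count=float(np.mean(planted_counts)),
        n_replicates=n_replicates,
        n_planted=len(planted),
    )
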