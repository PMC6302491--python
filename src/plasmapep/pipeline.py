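"""End-to-end orchestration: config, stage funnel, artifact bundle.

The pipeline replaces a relational store with a flat-file data model: every
stage reads and writes TSV, and a YAML manifest echoes the configuration,
library/package versions and the row count at each filter stage, which is
sufficient to re-run a simulation identically and to audit the filter
funnel (counts are monotone non-increasing).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import run_all_genes
from .frequency import (
    RULE_CHI2_15,
    RULE_CHI2_60,
    analyze_contrast,
    average_chi2_per_symbol,
    count_frequencies,
    cumulative_protein_pvalues,
    delta_quantile_diagnostic,
    select_candidates,
)
from .ingest import (
    INTENSITY_THRESHOLD,
    annotate_psms,
    apply_intensity_threshold,
    read_psm_table,
    select_best_fit,
    write_psm_table,
)
from .library import ProteinLibrary
from .simulate import (
    EffectSpec,
    NoiseModel,
    PlantedEffect,
    StudyDesign,
    Treatment,
    generate_protein_library,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class FitRate(NamedTuple):
    percent: int  # headline figure, rounded to the nearest integer
    percent_exact: float


def report_fit_rate(total_spectra: int, fitted_spectra: int) -> FitRate:
    """Percentage of MS/MS spectra assigned to a best-fit peptide."""
    if total_spectra == 0:
        raise ValueError("fit rate is undefined for zero total spectra")
    exact = 100.0 * fitted_spectra / total_spectra
    return FitRate(percent=round(exact), percent_exact=exact)


@dataclass(frozen=True)
class Contrast:
    disease: int
    control: int
    pool: str = "TRYP"


@dataclass
class SimulateConfig:
    n_symbols: int = 50
    accessions_per_symbol: int = 2
    treatments: list[dict] = field(
        default_factory=lambda: [
            {"treatment_id": 9, "label": "disease", "condition": "disease", "pool": "TRYP"},
            {
                "treatment_id": 7,
                "label": "matched normal",
                "condition": "matched_normal",
                "pool": "TRYP",
            },
        ]
    )
    samples_per_treatment: int = 5
    fractions_per_sample: int = 10
    spectra_per_fraction: int = 140
    noise_fraction: float = 0.88
    enriched: list[dict] = field(default_factory=list)
    acute_phase: list[str] = field(default_factory=list)
    ice_cold_detection_scale: float = 0.2

    def design(self) -> StudyDesign:
        return StudyDesign(
            treatments=tuple(Treatment(**t) for t in self.treatments),
            samples_per_treatment=self.samples_per_treatment,
            fractions_per_sample=self.fractions_per_sample,
            spectra_per_fraction=self.spectra_per_fraction,
        )

    def effects(self) -> EffectSpec:
        return EffectSpec(
            enriched=tuple(PlantedEffect(**e) for e in self.enriched),
            acute_phase=tuple(self.acute_phase),
            ice_cold_detection_scale=self.ice_cold_detection_scale,
        )

    def noise(self) -> NoiseModel:
        return NoiseModel(noise_fraction=self.noise_fraction)


@dataclass
class PipelineConfig:
    """Single flat config for the whole run (YAML round-trippable)."""

    mode: str = "simulate"  # simulate | ingest
    seed: int = 0
    psm_path: str | None = None  # ingest mode inputs
    library_path: str | None = None
    contrasts: list[dict] = field(
        default_factory=lambda: [{"disease": 9, "control": 7, "pool": "TRYP"}]
    )
    intensity_threshold: float = INTENSITY_THRESHOLD
    alpha: float = 0.05
    within_engine: bool = False
    engine: str | None = None  # restrict counting to one search engine
    combine: str = "fisher"  # cumulative protein p-value strategy
    accession_level: bool = False  # also write mean chi2 per symbol over accessions
    anova_min_observations: int = 3
    one_way_letters: bool = False
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.intensity_threshold <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        if isinstance(self.simulate, dict):
            self.simulate = SimulateConfig(**self.simulate)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    manifest: dict
    out_dir: Path
    accepted: pd.DataFrame
    contrast_tables: dict[tuple[int, int, str], pd.DataFrame]


def _plot_delta_quantiles(diag, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(diag.table["quantile"], diag.table["delta"], ".", ms=3)
    ax.axhline(0.0, color="red", lw=1)
    ax.axvline(0.0, color="red", lw=1)
    ax.set_xlabel("standard normal quantile")
    ax.set_ylabel("corrected delta")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run the configured analysis and write the artifact bundle.

    Deterministic for a fixed seed in simulate mode.  Any stage failure is
    re-raised as :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "configure"
    try:
        # ---------------- input ----------------
        if config.mode == "simulate":
            stage = "simulate"
            sim = config.simulate
            library = generate_protein_library(
                sim.n_symbols, sim.accessions_per_symbol, seed=config.seed
            )
            library.to_fasta(out / "library.fasta")
            psms, truth = simulate_cohort(
                library,
                sim.design(),
                sim.effects(),
                sim.noise(),
                seed=config.seed,
            )
            write_psm_table(psms, out / "psms.tsv")
            truth.to_tsv(out / "truth.tsv")
        else:
            stage = "ingest"
            if not config.psm_path or not config.library_path:
                raise ValueError("ingest mode requires psm_path and library_path")
            library = ProteinLibrary.from_fasta(config.library_path)
            psms, read_rejects = read_psm_table(config.psm_path)
            read_rejects.to_csv(out / "read_rejects.tsv", sep="\t", index=False)
        counts["raw_candidates"] = len(psms)
        counts["raw_spectra"] = psms["spectrum_id"].nunique()

        # ---------------- acceptance funnel ----------------
        stage = "intensity_threshold"
        if config.engine is not None:
            psms = psms[psms["engine"] == config.engine]
        thresholded = apply_intensity_threshold(psms, config.intensity_threshold)
        counts["above_threshold"] = len(thresholded)

        stage = "best_fit"
        best = select_best_fit(thresholded, within_engine=config.within_engine)
        counts["best_fit"] = len(best)

        stage = "annotate"
        accepted, rejects = annotate_psms(best, library)
        counts["accepted"] = len(accepted)
        rejects.to_csv(out / "rejects.tsv", sep="\t", index=False)
        accepted.to_csv(out / "accepted_psms.tsv", sep="\t", index=False)
        fit = report_fit_rate(counts["raw_spectra"], accepted["spectrum_id"].nunique())

        # ---------------- frequency + chi-square ----------------
        stage = "frequency"
        contrast_tables: dict[tuple[int, int, str], pd.DataFrame] = {}
        selected: set[str] = set()
        treatment_ids = sorted(accepted["treatment_id"].unique()) if len(accepted) else []
        for pool in ("TRYP", "STYP"):
            fm = count_frequencies(accepted, pool, treatments=treatment_ids)
            if fm.counts.empty:
                continue
            fm.to_tsv(out / f"frequency_{pool}.tsv")
            for c in config.contrasts:
                contrast = Contrast(**c)
                if contrast.pool != pool:
                    continue
                table = analyze_contrast(fm, contrast.disease, contrast.control)
                key = (contrast.disease, contrast.control, pool)
                contrast_tables[key] = table
                tag = f"{contrast.disease}_vs_{contrast.control}_{pool}"
                table.to_csv(out / f"contrast_{tag}.tsv", sep="\t")
                diag = delta_quantile_diagnostic(table["delta"])
                diag.table.to_csv(out / f"delta_quantiles_{tag}.tsv", sep="\t", index=False)
                _plot_delta_quantiles(diag, out / f"delta_quantiles_{tag}.png")
                genes15 = select_candidates(table, RULE_CHI2_15)
                (out / f"genes_chi2_15_{tag}.txt").write_text(
                    "\n".join(genes15) + ("\n" if genes15 else "")
                )
                genes60 = select_candidates(table, RULE_CHI2_60)
                (out / f"genes_chi2_60_{tag}.txt").write_text(
                    "\n".join(genes60) + ("\n" if genes60 else "")
                )
                selected.update(genes15)
                protein_p = cumulative_protein_pvalues(
                    accepted, pool, contrast.disease, contrast.control, method=config.combine
                )
                protein_p.to_csv(out / f"protein_pvalues_{tag}.tsv", sep="\t")
                if config.accession_level:
                    avg = average_chi2_per_symbol(
                        accepted, pool, contrast.disease, contrast.control, library
                    )
                    avg.to_csv(out / f"avg_chi2_per_symbol_{tag}.tsv", sep="\t")

        # ---------------- per-gene ANOVA ----------------
        stage = "anova"
        results, skipped = run_all_genes(
            accepted,
            sorted(selected),
            min_observations=config.anova_min_observations,
            alpha=config.alpha,
            one_way_letters=config.one_way_letters,
        )
        skipped.to_csv(out / "anova_skipped.tsv", sep="\t", index=False)
        summary_rows = []
        anova_rows = []
        for gene, res in sorted(results.items()):
            s = res.summaries.copy()
            s.insert(0, "gene_symbol", gene)
            summary_rows.append(s)
            a = res.anova.reset_index()
            a.insert(0, "gene_symbol", gene)
            anova_rows.append(a)
        (
            pd.concat(summary_rows, ignore_index=True)
            if summary_rows
            else pd.DataFrame(
                columns=["gene_symbol", "treatment_id", "mean", "sd", "se", "n", "letters"]
            )
        ).to_csv(out / "anova_treatment_summaries.tsv", sep="\t", index=False)
        (
            pd.concat(anova_rows, ignore_index=True)
            if anova_rows
            else pd.DataFrame(columns=["gene_symbol", "term", "sum_sq", "df", "F", "p"])
        ).to_csv(out / "anova_tables.tsv", sep="\t", index=False)

        # ---------------- manifest ----------------
        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "versions": {
                "plasmapep": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "stage_counts": counts,
            "fit_rate_percent": fit.percent,
            "fit_rate_percent_exact": fit.percent_exact,
            "n_genes_analyzed": len(results),
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return PipelineResult(
        manifest=manifest,
        out_dir=out,
        accepted=accepted,
        contrast_tables=contrast_tables,
    )
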