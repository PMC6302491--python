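import numpy as np
import pandas as pd
import pytest

from plasmapep import (
    EffectSpec,
    PlantedEffect,
    StudyDesign,
    Treatment,
    accept_psms,
    generate_protein_library,
    simulate_cohort,
)
from plasmapep.library import ProteinLibrary, ProteinLibraryEntry


@pytest.fixture(scope="session")
def hand_library() -> ProteinLibrary:
    """Tiny handmade library with known tryptic structure.

    HP owns two accessions sharing the peptide ELVISLIVESK; C4A and C4B
    share the degenerate peptide CCCDDDEEEK.
    """
    return ProteinLibrary(
        [
            ProteinLibraryEntry("HP.1", "HP", "MKELVISLIVESKAAAGGGK"),
            ProteinLibraryEntry("HP.2", "HP", "ELVISLIVESKWWWYYYHHR"),
            ProteinLibraryEntry("C4A.1", "C4A", "MRCCCDDDEEEKFFFGGGR"),
            ProteinLibraryEntry("C4B.1", "C4B", "MKCCCDDDEEEKLLLMMMR"),
        ]
    )


@pytest.fixture(scope="session")
def demo_library() -> ProteinLibrary:
    return generate_protein_library(12, 2, seed=7)


@pytest.fixture(scope="session")
def wide_library():
    """Library wide enough that per-fraction sampling stays unsaturated."""
    return generate_protein_library(50, 2, seed=13)


@pytest.fixture(scope="session")
def demo_design() -> StudyDesign:
    return StudyDesign(
        treatments=(
            Treatment(9, "cancer ovarian", "disease", "TRYP"),
            Treatment(7, "cancer control", "matched_normal", "TRYP"),
            Treatment(10, "cancer ovarian STYP", "disease", "STYP"),
        ),
        samples_per_treatment=3,
        fractions_per_sample=5,
        spectra_per_fraction=120,
    )


@pytest.fixture(scope="session")
def demo_effects() -> EffectSpec:
    return EffectSpec(
        enriched=(PlantedEffect("GS0001", 9, 5.0, 0.5),),
        acute_phase=("GS0002",),
    )


@pytest.fixture(scope="session")
def demo_cohort(demo_library, demo_design, demo_effects):
    psms, truth = simulate_cohort(
        demo_library, demo_design, demo_effects, seed=11
    )
    return psms, truth


@pytest.fixture(scope="session")
def demo_accepted(demo_cohort, demo_library) -> pd.DataFrame:
    psms, _ = demo_cohort
    return accept_psms(psms, demo_library).accepted


def null_two_treatment_design(
    spectra_per_fraction: int = 120,
    samples: int = 3,
    fractions: int = 5,
    disease_scale: float = 1.0,
) -> StudyDesign:
    """Two-treatment null design helper (optionally total-imbalanced)."""
    return StudyDesign(
        treatments=(
            Treatment(1, "A", "matched_normal", "TRYP", spectra_scale=disease_scale),
            Treatment(2, "B", "matched_normal", "TRYP"),
        ),
        samples_per_treatment=samples,
        fractions_per_sample=fractions,
        spectra_per_fraction=spectra_per_fraction,
    )
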