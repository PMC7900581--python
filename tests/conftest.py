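"""Shared fixtures: mixtures, instruments and simulated runs built in memory."""

from __future__ import annotations

import pytest
from hypothesis import settings

from clicklipid import (
    FattyAcyl,
    InstrumentModel,
    InternalStandard,
    LipidClass,
    MixtureSpec,
    Subspecies,
    SumSpecies,
)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_sub(species_name: str, chains: str) -> Subspecies:
    sp = SumSpecies.from_name(species_name)
    fa1, fa2 = (FattyAcyl.from_name(x) for x in chains.split("_"))
    if not (sp.lipid_class.is_ether or sp.lipid_class.is_sphingo):
        fa1, fa2 = sorted((fa1, fa2))
    return Subspecies(sp, fa1, fa2)


@pytest.fixture(scope="session")
def istd() -> InternalStandard:
    """The standard spike: 240 pmol pPC 31:1 (FA 14:0 + FA 17:1)."""
    return InternalStandard(SumSpecies(LipidClass.PPC, 31, 1), 240.0,
                            (FattyAcyl(14, 0), FattyAcyl(17, 1)))


# One subspecies per species (so FA- and NL-based amounts coincide without
# chain-specific suppression); amounts follow a measured labeled-cell pool.
MIX20 = [
    ("pPC 30:0", "16:0_14:0", 19.3),
    ("pPC 30:1", "16:1_14:0", 3.1),
    ("pPC 32:0", "16:0_16:0", 80.0),
    ("pPC 32:1", "16:0_16:1", 183.6),
    ("pPC 32:2", "16:1_16:1", 7.8),
    ("pPC 34:1", "18:1_16:0", 686.1),
    ("pPC 34:2", "18:1_16:1", 55.6),
    ("pPC 34:3", "20:3_14:0", 10.9),
    ("pPC 34:4", "20:4_14:0", 25.6),
    ("pPC 36:1", "18:0_18:1", 77.7),
    ("pPC 36:2", "18:1_18:1", 109.3),
    ("pPC 36:3", "20:3_16:0", 27.0),
    ("pPC 36:4", "18:2_18:2", 60.9),   # di-PUFA
    ("pPC 36:5", "20:5_16:0", 8.5),
    ("pPC 38:2", "20:1_18:1", 12.6),
    ("pPC 38:4", "20:4_18:0", 17.4),
    ("pPC 38:5", "20:4_18:1", 18.1),
    ("pPC 38:6", "22:6_16:0", 19.9),
    ("pPC 40:6", "22:5_18:1", 11.6),
    ("pPC 40:7", "20:3_20:4", 7.4),    # di-PUFA
]


@pytest.fixture(scope="session")
def mixture20(istd: InternalStandard) -> MixtureSpec:
    comps = tuple((make_sub(sp, ch), pmol) for sp, ch, pmol in MIX20)
    return MixtureSpec(comps, internal_standards=(istd,))


@pytest.fixture(scope="session")
def candidates20(mixture20: MixtureSpec) -> list[SumSpecies]:
    return sorted({c[0].parent for c in mixture20.all_entries()},
                  key=lambda s: s.sort_key)


@pytest.fixture
def clean_instrument() -> InstrumentModel:
    """Noise-free instrument with deterministic branching."""
    return InstrumentModel()


@pytest.fixture
def noisy_instrument() -> InstrumentModel:
    """10% log-normal intensity noise, 5 ppm mass jitter, light noise floor."""
    return InstrumentModel(mass_error_ppm_sd=5.0, lognormal_sd=0.1,
                           noise_peaks_per_scan=3.0, noise_intensity_scale=20.0)
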