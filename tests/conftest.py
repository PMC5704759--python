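import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from nanouptake.dosimetry import ExposureSetup, ParticleSpecies, SizeDistribution


@pytest.fixture(scope="session")
def aunp() -> ParticleSpecies:
    """Polymer-shelled gold particle (d_c 4.7 +/- 2 nm, d_h 11 +/- 3 nm)."""
    return ParticleSpecies(
        name="AuNP",
        core_density=19.2,
        shell_density=1.0,
        core_radius=SizeDistribution.from_diameter(4.7, 2.0),
        hydrodynamic_radius=SizeDistribution.from_diameter(11.0, 3.0),
        mass_concentration=38.6,
        channel="NP1",
    )


@pytest.fixture(scope="session")
def feox() -> ParticleSpecies:
    """Polymer-shelled iron oxide particle (d_c 13.6 +/- 4 nm, d_h 28 +/- 9 nm)."""
    return ParticleSpecies(
        name="FeOx",
        core_density=5.24,
        shell_density=1.0,
        core_radius=SizeDistribution.from_diameter(13.6, 4.0),
        hydrodynamic_radius=SizeDistribution.from_diameter(28.0, 9.0),
        mass_concentration=54.8,
        channel="NP2",
    )


@pytest.fixture(scope="session")
def chamber() -> ExposureSetup:
    """Four-chamber slide well: 1.7 cm^2, 0.4 mL, 37 C aqueous medium."""
    return ExposureSetup()


def iou(a: np.ndarray, b: np.ndarray) -> float:
    return float((a & b).sum()) / float((a | b).sum())


def match_truth(mask, truth_masks):
    """Ground-truth cell with the largest footprint overlap."""
    return max(truth_masks, key=lambda t: (t.footprint & mask.footprint).sum())
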