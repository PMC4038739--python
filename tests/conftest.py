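import numpy as np
import pytest

from chromsig.data_model import ContactMatrix
from chromsig.synthetic import (
    PlantedEffect,
    SimulationDesign,
    paper_like_design,
    simulate_panel,
)


def random_contact_matrix(
    rng: np.random.Generator, n: int = 6, missing_frac: float = 0.0
) -> ContactMatrix:
    """Symmetric nonnegative matrix with an optional random unmeasured mask."""
    a = rng.uniform(0.0, 50.0, size=(n, n))
    values = 0.5 * (a + a.T)
    if missing_frac > 0:
        drop = rng.random((n, n)) < missing_frac
        drop = drop | drop.T
        values[drop] = np.nan
    return ContactMatrix.from_dense(values)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def paper_panel():
    """The default study-design panel: 20 fusion (10 AF9 + 10 ENL) vs 10 wt,
    40 fragments, planted fold-change 2.5, lognormal noise sigma 0.3."""
    panel, truths = simulate_panel(paper_like_design(seed=7))
    return panel, truths


@pytest.fixture(scope="session")
def small_separable_panel():
    """Tiny low-noise panel, normalized, that a sound classifier separates
    perfectly."""
    from chromsig.normalization import normalize_panel

    design = SimulationDesign(
        n_fragments=12,
        planted_effects=(
            PlantedEffect((3, 8), 4.0, "fusion"),
            PlantedEffect((4, 9), 4.0, "fusion"),
            PlantedEffect((2, 11), 4.0, "wt"),
        ),
        class_sizes=(("AF9", 4), ("ENL", 4), ("wt", 4)),
        noise_sigma=0.1,
        efficiency_sigma=0.1,
        seed=11,
    )
    panel, _ = simulate_panel(design)
    panel, _ = normalize_panel(panel)
    return panel, design
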