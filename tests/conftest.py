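import numpy as np
import pytest

from crossvar import (
    ArchitectureSpec,
    default_marker_map,
    simulate_genotypes,
    simulate_phenotypes,
)
from crossvar.kinship import build_kinship_set


@pytest.fixture(scope="session")
def small_map():
    return default_marker_map(n_markers=300, n_chromosomes=8)


@pytest.fixture(scope="session")
def small_panel(small_map):
    """300 markers x 200 segregants; shared read-only panel."""
    return simulate_genotypes(small_map, 200, seed=11)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    spec = ArchitectureSpec(
        n_additive_qtl=8,
        n_interactions=4,
        h2_additive=0.40,
        H2_total=0.55,
        strain_var=0.10,
        n_replicates=2,
        seed=7,
    )
    return simulate_phenotypes(small_panel, spec)


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    return build_kinship_set(small_panel)


@pytest.fixture(scope="session")
def medium_panel():
    """1,000 segregants on a compact 8-chromosome genome (800 markers)."""
    mmap = default_marker_map(n_markers=800, n_chromosomes=8)
    return simulate_genotypes(mmap, 1000, seed=23)


@pytest.fixture(scope="session")
def medium_kinship(medium_panel):
    return build_kinship_set(medium_panel)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
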