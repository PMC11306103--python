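import numpy as np
import pandas as pd
import pytest

from cropscreen import synth


@pytest.fixture(scope="session")
def small_library():
    spec = synth.LibrarySpec(n_genes=4, guides_per_gene=3, n_controls=5, t0_batches=2, seed=7)
    return synth.make_library(spec)


@pytest.fixture(scope="session")
def default_library():
    """The default 500-guide screen library: 150 genes x 3 guides + 50 controls."""
    return synth.make_library(synth.LibrarySpec(seed=11))


@pytest.fixture(scope="session")
def whitelists():
    """Three 97-entry section whitelists with min pairwise Hamming distance 3."""
    return synth.make_whitelists(seed=5)


@pytest.fixture(scope="session")
def null_expression():
    """A null expression matrix: 6 perturbed genes + controls, no planted effects."""
    spec = synth.LibrarySpec(n_genes=6, guides_per_gene=3, n_controls=6, seed=3)
    lib = synth.make_library(spec)
    truth = synth.PlantedTruth.null(lib, modules=["m1"])
    assignments = synth.simulate_screen(lib, truth, 900, 1, seed=4)
    modules = {"m1": [f"mg{i}" for i in range(1, 11)]}
    adata = synth.simulate_expression(assignments, modules, truth, n_genes_total=150, seed=5)
    return lib, adata, modules


def control_perturbations(labels: pd.Series) -> list[str]:
    return sorted({p for p in labels if str(p).startswith("ctrl_")})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
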