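import numpy as np
import pytest

import finspec as fs


@pytest.fixture(scope="session")
def fluor_mode():
    return fs.ModeSpec.default("Fluor")


@pytest.fixture(scope="session")
def tiny_cfg():
    """Six species in two confusable clusters, Fluor only; small and fast."""
    return fs.GeneratorConfig(
        n_species=6, cluster_sizes=(3, 3), fillets_per_species=4, voxels_per_fillet=8, seed=11
    )


@pytest.fixture(scope="session")
def tiny_library(tiny_cfg, fluor_mode):
    return fs.generate_species_library(tiny_cfg, {"Fluor": fluor_mode})


@pytest.fixture(scope="session")
def tiny_dataset(tiny_library, tiny_cfg):
    return fs.generate_point_spectra(tiny_library, tiny_cfg)


@pytest.fixture(scope="session")
def separable_dataset(fluor_mode):
    """Well-separated 6-species dataset where near-perfect recall is attainable."""
    cfg = fs.GeneratorConfig(
        n_species=6, cluster_sizes=(3, 3), fillets_per_species=4, voxels_per_fillet=8,
        within_cluster_sep=1.0, between_cluster_sep=1.4, seed=5,
    )
    lib = fs.generate_species_library(cfg, {"Fluor": fluor_mode})
    return fs.generate_point_spectra(lib, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def quick_global_spec(seed=0, epochs=50):
    return fs.GlobalModelSpec(epochs=epochs, patience=12, seed=seed)


def quick_dispute_spec(seed=0, epochs=50):
    return fs.DisputeModelSpec(epochs=epochs, patience=12, seed=seed)
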