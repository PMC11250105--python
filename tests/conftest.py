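import numpy as np
import pytest

from isletpheno.perifusion import build_feature_table
from isletpheno.simulate import GeneratorConfig, simulate_cohort


def small_config(**overrides) -> GeneratorConfig:
    """A reduced-scale cohort that keeps every planted structure."""
    base = dict(
        n_nd=30, n_t2d=8, n_proteins=300, n_genes=450, n_modules=3,
        module_size_range=(25, 45), n_de_protein_up=20, n_de_protein_down=20,
        n_de_rna_up=25, n_de_rna_down=25, n_markers_per_type=4,
        module_trait_coupling={0: ("auc_fat", 0.6), 1: ("auc_glucose15", 0.5)},
        seed=7,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def noise_free_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_nd=3, n_t2d=2, pi_fat=0.0, pi_leu=0.0, assay_cv=0.0, n_tech_reps=1,
        capacity_cv=0.0, response_cv=0.0, seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def cohort_small():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def features_small(cohort_small):
    return build_feature_table(cohort_small.traces, cohort_small.protocols)


@pytest.fixture(scope="session")
def cohort_noise_free():
    return simulate_cohort(noise_free_config(), omics=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
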