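import numpy as np
import pytest

import svpredict as sv


@pytest.fixture(scope="session")
def small_pop() -> sv.SimulatedPopulation:
    """A modest structured panel with all six marker classes and planted
    SV-SNP linkage, shared across tests that only read it."""
    cfg = sv.PopulationConfig(
        n_per_group={"IND": 60, "JAP": 45, "AUS": 30, "ARO": 15, "ADM": 15},
        marker_counts={"SNP": 300, "MITE-DTX": 60, "RLX-RIX": 40,
                       "DEL": 90, "DUP": 40, "INV": 20},
        linked_pairs=[("DEL", 1.0, 6), ("MITE-DTX", 0.9, 4)],
        seed=77,
    )
    return sv.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_trait(small_pop):
    """Quantitative trait on the shared panel, with ground truth."""
    spec = sv.TraitSpec(
        h2=0.6,
        class_variance_shares={"SNP": 0.4, "MITE-DTX": 0.2, "DEL": 0.3, "DUP": 0.1},
        n_causal_per_class={"SNP": 25, "MITE-DTX": 15, "DEL": 20, "DUP": 10},
        seed=78,
    )
    return sv.simulate_phenotypes(small_pop.genotypes, spec, groups=small_pop.groups)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def hwe_snp_panel(n: int, m: int, seed: int = 0) -> sv.GenotypeMatrix:
    """Unstructured SNP-only panel in Hardy-Weinberg proportions."""
    cfg = sv.PopulationConfig(
        n_per_group={"IND": n, "JAP": 0, "AUS": 0, "ARO": 0, "ADM": 0},
        fst=0.0, marker_counts={"SNP": m}, linked_pairs=[], seed=seed,
    )
    return sv.simulate_population(cfg).genotypes
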