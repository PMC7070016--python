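import numpy as np
import pytest

from httscan.pipeline import PipelineConfig, run_pipeline
from httscan.simulate import (
    HTTEventConfig,
    SimulationConfig,
    SuperfamilyConfig,
    simulate_dataset,
)

#: A small asymmetric ultrametric tree used across tree-level tests.
SMALL_NEWICK = "((A:10,B:10):30,C:40);"

#: Three deep lineages (F vs T: 150 My; each vs V: 450 My), so a TE carried
#: from V into both F and T leaves an indirect F-T hit group.
THREE_SIDE_NEWICK = (
    "(((F1:15,F2:15,F3:15):135,(T1:15,T2:15,T3:15):135):300,"
    "(V1:15,V2:15,V3:15):435);"
)


def indirect_config(seed: int, n_core_genes: int = 100) -> "SimulationConfig":
    """Two direct transfers out of the V lineage whose recipient cohorts
    also resemble each other, creating one indirect F-T hit group."""
    return SimulationConfig(
        newick=THREE_SIDE_NEWICK,
        seed=seed,
        n_core_genes=n_core_genes,
        superfamilies=[SuperfamilyConfig("Tc1_Mariner", "DNA_transposon",
                                         1.0)],
        htt_events=[
            HTTEventConfig("eF", "V1", "F1", 18, "Tc1_Mariner"),
            HTTEventConfig("eT", "V1", "T1", 15, "Tc1_Mariner"),
        ],
    )


def two_event_config(seed: int, n_core_genes: int = 120) -> SimulationConfig:
    """Default-tree dataset with one DNA-transposon and one retrotransposon
    transfer between the two deep sides."""
    return SimulationConfig(
        seed=seed,
        n_core_genes=n_core_genes,
        htt_events=[
            HTTEventConfig("e1", "T1", "F1", 22, "Tc1_Mariner"),
            HTTEventConfig("e2", "T4", "F4", 18, "LINE1"),
        ],
    )


def recovery_config(K: int, seed: int,
                    n_core_genes: int = 100) -> SimulationConfig:
    """K well-separated transfers, one superfamily each, alternating TE
    classes, donors/recipients cycling over the four young clades."""
    recips = ["F1", "F4", "T1", "T4"]
    donors = ["T1", "T4", "F1", "F4"]
    sfs, evs = [], []
    for k in range(K):
        te_class = "DNA_transposon" if k % 2 == 0 else "retrotransposon"
        omega = 1.0 if k % 2 == 0 else 0.2
        sfs.append(SuperfamilyConfig(f"SF{k}", te_class, omega))
        evs.append(HTTEventConfig(f"e{k}", donors[k % 4], recips[k % 4],
                                  16.0 + (k * 7) % 9, f"SF{k}"))
    return SimulationConfig(seed=seed, n_core_genes=n_core_genes,
                            superfamilies=sfs, htt_events=evs)


@pytest.fixture(scope="session")
def two_event_dataset():
    return simulate_dataset(two_event_config(seed=42))


@pytest.fixture(scope="session")
def two_event_result(two_event_dataset):
    return run_pipeline(two_event_dataset, PipelineConfig(),
                        run_permutations=False, run_selection=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
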