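import numpy as np
import pandas as pd
import pytest

from cometddi import classify as cls
from cometddi import qc
from cometddi import synthetic as syn


@pytest.fixture(scope="session")
def sim_config():
    return syn.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def training_set(sim_config):
    mat, labels = syn.generate_training_set(sim_config)
    return cls.TrainingSet(mat, labels)


@pytest.fixture(scope="session")
def ddi_truth():
    return syn.GroundTruth("DDIX", True, true_bmc_tgx=10.0,
                           true_bmc_comet=12.0, viability_ec50=160.0)


@pytest.fixture(scope="session")
def ddi_experiment(ddi_truth, sim_config):
    return syn.generate_test_experiment(ddi_truth, sim_config)


@pytest.fixture(scope="session")
def ddi_gene_level(ddi_experiment, training_set):
    norm = qc.normalize_counts(ddi_experiment.counts)
    return cls.collapse_probes(norm.log2_shifted,
                               ddi_experiment.probe_gene_map,
                               required_genes=pd.Index(training_set.genes))


def toy_training(seed=0, n_genes=6, n_per_class=4, effect=2.0, sd=0.3):
    """Small random training set with a clear class separation."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    compounds = [f"d{i}" for i in range(n_per_class)] + \
                [f"n{i}" for i in range(n_per_class)]
    labels = pd.Series(["DDI"] * n_per_class + ["non-DDI"] * n_per_class,
                       index=compounds)
    signs = np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0)
    mean = np.zeros((n_genes, 2 * n_per_class))
    mean[:, :n_per_class] = (signs * effect)[:, None]
    mat = pd.DataFrame(mean + rng.normal(0, sd, mean.shape),
                       index=genes, columns=compounds)
    return cls.TrainingSet(mat, labels)
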