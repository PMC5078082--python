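import numpy as np
import pandas as pd
import pytest

from egwaskit.synth import CompendiumConfig, ExpressionExperiment, generate_compendium


def build_experiment(values, n_cases, genes=None, experiment_id="T01"):
    """Experiment from a (genes x samples) array; the first n_cases columns
    are cases."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    labels = pd.Series(
        ["case"] * n_cases + ["control"] * (n_samples - n_cases),
        index=samples,
    )
    return ExpressionExperiment(experiment_id, matrix, labels)


@pytest.fixture(scope="session")
def small_config():
    return CompendiumConfig(
        n_genes=300,
        n_experiments=3,
        cases_per_experiment=(6, 6, 6),
        controls_per_experiment=(8, 8, 8),
        n_true=8,
        effect_size=2.0,
        activity_prob=0.9,
        coverage_fraction=0.9,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_compendium(small_config):
    return generate_compendium(small_config)


@pytest.fixture(scope="session")
def strong_experiment():
    """One experiment with a large, fully active planted signal."""
    cfg = CompendiumConfig(
        n_genes=400,
        n_experiments=1,
        cases_per_experiment=(20,),
        controls_per_experiment=(20,),
        n_true=15,
        effect_size=2.5,
        activity_prob=1.0,
        coverage_fraction=1.0,
        seed=11,
    )
    experiments, truth = generate_compendium(cfg)
    return experiments[0], truth
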