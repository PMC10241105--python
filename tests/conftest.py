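import numpy as np
import pandas as pd
import pytest

from mirgrn import GeneratorConfig, generate_experiment
from mirgrn.io_formats import CountMatrix, SampleMetadata


@pytest.fixture(scope="session")
def experiment():
    """A moderately sized synthetic experiment shared across tests."""
    cfg = GeneratorConfig(n_mirna=80, n_gene=2000, n_true_targets=50, seed=2)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def experiment_files(experiment, tmp_path_factory):
    from mirgrn import write_experiment

    outdir = tmp_path_factory.mktemp("expdata")
    return write_experiment(experiment, outdir)


def two_group_counts(
    rng: np.random.Generator,
    n_features: int,
    n_per_group: int = 4,
    mean: float = 1000.0,
    phi: float = 0.1,
    log2fc=0.0,
) -> tuple[CountMatrix, SampleMetadata]:
    """NB counts for a simple two-time-point design (helper, not a fixture)."""
    log2fc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_features,))
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (n_features,))
    mu_a = mean
    mu_b = mean * 2.0 ** log2fc
    r = 1.0 / phi
    draw = lambda mu: rng.negative_binomial(
        r, r / (r + mu[:, None]), size=(n_features, n_per_group)
    )
    counts = np.hstack([draw(mu_a), draw(mu_b)])
    samples = [f"T0_r{i+1}" for i in range(n_per_group)] + [
        f"T1_r{i+1}" for i in range(n_per_group)
    ]
    cm = CountMatrix(
        pd.DataFrame(counts, index=[f"f{i:04d}" for i in range(n_features)], columns=samples)
    )
    md = SampleMetadata(
        time_point={s: s.split("_")[0] for s in samples}, time_points_order=["T0", "T1"]
    )
    return cm, md
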