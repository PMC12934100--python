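import numpy as np
import pandas as pd
import pytest

from dormsig import SimulationConfig, default_signature


@pytest.fixture(scope="session")
def sig():
    return default_signature()


@pytest.fixture()
def default_cohort():
    """One default synthetic cohort (11 dormant + 11 proliferative)."""
    from dormsig import simulate_expression

    cfg = SimulationConfig(seed=42)
    matrix, labels = simulate_expression(cfg)
    return cfg, matrix, labels


def make_z(data: dict[str, list[float]], samples=None) -> pd.DataFrame:
    """Small z-score-like matrix builder: gene -> per-sample values."""
    df = pd.DataFrame.from_dict(data, orient="index").astype(float)
    if samples is not None:
        df.columns = samples
    df.index.name = "gene_id"
    return df


@pytest.fixture(scope="session")
def pairwise_auc():
    """Brute-force AUC oracle: concordant-pair count with half credit for ties."""

    def _oracle(pos, neg):
        pos, neg = np.asarray(pos, float), np.asarray(neg, float)
        wins = sum(float(p > n) + 0.5 * float(p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    return _oracle
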