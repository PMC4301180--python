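import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coldcourse import ExpressionDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(group_means: dict[float, np.ndarray], noise_sd: float = 0.0,
                 n_replicates: int = 3, seed: int = 0) -> ExpressionDataset:
    """Build a dataset with prescribed per-gene linear group means plus
    multiplicative (log2-normal) noise."""
    rng = np.random.default_rng(seed)
    tps = sorted(group_means)
    n_genes = len(next(iter(group_means.values())))
    cols, data, rows = [], [], []
    for t in tps:
        for r in range(1, n_replicates + 1):
            cols.append(f"t{t:g}h_r{r}")
            rows.append((f"t{t:g}h_r{r}", float(t), r))
            noise = rng.normal(0, noise_sd, n_genes) if noise_sd else 0.0
            data.append(np.asarray(group_means[t], float) * np.exp2(noise))
    matrix = pd.DataFrame(
        np.column_stack(data), columns=cols,
        index=[f"g{i:04d}" for i in range(n_genes)],
    )
    design = pd.DataFrame(rows, columns=["sample_id", "time_point_h", "replicate"]).set_index("sample_id")
    return ExpressionDataset(matrix=matrix, design=design)


@pytest.fixture
def five_point_dataset():
    """50 null genes plus one gene strongly induced at 8 h and 24 h only."""
    rng = np.random.default_rng(42)
    n = 51
    base = np.full(n, 256.0)
    means = {t: base.copy() for t in (0.0, 1.0, 3.0, 8.0, 24.0)}
    for t in (8.0, 24.0):
        means[t][0] = base[0] * 2 ** 5  # +5 log2 planted effect
    return make_dataset(means, noise_sd=0.05, seed=1)
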