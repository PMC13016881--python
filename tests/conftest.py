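import numpy as np
import pytest

from wingfa.io import GenotypeSample


def anova_oracle(y):
    """Brute-force sums-of-squares decomposition with explicit loops.

    Independent of the package's vectorized path: every marginal and cell
    mean is formed by direct averaging and squared deviations are
    accumulated stratum by stratum.
    """
    y = np.asarray(y, dtype=float)
    n, s, r = y.shape
    grand = y.sum() / y.size
    ind_means = [y[i].sum() / (s * r) for i in range(n)]
    side_means = [y[:, j].sum() / (n * r) for j in range(s)]
    cell_means = [[y[i, j].sum() / r for j in range(s)] for i in range(n)]

    ss_ind = sum(s * r * (ind_means[i] - grand) ** 2 for i in range(n))
    ss_side = sum(n * r * (side_means[j] - grand) ** 2 for j in range(s))
    ss_int = 0.0
    ss_res = 0.0
    for i in range(n):
        for j in range(s):
            ss_int += r * (cell_means[i][j] - ind_means[i] - side_means[j] + grand) ** 2
            for k in range(r):
                ss_res += (y[i, j, k] - cell_means[i][j]) ** 2
    ss_total = sum((y[i, j, k] - grand) ** 2
                   for i in range(n) for j in range(s) for k in range(r))
    return {
        "ms_side": ss_side / (s - 1),
        "ms_individual": ss_ind / (n - 1),
        "ms_interaction": ss_int / ((n - 1) * (s - 1)),
        "ms_residual": ss_res / (n * s * (r - 1)),
        "ss_total": ss_total,
    }


def make_sample(values, genotype="g", series="S1", ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"i{k + 1}" for k in range(values.shape[0])]
    return GenotypeSample(genotype, series, ids, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
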