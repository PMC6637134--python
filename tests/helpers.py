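"""Shared independent reference implementations used as test oracles."""

import math

import numpy as np


def reference_description_length(model, sigma_min=0.1, mu_zero=False):
    """Literal plain-Python re-evaluation of the MDL criterion."""
    N = len(model.labels)
    K = model.K
    ln2 = math.log(2)
    L_which = N * math.log2(K + 1) / ln2
    L_out = model.n_outliers * math.log2(model.bbox_area) / ln2
    prod = 1.0
    for Ni in model.cluster_sizes:
        prod *= Ni
    L_model = 3.0 / (2 * ln2) * math.log2(prod)
    L_res = 0.0
    for i in range(K):
        rs = [model.residuals[j] for j in range(N) if model.labels[j] == i]
        Ni = len(rs)
        for ax in range(2):
            vals = [r[ax] for r in rs]
            mu = 0.0 if mu_zero else sum(vals) / Ni
            var = sum((v - mu) ** 2 for v in vals) / Ni
            sd = max(math.sqrt(var), sigma_min)
            L_res += Ni / 2 * math.log(2 * math.pi * sd * sd)
            L_res += sum((v - mu) ** 2 for v in vals) / (2 * sd * sd)
    return L_which + L_out + L_model + L_res


def random_piecewise_series(rng, n_max=20, k_max=3, sd=1.0):
    """A short Gaussian series with 1..k_max true segments."""
    n = int(rng.integers(6, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False)) if k > 1 else []
    lengths = np.diff([0, *cuts, n])
    means = rng.normal(0, 3, k)
    return np.repeat(means, lengths) + rng.normal(0, sd, n)
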