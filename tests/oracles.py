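"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's matrix code paths: correlations come
from scipy.stats.pearsonr pair by pair, jackknife loops are explicit, and
the Fisher Z test is recomputed from its closed form with math functions.
"""

import itertools
import math

from scipy import stats


def brute_pearson_p(x, y):
    res = stats.pearsonr(x, y)
    return res.statistic, res.pvalue


def brute_reliable_edges(values, alpha):
    """All-iterations leave-one-out reliability, pair by pair.

    Returns {(i, j): sign} for i < j surviving p < alpha with a consistent
    r sign in every one of the n leave-one-out subsamples.
    """
    n, p = values.shape
    out = {}
    for i, j in itertools.combinations(range(p), 2):
        signs = set()
        ok = True
        for drop in range(n):
            keep = [k for k in range(n) if k != drop]
            r, pval = brute_pearson_p(values[keep, i], values[keep, j])
            if not pval < alpha:
                ok = False
                break
            signs.add(1 if r > 0 else -1)
        if ok and len(signs) == 1:
            r_full, _ = brute_pearson_p(values[:, i], values[:, j])
            out[(i, j)] = 1 if r_full > 0 else -1
    return out


def brute_fisher_z(r1, r2, n1, n2):
    num = math.atanh(r1) - math.atanh(r2)
    return num / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))


def brute_fisher_p(z):
    return 2.0 * (1.0 - stats.norm.cdf(abs(z)))


def brute_reliable_differences(values1, values2, alpha):
    """Explicit 2n-loop double jackknife, pair by pair.

    Returns {(i, j): sign of full-sample Z} for differences with p < alpha
    and consistent Z sign in all n1 + n2 drop-one iterations.
    """
    n1, p = values1.shape
    n2 = values2.shape[0]
    subsets = [([k for k in range(n1) if k != d], list(range(n2)))
               for d in range(n1)]
    subsets += [(list(range(n1)), [k for k in range(n2) if k != d])
                for d in range(n2)]
    out = {}
    for i, j in itertools.combinations(range(p), 2):
        signs = set()
        ok = True
        for keep1, keep2 in subsets:
            r1, _ = brute_pearson_p(values1[keep1, i], values1[keep1, j])
            r2, _ = brute_pearson_p(values2[keep2, i], values2[keep2, j])
            z = brute_fisher_z(r1, r2, len(keep1), len(keep2))
            if not brute_fisher_p(z) < alpha:
                ok = False
                break
            signs.add(1 if z > 0 else -1)
        if ok and len(signs) == 1:
            r1, _ = brute_pearson_p(values1[:, i], values1[:, j])
            r2, _ = brute_pearson_p(values2[:, i], values2[:, j])
            zf = brute_fisher_z(r1, r2, n1, n2)
            out[(i, j)] = 1 if zf > 0 else -1
    return out


def brute_permutation_p(x, y, n_perm=2000, seed=0):
    """Permutation p-value for Pearson r, as a cross-check of the t-based p."""
    import numpy as np
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(stats.pearsonr(x, y).statistic)
    hits = 0
    for _ in range(n_perm):
        r = abs(stats.pearsonr(x, rng.permutation(y)).statistic)
        hits += r >= r_obs
    return (hits + 1) / (n_perm + 1)
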