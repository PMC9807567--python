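"""Shared fixtures and independent oracle implementations.

The oracles here (normal-equations OLS, definitional two-way ANOVA ICC,
full-enumeration rank tests, residual-regression partial correlation) are
deliberately written from first principles and never call into the package
paths they are used to check.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from enhv import (
    GeneratorConfig,
    generate_dai_cohort,
    generate_healthy_cohort,
    published_model,
    subjects_to_frame,
)


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def published():
    return published_model()


@pytest.fixture(scope="session")
def healthy_frame(config):
    """A default-condition healthy cohort (n=182) as a DataFrame."""
    return subjects_to_frame(generate_healthy_cohort(config, n=182, seed=11))


@pytest.fixture(scope="session")
def holdout_frame(config):
    """A disjoint healthy validation cohort (n=47)."""
    return subjects_to_frame(generate_healthy_cohort(config, n=47, seed=12))


@pytest.fixture(scope="session")
def dai_frame(config):
    """A default-condition DAI cohort (n=22)."""
    return subjects_to_frame(generate_dai_cohort(config, n=22, seed=13))


# ---------------------------------------------------------------------------
# oracles


def ols_normal_equations(y, *predictors):
    """Closed-form OLS (predictors..., intercept) via the normal equations."""
    X = np.column_stack(list(predictors) + [np.ones(len(y))])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


def icc_a1_bruteforce(x, y):
    """ICC(A,1) from definitional sums of squares of the n×2 layout."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    msr = k * sum((data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def mannwhitney_exact_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    n_a = len(a)

    def u_of(idx):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for x in grp for y in rest if x > y) + \
            0.5 * sum(1 for x in grp for y in rest if x == y)

    u_obs = u_of(tuple(range(n_a)))
    us = [u_of(idx) for idx in combinations(range(len(pooled)), n_a)]
    n_tot = len(us)
    # two-sided: double the smaller tail (matching the exact distribution
    # convention), capped at 1
    lo = sum(1 for u in us if u <= u_obs) / n_tot
    hi = sum(1 for u in us if u >= u_obs) / n_tot
    return min(1.0, 2 * min(lo, hi))


def wilcoxon_exact_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=n)]
    n_tot = len(ws)
    lo = sum(1 for w in ws if w <= w_obs) / n_tot
    hi = sum(1 for w in ws if w >= w_obs) / n_tot
    return min(1.0, 2 * min(lo, hi))


def partial_corr_residuals(x, y, z):
    """Partial correlation as the Pearson r of OLS residuals on z."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    Z = np.column_stack([z, np.ones(len(z))])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
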