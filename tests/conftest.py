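"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain per-pair Python loops — the slow,
obviously-correct formulation — so they stay independent of the matrix
code paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from gbskinship.grm import AlleleFrequencies, ScoreMatrix


def g4_oracle(X, D, p):
    """Per-pair loop: relatedness using only SNPs called in both."""
    X = np.asarray(X, dtype=float)
    D = np.asarray(D)
    p = np.asarray(p, dtype=float)
    n = X.shape[0]
    G = np.full((n, n), np.nan)
    for i in range(n):
        for i2 in range(n):
            both = (D[i] > 0) & (D[i2] > 0)
            if not both.any():
                continue
            num = 0.0
            den = 0.0
            for j in np.flatnonzero(both):
                num += (X[i, j] - 2 * p[j]) * (X[i2, j] - 2 * p[j])
                den += 2 * p[j] * (1 - p[j])
            G[i, i2] = num / den
    return G


def g5_diag_oracle(X, D, p):
    """Per-individual loop: depth-corrected self-relatedness."""
    X = np.asarray(X, dtype=float)
    D = np.asarray(D)
    p = np.asarray(p, dtype=float)
    n = X.shape[0]
    diag = np.full(n, np.nan)
    for i in range(n):
        num = 0.0
        den = 0.0
        any_used = False
        for j in range(X.shape[1]):
            if D[i, j] < 2:
                continue
            any_used = True
            K = 0.5 ** min(int(D[i, j]), 64)
            s = (X[i, j] - 2 * p[j]) ** 2
            num += (s - 8 * p[j] * (1 - p[j]) * K) / (1 - 2 * K)
            den += 2 * p[j] * (1 - p[j])
        if any_used:
            diag[i] = num / den
    return diag


def jackknife_se(values, units_a, units_b):
    """Delete-one-unit jackknife SE of a mean over (possibly dependent)
    pair values; ``units_a``/``units_b`` give each value's two unit labels.

    Accounts for the correlation between pairs sharing an individual,
    which a naive sd/sqrt(n_pairs) ignores.
    """
    values = np.asarray(values, dtype=float)
    units_a = np.asarray(units_a)
    units_b = np.asarray(units_b)
    units = np.unique(np.concatenate([units_a, units_b]))
    means = []
    for u in units:
        keep = (units_a != u) & (units_b != u)
        if keep.any():
            means.append(values[keep].mean())
    means = np.asarray(means)
    n = len(means)
    return float(np.sqrt((n - 1) / n * ((means - means.mean()) ** 2).sum()))


def random_panel(rng, n=8, m=30, missing=0.3, max_depth=10):
    """Random ScoreMatrix + frequencies with arbitrary missingness."""
    p = rng.uniform(0.05, 0.95, m)
    D = rng.integers(1, max_depth + 1, size=(n, m))
    D[rng.random((n, m)) < missing] = 0
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    X[D == 0] = np.nan
    scores = ScoreMatrix(
        X=X,
        D=D,
        individual_ids=[f"i{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
    )
    return scores, AlleleFrequencies(p=p, source="external")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_counts():
    """2 individuals x 2 SNPs: the wide-format reference fixture."""
    ref = np.array([[2, 0], [1, 1]])
    alt = np.array([[0, 3], [1, 0]])
    return ref, alt
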