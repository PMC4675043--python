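"""Single-SNP probability model and method-of-moments relatedness estimators.

This is the mathematical kernel of the package.  Everything here is a pure
function of scalars or numpy arrays (elementwise, broadcasting allowed) with
no file I/O and no state.

Model
-----
A biallelic SNP has alleles A (reference) and B.  A genotype observed from
``k`` error-free sequence reads drawn at random from the individual's two
alleles misreports a true heterozygote as a given homozygote with
probability ``K = 1/2**k``; true homozygotes are always observed correctly.
Depth ``k = 0`` means the genotype is missing.

The observed genotype score ``x`` counts reference alleles in the observed
genotype (2 = only A seen, 1 = both seen, 0 = only B seen).  Relatedness
estimators are built from the centred cross-products
``S = (x_i - 2p)(x_i' - 2p)`` whose expectations have closed forms in the
allele frequency ``p``, the inbreeding coefficient ``F``, the coancestry
``theta`` and the depth factor ``K``.  Crucially, ``E(S)`` for a *pair* of
individuals does not depend on depth, while the *self* term does and can be
corrected exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MAX_K_DEPTH",
    "depth_to_K",
    "call_genotype",
    "observed_genotype_probs",
    "pair_S",
    "single_snp_relatedness",
    "adjusted_self_S",
    "single_snp_inbreeding",
    "expected_S",
]

#: Depths are capped here before computing 1/2**k; beyond this the depth
#: factor is exactly 0.0 in float64 anyway, so there is no behavioural
#: difference — the cap only avoids integer-overflow surprises.
MAX_K_DEPTH = 64


def _is_scalar(*xs) -> bool:
    return all(np.ndim(x) == 0 for x in xs)


def _check_prob_open(p, name: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(f"{name} must be strictly inside (0, 1)")
    return p


def _check_range(x, lo: float, hi: float, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < lo) | (x > hi)):
        raise ValueError(f"{name} must be in [{lo}, {hi}]")
    return x


def depth_to_K(k):
    """Depth factor ``K = 1/2**k`` for read depth ``k``.

    ``K`` is the probability that a true heterozygote is observed as one
    given homozygote.  At ``k = 1``, ``K = 1/2``; as ``k`` grows, ``K -> 0``
    and the observed genotype is the true genotype.  ``k = 0`` carries no
    genotype at all, so ``K`` is undefined there and NaN is returned.

    Parameters
    ----------
    k : int or integer array
        Read depth(s), ``>= 0``.

    Returns
    -------
    float or ndarray
        ``1/2**k`` (NaN where ``k == 0``).
    """
    arr = np.asarray(k)
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("read depth must be numeric")
    if np.issubdtype(arr.dtype, np.floating):
        if np.any(arr != np.floor(arr)):
            raise ValueError("read depth must be integer-valued")
    elif not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("read depth must be integer-valued")
    if np.any(arr < 0):
        raise ValueError("read depth must be non-negative")
    kk = np.minimum(arr.astype(np.int64), MAX_K_DEPTH)
    K = np.where(kk == 0, np.nan, np.ldexp(1.0, -kk))
    return float(K) if _is_scalar(k) else K


def call_genotype(ref_reads, alt_reads):
    """Call observed genotype scores from reference/alternate read counts.

    Reads are assumed error-free: seeing both alleles means heterozygote,
    seeing one allele only means (observed) homozygote.

    Returns
    -------
    (x, k)
        ``x`` — score (2, 1, 0; NaN where depth is zero), ``k`` — total
        read depth ``ref + alt``.
    """
    ref = np.asarray(ref_reads)
    alt = np.asarray(alt_reads)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    k = ref + alt
    x = np.full(np.broadcast(ref, alt).shape, np.nan)
    x = np.where((ref > 0) & (alt == 0), 2.0, x)
    x = np.where((ref > 0) & (alt > 0), 1.0, x)
    x = np.where((ref == 0) & (alt > 0), 0.0, x)
    if _is_scalar(ref_reads, alt_reads):
        return float(x), int(k)
    return x, k


def observed_genotype_probs(p, F=0.0, K=0.0):
    """Probabilities of the three *observed* genotypes AA*, AB*, BB*.

    For an individual with inbreeding ``F`` at a SNP with reference-allele
    frequency ``p``, observed through the depth factor ``K``::

        P(AA*) = p^2 + p(1-p)F + 2p(1-p)(1-F)K
        P(AB*) = 2p(1-p)(1-F)(1-2K)
        P(BB*) = (1-p)^2 + p(1-p)F + 2p(1-p)(1-F)K

    The three always sum to one.
    """
    scalar = _is_scalar(p, F, K)
    p = _check_prob_open(p)
    F = _check_range(F, 0.0, 1.0, "F")
    K = _check_range(K, 0.0, 0.5, "K")
    pq = p * (1.0 - p)
    p_aa = p * p + pq * F + 2.0 * pq * (1.0 - F) * K
    p_ab = 2.0 * pq * (1.0 - F) * (1.0 - 2.0 * K)
    p_bb = (1.0 - p) ** 2 + pq * F + 2.0 * pq * (1.0 - F) * K
    if scalar:
        return float(p_aa), float(p_ab), float(p_bb)
    return p_aa, p_ab, p_bb


def pair_S(x_i, x_i2, p):
    """Centred score cross-product ``S = (x_i - 2p)(x_i' - 2p)``.

    Symmetric in the two scores; NaN scores propagate to NaN.
    """
    scalar = _is_scalar(x_i, x_i2, p)
    p = _check_prob_open(p)
    s = (np.asarray(x_i, dtype=float) - 2.0 * p) * (
        np.asarray(x_i2, dtype=float) - 2.0 * p
    )
    return float(s) if scalar else s


def single_snp_relatedness(x_i, x_i2, p):
    """Moment estimator of relatedness ``2*theta`` from one SNP.

    ``S / (2p(1-p))`` — unbiased for the pair relatedness at any read
    depth, because ``E(S)`` for distinct individuals does not involve
    the depth factor.
    """
    scalar = _is_scalar(x_i, x_i2, p)
    p = _check_prob_open(p)
    est = pair_S(x_i, x_i2, p) / (2.0 * p * (1.0 - p))
    return float(est) if scalar else est


def adjusted_self_S(S_ii, p, K):
    """Depth-corrected self term ``(S_ii - 8p(1-p)K) / (1 - 2K)``.

    Its expectation is ``2p(1-p)(1+F)`` for every admissible ``K < 1/2``
    (an algebraic identity).  ``K = 1/2`` (depth 1) carries no
    self-relatedness information and is rejected.
    """
    scalar = _is_scalar(S_ii, p, K)
    p = _check_prob_open(p)
    K = _check_range(K, 0.0, 0.5, "K")
    if np.any(K == 0.5):
        raise ValueError(
            "K = 1/2 (depth 1): self term carries no inbreeding information; "
            "exclude this SNP"
        )
    pq = p * (1.0 - p)
    adj = (np.asarray(S_ii, dtype=float) - 8.0 * pq * K) / (1.0 - 2.0 * K)
    return float(adj) if scalar else adj


def single_snp_inbreeding(S_ii, p, K):
    """Moment estimator of the inbreeding coefficient from one SNP.

    ``F_hat = (S_ii - 2p(1-p)(1+2K)) / (2p(1-p)(1-2K))``.  Single-SNP
    values are returned unclipped and routinely fall outside [0, 1];
    only averages over many SNPs are interpretable.
    """
    scalar = _is_scalar(S_ii, p, K)
    p = _check_prob_open(p)
    K = _check_range(K, 0.0, 0.5, "K")
    if np.any(K == 0.5):
        raise ValueError("K = 1/2 (depth 1): E(S_ii) does not depend on F")
    pq = p * (1.0 - p)
    f = (np.asarray(S_ii, dtype=float) - 2.0 * pq * (1.0 + 2.0 * K)) / (
        2.0 * pq * (1.0 - 2.0 * K)
    )
    return float(f) if scalar else f


def expected_S(p, F=0.0, theta=0.0, K=0.0, mode="self"):
    """Closed-form expectation of ``S`` — the test oracle.

    ``mode='self'``:  ``2p(1-p)(1 + F + 2K - 2FK)`` — depends on depth
    through ``K`` unless ``F = 1``.
    ``mode='pair'``:  ``4p(1-p)*theta`` — independent of depth.
    """
    scalar = _is_scalar(p, F, theta, K)
    p = _check_prob_open(p)
    pq = p * (1.0 - p)
    if mode == "self":
        F = _check_range(F, 0.0, 1.0, "F")
        K = _check_range(K, 0.0, 0.5, "K")
        val = 2.0 * pq * (1.0 + F + 2.0 * K - 2.0 * F * K)
    elif mode == "pair":
        val = 4.0 * pq * np.asarray(theta, dtype=float)
    else:
        raise ValueError("mode must be 'self' or 'pair'")
    return float(val) if scalar else val
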