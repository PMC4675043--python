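"""Whole-panel relatedness matrix construction from score/depth matrices.

Four estimators are provided, named by the method labels used throughout
the package:

- ``G1``  — centred scores with missing values zeroed and a single pooled
  denominator ``2*sum_j p_j(1-p_j)``; biased at low depth.
- ``G4``  — same numerator but a per-pair denominator built from only the
  SNPs called in *both* individuals (pairwise-complete).
- ``G5``  — ``G4`` with the diagonal replaced by a depth-corrected
  estimate of self-relatedness ``1 + F``; the fully corrected estimator.
- ``G3``  — one read sampled per cell (depth collapsed to 1), combined
  with the per-pair denominator; its diagonal is uninformative.

Off-diagonal entries estimate the relatedness ``2*theta`` of the pair;
valid diagonal entries estimate ``1 + F``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MAX_K_DEPTH

__all__ = [
    "ScoreMatrix",
    "AlleleFrequencies",
    "RelatednessMatrix",
    "estimate_allele_frequencies",
    "center_scores",
    "compute_G1",
    "compute_G4",
    "adjust_diagonal",
    "compute_G3",
    "summarize_grm",
]


@dataclass
class ScoreMatrix:
    """Observed genotype scores and read depths, individuals x SNPs.

    ``X`` holds scores 0/1/2 as floats with NaN exactly where the depth
    matrix ``D`` is zero (a missing genotype).
    """

    X: np.ndarray = field(repr=False)
    D: np.ndarray = field(repr=False)
    individual_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.D = np.asarray(self.D)
        if self.X.shape != self.D.shape:
            raise ValueError("score and depth matrices must have the same shape")
        if self.X.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError("id labels do not match matrix dimensions")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if np.any(np.isnan(self.X) != (self.D == 0)):
            raise ValueError("scores must be missing exactly where depth is zero")

    @classmethod
    def from_counts(cls, ref, alt, individual_ids=None, snp_ids=None) -> "ScoreMatrix":
        """Call genotypes from aligned reference/alternate count matrices."""
        from .core import call_genotype

        ref = np.asarray(ref)
        alt = np.asarray(alt)
        if ref.shape != alt.shape:
            raise ValueError("ref and alt count matrices must have the same shape")
        x, k = call_genotype(ref, alt)
        n, m = ref.shape
        if individual_ids is None:
            individual_ids = [f"ind{i}" for i in range(n)]
        if snp_ids is None:
            snp_ids = [f"snp{j}" for j in range(m)]
        return cls(X=x, D=k, individual_ids=list(individual_ids), snp_ids=list(snp_ids))

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    @property
    def called(self) -> np.ndarray:
        return self.D > 0

    def mean_sample_depth(self) -> np.ndarray:
        """Mean read depth per individual over all SNPs (zeros included)."""
        return np.asarray(self.D, dtype=float).mean(axis=1)

    def select_snps(self, index) -> "ScoreMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ScoreMatrix(
            X=self.X[:, idx],
            D=self.D[:, idx],
            individual_ids=list(self.individual_ids),
            snp_ids=[self.snp_ids[j] for j in idx],
        )


@dataclass
class AlleleFrequencies:
    """Per-SNP reference allele frequencies plus provenance."""

    p: np.ndarray
    source: str  # read_counts | genotype_calls | external
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)

    @property
    def polymorphic(self) -> np.ndarray:
        """Mask of SNPs usable in estimation (frequency strictly in (0,1))."""
        with np.errstate(invalid="ignore"):
            return (self.p > 0.0) & (self.p < 1.0)

    def require_polymorphic(self) -> None:
        if not np.all(self.polymorphic):
            bad = int((~self.polymorphic).sum())
            raise ValueError(
                f"{bad} SNP(s) are monomorphic or unobserved; drop them first "
                "(see AlleleFrequencies.polymorphic)"
            )

    def select(self, index) -> "AlleleFrequencies":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ids = None if self.snp_ids is None else [self.snp_ids[j] for j in idx]
        return AlleleFrequencies(p=self.p[idx], source=self.source, snp_ids=ids)


@dataclass
class RelatednessMatrix:
    """Symmetric individuals x individuals relatedness estimate."""

    G: np.ndarray = field(repr=False)
    method: str
    individual_ids: list[str]
    diagonal_valid: bool = True
    n_snps_used: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.individual_ids)
        if self.G.shape != (n, n):
            raise ValueError("relatedness matrix shape does not match ids")

    def index_of(self, ind_id: str) -> int:
        try:
            return self.individual_ids.index(ind_id)
        except ValueError:
            raise KeyError(f"individual {ind_id!r} not in matrix") from None

    def eigen_report(self) -> dict:
        """Smallest/largest eigenvalue and negative count.

        No positive-semi-definiteness repair is attempted; this report lets
        users judge invertibility for downstream mixed-model use.
        """
        g = np.array(self.G, copy=True)
        g[np.isnan(g)] = 0.0
        vals = np.linalg.eigvalsh((g + g.T) / 2.0)
        return {
            "min_eigenvalue": float(vals[0]),
            "max_eigenvalue": float(vals[-1]),
            "n_negative": int((vals < 0).sum()),
        }


def estimate_allele_frequencies(ref, alt, snp_ids=None) -> AlleleFrequencies:
    """Estimate per-SNP reference allele frequencies from total read counts.

    ``p_j = sum_i ref_ij / sum_i (ref_ij + alt_ij)`` — every read counts
    equally, regardless of which individual it came from.  SNPs with no
    reads at all get NaN; monomorphic SNPs get 0 or 1.  Both are excluded
    by the ``polymorphic`` mask of the result.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    if ref.shape != alt.shape:
        raise ValueError("ref and alt count matrices must have the same shape")
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    tot = ref.sum(axis=0) + alt.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, ref.sum(axis=0) / np.where(tot > 0, tot, 1.0), np.nan)
    return AlleleFrequencies(p=p, source="read_counts", snp_ids=snp_ids)


def center_scores(scores: ScoreMatrix, freqs: AlleleFrequencies) -> np.ndarray:
    """Centred score matrix Z: ``x - 2p`` where called, 0 where missing.

    Zeroing missing cells makes un-called SNPs contribute nothing to the
    cross-product numerator of any pair involving that individual.
    """
    if len(freqs.p) != scores.n_snps:
        raise ValueError("allele frequencies not aligned with SNP columns")
    z = scores.X - 2.0 * freqs.p[np.newaxis, :]
    z[~scores.called] = 0.0
    return z


def _pooled_denominator(p: np.ndarray) -> float:
    return 2.0 * float(np.sum(p * (1.0 - p)))


def compute_G1(scores: ScoreMatrix, freqs: AlleleFrequencies) -> RelatednessMatrix:
    """Pooled-denominator relatedness matrix ``Z Z' / (2 sum_j p_j(1-p_j))``.

    The classic chip-data construction.  With complete, high-depth calls it
    is fine; with low-depth GBS data its off-diagonals are biased toward 0
    and its diagonal is inflated — kept here as the comparison baseline.
    """
    freqs.require_polymorphic()
    if scores.n_snps < 1:
        raise ValueError("need at least one polymorphic SNP")
    denom = _pooled_denominator(freqs.p)
    if denom == 0.0:
        raise ValueError("zero denominator: all SNPs monomorphic")
    z = center_scores(scores, freqs)
    g = (z @ z.T) / denom
    return RelatednessMatrix(
        G=g,
        method="G1",
        individual_ids=list(scores.individual_ids),
        diagonal_valid=True,
    )


def _pairwise_complete(
    z: np.ndarray,
    called: np.ndarray,
    p: np.ndarray,
    snp_block: int | None,
):
    """Numerator, per-pair denominator and co-call counts for G3/G4.

    The denominator is ``2 * P0 P1'`` where row i of P0 (P1) holds
    ``p_j`` (``1-p_j``) zeroed at individual i's missing cells — so cell
    (i, i') sums ``2 p_j (1-p_j)`` over exactly the SNPs called in both.
    ``snp_block`` switches to a SNP-chunked accumulation with identical
    results but bounded memory.
    """
    calledf = called.astype(float)
    if snp_block is None:
        num = z @ z.T
        p0 = calledf * p[np.newaxis, :]
        p1 = calledf * (1.0 - p)[np.newaxis, :]
        denom = 2.0 * (p0 @ p1.T)
    else:
        n = z.shape[0]
        num = np.zeros((n, n))
        denom = np.zeros((n, n))
        for j0 in range(0, z.shape[1], snp_block):
            sl = slice(j0, j0 + snp_block)
            zc = z[:, sl]
            cc = calledf[:, sl]
            num += zc @ zc.T
            denom += 2.0 * ((cc * p[sl]) @ (cc * (1.0 - p[sl])).T)
    n_co = calledf @ calledf.T
    return num, denom, n_co.astype(np.int64)


def compute_G4(
    scores: ScoreMatrix,
    freqs: AlleleFrequencies,
    snp_block: int | None = None,
) -> RelatednessMatrix:
    """Pairwise-complete relatedness matrix: each cell uses only the SNPs
    called in both of its individuals.

    Off-diagonals are unbiased for ``2*theta`` at any depth.  The diagonal
    is *not* depth-corrected (see :func:`adjust_diagonal`) and is flagged
    invalid.  Pairs with zero co-called SNPs become NaN with a warning.
    """
    freqs.require_polymorphic()
    z = center_scores(scores, freqs)
    num, denom, n_co = _pairwise_complete(z, scores.called, freqs.p, snp_block)
    empty = denom == 0.0
    if np.any(empty):
        n_empty = int(empty.sum() - np.trace(empty)) // 2
        if n_empty:
            warnings.warn(
                f"{n_empty} pair(s) share no called SNP; cells set to NaN",
                stacklevel=2,
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(empty, np.nan, num / np.where(empty, 1.0, denom))
    return RelatednessMatrix(
        G=g,
        method="G4",
        individual_ids=list(scores.individual_ids),
        diagonal_valid=False,
        n_snps_used=n_co,
    )


def adjust_diagonal(
    g4: RelatednessMatrix,
    scores: ScoreMatrix,
    freqs: AlleleFrequencies,
    denominator: str = "matched",
) -> RelatednessMatrix:
    """Replace the diagonal with the depth-corrected self-relatedness (G5).

    For individual i the diagonal becomes::

        sum_j (S_iij - 8 p_j(1-p_j) K_ij) / (1 - 2 K_ij)
        -------------------------------------------------
                  2 sum_j p_j (1 - p_j)

    with both sums over the SNPs called in i with depth >= 2 (where
    ``K < 1/2``); depth-1 observations carry no information about
    inbreeding (the correction term's denominator vanishes at ``K = 1/2``).
    Individuals with no depth->=2 SNP get a NaN diagonal.

    ``denominator='all'`` sums ``2 p_j(1-p_j)`` over every SNP instead of
    the numerator-matched set (exposed for comparison; 'matched' is the
    default and the consistent choice with the per-pair construction).

    Off-diagonal cells are copied from ``g4`` unchanged.
    """
    if denominator not in ("matched", "all"):
        raise ValueError("denominator must be 'matched' or 'all'")
    freqs.require_polymorphic()
    p = freqs.p
    pq = p * (1.0 - p)
    D = np.asarray(scores.D)
    use = D >= 2  # K < 1/2
    kk = np.minimum(np.where(use, D, 2).astype(np.int64), MAX_K_DEPTH)
    K = np.ldexp(1.0, -kk)
    z = scores.X - 2.0 * p[np.newaxis, :]
    s_ii = np.where(use, z * z, 0.0)
    term = np.where(use, (s_ii - 8.0 * pq * K) / (1.0 - 2.0 * K), 0.0)
    num = term.sum(axis=1)
    if denominator == "matched":
        den = 2.0 * (use * pq[np.newaxis, :]).sum(axis=1)
    else:
        den = np.full(scores.n_individuals, _pooled_denominator(p))
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.nan)
    g = np.array(g4.G, copy=True)
    np.fill_diagonal(g, diag)
    n_used = None
    if g4.n_snps_used is not None:
        n_used = np.array(g4.n_snps_used, copy=True)
        np.fill_diagonal(n_used, use.sum(axis=1))
    return RelatednessMatrix(
        G=g,
        method="G5",
        individual_ids=list(g4.individual_ids),
        diagonal_valid=True,
        n_snps_used=n_used,
    )


def compute_G3(
    ref,
    alt,
    freqs: AlleleFrequencies,
    seed,
    individual_ids=None,
    snp_ids=None,
) -> RelatednessMatrix:
    """Single-sampled-read relatedness matrix.

    For every cell with at least one read, one read is drawn at random
    (reference with probability ``ref/(ref+alt)``), giving a score of 2 or
    0 — exactly the depth-1, ``K = 1/2`` model.  The scores are combined
    with the pairwise-complete denominator of ``G4``.  Robust to read
    depth modelling but noisier than ``G5``; the diagonal carries no
    self-relatedness information and is flagged invalid.
    """
    freqs.require_polymorphic()
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = np.where(k > 0, ref / np.where(k > 0, k, 1), 0.0)
    sampled_ref = rng.random(ref.shape) < p_ref
    x = np.where(k > 0, np.where(sampled_ref, 2.0, 0.0), np.nan)
    scores = ScoreMatrix(
        X=x,
        D=(k > 0).astype(np.int64),
        individual_ids=(
            list(individual_ids)
            if individual_ids is not None
            else [f"ind{i}" for i in range(ref.shape[0])]
        ),
        snp_ids=(
            list(snp_ids)
            if snp_ids is not None
            else [f"snp{j}" for j in range(ref.shape[1])]
        ),
    )
    g = compute_G4(scores, freqs)
    return RelatednessMatrix(
        G=g.G,
        method="G3",
        individual_ids=g.individual_ids,
        diagonal_valid=False,
        n_snps_used=g.n_snps_used,
    )


def summarize_grm(
    rel: RelatednessMatrix,
    groups: dict[str, list[tuple[str, str]]],
) -> pd.DataFrame:
    """Mean/sd of relatedness estimates over designated pair groups.

    ``groups`` maps a group name to (id, id) pairs; self pairs read the
    diagonal.  NaN cells are skipped and counted in ``n_missing``.  Empty
    groups are omitted with a warning.
    """
    idx = {ind: i for i, ind in enumerate(rel.individual_ids)}
    rows = []
    for name, pairs in groups.items():
        if not pairs:
            warnings.warn(f"group {name!r} is empty; omitted", stacklevel=2)
            continue
        ii = np.array([idx[a] for a, _ in pairs])
        jj = np.array([idx[b] for _, b in pairs])
        vals = rel.G[ii, jj]
        ok = ~np.isnan(vals)
        vals = vals[ok]
        rows.append(
            {
                "group": name,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n_pairs": int(vals.size),
                "n_missing": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "mean", "sd", "n_pairs", "n_missing"])
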