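"""Per-SNP / per-sample QC statistics, the fin plot, SNP filters and
pedigree-based parentage verification.

The central diagnostic is Hardy-Weinberg disequilibrium: the observed
frequency of the reference-allele homozygote minus its expected value
under random mating, computed from genotype calls.  Plotted against MAF
it is bounded above by ``MAF - MAF^2`` (maximal homozygosity) and below
by ``-MAF^2`` (maximal heterozygosity) — the "fin" shape.  SNPs hugging
the lower boundary at high depth typically come from collapsed genome
duplications and should be filtered before relatedness estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grm import RelatednessMatrix, ScoreMatrix
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "FilterSpec",
    "DepthSlope",
    "hw_disequilibrium",
    "snp_diagnostics",
    "fin_plot_data",
    "plot_fin",
    "apply_filters",
    "self_relatedness_depth_check",
    "verify_parentage",
    "sample_and_cocall_rates",
]


@dataclass(frozen=True)
class FilterSpec:
    """Conjunctive SNP filter thresholds; ``None`` disables a criterion.

    Defaults keep everything except SNPs with Hardy-Weinberg
    disequilibrium below -0.05 (excess heterozygosity).
    """

    hw_dis_min: float | None = -0.05
    maf_max: float | None = None
    maf_min: float | None = None
    call_rate_min: float | None = None

    def __post_init__(self) -> None:
        if self.hw_dis_min is not None and not -0.25 <= self.hw_dis_min <= 0.25:
            raise ValueError("hw_dis_min outside the statistic's range [-0.25, 0.25]")
        for name in ("maf_max", "maf_min"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")
        if self.call_rate_min is not None and not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")


def hw_disequilibrium(scores, fold: bool = False):
    """Hardy-Weinberg disequilibrium of one SNP from called genotypes.

    ``obs - p_hat**2`` where ``obs`` is the observed frequency of the
    reference-allele homozygote among called individuals and ``p_hat``
    the call-based reference allele frequency.  With ``fold=True`` the
    major-allele homozygote is used instead when the reference allele is
    the minor one.  Returns NaN when nothing is called.

    Accepts a 1-D vector (one SNP) or a 2-D individuals x SNPs matrix
    (returns one value per SNP).
    """
    x = np.asarray(scores, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, np.newaxis]
    called = ~np.isnan(x)
    n_called = called.sum(axis=0)
    n_aa = np.nansum(x == 2, axis=0)
    n_ab = np.nansum(x == 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(n_called > 0, n_called, 1)
        p_hat = (2.0 * n_aa + n_ab) / (2.0 * safe)
        obs = n_aa / safe
        if fold:
            n_bb = n_called - n_aa - n_ab
            obs = np.where(p_hat <= 0.5, n_bb / safe, obs)
            p_hat = np.where(p_hat <= 0.5, 1.0 - p_hat, p_hat)
        dis = np.where(n_called > 0, obs - p_hat**2, np.nan)
    return float(dis[0]) if one_d else dis


def snp_diagnostics(scores: ScoreMatrix, fold: bool = False) -> pd.DataFrame:
    """Per-SNP QC table: call rate, MAF, mean depth, HW disequilibrium.

    MAF is computed from genotype calls (not read counts) so that the
    fin-plot boundaries hold exactly.
    """
    X, D = scores.X, np.asarray(scores.D, dtype=float)
    called = scores.called
    n = scores.n_individuals
    n_called = called.sum(axis=0)
    n_aa = np.nansum(X == 2, axis=0)
    n_ab = np.nansum(X == 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(n_called > 0, n_called, 1)
        p_hat = (2.0 * n_aa + n_ab) / (2.0 * safe)
        p_hat = np.where(n_called > 0, p_hat, np.nan)
    maf = np.minimum(p_hat, 1.0 - p_hat)
    return pd.DataFrame(
        {
            "snp_id": scores.snp_ids,
            "call_rate": n_called / n,
            "maf": maf,
            "mean_depth": D.mean(axis=0),
            "hw_dis": hw_disequilibrium(X, fold=fold),
        }
    )


def fin_plot_data(scores: ScoreMatrix, fold: bool = False) -> pd.DataFrame:
    """Fin-plot coordinates: diagnostics plus the two boundary curves.

    Adds ``upper = maf - maf^2`` and ``lower = -maf^2``; every SNP's
    ``hw_dis`` lies inside [lower, upper].
    """
    tab = snp_diagnostics(scores, fold=fold)
    tab["upper"] = tab["maf"] - tab["maf"] ** 2
    tab["lower"] = -(tab["maf"] ** 2)
    return tab


def plot_fin(data: pd.DataFrame, path: str, title: str | None = None) -> None:
    """Render a fin plot to ``path`` (PNG/SVG by extension).

    Points are shaded from grey (low SNP mean depth) to blue (high),
    with the analytic boundaries drawn as black curves.
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.colors import LinearSegmentedColormap
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6.5, 5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    cmap = LinearSegmentedColormap.from_list("depth", ["#b0b0b0", "#0040c0"])
    depth = data["mean_depth"].to_numpy(dtype=float)
    shade = np.log1p(depth)
    sc = ax.scatter(
        data["maf"], data["hw_dis"], c=shade, cmap=cmap, s=6, alpha=0.6, lw=0
    )
    grid = np.linspace(0.0, 0.5, 200)
    ax.plot(grid, grid - grid**2, "k-", lw=1)
    ax.plot(grid, -(grid**2), "k-", lw=1)
    ax.set_xlabel("MAF")
    ax.set_ylabel("Hardy-Weinberg disequilibrium")
    if title:
        ax.set_title(title)
    cb = fig.colorbar(sc, ax=ax)
    cb.set_label("log(1 + mean depth)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


#: Report attribution order: a removed SNP is charged to the first
#: criterion it fails.  The kept set itself is order-invariant.
FILTER_ORDER = ("call_rate", "maf_min", "maf_max", "hw_dis")


def apply_filters(diag: pd.DataFrame, spec: FilterSpec):
    """Apply conjunctive SNP filters to a diagnostics table.

    A SNP is kept iff it passes every enabled criterion; ``maf_max``
    removes SNPs with ``maf >= maf_max`` and ``hw_dis_min`` removes SNPs
    with ``hw_dis < hw_dis_min``.  NaN statistics fail the corresponding
    enabled criterion.

    Returns
    -------
    (kept_ids, report)
        ``kept_ids`` — list of surviving snp_ids; ``report`` — DataFrame
        of per-criterion removal counts (first-failing attribution).
    """
    fails: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore"):
        if spec.call_rate_min is not None:
            fails["call_rate"] = ~(
                diag["call_rate"].to_numpy() >= spec.call_rate_min
            )
        if spec.maf_min is not None:
            fails["maf_min"] = ~(diag["maf"].to_numpy() >= spec.maf_min)
        if spec.maf_max is not None:
            fails["maf_max"] = ~(diag["maf"].to_numpy() < spec.maf_max)
        if spec.hw_dis_min is not None:
            fails["hw_dis"] = ~(diag["hw_dis"].to_numpy() >= spec.hw_dis_min)

    n = len(diag)
    keep = np.ones(n, dtype=bool)
    attributed = np.zeros(n, dtype=bool)
    rows = []
    for crit in FILTER_ORDER:
        if crit not in fails:
            continue
        bad = fails[crit]
        keep &= ~bad
        first_fail = bad & ~attributed
        attributed |= bad
        rows.append({"criterion": crit, "n_removed": int(first_fail.sum())})
    rows.append({"criterion": "kept", "n_removed": int(keep.sum())})
    if not keep.any():
        raise ValueError("all SNPs removed by the requested filters")
    kept_ids = [diag["snp_id"].iloc[j] for j in np.flatnonzero(keep)]
    return kept_ids, pd.DataFrame(rows)


@dataclass(frozen=True)
class DepthSlope:
    """Least-squares fit of self-relatedness on log mean sample depth."""

    slope: float
    correlation: float
    stderr: float
    pvalue: float
    n: int


def self_relatedness_depth_check(
    rel: RelatednessMatrix, sample_mean_depths
) -> DepthSlope:
    """Regress the matrix diagonal on log(mean sample depth).

    Under a correctly specified depth model the diagonal is independent
    of how deeply a sample was sequenced, so slope and correlation should
    sit within their null sampling band.  A positive slope is the
    signature of non-Mendelian (e.g. duplicated-region) SNPs.
    """
    if not rel.diagonal_valid:
        raise ValueError(f"diagonal of a {rel.method} matrix is not interpretable")
    depths = np.asarray(sample_mean_depths, dtype=float)
    diag = np.diag(rel.G)
    if depths.shape != diag.shape:
        raise ValueError("one mean depth per individual required")
    ok = ~np.isnan(diag) & (depths > 0)
    x = np.log(depths[ok])
    y = diag[ok]
    if np.ptp(x) == 0.0:
        return DepthSlope(0.0, np.nan, np.nan, np.nan, int(ok.sum()))
    fit = stats.linregress(x, y)
    return DepthSlope(
        slope=float(fit.slope),
        correlation=float(fit.rvalue),
        stderr=float(fit.stderr),
        pvalue=float(fit.pvalue),
        n=int(ok.sum()),
    )


def verify_parentage(
    rel: RelatednessMatrix, ped: Pedigree, threshold: float = 0.25
) -> pd.DataFrame:
    """Flag recorded offspring whose estimated relatedness with a recorded
    parent falls below ``threshold``.

    Parents absent from the matrix are skipped with a warning (their
    check contributes nothing).  Returns one row per offspring with the
    per-parent estimates and a ``flagged`` column.
    """
    ids = set(rel.individual_ids)
    rows = []
    for r in ped.offspring().itertuples():
        if r.id not in ids:
            continue
        i = rel.index_of(r.id)
        vals = {}
        for role, parent in (("sire", r.sire), ("dam", r.dam)):
            if parent == UNKNOWN:
                vals[role] = np.nan
            elif parent not in ids:
                warnings.warn(
                    f"{role} {parent!r} of {r.id!r} absent from matrix; "
                    "check skipped",
                    stacklevel=2,
                )
                vals[role] = np.nan
            else:
                vals[role] = rel.G[i, rel.index_of(parent)]
        checked = [v for v in vals.values() if not np.isnan(v)]
        rows.append(
            {
                "offspring": r.id,
                "sire": r.sire,
                "dam": r.dam,
                "sire_relatedness": vals["sire"],
                "dam_relatedness": vals["dam"],
                "flagged": bool(checked) and any(v < threshold for v in checked),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "offspring",
            "sire",
            "dam",
            "sire_relatedness",
            "dam_relatedness",
            "flagged",
        ],
    )


def sample_and_cocall_rates(depths) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample call rates and the pairwise co-call matrix.

    Call rate: proportion of SNPs with depth >= 1 for the individual.
    Co-call rate: proportion of SNPs called in both individuals.  The
    co-call matrix is symmetric with the call rates on its diagonal.
    """
    D = np.asarray(depths)
    called = (D >= 1).astype(float)
    m = D.shape[1]
    call = called.mean(axis=1)
    cocall = (called @ called.T) / m
    return call, cocall
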