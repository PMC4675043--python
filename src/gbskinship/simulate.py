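"""Pedigreed genotype and GBS read-count simulator, plus the three
standard simulation experiments used to benchmark the estimators.

Design: families of two unrelated parents with two full-sib offspring
each; unlinked biallelic SNPs; per-cell read depth Poisson with mean
``d``; reads drawn with replacement from the individual's two alleles.

One global seed is split (via ``numpy.random.SeedSequence.spawn``) into
independent per-stage streams — allele frequencies, genotypes, reads —
so a stage can be re-run in isolation and experiments are bit-reproducible
for a given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import (
    RelatednessMatrix,
    ScoreMatrix,
    adjust_diagonal,
    compute_G1,
    compute_G3,
    compute_G4,
    estimate_allele_frequencies,
    summarize_grm,
)
from .grm import AlleleFrequencies
from .pedigree import Pedigree, relationship_groups

__all__ = [
    "SimConfig",
    "SimResult",
    "make_pedigree",
    "simulate_genotypes",
    "simulate_gbs",
    "drop_monomorphic",
    "run_design",
    "compute_all_methods",
    "experiment_method_comparison",
    "experiment_fixed_effort",
    "experiment_freq_grid",
]

FREQ_MODELS = ("uniform01", "uniform_0.1_0.5")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated GBS panel.

    ``freq_model`` is ``'uniform01'``, ``'uniform_0.1_0.5'`` or a float
    (all SNPs share that frequency).  If ``total_effort`` (number of SNPs
    times mean depth) is given it must match ``n_snps * mean_depth``.
    """

    n_families: int = 100
    n_snps: int = 10_000
    freq_model: str | float = "uniform01"
    mean_depth: float = 2.0
    total_effort: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_snps < 1:
            raise ValueError("n_families and n_snps must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if isinstance(self.freq_model, str) and self.freq_model not in FREQ_MODELS:
            raise ValueError(f"unknown freq_model {self.freq_model!r}")
        if self.total_effort is not None:
            if abs(self.n_snps * self.mean_depth - self.total_effort) > 1e-9:
                raise ValueError(
                    "total_effort must equal n_snps * mean_depth "
                    f"({self.n_snps} * {self.mean_depth} != {self.total_effort})"
                )

    @classmethod
    def from_effort(
        cls, total_effort: float, mean_depth: float, **kwargs
    ) -> "SimConfig":
        """Fixed-effort config: n_snps = round(total_effort / mean_depth).

        Non-integer SNP counts are rounded to the nearest integer; the
        realized effort (``n_snps * mean_depth``) is what gets recorded.
        """
        n_snps = int(round(total_effort / mean_depth))
        return cls(
            n_snps=n_snps,
            mean_depth=mean_depth,
            total_effort=n_snps * mean_depth,
            **kwargs,
        )


@dataclass
class SimResult:
    """A simulated panel: truth plus observed GBS counts.

    Matrices are already restricted to the SNPs kept after the
    monomorphic-SNP drop; ``kept`` holds their indices in the original
    simulation and ``true_freqs`` the frequencies the panel was drawn
    from.  ``duplicated`` marks planted non-Mendelian SNPs, if any.
    """

    config: SimConfig
    pedigree: Pedigree
    genotypes: np.ndarray = field(repr=False)  # true allele dosages 0/1/2
    ref: np.ndarray = field(repr=False)
    alt: np.ndarray = field(repr=False)
    true_freqs: np.ndarray = field(repr=False)
    kept: np.ndarray = field(repr=False)
    n_dropped: int = 0
    duplicated: np.ndarray | None = field(default=None, repr=False)

    def scores(self) -> ScoreMatrix:
        return ScoreMatrix.from_counts(
            self.ref,
            self.alt,
            individual_ids=self.pedigree.ids,
            snp_ids=[f"snp{j}" for j in self.kept],
        )

    def estimated_freqs(self) -> AlleleFrequencies:
        return estimate_allele_frequencies(self.ref, self.alt)

    def parent_rows(self) -> np.ndarray:
        ids = self.pedigree.ids
        parents = set(self.pedigree.parents())
        return np.array([i for i, ind in enumerate(ids) if ind in parents])


def make_pedigree(n_families: int) -> Pedigree:
    """Default design: ``n_families`` sire-dam pairs of unrelated parents,
    each with exactly two full-sib offspring.  Parents come first."""
    rows = []
    width = len(str(n_families))
    for f in range(1, n_families + 1):
        rows.append({"id": f"S{f:0{width}d}", "sire": "", "dam": ""})
        rows.append({"id": f"D{f:0{width}d}", "sire": "", "dam": ""})
    for f in range(1, n_families + 1):
        for c in "ab":
            rows.append(
                {
                    "id": f"O{f:0{width}d}{c}",
                    "sire": f"S{f:0{width}d}",
                    "dam": f"D{f:0{width}d}",
                }
            )
    return Pedigree(pd.DataFrame(rows))


def _draw_freqs(model, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(model, str):
        if model == "uniform01":
            return rng.uniform(0.0, 1.0, n_snps)
        if model == "uniform_0.1_0.5":
            return rng.uniform(0.1, 0.5, n_snps)
        raise ValueError(f"unknown freq_model {model!r}")
    p = float(model)
    if not 0.0 < p < 1.0:
        raise ValueError("fixed allele frequency must be in (0, 1)")
    return np.full(n_snps, p)


def simulate_genotypes(
    pedigree: Pedigree, freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Simulate true allele dosages (number of reference alleles).

    Founders get two i.i.d. Bernoulli(p) alleles per SNP; offspring
    receive one allele from each parent, chosen uniformly and
    independently per SNP (unlinked loci).  With dosage g, the
    transmitted allele is reference with probability g/2.
    """
    tab = pedigree.table
    ids = list(tab["id"])
    pos = {ind: i for i, ind in enumerate(ids)}
    n, m = len(ids), len(freqs)
    geno = np.zeros((n, m), dtype=np.int8)
    founder = (tab["sire"] == "") & (tab["dam"] == "")
    f_idx = np.flatnonzero(founder.to_numpy())
    geno[f_idx] = rng.binomial(2, freqs, size=(len(f_idx), m))
    for i in np.flatnonzero(~founder.to_numpy()):
        sire, dam = tab.at[i, "sire"], tab.at[i, "dam"]
        if sire not in pos or dam not in pos:
            raise ValueError(f"offspring {ids[i]!r} has out-of-panel parents")
        a1 = rng.random(m) < geno[pos[sire]] / 2.0
        a2 = rng.random(m) < geno[pos[dam]] / 2.0
        geno[i] = a1.astype(np.int8) + a2.astype(np.int8)
    return geno


def simulate_gbs(
    genotypes: np.ndarray, mean_depth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate GBS read counts from true dosages.

    Per-cell depth is Poisson(``mean_depth``); each read independently
    copies one of the individual's two alleles (so a true heterozygote's
    reference-read count is Binomial(k, 1/2) and homozygotes always read
    their own allele).  ``mean_depth`` may be a scalar or a per-individual
    vector (one Poisson mean per row).
    """
    geno = np.asarray(genotypes)
    d = np.asarray(mean_depth, dtype=float)
    if np.any(d <= 0):
        raise ValueError("mean depth must be positive")
    if d.ndim == 1:
        d = d[:, np.newaxis]
    k = rng.poisson(np.broadcast_to(d, geno.shape))
    ref = rng.binomial(k, geno / 2.0)
    return ref.astype(np.int32), (k - ref).astype(np.int32)


def drop_monomorphic(genotypes, ref, alt) -> np.ndarray:
    """Indices of SNPs polymorphic in BOTH the true genotypes and the reads.

    A SNP whose minor allele was never drawn into the panel, or never
    sequenced, contributes nothing and would break frequency estimation.
    """
    geno = np.asarray(genotypes)
    tot = geno.sum(axis=0)
    poly_geno = (tot > 0) & (tot < 2 * geno.shape[0])
    r = np.asarray(ref).sum(axis=0)
    a = np.asarray(alt).sum(axis=0)
    poly_reads = (r > 0) & (a > 0)
    keep = np.flatnonzero(poly_geno & poly_reads)
    if keep.size == 0:
        raise ValueError("all SNPs are monomorphic in genotypes or reads")
    return keep


def run_design(
    config: SimConfig,
    per_individual_depth: np.ndarray | None = None,
    n_duplicated: int = 0,
    duplicate_depth_factor: float = 2.0,
) -> SimResult:
    """Simulate one full panel under ``config``.

    ``per_individual_depth`` (length = number of individuals) overrides
    the common ``mean_depth`` with one Poisson mean per individual.
    ``n_duplicated`` appends that many planted non-Mendelian SNPs
    mimicking collapsed genome duplications: every individual is a true
    heterozygote and the locus attracts ``duplicate_depth_factor`` times
    the read depth.
    """
    ped = make_pedigree(config.n_families)
    n = len(ped.ids)
    root = np.random.SeedSequence(config.seed)
    ss_freq, ss_geno, ss_reads = root.spawn(3)
    rng_freq = np.random.default_rng(ss_freq)
    rng_geno = np.random.default_rng(ss_geno)
    rng_reads = np.random.default_rng(ss_reads)

    p = _draw_freqs(config.freq_model, config.n_snps, rng_freq)
    geno = simulate_genotypes(ped, p, rng_geno)
    dup_flag = np.zeros(config.n_snps + n_duplicated, dtype=bool)
    if n_duplicated:
        geno = np.concatenate(
            [geno, np.ones((n, n_duplicated), dtype=np.int8)], axis=1
        )
        p = np.concatenate([p, np.full(n_duplicated, 0.5)])
        dup_flag[config.n_snps :] = True

    depth = (
        np.full(n, config.mean_depth)
        if per_individual_depth is None
        else np.asarray(per_individual_depth, dtype=float)
    )
    if depth.shape != (n,):
        raise ValueError("per_individual_depth must have one entry per individual")
    ref, alt = simulate_gbs(geno[:, ~dup_flag], depth, rng_reads)
    if n_duplicated:
        dref, dalt = simulate_gbs(
            geno[:, dup_flag], depth * duplicate_depth_factor, rng_reads
        )
        ref = np.concatenate([ref, dref], axis=1)
        alt = np.concatenate([alt, dalt], axis=1)

    keep = drop_monomorphic(geno, ref, alt)
    return SimResult(
        config=config,
        pedigree=ped,
        genotypes=geno[:, keep],
        ref=ref[:, keep],
        alt=alt[:, keep],
        true_freqs=p[keep],
        kept=keep,
        n_dropped=geno.shape[1] - keep.size,
        duplicated=dup_flag[keep] if n_duplicated else None,
    )


def _chip_g1(sim: SimResult) -> RelatednessMatrix:
    """G1 on the true genotypes (the array-genotyping benchmark)."""
    geno = sim.genotypes.astype(float)
    scores = ScoreMatrix(
        X=geno,
        D=np.full(geno.shape, 2, dtype=np.int64),
        individual_ids=sim.pedigree.ids,
        snp_ids=[f"snp{j}" for j in sim.kept],
    )
    p_hat = geno.mean(axis=0) / 2.0
    freqs = AlleleFrequencies(p=p_hat, source="genotype_calls")
    g = compute_G1(scores, freqs)
    return RelatednessMatrix(
        G=g.G, method="Chip", individual_ids=g.individual_ids, diagonal_valid=True
    )


def compute_all_methods(
    sim: SimResult,
    methods=("G1", "G3", "G4", "G5"),
    include_chip: bool = False,
    use_true_freqs: bool = False,
    g3_seed: int | None = None,
) -> dict[str, RelatednessMatrix]:
    """Estimate the requested relatedness matrices from one simulated panel.

    Frequencies are re-estimated from the simulated reads by default;
    ``use_true_freqs=True`` plugs in the simulation truth instead (used to
    isolate the frequency-estimation contribution to bias).
    """
    scores = sim.scores()
    if use_true_freqs:
        freqs = AlleleFrequencies(p=sim.true_freqs, source="external")
    else:
        freqs = sim.estimated_freqs()
    out: dict[str, RelatednessMatrix] = {}
    if include_chip:
        out["Chip"] = _chip_g1(sim)
    g4 = None
    if {"G4", "G5"} & set(methods):
        g4 = compute_G4(scores, freqs)
    for m in methods:
        if m == "G1":
            out["G1"] = compute_G1(scores, freqs)
        elif m == "G3":
            if g3_seed is None:
                g3_seed = np.random.SeedSequence(sim.config.seed).spawn(4)[3]
            out["G3"] = compute_G3(
                sim.ref,
                sim.alt,
                freqs,
                seed=np.random.default_rng(g3_seed),
                individual_ids=sim.pedigree.ids,
            )
        elif m == "G4":
            out["G4"] = g4
        elif m == "G5":
            out["G5"] = adjust_diagonal(g4, scores, freqs)
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def _summaries(
    mats: dict[str, RelatednessMatrix], ped: Pedigree, extra: dict
) -> pd.DataFrame:
    groups = relationship_groups(ped)
    frames = []
    for name, rel in mats.items():
        tab = summarize_grm(rel, groups)
        tab.insert(0, "method", name)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    for k, v in extra.items():
        out[k] = v
    return out


def experiment_method_comparison(
    depths=(1.0, 2.0, 8.0),
    n_families: int = 100,
    n_snps: int = 10_000,
    freq_model: str | float = "uniform01",
    seed: int = 0,
) -> pd.DataFrame:
    """Group means/sds for Chip, G1, G3, G4 and G5 at each mean depth.

    Each depth is an independent simulation (its own genotype draw), so
    the Chip benchmark differs slightly between depths.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(2 * len(depths))
    frames = []
    for idx, d in enumerate(depths):
        cfg = SimConfig(
            n_families=n_families,
            n_snps=n_snps,
            freq_model=freq_model,
            mean_depth=d,
            seed=int(children[2 * idx].generate_state(1)[0]),
        )
        sim = run_design(cfg)
        mats = compute_all_methods(
            sim, include_chip=True, g3_seed=children[2 * idx + 1]
        )
        frames.append(_summaries(mats, sim.pedigree, {"depth": d}))
    return pd.concat(frames, ignore_index=True)


def experiment_fixed_effort(
    total_effort: float = 10_000,
    depths=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 20.0),
    n_families: int = 100,
    freq_model: str = "uniform_0.1_0.5",
    seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Fixed total sequencing effort spread over varying SNP counts.

    Each mean depth d gets ``round(total_effort / d)`` SNPs.  Only G5 is
    computed.  With ``replicates > 1`` the per-depth group means and sds
    are averaged across independent replicates, tightening the
    Monte-Carlo noise in the reported curves.  The returned table also
    carries the mean number of parents called per SNP.
    """
    root = np.random.SeedSequence(seed)
    frames = []
    for d in depths:
        reps = []
        for ss in root.spawn(replicates):
            cfg = SimConfig.from_effort(
                total_effort,
                d,
                n_families=n_families,
                freq_model=freq_model,
                seed=int(ss.generate_state(1)[0]),
            )
            sim = run_design(cfg)
            mats = compute_all_methods(sim, methods=("G4", "G5"))
            par = sim.parent_rows()
            called = (sim.ref[par] + sim.alt[par]) > 0
            tab = _summaries(
                {"G5": mats["G5"]},
                sim.pedigree,
                {
                    "depth": d,
                    "n_snps": cfg.n_snps,
                    "mean_parents_called": float(called.sum(axis=0).mean()),
                },
            )
            reps.append(tab)
        rep = pd.concat(reps, ignore_index=True)
        agg = (
            rep.groupby(["method", "group", "depth", "n_snps"], as_index=False)
            .agg(
                mean=("mean", "mean"),
                sd=("sd", "mean"),
                n_pairs=("n_pairs", "first"),
                mean_parents_called=("mean_parents_called", "mean"),
                n_replicates=("mean", "size"),
            )
        )
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def experiment_freq_grid(
    mean_depth: float = 2.0,
    freqs=(0.01, 0.05, 0.1, 0.2, 0.35, 0.5),
    n_snps_list=(1_000, 5_000, 10_000, 50_000),
    n_families: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """SD surface over (shared allele frequency, SNP count) at fixed depth.

    All SNPs in one run share the same allele frequency.  Returns group
    means/sds per (freq, n_snps) cell for G5.
    """
    root = np.random.SeedSequence(seed)
    cells = [(p, m) for p in freqs for m in n_snps_list]
    frames = []
    for (p, m), ss in zip(cells, root.spawn(len(cells))):
        cfg = SimConfig(
            n_families=n_families,
            n_snps=m,
            freq_model=float(p),
            mean_depth=mean_depth,
            seed=int(ss.generate_state(1)[0]),
        )
        sim = run_design(cfg)
        mats = compute_all_methods(sim, methods=("G4", "G5"))
        frames.append(
            _summaries(
                {"G5": mats["G5"]}, sim.pedigree, {"freq": p, "n_snps": m}
            )
        )
    return pd.concat(frames, ignore_index=True)
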