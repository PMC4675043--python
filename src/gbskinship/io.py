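"""Readers and writers for count matrices, VCF allelic depths, pedigrees
and relatedness matrices.

Conventions: rows are individuals and columns are SNPs everywhere; a read
depth of zero is the single encoding of a missing genotype (no sentinel
codes in files); counts are non-negative integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import RelatednessMatrix
from .pedigree import Pedigree

__all__ = [
    "AlleleCountMatrix",
    "read_counts",
    "write_counts",
    "read_grm",
    "write_grm",
    "read_pedigree",
    "write_pedigree",
]

log = logging.getLogger("gbskinship")

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


@dataclass
class AlleleCountMatrix:
    """Aligned reference/alternate read-count matrices with labels."""

    ref: np.ndarray = field(repr=False)
    alt: np.ndarray = field(repr=False)
    individual_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt matrices must have the same shape")
        if self.ref.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError("labels do not match matrix dimensions")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if np.any(self.ref < 0) or np.any(self.alt < 0):
            raise ValueError("negative read counts")

    def scores(self):
        from .grm import ScoreMatrix

        return ScoreMatrix.from_counts(
            self.ref, self.alt, self.individual_ids, self.snp_ids
        )


def _read_wide_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if tab.index.duplicated().any():
        raise ValueError(f"{path}: duplicate individual ids")
    if tab.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate SNP ids")
    vals = tab.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(np.isnan(vals)):
        raise ValueError(f"{path}: counts must be complete and numeric")
    if np.any(vals < 0) or np.any(vals != np.floor(vals)):
        raise ValueError(f"{path}: counts must be non-negative integers")
    return tab


def _read_counts_wide(paths) -> AlleleCountMatrix:
    try:
        ref_path, alt_path = paths
    except (TypeError, ValueError):
        raise ValueError(
            "wide format needs a (ref_path, alt_path) pair of tables"
        ) from None
    ref = _read_wide_table(ref_path)
    alt = _read_wide_table(alt_path)
    if list(ref.index) != list(alt.index) or list(ref.columns) != list(alt.columns):
        raise ValueError("ref and alt tables have different row/column labels")
    return AlleleCountMatrix(
        ref=ref.to_numpy(dtype=np.int64),
        alt=alt.to_numpy(dtype=np.int64),
        individual_ids=[str(i) for i in ref.index],
        snp_ids=[str(c) for c in ref.columns],
    )


def _read_counts_long(path) -> AlleleCountMatrix:
    tab = pd.read_csv(path, sep="\t", dtype={"individual": str, "snp": str})
    required = {"individual", "snp", "ref_count", "alt_count"}
    if not required.issubset(tab.columns):
        raise ValueError(f"{path}: long format needs columns {sorted(required)}")
    if tab.duplicated(["individual", "snp"]).any():
        bad = tab[tab.duplicated(["individual", "snp"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for ({bad['individual']}, {bad['snp']})"
        )
    for col in ("ref_count", "alt_count"):
        if (tab[col] < 0).any():
            raise ValueError(f"{path}: negative counts in {col}")
    inds = list(dict.fromkeys(tab["individual"]))
    snps = list(dict.fromkeys(tab["snp"]))
    ref = np.zeros((len(inds), len(snps)), dtype=np.int64)
    alt = np.zeros_like(ref)
    ii = tab["individual"].map({v: i for i, v in enumerate(inds)}).to_numpy()
    jj = tab["snp"].map({v: j for j, v in enumerate(snps)}).to_numpy()
    ref[ii, jj] = tab["ref_count"].to_numpy()
    alt[ii, jj] = tab["alt_count"].to_numpy()
    return AlleleCountMatrix(ref=ref, alt=alt, individual_ids=inds, snp_ids=snps)


def _read_counts_vcf(path) -> AlleleCountMatrix:
    """Extract per-sample allelic depths (AD) from biallelic SNP records.

    Multiallelic records are skipped (with a logged count); a missing AD
    entry becomes depth 0, i.e. a missing genotype.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    inds = list(vcf.samples)
    refs, alts, snp_ids = [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            refs.append(np.zeros(len(inds), dtype=np.int64))
            alts.append(np.zeros(len(inds), dtype=np.int64))
        else:
            ad = np.asarray(ad)
            ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
            refs.append(ad[:, 0].astype(np.int64))
            alts.append(ad[:, 1].astype(np.int64))
    vcf.close()
    if n_multi:
        log.info("skipped %d multiallelic VCF record(s)", n_multi)
    if not snp_ids:
        raise ValueError(f"{path}: no biallelic records found")
    return AlleleCountMatrix(
        ref=np.column_stack(refs),
        alt=np.column_stack(alts),
        individual_ids=inds,
        snp_ids=snp_ids,
    )


def read_counts(path, format: str = "wide") -> AlleleCountMatrix:
    """Read an allele-count matrix.

    ``format='wide'``: ``path`` is a (ref, alt) pair of TSV tables with
    individual ids in the first column and SNP ids in the header.
    ``format='long'``: one TSV with columns individual/snp/ref_count/
    alt_count; absent combinations mean depth 0.
    ``format='vcf_ad'``: per-sample AD field of biallelic VCF records.
    """
    if format == "wide":
        return _read_counts_wide(path)
    if format == "long":
        return _read_counts_long(path)
    if format == "vcf_ad":
        return _read_counts_vcf(path)
    raise ValueError(f"unknown counts format {format!r}")


def write_counts(
    counts: AlleleCountMatrix, path, format: str = "wide"
) -> list[str]:
    """Write counts; wide format takes a path prefix and produces
    ``<prefix>_ref.tsv`` / ``<prefix>_alt.tsv``.  Returns written paths."""
    if format == "wide":
        out = []
        for name, mat in (("ref", counts.ref), ("alt", counts.alt)):
            p = f"{path}_{name}.tsv"
            pd.DataFrame(
                mat, index=counts.individual_ids, columns=counts.snp_ids
            ).to_csv(p, sep="\t", index_label="id")
            out.append(p)
        return out
    if format == "long":
        n, m = counts.ref.shape
        tab = pd.DataFrame(
            {
                "individual": np.repeat(counts.individual_ids, m),
                "snp": np.tile(counts.snp_ids, n),
                "ref_count": counts.ref.ravel(),
                "alt_count": counts.alt.ravel(),
            }
        )
        tab = tab[(tab["ref_count"] > 0) | (tab["alt_count"] > 0)]
        tab.to_csv(path, sep="\t", index=False)
        return [str(path)]
    raise ValueError(f"unknown counts format {format!r}")


def write_grm(rel: RelatednessMatrix, path, format: str = "square_csv") -> None:
    """Write a relatedness matrix.

    ``square_csv``: ids in the header and first column, NaN cells empty.
    ``long_tsv``: one row per unordered pair (diagonal included) with
    columns id1/id2/method/n_snps_used/value; floats are printed with 17
    significant digits so the round-trip is bit-exact.
    """
    if format == "square_csv":
        pd.DataFrame(
            rel.G, index=rel.individual_ids, columns=rel.individual_ids
        ).to_csv(path, index_label="id", float_format=_FLOAT_FMT)
        return
    if format == "long_tsv":
        n = len(rel.individual_ids)
        iu = np.triu_indices(n)
        used = rel.n_snps_used
        with open(path, "w") as fh:
            fh.write("id1\tid2\tmethod\tn_snps_used\tvalue\n")
            for i, j in zip(*iu):
                val = rel.G[i, j]
                sval = "" if np.isnan(val) else _FLOAT_FMT % val
                nused = "" if used is None else str(int(used[i, j]))
                fh.write(
                    f"{rel.individual_ids[i]}\t{rel.individual_ids[j]}\t"
                    f"{rel.method}\t{nused}\t{sval}\n"
                )
        return
    raise ValueError(f"unknown GRM format {format!r}")


def read_grm(path, format: str = "square_csv", method: str | None = None):
    """Read a relatedness matrix written by :func:`write_grm`."""
    if format == "square_csv":
        tab = pd.read_csv(path, index_col=0, float_precision="round_trip")
        ids = [str(i) for i in tab.index]
        return RelatednessMatrix(
            G=tab.to_numpy(dtype=float),
            method=method or "unknown",
            individual_ids=ids,
            diagonal_valid=True,
        )
    if format == "long_tsv":
        tab = pd.read_csv(
            path,
            sep="\t",
            dtype={"id1": str, "id2": str},
            float_precision="round_trip",
        )
        ids = list(dict.fromkeys(pd.concat([tab["id1"], tab["id2"]])))
        pos = {v: i for i, v in enumerate(ids)}
        n = len(ids)
        g = np.full((n, n), np.nan)
        used = None
        if tab["n_snps_used"].notna().any():
            used = np.zeros((n, n), dtype=np.int64)
        for r in tab.itertuples():
            i, j = pos[r.id1], pos[r.id2]
            g[i, j] = g[j, i] = r.value
            if used is not None and not pd.isna(r.n_snps_used):
                used[i, j] = used[j, i] = int(r.n_snps_used)
        file_method = str(tab["method"].iloc[0]) if len(tab) else "unknown"
        m = method or file_method
        return RelatednessMatrix(
            G=g,
            method=m,
            individual_ids=ids,
            diagonal_valid=m not in ("G3", "G4"),
            n_snps_used=used,
        )
    raise ValueError(f"unknown GRM format {format!r}")


def read_pedigree(path) -> Pedigree:
    """Pedigree CSV with columns id, sire, dam; empty field = unknown."""
    tab = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Pedigree(tab)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, index=False)
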