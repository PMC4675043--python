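# gbskinship

Depth-aware estimation of genomic relatedness (kinship) matrices from
genotyping-by-sequencing (GBS) allele counts.

Low-coverage GBS often reads only one of a heterozygote's two alleles, so
naive genomic relationship matrices (GRMs) built from called genotypes are
biased: off-diagonals shrink toward zero and diagonals inflate. This
package implements moment estimators that correct for read depth —
including depth zero (missing genotypes) — so that relatedness can be
estimated without depth filtering or imputation:

- **G1** — classic pooled-denominator GRM on centred scores (baseline;
  biased at low depth).
- **G3** — one randomly sampled read per genotype, combined with per-pair
  denominators (robust, noisier; diagonal uninformative).
- **G4** — per-pair denominators using only SNPs called in *both*
  individuals (unbiased off-diagonals at any depth).
- **G5** — G4 plus a depth-corrected diagonal estimating `1 + F`
  (the fully corrected estimator).

Also included: a pedigreed GBS simulator (families of unrelated parents
with full-sib offspring, Poisson read depths), per-SNP QC diagnostics with
the "fin plot" (Hardy–Weinberg disequilibrium vs MAF, bounded by
`MAF − MAF²` above and `−MAF²` below) for detecting non-Mendelian
(duplicated-region) SNPs, conjunctive SNP filters, a self-relatedness
vs log-depth regression diagnostic, and pedigree parentage verification.

## Command line

```sh
# simulate a pedigreed GBS panel (counts + truth + pedigree + summaries)
gbskinship simulate --families 100 --snps 10000 --depth 8 --seed 1 --out-dir sim/

# estimate the depth-corrected GRM (G5 is the default method)
gbskinship compute --ref sim/counts_ref.tsv --alt sim/counts_alt.tsv \
    --method G5 --out g5.csv

# QC: per-SNP diagnostics and a fin plot, then filter on HW disequilibrium
gbskinship diagnose --ref sim/counts_ref.tsv --alt sim/counts_alt.tsv \
    --out diag.tsv --plot fin.png
gbskinship filter --diagnostics diag.tsv --hwdis-min -0.05 --out kept.txt

# check recorded parentage against the estimated relatedness
gbskinship verify-parentage --grm g5.csv --pedigree sim/pedigree.csv \
    --threshold 0.25 --out parentage.tsv
```

Inputs: wide ref/alt count TSVs, long-format count TSV
(`individual  snp  ref_count  alt_count`), or VCF with per-sample `AD`
(biallelic records). Depth 0 is the single encoding of a missing
genotype. GRMs are written as square CSV or bit-exact long TSV.

## Python API

```python
import gbskinship as gk

sim = gk.run_design(gk.SimConfig(n_families=100, n_snps=10_000,
                                 mean_depth=8.0, seed=1))
scores = sim.scores()
freqs = gk.estimate_allele_frequencies(sim.ref, sim.alt)
g4 = gk.compute_G4(scores, freqs)
g5 = gk.adjust_diagonal(g4, scores, freqs)   # depth-corrected diagonal
table = gk.summarize_grm(g5, gk.relationship_groups(sim.pedigree))
```

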