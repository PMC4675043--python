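"""Tests for whole-panel relatedness matrix construction."""

import numpy as np
import pytest

from gbskinship.core import single_snp_relatedness
from gbskinship.grm import (
    AlleleFrequencies,
    RelatednessMatrix,
    ScoreMatrix,
    adjust_diagonal,
    center_scores,
    compute_G1,
    compute_G3,
    compute_G4,
    estimate_allele_frequencies,
    summarize_grm,
)

from conftest import g4_oracle, g5_diag_oracle, random_panel


def _panel(X, D, p):
    X = np.asarray(X, dtype=float)
    D = np.asarray(D)
    scores = ScoreMatrix(
        X=X,
        D=D,
        individual_ids=[f"i{i}" for i in range(X.shape[0])],
        snp_ids=[f"s{j}" for j in range(X.shape[1])],
    )
    return scores, AlleleFrequencies(p=np.asarray(p, dtype=float), source="external")


# ------------------------------------------------------- allele frequencies


class TestEstimateAlleleFrequencies:
    def test_simple_pooled_counts(self):
        ref = np.array([[2], [0], [1]])
        alt = np.array([[0], [2], [1]])
        f = estimate_allele_frequencies(ref, alt)
        assert f.p[0] == 0.5
        assert f.polymorphic[0]

    def test_monomorphic_flagged(self):
        f = estimate_allele_frequencies(np.array([[4], [0]]), np.array([[0], [0]]))
        assert f.p[0] == 1.0
        assert not f.polymorphic[0]

    def test_hand_count(self):
        ref = np.array([[1], [0], [0], [2]])
        alt = np.array([[1], [2], [0], [0]])
        assert estimate_allele_frequencies(ref, alt).p[0] == 0.5

    def test_zero_depth_column_is_nan_and_flagged(self):
        f = estimate_allele_frequencies(np.zeros((3, 1)), np.zeros((3, 1)))
        assert np.isnan(f.p[0]) and not f.polymorphic[0]

    def test_source_recorded(self):
        f = estimate_allele_frequencies(np.ones((2, 2)), np.ones((2, 2)))
        assert f.source == "read_counts"


# ----------------------------------------------------------- centring


class TestCenterScores:
    def test_examples(self):
        scores, freqs = _panel([[2.0, np.nan]], [[3, 0]], [0.5, 0.3])
        z = center_scores(scores, freqs)
        assert z[0, 0] == 1.0
        assert z[0, 1] == 0.0  # missing -> zero

    def test_fractional_frequency(self):
        scores, freqs = _panel([[1.0]], [[2]], [0.3])
        assert center_scores(scores, freqs)[0, 0] == pytest.approx(0.4)

    def test_misaligned_rejected(self):
        scores, _ = _panel([[1.0]], [[2]], [0.3])
        with pytest.raises(ValueError):
            center_scores(scores, AlleleFrequencies(p=[0.3, 0.4], source="external"))


# ----------------------------------------------------------------------- G1


class TestG1:
    def test_identical_individuals(self):
        scores, freqs = _panel(
            [[2.0, 0.0], [2.0, 0.0]], [[1, 1], [1, 1]], [0.5, 0.5]
        )
        g = compute_G1(scores, freqs)
        assert g.G[0, 1] == pytest.approx(2.0)
        assert g.method == "G1" and g.diagonal_valid

    def test_single_individual_diagonal(self):
        scores, freqs = _panel([[2.0]], [[1]], [0.5])
        assert compute_G1(scores, freqs).G[0, 0] == pytest.approx(2.0)

    def test_equal_frequency_panel_equals_mean_single_snp_estimate(self, rng):
        # with a common p the pooled denominator reduces to the plain mean
        # of per-SNP estimates — checked against the scalar kernel
        X = rng.integers(0, 3, size=(3, 4)).astype(float)
        p = np.full(4, 0.4)
        scores, freqs = _panel(X, np.ones_like(X, dtype=int), p)
        g = compute_G1(scores, freqs)
        for i in range(3):
            for j in range(3):
                want = np.mean(
                    [single_snp_relatedness(X[i, k], X[j, k], 0.4) for k in range(4)]
                )
                assert g.G[i, j] == pytest.approx(want)

    def test_unequal_frequencies_match_pooled_oracle(self, rng):
        X = rng.integers(0, 3, size=(4, 6)).astype(float)
        p = rng.uniform(0.1, 0.9, 6)
        scores, freqs = _panel(X, np.ones_like(X, dtype=int), p)
        g = compute_G1(scores, freqs)
        denom = 2 * np.sum(p * (1 - p))
        for i in range(4):
            for j in range(4):
                num = sum(
                    (X[i, k] - 2 * p[k]) * (X[j, k] - 2 * p[k]) for k in range(6)
                )
                assert g.G[i, j] == pytest.approx(num / denom)

    def test_monomorphic_rejected(self):
        scores, _ = _panel([[2.0]], [[1]], [0.5])
        with pytest.raises(ValueError):
            compute_G1(scores, AlleleFrequencies(p=[1.0], source="external"))


# ----------------------------------------------------------------------- G4


class TestG4:
    def test_equals_g1_without_missingness(self, rng):
        scores, freqs = random_panel(rng, n=6, m=20, missing=0.0)
        g1 = compute_G1(scores, freqs)
        g4 = compute_G4(scores, freqs)
        np.testing.assert_allclose(g4.G, g1.G, atol=1e-12)

    def test_two_individuals_one_shared_snp(self):
        # individual 2 missing SNP 2: off-diagonal must use SNP 1 only
        scores, freqs = _panel(
            [[2.0, 1.0], [0.0, np.nan]], [[2, 3], [1, 0]], [0.5, 0.25]
        )
        g = compute_G4(scores, freqs)
        assert g.G[0, 1] == pytest.approx(single_snp_relatedness(2, 0, 0.5))
        assert g.n_snps_used[0, 1] == 1
        assert g.n_snps_used[0, 0] == 2

    def test_checkerboard_matches_oracle(self):
        X = np.array(
            [
                [2, np.nan, 1, np.nan, 0, np.nan],
                [np.nan, 1, np.nan, 2, np.nan, 0],
                [0, np.nan, 2, np.nan, 1, np.nan],
                [np.nan, 0, np.nan, 1, np.nan, 2],
            ],
            dtype=float,
        )
        D = np.where(np.isnan(X), 0, 2)
        p = np.array([0.3, 0.5, 0.7, 0.2, 0.4, 0.6])
        scores, freqs = _panel(X, D, p)
        with pytest.warns(UserWarning, match="no called SNP"):
            g = compute_G4(scores, freqs)
        np.testing.assert_allclose(g.G, g4_oracle(X, D, p), atol=1e-10, equal_nan=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores, freqs = random_panel(rng, n=10, m=50, missing=0.4)
        g = compute_G4(scores, freqs)
        want = g4_oracle(scores.X, scores.D, freqs.p)
        np.testing.assert_allclose(g.G, want, atol=1e-10, equal_nan=True)

    def test_zero_cocall_pair_is_missing_with_warning(self):
        X = np.array([[2.0, np.nan], [np.nan, 0.0]])
        D = np.array([[1, 0], [0, 1]])
        scores, freqs = _panel(X, D, [0.5, 0.5])
        with pytest.warns(UserWarning, match="no called SNP"):
            g = compute_G4(scores, freqs)
        assert np.isnan(g.G[0, 1])
        assert not np.isnan(g.G[0, 0])

    def test_snp_block_mode_identical(self, rng):
        scores, freqs = random_panel(rng, n=8, m=37, missing=0.3)
        full = compute_G4(scores, freqs)
        blocked = compute_G4(scores, freqs, snp_block=10)
        np.testing.assert_allclose(blocked.G, full.G, atol=1e-12, equal_nan=True)

    def test_flags(self, rng):
        scores, freqs = random_panel(rng, n=4, m=10, missing=0.2)
        g = compute_G4(scores, freqs)
        assert g.method == "G4" and not g.diagonal_valid


# ------------------------------------------------------------- G5 diagonal


class TestAdjustDiagonal:
    def test_single_snp_depth_eight(self):
        # S=1 at p=1/2: the correction is exactly neutral, diagonal = 2
        scores, freqs = _panel([[2.0]], [[8]], [0.5])
        g5 = adjust_diagonal(compute_G4(scores, freqs), scores, freqs)
        assert g5.G[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert g5.method == "G5" and g5.diagonal_valid

    def test_all_depth_one_gives_missing_diagonal(self):
        scores, freqs = _panel([[2.0, 0.0]], [[1, 1]], [0.5, 0.5])
        g5 = adjust_diagonal(compute_G4(scores, freqs), scores, freqs)
        assert np.isnan(g5.G[0, 0])
        assert g5.n_snps_used[0, 0] == 0

    def test_offdiagonals_bit_identical_to_g4(self, rng):
        scores, freqs = random_panel(rng, n=7, m=30, missing=0.3)
        g4 = compute_G4(scores, freqs)
        g5 = adjust_diagonal(g4, scores, freqs)
        off = ~np.eye(7, dtype=bool)
        np.testing.assert_array_equal(g5.G[off], g4.G[off])

    @pytest.mark.parametrize("seed", range(5))
    def test_diagonal_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores, freqs = random_panel(rng, n=10, m=50, missing=0.4)
        g5 = adjust_diagonal(compute_G4(scores, freqs), scores, freqs)
        want = g5_diag_oracle(scores.X, scores.D, freqs.p)
        np.testing.assert_allclose(
            np.diag(g5.G), want, atol=1e-10, equal_nan=True
        )

    def test_matches_g1_diagonal_at_high_depth_complete_data(self, rng):
        scores, freqs = random_panel(rng, n=5, m=40, missing=0.0, max_depth=60)
        scores.D[:] = 60  # effectively infinite depth
        g1 = compute_G1(scores, freqs)
        g5 = adjust_diagonal(compute_G4(scores, freqs), scores, freqs)
        np.testing.assert_allclose(np.diag(g5.G), np.diag(g1.G), atol=1e-10)

    def test_all_snp_denominator_variant(self):
        # depth-1 SNPs drop from the matched denominator but not from 'all'
        scores, freqs = _panel([[2.0, 2.0]], [[8, 1]], [0.5, 0.5])
        g4 = compute_G4(scores, freqs)
        matched = adjust_diagonal(g4, scores, freqs, denominator="matched")
        allsnp = adjust_diagonal(g4, scores, freqs, denominator="all")
        assert matched.G[0, 0] == pytest.approx(2.0)
        assert allsnp.G[0, 0] == pytest.approx(1.0)

    def test_bad_denominator_flag(self):
        scores, freqs = _panel([[2.0]], [[2]], [0.5])
        with pytest.raises(ValueError):
            adjust_diagonal(compute_G4(scores, freqs), scores, freqs, "nope")


# ----------------------------------------------------------------------- G3


class TestG3:
    def test_pure_reference_cell_always_scores_two(self):
        ref = np.full((1, 200), 3)
        alt = np.zeros((1, 200), dtype=int)
        freqs = AlleleFrequencies(p=np.full(200, 0.5), source="external")
        g = compute_G3(ref, alt, freqs, seed=0)
        # every sampled score is 2 -> diagonal = (2-1)^2 sum / denom = 2
        assert g.G[0, 0] == pytest.approx(2.0)

    def test_depth_one_matches_g4_offdiagonals(self, rng):
        ref = rng.integers(0, 2, size=(5, 60))
        alt = rng.integers(0, 2, size=(5, 60)) * (1 - ref)  # depth <= 1
        freqs = AlleleFrequencies(p=rng.uniform(0.2, 0.8, 60), source="external")
        scores = ScoreMatrix.from_counts(ref, alt)
        g4 = compute_G4(scores, freqs)
        g3 = compute_G3(ref, alt, freqs, seed=1)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(g3.G[off], g4.G[off], atol=1e-12)

    def test_seed_reproducibility(self, rng):
        ref = rng.integers(0, 5, size=(4, 40))
        alt = rng.integers(0, 5, size=(4, 40))
        keep = (ref.sum(0) > 0) & (alt.sum(0) > 0)
        ref, alt = ref[:, keep], alt[:, keep]
        freqs = estimate_allele_frequencies(ref, alt)
        a = compute_G3(ref, alt, freqs, seed=42)
        b = compute_G3(ref, alt, freqs, seed=42)
        c = compute_G3(ref, alt, freqs, seed=43)
        np.testing.assert_array_equal(a.G, b.G)
        assert not np.array_equal(a.G, c.G)

    def test_diagonal_flagged_invalid(self, rng):
        ref = rng.integers(1, 4, size=(3, 20))
        alt = rng.integers(1, 4, size=(3, 20))
        freqs = estimate_allele_frequencies(ref, alt)
        assert not compute_G3(ref, alt, freqs, seed=0).diagonal_valid


# ------------------------------------------------------------- global props


class TestMatrixProperties:
    @pytest.mark.parametrize("seed", range(3))
    def test_all_methods_symmetric(self, seed):
        rng = np.random.default_rng(200 + seed)
        scores, freqs = random_panel(rng, n=8, m=40, missing=0.3)
        ref = np.where(scores.X == 0.0, 0, scores.D)
        alt = np.where(scores.X == 2.0, 0, scores.D)
        # heterozygotes need at least one of each read
        het = scores.X == 1.0
        ref = np.where(het, np.maximum(scores.D - 1, 1), ref)
        alt = np.where(het, 1, alt)
        for rel in (
            compute_G1(scores, freqs),
            compute_G4(scores, freqs),
            adjust_diagonal(compute_G4(scores, freqs), scores, freqs),
            compute_G3(ref, alt, freqs, seed=seed),
        ):
            np.testing.assert_allclose(rel.G, rel.G.T, atol=1e-12, equal_nan=True)

    def test_eigen_report(self):
        rel = RelatednessMatrix(
            G=np.array([[1.0, 0.9], [0.9, 1.0]]),
            method="G5",
            individual_ids=["a", "b"],
        )
        rep = rel.eigen_report()
        assert rep["min_eigenvalue"] == pytest.approx(0.1)
        assert rep["n_negative"] == 0


# ------------------------------------------------------------- summaries


class TestSummarizeGrm:
    def _rel(self):
        g = np.array(
            [[1.0, 0.4, 0.1], [0.4, 1.0, 0.6], [0.1, 0.6, 1.0]]
        )
        return RelatednessMatrix(G=g, method="G5", individual_ids=["a", "b", "c"])

    def test_identity_group(self):
        tab = summarize_grm(self._rel(), {"self": [("a", "a"), ("b", "b"), ("c", "c")]})
        assert tab.loc[0, "mean"] == 1.0 and tab.loc[0, "sd"] == 0.0

    def test_pair_mean(self):
        tab = summarize_grm(self._rel(), {"g": [("a", "b"), ("b", "c")]})
        assert tab.loc[0, "mean"] == pytest.approx(0.5)
        assert tab.loc[0, "n_pairs"] == 2

    def test_missing_cells_skipped_and_counted(self):
        rel = self._rel()
        rel.G[0, 1] = rel.G[1, 0] = np.nan
        tab = summarize_grm(rel, {"g": [("a", "b"), ("b", "c")]})
        assert tab.loc[0, "n_pairs"] == 1 and tab.loc[0, "n_missing"] == 1
        assert tab.loc[0, "mean"] == pytest.approx(0.6)

    def test_empty_group_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            tab = summarize_grm(self._rel(), {"none": [], "g": [("a", "b")]})
        assert list(tab["group"]) == ["g"]
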