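"""The assessment battery against enumeration oracles and hand examples."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mcimpute import (
    CellLabels,
    ExpressionMatrix,
    SamplingMask,
    ValidationError,
    clustering_ari,
    cts_score,
    cv_mean_relation,
    de_auc,
    generate_lowrank,
    mask_at_random,
    pca_embed,
    recovery_metrics,
    silhouette_on_embedding,
    singular_spectrum,
    wilcoxon_de,
    zero_fraction_by_bins,
)
from mcimpute.synthetic import generate_scrnaseq


def _matrix(values, layer="log"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(
        values, [f"c{i}" for i in range(m)], [f"g{j}" for j in range(n)], layer
    )


class TestMaskAtRandom:
    def test_exact_observed_count(self, rng):
        X = rng.random((10, 10)) + 0.1
        Y, held = mask_at_random(X, 0.5, seed=7)
        assert held.complement().n_observed == 50
        assert (Y[held.mask == 1] == 0).all()

    def test_same_seed_same_mask(self, rng):
        X = rng.random((8, 9)) + 0.1
        _, h1 = mask_at_random(X, 0.3, seed=5)
        _, h2 = mask_at_random(X, 0.3, seed=5)
        np.testing.assert_array_equal(h1.mask, h2.mask)

    def test_high_ratio_rounds_to_everything_observed(self, rng):
        X = rng.random((2, 2)) + 0.1
        Y, held = mask_at_random(X, 0.99, seed=1)
        assert held.n_observed == 0  # round(3.96) = 4 observed
        np.testing.assert_array_equal(Y, X)

    def test_invalid_ratio_rejected(self, rng):
        X = rng.random((3, 3))
        for ratio in (0.0, 1.0, -0.2):
            with pytest.raises(ValidationError):
                mask_at_random(X, ratio, seed=0)


class TestRecoveryMetrics:
    def test_perfect_estimate_all_zero(self, rng):
        X = rng.random((4, 4))
        held = SamplingMask((rng.random((4, 4)) > 0.5).astype(float))
        met = recovery_metrics(X, X, held)
        assert met.nmse == met.rmse == met.mae == 0.0

    def test_worked_example(self):
        # held-out truths [1, 2] against estimates [0, 0]
        t = np.array([[1.0, 2.0]])
        e = np.zeros((1, 2))
        met = recovery_metrics(t, e, SamplingMask(np.ones((1, 2))))
        assert met.rmse == pytest.approx(math.sqrt(2.5))
        assert met.mae == pytest.approx(1.5)
        assert met.nmse == pytest.approx(1.0)

    def test_matches_bruteforce_loops(self, rng):
        t = rng.random((5, 6))
        e = rng.random((5, 6))
        sel = rng.random((5, 6)) > 0.5
        met = recovery_metrics(t, e, SamplingMask(sel.astype(float)))
        sq, ab, t2, n = 0.0, 0.0, 0.0, 0
        for i in range(5):
            for j in range(6):
                if sel[i, j]:
                    d = t[i, j] - e[i, j]
                    sq += d * d
                    ab += abs(d)
                    t2 += t[i, j] ** 2
                    n += 1
        assert met.rmse == pytest.approx(math.sqrt(sq / n), abs=1e-12)
        assert met.mae == pytest.approx(ab / n, abs=1e-12)
        assert met.nmse == pytest.approx(sq / t2, abs=1e-12)

    def test_rmse_at_least_mae(self, rng):
        t, e = rng.random((6, 6)), rng.random((6, 6))
        met = recovery_metrics(t, e, SamplingMask(np.ones((6, 6))))
        assert met.rmse >= met.mae

    def test_all_zero_truth_flags_nmse_undefined(self):
        t = np.zeros((2, 2))
        e = np.ones((2, 2))
        with pytest.warns(UserWarning, match="undefined"):
            met = recovery_metrics(t, e, SamplingMask(np.ones((2, 2))))
        assert not met.nmse_defined
        assert np.isnan(met.nmse)
        assert met.rmse == 1.0


class TestCTS:
    def test_identical_and_reversed_vectors(self):
        # group A: copies of an increasing vector (intra Spearman = 1);
        # group B: copies of its decreasing rearrangement (inter = -1)
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = v[::-1]
        E = _matrix(np.vstack([v, v, v, w, w, w]))
        labels = CellLabels(["A"] * 3 + ["B"] * 3, E.cell_ids)
        res = cts_score(E, labels, "A", "B")
        assert res.intra_scatter["A"] == pytest.approx(1.0)
        assert res.intra_scatter["B"] == pytest.approx(1.0)
        assert res.inter_scatter == pytest.approx(-1.0)
        assert res.cts == pytest.approx(2.0)

    def test_indistinguishable_groups_score_zero(self, rng):
        # both groups are copies of one cell: every pair correlates at 1,
        # so intra and inter coincide and the separability vanishes
        v = rng.random(6)
        E = _matrix(np.tile(v, (6, 1)))
        labels = CellLabels(["A"] * 3 + ["B"] * 3, E.cell_ids)
        res = cts_score(E, labels, "A", "B")
        assert res.cts == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_heterogeneous_group_never_positive(self, rng):
        # duplicating one heterogeneous group into two: the cross pairs
        # include perfectly correlated copies, so the median inter scatter
        # is at least the median intra scatter and CTS cannot be positive
        block = rng.random((3, 5))
        E = _matrix(np.vstack([block, block]))
        labels = CellLabels(["A"] * 3 + ["B"] * 3, E.cell_ids)
        res = cts_score(E, labels, "A", "B")
        assert res.cts <= 1e-12

    def test_symmetric_under_group_swap(self, rng):
        E = _matrix(rng.random((7, 6)))
        labels = CellLabels(["A"] * 4 + ["B"] * 3, E.cell_ids)
        ab = cts_score(E, labels, "A", "B")
        ba = cts_score(E, labels, "B", "A")
        assert ab.cts == pytest.approx(ba.cts, abs=1e-12)
        assert ab.inter_scatter == pytest.approx(ba.inter_scatter, abs=1e-12)

    def test_matches_pairloop_spearman_oracle(self, rng):
        E = _matrix(rng.random((8, 6)))
        labels = CellLabels(["A"] * 4 + ["B"] * 4, E.cell_ids)
        res = cts_score(E, labels, "A", "B")
        idx_a, idx_b = range(4), range(4, 8)

        def med(pairs):
            return float(np.median([
                stats.spearmanr(E.values[i], E.values[j]).statistic
                for i, j in pairs
            ]))

        intra_a = med(itertools.combinations(idx_a, 2))
        intra_b = med(itertools.combinations(idx_b, 2))
        inter = med(itertools.product(idx_a, idx_b))
        assert res.intra_scatter["A"] == pytest.approx(intra_a, abs=1e-12)
        assert res.intra_scatter["B"] == pytest.approx(intra_b, abs=1e-12)
        assert res.inter_scatter == pytest.approx(inter, abs=1e-12)
        assert res.cts == pytest.approx((intra_a + intra_b) / 2 - inter, abs=1e-12)

    def test_tiny_group_rejected(self, rng):
        E = _matrix(rng.random((3, 4)))
        labels = CellLabels(["A", "B", "B"], E.cell_ids)
        with pytest.raises(ValidationError, match="need >= 2"):
            cts_score(E, labels, "A", "B")

    def test_constant_cell_pairs_excluded_with_warning(self, rng):
        vals = rng.random((5, 4))
        vals[0] = 2.0  # constant cell: Spearman undefined
        E = _matrix(vals)
        labels = CellLabels(["A"] * 3 + ["B"] * 2, E.cell_ids)
        with pytest.warns(UserWarning, match="constant"):
            res = cts_score(E, labels, "A", "B")
        assert np.isfinite(res.cts)


class TestClusteringARI:
    def test_separated_blobs_score_one(self, rng):
        a = rng.standard_normal((20, 10)) * 0.05
        b = rng.standard_normal((20, 10)) * 0.05 + 40.0
        E = _matrix(np.abs(np.vstack([a, b])))
        labels = CellLabels(["A"] * 20 + ["B"] * 20, E.cell_ids)
        aris = clustering_ari(E, labels, n_runs=10, seed=0)
        assert aris.shape == (10,)
        np.testing.assert_allclose(aris, 1.0)

    def test_random_labels_near_zero_expectation(self, rng):
        E = _matrix(rng.random((200, 8)))
        labels = CellLabels(
            list(rng.choice(["A", "B"], size=200)), E.cell_ids
        )
        aris = clustering_ari(E, labels, n_runs=20, seed=1)
        assert abs(np.mean(aris)) < 0.05

    def test_ari_matches_pair_enumeration_oracle(self):
        # two fixed partitions of 6 items; ARI from the adjusted pair-count
        # formula evaluated by explicit enumeration
        from sklearn.metrics import adjusted_rand_score

        p1 = [0, 0, 0, 1, 1, 1]
        p2 = [0, 0, 1, 1, 2, 2]

        def pair_count_ari(x, y):
            n = len(x)
            same_x = {(i, j): x[i] == x[j] for i, j in itertools.combinations(range(n), 2)}
            same_y = {(i, j): y[i] == y[j] for i, j in itertools.combinations(range(n), 2)}
            a = sum(1 for k in same_x if same_x[k] and same_y[k])
            b = sum(1 for k in same_x if not same_x[k] and not same_y[k])
            pairs = n * (n - 1) / 2
            # expected index from marginal pair counts
            sx = sum(1 for k in same_x if same_x[k])
            sy = sum(1 for k in same_y if same_y[k])
            expected = sx * sy / pairs
            maximum = (sx + sy) / 2
            return (a - expected) / (maximum - expected)

        assert adjusted_rand_score(p1, p2) == pytest.approx(pair_count_ari(p1, p2))
        assert adjusted_rand_score(p1, p1) == 1.0

    def test_k_larger_than_cells_rejected(self, rng):
        E = _matrix(rng.random((3, 4)))
        labels = CellLabels(["A", "B", "C"], E.cell_ids)
        with pytest.raises(ValidationError, match="exceeds"):
            clustering_ari(E, labels, k=5, n_runs=2, seed=0)

    def test_pca_projection_is_deterministic(self, rng):
        vals = rng.random((10, 6))
        np.testing.assert_array_equal(pca_embed(vals), pca_embed(vals))


class TestZeroFractionBins:
    def test_bin_zero_of_silent_genes(self):
        # two genes with zero bulk expression, all-zero in single cells
        single = _matrix(np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 7.0]]), "counts")
        bulk = np.array([0.0, 0.0, 100.0])
        res = zero_fraction_by_bins(single, bulk)
        assert res.fractions[0] == 1.0

    def test_no_values_below_threshold_gives_zero_fractions(self):
        single = _matrix(np.full((3, 4), 2.0), "counts")
        bulk = np.array([10.0, 60.0, 110.0, 450.0])
        res = zero_fraction_by_bins(single, bulk)
        defined = res.fractions[~np.isnan(res.fractions)]
        assert (defined == 0).all()

    def test_hand_placed_zeros_enumeration(self):
        # 6 genes over 2 cells; bulk values chosen so genes fall in known bins
        # (bin width is 500/9 ~ 55.6): g0,g1 -> bin 0 (bulk 0); g2,g3 -> bin 1;
        # g4 -> bin 2; g5 excluded (bulk > 500)
        vals = np.array(
            [
                [0.0, 1.0, 0.2, 3.0, 0.0, 9.0],
                [0.0, 0.0, 0.6, 0.4, 2.0, 9.0],
            ]
        )
        bulk = np.array([0.0, 0.0, 10.0, 50.0, 100.0, 600.0])
        res = zero_fraction_by_bins(_matrix(vals, "counts"), bulk)
        # bin 0 entries: g0, g1 across 2 cells -> values 0,0,1,0 -> 3/4 below 0.5
        assert res.fractions[0] == pytest.approx(3 / 4)
        # bin 1 entries: g2, g3 -> 0.2, 3.0, 0.6, 0.4 -> 2/4 below 0.5
        assert res.fractions[1] == pytest.approx(2 / 4)
        # bin 2: g4 -> 0.0, 2.0 -> 1/2
        assert res.fractions[2] == pytest.approx(1 / 2)
        assert res.genes_per_bin[0] == 2 and res.genes_per_bin[2] == 1
        # g5 excluded: total binned genes is 5
        assert res.genes_per_bin.sum() == 5

    def test_empty_bins_are_nan_not_zero(self):
        single = _matrix(np.ones((2, 2)), "counts")
        bulk = np.array([10.0, 20.0])
        res = zero_fraction_by_bins(single, bulk)
        assert np.isnan(res.fractions[-1])


class TestCVMeanRelation:
    def test_constant_gene_excluded(self, rng):
        vals = rng.random((50, 3)) + 0.5
        vals[:, 1] = 3.0
        with pytest.warns(UserWarning, match="excluded"):
            res = cv_mean_relation(_matrix(vals, "normalized"))
        assert res.n_excluded == 1
        assert len(res.gene_ids) == 2

    def test_poisson_slope_near_minus_half(self):
        rng = np.random.default_rng(77)
        mus = np.concatenate([np.full(30, 1.0), np.full(30, 10.0), np.full(30, 100.0)])
        vals = rng.poisson(mus, size=(5000, 90)).astype(float)
        res = cv_mean_relation(_matrix(vals, "normalized"))
        assert abs(res.slope + 0.5) < 0.05

    def test_cv_invariant_to_global_scaling(self, rng):
        vals = rng.random((40, 5)) + 0.2
        r1 = cv_mean_relation(_matrix(vals, "normalized"))
        r2 = cv_mean_relation(_matrix(vals * 7.0, "normalized"))
        np.testing.assert_allclose(r1.log10_cv, r2.log10_cv, atol=1e-12)
        np.testing.assert_allclose(r2.log10_mean, r1.log10_mean + np.log10(7), atol=1e-12)


class TestSilhouette:
    def test_far_separated_tight_groups_approach_one(self, rng):
        a = rng.standard_normal((10, 2)) * 0.01
        b = rng.standard_normal((10, 2)) * 0.01 + 1000.0
        emb = np.vstack([a, b])
        labels = CellLabels(["A"] * 10 + ["B"] * 10)
        assert silhouette_on_embedding(emb, labels) > 0.99

    def test_identical_points_score_zero(self):
        emb = np.zeros((6, 2))
        labels = CellLabels(["A"] * 3 + ["B"] * 3)
        assert silhouette_on_embedding(emb, labels) == 0.0

    def test_five_point_hand_computation(self):
        # 1-D layout: A at 0 and 1; B at 10, 11, 12 (embedded in 2-D)
        emb = np.array([[0.0, 0], [1.0, 0], [10.0, 0], [11.0, 0], [12.0, 0]])
        labels = CellLabels(["A", "A", "B", "B", "B"])

        def hand():
            pts = emb[:, 0]
            lab = ["A", "A", "B", "B", "B"]
            s = []
            for i in range(5):
                same = [abs(pts[i] - pts[j]) for j in range(5) if j != i and lab[j] == lab[i]]
                other = [abs(pts[i] - pts[j]) for j in range(5) if lab[j] != lab[i]]
                a_i = np.mean(same)
                b_i = np.mean(other)
                s.append((b_i - a_i) / max(a_i, b_i))
            return float(np.mean(s))

        assert silhouette_on_embedding(emb, labels) == pytest.approx(hand(), abs=1e-12)

    def test_singleton_group_warns(self):
        emb = np.array([[0.0, 0], [5.0, 0], [6.0, 0]])
        labels = CellLabels(["A", "B", "B"])
        with pytest.warns(UserWarning, match="singleton"):
            silhouette_on_embedding(emb, labels)


class TestWilcoxonDE:
    def test_identical_distributions_give_large_p(self, rng):
        block = rng.random((4, 6))
        E = _matrix(np.vstack([block, block]))
        labels = CellLabels(["A"] * 4 + ["B"] * 4, E.cell_ids)
        res = wilcoxon_de(E, labels, "A", "B")
        assert (res.p_values > 0.5).all()

    def test_complete_separation_matches_permutation_oracle(self, rng):
        # one gene fully separating two groups of 5 vs 5; the exact two-sided
        # rank-sum p equals the tail mass of the enumerated permutation null
        lo = rng.random(5)
        hi = rng.random(5) + 10.0
        vals = np.concatenate([lo, hi])[:, None]
        E = _matrix(vals)
        labels = CellLabels(["A"] * 5 + ["B"] * 5, E.cell_ids)
        res = wilcoxon_de(E, labels, "A", "B")

        ranks = stats.rankdata(vals[:, 0])
        observed = ranks[:5].sum()
        null = [
            sum(c) for c in itertools.combinations(ranks, 5)
        ]
        mean_null = float(np.mean(null))
        extreme = sum(
            1 for w in null if abs(w - mean_null) >= abs(observed - mean_null) - 1e-12
        )
        p_exact = extreme / len(null)
        assert res.p_values[0] == pytest.approx(p_exact, abs=1e-12)

    def test_all_tied_gene_p_one(self, rng):
        vals = np.column_stack([np.full(8, 3.0), rng.random(8)])
        E = _matrix(vals)
        labels = CellLabels(["A"] * 4 + ["B"] * 4, E.cell_ids)
        with pytest.warns(UserWarning, match="tied"):
            res = wilcoxon_de(E, labels, "A", "B")
        assert res.p_values[0] == 1.0

    def test_auc_perfect_ranking(self, rng):
        # 3 strongly DE genes vs 5 null genes
        a = rng.random((10, 8))
        b = rng.random((10, 8))
        b[:, :3] += 10.0
        E = _matrix(np.vstack([a, b]))
        labels = CellLabels(["A"] * 10 + ["B"] * 10, E.cell_ids)
        res = wilcoxon_de(E, labels, "A", "B")
        truth = np.array([True] * 3 + [False] * 5)
        assert de_auc(res, truth) == 1.0


class TestSingularSpectrum:
    def test_planted_rank_two(self):
        X = generate_lowrank(12, 9, 2, seed=5)
        s, energy = singular_spectrum(X)
        assert (s[2:] < 1e-10 * s[0]).all()
        assert energy[-1] == pytest.approx(1.0)

    def test_energy_monotone_nondecreasing(self, rng):
        s, energy = singular_spectrum(rng.random((8, 6)))
        assert (np.diff(energy) >= -1e-15).all()


class TestImputationImprovesBiologySignals:
    """Desk-scale analogue: imputation should not degrade, and typically
    improves, clustering agreement and cell-type separability."""

    def test_cts_improves_on_dropout_data(self):
        from mcimpute import mcimpute
        from mcimpute.preprocess import PreprocessConfig, preprocess

        truth, observed = generate_scrnaseq(
            m_cells=120, n_genes=80, k_clusters=2, r=4,
            dropout_strength=0.15, seed=55,
        )
        pre = PreprocessConfig(filter=False)
        out = mcimpute(observed, method="nnm", preprocess_cfg=pre)
        logged, _ = preprocess(observed, pre)
        g = truth.labels.groups
        before = cts_score(logged, truth.labels, g[0], g[1]).cts
        after = cts_score(out.log, truth.labels, g[0], g[1]).cts
        assert after >= before
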