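import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microguild.data_model import AbundanceTable, MetadataTable, SampleMetadata
from microguild.stats import (
    ClrMatrix,
    DistanceMatrix,
    aitchison_distance_matrix,
    alpha_diversity,
    attach_bh_q,
    beta_dispersion_summaries,
    bh_fdr,
    clr_transform,
    friedman_dunn,
    paired_rank_test,
    permanova,
    unpaired_rank_test,
)


def make_table(values, mode="counts"):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        [f"s{i}" for i in range(values.shape[0])],
        [f"o{j}" for j in range(values.shape[1])],
        values,
        mode,
    )


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        clr = clr_transform(make_table([[1, 1, 1, 1]]), pseudocount=0.0)
        np.testing.assert_allclose(clr.values, 0.0, atol=1e-12)

    def test_hand_computed_row(self):
        # (1, 2, 4) with no pseudocount: geometric mean 2 -> (-ln2, 0, ln2)
        clr = clr_transform(make_table([[1, 2, 4]]), pseudocount=0.0)
        np.testing.assert_allclose(
            clr.values[0], [-math.log(2), 0.0, math.log(2)], atol=1e-12
        )

    def test_row_sums_zero(self, small_study):
        clr = clr_transform(small_study.counts)
        np.testing.assert_allclose(clr.values.sum(axis=1), 0.0, atol=1e-9)

    def test_scale_invariance_at_zero_pseudocount(self):
        rng = np.random.default_rng(0)
        row = rng.integers(1, 100, size=12).astype(float)
        a = clr_transform(make_table([row]), pseudocount=0.0)
        b = clr_transform(make_table([row * 7]), pseudocount=0.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_relative_mode_uses_depth_equivalent(self):
        counts = make_table([[10.0, 30.0]])
        rel = make_table([[0.25, 0.75]], mode="relative")
        a = clr_transform(counts, pseudocount=0.5, depth=40)
        b = clr_transform(rel, pseudocount=0.5 / 40, depth=1)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_nonpositive_adjusted_value_errors(self):
        with pytest.raises(ValueError):
            clr_transform(make_table([[0, 1]]), pseudocount=0.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_property_row_sums_zero(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(rng.integers(0, 500, size=(3, 8)))
        clr = clr_transform(table)
        assert np.all(np.abs(clr.values.sum(axis=1)) < 1e-9)


class TestAitchison:
    def test_identical_rows_distance_zero(self):
        clr = ClrMatrix(["a", "b"], ["x", "y"], np.array([[1.0, -1.0], [1.0, -1.0]]))
        d = aitchison_distance_matrix(clr)
        assert d["a", "b"] == 0.0

    def test_hand_computed_distance(self):
        clr = ClrMatrix(["a", "b"], ["x", "y"], np.array([[0.0, 0.0], [3.0, -3.0]]))
        d = aitchison_distance_matrix(clr)
        assert d["a", "b"] == pytest.approx(math.sqrt(18))

    def test_otu_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((4, 6))
        vals -= vals.mean(axis=1, keepdims=True)
        clr1 = ClrMatrix([f"s{i}" for i in range(4)], [f"o{j}" for j in range(6)], vals)
        perm = rng.permutation(6)
        clr2 = ClrMatrix(
            clr1.sample_ids, [clr1.otu_ids[j] for j in perm], vals[:, perm]
        )
        np.testing.assert_allclose(
            aitchison_distance_matrix(clr1).values,
            aitchison_distance_matrix(clr2).values,
            atol=1e-12,
        )


class TestAlphaDiversity:
    def test_uniform_four_otus(self):
        out = alpha_diversity(make_table([[25, 25, 25, 25]]))
        assert out["shannon"].iloc[0] == pytest.approx(math.log(4))
        assert out["richness"].iloc[0] == 4

    def test_single_otu(self):
        out = alpha_diversity(make_table([[100, 0, 0]]))
        assert out["shannon"].iloc[0] == 0.0
        assert out["richness"].iloc[0] == 1

    def test_half_half(self):
        out = alpha_diversity(make_table([[0.5, 0.5, 0.0]], mode="relative"))
        assert out["shannon"].iloc[0] == pytest.approx(math.log(2))
        assert out["richness"].iloc[0] == 2

    def test_empty_sample_errors(self):
        table = AbundanceTable(["s"], ["a"], np.array([[0.0]]), "counts")
        with pytest.raises(ValueError):
            alpha_diversity(table)


def permanova_oracle_f(d2, labels):
    """Naive pseudo-F computed straight from the definition."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    g = len(groups)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for lab in groups:
        idx = np.flatnonzero(labels == lab)
        pair_sum = sum(
            d2[idx[a], idx[b]]
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
        )
        ss_within += pair_sum / len(idx)
    return ((ss_total - ss_within) / (g - 1)) / (ss_within / (n - g))


def permanova_enumeration_oracle(d, labels):
    """Exact p by enumerating every label permutation."""
    d2 = d.values**2
    labels = np.asarray(labels)
    n = len(labels)
    f_obs = permanova_oracle_f(d2, labels)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if permanova_oracle_f(d2, labels[list(perm)]) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def _points_to_dm(self, points):
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(len(points))]
        return DistanceMatrix(ids, squareform(pdist(points)))

    def test_two_tight_clusters_minimal_p(self):
        points = np.vstack(
            [np.random.default_rng(0).normal(0, 0.01, (3, 2)),
             np.random.default_rng(1).normal(10, 0.01, (3, 2))]
        )
        d = self._points_to_dm(points)
        labels = [0, 0, 0, 1, 1, 1]
        oracle = permanova_enumeration_oracle(d, labels)
        res = permanova(d, labels, n_perm=999, seed=0)
        assert res.p == pytest.approx(oracle, abs=0.02)  # Monte Carlo error
        exact = permanova(d, labels, method="exact")
        assert exact.p == oracle

    def test_exact_matches_enumeration_on_random_data(self):
        rng = np.random.default_rng(5)
        points = rng.standard_normal((6, 3))
        d = self._points_to_dm(points)
        labels = [0, 1, 0, 1, 0, 1]
        assert permanova(d, labels, method="exact").p == pytest.approx(
            permanova_enumeration_oracle(d, labels)
        )

    def test_f_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        points = rng.standard_normal((12, 4))
        d = self._points_to_dm(points)
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, labels, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, ids=d.ids), grouping=labels, permutations=99
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(3)
        d = self._points_to_dm(rng.standard_normal((8, 2)))
        f1 = permanova(d, [0, 0, 0, 0, 1, 1, 1, 1], n_perm=49, seed=0).pseudo_f
        f2 = permanova(d, [1, 1, 1, 1, 0, 0, 0, 0], n_perm=49, seed=0).pseudo_f
        assert f1 == pytest.approx(f2)

    def test_degenerate_matrix_errors(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            permanova(d, [0, 0, 1])

    def test_single_group_errors(self):
        rng = np.random.default_rng(4)
        d = self._points_to_dm(rng.standard_normal((4, 2)))
        with pytest.raises(ValueError):
            permanova(d, [0, 0, 0, 0])


class TestPairedRankTest:
    def test_no_change_gives_p_one(self):
        x = np.arange(1.0, 9.0)
        with pytest.warns(UserWarning):
            res = paired_rank_test(x, x)
        assert res.p == 1.0

    def test_all_increased_n8_exact(self):
        before = np.arange(1.0, 9.0)
        after = before + np.linspace(0.5, 1.5, 8)
        res = paired_rank_test(before, after)
        assert res.p == pytest.approx(2 / 2**8)
        assert res.direction == 1

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(0)
        before = rng.standard_normal(10)
        after = before + rng.standard_normal(10)
        perm = rng.permutation(10)
        assert paired_rank_test(before, after).p == pytest.approx(
            paired_rank_test(before[perm], after[perm]).p
        )


class TestUnpairedRankTest:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert unpaired_rank_test(x, x).p == pytest.approx(1.0)

    def test_fully_separated_3v3_exact(self):
        res = unpaired_rank_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.p == pytest.approx(0.1)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(6), rng.standard_normal(7)
        assert unpaired_rank_test(a, b).p == pytest.approx(unpaired_rank_test(b, a).p)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            unpaired_rank_test([], [1.0, 2.0, 3.0])


class TestFriedmanDunn:
    def test_identical_columns_omnibus_p_one(self):
        matrix = np.tile(np.arange(6.0)[:, None], (1, 3))
        omnibus, pairwise = friedman_dunn(matrix)
        assert omnibus.p == 1.0
        assert all(t.p == 1.0 for t in pairwise)

    def test_maximal_chi2_rank_algebra(self):
        # every row ranks columns identically: chi2 = n(k-1) = 20
        rng = np.random.default_rng(0)
        matrix = np.sort(rng.standard_normal((10, 3)), axis=1)
        omnibus, _ = friedman_dunn(matrix)
        assert omnibus.statistic == pytest.approx(10 * (3 - 1))

    def test_pairwise_p_capped_at_one(self):
        rng = np.random.default_rng(2)
        _, pairwise = friedman_dunn(rng.standard_normal((8, 4)))
        assert all(0 <= t.p <= 1 for t in pairwise)

    def test_two_columns_directed_to_paired_test(self):
        with pytest.raises(ValueError, match="paired_rank_test"):
            friedman_dunn(np.zeros((5, 2)))

    def test_dunn_z_formula(self):
        rng = np.random.default_rng(3)
        matrix = rng.standard_normal((7, 3))
        from scipy.stats import norm, rankdata

        _, pairwise = friedman_dunn(matrix)
        ranks = rankdata(matrix, axis=1).mean(axis=0)
        se = math.sqrt(3 * 4 / (6 * 7))
        z01 = (ranks[0] - ranks[1]) / se
        assert pairwise[0].statistic == pytest.approx(z01)
        assert pairwise[0].p == pytest.approx(min(1.0, 3 * 2 * norm.sf(abs(z01))))


def bh_oracle(p):
    """Brute-force BH definition: q_i = min over {j: p_j >= p_i} of m p_j / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    rank_of = np.empty(m, dtype=int)
    rank_of[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(m * p[j] / rank_of[j] for j in range(m) if p[j] >= p[i]), 1.0
        )
    return q


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(40)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(2)
        p = rng.random(25)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_attach_q(self):
        results = [paired_rank_test(np.arange(8.0), np.arange(8.0) + i + 1)
                   for i in range(3)]
        out = attach_bh_q(results)
        assert all(r.q is not None and r.q >= r.p - 1e-12 for r in out)


class TestBetaDispersion:
    def _meta(self):
        recs = []
        for subj, arm in (("S1", "AX"), ("S2", "AX"), ("S3", "AX")):
            for tp in ("BL", "W6"):
                recs.append(
                    SampleMetadata(f"{subj}_{tp}", subj, arm, "female", 25.0, tp)
                )
        return MetadataTable(recs)

    def _dm(self, rows):
        from scipy.spatial.distance import pdist, squareform

        ids = [f"S{i}_{tp}" for i in (1, 2, 3) for tp in ("BL", "W6")]
        return DistanceMatrix(ids, squareform(pdist(rows)))

    def test_three_subjects_three_inter_pairs(self):
        rng = np.random.default_rng(0)
        inter, intra = beta_dispersion_summaries(
            self._dm(rng.standard_normal((6, 3))), self._meta()
        )
        assert len(inter[inter.timepoint == "BL"]) == 3
        assert len(intra) == 3

    def test_identical_profiles_zero_shift(self):
        rows = np.tile(np.arange(3.0), (6, 1))
        rows[1] += 5  # S1_W6 differs; S2, S3 identical across timepoints
        inter, intra = beta_dispersion_summaries(self._dm(rows), self._meta())
        s2 = intra[intra.subject_id == "S2"]
        assert s2["distance"].iloc[0] == 0.0

    def test_single_subject_arm_warns(self):
        recs = [
            SampleMetadata("S1_BL", "S1", "AX", "female", 25.0, "BL"),
            SampleMetadata("S1_W6", "S1", "AX", "female", 25.0, "W6"),
        ]
        d = DistanceMatrix(
            ["S1_BL", "S1_W6"], np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        with pytest.warns(UserWarning, match="fewer than two"):
            inter, _ = beta_dispersion_summaries(d, MetadataTable(recs))
        assert inter.empty

    def test_missing_baseline_excluded_with_warning(self):
        recs = [
            SampleMetadata("S1_BL", "S1", "AX", "female", 25.0, "BL"),
            SampleMetadata("S1_W6", "S1", "AX", "female", 25.0, "W6"),
            SampleMetadata("S2_W6", "S2", "AX", "female", 25.0, "W6"),
        ]
        rng = np.random.default_rng(1)
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(
            ["S1_BL", "S1_W6", "S2_W6"], squareform(pdist(rng.standard_normal((3, 2))))
        )
        with pytest.warns(UserWarning, match="lacks baseline"):
            _, intra = beta_dispersion_summaries(d, MetadataTable(recs))
        assert set(intra.subject_id) == {"S1"}
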