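import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from timedrivers.core_model import ExpressionMatrix
from timedrivers.time_features import (
    Feature,
    ScoringMethod,
    SignatureDef,
    SignatureError,
    compute_time_levels,
    levels_by_cluster,
    levels_by_quartile,
    score_mean_log2,
    score_ssgsea,
)


def _expr(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestMeanLog2:
    def test_zero_fpkm_scores_zero(self):
        e = _expr([[0.0], [0.0]])
        assert score_mean_log2(e, ["g0", "g1"]).iloc[0] == 0.0

    def test_closed_form(self):
        e = _expr([[1.0], [3.0]])
        assert score_mean_log2(e, ["g0", "g1"]).iloc[0] == pytest.approx(1.5)

    def test_ten_gene_fixture_matches_hand_computation(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 50, size=(10, 4))
        e = _expr(vals)
        got = score_mean_log2(e, [f"g{i}" for i in range(10)])
        expected = np.log2(vals + 1).mean(axis=0)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)

    def test_absent_genes_error(self):
        with pytest.raises(SignatureError, match="CPI"):
            score_mean_log2(_expr([[1.0]]), ["nope"], feature="CPI")

    @given(st.integers(0, 9), st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_any_signature_gene(self, gene_idx, bump):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 20, size=(10, 3))
        genes = [f"g{i}" for i in range(10)]
        base = score_mean_log2(_expr(vals.copy()), genes)
        vals2 = vals.copy()
        vals2[gene_idx] += bump
        raised = score_mean_log2(_expr(vals2), genes)
        assert (raised >= base - 1e-12).all()


class TestSsgsea:
    def test_top_genes_signature_is_maximal(self):
        """The |S| highest-expressed genes maximize the score over all
        gene sets of that size (checked by full enumeration)."""
        rng = np.random.default_rng(2)
        vals = rng.permutation(np.arange(1.0, 9.0))[:, None]
        genes = [f"g{i}" for i in range(8)]
        e = _expr(vals, genes=genes)
        top3 = [genes[i] for i in np.argsort(-vals[:, 0])[:3]]
        top_score = score_ssgsea(e, top3).iloc[0]
        for combo in itertools.combinations(genes, 3):
            assert score_ssgsea(e, list(combo)).iloc[0] <= top_score + 1e-12

    def test_random_signature_mean_near_zero(self):
        rng = np.random.default_rng(3)
        scores = []
        genes = [f"g{i}" for i in range(30)]
        for _ in range(300):
            vals = rng.uniform(0, 10, size=(30, 1))
            e = _expr(vals, genes=genes)
            sig = list(rng.choice(genes, size=5, replace=False))
            scores.append(score_ssgsea(e, sig).iloc[0])
        assert abs(np.mean(scores)) < 0.5  # scores span roughly [-8, 8]

    def test_reversal_negates_score(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 10, size=(20, 1))
        genes = [f"g{i}" for i in range(20)]
        sig = genes[::4]
        s_fwd = score_ssgsea(_expr(vals, genes=genes), sig).iloc[0]
        # reverse the ranking: any strictly decreasing transform
        s_rev = score_ssgsea(_expr(-vals + 11.0, genes=genes), sig).iloc[0]
        assert s_rev == pytest.approx(-s_fwd, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.1, 10, size=(15, 3))
        genes = [f"g{i}" for i in range(15)]
        sig = genes[:4]
        s1 = score_ssgsea(_expr(vals, genes=genes), sig)
        s2 = score_ssgsea(_expr(np.log(vals) * 3 + 7, genes=genes), sig)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_constant_sample_warns_and_zeroes(self):
        e = _expr(np.ones((6, 1)))
        with pytest.warns(UserWarning, match="constant"):
            s = score_ssgsea(e, ["g0", "g1"])
        assert s.iloc[0] == 0.0


class TestQuartileLevels:
    def test_exact_quartiles_on_1_to_8(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
        groups = pd.Series("A", index=scores.index)
        lv = levels_by_quartile(scores, groups)
        assert list(lv) == [1, 1, 2, 2, 2, 2, 3, 3]

    def test_all_identical_scores_are_low(self):
        scores = pd.Series(2.0, index=[f"s{i}" for i in range(6)])
        lv = levels_by_quartile(scores, pd.Series("A", index=scores.index))
        assert (lv == 1).all()   # ties collapse onto Q1: the <=Q1 rule wins

    def test_groups_discretized_independently(self):
        scores = pd.Series([1, 2, 3, 4, 101, 102, 103, 104.0],
                           index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=scores.index)
        lv = levels_by_quartile(scores, groups)
        # B's minimum (101) is low within B despite being the cohort maximum range
        assert lv["s4"] == 1 and lv["s7"] == 3
        assert lv["s0"] == 1 and lv["s3"] == 3

    def test_small_group_goes_medium_with_warning(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="<4"):
            lv = levels_by_quartile(scores, pd.Series("A", index=scores.index))
        assert (lv == 2).all()

    def test_tie_free_composition(self):
        """With no ties the low/high groups hold the expected quartile mass
        and the three levels partition the samples."""
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.permutation(np.arange(100.0)),
                           index=[f"s{i}" for i in range(100)])
        lv = levels_by_quartile(scores, pd.Series("A", index=scores.index))
        assert (lv == 1).sum() == 25
        assert (lv == 3).sum() == 25
        assert (lv == 2).sum() == 50


class TestClusterLevels:
    def test_planted_blobs_recovered_in_score_order(self):
        rng = np.random.default_rng(7)
        centers = [0.0, 5.0, 10.0]
        blocks = [rng.normal(c, 0.2, size=(20, 4)) for c in centers]
        vals = np.vstack(blocks).T
        samples = [f"s{i:02d}" for i in range(60)]
        e = _expr(vals, genes=[f"g{i}" for i in range(4)], samples=samples)
        _, lv = levels_by_cluster(e, [f"g{i}" for i in range(4)], k=3,
                                  level_map={1: 1, 2: 2, 3: 3})
        assert (lv[samples[:20]] == 1).all()
        assert (lv[samples[20:40]] == 2).all()
        assert (lv[samples[40:]] == 3).all()

    def test_k1_single_level(self):
        rng = np.random.default_rng(8)
        e = _expr(rng.uniform(0, 5, size=(3, 10)))
        _, lv = levels_by_cluster(e, ["g0", "g1", "g2"], k=1, level_map={1: 2})
        assert (lv == 2).all()

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 5, size=(4, 30))
        genes = [f"g{i}" for i in range(4)]
        samples = [f"s{i:02d}" for i in range(30)]
        e1 = _expr(vals, genes=genes, samples=samples)
        perm = rng.permutation(30)
        e2 = ExpressionMatrix(e1.values.iloc[:, perm])
        _, lv1 = levels_by_cluster(e1, genes, k=3, level_map={1: 1, 2: 2, 3: 3})
        _, lv2 = levels_by_cluster(e2, genes, k=3, level_map={1: 1, 2: 2, 3: 3})
        pd.testing.assert_series_equal(lv1.sort_index(), lv2.sort_index(),
                                       check_names=False)

    def test_too_few_samples_error(self):
        e = _expr(np.ones((2, 2)) * [[1.0, 2.0]])
        with pytest.raises(SignatureError, match="< k"):
            levels_by_cluster(e, ["g0", "g1"], k=5, level_map={})


class TestComputeTimeLevels:
    def test_scores_track_latent_axes(self, planted_cohort):
        cohort, truth = planted_cohort
        defs = [SignatureDef(feature=f, genes=truth.signatures[f],
                             method=ScoringMethod.MEAN_LOG2)
                for f in (Feature.IS, Feature.CPI)]
        table = compute_time_levels(cohort, defs)
        for f in ("IS", "CPI"):
            rho = spearmanr(table.scores[f], truth.latent_scores[f]).statistic
            assert rho > 0.5

    def test_row_count(self, planted_cohort):
        cohort, truth = planted_cohort
        defs = [SignatureDef(feature=f, genes=truth.signatures[f],
                             method=ScoringMethod.MEAN_LOG2) for f in Feature]
        table = compute_time_levels(cohort, defs)
        long = table.to_long_frame()
        assert len(long) == len(cohort.samples) * len(list(Feature))

    def test_feature_with_absent_genes_errors(self, planted_cohort):
        cohort, _ = planted_cohort
        defs = [SignatureDef(feature=Feature.TIS, genes=["missing1", "missing2"])]
        with pytest.raises(SignatureError, match="TIS"):
            compute_time_levels(cohort, defs)
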