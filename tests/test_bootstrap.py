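"""Spearman bootstrap, ROC thresholding and stability scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfsignals.bootstrap import (
    BootstrapResult,
    StabilityScores,
    bootstrap_correlations,
    fpr_threshold,
    median_roc_threshold,
    roc_for_sample,
    select_stability_threshold,
    spearman,
    stability_scores,
)
from tfsignals.datamodel import (
    KnownInteractionSet,
    MetaboliteAbundanceMatrix,
    TFActivityMatrix,
)


def _act(values, tfs=None):
    values = np.asarray(values, dtype=float)
    tfs = tfs or [f"t{i}" for i in range(values.shape[0])]
    conds = [f"c{j}" for j in range(values.shape[1])]
    return TFActivityMatrix(values=pd.DataFrame(values, index=tfs, columns=conds))


def _met(values, mets=None):
    values = np.asarray(values, dtype=float)
    mets = mets or [f"m{i}" for i in range(values.shape[0])]
    conds = [f"c{j}" for j in range(values.shape[1])]
    return MetaboliteAbundanceMatrix(
        values=pd.DataFrame(values, index=mets, columns=conds)
    )


def _known(pairs, effect="activating"):
    return KnownInteractionSet(
        entries=pd.DataFrame(
            [{"tf": t, "metabolite": m, "effect": effect} for t, m in pairs]
        )
    )


class TestSpearman:
    def test_monotone_identity(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0, abs=1e-12)
        assert spearman(x, -(x**3)) == pytest.approx(-1.0, abs=1e-12)

    def test_tie_handling_matches_scipy(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        # independent oracle: Pearson correlation of average ranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected)
        assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_constant_profile_missing(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [1.0, 2.0])


class TestBootstrapCorrelations:
    def test_pair_count_conservation(self):
        rng = np.random.default_rng(20)
        boot = bootstrap_correlations(
            _act(rng.standard_normal((7, 12))),
            _met(rng.uniform(1, 5, (11, 12))),
            n_samples=10,
            subsample_size=8,
            seed=0,
        )
        assert boot.n_pairs == 77
        assert boot.mean_correlation.shape == (7, 11)

    def test_no_resampling_limit(self):
        rng = np.random.default_rng(21)
        A = rng.standard_normal((3, 10))
        M = rng.uniform(1, 5, (4, 10))
        boot = bootstrap_correlations(
            _act(A), _met(M), n_samples=5, subsample_size=10, seed=0
        )
        assert np.allclose(boot.samples.std(axis=0), 0.0, atol=1e-7)
        for i in range(3):
            for j in range(4):
                assert boot.mean_correlation.iloc[i, j] == pytest.approx(
                    spearman(A[i], M[j]), abs=1e-6
                )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(22)
        A, M = rng.standard_normal((4, 15)), rng.uniform(1, 5, (5, 15))
        b1 = bootstrap_correlations(_act(A), _met(M), 20, 10, seed=9)
        b2 = bootstrap_correlations(_act(A), _met(M), 20, 10, seed=9)
        np.testing.assert_array_equal(b1.samples, b2.samples)
        pd.testing.assert_frame_equal(b1.mean_correlation, b2.mean_correlation)

    def test_planted_pair_strongly_correlated(self, default_bundle, pipeline_result):
        boot = pipeline_result.bootstrap
        for tf, m in default_bundle.planted_pairs("activating"):
            assert boot.mean_correlation.at[tf, m] > 0.8, (tf, m)

    def test_oversized_subsample_rejected(self):
        rng = np.random.default_rng(23)
        with pytest.raises(ValueError):
            bootstrap_correlations(
                _act(rng.standard_normal((2, 5))),
                _met(rng.uniform(1, 2, (2, 5))),
                n_samples=2,
                subsample_size=6,
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(24)
        A = rng.standard_normal((4, 12))
        M = rng.uniform(1, 5, (5, 12))
        b1 = bootstrap_correlations(_act(A), _met(M), 15, 9, seed=3)
        b2 = bootstrap_correlations(
            _act(np.exp(A)), _met(M**3), 15, 9, seed=3
        )
        np.testing.assert_allclose(b1.samples, b2.samples, atol=1e-6)


class TestROC:
    def test_perfect_separation_auc_one(self):
        flat = pd.Series(
            [0.9, 0.8, 0.1, 0.0],
            index=pd.MultiIndex.from_tuples(
                [("t1", "m1"), ("t1", "m2"), ("t1", "m3"), ("t1", "m4")],
                names=["tf", "metabolite"],
            ),
        )
        curve = roc_for_sample(flat, _known([("t1", "m1"), ("t1", "m2")]))
        assert curve.auc == 1.0

    def test_single_positive_below_all_auc_zero(self):
        flat = pd.Series(
            [0.9, 0.8, -0.5],
            index=pd.MultiIndex.from_tuples(
                [("t1", "m1"), ("t1", "m2"), ("t1", "m3")],
                names=["tf", "metabolite"],
            ),
        )
        assert roc_for_sample(flat, _known([("t1", "m3")])).auc == 0.0

    def test_auc_equals_mannwhitney_u(self):
        # tie-corrected U / (P * N) oracle on 100 seeded score/label sets
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            scores = np.round(rng.uniform(-1, 1, n), 1)  # force ties
            labels = rng.uniform(size=n) < 0.3
            if not labels.any() or labels.all():
                continue
            flat = pd.Series(
                scores,
                index=pd.MultiIndex.from_tuples(
                    [("t", f"m{i}") for i in range(n)], names=["tf", "metabolite"]
                ),
            )
            known = _known([("t", f"m{i}") for i in np.flatnonzero(labels)])
            auc = roc_for_sample(flat, known).auc
            u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
            assert auc == pytest.approx(u / (labels.sum() * (~labels).sum()))

    def test_random_labels_median_auc_half(self):
        rng = np.random.default_rng(6)
        aucs = []
        for _ in range(100):
            scores = rng.uniform(-1, 1, 200)
            labels = np.zeros(200, dtype=bool)
            labels[rng.choice(200, 20, replace=False)] = True
            flat = pd.Series(
                scores,
                index=pd.MultiIndex.from_tuples(
                    [("t", f"m{i}") for i in range(200)], names=["tf", "metabolite"]
                ),
            )
            known = _known([("t", f"m{i}") for i in np.flatnonzero(labels)])
            aucs.append(roc_for_sample(flat, known).auc)
        assert abs(np.median(aucs) - 0.5) < 0.05

    def test_inactivating_effect_negates_scores(self):
        flat = pd.Series(
            [-0.9, 0.1, 0.8],
            index=pd.MultiIndex.from_tuples(
                [("t1", "m1"), ("t1", "m2"), ("t1", "m3")],
                names=["tf", "metabolite"],
            ),
        )
        known = _known([("t1", "m1")], effect="inactivating")
        assert roc_for_sample(flat, known, effect="inactivating").auc == 1.0


class TestFprThreshold:
    def test_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(20, 60))
            scores = np.round(rng.uniform(-1, 1, n), 1)
            labels = rng.uniform(size=n) < 0.2
            neg = scores[~labels]
            if neg.size == 0:
                continue
            got = fpr_threshold(scores, labels, 0.1)
            # brute force: smallest observed score value with FPR <= 0.1
            candidates = [
                t for t in np.unique(scores)
                if (neg > t).sum() / neg.size <= 0.1
            ]
            assert got == min(candidates)


class TestMedianRocThreshold:
    def _result(self, samples, tfs, mets):
        samples = np.asarray(samples, dtype=np.float32)
        mean = samples.mean(axis=0)
        return BootstrapResult(
            tfs=tfs,
            metabolites=mets,
            mean_correlation=pd.DataFrame(mean, index=tfs, columns=mets),
            samples=samples,
            n_samples=samples.shape[0],
            subsample_size=3,
            seed=0,
        )

    def test_degenerate_bootstrap_equals_single_sample(self):
        one = np.array([[0.9, 0.5, 0.1, -0.2]]).reshape(1, 1, 4)
        res = self._result(np.repeat(one, 7, axis=0), ["t1"], list("abcd"))
        known = _known([("t1", "a")])
        thr, _ = median_roc_threshold(res, known, target_fpr=0.1)
        flat = pd.Series(
            one[0].ravel(),
            index=pd.MultiIndex.from_product([["t1"], list("abcd")]),
        )
        labels = np.array([True, False, False, False])
        assert thr == fpr_threshold(one[0].ravel(), labels, 0.1)

    def test_separable_threshold_in_gap(self):
        rng = np.random.default_rng(8)
        samples = []
        for _ in range(10):
            pos = rng.uniform(0.7, 0.9, 2)
            neg = rng.uniform(-0.3, 0.2, 6)
            samples.append(np.concatenate([pos, neg]).reshape(1, 8))
        res = self._result(np.stack(samples), ["t1"], [f"m{i}" for i in range(8)])
        known = _known([("t1", "m0"), ("t1", "m1")])
        thr, curve = median_roc_threshold(res, known, target_fpr=0.1)
        # smallest qualifying threshold is the top negative score, i.e. the
        # lower edge of the separation gap; positives all lie above it
        assert -0.3 <= thr < 0.7
        assert curve["tpr"].iloc[-1] == 1.0
        assert (np.stack(samples)[:, 0, :2] > thr).mean() > 0.9

    def test_median_of_per_sample_thresholds(self):
        rng = np.random.default_rng(9)
        samples = rng.uniform(-1, 1, size=(20, 2, 10)).astype(np.float32)
        tfs, mets = ["t1", "t2"], [f"m{i}" for i in range(10)]
        res = self._result(samples, tfs, mets)
        known = _known([("t1", "m0"), ("t2", "m3")])
        thr, _ = median_roc_threshold(res, known, target_fpr=0.1)
        labels = np.zeros(20, dtype=bool)
        labels[[0, 13]] = True  # flattened positions of the known pairs
        per_sample = [
            fpr_threshold(samples[s].ravel().astype(float), labels, 0.1)
            for s in range(20)
        ]
        assert thr == pytest.approx(np.median(per_sample))


class TestStability:
    def _result(self, samples):
        samples = np.asarray(samples, dtype=np.float32)[:, None, :]
        return BootstrapResult(
            tfs=["t1"],
            metabolites=[f"m{i}" for i in range(samples.shape[2])],
            mean_correlation=pd.DataFrame(
                samples.mean(axis=0), index=["t1"],
                columns=[f"m{i}" for i in range(samples.shape[2])],
            ),
            samples=samples,
            n_samples=samples.shape[0],
            subsample_size=3,
            seed=0,
        )

    def test_all_above_and_none_above(self):
        res = self._result(np.column_stack([np.full(1000, 0.9), np.full(1000, 0.1)]))
        stab = stability_scores(res, threshold=0.5)
        assert stab.values.at["t1", "m0"] == 1.0
        assert stab.values.at["t1", "m1"] == 0.0

    def test_proportion_arithmetic(self):
        col = np.concatenate([np.full(128, 0.9), np.full(872, 0.1)])
        res = self._result(col.reshape(-1, 1))
        stab = stability_scores(res, threshold=0.5)
        assert stab.values.at["t1", "m0"] == pytest.approx(0.128)

    def test_strictly_exceeds_rule(self):
        res = self._result(np.full((10, 1), 0.5))
        assert stability_scores(res, threshold=0.5).values.at["t1", "m0"] == 0.0


class TestSelectStabilityThreshold:
    def _scores(self, values, mets):
        return StabilityScores(
            values=pd.DataFrame([values], index=["t1"], columns=mets),
            threshold=0.3,
        )

    def test_separable_case_retains_known_set(self):
        scores = self._scores([1.0, 1.0, 0.4, 0.2], list("abcd"))
        known = _known([("t1", "a"), ("t1", "b")])
        cut = select_stability_threshold(scores, known)
        assert cut == 1.0

    def test_degenerate_identical_scores(self):
        scores = self._scores([0.7, 0.7, 0.7], list("abc"))
        cut = select_stability_threshold(scores, _known([("t1", "a")]))
        assert cut == 0.7

    def test_bruteforce_argmax_oracle(self):
        rng = np.random.default_rng(10)
        vals = np.round(rng.uniform(0, 1, 50), 2)
        mets = [f"m{i}" for i in range(50)]
        known_idx = rng.choice(50, 5, replace=False)
        scores = self._scores(vals, mets)
        known = _known([("t1", f"m{i}") for i in known_idx])
        got = select_stability_threshold(scores, known)
        known_mask = np.zeros(50, dtype=bool)
        known_mask[known_idx] = True
        best, best_ratio = None, -1.0
        for cut in sorted(np.unique(vals)):
            kept = vals >= cut
            ratio = (kept & known_mask).sum() / kept.sum()
            if ratio >= best_ratio:
                best_ratio, best = ratio, cut
        assert got == pytest.approx(best)

    def test_no_known_pairs_rejected(self):
        scores = self._scores([0.5], ["a"])
        with pytest.raises(ValueError):
            select_stability_threshold(scores, _known([("tX", "zz")]))
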