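"""FDR/ROC evaluation and the Poisson-vs-NB overdispersion test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ebcount import FDRCurve, ROCCurve, fdr_curve, mean_curves, roc_curve
from ebcount.evaluate import overdispersion_lrt


def brute_force_roc(scores, truth):
    """Oracle: enumerate every threshold, computing (fpr, tpr) directly."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for thr in np.unique(scores):
        sel = scores >= thr
        pts.add(
            (
                np.sum(sel & ~truth) / np.sum(~truth),
                np.sum(sel & truth) / np.sum(truth),
            )
        )
    return sorted(pts)


class TestFDRCurve:
    def test_hand_counted_example(self):
        truth = pd.Series({"a": True, "b": False, "c": True})
        c = fdr_curve(["a", "b", "c"], truth, depths=[1, 2, 3])
        np.testing.assert_allclose(c.fdr, [0.0, 0.5, 1.0 / 3.0])
        np.testing.assert_array_equal(c.fp_count, [0, 1, 1])

    def test_perfect_ranking_has_zero_fdr(self):
        truth = pd.Series({f"t{i}": i < 5 for i in range(10)})
        c = fdr_curve([f"t{i}" for i in range(10)], truth, depths=[1, 3, 5])
        np.testing.assert_array_equal(c.fdr, 0.0)

    def test_unlabeled_id_raises(self):
        with pytest.raises(KeyError, match="mystery"):
            fdr_curve(["a", "mystery"], pd.Series({"a": True, "b": False}))

    def test_random_ranking_expectation(self, rng):
        # 1000 DE in 10000: expected FDR at any depth is 0.9
        ids = [f"t{i}" for i in range(10000)]
        truth = pd.Series(dict(zip(ids, [True] * 1000 + [False] * 9000)))
        fdrs = []
        for _ in range(10):
            order = rng.permutation(ids)
            fdrs.append(fdr_curve(order, truth, depths=[500]).fdr[0])
        assert np.mean(fdrs) == pytest.approx(0.9, abs=0.02)

    def test_invariants(self, rng):
        ids = [f"t{i}" for i in range(50)]
        truth = pd.Series(dict(zip(ids, rng.random(50) < 0.4)))
        c = fdr_curve(rng.permutation(ids), truth)
        assert np.all(np.diff(c.fp_count) >= 0)
        assert np.all(c.fp_count <= c.depths)
        assert np.all((c.fdr >= 0) & (c.fdr <= 1))


class TestROCCurve:
    def test_perfect_separation(self):
        c = roc_curve([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert c.auc == pytest.approx(1.0)
        assert (0.0, 1.0) in set(zip(c.fpr, c.tpr))

    def test_constant_scores_give_diagonal(self):
        c = roc_curve([0.5] * 6, [True, False, True, False, False, True])
        assert c.auc == pytest.approx(0.5)
        assert c.fpr[0] == 0 and c.tpr[0] == 0
        assert c.fpr[-1] == 1 and c.tpr[-1] == 1

    def test_degenerate_truth_raises(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [True, True])

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(4, 13)
            scores = rng.choice([0.1, 0.3, 0.5, 0.9], size=n)
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            c = roc_curve(scores, truth)
            assert sorted(set(zip(c.fpr, c.tpr))) == brute_force_roc(scores, truth)

    def test_exhaustive_tiny_instances(self):
        # all labelings and tie configurations for n <= 6 tuples
        score_pool = [0.2, 0.8]
        for n in (3, 4, 6):
            for scores in itertools.product(score_pool, repeat=n):
                for k in range(1, n):
                    truth = np.array([True] * k + [False] * (n - k))
                    c = roc_curve(np.array(scores), truth)
                    assert sorted(set(zip(c.fpr, c.tpr))) == brute_force_roc(
                        scores, truth
                    )
                    assert np.all(np.diff(c.fpr) >= 0)
                    assert np.all(np.diff(c.tpr) >= 0)


class TestMeanCurves:
    def test_identical_replicates(self):
        c = FDRCurve(depths=[1, 2], fdr=[0.0, 0.5], fp_count=[0, 1])
        m = mean_curves([c, c, c])
        np.testing.assert_allclose(m.fdr, c.fdr)
        np.testing.assert_allclose(m.se, 0.0)

    def test_two_replicate_arithmetic(self):
        a = FDRCurve(depths=[200], fdr=[0.05], fp_count=[10])
        b = FDRCurve(depths=[200], fdr=[0.10], fp_count=[20])
        m = mean_curves([a, b])
        assert m.fp_count[0] == pytest.approx(15.0)
        assert m.se[0] == pytest.approx(5.0)  # sd/sqrt(2) = (5*sqrt2)/sqrt2

    def test_mismatched_grids_raise(self):
        a = FDRCurve(depths=[1, 2], fdr=[0, 0], fp_count=[0, 0])
        b = FDRCurve(depths=[1, 3], fdr=[0, 0], fp_count=[0, 0])
        with pytest.raises(ValueError, match="mismatched"):
            mean_curves([a, b])

    def test_replicate_order_invariance(self, rng):
        curves = [
            FDRCurve(depths=[100], fdr=[f / 100], fp_count=[f])
            for f in rng.integers(0, 50, 8)
        ]
        m1 = mean_curves(curves)
        m2 = mean_curves(curves[::-1])
        np.testing.assert_allclose(m1.fp_count, m2.fp_count)
        np.testing.assert_allclose(m1.se, m2.se)

    def test_se_matches_sampling_distribution(self, rng):
        # fp ~ Binomial(200, 0.3): SE of the mean over 100 reps is sigma/10
        sigma = np.sqrt(200 * 0.3 * 0.7)
        curves = [
            FDRCurve(depths=[200], fdr=[0], fp_count=[rng.binomial(200, 0.3)])
            for _ in range(100)
        ]
        m = mean_curves(curves)
        assert abs(m.se[0] - sigma / 10) / (sigma / 10) < 0.3

    def test_roc_interpolated_mean(self):
        a = ROCCurve(fpr=[0, 0, 1], tpr=[0, 1, 1])  # perfect
        b = ROCCurve(fpr=[0, 1], tpr=[0, 1])  # diagonal
        m = mean_curves([a, b])
        assert m.auc == pytest.approx(0.75, abs=0.01)


class TestOverdispersionLRT:
    def test_constant_counts_no_signal(self):
        r = overdispersion_lrt([5, 5, 5, 5], [1.0] * 4, ["A", "A", "B", "B"])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_all_zero_tuple(self):
        r = overdispersion_lrt([0, 0, 0, 0], [1.0] * 4, ["A", "A", "B", "B"])
        assert r.pvalue == 1.0
        assert r.mean_expression == 0.0

    def test_null_calibration_on_poisson_data(self):
        # type-I error at nominal 5% stays at or below 5% (+3 binomial SEs)
        from ebcount import CountData
        from ebcount.evaluate import overdispersion_lrt_table

        rng = np.random.default_rng(21)
        C = 5000
        lib = rng.uniform(800, 1200, 6)
        lam = rng.uniform(0.005, 0.05, C)
        counts = rng.poisson(lam[:, None] * lib[None, :])
        data = CountData(counts=counts, lib_sizes=lib)
        table = overdispersion_lrt_table(data, ["A"] * 3 + ["B"] * 3)
        rej = (table["pvalue"] < 0.05).mean()
        assert rej <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / C)

    def test_power_on_overdispersed_data(self):
        rng = np.random.default_rng(22)
        lib = np.full(6, 1000.0)
        groups = ["A"] * 3 + ["B"] * 3
        phi, lam = 1.0, 0.1  # high mean, strong overdispersion
        r = 1 / phi
        hits = 0
        n_draws = 40
        for _ in range(n_draws):
            counts = rng.negative_binomial(r, r / (r + lam * lib))
            if overdispersion_lrt(counts, lib, groups).pvalue < 1e-4:
                hits += 1
        assert hits / n_draws > 0.9

    def test_boundary_correction_halves_pvalue(self):
        rng = np.random.default_rng(23)
        counts = rng.negative_binomial(2.0, 0.05, 6)
        lib = np.full(6, 1.0)
        groups = ["A"] * 3 + ["B"] * 3
        a = overdispersion_lrt(counts, lib, groups, boundary_correction=True)
        b = overdispersion_lrt(counts, lib, groups, boundary_correction=False)
        if a.statistic > 0:
            assert a.pvalue == pytest.approx(b.pvalue / 2)
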