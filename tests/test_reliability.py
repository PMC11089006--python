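"""NMI, split-half reliability, brain-behavior vectors, rise-to-max fits."""

import numpy as np
import pytest

from precisionmap.gray_model import DenseTimeseries, GrayordinateSpace, LabelMap
from precisionmap.reliability import (brain_behavior_vector, fit_rise_to_max,
                                      nmi, split_half, split_timeseries,
                                      subset_reliability)


def space_of(n, rng):
    return GrayordinateSpace(structure=np.array(["LEFT_CORTEX"] * n),
                             coords=rng.normal(size=(n, 3)) * 40)


class TestNMI:
    def test_identical_maps_score_one(self, rng):
        sp = space_of(300, rng)
        labels = rng.integers(1, 5, size=300)
        lm = LabelMap(space=sp, labels=labels)
        assert nmi(lm, lm) == pytest.approx(1.0)

    def test_invariant_to_relabeling(self, rng):
        sp = space_of(300, rng)
        labels = rng.integers(1, 5, size=300)
        perm = {1: 3, 2: 4, 3: 1, 4: 2}
        permuted = np.array([perm[l] for l in labels])
        a = LabelMap(space=sp, labels=labels)
        b = LabelMap(space=sp, labels=permuted)
        assert nmi(a, b) == pytest.approx(1.0)

    def test_independent_maps_score_near_zero(self, rng):
        sp = space_of(10_000, rng)
        a = LabelMap(space=sp, labels=rng.integers(1, 5, size=10_000))
        b = LabelMap(space=sp, labels=rng.integers(1, 5, size=10_000))
        assert nmi(a, b) < 0.02

    def test_symmetric(self, rng):
        sp = space_of(200, rng)
        a = LabelMap(space=sp, labels=rng.integers(0, 4, size=200))
        b = LabelMap(space=sp, labels=rng.integers(0, 4, size=200))
        assert nmi(a, b) == pytest.approx(nmi(b, a))

    def test_unassigned_excluded_pairwise(self, rng):
        sp = space_of(400, rng)
        labels = rng.integers(1, 4, size=400)
        a = LabelMap(space=sp, labels=labels)
        noisy = labels.copy()
        noisy[:200] = 0              # half unassigned in b
        b = LabelMap(space=sp, labels=noisy)
        assert nmi(a, b) == pytest.approx(1.0)  # agreement where both assigned

    def test_no_joint_assignment_rejected(self, rng):
        sp = space_of(10, rng)
        a = LabelMap(space=sp, labels=np.r_[np.ones(5, int), np.zeros(5, int)])
        b = LabelMap(space=sp, labels=np.r_[np.zeros(5, int), np.ones(5, int)])
        with pytest.raises(ValueError, match="jointly"):
            nmi(a, b)


class TestSplitHalf:
    def test_interleaved_split_shapes(self, rng):
        sp = space_of(50, rng)
        ts = DenseTimeseries(space=sp, tr_seconds=0.8,
                             values=rng.normal(size=(101, 50)))
        h1, h2 = split_timeseries(ts, "interleaved")
        assert h1.n_frames == 51 and h2.n_frames == 50
        assert np.array_equal(h1.values[0], ts.values[0])
        assert np.array_equal(h2.values[0], ts.values[1])

    def test_identical_halves_give_intra_one(self, rng):
        sp = space_of(60, rng)
        cohort = []
        for i in range(4):
            half = np.random.default_rng(i).normal(size=(20, 60))
            vals = np.empty((40, 60))
            vals[0::2] = half
            vals[1::2] = half           # interleaved halves identical
            cohort.append(DenseTimeseries(space=sp, tr_seconds=0.8,
                                          values=vals))

        def mapper(ts):
            # deterministic mapper: threshold the first frame
            labels = (ts.values[0] > 0).astype(int) + 1
            return LabelMap(space=sp, labels=labels, palette=("DMN", "Vis"))

        res = split_half(cohort, mapper)
        assert np.allclose(res.intra_nmi, 1.0)

    def test_separates_distinct_participants(self, tiny_cohort,
                                             tiny_templates):
        from precisionmap.pipeline import _tm_mapper

        cohort = [p.timeseries for p in tiny_cohort.participants]
        res = split_half(cohort, _tm_mapper(tiny_templates, 1.0))
        assert res.intra_nmi.mean() > res.inter_nmi.mean()
        assert res.p_value < 0.01
        assert res.variance_assumption == "unequal"
        assert res.tail == "one"

    def test_reproducible_result_object(self, tiny_cohort, tiny_templates):
        from precisionmap.pipeline import _tm_mapper

        cohort = [p.timeseries for p in tiny_cohort.participants[:3]]
        a = split_half(cohort, _tm_mapper(tiny_templates, 1.0))
        b = split_half(cohort, _tm_mapper(tiny_templates, 1.0))
        assert np.array_equal(a.intra_nmi, b.intra_nmi)
        assert a.t_statistic == b.t_statistic


class TestBrainBehavior:
    def test_behavior_equal_to_edge_gives_r_one(self, rng):
        stack = rng.normal(size=(30, 5, 5))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        iu = np.triu_indices(5, k=1)
        behavior = stack[:, iu[0][3], iu[1][3]]
        r = brain_behavior_vector(stack, behavior)
        assert r[3] == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_edge_scalar_oracle(self, rng):
        stack = rng.normal(size=(20, 4, 4))
        behavior = rng.normal(size=20)
        r = brain_behavior_vector(stack, behavior)
        iu = np.triu_indices(4, k=1)
        for e, (i, j) in enumerate(zip(*iu)):
            expected = np.corrcoef(stack[:, i, j], behavior)[0, 1]
            assert r[e] == pytest.approx(expected, abs=1e-9)

    def test_independent_behavior_small_and_symmetric(self, rng):
        stack = rng.normal(size=(100, 8, 8))
        behavior = rng.normal(size=100)
        r = brain_behavior_vector(stack, behavior)
        assert np.abs(r).max() < 0.5
        assert abs(np.mean(r)) < 0.1

    def test_zero_variance_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            brain_behavior_vector(rng.normal(size=(10, 3, 3)), np.ones(10))

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError, match="4"):
            brain_behavior_vector(rng.normal(size=(3, 3, 3)), np.arange(3))


class TestSubsetReliability:
    @pytest.fixture()
    def group(self, rng):
        n, p = 60, 6
        stack = np.stack([np.corrcoef(rng.normal(size=(p, 40)))
                          for _ in range(n)])
        iu = np.triu_indices(p, k=1)
        behavior = stack[:, iu[0][0], iu[1][0]] + rng.normal(
            scale=0.05, size=n)
        return stack, behavior

    def test_full_sample_vs_own_reference_is_one(self, group):
        stack, behavior = group
        ref = brain_behavior_vector(stack, behavior)
        curve = subset_reliability(stack, behavior, ref,
                                   sizes=[10, 30, len(stack)], reps=3,
                                   seed=0, fit=False)
        assert curve.correlations[-1] == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_reproduces_curve(self, group):
        stack, behavior = group
        ref = brain_behavior_vector(stack, behavior)
        a = subset_reliability(stack, behavior, ref, sizes=[8, 20], reps=4,
                               seed=9, fit=False)
        b = subset_reliability(stack, behavior, ref, sizes=[8, 20], reps=4,
                               seed=9, fit=False)
        assert np.array_equal(a.correlations, b.correlations)

    def test_reliability_grows_with_sample_size(self, group):
        stack, behavior = group
        ref = brain_behavior_vector(stack, behavior)
        curve = subset_reliability(stack, behavior, ref,
                                   sizes=[6, 15, 40], reps=20, seed=1,
                                   fit=False)
        assert curve.means[0] < curve.means[-1]

    def test_size_below_four_rejected(self, group):
        stack, behavior = group
        with pytest.raises(ValueError, match="4"):
            subset_reliability(stack, behavior, np.zeros(15), sizes=[3],
                               reps=2, seed=0)


class TestFitRiseToMax:
    def test_noiseless_parameters_recovered(self):
        x = np.array([10, 25, 50, 100, 200, 400, 800, 1600], dtype=float)
        y = 0.3 + 0.6 * (1 - np.exp(-0.004 * x))
        fit = fit_rise_to_max(x, y)
        assert fit.y0 == pytest.approx(0.3, abs=1e-6)
        assert fit.a == pytest.approx(0.6, abs=1e-6)
        assert fit.b == pytest.approx(0.004, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_response_flagged_degenerate(self):
        fit = fit_rise_to_max(np.array([1.0, 2, 3, 4]),
                              np.full(4, 0.7))
        assert fit.degenerate
        assert fit.a == pytest.approx(0.0, abs=1e-9)

    def test_noisy_rate_recovered_within_twenty_percent(self, rng):
        sizes = np.array([10, 25, 50, 100, 200, 400, 800, 1600], dtype=float)
        x = np.repeat(sizes, 10)
        y = 0.3 + 0.6 * (1 - np.exp(-0.004 * x))
        y = y + rng.normal(scale=0.02, size=len(y))
        fit = fit_rise_to_max(x, y)
        assert fit.b == pytest.approx(0.004, rel=0.2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rise_to_max(np.array([1.0, 2, 3]), np.array([0.1, 0.2, 0.3]))
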