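"""Probabilistic atlases, ROI derivation, integration zones, parcel stats."""

import numpy as np
import pytest

from precisionmap.atlas import (IntegrationZoneMap, Parcellation,
                                ProbabilityAtlas, derive_roiset,
                                integration_zones, network_block_stats,
                                parcel_connectivity, parcellate_timeseries,
                                probability_maps)
from precisionmap.gray_model import (DenseTimeseries, GrayordinateSpace,
                                     LabelMap, OverlapMap, ScalarMap)


def chain_space(n, knn_k=2):
    coords = np.column_stack([np.arange(n, dtype=float) * 5,
                              np.zeros(n), np.zeros(n)])
    return GrayordinateSpace(structure=np.array(["LEFT_CORTEX"] * n),
                             coords=coords, knn_k=knn_k)


class TestProbabilityMaps:
    def test_two_participants_disagreeing_give_half(self, small_space):
        n = small_space.n_gray
        a = LabelMap(space=small_space, labels=np.ones(n, int),
                     palette=("DMN", "Vis"))
        b = LabelMap(space=small_space, labels=np.full(n, 2, int),
                     palette=("DMN", "Vis"))
        atlas = probability_maps([a, b])
        assert np.allclose(atlas.values[0], 0.5)
        assert np.allclose(atlas.values[1], 0.5)

    def test_identical_cohort_gives_zero_one(self, small_space, rng):
        labels = rng.integers(0, 3, size=small_space.n_gray)
        lm = LabelMap(space=small_space, labels=labels,
                      palette=("DMN", "Vis"))
        atlas = probability_maps([lm, lm, lm])
        assert set(np.unique(atlas.values)) <= {0.0, 1.0}

    def test_single_assignment_column_sums_bounded(self, small_space, rng):
        maps = [LabelMap(space=small_space,
                         labels=rng.integers(0, 3, size=small_space.n_gray),
                         palette=("DMN", "Vis")) for _ in range(5)]
        atlas = probability_maps(maps)
        assert atlas.values.sum(axis=0).max() <= 1 + 1e-12

    def test_self_concatenation_invariance(self, small_space, rng):
        maps = [LabelMap(space=small_space,
                         labels=rng.integers(0, 3, size=small_space.n_gray),
                         palette=("DMN", "Vis")) for _ in range(4)]
        a = probability_maps(maps)
        b = probability_maps(maps + maps)
        assert np.allclose(a.values, b.values)

    def test_overlap_cohort_in_omni_mode(self, small_space, rng):
        member = (rng.random((3, small_space.n_gray)) < 0.5).astype(int)
        om = OverlapMap(space=small_space, membership=member,
                        palette=("DMN", "Vis", "FPN"))
        atlas = probability_maps([om, om])
        assert atlas.source_mode == "omni"
        assert np.allclose(atlas.values, member)

    def test_palette_mismatch_rejected(self, small_space):
        n = small_space.n_gray
        a = LabelMap(space=small_space, labels=np.zeros(n, int),
                     palette=("DMN",))
        b = LabelMap(space=small_space, labels=np.zeros(n, int),
                     palette=("Vis",))
        with pytest.raises(ValueError, match="palette"):
            probability_maps([a, b])


class TestDeriveRoiset:
    def plateau_atlas(self, space, start, stop, p=0.9):
        values = np.zeros((1, space.n_gray))
        values[0, start:stop] = p
        return ProbabilityAtlas(space=space, values=values,
                                palette=("DMN",), n_participants=10)

    def test_forty_plateau_kept_as_one_parcel(self):
        space = chain_space(200)
        roi = derive_roiset(self.plateau_atlas(space, 20, 60), 0.8)
        assert roi.n_parcels == 1
        assert np.array_equal(np.sort(roi.parcels[0].members),
                              np.arange(20, 60))

    def test_29_plateau_dropped_by_cluster_rule(self):
        space = chain_space(200)
        roi = derive_roiset(self.plateau_atlas(space, 20, 49), 0.8)
        assert roi.n_parcels == 0

    def test_parcels_disjoint_above_half_threshold(self, small_space, rng):
        maps = [LabelMap(space=small_space,
                         labels=rng.integers(1, 4, size=small_space.n_gray),
                         palette=("DMN", "Vis", "FPN")) for _ in range(6)]
        atlas = probability_maps(maps)
        roi = derive_roiset(atlas, 0.75, min_cluster=1)
        seen = np.zeros(small_space.n_gray, int)
        for p in roi.parcels:
            seen[p.members] += 1
        assert seen.max() <= 1

    def test_monotone_in_threshold(self):
        space = chain_space(200)
        values = np.zeros((1, space.n_gray))
        values[0, 10:150] = np.linspace(0.7, 1.0, 140)
        atlas = ProbabilityAtlas(space=space, values=values,
                                 palette=("DMN",), n_participants=10)
        lo = derive_roiset(atlas, 0.75, min_cluster=5)
        hi = derive_roiset(atlas, 0.9, min_cluster=5)
        lo_mask = np.zeros(space.n_gray, bool)
        for p in lo.parcels:
            lo_mask[p.members] = True
        for p in hi.parcels:
            assert lo_mask[p.members].all()

    def test_empty_result_warns_not_raises(self):
        space = chain_space(100)
        roi = derive_roiset(self.plateau_atlas(space, 0, 10, p=0.3), 0.8)
        assert roi.n_parcels == 0


class TestIntegrationZones:
    def test_identical_cohort_mean_equals_member(self):
        space = chain_space(100)
        counts = np.zeros(space.n_gray)
        counts[30:70] = 3.0
        sm = ScalarMap(space=space, name="c", values=counts)
        iz = integration_zones([sm, sm, sm], threshold=2.2, min_cluster=10)
        assert np.allclose(iz.mean_counts.values, counts)
        assert len(iz.parcels) == 1
        assert np.array_equal(np.sort(iz.parcels[0].members),
                              np.arange(30, 70))

    def test_threshold_above_max_count_empty(self):
        space = chain_space(100)
        sm = ScalarMap(space=space, name="c", values=np.ones(space.n_gray))
        iz = integration_zones([sm], threshold=2.2, min_cluster=10)
        assert iz.parcels == []
        assert not iz.zone_mask().any()


class TestParcelOperations:
    @pytest.fixture()
    def setup(self, rng):
        space = chain_space(60)
        from precisionmap.atlas import Parcel

        parcels = [Parcel(1, "DMN", np.arange(0, 20)),
                   Parcel(2, "DMN", np.arange(20, 40)),
                   Parcel(3, "Vis", np.arange(40, 60))]
        parc = Parcellation(space=space, parcels=parcels,
                            palette=("DMN", "Vis"), threshold=0.8)
        return space, parc

    def test_constant_parcel_gives_constant_series(self, setup, rng):
        space, parc = setup
        vals = rng.normal(size=(30, 60))
        vals[:, 40:60] = 2.5
        ts = DenseTimeseries(space=space, tr_seconds=0.8, values=vals)
        series = parcellate_timeseries(ts, parc)
        assert np.allclose(series[2], 2.5)

    def test_matches_groupby_oracle(self, setup, rng):
        space, parc = setup
        ts = DenseTimeseries(space=space, tr_seconds=0.8,
                             values=rng.normal(size=(30, 60)))
        series = parcellate_timeseries(ts, parc)
        for i, p in enumerate(parc.parcels):
            assert np.allclose(series[i], ts.values[:, p.members].mean(axis=1))

    def test_perfectly_coupled_parcels_within_one(self, setup, rng):
        space, parc = setup
        base = rng.normal(size=30)
        series = np.stack([base, base, rng.normal(size=30)])
        conn = parcel_connectivity(series)
        stats_out = network_block_stats(conn, parc.parcel_networks())
        assert stats_out["within"]["DMN"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_parcels_near_zero(self, rng):
        series = rng.normal(size=(6, 2000))
        conn = parcel_connectivity(series)
        nets = ["DMN", "DMN", "DMN", "Vis", "Vis", "Vis"]
        stats_out = network_block_stats(conn, nets)
        assert abs(stats_out["within"]["DMN"]) < 0.1
        assert abs(stats_out["between"]) < 0.1

    def test_block_means_match_bruteforce(self, rng):
        conn = np.corrcoef(rng.normal(size=(5, 50)))
        nets = ["DMN", "DMN", "Vis", "Vis", "Vis"]
        stats_out = network_block_stats(conn, nets)
        assert stats_out["within"]["DMN"] == pytest.approx(conn[0, 1])
        vis_pairs = [conn[2, 3], conn[2, 4], conn[3, 4]]
        assert stats_out["within"]["Vis"] == pytest.approx(np.mean(vis_pairs))
        cross = [conn[i, j] for i in (0, 1) for j in (2, 3, 4)]
        assert stats_out["between"] == pytest.approx(np.mean(cross))

    def test_single_parcel_network_reported_missing(self, rng):
        conn = np.corrcoef(rng.normal(size=(3, 50)))
        stats_out = network_block_stats(conn, ["DMN", "Vis", "Vis"])
        assert stats_out["within"]["DMN"] is None
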