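"""Domain-anchor distances, correlations, kink angles, cluster maps."""

import numpy as np
import pytest
from scipy import stats

import confland as c
from confland.structure_io import DomainAnchors, KinkSpec
from confland.superposition import GeometryError

from conftest import random_rotation


def make_kinked_quadruplet(receptor, angle_deg, spec=None):
    """Four Calpha positions whose kink angle is exactly ``angle_deg``:
    lower axis along +z, upper axis rotated by the angle about x."""
    a = np.deg2rad(angle_deg)
    upper_dir = np.array([0.0, np.sin(a), np.cos(a)])
    coords = receptor.xyz.copy()
    kink = spec or KinkSpec(upper_pair=((None, 597), (None, 585)),
                            lower_pair=((None, 581), (None, 565)),
                            reference_angle=44.0)

    def idx(resid):
        return int(np.nonzero(receptor.residue_number == resid)[0][0])

    coords[idx(kink.lower_pair[1][1])] = [0.0, 0.0, 0.0]
    coords[idx(kink.lower_pair[0][1])] = [0.0, 0.0, 6.0]
    coords[idx(kink.upper_pair[1][1])] = [0.0, 0.0, 7.0]
    coords[idx(kink.upper_pair[0][1])] = np.array([0.0, 0.0, 7.0]) + 5.0 * upper_dir
    return receptor.with_coordinates(coords), kink


class TestDomainDistances:
    def test_static_structure_gives_length_one_series(self, receptor, fshr):
        series = c.domain_distances(receptor, fshr.anchors)
        assert series.n_frames == 1
        assert series.lrr_hr[0] > 10 and series.lrr_tm[0] > 10

    def test_anchor_paired_with_itself_is_zero(self, receptor):
        with pytest.warns(UserWarning):
            anchors = DomainAnchors(lrr_anchor=(None, 31, "CA"),
                                    hr_anchor=(None, 303, "CA"),
                                    tm_anchor=(None, 460, "CA"),
                                    tm_hr_anchor=(None, 303, "CA"))
        series = c.domain_distances(receptor, anchors)
        assert series.tm_hr[0] == 0.0  # HR anchor against itself

    def test_distances_match_manual_euclidean(self, receptor, fshr):
        series = c.domain_distances(receptor, fshr.anchors)

        def pos(resid):
            return receptor.xyz[receptor.residue_number == resid][0]

        assert series.lrr_hr[0] == pytest.approx(
            np.linalg.norm(pos(31) - pos(303)), rel=1e-12)
        assert series.lrr_tm[0] == pytest.approx(
            np.linalg.norm(pos(31) - pos(460)), rel=1e-12)

    def test_invariant_under_rigid_transform(self, receptor, fshr):
        rng = np.random.default_rng(4)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = receptor.with_coordinates(receptor.xyz @ R.T + t)
        a = c.domain_distances(receptor, fshr.anchors)
        b = c.domain_distances(moved, fshr.anchors)
        for p in ("lrr_hr", "lrr_tm", "tm_hr"):
            assert a.pair(p)[0] == pytest.approx(b.pair(p)[0], abs=1e-9)

    def test_unresolvable_anchor_named_in_error(self, receptor):
        anchors = DomainAnchors(lrr_anchor=(None, 31, "CA"),
                                hr_anchor=(None, 9999, "CA"),
                                tm_anchor=(None, 460, "CA"))
        with pytest.raises(Exception, match="9999"):
            c.domain_distances(receptor, anchors)

    def test_dual_tm_anchor_used_for_tm_hr(self, receptor):
        with pytest.warns(UserWarning):
            anchors = DomainAnchors(lrr_anchor=(None, 31, "CA"),
                                    hr_anchor=(None, 303, "CA"),
                                    tm_anchor=(None, 460, "CA"),
                                    tm_hr_anchor=(None, 500, "CA"))
        series = c.domain_distances(receptor, anchors)

        def pos(resid):
            return receptor.xyz[receptor.residue_number == resid][0]

        assert series.tm_hr[0] == pytest.approx(
            np.linalg.norm(pos(500) - pos(303)), rel=1e-12)
        assert series.lrr_tm[0] == pytest.approx(
            np.linalg.norm(pos(31) - pos(460)), rel=1e-12)


class TestPairwiseCorrelation:
    def test_series_against_itself_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(50, 70, 100)
        series = c.DistanceSeries(lrr_hr=x, lrr_tm=x, tm_hr=x + rng.normal(size=100),
                                  times=np.arange(100) * 10.0)
        corr = c.pairwise_correlation(series)
        assert corr[("lrr_hr", "lrr_tm")] == pytest.approx(1.0)

    def test_recovers_seeded_bivariate_correlation(self):
        rng = np.random.default_rng(101)
        n = 10_000
        rho = 0.5
        z1 = rng.normal(size=n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=n)
        series = c.DistanceSeries(lrr_hr=60 + z1, lrr_tm=80 + z2,
                                  tm_hr=70 + rng.normal(size=n),
                                  times=np.arange(n) * 10.0)
        corr = c.pairwise_correlation(series)
        assert corr[("lrr_hr", "lrr_tm")] == pytest.approx(0.5, abs=0.02)
        assert abs(corr[("lrr_hr", "tm_hr")]) < 0.05

    def test_matches_scipy_on_trajectory(self, two_state, fshr):
        _, traj, _ = two_state
        series = c.domain_distances(traj, fshr.anchors)
        corr = c.pairwise_correlation(series)
        expected = stats.pearsonr(series.lrr_tm, series.tm_hr).statistic
        assert corr[("lrr_tm", "tm_hr")] == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_affine_rescaling(self, two_state, fshr):
        _, traj, _ = two_state
        series = c.domain_distances(traj, fshr.anchors)
        scaled = c.DistanceSeries(lrr_hr=3.0 * series.lrr_hr + 7.0,
                                  lrr_tm=series.lrr_tm, tm_hr=series.tm_hr,
                                  times=series.times)
        a = c.pairwise_correlation(series)
        b = c.pairwise_correlation(scaled)
        assert a[("lrr_hr", "lrr_tm")] == pytest.approx(b[("lrr_hr", "lrr_tm")],
                                                        abs=1e-12)

    def test_constant_series_rejected(self):
        series = c.DistanceSeries(lrr_hr=np.full(10, 60.0),
                                  lrr_tm=np.linspace(70, 80, 10),
                                  tm_hr=np.linspace(60, 66, 10),
                                  times=np.arange(10) * 10.0)
        with pytest.raises(ValueError, match="constant"):
            c.pairwise_correlation(series)

    def test_too_few_frames_rejected(self):
        series = c.DistanceSeries(lrr_hr=[1.0, 2.0], lrr_tm=[1.0, 2.0],
                                  tm_hr=[1.0, 2.0], times=[0.0, 10.0])
        with pytest.raises(ValueError):
            c.pairwise_correlation(series)


class TestKinkAngle:
    def test_collinear_vectors_read_zero(self, receptor):
        model, kink = make_kinked_quadruplet(receptor, 0.0)
        series = c.kink_angle(model, kink)
        assert series.angles[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 90.0, 150.0])
    def test_constructed_bend_recovered_exactly(self, receptor, angle):
        model, kink = make_kinked_quadruplet(receptor, angle)
        series = c.kink_angle(model, kink)
        assert series.angles[0] == pytest.approx(angle, abs=1e-9)
        assert series.relative[0] == pytest.approx(angle - 44.0, abs=1e-9)

    def test_whole_turn_pairs_on_ideal_helix_read_zero(self, receptor):
        """Calpha pairs spanning whole helical turns (18 residues = 5 turns at
        100 deg/residue) align with the axis, so the ideal TM6 reads ~0 deg."""
        kink = KinkSpec(upper_pair=((None, 597), (None, 579)),
                        lower_pair=((None, 585), (None, 567)),
                        reference_angle=44.0)
        series = c.kink_angle(receptor, kink)
        assert series.angles[0] == pytest.approx(0.0, abs=1e-6)

    def test_invariant_under_rigid_transform_and_scaling(self, receptor):
        model, kink = make_kinked_quadruplet(receptor, 30.0)
        rng = np.random.default_rng(7)
        R = random_rotation(rng)
        moved = model.with_coordinates(model.xyz @ R.T + rng.uniform(-9, 9, 3))
        scaled = model.with_coordinates(model.xyz * 2.5)
        for variant in (moved, scaled):
            assert c.kink_angle(variant, kink).angles[0] == pytest.approx(
                30.0, abs=1e-9)

    def test_zero_length_vector_raises(self, receptor):
        coords = receptor.xyz.copy()
        kink = KinkSpec(upper_pair=((None, 597), (None, 585)),
                        lower_pair=((None, 581), (None, 565)),
                        reference_angle=44.0)
        i581 = int(np.nonzero(receptor.residue_number == 581)[0][0])
        i565 = int(np.nonzero(receptor.residue_number == 565)[0][0])
        coords[i581] = coords[i565]
        with pytest.raises(GeometryError):
            c.kink_angle(receptor.with_coordinates(coords), kink)

    def test_quadruplet_must_be_distinct(self):
        with pytest.raises(ValueError):
            KinkSpec(upper_pair=((None, 1), (None, 2)),
                     lower_pair=((None, 2), (None, 3)))


class TestClusterDistanceMap:
    def test_two_states_occupy_disjoint_distance_ranges(self, two_state,
                                                        tm_idx, fshr):
        _, traj, labels = two_state
        series = c.domain_distances(traj, fshr.anchors)
        m = c.rmsd_matrix(traj, tm_idx, stride=2)
        assignment = c.threshold_cluster(m, 1.0)
        out = c.cluster_distance_map(assignment, series)
        assert len(out["subsets"]) == 2
        (a, b) = sorted(out["subsets"])
        # imposed LRR offset separates the lrr_tm ranges between the states
        ra = out["subsets"][a].lrr_tm
        rb = out["subsets"][b].lrr_tm
        assert (ra.max() < rb.min()) or (rb.max() < ra.min())
        assert out["overlap"][(a, b)] < 0.05

    def test_single_cluster_subset_is_full_series(self, two_state, tm_idx, fshr):
        _, traj, _ = two_state
        series = c.domain_distances(traj, fshr.anchors)
        m = c.rmsd_matrix(traj, tm_idx, stride=4)
        assignment = c.threshold_cluster(m, 1e3)
        out = c.cluster_distance_map(assignment, series)
        sub = next(iter(out["subsets"].values()))
        assert sub.n_frames == m.n_frames

    def test_singleton_cluster_min_equals_max(self, fshr, receptor):
        from confland.superposition import RMSDMatrix
        v = np.array([[0.0, 5.0], [5.0, 0.0]])
        m = RMSDMatrix(values=v, frame_indices=np.arange(2), times=[0.0, 10.0])
        assignment = c.threshold_cluster(m, 1.0)
        series = c.domain_distances(
            c.TrajectoryEnsemble(coordinates=np.repeat(receptor.xyz[None], 2, 0),
                                 times=[0.0, 10.0], atom_table=receptor),
            fshr.anchors)
        out = c.cluster_distance_map(assignment, series)
        table = out["table"]
        assert (table["min_A"] == table["max_A"]).all()
        assert (table["min_A"] == table["mean_A"]).all()


class TestRangeSummary:
    def test_constant_series(self):
        series = c.DistanceSeries(lrr_hr=np.full(5, 60.0), lrr_tm=np.full(5, 70.0),
                                  tm_hr=np.full(5, 80.0), times=np.arange(5) * 10.0)
        summary = c.range_summary(series)
        assert summary["lrr_hr"] == (60.0, 60.0)

    def test_inserted_extremes_recovered(self, two_state, fshr):
        _, traj, _ = two_state
        series = c.domain_distances(traj, fshr.anchors)
        doctored = c.DistanceSeries(
            lrr_hr=np.concatenate([series.lrr_hr, [5.0, 500.0]]),
            lrr_tm=np.concatenate([series.lrr_tm, [4.0, 400.0]]),
            tm_hr=np.concatenate([series.tm_hr, [3.0, 300.0]]),
            times=np.arange(series.n_frames + 2) * 10.0)
        summary = c.range_summary(doctored)
        assert summary["lrr_hr"] == (5.0, 500.0)
        assert summary["lrr_tm"] == (4.0, 400.0)
        assert summary["tm_hr"] == (3.0, 300.0)
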