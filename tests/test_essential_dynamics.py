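"""Essential dynamics: covariance eigendecomposition, projections,
distributions, porcupine vectors."""

import numpy as np
import pytest

import confland as c
from confland import essential_dynamics as ed


@pytest.fixture(scope="module")
def two_state_decomp(two_state, tm_idx, ca_idx):
    _, traj, labels = two_state
    decomp = c.covariance_analysis(traj, tm_idx, ca_idx, exclude_leading_ps=0.0)
    return traj, labels, decomp


class TestCovarianceAnalysis:
    def test_rigid_trajectory_all_eigenvalues_zero(self, receptor, tm_idx, ca_idx):
        spec = c.SyntheticSpec(n_frames=12, seed=0, noise_sigma=0.0,
                               states=(c.StateDefinition("A"),))
        traj, _ = c.generate_trajectory(receptor, spec)  # rigid jitter only
        decomp = c.covariance_analysis(traj, tm_idx, ca_idx, exclude_leading_ps=0.0)
        assert np.all(np.abs(decomp.eigenvalues) < 1e-9)

    def test_single_breathing_mode_recovers_imposed_variance(self, receptor, tm_idx):
        """One atom oscillating along x outside the fit group: lambda_1 equals
        the variance of the imposed motion, all other eigenvalues ~0."""
        rng = np.random.default_rng(1)
        amplitudes = rng.normal(scale=1.5, size=50)
        coords = np.repeat(receptor.xyz[None], 50, axis=0)
        moving_atom = 0  # LRR atom, far from the TM fit group
        coords[:, moving_atom, 0] += amplitudes
        traj = c.TrajectoryEnsemble(coordinates=coords,
                                    times=np.arange(50) * 10.0,
                                    atom_table=receptor)
        decomp = c.covariance_analysis(traj, tm_idx, np.arange(receptor.n_atoms),
                                       exclude_leading_ps=0.0)
        imposed_var = amplitudes.var()
        assert decomp.eigenvalues[0] == pytest.approx(imposed_var, rel=1e-6)
        assert np.all(np.abs(decomp.eigenvalues[1:]) < 1e-9)

    def test_eigenvalue_sum_equals_covariance_trace(self, two_state_decomp,
                                                    two_state, tm_idx, ca_idx):
        traj, _, decomp = two_state_decomp
        # independent trace: total variance of fitted, centred coordinates
        from confland.superposition import kabsch_fit
        fitted = np.empty_like(traj.coordinates)
        for i in range(traj.n_frames):
            t, _ = kabsch_fit(traj.coordinates[i][decomp.fit_indices],
                              decomp.fit_mean)
            fitted[i] = t.apply(traj.coordinates[i])
        X = fitted[:, ca_idx].reshape(traj.n_frames, -1)
        trace = ((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert decomp.total_fluctuation == pytest.approx(trace, rel=1e-6)

    def test_eigenvectors_orthonormal_and_descending(self, two_state_decomp):
        _, _, decomp = two_state_decomp
        V = decomp.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        assert np.all(np.diff(decomp.eigenvalues) <= 1e-12)
        assert np.all(decomp.eigenvalues >= -1e-9)

    def test_sign_convention_largest_entry_positive(self, two_state_decomp):
        _, _, decomp = two_state_decomp
        V = decomp.eigenvectors
        peaks = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])]
        assert np.all(peaks >= 0)

    def test_exclusion_longer_than_span_raises(self, two_state, tm_idx, ca_idx):
        _, traj, _ = two_state
        with pytest.raises(ValueError):
            c.covariance_analysis(traj, tm_idx, ca_idx,
                                  exclude_leading_ps=1e9)

    def test_burn_in_drops_leading_frames_only(self, receptor, tm_idx, ca_idx):
        spec = c.SyntheticSpec(n_frames=60, seed=4)
        traj, _ = c.generate_trajectory(receptor, spec)
        full = c.covariance_analysis(traj, tm_idx, ca_idx, exclude_leading_ps=0.0)
        tail = c.covariance_analysis(traj, tm_idx, ca_idx,
                                     exclude_leading_ps=200.0)
        ref = c.covariance_analysis(traj.slice_frames(np.arange(20, 60)),
                                    tm_idx, ca_idx, exclude_leading_ps=0.0)
        np.testing.assert_allclose(tail.eigenvalues, ref.eigenvalues, rtol=1e-9)
        assert not np.allclose(full.eigenvalues[:3], tail.eigenvalues[:3])


class TestProjections:
    def test_projection_of_mean_is_zero(self, two_state_decomp):
        traj, _, decomp = two_state_decomp
        mean_model = traj.atom_table.with_coordinates(
            np.asarray(decomp.mean_coords))
        series = c.project(c.static_ensemble(mean_model), decomp,
                           components=(1, 2, 3))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-8)

    def test_source_trajectory_projections_are_centred(self, two_state_decomp):
        traj, _, decomp = two_state_decomp
        series = c.project(traj, decomp, components=(1, 2, 3, 4))
        stdev = series.values.std(axis=0)
        assert np.all(np.abs(series.values.mean(axis=0)) < 1e-6 * stdev)

    def test_parseval_projection_variance_equals_eigenvalue_sum(
            self, two_state_decomp):
        traj, _, decomp = two_state_decomp
        n3 = decomp.eigenvalues.size
        series = c.project(traj, decomp, components=range(1, n3 + 1))
        total = series.values.var(axis=0).sum()
        assert total == pytest.approx(decomp.total_fluctuation, rel=1e-6)

    def test_reconstruction_from_all_components(self, two_state_decomp):
        traj, _, decomp = two_state_decomp
        n3 = decomp.eigenvalues.size
        series = c.project(traj, decomp, components=range(1, n3 + 1))
        rebuilt = ed.reconstruct(decomp, series.values[:5])
        # oracle: refit the original frames exactly as project() does
        from confland.superposition import kabsch_fit
        for i in range(5):
            t, _ = kabsch_fit(traj.coordinates[i][decomp.fit_indices],
                              decomp.fit_mean)
            fitted = t.apply(traj.coordinates[i][decomp.analysis_indices])
            np.testing.assert_allclose(rebuilt[i], fitted, atol=1e-6)

    def test_pc1_separates_ground_truth_states(self, two_state_decomp):
        traj, labels, decomp = two_state_decomp
        pc1 = c.project(traj, decomp, components=(1,)).values[:, 0]
        mid = 0.5 * (pc1[labels == 0].mean() + pc1[labels == 1].mean())
        side = (pc1 > mid).astype(int)
        accuracy = max((side == labels).mean(), (side != labels).mean())
        assert accuracy > 0.95

    def test_cross_replicate_projection_overlaps(self, receptor, tm_idx,
                                                 ca_idx, two_state_decomp):
        """A second replicate projected on the first replicate's PC1 samples
        the same range as the first replicate's own projections."""
        traj1, _, decomp = two_state_decomp
        spec2 = c.SyntheticSpec(n_frames=200, seed=99)
        traj2, _ = c.generate_trajectory(receptor, spec2)
        proj1 = c.project(traj1, decomp, components=(1,)).values[:, 0]
        proj2 = c.project(traj2, decomp, components=(1,)).values[:, 0]
        # same state definitions, same modes: the distributions overlap
        lo = max(proj1.min(), proj2.min())
        hi = min(proj1.max(), proj2.max())
        assert hi > lo
        assert np.mean((proj2 > lo) & (proj2 < hi)) > 0.5

    def test_atom_mismatch_raises(self, two_state_decomp, receptor):
        _, _, decomp = two_state_decomp
        small = receptor.subset(np.arange(10))
        with pytest.raises(ValueError):
            c.project(c.static_ensemble(small), decomp, components=(1,))


class TestDistributions:
    def test_unimodal_gaussian_single_maximum(self):
        rng = np.random.default_rng(8)
        x = rng.normal(loc=2.0, scale=1.0, size=20_000)
        centers, density, maxima = c.projection_distribution(x, bin_width=0.25)
        assert maxima.size == 1
        assert maxima[0] == pytest.approx(2.0, abs=0.5)
        # density-normalised histogram integrates to 1
        assert density.sum() * 0.25 == pytest.approx(1.0, rel=1e-9)

    def test_two_separated_states_two_maxima(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-5.0, 0.5, 5000),
                            rng.normal(5.0, 0.5, 5000)])
        _, _, maxima = c.projection_distribution(x, bin_width=0.5)
        assert maxima.size == 2
        assert maxima[0] == pytest.approx(-5.0, abs=0.5)
        assert maxima[1] == pytest.approx(5.0, abs=0.5)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            c.projection_distribution(np.full(100, 3.0), bin_width=0.5)


class TestFluctuationFraction:
    def test_all_components_give_exactly_one(self, two_state_decomp):
        _, _, decomp = two_state_decomp
        n3 = decomp.eigenvalues.size
        assert c.fluctuation_fraction(decomp, n3) == pytest.approx(1.0)

    def test_isotropic_noise_uniform_increments(self, receptor, tm_idx):
        """Isotropic unit-variance noise on 10 analysis atoms: each of the 30
        eigenvalues carries ~1/30 of the fluctuation."""
        rng = np.random.default_rng(12)
        coords = np.repeat(receptor.xyz[None], 4000, axis=0)
        analysis = np.arange(10)  # far from the TM fit group
        coords[:, analysis] += rng.normal(size=(4000, 10, 3))
        traj = c.TrajectoryEnsemble(coordinates=coords,
                                    times=np.arange(4000) * 10.0,
                                    atom_table=receptor)
        decomp = c.covariance_analysis(traj, tm_idx, analysis,
                                       exclude_leading_ps=0.0)
        fractions = np.diff([0] + [c.fluctuation_fraction(decomp, k)
                                   for k in range(1, 31)])
        np.testing.assert_allclose(fractions, 1 / 30, atol=0.01)

    def test_out_of_range_k_rejected(self, two_state_decomp):
        _, _, decomp = two_state_decomp
        with pytest.raises(ValueError):
            c.fluctuation_fraction(decomp, 0)


class TestPorcupine:
    def test_zero_eigenvalue_component_gives_zero_vectors(
            self, receptor, tm_idx, ca_idx):
        spec = c.SyntheticSpec(n_frames=12, seed=0, noise_sigma=0.0,
                               states=(c.StateDefinition("A"),))
        traj, _ = c.generate_trajectory(receptor, spec)
        decomp = c.covariance_analysis(traj, tm_idx, ca_idx,
                                       exclude_leading_ps=0.0)
        vec = c.porcupine_vectors(decomp, decomp.eigenvalues.size)
        np.testing.assert_allclose(vec, 0.0, atol=1e-6)

    def test_single_mode_vectors_parallel_to_imposed_direction(
            self, receptor, tm_idx):
        rng = np.random.default_rng(2)
        direction = np.array([1.0, 0.0, 0.0])
        coords = np.repeat(receptor.xyz[None], 60, axis=0)
        coords[:, 0] += np.outer(rng.normal(scale=2.0, size=60), direction)
        traj = c.TrajectoryEnsemble(coordinates=coords,
                                    times=np.arange(60) * 10.0,
                                    atom_table=receptor)
        decomp = c.covariance_analysis(traj, tm_idx, np.arange(receptor.n_atoms),
                                       exclude_leading_ps=0.0)
        vec = c.porcupine_vectors(decomp, 1)
        v0 = vec[0] / np.linalg.norm(vec[0])
        assert abs(v0 @ direction) > 0.99

    def test_scale_linearity(self, two_state_decomp):
        _, _, decomp = two_state_decomp
        np.testing.assert_allclose(c.porcupine_vectors(decomp, 1, scale=2.0),
                                   2.0 * c.porcupine_vectors(decomp, 1),
                                   rtol=1e-12)


class TestClusterProjection:
    def test_single_cluster_subset_equals_full_series(self, two_state, tm_idx,
                                                      two_state_decomp):
        traj, _, decomp = two_state_decomp
        series = c.project(traj, decomp, components=(1, 2))
        m = c.rmsd_matrix(traj, tm_idx, stride=4)
        assignment = c.threshold_cluster(m, cutoff=100.0)  # everything merges
        out = c.cluster_projection(assignment, series, bin_width=2.0)
        assert len(out) == 1
        sub = next(iter(out.values()))["series"]
        assert sub.n_frames == m.n_frames

    def test_state_cluster_centred_at_state_projection(self, two_state, tm_idx,
                                                       two_state_decomp):
        traj, labels, decomp = two_state_decomp
        series = c.project(traj, decomp, components=(1,))
        m = c.rmsd_matrix(traj, tm_idx, stride=2)
        assignment = c.threshold_cluster(m, cutoff=1.0)
        out = c.cluster_projection(assignment, series, bin_width=2.0)
        assert len(out) == 2
        for cid, info in out.items():
            member_states = labels[assignment.members(cid)]
            assert np.unique(member_states).size == 1  # pure clusters
            state = member_states[0]
            state_centre = series.values[labels == state, 0].mean()
            sub_mean = info["series"].values[:, 0].mean()
            assert sub_mean == pytest.approx(state_centre, abs=1.0)
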