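"""Superposition, Schlitter entropy, PCA free-energy surfaces and
pose-event filtering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neqbind.entropy import (
    GeometrySeries,
    TrajectoryEnsemble,
    entropy_contribution,
    filter_events,
    fit_pca,
    mean_structure_reference,
    project_fes,
    schlitter_entropy,
    schlitter_entropy_from_covariance,
    superpose,
)
from neqbind.constants import kt_kj
from neqbind.synthetic import (
    EnsembleGenSpec,
    PoseSeriesSpec,
    gen_gaussian_ensemble,
    gen_pose_series,
)

from oracles import schlitter_closed_form_1d


def _rigid_scaffold(rng, n_atoms=8, spread=1.0):
    """A well-spread mean structure so rotations are well-determined."""
    return rng.uniform(-spread, spread, (n_atoms, 3))


class TestSuperpose:
    def test_aligned_ensemble_is_fixed_point(self):
        rng = np.random.default_rng(0)
        ref = _rigid_scaffold(rng)
        coords = np.tile(ref[None], (10, 1, 1))
        ens = TrajectoryEnsemble(coordinates=coords, masses=np.full(8, 12.0))
        fitted, rmsd = superpose(ens, ref)
        assert np.allclose(fitted.coordinates, coords, atol=1e-12)
        assert np.all(rmsd < 1e-12)
        assert fitted.superposed

    def test_fit_never_increases_rmsd(self):
        rng = np.random.default_rng(20)
        mean = _rigid_scaffold(rng)
        spec = EnsembleGenSpec(
            covariance=np.eye(24) * 1e-4, masses=np.full(8, 12.0), n_frames=50, seed=1,
            mean=mean,
        )
        ens = gen_gaussian_ensemble(spec)
        ref = ens.coordinates[0]
        before = np.sqrt(((ens.coordinates - ref) ** 2).sum(axis=(1, 2)) / 8)
        _, after = superpose(ens, ref)
        assert np.all(after <= before + 1e-12)

    def test_rotated_copy_recovers_reference(self):
        rng = np.random.default_rng(1)
        ref = _rigid_scaffold(rng)
        rot = Rotation.random(random_state=2).as_matrix()
        frame = ref @ rot.T + np.array([1.0, -2.0, 0.5])
        ens = TrajectoryEnsemble(
            coordinates=frame[None], masses=np.full(8, 12.0)
        )
        fitted, rmsd = superpose(ens, ref)
        assert rmsd[0] < 1e-10

    def test_entropy_invariant_under_per_frame_rigid_motion(self):
        """Randomly rotating/translating every frame and re-fitting
        changes the Schlitter entropy by < 0.5%."""
        rng = np.random.default_rng(3)
        mean = _rigid_scaffold(rng, n_atoms=10)
        cov = np.diag(rng.uniform(0.0005, 0.002, 30))
        spec = EnsembleGenSpec(
            covariance=cov, masses=np.full(10, 12.0), n_frames=4000, seed=4, mean=mean
        )
        ens = gen_gaussian_ensemble(spec)
        moved = ens.coordinates.copy()
        rots = Rotation.random(len(moved), random_state=5)
        for i in range(len(moved)):
            moved[i] = moved[i] @ rots[i].as_matrix().T + rng.uniform(-1, 1, 3)
        scrambled = TrajectoryEnsemble(coordinates=moved, masses=ens.masses)

        ref = mean_structure_reference([ens])
        s_base = schlitter_entropy(superpose(ens, ref)[0], 298.0)
        s_scrambled = schlitter_entropy(
            superpose(scrambled, mean_structure_reference([scrambled]))[0], 298.0
        )
        assert abs(s_scrambled - s_base) / s_base < 0.005

    def test_collinear_selection_rejected(self):
        coords = np.zeros((2, 4, 3))
        coords[:, :, 0] = np.arange(4)  # all atoms on the x axis
        ens = TrajectoryEnsemble(coordinates=coords, masses=np.ones(4))
        with pytest.raises(ValueError, match="degenerate"):
            superpose(ens, coords[0])


class TestSchlitterEntropy:
    def test_zero_covariance_gives_zero(self):
        coords = np.tile(np.arange(12.0).reshape(1, 4, 3), (5, 1, 1))
        ens = TrajectoryEnsemble(coordinates=coords, masses=np.ones(4), superposed=True)
        assert schlitter_entropy(ens, 298.0) == pytest.approx(0.0, abs=1e-12)

    def test_1d_closed_form_convergence(self):
        """Sampled single-mode ensemble converges to the 1-D closed form
        within 1% at 5e4 frames."""
        mass, var, t = 12.0, 0.01, 298.0
        cov = np.zeros((3, 3))
        cov[0, 0] = var
        spec = EnsembleGenSpec(
            covariance=cov, masses=np.array([mass]), n_frames=50000, seed=6
        )
        s = schlitter_entropy(gen_gaussian_ensemble(spec), t)
        s_exact = schlitter_closed_form_1d(mass, var, t)
        assert abs(s - s_exact) / s_exact < 0.01

    def test_sampled_matches_generating_covariance_closed_form(
        self, small_gaussian_ensemble
    ):
        ens, spec = small_gaussian_ensemble
        s = schlitter_entropy(ens, 298.0)
        s0 = schlitter_entropy_from_covariance(spec.covariance, spec.masses, 298.0)
        assert abs(s - s0) / s0 < 0.01

    def test_variance_doubling_increases_entropy(self, small_gaussian_ensemble):
        ens, spec = small_gaussian_ensemble
        s1 = schlitter_entropy(ens, 298.0)
        doubled = TrajectoryEnsemble(
            coordinates=(ens.coordinates - ens.coordinates.mean(0)) * np.sqrt(2.0),
            masses=ens.masses,
            superposed=True,
        )
        assert schlitter_entropy(doubled, 298.0) > s1

    def test_monotonic_in_temperature(self, small_gaussian_ensemble):
        ens, _ = small_gaussian_ensemble
        assert schlitter_entropy(ens, 350.0) > schlitter_entropy(ens, 250.0)

    def test_unsuperposed_input_requires_flag(self):
        coords = np.random.default_rng(0).normal(0, 0.1, (10, 2, 3))
        ens = TrajectoryEnsemble(coordinates=coords, masses=np.ones(2))
        with pytest.raises(ValueError, match="superposed"):
            schlitter_entropy(ens, 300.0)
        schlitter_entropy(ens, 300.0, assume_superposed=True)  # explicit opt-in


class TestEntropyContribution:
    @pytest.mark.parametrize(
        "s_holo,s_apo,t,expected,tol",
        [
            (458.0, 643.0, 300.15, -13.3, 0.15),
            (340.0, 385.0, 298.0, -3.2, 0.15),
            (465.0, 641.0, 300.15, -12.6, 0.15),
        ],
    )
    def test_published_style_cells(self, s_holo, s_apo, t, expected, tol):
        assert entropy_contribution(s_holo, s_apo, t) == pytest.approx(expected, abs=tol)

    def test_equal_entropies_zero(self):
        assert entropy_contribution(500.0, 500.0, 310.0) == 0.0

    def test_sign_favours_higher_entropy_state(self):
        assert entropy_contribution(400.0, 500.0, 300.0) < 0  # apo richer -> negative


class TestPca:
    def test_single_direction_dominates(self):
        rng = np.random.default_rng(8)
        direction = rng.normal(size=9)
        direction /= np.linalg.norm(direction)
        amplitude = rng.normal(0, 1.0, 500)
        coords = (amplitude[:, None] * direction[None]).reshape(500, 3, 3)
        coords += rng.normal(0, 1e-4, coords.shape)
        ens = TrajectoryEnsemble(coordinates=coords, masses=np.ones(3), superposed=True)
        model = fit_pca([ens])
        assert model.eigenvalues[0] / model.eigenvalues.sum() > 0.999

    def test_eigenvalue_sum_equals_covariance_trace(self, small_gaussian_ensemble):
        ens, _ = small_gaussian_ensemble
        model = fit_pca([ens])
        x = ens.selected_coordinates()
        trace = np.var(x, axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(trace, rel=1e-10)

    def test_planted_two_component_recovery(self):
        rng = np.random.default_rng(9)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        eigvals = np.array([9.0, 1.0, 1e-4, 1e-4, 1e-4, 1e-4]) * 1e-3
        cov = (q * eigvals) @ q.T
        spec = EnsembleGenSpec(
            covariance=cov, masses=np.ones(2), n_frames=30000, seed=10
        )
        model = fit_pca([gen_gaussian_ensemble(spec)])
        assert model.eigenvalues[0] == pytest.approx(9e-3, rel=0.05)
        assert model.eigenvalues[1] == pytest.approx(1e-3, rel=0.05)

    def test_sign_convention_fixed(self, small_gaussian_ensemble):
        ens, _ = small_gaussian_ensemble
        model = fit_pca([ens])
        for k in range(3):
            j = np.argmax(np.abs(model.eigenvectors[:, k]))
            assert model.eigenvectors[j, k] > 0


class TestFes:
    def test_identical_frames_single_zero_bin(self):
        coords = np.tile(np.arange(6.0).reshape(1, 2, 3), (50, 1, 1))
        ens = TrajectoryEnsemble(coordinates=coords, masses=np.ones(2), superposed=True)
        model = fit_pca([ens])
        grid = project_fes(ens, model, 300.0, bins=5)
        occupied = ~grid.mask
        assert occupied.sum() == 1
        assert grid.free_energy[occupied][0] == 0.0

    def test_isotropic_gaussian_recovers_quadratic_well(self):
        """FES of an isotropic 2-D Gaussian is r^2 kT/(2 sigma^2):
        linear fit of dG vs r^2 recovers the curvature."""
        sigma2 = 4e-3
        cov = np.zeros((6, 6))
        cov[0, 0] = cov[1, 1] = sigma2
        spec = EnsembleGenSpec(covariance=cov, masses=np.ones(2), n_frames=200000, seed=11)
        ens = gen_gaussian_ensemble(spec)
        model = fit_pca([ens])
        t = 300.0
        grid = project_fes(ens, model, t, bins=40)
        c1 = 0.5 * (grid.pc1_edges[:-1] + grid.pc1_edges[1:])
        c2 = 0.5 * (grid.pc2_edges[:-1] + grid.pc2_edges[1:])
        r2, g = [], []
        for i in range(len(c1)):
            for j in range(len(c2)):
                if not grid.mask[i, j] and grid.free_energy[i, j] < 2.0:
                    r2.append(c1[i] ** 2 + c2[j] ** 2)
                    g.append(grid.free_energy[i, j] * 4.184)  # back to kJ
        slope = np.polyfit(r2, g, 1)[0]
        expected = kt_kj(t) / (2 * sigma2)
        assert slope == pytest.approx(expected, rel=0.1)

    def test_minimum_of_occupied_bins_is_zero_and_mask_lossless(
        self, small_gaussian_ensemble
    ):
        ens, _ = small_gaussian_ensemble
        model = fit_pca([ens])
        grid = project_fes(ens, model, 298.0, bins=30)
        assert grid.occupied_min() == 0.0
        assert grid.mask.sum() + (~grid.mask).sum() == grid.free_energy.size

    def test_too_few_bins_rejected(self, small_gaussian_ensemble):
        ens, _ = small_gaussian_ensemble
        with pytest.raises(ValueError):
            project_fes(ens, fit_pca([ens]), 298.0, bins=1)


class TestFilterEvents:
    def test_clean_bound_series(self):
        series = GeometrySeries(
            com_distance=np.full(200, 0.3), orientation_cos=np.full(200, 0.9)
        )
        labels, verdict = filter_events(series)
        assert verdict.status == "clean" and not verdict.low_confidence
        assert set(labels) == {"primary"}

    def test_noiseless_flip_detected_at_exact_frame(self):
        series = gen_pose_series(
            PoseSeriesSpec(n_frames=1000, flip_frame=500, noise_sd=0.0)
        )
        labels, verdict = filter_events(series)
        assert verdict.status == "flipped" and verdict.frame == 500
        assert labels[499] == "primary" and labels[500] == "secondary"

    def test_noiseless_unbind_detected(self):
        series = gen_pose_series(
            PoseSeriesSpec(n_frames=400, unbind_frame=150, noise_sd=0.0)
        )
        _, verdict = filter_events(series)
        assert verdict.status == "unbound" and verdict.frame == 150

    def test_noisy_flip_recovered_within_tolerance(self):
        """Detector recovers the planted flip within +-20 frames across
        many noisy realizations."""
        for seed in range(30):
            series = gen_pose_series(
                PoseSeriesSpec(n_frames=1000, flip_frame=500, noise_sd=0.1, seed=seed)
            )
            _, verdict = filter_events(series)
            assert verdict.status == "flipped"
            assert abs(verdict.frame - 500) <= 20

    def test_transient_blip_below_persistence_ignored(self):
        cos = np.full(300, 0.9)
        cos[100:120] = -0.9  # 20-frame excursion < min_persistence=50
        series = GeometrySeries(com_distance=np.full(300, 0.3), orientation_cos=cos)
        _, verdict = filter_events(series, min_persistence=50)
        assert verdict.status == "clean"

    def test_all_noise_series_is_low_confidence(self):
        rng = np.random.default_rng(12)
        series = GeometrySeries(
            com_distance=np.full(100, 0.3),
            orientation_cos=rng.uniform(-0.15, 0.15, 100),
        )
        _, verdict = filter_events(series, flip_hysteresis=0.2)
        assert verdict.low_confidence

    def test_deterministic_and_idempotent(self):
        series = gen_pose_series(
            PoseSeriesSpec(n_frames=500, flip_frame=200, noise_sd=0.05, seed=1)
        )
        l1, v1 = filter_events(series)
        l2, v2 = filter_events(series)
        assert np.array_equal(l1, l2) and v1 == v2
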