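"""Shape-model fitting, missing-landmark inference and persistence."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from dentaxis import (
    DentalShapeModel,
    Jaw,
    LandmarkKind,
    PartialObservation,
    ReconstructionConfig,
    RigidTransform,
    ShapeModelResults,
    build_model,
    load_model,
    make_template,
    predict_axes,
    reconstruct,
    sample_shape,
    save_model,
    to_vector,
)
from dentaxis.synthetic import SyntheticPopulationSpec, generate_population
from dentaxis.axes import angle_between_axes, fit_tooth_axis
from dentaxis.evaluation import _root_points


def random_rigid(rng) -> RigidTransform:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    return RigidTransform(R, rng.uniform(-10, 10, 3))


@pytest.fixture(scope="module")
def noiseless_population():
    """Pose-free, noise-free population spanned by exactly 3 modes."""
    spec = SyntheticPopulationSpec(
        n_individuals=10, n_modes=3, landmark_noise_sd_mm=0.0,
        pose="none", seed=5)
    return generate_population(spec)


@pytest.fixture(scope="module")
def upper_model(noiseless_population):
    dataset, _ = noiseless_population
    return DentalShapeModel(dataset, Jaw.UPPER, variance_fraction=0.98).fit()


@pytest.fixture(scope="module")
def one_mode_model(template):
    """A hand-built single-mode model where crowns determine roots."""
    protocol = template.protocol
    labels = protocol.labels_of_jaw(Jaw.UPPER)
    mean = to_vector(template, labels)
    gen = np.random.default_rng(11)
    mode = gen.normal(size=mean.size)
    mode /= np.linalg.norm(mode)
    return ShapeModelResults(
        protocol=protocol, jaw=Jaw.UPPER, labels=labels, mean=mean,
        modes=mode[:, None], variances=np.array([25.0]),
        total_variance=25.0, n_train=10, variance_fraction=1.0)


def crown_observation(results, dentition):
    crown = [l for l in results.labels if l.kind is LandmarkKind.CROWN]
    return PartialObservation.from_dentition(dentition, crown)


class TestBuildModel:
    def test_no_variation_gives_zero_modes(self, rng):
        shape = rng.normal(size=(1, 20, 3))
        aligned = np.repeat(shape, 5, axis=0)
        res = build_model(aligned, labels=tuple(range(20)), protocol=None, jaw=None)
        assert res.n_modes == 0 and res.total_variance == pytest.approx(0.0, abs=1e-20)

    def test_subspace_recovery_on_exact_low_rank_data(self, rng, protocol):
        """PCA recovers the generating 3-dim subspace to < 1e-6 rad."""
        K = 50
        mean = rng.normal(scale=10.0, size=3 * K)
        gen_modes, _ = np.linalg.qr(rng.normal(size=(3 * K, 3)))
        scores = rng.normal(scale=[4.0, 2.0, 1.0], size=(12, 3))
        data = mean + scores @ gen_modes.T
        res = build_model(data.reshape(12, K, 3), labels=tuple(range(K)),
                          protocol=protocol, jaw=None, variance_fraction=1.0)
        assert res.n_modes == 3
        assert np.max(subspace_angles(res.modes, gen_modes)) < 1e-6

    def test_full_rank_round_trip(self, rng, protocol):
        data = rng.normal(scale=5.0, size=(6, 30, 3))
        res = build_model(data, labels=tuple(range(30)), protocol=protocol,
                          jaw=None, variance_fraction=1.0)
        for shape in data.reshape(6, -1):
            coeffs = res.modes.T @ (shape - res.mean)
            back = res.mean + res.modes @ coeffs
            np.testing.assert_allclose(back, shape, atol=1e-8)

    def test_variances_non_increasing_and_modes_orthonormal(self, upper_model):
        assert np.all(np.diff(upper_model.variances) <= 1e-12)
        m = upper_model.n_modes
        np.testing.assert_allclose(
            upper_model.modes.T @ upper_model.modes, np.eye(m), atol=1e-8)
        assert m <= upper_model.n_train - 1


class TestAlignPartial:
    def test_recovers_known_rotation_of_mean_crowns(self, upper_model, rng):
        obs_d = upper_model.mean_dentition()
        tf = random_rigid(rng)
        crown = [l for l in upper_model.labels if l.kind is LandmarkKind.CROWN]
        moved = PartialObservation(
            tuple(crown), tf.apply(to_vector(obs_d, crown).reshape(-1, 3)).reshape(-1))
        recovered = upper_model.align_partial(moved)
        np.testing.assert_allclose(recovered.rotation, tf.inverse().rotation, atol=1e-8)
        np.testing.assert_allclose(recovered.translation, tf.inverse().translation,
                                   atol=1e-7)

    def test_small_noise_small_pose_error(self, upper_model, rng):
        crown = [l for l in upper_model.labels if l.kind is LandmarkKind.CROWN]
        clean = upper_model.mean[upper_model._label_rows(crown)].reshape(-1, 3)
        for _ in range(5):
            noisy = clean + rng.normal(scale=0.01, size=clean.shape)
            tf = upper_model.align_partial(
                PartialObservation(tuple(crown), noisy.reshape(-1)))
            assert np.linalg.norm(tf.rotation - np.eye(3)) < 0.01
            assert np.linalg.norm(tf.translation) < 0.01

    def test_collinear_observation_rejected(self, upper_model):
        labels = upper_model.labels[:3]
        coords = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2.0])
        with pytest.raises(ValueError, match="collinear"):
            upper_model.align_partial(PartialObservation(tuple(labels), coords))


class TestReconstruct:
    def test_mean_observation_gives_zero_scores(self, upper_model):
        obs = crown_observation(upper_model, upper_model.mean_dentition())
        rec = upper_model.reconstruct(obs)
        np.testing.assert_allclose(rec.scores, 0.0, atol=1e-8)
        np.testing.assert_allclose(
            to_vector(rec.full_configuration, upper_model.labels),
            upper_model.mean, atol=1e-7)

    def test_identifiable_one_mode_recovery(self, one_mode_model, template):
        """Noiseless observation from the mode: roots match ground truth."""
        truth_vec = one_mode_model.mean + one_mode_model.modes[:, 0] * 5.0
        from dentaxis.dentition import from_vector
        truth = from_vector(truth_vec, one_mode_model.labels, one_mode_model.protocol)
        obs = crown_observation(one_mode_model, truth)
        rec = reconstruct(one_mode_model, obs,
                          ReconstructionConfig(noise_sd_mm=1e-6))
        assert rec.scores[0] == pytest.approx(5.0, abs=1e-4)
        for label in one_mode_model.labels:
            if label.kind is LandmarkKind.ROOT:
                np.testing.assert_allclose(
                    rec.full_configuration[label], truth[label], atol=1e-4)

    def test_noise_to_zero_convergence_on_observed_block(self, one_mode_model):
        """Ridge limit: observed coordinates are reproduced as sigma -> 0."""
        truth_vec = one_mode_model.mean + one_mode_model.modes[:, 0] * 5.0
        from dentaxis.dentition import from_vector
        truth = from_vector(truth_vec, one_mode_model.labels, one_mode_model.protocol)
        obs = crown_observation(one_mode_model, truth)
        discrepancies = []
        for sd in (1.0, 0.1, 0.01, 0.001):
            rec = reconstruct(one_mode_model, obs,
                              ReconstructionConfig(noise_sd_mm=sd))
            pred = np.concatenate(
                [rec.full_configuration[l] for l in obs.labels])
            discrepancies.append(np.max(np.abs(pred - obs.coordinates)))
        assert all(a >= b - 1e-12 for a, b in zip(discrepancies, discrepancies[1:]))
        assert discrepancies[-1] < 1e-5

    def test_empty_observation_rejected(self, upper_model):
        with pytest.raises(ValueError, match="at least 3|empty"):
            upper_model.reconstruct(PartialObservation((), np.empty(0)))

    def test_projection_method_agrees_in_low_noise_limit(self, one_mode_model):
        truth_vec = one_mode_model.mean + one_mode_model.modes[:, 0] * 3.0
        from dentaxis.dentition import from_vector
        truth = from_vector(truth_vec, one_mode_model.labels, one_mode_model.protocol)
        obs = crown_observation(one_mode_model, truth)
        posterior = reconstruct(one_mode_model, obs,
                                ReconstructionConfig(noise_sd_mm=1e-6))
        projection = reconstruct(one_mode_model, obs,
                                 ReconstructionConfig(method="projection"))
        np.testing.assert_allclose(posterior.scores, projection.scores, atol=1e-4)

    def test_mahalanobis_cap_shrinks_extreme_observations(self, one_mode_model):
        truth_vec = one_mode_model.mean + one_mode_model.modes[:, 0] * 100.0
        from dentaxis.dentition import from_vector
        truth = from_vector(truth_vec, one_mode_model.labels, one_mode_model.protocol)
        obs = crown_observation(one_mode_model, truth)
        rec = reconstruct(one_mode_model, obs,
                          ReconstructionConfig(noise_sd_mm=1e-6, max_mahalanobis=3.0))
        assert rec.mahalanobis <= 3.0 + 1e-9


class TestPredictAxes:
    def test_mean_crowns_give_mean_axes(self, upper_model):
        obs = crown_observation(upper_model, upper_model.mean_dentition())
        axes = upper_model.predict_axes(obs)
        mean_d = upper_model.mean_dentition()
        for tooth, axis in axes.items():
            expected = fit_tooth_axis(_root_points(mean_d, tooth))
            assert angle_between_axes(axis, expected) < 1e-5

    def test_in_sample_self_consistency(self, noiseless_population, upper_model):
        """Crowns of a training case predict its own axes to < 0.5 deg."""
        dataset, truth = noiseless_population
        i = 3
        obs = crown_observation(upper_model, dataset[i])
        axes = upper_model.predict_axes(
            obs, ReconstructionConfig(noise_sd_mm=1e-4))
        errs = [angle_between_axes(axes[t], truth.true_axes[i][t])
                for t in axes]
        assert max(errs) < 0.5

    def test_rigid_equivariance(self, upper_model, noiseless_population, rng):
        dataset, _ = noiseless_population
        obs = crown_observation(upper_model, dataset[2])
        axes = upper_model.predict_axes(obs)
        tf = random_rigid(rng)
        moved = PartialObservation(
            obs.labels, tf.apply(obs.points).reshape(-1))
        moved_axes = upper_model.predict_axes(moved)
        for tooth in axes:
            expected = axes[tooth].transformed(tf.rotation, tf.translation)
            assert angle_between_axes(expected, moved_axes[tooth]) < 1e-5
            np.testing.assert_allclose(
                moved_axes[tooth].anchor, expected.anchor, atol=1e-4)


class TestSampleAndPersistence:
    def test_zero_scores_give_mean(self, upper_model):
        d = sample_shape(upper_model, scores=np.zeros(upper_model.n_modes))
        np.testing.assert_array_equal(
            to_vector(d, upper_model.labels), upper_model.mean)

    def test_score_length_checked(self, upper_model):
        with pytest.raises(ValueError):
            sample_shape(upper_model, scores=np.zeros(upper_model.n_modes + 1))

    def test_sampled_population_variance_matches_model(self, upper_model):
        samples = np.stack([
            to_vector(sample_shape(upper_model, rng=seed), upper_model.labels)
            for seed in range(1000)])
        coeffs = (samples - upper_model.mean) @ upper_model.modes
        empirical = coeffs.var(axis=0, ddof=1)
        np.testing.assert_allclose(empirical, upper_model.variances, rtol=0.10)

    def test_save_load_round_trip(self, upper_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(upper_model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.mean, upper_model.mean)
        np.testing.assert_array_equal(loaded.modes, upper_model.modes)
        np.testing.assert_array_equal(loaded.variances, upper_model.variances)
        assert loaded.labels == upper_model.labels
        assert loaded.jaw is upper_model.jaw
        assert loaded.n_train == upper_model.n_train

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema_version": 99}')
        with pytest.raises(ValueError, match="schema"):
            load_model(path)

    def test_summary_reports_fit(self, upper_model):
        text = upper_model.summary()
        assert "upper" in text
        assert str(upper_model.n_train) in text
        assert "mode" in text
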