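"""The per-jaw statistical shape model (SSM) and missing-landmark inference.

The model follows the classic point-distribution construction: training
configurations are brought into a common frame by size-preserving
generalized Procrustes alignment, and the aligned coordinate vectors are
decomposed by PCA into a mean shape, orthonormal variation modes and
per-mode variances.  Any plausible dentition is then ``mean + modes @ s``
for a score vector ``s`` with prior ``s_j ~ N(0, variance_j)``.

Given a *partial* observation (typically the crown landmarks of a surface
scan, possibly with one tooth missing), the unobserved landmarks -- the
root-canal landmarks -- are inferred in three steps:

1. rigid pose of the observation into model space, fitted on the observed
   landmarks against the corresponding mean-shape landmarks;
2. posterior-mean mode scores under the probabilistic-PCA observation model
   ``x_obs = mean_obs + M_obs @ s + eps``, ``eps ~ N(0, sigma^2 I)``:

       s* = (Sigma^-1 + M_obs' M_obs / sigma^2)^-1 M_obs' (x_obs - mean_obs) / sigma^2

   with ``Sigma = diag(variances)``; the ridge term keeps the inference
   stable when the observed block is rank-deficient and shrinks implausible
   shapes toward the mean;
3. synthesis of the full configuration and mapping back into the
   observation's original spatial frame.

Usage mirrors the statsmodels convention: build a :class:`DentalShapeModel`
from a dataset, call :meth:`~DentalShapeModel.fit`, and work with the
returned :class:`ShapeModelResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .axes import ToothAxisLine, fit_tooth_axis
from .dentition import (
    DentitionDataset,
    DentitionLandmarks,
    from_vector,
    to_vector,
)
from .procrustes import GPAResult, RigidTransform, gpa_align, rigid_fit
from .protocol import (
    Jaw,
    LandmarkKind,
    LandmarkLabel,
    LandmarkProtocol,
    ToothId,
    make_default_protocol,
)

__all__ = [
    "DentalShapeModel",
    "ShapeModelResults",
    "PartialObservation",
    "Reconstruction",
    "ReconstructionConfig",
    "build_model",
    "align_partial",
    "reconstruct",
    "predict_axes",
    "sample_shape",
    "save_model",
    "load_model",
]

MODEL_SCHEMA_VERSION = 1

#: Eigenvalues below this fraction of the largest are treated as numerically
#: zero and never retained, independent of ``variance_fraction``.
_EIG_REL_TOL = 1e-12


@dataclass(frozen=True)
class ReconstructionConfig:
    """Settings for missing-landmark inference.

    noise_sd_mm
        Assumed isotropic landmark noise (mm); order of the combined scan
        and landmark-placement error.  Acts as the ridge strength.
    max_mahalanobis
        Cap on the total Mahalanobis norm of the scores; ``None`` derives
        the default ``3 * sqrt(m)`` from the number of modes.  Keeps
        reconstructions within the plausible shape population.
    method
        ``"posterior"`` (probabilistic-PCA posterior mean, default) or
        ``"projection"`` (unregularized least squares onto the modes).
    """

    noise_sd_mm: float = 0.3
    max_mahalanobis: float | None = None
    method: str = "posterior"
    max_pose_iterations: int = 50
    pose_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.noise_sd_mm <= 0:
            raise ValueError("noise_sd_mm must be positive")
        if self.method not in ("posterior", "projection"):
            raise ValueError(f"unknown reconstruction method {self.method!r}")
        if self.max_pose_iterations < 1:
            raise ValueError("max_pose_iterations must be >= 1")


@dataclass(frozen=True)
class PartialObservation:
    """A label subset with coordinates, in an arbitrary spatial frame."""

    labels: tuple[LandmarkLabel, ...]
    coordinates: np.ndarray  # flat, length 3 * len(labels)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3 * len(self.labels),):
            raise ValueError("coordinates length must be 3 x number of labels")
        coords.setflags(write=False)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "coordinates", coords)

    @classmethod
    def from_dentition(cls, dentition: DentitionLandmarks,
                       labels: Sequence[LandmarkLabel] | None = None,
                       ) -> "PartialObservation":
        labels = tuple(labels) if labels is not None else dentition.labels
        return cls(labels, to_vector(dentition, labels))

    @property
    def points(self) -> np.ndarray:
        return self.coordinates.reshape(-1, 3)


@dataclass(frozen=True)
class Reconstruction:
    """A completed configuration in the observation's original frame."""

    full_configuration: DentitionLandmarks
    scores: np.ndarray
    pose: RigidTransform  # model space -> observation space
    mahalanobis: float


class DentalShapeModel:
    """Point-distribution shape model of one jaw, fitted by GPA + PCA.

    Parameters
    ----------
    dataset : DentitionDataset
        Training individuals; each must be complete for ``jaw``.
    jaw : Jaw
        Which dental arch to model.  Per-jaw models are the default because
        the evaluation protocol reports the two arches separately; a
        combined model can be built by passing ``jaw=None``.
    variance_fraction : float
        Fraction of total sample variance the retained modes must explain,
        in (0, 1].  1.0 keeps every non-null mode.
    """

    def __init__(self, dataset: DentitionDataset, jaw: Jaw | None,
                 variance_fraction: float = 0.98):
        if not 0 < variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        if dataset.n_individuals < 2:
            raise ValueError("model fitting needs at least 2 individuals")
        self.dataset = dataset
        self.jaw = jaw
        self.variance_fraction = float(variance_fraction)
        proto = dataset.protocol
        self.labels: tuple[LandmarkLabel, ...] = (
            proto.labels_of_jaw(jaw) if jaw is not None else proto.label_order)
        for ind in dataset:
            missing = [l for l in self.labels if l not in ind]
            if missing:
                raise ValueError(
                    f"individual {ind.individual_id!r} lacks {len(missing)} "
                    f"labels required for the {jaw.value if jaw else 'combined'} model")

    def fit(self, gpa_tol: float = 1e-7, gpa_max_iter: int = 100) -> "ShapeModelResults":
        """Align the training set and decompose it into variation modes."""
        n = self.dataset.n_individuals
        K = len(self.labels)
        configs = np.stack([
            to_vector(ind, self.labels).reshape(K, 3) for ind in self.dataset
        ])
        gpa = gpa_align(configs, tol=gpa_tol, max_iter=gpa_max_iter)
        flat = gpa.aligned.reshape(n, 3 * K)
        mean = flat.mean(axis=0)
        centered = flat - mean
        # Thin SVD of the centered data matrix; eigenvalues of the sample
        # covariance (n-1 divisor) are s^2 / (n-1).
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eig = s ** 2 / (n - 1)
        nonnull = eig > _EIG_REL_TOL * max(eig[0], 1.0) if eig.size else eig > 0
        eig = eig[nonnull]
        vt = vt[nonnull]
        if eig.size:
            cum = np.cumsum(eig) / eig.sum()
            m = int(np.searchsorted(cum, self.variance_fraction - 1e-12) + 1)
            m = min(m, eig.size)
        else:
            m = 0
        return ShapeModelResults(
            model=self,
            protocol=self.dataset.protocol,
            jaw=self.jaw,
            labels=self.labels,
            mean=mean,
            modes=vt[:m].T.copy(),
            variances=eig[:m].copy(),
            total_variance=float(eig.sum()) if eig.size else 0.0,
            n_train=n,
            variance_fraction=self.variance_fraction,
            gpa=gpa,
        )


@dataclass(frozen=True)
class ShapeModelResults:
    """A fitted SSM: mean shape, orthonormal modes, per-mode variances.

    ``mean`` is a flat vector of length ``3K`` over ``labels`` (mm, model
    frame); ``modes`` is ``(3K, m)`` column-orthonormal; ``variances`` the
    corresponding eigenvalues of the sample covariance, non-increasing.
    """

    protocol: LandmarkProtocol
    jaw: Jaw | None
    labels: tuple[LandmarkLabel, ...]
    mean: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    total_variance: float
    n_train: int
    variance_fraction: float
    gpa: GPAResult | None = None
    model: DentalShapeModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        modes = np.asarray(self.modes, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        if modes.shape != (mean.size, variances.size):
            raise ValueError("modes must be (3K, m) matching mean and variances")
        if variances.size and np.any(np.diff(variances) > 1e-9 * variances[0]):
            raise ValueError("variances must be non-increasing")
        if modes.size and not np.allclose(modes.T @ modes,
                                          np.eye(variances.size), atol=1e-8):
            raise ValueError("modes must be column-orthonormal")
        for arr in (mean, modes, variances):
            arr.setflags(write=False)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "variances", variances)

    # -- basic queries ----------------------------------------------------

    @property
    def n_modes(self) -> int:
        return int(self.variances.size)

    @property
    def n_landmarks(self) -> int:
        return len(self.labels)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros(self.n_modes)
        return self.variances / self.total_variance

    def mean_dentition(self, individual_id: str = "mean") -> DentitionLandmarks:
        return from_vector(self.mean, self.labels, self.protocol, individual_id)

    def _label_rows(self, labels: Sequence[LandmarkLabel]) -> np.ndarray:
        """Flat-vector row indices of the given labels (3 per landmark)."""
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = []
        for l in labels:
            if l not in pos:
                raise KeyError(f"label {l} not in model")
            base = 3 * pos[l]
            idx.extend((base, base + 1, base + 2))
        return np.asarray(idx, dtype=int)

    # -- inference --------------------------------------------------------

    def align_partial(self, obs: PartialObservation) -> RigidTransform:
        return align_partial(self, obs)

    def reconstruct(self, obs: PartialObservation,
                    config: ReconstructionConfig | None = None) -> Reconstruction:
        return reconstruct(self, obs, config)

    def predict_axes(self, obs: PartialObservation,
                     config: ReconstructionConfig | None = None,
                     ) -> dict[ToothId, ToothAxisLine]:
        return predict_axes(self, obs, config)

    def sample_shape(self, scores: np.ndarray | None = None,
                     rng: np.random.Generator | int | None = None,
                     individual_id: str = "sample") -> DentitionLandmarks:
        return sample_shape(self, scores=scores, rng=rng, individual_id=individual_id)

    def save(self, path: str | Path) -> None:
        save_model(self, path)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit report: size, spectrum, GPA diagnostics."""
        lines = [
            "Dental Shape Model Results",
            "=" * 60,
            f"Jaw:                 {self.jaw.value if self.jaw else 'combined'}",
            f"Landmarks (K):       {self.n_landmarks}  ({3 * self.n_landmarks} coordinates)",
            f"Training individuals: {self.n_train}",
            f"Retained modes:      {self.n_modes} "
            f"(target variance fraction {self.variance_fraction:g})",
            f"Total shape variance: {self.total_variance:.4f} mm^2",
        ]
        if self.gpa is not None:
            lines.append(
                f"GPA:                 {self.gpa.n_iterations} iterations, "
                f"{'converged' if self.gpa.converged else 'NOT converged'}")
        if self.n_modes:
            lines += ["-" * 60, "mode   variance(mm^2)   sd(mm)   explained   cumulative"]
            cum = 0.0
            for j in range(self.n_modes):
                frac = float(self.explained_variance_ratio[j])
                cum += frac
                lines.append(
                    f"{j + 1:>4}   {self.variances[j]:>13.5f}   "
                    f"{np.sqrt(self.variances[j]):>6.3f}   {frac:>8.1%}   {cum:>9.1%}")
        lines.append("=" * 60)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional layer


def build_model(aligned: np.ndarray, labels: Sequence[LandmarkLabel],
                protocol: LandmarkProtocol, jaw: Jaw | None,
                variance_fraction: float = 0.98,
                gpa: GPAResult | None = None) -> ShapeModelResults:
    """PCA decomposition of already-aligned configurations.

    ``aligned`` is (n, K, 3) in a common frame (e.g. :func:`gpa_align`
    output).  Exposed for callers that manage alignment themselves; the
    usual entry point is :meth:`DentalShapeModel.fit`.
    """
    aligned = np.asarray(aligned, dtype=float)
    n = aligned.shape[0]
    if n < 2:
        raise ValueError("model fitting needs at least 2 configurations")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    flat = aligned.reshape(n, -1)
    mean = flat.mean(axis=0)
    _, s, vt = np.linalg.svd(flat - mean, full_matrices=False)
    eig = s ** 2 / (n - 1)
    nonnull = eig > _EIG_REL_TOL * max(eig[0], 1.0) if eig.size else eig > 0
    eig, vt = eig[nonnull], vt[nonnull]
    if eig.size:
        cum = np.cumsum(eig) / eig.sum()
        m = min(int(np.searchsorted(cum, variance_fraction - 1e-12) + 1), eig.size)
    else:
        m = 0
    return ShapeModelResults(
        protocol=protocol, jaw=jaw, labels=tuple(labels), mean=mean,
        modes=vt[:m].T.copy(), variances=eig[:m].copy(),
        total_variance=float(eig.sum()) if eig.size else 0.0,
        n_train=n, variance_fraction=variance_fraction, gpa=gpa)


def align_partial(results: ShapeModelResults, obs: PartialObservation) -> RigidTransform:
    """Rigid pose of an observation into model space (no scaling).

    Fitted on the observed landmarks against the corresponding mean-shape
    landmarks; needs >= 3 non-collinear observed landmarks.
    """
    if len(obs.labels) < 3:
        raise ValueError("pose alignment needs at least 3 observed landmarks")
    rows = results._label_rows(obs.labels)
    target = results.mean[rows].reshape(-1, 3)
    return rigid_fit(obs.points, target)


def reconstruct(results: ShapeModelResults, obs: PartialObservation,
                config: ReconstructionConfig | None = None) -> Reconstruction:
    """Infer the full configuration from a partial observation.

    See the module docstring for the three-step procedure.  Deterministic
    given inputs.  Scores whose total Mahalanobis norm exceeds the cap are
    shrunk radially onto the cap.
    """
    config = config or ReconstructionConfig()
    if len(obs.labels) == 0:
        raise ValueError("cannot reconstruct from an empty observation")
    rows = results._label_rows(obs.labels)
    mu_obs = results.mean[rows]
    M = results.modes[rows, :]  # (3k_obs, m)
    m = results.n_modes
    cap = (config.max_mahalanobis if config.max_mahalanobis is not None
           else 3.0 * np.sqrt(m))

    def solve_scores(dev: np.ndarray) -> np.ndarray:
        if config.method == "posterior":
            sigma2 = config.noise_sd_mm ** 2
            A = np.diag(1.0 / results.variances) + (M.T @ M) / sigma2
            s = np.linalg.solve(A, M.T @ dev / sigma2)
        else:  # plain least-squares projection
            s, *_ = np.linalg.lstsq(M, dev, rcond=None)
        maha = float(np.sqrt(np.sum(s ** 2 / results.variances)))
        if np.isfinite(maha) and maha > cap > 0:
            s = s * (cap / maha)
        return s

    # Alternate pose and scores: the first pose targets the mean shape
    # (observed block), each refinement re-poses the observation onto the
    # current reconstruction.  Without refinement the rigid fit absorbs
    # part of the shape deformation visible on the observed block, which
    # biases the inferred scores; iterating removes that first-order bias.
    scores = np.zeros(m)
    pose_to_model = align_partial(results, obs)
    if m > 0:
        for _ in range(config.max_pose_iterations):
            dev = pose_to_model.apply(obs.points).reshape(-1) - mu_obs
            new_scores = solve_scores(dev)
            delta = float(np.linalg.norm(new_scores - scores))
            scores = new_scores
            target = (mu_obs + M @ scores).reshape(-1, 3)
            pose_to_model = rigid_fit(obs.points, target)
            if delta < config.pose_tol:
                break
    full_model_frame = results.mean + results.modes @ scores
    pose_to_obs = pose_to_model.inverse()
    full_obs_frame = pose_to_obs.apply(full_model_frame.reshape(-1, 3)).reshape(-1)
    maha = float(np.sqrt(np.sum(scores ** 2 / results.variances))) if m else 0.0
    return Reconstruction(
        full_configuration=from_vector(full_obs_frame, results.labels,
                                       results.protocol, "reconstructed"),
        scores=scores,
        pose=pose_to_obs,
        mahalanobis=maha,
    )


def predict_axes(results: ShapeModelResults, obs: PartialObservation,
                 config: ReconstructionConfig | None = None,
                 ) -> dict[ToothId, ToothAxisLine]:
    """Reconstruct, then fit the root axis of every tooth in the model's jaw.

    Axes are returned in the observation's original spatial frame.
    """
    rec = reconstruct(results, obs, config)
    axes: dict[ToothId, ToothAxisLine] = {}
    teeth = {l.tooth for l in results.labels}
    for tooth in sorted(teeth):
        root = np.stack([
            rec.full_configuration[LandmarkLabel(tooth, LandmarkKind.ROOT, k)]
            for k in range(1, 5)
        ])
        axes[tooth] = fit_tooth_axis(root)
    return axes


def sample_shape(results: ShapeModelResults, scores: np.ndarray | None = None,
                 rng: np.random.Generator | int | None = None,
                 individual_id: str = "sample") -> DentitionLandmarks:
    """Synthesize ``mean + modes @ s``; draw s from the model prior if absent."""
    if scores is None:
        gen = np.random.default_rng(rng)
        scores = gen.normal(0.0, np.sqrt(results.variances))
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (results.n_modes,):
        raise ValueError(
            f"expected {results.n_modes} scores, got shape {scores.shape}")
    vec = results.mean + results.modes @ scores
    return from_vector(vec, results.labels, results.protocol, individual_id)


# ---------------------------------------------------------------------------
# persistence (JSON, versioned, text-only)


def _label_str(l: LandmarkLabel) -> str:
    return f"{l.tooth.fdi_code}_{l.kind.value}_{l.index}"


def _label_from_str(s: str) -> LandmarkLabel:
    fdi, kind, idx = s.split("_")
    return LandmarkLabel(ToothId(int(fdi)), LandmarkKind(kind), int(idx))


def save_model(results: ShapeModelResults, path: str | Path,
               metadata: Mapping[str, str] | None = None) -> None:
    """Serialize a fitted model to a versioned JSON file (repr-exact floats)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "protocol_hash": results.protocol.content_hash(),
        "crown_counts": {str(t.fdi_code): n
                         for t, n in results.protocol.crown_counts.items()},
        "jaw": results.jaw.value if results.jaw is not None else None,
        "labels": [_label_str(l) for l in results.labels],
        "mean": results.mean.tolist(),
        "modes": results.modes.tolist(),
        "variances": results.variances.tolist(),
        "total_variance": results.total_variance,
        "n_train": results.n_train,
        "variance_fraction": results.variance_fraction,
        "metadata": dict(metadata or {}),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ShapeModelResults:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {payload.get('schema_version')!r}")
    crown_counts = {ToothId(int(k)): int(v)
                    for k, v in payload["crown_counts"].items()}
    protocol = LandmarkProtocol(crown_counts=crown_counts)
    if protocol.content_hash() != payload["protocol_hash"]:
        raise ValueError("model file protocol hash mismatch (corrupt file?)")
    labels = tuple(_label_from_str(s) for s in payload["labels"])
    return ShapeModelResults(
        protocol=protocol,
        jaw=Jaw(payload["jaw"]) if payload["jaw"] else None,
        labels=labels,
        mean=np.asarray(payload["mean"], dtype=float),
        modes=np.asarray(payload["modes"], dtype=float).reshape(
            len(payload["mean"]), len(payload["variances"])),
        variances=np.asarray(payload["variances"], dtype=float),
        total_variance=float(payload["total_variance"]),
        n_train=int(payload["n_train"]),
        variance_fraction=float(payload["variance_fraction"]),
    )
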