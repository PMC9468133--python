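"""Synthetic dentition populations with known ground truth.

No patient landmark data are deposited with the method this package
implements, so every pipeline stage is exercised on generated populations
that have exactly the statistical structure the shape model assumes:

    individual = template + sum_j s_ij * mode_j + noise,  then rigid pose

* The *template* is an idealized, midsagittally mirror-symmetric dentition:
  tooth centers on a parabolic arch per jaw, crown landmarks arranged
  around each tooth center by tooth class, root landmarks LM-1 at the CEJ
  reference point, LM-2..LM-4 at exactly 2 mm apical steps along a
  tooth-local inclined axis, LM-5 at the root apex.
* The *modes* are smooth parametric deformation fields (arch width, arch
  depth, whole-tooth inclination, root flare, left/right asymmetry, arch
  curvature), orthonormalized.  Because inclination and arch fields move
  crown and root landmarks of a tooth together, crown positions genuinely
  carry information about root axes -- the identifiability property the
  reconstruction method rests on.  The root-flare field moves roots only
  and represents variation that crowns cannot predict.
* Scores are centered Gaussian with per-mode standard deviations given in
  configuration-vector norm units; landmark noise is iid isotropic.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .axes import ToothAxisLine, fit_tooth_axis
from .dentition import DentitionDataset, DentitionLandmarks, from_vector, to_vector
from .procrustes import RigidTransform
from .protocol import (
    Jaw,
    LandmarkKind,
    LandmarkLabel,
    LandmarkProtocol,
    ToothClass,
    ToothId,
    make_default_protocol,
)

__all__ = [
    "ArchTemplateParams",
    "SyntheticPopulationSpec",
    "GroundTruth",
    "make_template",
    "generate_population",
    "benchmark_dataset",
    "BENCHMARK_PRESETS",
]


@dataclass(frozen=True)
class ArchTemplateParams:
    """Geometry of the idealized template dentition (all lengths mm)."""

    arch_width_mm: float = 60.0
    arch_depth_mm: float = 45.0
    crown_height_mm: float = 8.0
    root_length_mm: Mapping[ToothClass, float] = field(default_factory=lambda: {
        ToothClass.INCISOR: 12.0,
        ToothClass.CANINE: 16.0,
        ToothClass.PREMOLAR: 13.0,
        ToothClass.MOLAR: 12.0,
    })
    #: apical spacing of root landmarks LM-1..LM-4 along the local axis
    inter_landmark_spacing_mm: float = 2.0
    #: vertical separation between the two jaws' CEJ planes
    jaw_separation_mm: float = 30.0

    def __post_init__(self) -> None:
        lengths = [self.arch_width_mm, self.arch_depth_mm, self.crown_height_mm,
                   self.inter_landmark_spacing_mm, *self.root_length_mm.values()]
        if any(v <= 0 for v in lengths):
            raise ValueError("all template lengths must be positive")


_CROWN_RADIUS = {  # ring radius of crown landmarks per tooth class, mm
    ToothClass.INCISOR: 2.2,
    ToothClass.CANINE: 2.6,
    ToothClass.PREMOLAR: 3.0,
    ToothClass.MOLAR: 3.8,
}
_AXIS_TILT = {  # outward (buccal) tilt of the root axis per class
    ToothClass.INCISOR: 0.22,
    ToothClass.CANINE: 0.18,
    ToothClass.PREMOLAR: 0.10,
    ToothClass.MOLAR: 0.06,
}


def _arch_param(tooth: ToothId) -> float:
    """Signed arch coordinate u in (-1, 1); negative on quadrant 1/4 side."""
    side = -1.0 if tooth.quadrant in (1, 4) else 1.0
    return side * (tooth.position - 0.5) / 7.0


def _tooth_frame(tooth: ToothId, params: ArchTemplateParams):
    """(center, outward normal, distal tangent, apical axis) of one tooth.

    The frame is defined purely from the arch geometry with side-symmetric
    rules (outward, distal), so mirror teeth get mirrored frames and the
    template is exactly symmetric about the midsagittal plane x = 0.
    """
    u = _arch_param(tooth)
    w2 = params.arch_width_mm / 2.0
    d = params.arch_depth_mm
    x = w2 * u
    y = d * (1.0 - u * u)
    z_cej = 0.0 if tooth.jaw is Jaw.UPPER else -params.jaw_separation_mm
    center = np.array([x, y, z_cej])

    # outward normal of the parabola (x(u), y(u)): rotate tangent (w2, -2du)
    normal_xy = np.array([2.0 * d * u, w2])
    outward = np.append(normal_xy / np.linalg.norm(normal_xy), 0.0)
    tangent_xy = np.array([w2, -2.0 * d * u])
    sign = -1.0 if u < 0 else 1.0
    distal = np.append(sign * tangent_xy / np.linalg.norm(tangent_xy), 0.0)

    apical_z = 1.0 if tooth.jaw is Jaw.UPPER else -1.0
    axis = np.array([0.0, 0.0, apical_z]) + _AXIS_TILT[tooth.tooth_class] * outward
    axis = axis / np.linalg.norm(axis)
    return center, outward, distal, axis


def make_template(protocol: LandmarkProtocol | None = None,
                  params: ArchTemplateParams | None = None) -> DentitionLandmarks:
    """Deterministic idealized dentition under the given protocol."""
    protocol = protocol or make_default_protocol()
    params = params or ArchTemplateParams()
    spacing = params.inter_landmark_spacing_mm
    points: dict[LandmarkLabel, np.ndarray] = {}
    for tooth in protocol.teeth:
        center, outward, distal, axis = _tooth_frame(tooth, params)
        coronal = -axis
        # crown landmarks: a ring in the (outward, distal) plane at
        # mid-crown height, starting buccally; deterministic per class
        n_crown = protocol.crown_counts[tooth]
        r = _CROWN_RADIUS[tooth.tooth_class]
        for j in range(1, n_crown + 1):
            theta = 2.0 * np.pi * (j - 1) / n_crown
            offset = r * (np.cos(theta) * outward + np.sin(theta) * distal)
            depth = 0.55 * params.crown_height_mm if j % 2 else 0.85 * params.crown_height_mm
            p = center + offset + depth * coronal
            points[LandmarkLabel(tooth, LandmarkKind.CROWN, j)] = p
        # root landmarks: LM-1 at CEJ, LM-2..4 at exact 2 mm apical steps,
        # LM-5 at the apex
        for k in range(1, 5):
            points[LandmarkLabel(tooth, LandmarkKind.ROOT, k)] = (
                center + spacing * (k - 1) * axis)
        apex = center + params.root_length_mm[tooth.tooth_class] * axis
        points[LandmarkLabel(tooth, LandmarkKind.ROOT, 5)] = apex
    return DentitionLandmarks("template", points, protocol)


# ---------------------------------------------------------------------------
# deformation-mode construction


def _mode_fields(template: DentitionLandmarks,
                 params: ArchTemplateParams) -> np.ndarray:
    """Raw (un-orthonormalized) deformation fields, one row per field.

    Order: arch width, whole-tooth inclination, arch depth, root flare,
    left/right inclination asymmetry, arch curvature.  Fields 1-3 and 5-6
    move crowns and roots coherently; field 4 moves roots only.
    """
    protocol = template.protocol
    labels = protocol.label_order
    P = to_vector(template, labels).reshape(-1, 3)
    frames = {t: _tooth_frame(t, params) for t in protocol.teeth}

    fields = np.zeros((6, len(labels), 3))
    for i, label in enumerate(labels):
        tooth = label.tooth
        center, outward, distal, axis = frames[tooth]
        p = P[i]
        rel = p - center
        u = _arch_param(tooth)
        # 1: arch width -- lateral stretch
        fields[0, i] = np.array([p[0], 0.0, 0.0])
        # 2: inclination -- rigid rotation of each tooth about its CEJ
        # around the distal tangent (linearized); crowns and roots swing
        # in opposite senses, the core crown->root coupling
        fields[1, i] = np.cross(distal, rel)
        # 3: arch depth -- anteroposterior stretch
        fields[2, i] = np.array([0.0, p[1], 0.0])
        # 4: root flare -- roots splay buccally with apical distance
        if label.kind is LandmarkKind.ROOT:
            apical_dist = float(rel @ axis)
            fields[3, i] = apical_dist / 6.0 * outward
        # 5: asymmetry -- inclination growing linearly across the arch
        fields[4, i] = u * np.cross(distal, rel)
        # 6: curvature -- anterior teeth rise, posterior sink (per jaw)
        zsign = 1.0 if tooth.jaw is Jaw.UPPER else -1.0
        fields[5, i] = np.array([0.0, 0.0, zsign * (1.0 - 2.0 * u * u)])
    return fields.reshape(6, -1)


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Configuration of one synthetic population draw.

    ``mode_sd_mm`` are standard deviations of the per-mode scores in
    configuration-vector norm units (the modes are unit vectors over the
    full flattened configuration, so a score sd of 8 mm corresponds to a
    per-landmark RMS displacement of about 8 / sqrt(270) ~ 0.5 mm).
    """

    n_individuals: int = 30
    n_modes: int = 4
    mode_sd_mm: tuple[float, ...] = (8.0, 6.0, 5.0, 4.0, 3.0, 2.0)
    landmark_noise_sd_mm: float = 0.05
    pose: str = "random_rigid"  # or "none"
    seed: int = 0
    protocol: LandmarkProtocol | None = None
    template_params: ArchTemplateParams | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_modes < 0 or self.n_modes > 6:
            raise ValueError("n_modes must be between 0 and 6 (available fields)")
        if len(self.mode_sd_mm) < self.n_modes:
            raise ValueError("need a mode_sd_mm entry per mode")
        if any(sd < 0 for sd in self.mode_sd_mm) or self.landmark_noise_sd_mm < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.pose not in ("none", "random_rigid"):
            raise ValueError(f"unknown pose option {self.pose!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knew: the recipe of each individual."""

    template: DentitionLandmarks
    modes: np.ndarray                    # (n_modes, 3K) orthonormal rows
    scores: np.ndarray                   # (n, n_modes)
    transforms: tuple[RigidTransform, ...]   # applied pose per individual
    true_axes: tuple[Mapping[ToothId, ToothAxisLine], ...]  # noiseless, posed


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via quaternion draw."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def generate_population(spec: SyntheticPopulationSpec,
                        ) -> tuple[DentitionDataset, GroundTruth]:
    """Draw a population of dentitions according to ``spec``.

    Per-individual noiseless shapes live exactly in the affine span of the
    template and the first ``n_modes`` orthonormalized deformation fields;
    the ground truth records modes, scores, poses and the true (noiseless)
    tooth axes in each individual's final frame.
    """
    protocol = spec.protocol or make_default_protocol()
    params = spec.template_params or ArchTemplateParams()
    template = make_template(protocol, params)
    labels = protocol.label_order
    t_vec = to_vector(template, labels)

    raw = _mode_fields(template, params)
    # orthonormalize, preserving the field order (QR on the transpose)
    q, _ = np.linalg.qr(raw.T)
    modes = q.T[: spec.n_modes]

    rng = np.random.default_rng(spec.seed)
    sds = np.asarray(spec.mode_sd_mm[: spec.n_modes], dtype=float)
    scores = rng.normal(0.0, 1.0, size=(spec.n_individuals, spec.n_modes)) * sds
    noise = rng.normal(0.0, spec.landmark_noise_sd_mm,
                       size=(spec.n_individuals, t_vec.size))

    individuals = []
    transforms = []
    true_axes = []
    root_idx = {t: [labels.index(LandmarkLabel(t, LandmarkKind.ROOT, k))
                    for k in range(1, 5)] for t in protocol.teeth}
    for i in range(spec.n_individuals):
        clean = t_vec + modes.T @ scores[i] if spec.n_modes else t_vec.copy()
        noisy = clean + noise[i]
        if spec.pose == "random_rigid":
            R = _random_rotation(rng)
            t = rng.uniform(-20.0, 20.0, size=3)
            tf = RigidTransform(R, t)
        else:
            tf = RigidTransform.identity()
        transforms.append(tf)
        posed = tf.apply(noisy.reshape(-1, 3)).reshape(-1)
        clean_posed = tf.apply(clean.reshape(-1, 3))
        individuals.append(from_vector(posed, labels, protocol, f"syn{i:03d}"))
        axes = {}
        for tooth in protocol.teeth:
            axes[tooth] = fit_tooth_axis(clean_posed[root_idx[tooth]])
        true_axes.append(axes)

    dataset = DentitionDataset(tuple(individuals), metadata={
        "generator": "dentaxis.synthetic", "seed": str(spec.seed),
        "n_modes": str(spec.n_modes), "pose": spec.pose,
        "landmark_noise_sd_mm": str(spec.landmark_noise_sd_mm),
    })
    truth = GroundTruth(template=template, modes=modes, scores=scores,
                        transforms=tuple(transforms), true_axes=tuple(true_axes))
    return dataset, truth


#: Named benchmark conditions.  ``paper_scale`` matches the evaluated cohort
#: size of 71 individuals (270 landmarks each, 19,170 in total).
BENCHMARK_PRESETS: dict[str, SyntheticPopulationSpec] = {
    "smoke": SyntheticPopulationSpec(
        n_individuals=10, n_modes=2, landmark_noise_sd_mm=0.05, seed=101),
    "default": SyntheticPopulationSpec(
        n_individuals=30, n_modes=4, landmark_noise_sd_mm=0.05, seed=202),
    "paper_scale": SyntheticPopulationSpec(
        n_individuals=71, n_modes=6, landmark_noise_sd_mm=0.15, seed=303),
}


def benchmark_dataset(preset: str, seed: int | None = None,
                      ) -> tuple[DentitionDataset, GroundTruth]:
    """One of the named presets; ``seed`` overrides the preset's fixed seed."""
    if preset not in BENCHMARK_PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; choose from {sorted(BENCHMARK_PRESETS)}")
    spec = BENCHMARK_PRESETS[preset]
    if seed is not None:
        from dataclasses import replace
        spec = replace(spec, seed=seed)
    return generate_population(spec)
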