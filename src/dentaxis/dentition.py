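"""Labeled landmark configurations of single individuals and datasets.

A :class:`DentitionLandmarks` maps landmark labels to 3D coordinates in
millimeters.  Configurations may be *complete* (every label of the protocol
present) or *partial* (crowns only, one tooth removed, ...); partial
configurations are first-class everywhere downstream -- operations work on
the subset of labels that is present, never on sentinel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .protocol import (
    Jaw,
    LandmarkKind,
    LandmarkLabel,
    LandmarkProtocol,
    ToothId,
)

__all__ = [
    "DentitionLandmarks",
    "DentitionDataset",
    "Violation",
    "validate",
    "to_vector",
    "from_vector",
    "drop_tooth",
    "crowns_only",
    "restrict_to_jaw",
]


@dataclass(frozen=True)
class DentitionLandmarks:
    """One individual's labeled 3D landmark configuration (mm)."""

    individual_id: str
    points: Mapping[LandmarkLabel, np.ndarray]
    protocol: LandmarkProtocol

    def __post_init__(self) -> None:
        pts = {}
        for label, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"point for {label} must be a 3-vector, got {arr.shape}")
            arr.setflags(write=False)
            pts[label] = arr
        object.__setattr__(self, "points", pts)

    @property
    def labels(self) -> tuple[LandmarkLabel, ...]:
        """Present labels, in canonical protocol order."""
        return tuple(l for l in self.protocol.label_order if l in self.points)

    @property
    def n_landmarks(self) -> int:
        return len(self.points)

    def is_complete(self) -> bool:
        return set(self.points) == set(self.protocol.label_order)

    def teeth_present(self) -> tuple[ToothId, ...]:
        present = {l.tooth for l in self.points}
        return tuple(t for t in self.protocol.teeth if t in present)

    def __getitem__(self, label: LandmarkLabel) -> np.ndarray:
        return self.points[label]

    def __contains__(self, label: LandmarkLabel) -> bool:
        return label in self.points

    def with_points(self, points: Mapping[LandmarkLabel, np.ndarray],
                    individual_id: str | None = None) -> "DentitionLandmarks":
        return DentitionLandmarks(
            individual_id=individual_id or self.individual_id,
            points=points,
            protocol=self.protocol,
        )


@dataclass(frozen=True)
class DentitionDataset:
    """An ordered collection of individuals sharing one protocol."""

    individuals: tuple[DentitionLandmarks, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "individuals", tuple(self.individuals))
        if not self.individuals:
            raise ValueError("dataset must contain at least one individual")
        proto = self.individuals[0].protocol
        ids = set()
        for ind in self.individuals:
            if ind.protocol is not proto and ind.protocol != proto:
                raise ValueError("all individuals must share one protocol")
            if ind.individual_id in ids:
                raise ValueError(f"duplicate individual_id {ind.individual_id!r}")
            ids.add(ind.individual_id)

    @property
    def protocol(self) -> LandmarkProtocol:
        return self.individuals[0].protocol

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_landmarks_total(self) -> int:
        return sum(ind.n_landmarks for ind in self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, key: int | str) -> DentitionLandmarks:
        if isinstance(key, str):
            for ind in self.individuals:
                if ind.individual_id == key:
                    return ind
            raise KeyError(key)
        return self.individuals[key]

    def drop_individual(self, individual_id: str) -> "DentitionDataset":
        kept = tuple(i for i in self.individuals if i.individual_id != individual_id)
        if len(kept) == len(self.individuals):
            raise KeyError(individual_id)
        return DentitionDataset(kept, metadata=dict(self.metadata))


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is 'error' or 'info'."""

    severity: str
    message: str
    label: LandmarkLabel | None = None
    tooth: ToothId | None = None


def validate(dentition: DentitionLandmarks,
             protocol: LandmarkProtocol | None = None) -> list[Violation]:
    """Check a configuration against its protocol.

    Returns an empty list iff every present label belongs to the protocol
    and all coordinates are finite.  Absent or partial teeth are reported
    as informational findings, not errors.
    """
    protocol = protocol or dentition.protocol
    out: list[Violation] = []
    for label, p in dentition.points.items():
        if label not in protocol:
            out.append(Violation("error", f"unknown label {label}", label=label))
        if not np.all(np.isfinite(p)):
            out.append(Violation("error", f"non-finite coordinates at {label}", label=label))
    by_tooth: dict[ToothId, int] = {}
    for label in dentition.points:
        if label in protocol:
            by_tooth[label.tooth] = by_tooth.get(label.tooth, 0) + 1
    for tooth in protocol.teeth:
        expected = len(protocol.labels_of_tooth(tooth))
        got = by_tooth.get(tooth, 0)
        if got == 0:
            out.append(Violation("info", f"tooth {tooth} absent", tooth=tooth))
        elif got < expected:
            out.append(Violation(
                "info", f"tooth {tooth} partial ({got}/{expected} landmarks)", tooth=tooth))
    return [v for v in out if v.severity == "error"] + \
           [v for v in out if v.severity != "error"]


def to_vector(dentition: DentitionLandmarks,
              labels: Sequence[LandmarkLabel] | None = None) -> np.ndarray:
    """Flatten coordinates to shape ``(3*len(labels),)`` in label order.

    ``labels`` defaults to all present labels in canonical order; every
    requested label must be present.
    """
    if labels is None:
        labels = dentition.labels
    rows = []
    for label in labels:
        if label not in dentition.points:
            raise KeyError(f"label {label} not present in individual "
                           f"{dentition.individual_id!r}")
        rows.append(dentition.points[label])
    if not rows:
        return np.empty(0, dtype=float)
    return np.concatenate(rows)


def from_vector(vector: np.ndarray, labels: Sequence[LandmarkLabel],
                protocol: LandmarkProtocol,
                individual_id: str = "reconstructed") -> DentitionLandmarks:
    """Inverse of :func:`to_vector` for the given label sequence."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (3 * len(labels),):
        raise ValueError(
            f"vector length {vector.size} does not match 3 x {len(labels)} labels")
    pts = {label: vector[3 * i:3 * i + 3] for i, label in enumerate(labels)}
    return DentitionLandmarks(individual_id, pts, protocol)


def drop_tooth(dentition: DentitionLandmarks, tooth: ToothId) -> DentitionLandmarks:
    """Remove all crown and root landmarks of one tooth (original untouched)."""
    if tooth not in dentition.protocol.crown_counts:
        raise KeyError(f"tooth {tooth} not in protocol")
    kept = {l: p for l, p in dentition.points.items() if l.tooth != tooth}
    return dentition.with_points(kept)


def crowns_only(dentition: DentitionLandmarks) -> DentitionLandmarks:
    """Keep only crown landmarks (the surface-scan view of a case)."""
    kept = {l: p for l, p in dentition.points.items()
            if l.kind is LandmarkKind.CROWN}
    return dentition.with_points(kept)


def restrict_to_jaw(dentition: DentitionLandmarks, jaw: Jaw) -> DentitionLandmarks:
    kept = {l: p for l, p in dentition.points.items() if l.tooth.jaw is jaw}
    return dentition.with_points(kept)
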