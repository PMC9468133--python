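"""Reading and writing landmark tables, fiducial files and axis exports.

The canonical interchange format is a plain CSV with header
``individual_id,fdi_code,kind,index,x_mm,y_mm,z_mm`` (UTF-8, '.' decimal
separator).  Coordinates are serialized with 4 decimal places (0.1 um),
ample relative to scan accuracy; read/write round-trips at that precision.

3D Slicer fiducial markups (``.fcsv`` and markups ``.json``) can be imported
when the fiducial label encodes ``<fdi>_<kind>_<index>``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .axes import ToothAxisLine
from .dentition import DentitionDataset, DentitionLandmarks
from .protocol import (
    LandmarkKind,
    LandmarkLabel,
    LandmarkProtocol,
    ToothId,
    make_default_protocol,
)

__all__ = [
    "read_landmark_table",
    "write_landmark_table",
    "read_fiducials",
    "write_axes_table",
    "TABLE_COLUMNS",
    "COORD_DECIMALS",
]

TABLE_COLUMNS = ["individual_id", "fdi_code", "kind", "index", "x_mm", "y_mm", "z_mm"]
COORD_DECIMALS = 4


class LandmarkTableError(ValueError):
    """Malformed landmark table (bad row, duplicate label, unknown code)."""


def _parse_label(fdi_code: int, kind: str, index: int, row: int) -> LandmarkLabel:
    try:
        tooth = ToothId(int(fdi_code))
    except ValueError as exc:
        raise LandmarkTableError(f"row {row}: {exc}") from None
    try:
        kind_enum = LandmarkKind(str(kind))
    except ValueError:
        raise LandmarkTableError(
            f"row {row}: kind must be 'crown' or 'root', got {kind!r}") from None
    try:
        return LandmarkLabel(tooth, kind_enum, int(index))
    except ValueError as exc:
        raise LandmarkTableError(f"row {row}: {exc}") from None


def read_landmark_table(source: str | Path | IO[str],
                        protocol: LandmarkProtocol | None = None) -> DentitionDataset:
    """Read a landmark CSV into a dataset.

    Raises :class:`LandmarkTableError` (with the offending row number) on
    malformed rows, duplicate (individual, label) pairs, labels outside the
    protocol, or non-finite coordinates.
    """
    protocol = protocol or make_default_protocol()
    df = pd.read_csv(source)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkTableError(f"missing columns: {missing}")

    per_individual: dict[str, dict[LandmarkLabel, np.ndarray]] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        label = _parse_label(row.fdi_code, row.kind, row.index, i)
        if label not in protocol:
            raise LandmarkTableError(f"row {i}: label {label} not in protocol")
        xyz = np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise LandmarkTableError(f"row {i}: non-finite coordinates for {label}")
        ind = str(row.individual_id)
        if ind not in per_individual:
            per_individual[ind] = {}
            order.append(ind)
        if label in per_individual[ind]:
            raise LandmarkTableError(
                f"row {i}: duplicate landmark {label} for individual {ind!r}")
        per_individual[ind][label] = xyz

    individuals = tuple(
        DentitionLandmarks(ind, per_individual[ind], protocol) for ind in order
    )
    return DentitionDataset(individuals)


def write_landmark_table(dataset: DentitionDataset,
                         sink: str | Path | IO[str]) -> None:
    """Write a dataset as landmark CSV, rows sorted by individual then label."""
    records = []
    for ind in sorted(dataset, key=lambda d: d.individual_id):
        for label in ind.labels:  # canonical protocol order
            p = ind.points[label]
            records.append({
                "individual_id": ind.individual_id,
                "fdi_code": label.tooth.fdi_code,
                "kind": label.kind.value,
                "index": label.index,
                "x_mm": round(float(p[0]), COORD_DECIMALS),
                "y_mm": round(float(p[1]), COORD_DECIMALS),
                "z_mm": round(float(p[2]), COORD_DECIMALS),
            })
    pd.DataFrame.from_records(records, columns=TABLE_COLUMNS).to_csv(
        sink, index=False, float_format=f"%.{COORD_DECIMALS}f")


def _label_from_fiducial_name(name: str, row: int) -> LandmarkLabel:
    parts = name.strip().split("_")
    if len(parts) != 3:
        raise LandmarkTableError(
            f"row {row}: fiducial label {name!r} does not match '<fdi>_<kind>_<index>'")
    return _parse_label(int(parts[0]), parts[1], int(parts[2]), row)


def read_fiducials(source: str | Path, individual_id: str,
                   protocol: LandmarkProtocol | None = None) -> DentitionLandmarks:
    """Import one individual's landmarks from a 3D Slicer fiducial file.

    Supports legacy ``.fcsv`` (comment-prefixed CSV, columns id,x,y,z,...,label)
    and markups ``.json`` (``markups[*].controlPoints``).  Fiducial labels
    must encode ``<fdi>_<kind>_<index>``.
    """
    protocol = protocol or make_default_protocol()
    path = Path(source)
    points: dict[LandmarkLabel, np.ndarray] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for markup in payload.get("markups", []):
            for i, cp in enumerate(markup.get("controlPoints", []), start=1):
                label = _label_from_fiducial_name(cp["label"], i)
                points[label] = np.asarray(cp["position"], dtype=float)
    else:
        df = pd.read_csv(path, comment="#", header=None)
        # fcsv columns: id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,assoc
        for i, row in enumerate(df.itertuples(index=False), start=1):
            label = _label_from_fiducial_name(str(row[11]), i)
            points[label] = np.array([row[1], row[2], row[3]], dtype=float)
    return DentitionLandmarks(individual_id, points, protocol)


def write_axes_table(axes: Mapping[str, Mapping[ToothId, ToothAxisLine]],
                     sink: str | Path | IO[str]) -> None:
    """Export fitted/predicted axes as CSV (anchor in mm, unit direction).

    ``axes`` maps individual_id -> {tooth -> axis}.
    """
    records = []
    for ind_id in sorted(axes):
        for tooth in sorted(axes[ind_id]):
            ax = axes[ind_id][tooth]
            records.append({
                "individual_id": ind_id,
                "fdi_code": tooth.fdi_code,
                "anchor_x": ax.anchor[0], "anchor_y": ax.anchor[1],
                "anchor_z": ax.anchor[2],
                "dir_x": ax.direction[0], "dir_y": ax.direction[1],
                "dir_z": ax.direction[2],
            })
    cols = ["individual_id", "fdi_code", "anchor_x", "anchor_y", "anchor_z",
            "dir_x", "dir_y", "dir_z"]
    pd.DataFrame.from_records(records, columns=cols).to_csv(
        sink, index=False, float_format="%.6f")
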