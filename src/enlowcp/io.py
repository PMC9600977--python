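"""Landmark-file readers/writers, report export and run configuration.

Supported landmark formats
--------------------------
csv
    Hand-editable dialect: header ``name,laterality,x,y[,z]``, mm, UTF-8,
    '.' decimal separator. Laterality may be left empty.
json
    ``{"subject": ..., "dimensionality": "2D"|"3D", "unit": "mm",
    "landmarks": {name: [x, y(, z)], ...}}`` with an optional ``scale``
    (2D source-image magnification, applied at load).
fcsv
    3D Slicer markups fiducial files (``# Markups fiducial file`` header,
    comma-separated ``id,x,y,z,...,label`` records), mapped by label. The
    ``# CoordinateSystem`` header (RAS or LPS; RAS default) is honoured:
    the canonical frame here coincides with RAS (x left→right = patient
    right, y anterior, z superior), so LPS files get x and y negated.

Unknown landmark names are kept with a warning (they may be auxiliary
points); missing *required* names only fail later, at analysis time, so a
partial file can still be inspected.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .ceph2d import REQUIRED_LANDMARKS_2D, LandmarkSet2D
from .ceph3d import REQUIRED_LANDMARKS_3D, LandmarkSet3D, laterality_of
from .counterpart import HARMONY_THRESHOLD_MM, CohortTable, DiscrepancyReport
from .errors import LandmarkFileError
from .geometry import Point2, Point3

__all__ = [
    "RunConfig",
    "read_landmarks",
    "write_landmarks",
    "write_report",
    "read_report",
    "write_cohort_csv",
]

log = logging.getLogger("enlowcp")

_KNOWN_2D = set(REQUIRED_LANDMARKS_2D)
_KNOWN_3D = set(REQUIRED_LANDMARKS_3D)


@dataclass
class RunConfig:
    """Analysis settings, serialized into every report for provenance."""

    harmony_threshold_mm: float = HARMONY_THRESHOLD_MM
    alpha: float = 0.05
    ramus_side: str = "right"           # right | left | mean
    report_unit: str = "mm"             # mm | cm
    geometry_tolerance_mm: float = 1e-9
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = RunConfig.__dataclass_fields__
        unknown = set(data) - set(known)
        if unknown:
            raise LandmarkFileError(
                f"unknown config keys in {path}: {', '.join(sorted(unknown))}")
        return RunConfig(**data)

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".fcsv":
        return "fcsv"
    if suffix == ".json":
        return "json"
    if suffix == ".csv":
        return "csv"
    raise LandmarkFileError(f"cannot infer landmark format from {path.name!r}; "
                            "pass format explicitly (csv, json or fcsv)")


def read_landmarks(path, format: str | None = None, subject: str | None = None):
    """Read a landmark file into a LandmarkSet2D or LandmarkSet3D."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "csv":
        return _read_csv(path, subject)
    if fmt == "json":
        return _read_json(path, subject)
    if fmt == "fcsv":
        return _read_fcsv(path, subject)
    raise LandmarkFileError(f"unknown landmark format {fmt!r}")


def _warn_unknown(names, known, path):
    unknown = [n for n in names if n not in known]
    if unknown:
        log.warning("%s: unknown landmark names kept as-is: %s",
                    path.name, ", ".join(sorted(unknown)))


def _make_set(subject, dim, points, unit="mm"):
    if dim == 2:
        return LandmarkSet2D(subject=subject, points=points, unit=unit)
    return LandmarkSet3D(subject=subject, points=points, unit=unit)


def _read_csv(path: Path, subject):
    points: dict = {}
    dim = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise LandmarkFileError(f"{path}: empty file")
        header = [h.strip().lower() for h in header]
        if header[:2] != ["name", "laterality"] or header[2:] not in (
                ["x", "y"], ["x", "y", "z"]):
            raise LandmarkFileError(
                f"{path}:1: expected header 'name,laterality,x,y[,z]', "
                f"got {','.join(header)}")
        dim = len(header) - 2
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) != len(header):
                raise LandmarkFileError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            name = row[0].strip()
            if name in points:
                raise LandmarkFileError(
                    f"{path}:{lineno}: duplicate landmark label {name!r}")
            try:
                coords = [float(v) for v in row[2:]]
            except ValueError as exc:
                raise LandmarkFileError(
                    f"{path}:{lineno}: bad coordinate for {name!r}: {exc}") from exc
            points[name] = (Point2(*coords) if dim == 2 else Point3(*coords))
    _warn_unknown(points, _KNOWN_2D if dim == 2 else _KNOWN_3D, path)
    return _make_set(subject or path.stem, dim, points)


def _read_json(path: Path, subject):
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    try:
        dim = 2 if str(data["dimensionality"]).upper().startswith("2") else 3
        raw = data["landmarks"]
    except KeyError as exc:
        raise LandmarkFileError(f"{path}: missing key {exc}") from exc
    unit = data.get("unit", "mm")
    if unit not in ("mm", "cm"):
        raise LandmarkFileError(f"{path}: ambiguous unit {unit!r} "
                                "(only mm or cm accepted)")
    factor = 10.0 if unit == "cm" else 1.0
    scale = float(data.get("scale", 1.0))
    if dim == 3 and scale != 1.0:
        raise LandmarkFileError(f"{path}: scale factor only applies to 2D files")
    points = {}
    for name, coords in raw.items():
        coords = [float(c) * factor * scale for c in coords]
        if len(coords) != dim:
            raise LandmarkFileError(
                f"{path}: landmark {name!r} has {len(coords)} coordinates, "
                f"expected {dim}")
        points[name] = Point2(*coords) if dim == 2 else Point3(*coords)
    _warn_unknown(points, _KNOWN_2D if dim == 2 else _KNOWN_3D, path)
    return _make_set(subject or data.get("subject", path.stem), dim, points)


def _read_fcsv(path: Path, subject):
    """3D Slicer markups fiducial reader (label -> landmark name)."""
    coordinate_system = "RAS"
    points: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("coordinatesystem"):
                    value = body.split("=", 1)[1].strip() if "=" in body else ""
                    cs = {"0": "RAS", "1": "LPS"}.get(value, value.upper())
                    if cs not in ("RAS", "LPS"):
                        raise LandmarkFileError(
                            f"{path}:{lineno}: unknown coordinate system {value!r}")
                    coordinate_system = cs
                continue
            fields = line.split(",")
            if len(fields) < 12:
                raise LandmarkFileError(
                    f"{path}:{lineno}: expected >= 12 comma-separated fields "
                    f"in fiducial record, got {len(fields)}")
            label = fields[11].strip()
            if not label:
                raise LandmarkFileError(f"{path}:{lineno}: fiducial without label")
            if label in points:
                raise LandmarkFileError(
                    f"{path}:{lineno}: duplicate landmark label {label!r}")
            try:
                x, y, z = (float(fields[1]), float(fields[2]), float(fields[3]))
            except ValueError as exc:
                raise LandmarkFileError(
                    f"{path}:{lineno}: bad coordinate for {label!r}: {exc}") from exc
            if coordinate_system == "LPS":
                x, y = -x, -y       # LPS -> RAS (canonical) sign convention
            points[label] = Point3(x, y, z)
    _warn_unknown(points, _KNOWN_3D, path)
    return _make_set(subject or path.stem, 3, points)


def write_landmarks(lm, path, format: str | None = None) -> Path:
    """Write a landmark set (csv or json; fcsv for 3D sets)."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    dim = 2 if isinstance(lm, LandmarkSet2D) else 3
    names = sorted(lm.points)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "laterality", "x", "y"] +
                            (["z"] if dim == 3 else []))
            for name in names:
                p = lm.points[name]
                lat = laterality_of(name) if dim == 3 else ""
                writer.writerow([name, lat] +
                                [repr(c) for c in p.as_array().tolist()])
    elif fmt == "json":
        payload = {
            "subject": lm.subject,
            "dimensionality": f"{dim}D",
            "unit": lm.unit,
            "landmarks": {n: lm.points[n].as_array().tolist() for n in names},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "fcsv":
        if dim != 3:
            raise LandmarkFileError("fcsv output only supports 3D landmark sets")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# Markups fiducial file version = 4.11\n")
            fh.write("# CoordinateSystem = RAS\n")
            fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,"
                     "label,desc,associatedNodeID\n")
            for i, name in enumerate(names, start=1):
                p = lm.points[name]
                fh.write(f"F{i},{p.x!r},{p.y!r},{p.z!r},0,0,0,1,1,1,0,"
                         f"{name},,\n")
    else:
        raise LandmarkFileError(f"unknown landmark format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _plane_dict(plane) -> dict:
    return {
        "anchor": plane.anchor.as_array().tolist(),
        "normal": list(plane.normal),
        "provenance": plane.provenance,
    }


def subject_report(
    report: DiscrepancyReport,
    measurements=None,
    planes: dict | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Assemble the full JSON-serializable report for one subject."""
    out = report.as_dict()
    if measurements is not None:
        out["measurements_mm"] = measurements.as_dict()
    if planes:
        out["planes"] = {k: _plane_dict(v) for k, v in planes.items()}
    if config is not None:
        out["config"] = config.as_dict()
        out["config_digest"] = config.digest()
    return out


def write_report(report: dict | list, path) -> Path:
    """Write a report (dict, or list of dicts) as deterministic JSON."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_report(path) -> dict | list:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_cohort_csv(table: CohortTable, path) -> Path:
    """Flat cohort comparison table: one row per index, unit-tagged columns."""
    path = Path(path)
    df = table.to_dataframe()
    df.insert(0, "n", table.n)
    df.to_csv(path, index=False)
    return path
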