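"""Annotation data model, pixel calibration and anterior chamber depth.

One Scheimpflug radial cut yields seven manually placed landmarks: five
points on the anterior lens capsule (the conic-fit input) and two anterior
chamber depth (ACD) landmarks — the corneal apex and the lens reflex.  A
single isotropic scale (default 28 µm per pixel, derived by comparing apical
pachymetry with its pixel count) converts pixel distances to millimetres.

Annotations are exchanged as long-format CSV (one landmark per row) or as
JSON; both round-trip exactly.  Cohort-level biometry (PD, SE, AA, MAF, AL,
ACD from the optical biometer) travels in a separate metadata CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEMAND_LEVELS",
    "CalibrationScale",
    "CutAnnotation",
    "EyeMeasurement",
    "ValidationError",
    "CalibrationError",
    "pixels_to_mm",
    "derive_scale",
    "compute_acd",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
]

#: accommodative demands used in the protocol, dioptres
DEMAND_LEVELS = (0.0, 1.0, 3.0, 5.0)

_POINT_ROLES = tuple(f"capsule_{i}" for i in range(1, 6)) + ("apex", "reflex")

_ANNOTATION_COLUMNS = [
    "subject_id",
    "age",
    "demand",
    "cut_index",
    "point_role",
    "x_px",
    "y_px",
]

_METADATA_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "PD_mm",
    "SE_D",
    "AA_D",
    "MAF_cpm",
    "AL_mm",
    "ACD_mm",
]


class ValidationError(ValueError):
    """Annotation records violate the data-model invariants."""


class CalibrationError(ValueError):
    """Invalid pixel-to-millimetre calibration."""


@dataclass(frozen=True)
class CalibrationScale:
    """Isotropic pixel scale in microns per pixel (default 28)."""

    microns_per_pixel: float = 28.0

    def __post_init__(self):
        if not (np.isfinite(self.microns_per_pixel) and self.microns_per_pixel > 0):
            raise CalibrationError(
                f"microns_per_pixel must be positive, got {self.microns_per_pixel}"
            )


@dataclass(frozen=True)
class CutAnnotation:
    """Landmarks of one radial cut in pixel coordinates."""

    subject_id: str
    age: float
    demand: float
    cut_index: int
    capsule_points: tuple  # 5 (x, y) pairs, px
    apex_point: tuple  # corneal apex (x, y), px
    reflex_point: tuple  # lens reflex (x, y), px

    def __post_init__(self):
        if not (1 <= self.cut_index <= 16):
            raise ValidationError(f"cut_index must be in 1..16, got {self.cut_index}")
        if self.demand not in DEMAND_LEVELS:
            raise ValidationError(
                f"demand must be one of {DEMAND_LEVELS}, got {self.demand}"
            )
        pts = np.asarray(self.capsule_points, dtype=float)
        if pts.shape != (5, 2):
            raise ValidationError("capsule_points must be 5 (x, y) pairs")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("capsule_points must be finite")
        if len({tuple(p) for p in pts.tolist()}) < 5:
            raise ValidationError("capsule_points must be pairwise distinct")

    def capsule_array(self) -> np.ndarray:
        return np.asarray(self.capsule_points, dtype=float)


@dataclass
class EyeMeasurement:
    """One eye at one accommodative demand: up to 16 cuts plus biometry."""

    subject_id: str
    age: float
    demand: float
    cuts: dict = field(default_factory=dict)  # cut_index -> CutAnnotation
    metadata: dict = field(default_factory=dict)  # PD_mm, ACD_mm, AA_D, ...

    def add_cut(self, cut: CutAnnotation) -> None:
        if cut.subject_id != self.subject_id or cut.demand != self.demand:
            raise ValidationError(
                "cut subject/demand does not match the eye measurement"
            )
        if cut.cut_index in self.cuts:
            raise ValidationError(
                f"duplicate cut {cut.cut_index} for subject {self.subject_id} "
                f"at {self.demand} D"
            )
        self.cuts[cut.cut_index] = cut


def pixels_to_mm(point, scale: CalibrationScale):
    """Convert a pixel-frame point to millimetres (isotropic scale)."""
    x, y = float(point[0]), float(point[1])
    k = scale.microns_per_pixel / 1000.0
    return (x * k, y * k)


def derive_scale(pachymetry_um: float, apex_span_px: float) -> CalibrationScale:
    """Scale from known apical corneal thickness and its pixel span."""
    if not (pachymetry_um > 0 and apex_span_px > 0):
        raise CalibrationError(
            "pachymetry and pixel span must both be strictly positive"
        )
    return CalibrationScale(microns_per_pixel=pachymetry_um / apex_span_px)


def compute_acd(
    apex, reflex, scale: CalibrationScale, axis_only: bool = False
) -> float:
    """Anterior chamber depth in mm from the apex and lens-reflex landmarks.

    Euclidean pixel distance by default; ``axis_only`` projects onto the
    vertical image axis instead (the two conventions coincide for an
    on-axis chamber).
    """
    apex = np.asarray(apex, dtype=float)
    reflex = np.asarray(reflex, dtype=float)
    if axis_only:
        dist_px = abs(reflex[1] - apex[1])
    else:
        dist_px = float(np.hypot(*(reflex - apex)))
    if dist_px == 0.0:
        warnings.warn(
            "apex and lens-reflex landmarks coincide; ACD = 0 is anatomically "
            "implausible",
            stacklevel=2,
        )
    return dist_px * scale.microns_per_pixel / 1000.0


def _records_to_eyes(df: pd.DataFrame, metadata: dict | None) -> list[EyeMeasurement]:
    problems = []
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")

    bad_demand = ~df["demand"].astype(float).isin(DEMAND_LEVELS)
    for idx in df.index[bad_demand]:
        problems.append(f"row {idx}: demand {df.loc[idx, 'demand']!r} not in {DEMAND_LEVELS}")
    bad_role = ~df["point_role"].isin(_POINT_ROLES)
    for idx in df.index[bad_role]:
        problems.append(f"row {idx}: unknown point_role {df.loc[idx, 'point_role']!r}")
    bad_cut = ~df["cut_index"].astype(int).between(1, 16)
    for idx in df.index[bad_cut]:
        problems.append(f"row {idx}: cut_index {df.loc[idx, 'cut_index']!r} not in 1..16")
    dup = df.duplicated(["subject_id", "demand", "cut_index", "point_role"], keep=False)
    if dup.any():
        for idx in df.index[dup]:
            problems.append(
                f"row {idx}: duplicate landmark for (subject, demand, cut, role)"
            )
    if problems:
        raise ValidationError("invalid annotation rows:\n" + "\n".join(problems))

    eyes: dict[tuple, EyeMeasurement] = {}
    for (sid, demand, cut_idx), grp in df.groupby(
        ["subject_id", "demand", "cut_index"], sort=True
    ):
        roles = dict(zip(grp["point_role"], zip(grp["x_px"], grp["y_px"])))
        missing_roles = [r for r in _POINT_ROLES if r not in roles]
        if missing_roles:
            raise ValidationError(
                f"subject {sid} demand {demand} cut {cut_idx}: missing landmarks "
                f"{missing_roles}"
            )
        age = float(grp["age"].iloc[0])
        cut = CutAnnotation(
            subject_id=str(sid),
            age=age,
            demand=float(demand),
            cut_index=int(cut_idx),
            capsule_points=tuple(
                (float(roles[f"capsule_{i}"][0]), float(roles[f"capsule_{i}"][1]))
                for i in range(1, 6)
            ),
            apex_point=(float(roles["apex"][0]), float(roles["apex"][1])),
            reflex_point=(float(roles["reflex"][0]), float(roles["reflex"][1])),
        )
        key = (str(sid), float(demand))
        eye = eyes.get(key)
        if eye is None:
            meta = (metadata or {}).get(str(sid), {})
            eye = eyes[key] = EyeMeasurement(
                subject_id=str(sid), age=age, demand=float(demand), metadata=dict(meta)
            )
        eye.add_cut(cut)
    return [eyes[k] for k in sorted(eyes)]


def read_annotations(
    path, fmt: str | None = None, metadata: dict | None = None
) -> list[EyeMeasurement]:
    """Read per-cut landmark annotations from long-format CSV or JSON.

    CSV columns: ``subject_id, age, demand, cut_index, point_role, x_px, y_px``
    with ``point_role`` in ``capsule_1..capsule_5, apex, reflex``.  JSON holds
    the same rows as a list of objects.  Rows violating the data model are
    rejected with row-addressed messages.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"subject_id": str})
    elif fmt == "json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
        if not df.empty:
            df["subject_id"] = df["subject_id"].astype(str)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if df.empty:
        return []
    return _records_to_eyes(df, metadata)


def annotations_to_frame(eyes: list[EyeMeasurement]) -> pd.DataFrame:
    """Long-format landmark table for a list of eye measurements."""
    rows = []
    for eye in eyes:
        for cut_idx in sorted(eye.cuts):
            cut = eye.cuts[cut_idx]
            landmarks = [
                (f"capsule_{i + 1}", p) for i, p in enumerate(cut.capsule_points)
            ] + [("apex", cut.apex_point), ("reflex", cut.reflex_point)]
            for role, (x, y) in landmarks:
                rows.append(
                    {
                        "subject_id": eye.subject_id,
                        "age": eye.age,
                        "demand": eye.demand,
                        "cut_index": cut_idx,
                        "point_role": role,
                        "x_px": x,
                        "y_px": y,
                    }
                )
    return pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS)


def write_annotations(eyes: list[EyeMeasurement], path, fmt: str | None = None) -> None:
    """Write annotations as long-format CSV or JSON (inverse of read)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    df = annotations_to_frame(eyes)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


def load_calibration(path) -> CalibrationScale:
    """Calibration from a YAML config (``microns_per_pixel: 28``)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "microns_per_pixel" not in cfg:
        raise CalibrationError(f"{path}: missing 'microns_per_pixel'")
    return CalibrationScale(float(cfg["microns_per_pixel"]))


def save_calibration(scale: CalibrationScale, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({"microns_per_pixel": scale.microns_per_pixel}, fh)


def read_metadata(path) -> pd.DataFrame:
    """Cohort biometry table (one row per subject)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in ("subject_id", "age") if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata table missing columns: {missing}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    cols = [c for c in _METADATA_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols + [c for c in df.columns if c not in cols])
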