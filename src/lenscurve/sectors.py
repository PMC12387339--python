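"""Meridional sector reconstruction and accommodation-response series.

The Scheimpflug system acquires 16 radial cuts spanning 180° of meridians in
acquisition order, not angular order.  Cuts are grouped into two anatomically
coherent sectors, each a 22.5° wedge around a principal meridian:

* horizontal sector — core cuts 1, 13, 14; transitional cuts 8–12
* vertical sector — core cuts 5, 6, 7; transitional cuts 2–4 and 15–16

Sector eccentricity is the mean of the per-cut conic-fit eccentricities over
the core cuts (transitional cuts optionally included); non-elliptical fits
are excluded and reported as flagged.  The accommodation response is
expressed relative to the unaccommodated baseline: each subject/sector series
is divided by its 0 D value, so 1.0 means no change and values below 1.0 mean
a steeper (more curved) anterior surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    DEMAND_LEVELS,
    CalibrationScale,
    EyeMeasurement,
    compute_acd,
)
from .conic import UnsupportedShapeError, eccentricity, fit_conic_through_points

__all__ = [
    "HORIZONTAL_CORE",
    "HORIZONTAL_TRANSITIONAL",
    "VERTICAL_CORE",
    "VERTICAL_TRANSITIONAL",
    "DEFAULT_ANGLE_MAP",
    "SectorAssignment",
    "SectorSummary",
    "RelativeSeries",
    "assign_sector",
    "cut_eccentricity",
    "sector_eccentricity",
    "relative_series",
    "assign_age_group",
    "build_cohort_table",
]

HORIZONTAL_CORE = frozenset({1, 13, 14})
HORIZONTAL_TRANSITIONAL = frozenset({8, 9, 10, 11, 12})
VERTICAL_CORE = frozenset({5, 6, 7})
VERTICAL_TRANSITIONAL = frozenset({2, 3, 4, 15, 16})

SECTORS = ("horizontal", "vertical")

#: Default cut-index -> meridian angle (degrees, 0 = horizontal, mod 180).
#: Acquisition order is not angular order: the three core cuts of each sector
#: sit at -11.25°, 0°, +11.25° around its principal meridian (a 22.5° wedge
#: at the 180°/16 = 11.25° cut spacing); transitional cuts fill the remaining
#: multiples of 11.25°.  This is configuration, not measured geometry.
DEFAULT_ANGLE_MAP = {
    1: 0.0,
    14: 11.25,
    13: 168.75,
    6: 90.0,
    5: 78.75,
    7: 101.25,
    # vertical-transitional cuts, flanking the vertical wedge
    4: 45.0,
    3: 56.25,
    2: 67.5,
    15: 112.5,
    16: 123.75,
    # horizontal-transitional cuts, flanking the horizontal wedge
    8: 22.5,
    9: 33.75,
    10: 135.0,
    11: 146.25,
    12: 157.5,
}


@dataclass(frozen=True)
class SectorAssignment:
    cut_index: int
    sector: str  # horizontal | vertical
    role: str  # core | transitional


@dataclass(frozen=True)
class SectorSummary:
    """Mean core-cut eccentricity of one sector at one demand."""

    subject_id: str
    demand: float
    sector: str
    mean_e: float | None  # None marks a missing sector (no usable cuts)
    n_cuts_used: int
    flagged_cuts: tuple = ()


@dataclass
class RelativeSeries:
    """Baseline-normalised eccentricity trajectory of one subject/sector."""

    subject_id: str
    sector: str
    values: dict = field(default_factory=dict)  # demand -> relative e; [0 D] == 1.0


def assign_sector(cut_index: int) -> SectorAssignment:
    """Fixed sector/role of a cut index (the 16 assignments partition 1..16)."""
    if not (1 <= int(cut_index) <= 16):
        raise ValueError(f"cut_index must be in 1..16, got {cut_index}")
    cut_index = int(cut_index)
    if cut_index in HORIZONTAL_CORE:
        return SectorAssignment(cut_index, "horizontal", "core")
    if cut_index in HORIZONTAL_TRANSITIONAL:
        return SectorAssignment(cut_index, "horizontal", "transitional")
    if cut_index in VERTICAL_CORE:
        return SectorAssignment(cut_index, "vertical", "core")
    return SectorAssignment(cut_index, "vertical", "transitional")


def cut_eccentricity(cut) -> float:
    """Eccentricity of one cut's 5-point conic fit.

    Raises :class:`UnsupportedShapeError` for hyperbolic/degenerate fits so
    the caller can flag the cut.
    """
    coeffs = fit_conic_through_points(cut.capsule_array())
    return eccentricity(coeffs).e


def sector_eccentricity(
    eye: EyeMeasurement, include_transitional: bool = False
) -> list[SectorSummary]:
    """Per-sector mean eccentricity for one eye at one demand.

    Non-elliptical cuts are excluded from the mean and listed in
    ``flagged_cuts``; a sector with zero usable cuts yields ``mean_e=None``
    (missing data downstream, not an exception).
    """
    summaries = []
    for sector in SECTORS:
        es, flagged, used = [], [], 0
        for cut_idx in sorted(eye.cuts):
            asg = assign_sector(cut_idx)
            if asg.sector != sector:
                continue
            if asg.role == "transitional" and not include_transitional:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    es.append(cut_eccentricity(eye.cuts[cut_idx]))
                used += 1
            except UnsupportedShapeError:
                flagged.append(cut_idx)
        summaries.append(
            SectorSummary(
                subject_id=eye.subject_id,
                demand=eye.demand,
                sector=sector,
                mean_e=float(np.mean(es)) if es else None,
                n_cuts_used=used,
                flagged_cuts=tuple(flagged),
            )
        )
    return summaries


def relative_series(per_demand: dict) -> RelativeSeries:
    """Normalise one subject/sector's mean eccentricities to the 0 D baseline.

    ``per_demand`` maps demand -> SectorSummary (or bare mean_e).  The 0 D
    entry must be present and positive; the returned series has value 1.0 at
    0 D exactly.
    """

    def _mean(v):
        return v.mean_e if isinstance(v, SectorSummary) else v

    if 0.0 not in {float(d) for d in per_demand}:
        raise ValueError("relative series requires a 0 D baseline entry")
    baseline = _mean(per_demand[[d for d in per_demand if float(d) == 0.0][0]])
    if baseline is None or not baseline > 0:
        raise ValueError(f"0 D baseline eccentricity must be > 0, got {baseline}")
    first = next(iter(per_demand.values()))
    sid = first.subject_id if isinstance(first, SectorSummary) else ""
    sector = first.sector if isinstance(first, SectorSummary) else ""
    values = {}
    for d, v in per_demand.items():
        m = _mean(v)
        values[float(d)] = 1.0 if float(d) == 0.0 else (
            None if m is None else float(m) / float(baseline)
        )
    return RelativeSeries(subject_id=sid, sector=sector, values=values)


def assign_age_group(age: float) -> str | None:
    """Decade age group: G1=[20,30) .. G4=[50,60), G5=[60,inf); None below 20."""
    if age < 20:
        return None
    if age >= 60:
        return "G5"
    return f"G{int(age // 10) - 1}"


def build_cohort_table(
    eyes: list[EyeMeasurement],
    metadata: pd.DataFrame | None = None,
    include_transitional: bool = False,
    scale: CalibrationScale | None = None,
) -> pd.DataFrame:
    """Tidy analysis table: one row per (subject, demand, sector).

    Columns: subject_id, age, age_group, demand, sector, mean_e, relative_e,
    n_cuts_used, flagged_cuts, ACD_mm, PD_mm.  Relative eccentricity is
    normalised per subject/sector to its own 0 D baseline before any group
    averaging.  When a calibration ``scale`` is given, ACD is computed from
    the apex/lens-reflex landmarks (mean over cuts); otherwise the biometer
    value from the metadata is carried through.  Subjects younger than 20 or
    without an age are excluded with a warning (outside the study's
    grouping).
    """
    meta_by_sid = {}
    if metadata is not None and not metadata.empty:
        meta_by_sid = metadata.set_index("subject_id").to_dict(orient="index")

    rows = []
    for eye in eyes:
        group = assign_age_group(eye.age) if np.isfinite(eye.age) else None
        if group is None:
            warnings.warn(
                f"subject {eye.subject_id} (age {eye.age}) outside the 20+ "
                "grouping; excluded",
                stacklevel=2,
            )
            continue
        meta = dict(meta_by_sid.get(eye.subject_id, {}))
        meta.update(eye.metadata)
        acd = meta.get("ACD_mm", np.nan)
        if scale is not None and eye.cuts:
            acd = float(
                np.mean(
                    [
                        compute_acd(c.apex_point, c.reflex_point, scale)
                        for c in eye.cuts.values()
                    ]
                )
            )
        for summ in sector_eccentricity(eye, include_transitional):
            rows.append(
                {
                    "subject_id": eye.subject_id,
                    "age": eye.age,
                    "age_group": group,
                    "demand": eye.demand,
                    "sector": summ.sector,
                    "mean_e": summ.mean_e,
                    "n_cuts_used": summ.n_cuts_used,
                    "flagged_cuts": ";".join(map(str, summ.flagged_cuts)),
                    "ACD_mm": acd,
                    "PD_mm": meta.get("PD_mm", np.nan),
                }
            )
    cols = [
        "subject_id",
        "age",
        "age_group",
        "demand",
        "sector",
        "mean_e",
        "relative_e",
        "n_cuts_used",
        "flagged_cuts",
        "ACD_mm",
        "PD_mm",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)

    # per-subject/sector baseline normalisation
    def _rel(grp: pd.DataFrame) -> pd.Series:
        base = grp.loc[grp["demand"] == 0.0, "mean_e"]
        if base.empty or pd.isna(base.iloc[0]) or not base.iloc[0] > 0:
            return pd.Series(np.nan, index=grp.index)
        rel = grp["mean_e"] / base.iloc[0]
        rel[grp["demand"] == 0.0] = 1.0
        return rel

    df["relative_e"] = (
        df.groupby(["subject_id", "sector"], group_keys=False)[["demand", "mean_e"]]
        .apply(_rel)
    )
    return df[cols].sort_values(["subject_id", "demand", "sector"]).reset_index(
        drop=True
    )


def group_mean_relative(
    table: pd.DataFrame, normalize_group_mean: bool = False
) -> pd.DataFrame:
    """Group-level mean relative eccentricity per (age_group + TG, sector, demand).

    Default: arithmetic mean of per-subject relative values.  With
    ``normalize_group_mean`` the group mean of absolute eccentricity is
    normalised by the group's 0 D mean instead (sensitivity variant).
    """
    frames = []
    for label, sub in [("TG", table)] + [
        (g, table[table["age_group"] == g]) for g in sorted(table["age_group"].unique())
    ]:
        if sub.empty:
            continue
        if normalize_group_mean:
            m = sub.groupby(["sector", "demand"])["mean_e"].mean().rename("value")
            m = m.reset_index()
            base = m[m["demand"] == 0.0].set_index("sector")["value"]
            m["value"] = m.apply(lambda r: r["value"] / base[r["sector"]], axis=1)
        else:
            m = (
                sub.groupby(["sector", "demand"])["relative_e"]
                .mean()
                .rename("value")
                .reset_index()
            )
        m.insert(0, "group", label)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)
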