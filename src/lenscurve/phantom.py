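"""Synthetic lens-phantom cohorts with known ground truth.

The generator emulates the study design end-to-end without any images: for
each subject, each accommodative demand and each of the 16 radial cuts it
produces the seven pixel-space landmarks an annotator would have placed —
five points on an elliptical anterior-capsule arc plus the corneal-apex and
lens-reflex ACD landmarks — in the exact annotation formats the reader
consumes.

Forward model, per meridional cut: the anterior capsule is a prolate ellipse
with apex radius of curvature ``R`` and eccentricity ``e`` (semi-axes
``a = R/p``, ``b = R/sqrt(p)`` with ``p = 1 - e^2``), sampled over the
pupil-limited aperture; accommodation steepens the surface (``R`` shrinks
with demand) and drops ``e`` following per-age-group response profiles whose
5 D endpoints (and, for the middle-aged groups, all demand levels) are the
published group means.  Accommodative miosis shrinks the pupil with demand,
so higher demands sample shorter arcs — reproducing the clinical caveat that
small pupils limit peripheral capsule access.

Landmark placement noise is isotropic Gaussian in pixels.  Its default
(0.02 px) was fixed by a pre-build Monte-Carlo calibration of the 5-point
conic fit over pupil-limited arcs: it is the level at which single-cut
eccentricity recovery stays unbiased and ellipse-classified, so that the
configured group profiles are recoverable — it is deliberately far below
manual-annotation precision (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import (
    CalibrationScale,
    CutAnnotation,
    EyeMeasurement,
    annotations_to_frame,
    write_annotations,
    write_metadata,
)
from .sectors import DEFAULT_ANGLE_MAP, assign_sector

__all__ = [
    "ResponseProfile",
    "PhantomConfig",
    "PhantomCohort",
    "DEFAULT_PROFILES",
    "sample_capsule_arc",
    "generate_cohort",
]

DEMANDS = (0.0, 1.0, 3.0, 5.0)


@dataclass(frozen=True)
class ResponseProfile:
    """Target accommodation response of one group.

    ``relative_e[(sector, demand)]`` is the group-mean eccentricity at that
    demand relative to the 0 D baseline (1.0 at 0 D by construction);
    ``baseline_e[sector]`` the absolute group-mean eccentricity at 0 D.
    """

    group: str
    relative_e: dict
    baseline_e: dict
    between_subject_sd: float = 0.04
    within_subject_sd: float = 0.01

    def __post_init__(self):
        for s in ("horizontal", "vertical"):
            assert self.relative_e[(s, 0.0)] == 1.0
            assert all(self.relative_e[(s, d)] > 0 for d in DEMANDS)


def _profile(group, h, v, baseline=(0.78, 0.80)):
    rel = {("horizontal", 0.0): 1.0, ("vertical", 0.0): 1.0}
    for d, hv, vv in zip((1.0, 3.0, 5.0), h, v):
        rel[("horizontal", d)] = hv
        rel[("vertical", d)] = vv
    return ResponseProfile(
        group=group,
        relative_e=rel,
        baseline_e={"horizontal": baseline[0], "vertical": baseline[1]},
    )


#: Published group-mean relative-eccentricity responses.  The 5 D values of
#: TG and G1 and all values of G2-G5 are the printed group means; the TG/G1
#: 1 D and 3 D entries are not printed and are smooth monotone
#: interpolations chosen once for the phantom (docs/methods.md).
DEFAULT_PROFILES = {
    "TG": _profile("TG", (0.90, 0.75, 0.531), (0.93, 0.82, 0.606)),
    "G1": _profile("G1", (0.88, 0.65, 0.414), (0.91, 0.72, 0.491)),
    "G2": _profile("G2", (0.989, 0.726, 0.772), (0.946, 0.936, 0.939)),
    "G3": _profile("G3", (0.895, 0.806, 0.777), (0.998, 0.971, 0.878)),
    "G4": _profile("G4", (0.802, 0.781, 0.746), (0.839, 0.808, 0.768)),
    "G5": _profile("G5", (0.843, 0.882, 0.862), (0.864, 0.942, 0.974)),
}

#: (baseline mm, per-dioptre decrement) of pupil diameter per group —
#: baselines are the published group means; younger groups show stronger
#: accommodative miosis.
DEFAULT_PD_MODEL = {
    "G1": (6.83, 0.18),
    "G2": (6.27, 0.16),
    "G3": (6.04, 0.14),
    "G4": (5.81, 0.06),
    "G5": (5.74, 0.05),
}

#: (baseline mm, per-dioptre decrement, between-subject sd) of ACD per group;
#: baselines/sds follow the published unaccommodated means, the G1 decrement
#: reproduces the published 0 D -> 5 D drop (3.95 -> 3.79 mm).
DEFAULT_ACD_MODEL = {
    "G1": (3.95, 0.032, 0.42),
    "G2": (3.90, 0.020, 0.34),
    "G3": (3.63, 0.020, 0.55),
    "G4": (3.27, 0.010, 0.55),
    "G5": (2.67, 0.005, 0.26),
}

#: age ranges (inclusive) per decade group
GROUP_AGE_RANGE = {
    "G1": (20, 29),
    "G2": (30, 39),
    "G3": (40, 49),
    "G4": (50, 59),
    "G5": (60, 64),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Study-design parameters of the synthetic cohort."""

    # G2-G5 use the published group sizes; G1 is set so the cohort totals
    # 104 subjects (16 cuts x 104 = the 1664-image study design)
    n_subjects: dict = field(
        default_factory=lambda: {"G1": 56, "G2": 20, "G3": 12, "G4": 10, "G5": 6}
    )
    demands: tuple = DEMANDS
    cuts_per_eye: int = 16
    points_per_cut: int = 5
    pixel_noise_sd: float = 0.02  # px; pre-build calibrated (module docstring)
    scale: CalibrationScale = field(default_factory=CalibrationScale)
    apex_radius0_mm: float = 7.0  # anterior-capsule apex radius at 0 D
    apex_radius_slope: float = 0.3  # mm of steepening per dioptre of demand
    pd_model: dict = field(default_factory=lambda: dict(DEFAULT_PD_MODEL))
    pd_subject_sd: float = 0.6
    acd_model: dict = field(default_factory=lambda: dict(DEFAULT_ACD_MODEL))
    # AA/MAF linear-in-age aging models: (intercept, slope/yr, residual sd)
    aa_model: tuple = (18.55, -0.27, 2.5)
    maf_model: tuple = (21.2, -0.35, 3.0)
    apex_px: tuple = (400.0, 100.0)  # corneal-apex image position
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_subjects.values()):
            raise ValueError("subject counts must be positive")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel noise sd must be >= 0")
        if not (1 <= self.cuts_per_eye <= 16):
            raise ValueError("cuts_per_eye must be in 1..16")

    def to_yaml(self, path) -> None:
        """Write the full config (documented defaults included) as YAML."""
        import dataclasses

        import yaml

        d = dataclasses.asdict(self)
        d["scale"] = {"microns_per_pixel": self.scale.microns_per_pixel}
        d["demands"] = list(self.demands)
        d["apex_px"] = list(self.apex_px)
        for k in ("aa_model", "maf_model"):
            d[k] = list(d[k])
        d["pd_model"] = {g: list(v) for g, v in d["pd_model"].items()}
        d["acd_model"] = {g: list(v) for g, v in d["acd_model"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["scale"] = CalibrationScale(**d["scale"])
        d["demands"] = tuple(d["demands"])
        d["apex_px"] = tuple(d["apex_px"])
        for k in ("aa_model", "maf_model"):
            d[k] = tuple(d[k])
        d["pd_model"] = {g: tuple(v) for g, v in d["pd_model"].items()}
        d["acd_model"] = {g: tuple(v) for g, v in d["acd_model"].items()}
        return cls(**d)


def sample_capsule_arc(
    e_true: float,
    apex_radius_mm: float,
    aperture_mm: float,
    n_points: int = 5,
    noise_sd_px: float = 0.0,
    scale: CalibrationScale | None = None,
    rng: np.random.Generator | None = None,
    origin_px: tuple = (0.0, 0.0),
) -> np.ndarray:
    """Sample capsule landmarks on a prolate elliptical arc, in pixels.

    The ellipse has apex radius of curvature ``apex_radius_mm`` and
    eccentricity ``e_true`` (``a = R/p``, ``b = R/sqrt(p)``); lateral
    positions are evenly spread over ``[-aperture/2, +aperture/2]`` with a
    +/-20%-of-spacing jitter, sag is exact, coordinates are converted to
    pixels with the arc apex at ``origin_px`` (image convention: depth grows
    with +y) and isotropic Gaussian noise of ``noise_sd_px`` is added.
    """
    if not (0 <= e_true < 1):
        raise ValueError(f"eccentricity must be in [0, 1), got {e_true}")
    if aperture_mm <= 0:
        raise ValueError("aperture must be positive")
    scale = scale or CalibrationScale()
    rng = rng or np.random.default_rng()
    p = 1.0 - e_true * e_true
    a = apex_radius_mm / p
    b = apex_radius_mm / np.sqrt(p)
    if aperture_mm / 2 >= b:
        raise ValueError(
            f"aperture {aperture_mm} mm exceeds the lateral extent of the "
            f"ellipse (semi-minor {b:.3f} mm)"
        )
    u = np.linspace(-aperture_mm / 2, aperture_mm / 2, n_points)
    if n_points > 1:
        step = u[1] - u[0]
        u = u + rng.uniform(-0.2 * step, 0.2 * step, n_points)
    sag = a - a * np.sqrt(1.0 - (u / b) ** 2)
    mm_per_px = scale.microns_per_pixel / 1000.0
    pts = np.column_stack([u, sag]) / mm_per_px
    pts += np.asarray(origin_px, dtype=float)
    if noise_sd_px > 0:
        pts = pts + rng.normal(0.0, noise_sd_px, pts.shape)
    return pts


def _cut_eccentricity_target(cut_idx: int, e_h: float, e_v: float) -> float:
    """Per-cut target e: sector value for core cuts, angular interpolation
    between the two meridian values for transitional cuts."""
    asg = assign_sector(cut_idx)
    if asg.role == "core":
        return e_h if asg.sector == "horizontal" else e_v
    theta = DEFAULT_ANGLE_MAP[cut_idx]
    w = min(theta, 180.0 - theta) / 90.0  # 0 at horizontal, 1 at vertical
    return (1.0 - w) * e_h + w * e_v


@dataclass
class PhantomCohort:
    """Generated cohort: eye measurements, metadata, and ground truth."""

    eyes: list
    metadata: pd.DataFrame
    truth: pd.DataFrame  # per (subject, demand, sector)
    config: PhantomConfig

    @property
    def annotations(self) -> pd.DataFrame:
        return annotations_to_frame(self.eyes)

    def n_cut_annotations(self) -> int:
        return sum(len(e.cuts) for e in self.eyes)

    def write(self, directory, fmt: str = "csv") -> dict:
        """Write annotation, metadata, ground-truth and config files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotations": directory / f"annotations.{fmt}",
            "metadata": directory / "metadata.csv",
            "truth": directory / "ground_truth.csv",
            "config": directory / "phantom_config.yaml",
        }
        write_annotations(self.eyes, paths["annotations"], fmt=fmt)
        write_metadata(self.metadata, paths["metadata"])
        self.truth.to_csv(paths["truth"], index=False)
        self.config.to_yaml(paths["config"])
        return paths


def generate_cohort(
    config: PhantomConfig | None = None,
    profiles: dict | None = None,
    profile_override: str | None = None,
) -> PhantomCohort:
    """Generate a reproducible synthetic annotation cohort.

    Each subject draws an age within its group's decade, per-subject baseline
    eccentricities, and biometry from the group models; each (demand, cut)
    then yields capsule landmarks from :func:`sample_capsule_arc` with the
    cut's sector-dependent target eccentricity, plus ACD landmarks placed at
    the configured chamber depth.  ``profile_override`` forces a single
    response profile (e.g. ``"TG"``) onto every subject, used for
    total-group recovery studies.  Identical config and seed give identical
    output.
    """
    config = config or PhantomConfig()
    profiles = profiles or DEFAULT_PROFILES
    rng = np.random.default_rng(config.seed)
    mm_per_px = config.scale.microns_per_pixel / 1000.0

    eyes: list[EyeMeasurement] = []
    meta_rows, truth_rows = [], []
    sid_counter = 0
    for group in ("G1", "G2", "G3", "G4", "G5"):
        n = config.n_subjects.get(group, 0)
        prof = profiles[profile_override] if profile_override else profiles[group]
        lo, hi = GROUP_AGE_RANGE[group]
        pd0, pd_slope = config.pd_model[group]
        acd0, acd_slope, acd_sd = config.acd_model[group]
        for _ in range(n):
            sid_counter += 1
            sid = f"S{sid_counter:03d}"
            age = int(rng.integers(lo, hi + 1))
            sex = "F" if rng.random() < 60 / 104 else "M"
            base_e = {
                s: float(
                    np.clip(
                        prof.baseline_e[s] + rng.normal(0, prof.between_subject_sd),
                        0.05,
                        0.95,
                    )
                )
                for s in ("horizontal", "vertical")
            }
            subj_pd0 = float(np.clip(pd0 + rng.normal(0, config.pd_subject_sd), 4.2, 9.0))
            subj_acd0 = float(np.clip(acd0 + rng.normal(0, acd_sd), 2.5, 5.0))
            aa = float(
                max(0.25, config.aa_model[0] + config.aa_model[1] * age
                    + rng.normal(0, config.aa_model[2]))
            )
            maf = float(
                max(0.0, config.maf_model[0] + config.maf_model[1] * age
                    + rng.normal(0, config.maf_model[2]))
            )
            se = float(np.clip(rng.normal(-2.4, 2.1), -5.5, 2.5))
            al = float(np.clip(rng.normal(24.1, 1.1), 22.0, 26.0))
            meta_rows.append(
                {
                    "subject_id": sid,
                    "age": age,
                    "sex": sex,
                    "PD_mm": subj_pd0,
                    "SE_D": round(se, 2),
                    "AA_D": round(aa, 2),
                    "MAF_cpm": round(maf, 2),
                    "AL_mm": round(al, 2),
                    "ACD_mm": subj_acd0,
                    "age_group": group,
                }
            )

            e_by_demand: dict = {}
            for d in config.demands:
                e_by_demand[d] = {
                    s: float(
                        np.clip(
                            base_e[s]
                            * prof.relative_e[(s, d)]
                            * (1.0 + rng.normal(0, prof.within_subject_sd)),
                            0.02,
                            0.97,
                        )
                    )
                    for s in ("horizontal", "vertical")
                }

            for d in config.demands:
                pd_d = max(4.0, subj_pd0 - pd_slope * d)
                acd_d = max(2.3, subj_acd0 - acd_slope * d)
                radius = max(3.0, config.apex_radius0_mm - config.apex_radius_slope * d)
                eye = EyeMeasurement(
                    subject_id=sid,
                    age=float(age),
                    demand=float(d),
                    metadata={
                        "PD_mm": pd_d,
                        "ACD_mm": acd_d,
                        "AA_D": aa,
                        "MAF_cpm": maf,
                        "AL_mm": al,
                        "SE_D": se,
                    },
                )
                apex = np.asarray(config.apex_px, dtype=float)
                reflex = apex + np.array([0.0, acd_d / mm_per_px])
                e_h = e_by_demand[d]["horizontal"]
                e_v = e_by_demand[d]["vertical"]
                for cut_idx in range(1, config.cuts_per_eye + 1):
                    e_cut = _cut_eccentricity_target(cut_idx, e_h, e_v)
                    pts = sample_capsule_arc(
                        e_cut,
                        apex_radius_mm=radius,
                        aperture_mm=pd_d,
                        n_points=config.points_per_cut,
                        noise_sd_px=config.pixel_noise_sd,
                        scale=config.scale,
                        rng=rng,
                        origin_px=tuple(reflex),
                    )
                    if config.pixel_noise_sd > 0:
                        apex_obs = apex + rng.normal(0, config.pixel_noise_sd, 2)
                        reflex_obs = reflex + rng.normal(0, config.pixel_noise_sd, 2)
                    else:
                        apex_obs, reflex_obs = apex, reflex
                    eye.add_cut(
                        CutAnnotation(
                            subject_id=sid,
                            age=float(age),
                            demand=float(d),
                            cut_index=cut_idx,
                            capsule_points=tuple(map(tuple, pts)),
                            apex_point=tuple(apex_obs),
                            reflex_point=tuple(reflex_obs),
                        )
                    )
                eyes.append(eye)
                for s in ("horizontal", "vertical"):
                    truth_rows.append(
                        {
                            "subject_id": sid,
                            "age_group": group,
                            "demand": d,
                            "sector": s,
                            "true_e": e_by_demand[d][s],
                            "true_relative_e": e_by_demand[d][s]
                            / e_by_demand[0.0][s]
                            if 0.0 in e_by_demand
                            else np.nan,
                            "true_ACD_mm": acd_d,
                            "true_PD_mm": pd_d,
                        }
                    )

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return PhantomCohort(eyes=eyes, metadata=metadata, truth=truth, config=config)


def null_profiles(baseline=(0.78, 0.80)) -> dict:
    """Flat response profiles (no demand effect) for type-I-error studies."""
    flat = (1.0, 1.0, 1.0)
    return {
        g: _profile(g, flat, flat, baseline=baseline)
        for g in ("TG", "G1", "G2", "G3", "G4", "G5")
    }


def null_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Config with every demand effect removed (eccentricity profiles are
    flattened separately via :func:`null_profiles`): no miosis, no chamber
    shallowing, no surface steepening."""
    return PhantomConfig(
        pd_model={g: (b, 0.0) for g, (b, _) in DEFAULT_PD_MODEL.items()},
        acd_model={g: (b, 0.0, sd) for g, (b, _, sd) in DEFAULT_ACD_MODEL.items()},
        apex_radius_slope=0.0,
        seed=seed,
        **overrides,
    )
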