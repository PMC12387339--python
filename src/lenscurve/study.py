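"""Cohort-level modelling surface: annotations in, fitted study results out.

:class:`AccommodationStudy` bundles the whole pipeline — per-cut conic
fitting, meridional sector aggregation, baseline normalisation and the
non-parametric test battery — behind a statsmodels-style ``Model.fit() ->
Results`` interface.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotations import CalibrationScale, read_annotations, read_metadata
from .battery import CorrectionPolicy, StatReport, run_full_battery
from .sectors import build_cohort_table, group_mean_relative

__all__ = ["AccommodationStudy", "StudyResults"]


class AccommodationStudy:
    """Accommodation-response study over a cohort of annotated eyes.

    Parameters
    ----------
    eyes
        List of :class:`~lenscurve.annotations.EyeMeasurement` (one per
        subject per demand).
    metadata
        Per-subject biometry table (``subject_id, age, PD_mm, AA_D, ...``).
    scale
        Pixel calibration used for landmark-derived ACD (default 28 µm/px).
    include_transitional
        Include the transitional cuts in sector means (default: core only).
    """

    def __init__(
        self,
        eyes,
        metadata: pd.DataFrame | None = None,
        scale: CalibrationScale | None = None,
        include_transitional: bool = False,
    ):
        self.eyes = list(eyes)
        self.metadata = metadata
        self.scale = scale or CalibrationScale()
        self.include_transitional = include_transitional

    @classmethod
    def from_files(
        cls, annotations_path, metadata_path=None, **kwargs
    ) -> "AccommodationStudy":
        """Build a study from annotation CSV/JSON and optional metadata CSV."""
        metadata = read_metadata(metadata_path) if metadata_path else None
        eyes = read_annotations(annotations_path)
        return cls(eyes, metadata=metadata, **kwargs)

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "AccommodationStudy":
        """Build a study directly from a generated phantom cohort."""
        return cls(cohort.eyes, metadata=cohort.metadata, **kwargs)

    def fit(self, policy: CorrectionPolicy | None = None) -> "StudyResults":
        """Run conic fits, sector aggregation, normalisation and statistics."""
        table = build_cohort_table(
            self.eyes,
            metadata=self.metadata,
            include_transitional=self.include_transitional,
            scale=self.scale,
        )
        report = run_full_battery(table, metadata=self.metadata, policy=policy)
        return StudyResults(self, table, report)


class StudyResults:
    """Fitted study: cohort table, group response curves and test battery."""

    def __init__(self, model: AccommodationStudy, table: pd.DataFrame, report: StatReport):
        self.model = model
        self.table = table
        self.report = report

    def group_response(self, normalize_group_mean: bool = False) -> pd.DataFrame:
        """Group-mean relative eccentricity per (group, sector, demand)."""
        return group_mean_relative(self.table, normalize_group_mean)

    def relative_at(self, group: str, sector: str, demand: float) -> float:
        resp = self.group_response()
        row = resp[
            (resp["group"] == group)
            & (resp["sector"] == sector)
            & (resp["demand"] == demand)
        ]
        return float(row["value"].iloc[0])

    def qc_report(self) -> dict:
        """Per-subject flagged cuts and missing sectors."""
        out: dict = {}
        for (sid, d), grp in self.table.groupby(["subject_id", "demand"]):
            flagged = sorted(
                {
                    int(c)
                    for row in grp["flagged_cuts"]
                    if isinstance(row, str) and row
                    for c in row.split(";")
                }
            )
            missing = sorted(grp.loc[grp["mean_e"].isna(), "sector"])
            if flagged or missing:
                out.setdefault(sid, {})[f"{d:g}D"] = {
                    "flagged_cuts": flagged,
                    "missing_sectors": missing,
                }
        return out

    def plot_relative_series(self, groups=None, ax=None):
        """Relative-eccentricity response curves (one panel per group)."""
        from . import plotting

        return plotting.plot_relative_series(self, groups=groups, ax=ax)

    def save(self, directory) -> dict:
        """Write the tidy cohort table, QC report and battery JSON/CSVs."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "cohort_table": directory / "cohort_table.csv",
            "qc": directory / "qc_report.json",
            "battery": directory / "battery.json",
            "wilcoxon": directory / "wilcoxon_meridians.csv",
            "kruskal": directory / "kruskal_age_groups.csv",
            "friedman": directory / "friedman_demands.csv",
        }
        self.table.to_csv(paths["cohort_table"], index=False)
        with open(paths["qc"], "w") as fh:
            json.dump(self.qc_report(), fh, indent=1)
        self.report.to_json(paths["battery"])
        thr = self.report.policy.threshold

        def _mark(df, use_thr):
            lim = thr if use_thr else 0.05
            return df.map(
                lambda p: "NA" if pd.isna(p) else f"{p:.3f}" + ("*" if p < lim else "")
            )

        _mark(self.report.wilcoxon_meridians, False).to_csv(paths["wilcoxon"])
        _mark(self.report.kruskal_age_groups, False).to_csv(paths["kruskal"])
        _mark(self.report.friedman_demands, True).to_csv(paths["friedman"])
        return paths

    def summary(self) -> str:
        resp = self.group_response()
        tg = resp[resp["group"] == "TG"].pivot(
            index="demand", columns="sector", values="value"
        )
        n_subj = self.table["subject_id"].nunique()
        lines = [
            "Accommodation study results",
            "=" * 50,
            f"subjects: {n_subj}; rows: {len(self.table)}",
            "",
            "Total-group mean relative eccentricity:",
            tg.round(4).to_string(),
            "",
            self.report.summary(),
        ]
        return "\n".join(lines)
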