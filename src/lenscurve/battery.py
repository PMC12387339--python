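"""Non-parametric statistical battery for the accommodation study.

The analysis plan is entirely rank-based: Pearson correlation (with its
regression line) relates age to accommodative amplitude and facility;
Wilcoxon signed-rank compares the horizontal and vertical meridians within
subjects; Kruskal–Wallis compares age groups; the Friedman test evaluates
within-group change across the four accommodative demands, followed by
pairwise signed-rank post hocs under a Bonferroni-corrected threshold
(alpha/6 = 0.0083 for the six demand contrasts, strict inequality).

The signed-rank test is implemented here directly because the analysis
needs the exact null distribution for small groups (n <= 25) together with
mid-ranks under ties and Wilcoxon's zero-drop rule; larger samples use the
normal approximation with continuity and tie corrections.  Kruskal–Wallis
and Friedman use the tie-corrected chi-square forms from scipy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "StatReport",
    "CorrectionPolicy",
    "pearson_with_regression",
    "wilcoxon_paired",
    "kruskal_wallis",
    "friedman_repeated",
    "bonferroni",
    "run_full_battery",
]

GROUP_ORDER = ("TG", "G1", "G2", "G3", "G4", "G5")
DEMANDS = (0.0, 1.0, 3.0, 5.0)
SECTORS = ("horizontal", "vertical")


@dataclass(frozen=True)
class StatResult:
    """One test outcome: statistic, p-value, sample size and extras."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class CorrectionPolicy:
    """Bonferroni family-wise correction: threshold = alpha / m contrasts."""

    family_alpha: float = 0.05
    m: int = 6  # C(4, 2) pairwise contrasts among 4 demand levels

    @property
    def threshold(self) -> float:
        return self.family_alpha / self.m


def pearson_with_regression(x, y) -> StatResult:
    """Pearson r with two-sided t-test p and the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.linregress(x, y)
    return StatResult(
        test_name="pearson",
        statistic=float(res.rvalue),
        p_value=float(min(1.0, res.pvalue)),
        n=int(x.size),
        extras={
            "r": float(res.rvalue),
            "slope": float(res.slope),
            "intercept": float(res.intercept),
        },
    )


def _signed_rank_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p for the signed-rank sum via shift convolution.

    ``ranks2`` are the doubled mid-ranks (integers), ``w2`` the doubled
    observed positive-rank sum.  Enumerates the 2^n sign assignments by
    dynamic programming over achievable sums.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(a, b, exact_max_n: int = 25) -> StatResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's rule), tied absolute
    differences get mid-ranks.  The null distribution is exact (all sign
    assignments, via convolution) for n <= ``exact_max_n`` retained pairs
    and a continuity-corrected normal approximation with tie correction
    otherwise.  All differences zero gives a flagged degenerate result with
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    d = a - b
    d = d[np.isfinite(d)]
    nonzero = d[d != 0.0]
    n = int(nonzero.size)
    if n == 0:
        return StatResult(
            test_name="wilcoxon",
            statistic=0.0,
            p_value=1.0,
            n=0,
            extras={"degenerate": True, "reason": "all differences zero"},
        )
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(np.rint(2 * w_plus))
        p = _signed_rank_exact_p(ranks2, w2)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, t_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((t_counts**3 - t_counts) / 48.0).sum())
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            p = 1.0
        else:
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal"
    return StatResult(
        test_name="wilcoxon",
        statistic=w_plus,
        p_value=p,
        n=n,
        extras={"method": method},
    )


def kruskal_wallis(groups) -> StatResult:
    """Kruskal–Wallis H across independent groups (tie-corrected chi-square)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    n_total = int(sum(g.size for g in groups))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # scipy raises on all-identical data
        return StatResult(
            test_name="kruskal", statistic=0.0, p_value=1.0, n=n_total,
            extras={"k": len(groups), "degenerate": True},
        )
    h, p = sps.kruskal(*groups)
    return StatResult(
        test_name="kruskal",
        statistic=float(h),
        p_value=float(p),
        n=n_total,
        extras={"k": len(groups)},
    )


def friedman_repeated(block_matrix) -> StatResult:
    """Friedman chi-square over a subjects x conditions block matrix.

    Rows with any missing cell are dropped listwise.  Within-block ties get
    mid-ranks; the statistic is the tie-corrected chi-square with k-1 df.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("block matrix must be 2-D with >= 2 conditions")
    m = m[np.all(np.isfinite(m), axis=1)]
    b, k = m.shape
    if b < 2:
        raise ValueError("need at least 2 complete blocks")
    ranks = sps.rankdata(m, axis=1)
    if np.allclose(ranks.var(axis=1), 0.0):
        return StatResult(
            test_name="friedman", statistic=0.0, p_value=1.0, n=b,
            extras={"k": k, "degenerate": True},
        )
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (b * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * b * (k + 1)
    # tie correction: scale by 1 - sum(t^3 - t) / (b k (k^2 - 1))
    tie_sum = 0.0
    srt = np.sort(m, axis=1)
    has_ties = np.any(np.diff(srt, axis=1) == 0.0, axis=1)
    for row in m[has_ties]:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    c = 1.0 - tie_sum / (b * k * (k * k - 1))
    if c <= 0:
        return StatResult(
            test_name="friedman", statistic=0.0, p_value=1.0, n=b,
            extras={"k": k, "degenerate": True},
        )
    chi2 /= c
    p = float(sps.chi2.sf(chi2, k - 1))
    return StatResult(
        test_name="friedman", statistic=float(chi2), p_value=p, n=b, extras={"k": k}
    )


def bonferroni(policy: CorrectionPolicy, pairwise_p: dict) -> dict:
    """Mark each contrast significant iff p < alpha/m (strict inequality)."""
    if policy.m < 1:
        raise ValueError("need at least one contrast")
    thr = policy.threshold
    return {k: (p, bool(p < thr)) for k, p in pairwise_p.items()}


# --------------------------------------------------------------------------
# full battery over a cohort table
# --------------------------------------------------------------------------


@dataclass
class StatReport:
    """The study's full test battery over one cohort table.

    Attributes mirror the report layout: meridian comparisons (groups x
    demands), age-group comparisons (sectors x demands), within-group
    repeated-measures tests (groups x sectors) with Bonferroni post hocs,
    the two age correlations, and the PD/ACD repeated-measures analyses.
    """

    wilcoxon_meridians: pd.DataFrame
    kruskal_age_groups: pd.DataFrame
    friedman_demands: pd.DataFrame
    friedman_posthoc: dict
    correlations: dict
    pd_friedman: dict
    acd_friedman: dict
    policy: CorrectionPolicy

    def cell_p_values(self) -> np.ndarray:
        """Every finite p-value cell of the battery (all five test families)."""
        vals = []
        for df in (
            self.wilcoxon_meridians,
            self.kruskal_age_groups,
            self.friedman_demands,
        ):
            vals += list(df.to_numpy(dtype=float).ravel())
        for res in list(self.pd_friedman.values()) + list(self.acd_friedman.values()):
            if isinstance(res, StatResult):
                vals.append(res.p_value)
        vals = np.asarray(vals, dtype=float)
        return vals[np.isfinite(vals)]

    def significant_fraction(self, threshold: float | None = None) -> float:
        """Fraction of battery cells with p below ``threshold`` (default: the
        Bonferroni-corrected threshold)."""
        thr = self.policy.threshold if threshold is None else threshold
        p = self.cell_p_values()
        return float(np.mean(p < thr)) if p.size else 0.0

    def to_dict(self) -> dict:
        def _df(df):
            return {str(r): {str(c): v for c, v in row.items()} for r, row in df.to_dict(orient="index").items()}

        return {
            "wilcoxon_meridians": _df(self.wilcoxon_meridians),
            "kruskal_age_groups": _df(self.kruskal_age_groups),
            "friedman_demands": _df(self.friedman_demands),
            "friedman_posthoc": {
                f"{g}|{s}": {f"{c[0]:g}v{c[1]:g}": [p, sig] for c, (p, sig) in d.items()}
                for (g, s), d in self.friedman_posthoc.items()
            },
            "correlations": {
                k: {"r": v.statistic, "p": v.p_value, "n": v.n, **v.extras}
                for k, v in self.correlations.items()
            },
            "pd_friedman": {
                g: {"chi2": r.statistic, "p": r.p_value, "n": r.n}
                for g, r in self.pd_friedman.items()
                if isinstance(r, StatResult)
            },
            "acd_friedman": {
                g: {"chi2": r.statistic, "p": r.p_value, "n": r.n}
                for g, r in self.acd_friedman.items()
                if isinstance(r, StatResult)
            },
            "bonferroni_threshold": round(self.policy.threshold, 4),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=float)

    def summary(self) -> str:
        thr = self.policy.threshold

        def _fmt(df):
            out = df.copy()
            for c in out.columns:
                out[c] = out[c].map(
                    lambda p: "NA" if pd.isna(p) else f"{p:.3f}"
                )
            return out.to_string()

        star = self.friedman_demands.map(
            lambda p: "NA" if pd.isna(p) else f"{p:.3f}" + (" *" if p < thr else "")
        )
        lines = [
            "Accommodation-response statistical battery",
            "=" * 50,
            f"Bonferroni threshold (alpha=0.05, m=6): {thr:.4f}",
            "",
            "Wilcoxon horizontal vs vertical (p), groups x demands:",
            _fmt(self.wilcoxon_meridians),
            "",
            "Kruskal-Wallis across age groups (p), sectors x demands:",
            _fmt(self.kruskal_age_groups),
            "",
            "Friedman across demands (p, * = significant at corrected threshold):",
            star.to_string(),
        ]
        for name, res in self.correlations.items():
            ex = res.extras
            lines.append(
                f"\n{name}: r = {res.statistic:.3f}, p = {res.p_value:.3g}, "
                f"y = {ex['slope']:.3f} x + {ex['intercept']:.2f} (n = {res.n})"
            )
        return "\n".join(lines)


def _subject_demand_matrix(df: pd.DataFrame, value: str) -> np.ndarray:
    """subjects x demands matrix of a per-(subject, demand) value."""
    wide = df.pivot_table(
        index="subject_id", columns="demand", values=value, aggfunc="first"
    )
    wide = wide.reindex(columns=list(DEMANDS))
    return wide.to_numpy(dtype=float)


def run_full_battery(
    table: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    policy: CorrectionPolicy | None = None,
) -> StatReport:
    """Run the whole battery on a tidy cohort table.

    ``table`` is the (subject, demand, sector) table from
    :func:`lenscurve.sectors.build_cohort_table`; ``metadata`` supplies the
    per-subject age/AA/MAF columns for the correlations.  Cells whose group
    is too small for the test are left as NaN (reported ``NA``), never
    imputed.
    """
    policy = policy or CorrectionPolicy()
    groups = ["TG"] + sorted(g for g in table["age_group"].dropna().unique())

    def _sub(group):
        return table if group == "TG" else table[table["age_group"] == group]

    # --- Wilcoxon: horizontal vs vertical relative e, per group x demand
    wil = pd.DataFrame(index=groups, columns=list(DEMANDS), dtype=float)
    for g in groups:
        sub = _sub(g)
        for d in DEMANDS:
            cell = sub[sub["demand"] == d].pivot_table(
                index="subject_id", columns="sector", values="relative_e"
            )
            if not set(SECTORS) <= set(cell.columns):
                continue
            cell = cell.dropna(subset=list(SECTORS))
            if len(cell) < 1:
                continue
            res = wilcoxon_paired(cell["horizontal"], cell["vertical"])
            wil.loc[g, d] = res.p_value

    # --- Kruskal-Wallis: relative e across age groups, per sector x demand
    kru = pd.DataFrame(index=list(SECTORS), columns=list(DEMANDS), dtype=float)
    age_groups = [g for g in groups if g != "TG"]
    for s in SECTORS:
        for d in DEMANDS:
            samples = []
            for g in age_groups:
                sub = _sub(g)
                samples.append(
                    sub.loc[
                        (sub["sector"] == s) & (sub["demand"] == d), "relative_e"
                    ]
                    .dropna()
                    .to_numpy()
                )
            samples = [x for x in samples if x.size > 0]
            if len(samples) < 2 or sum(x.size for x in samples) < 5:
                continue
            kru.loc[s, d] = kruskal_wallis(samples).p_value

    # --- Friedman across demands per group x sector, with signed-rank post hocs
    fri = pd.DataFrame(index=groups, columns=list(SECTORS), dtype=float)
    posthoc: dict = {}
    for g in groups:
        for s in SECTORS:
            sub = _sub(g)
            sub = sub[sub["sector"] == s]
            mat = _subject_demand_matrix(sub, "relative_e")
            complete = mat[np.all(np.isfinite(mat), axis=1)]
            if complete.shape[0] < 2:
                continue
            fri.loc[g, s] = friedman_repeated(complete).p_value
            pairs = {
                (d1, d2): wilcoxon_paired(
                    complete[:, DEMANDS.index(d1)], complete[:, DEMANDS.index(d2)]
                ).p_value
                for d1, d2 in combinations(DEMANDS, 2)
            }
            posthoc[(g, s)] = bonferroni(policy, pairs)

    # --- age correlations (AA, MAF) from metadata
    correlations: dict = {}
    if metadata is not None and not metadata.empty:
        for col, name in (("AA_D", "age_vs_AA"), ("MAF_cpm", "age_vs_MAF")):
            if col not in metadata.columns:
                continue
            sub = metadata[["age", col]].dropna()
            if len(sub) >= 3 and sub["age"].nunique() > 1 and sub[col].nunique() > 1:
                correlations[name] = pearson_with_regression(sub["age"], sub[col])

    # --- PD and ACD Friedman per group (per-subject per-demand values)
    def _biometry_friedman(col: str) -> dict:
        out: dict = {}
        per_sd = table.drop_duplicates(["subject_id", "demand"])
        for g in groups:
            sub = per_sd if g == "TG" else per_sd[per_sd["age_group"] == g]
            mat = _subject_demand_matrix(sub, col)
            complete = mat[np.all(np.isfinite(mat), axis=1)]
            if complete.shape[0] < 2:
                out[g] = "NA(insufficient n)"
                continue
            out[g] = friedman_repeated(complete)
        return out

    return StatReport(
        wilcoxon_meridians=wil,
        kruskal_age_groups=kru,
        friedman_demands=fri,
        friedman_posthoc=posthoc,
        correlations=correlations,
        pd_friedman=_biometry_friedman("PD_mm"),
        acd_friedman=_biometry_friedman("ACD_mm"),
        policy=policy,
    )
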