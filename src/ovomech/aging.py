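"""Per-oocyte timelines, degradation alignment, group statistics, summaries.

Postovulatory aging experiments track each oocyte hourly (modulus E2,
dissipated viscous energy, optionally the cortical-granule fluorescence
signal) together with a morphology label. Because different oocytes degrade
at different absolute times, series are aligned on the first visually
degraded timepoint ("time before degradation", t_rel <= 0); never-degraded
oocytes keep absolute time and carry a flag.

Statistical comparisons (one-way ANOVA, Kruskal-Wallis with tie correction,
Mann-Whitney with continuity-corrected normal approximation) are implemented
from the standard formulas; tests cross-validate them against independent
references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "OocyteTimeline",
    "AlignedSeries",
    "GroupComparison",
    "align_to_degradation",
    "classify_groups",
    "compare_groups",
    "yield_table",
    "percentage",
    "headline_summary",
    "HeadlineReport",
]

MORPHOLOGY_LABELS = ("healthy", "degraded")

TIMELINE_COLUMNS = ["t_hours", "E2_Pa", "dissipation_fJ", "cg_area", "morphology"]


@dataclass
class OocyteTimeline:
    """Hourly record for one oocyte.

    ``data`` holds columns ``t_hours, E2_Pa, dissipation_fJ, cg_area,
    morphology``; time must be strictly increasing, and the morphology label
    may switch from healthy to degraded at most once (degraded is absorbing).
    """

    oocyte_id: str
    source: str  # "fresh" | "thawed"
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.source not in ("fresh", "thawed"):
            raise ValueError("source must be 'fresh' or 'thawed'")
        df = self.data
        for col in ("t_hours", "E2_Pa", "dissipation_fJ", "morphology"):
            if col not in df.columns:
                raise ValueError(f"timeline missing column '{col}'")
        if "cg_area" not in df.columns:
            df = df.assign(cg_area=np.nan)
        t = df["t_hours"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_hours must be strictly increasing")
        morph = df["morphology"].to_numpy()
        if not set(morph) <= set(MORPHOLOGY_LABELS):
            raise ValueError(f"morphology labels must be in {MORPHOLOGY_LABELS}")
        deg = morph == "degraded"
        if deg.any():
            first = int(np.argmax(deg))
            if not deg[first:].all():
                raise ValueError(
                    "degraded is absorbing: at most one healthy->degraded transition"
                )
        self.data = df.reset_index(drop=True)

    @property
    def degradation_time(self) -> float | None:
        """Time of the first degraded observation, None if never degraded."""
        deg = self.data["morphology"].to_numpy() == "degraded"
        if not deg.any():
            return None
        return float(self.data["t_hours"].iloc[int(np.argmax(deg))])


@dataclass
class AlignedSeries:
    """Timeline on the degradation-aligned axis (t_rel = 0 at degradation)."""

    oocyte_id: str
    source: str
    degraded: bool
    data: pd.DataFrame  # with added t_rel column


def align_to_degradation(tl: OocyteTimeline) -> AlignedSeries:
    """Re-zero a timeline on its first degraded observation.

    Degraded oocytes get ``t_rel = t - t_degradation`` (so max(t_rel) = 0);
    never-degraded oocytes keep absolute time and ``degraded=False``.
    """
    t_deg = tl.degradation_time
    df = tl.data.copy()
    if t_deg is None:
        df["t_rel"] = df["t_hours"]
        return AlignedSeries(tl.oocyte_id, tl.source, degraded=False, data=df)
    # drop observations after the first degraded one, if any (absorbing state
    # validated upstream; alignment keeps up to and including the transition)
    df = df[df["t_hours"] <= t_deg].copy()
    df["t_rel"] = df["t_hours"] - t_deg
    return AlignedSeries(tl.oocyte_id, tl.source, degraded=True, data=df)


def classify_groups(
    tls: list[OocyteTimeline], horizon: float = 6.0, closed: bool = True
) -> tuple[list[OocyteTimeline], list[OocyteTimeline]]:
    """Partition a cohort into (healthy-at-horizon, degraded-within-horizon).

    A degradation observed exactly at the horizon counts as degraded when
    ``closed`` (the default boundary rule). The partition is disjoint and
    exhaustive; empty groups are allowed.
    """
    healthy: list[OocyteTimeline] = []
    degraded: list[OocyteTimeline] = []
    for tl in tls:
        t_deg = tl.degradation_time
        is_deg = t_deg is not None and (
            t_deg <= horizon if closed else t_deg < horizon
        )
        (degraded if is_deg else healthy).append(tl)
    return healthy, degraded


# ---------------------------------------------------------------------------
# Statistical tests (from the standard formulas)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    test: str  # anova | kruskal_wallis | mann_whitney
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _anova(groups: list[np.ndarray]) -> tuple[float, float]:
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, int(ns.sum()) - k
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, float(sstats.f.sf(F, df_b, df_w))


def _kruskal(groups: list[np.ndarray]) -> tuple[float, float]:
    k = len(groups)
    all_vals = np.concatenate(groups)
    N = len(all_vals)
    ranks = sstats.rankdata(all_vals)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    if tie > 0:
        H /= tie
    return float(H), float(sstats.chi2.sf(H, k - 1))


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = len(x), len(y)
    # U of x over y by pair counting (ties count 1/2)
    diff = x[:, None] - y[None, :]
    U = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    mu = n1 * n2 / 2.0
    all_vals = np.concatenate([x, y])
    N = n1 + n2
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return U, 1.0
    sigma = np.sqrt(sigma2)
    # continuity correction toward the mean
    z = (U - mu - 0.5 * np.sign(U - mu)) / sigma if U != mu else 0.0
    return U, float(min(2.0 * sstats.norm.sf(abs(z)), 1.0))


def compare_groups(values_by_group, test: str = "mann_whitney") -> GroupComparison:
    """Compare groups of measurements with the named test.

    ``values_by_group`` is a sequence (or dict) of 1-D arrays. ANOVA and
    Kruskal-Wallis accept >= 2 groups; Mann-Whitney requires exactly 2.
    Each group must have n >= 3.
    """
    if isinstance(values_by_group, dict):
        groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs n >= 3")
    if test == "anova":
        stat, p = _anova(groups)
    elif test == "kruskal_wallis":
        stat, p = _kruskal(groups)
    elif test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney requires exactly 2 groups")
        stat, p = _mannwhitney(groups[0], groups[1])
    else:
        raise ValueError(f"unknown test '{test}'")
    return GroupComparison(
        test=test, statistic=stat, p_value=p,
        group_sizes=tuple(len(g) for g in groups),
    )


# ---------------------------------------------------------------------------
# Embryo-yield arithmetic
# ---------------------------------------------------------------------------


def percentage(count: int, total: int) -> int:
    """Integer percentage, rounded half-up (printed-table convention)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if count < 0 or count > total:
        raise ValueError("count must be in [0, total]")
    return int(np.floor(100.0 * count / total + 0.5))


def yield_table(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Embryo-yield percentages from per-group stage counts.

    ``counts`` maps group name -> {"total": N, stage: n, ...}. Each stage
    count must be <= total; percentages are rounded half-up to integers.
    """
    rows = []
    for group, c in counts.items():
        if "total" not in c:
            raise ValueError(f"group '{group}' missing 'total'")
        total = int(c["total"])
        if total <= 0:
            raise ValueError(f"group '{group}' has total = 0")
        row = {"group": group, "total": total}
        for stage, n in c.items():
            if stage == "total":
                continue
            if not 0 <= n <= total:
                raise ValueError(f"stage count {stage}={n} outside [0, {total}]")
            row[stage] = int(n)
            row[f"{stage}_pct"] = percentage(int(n), total)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Headline summary
# ---------------------------------------------------------------------------


@dataclass
class HeadlineReport:
    """Cohort summary on the aligned axis with change-point flags."""

    table: pd.DataFrame  # metric, t_rel, n, mean, se, p_vs_baseline
    flags: dict = field(default_factory=dict)  # metric -> (first flagged hour, direction)
    alpha: float = 0.05

    def to_json(self) -> dict:
        return {
            "alpha": self.alpha,
            "flags": {
                m: {"t_rel": h, "direction": d} for m, (h, d) in self.flags.items()
            },
            "table": self.table.to_dict(orient="records"),
        }


def headline_summary(
    aligned: list[AlignedSeries],
    metrics: tuple[str, ...] = ("E2_Pa", "dissipation_fJ"),
    test: str = "mann_whitney",
    alpha: float = 0.05,
    min_n: int = 5,
) -> HeadlineReport:
    """Per-hour cohort means ± SE and the first hour deviating from baseline.

    The baseline group is each oocyte's first measured value. At every later
    aligned hour with at least ``min_n`` oocytes, that hour's values are
    compared to the baseline group with the configured test; the first hour
    with p < alpha is flagged per metric, with the direction of the change.
    No multiple-testing correction is applied by default.
    """
    frames = []
    for s in aligned:
        df = s.data.copy()
        df["oocyte_id"] = s.oocyte_id
        df["hour"] = np.round(df["t_rel"]).astype(int)
        df["is_first"] = False
        df.loc[df.index[0], "is_first"] = True
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)

    rows = []
    flags: dict[str, tuple[int, int]] = {}
    for metric in metrics:
        baseline = pooled.loc[pooled["is_first"], metric].dropna().to_numpy()
        for hour in sorted(pooled["hour"].unique()):
            sel = pooled[(pooled["hour"] == hour) & (~pooled["is_first"])]
            vals = sel[metric].dropna().to_numpy()
            row = {
                "metric": metric,
                "t_rel": int(hour),
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                "p_vs_baseline": np.nan,
            }
            if len(vals) >= min_n and len(baseline) >= min_n:
                cmpres = compare_groups([baseline, vals], test=test)
                row["p_vs_baseline"] = cmpres.p_value
                if cmpres.p_value < alpha and metric not in flags:
                    direction = int(np.sign(vals.mean() - baseline.mean()))
                    flags[metric] = (int(hour), direction)
            rows.append(row)
    return HeadlineReport(table=pd.DataFrame(rows), flags=flags, alpha=alpha)
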