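"""7-day moving-window space-use metrics and phase detection.

Every metric is computed per post-release day (1-based) for each
animal: dBBMM core (50%) and range (95%) areas over the day's 7-day
window (the day itself plus 3 days before and after, truncated at the
series edges), mean distance to the release site, daily distance
travelled, and net squared displacement. Animals are then aggregated
into groups (status x release habitat) as mean +/- SE series, and the
exploration -> exploitation transition of a translocated group is the
first day its mean 95% range area drops to the resident reference
level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from translocmove.dbbmm import (
    DBBMMConfig,
    IsoplethSpec,
    VarianceProfile,
    compute_ud,
    dynamic_variance_profile,
    isopleth_area,
)
from translocmove.trajectory import Trajectory, compute_steps

logger = logging.getLogger(__name__)

METRICS = ["core_area_ha", "range_area_ha", "mean_dist_release_m", "daily_distance_m", "nsd_m2"]

EXPLORATION = "exploration"
EXPLOITATION = "exploitation"


@dataclass(frozen=True)
class WindowConfig:
    """Moving-window parameters.

    half_width_days
        Days included on each side of the focal day (3 -> 7-day window).
    horizon_days
        Monitoring horizon post release (90 days).
    expected_fixes_per_day
        Nominal fixes/day at 2-h cadence (12); informational only —
        days with fewer fixes still contribute.
    resident_reference
        How the resident comparison level for phase detection is
        formed: "grand_mean" (mean of the resident group's daily mean
        range areas over the horizon) or "day_matched".
    """

    half_width_days: int = 3
    horizon_days: int = 90
    expected_fixes_per_day: int = 12
    resident_reference: str = "grand_mean"

    def __post_init__(self) -> None:
        if self.half_width_days < 0:
            raise ValueError("half_width_days must be >= 0")
        if self.resident_reference not in ("grand_mean", "day_matched"):
            raise ValueError("resident_reference must be grand_mean|day_matched")


@dataclass
class PhaseAssignment:
    """Per-group transition day and daily phase labels.

    The crossing day — the first day the translocated group's mean
    range area is at or below the resident reference — is the *last*
    exploration day; ``transition_day`` = crossing_day + 1 is the
    first exploitation day. If the translocated series never reaches
    the resident level, transition_day = horizon+1 and every day stays
    exploration (``reached`` False).
    """

    group: str
    transition_day: int
    horizon: int
    reached: bool = True

    @property
    def crossing_day(self) -> int:
        return self.transition_day - 1

    def phase_of(self, day: int) -> str:
        return EXPLORATION if day < self.transition_day else EXPLOITATION

    @property
    def labels(self) -> pd.Series:
        days = np.arange(1, self.horizon + 1)
        return pd.Series(
            np.where(days < self.transition_day, EXPLORATION, EXPLOITATION),
            index=days, name="phase",
        )


def window_days(day: int, cfg: WindowConfig | None = None, last_day: int = 90) -> tuple[int, int]:
    """Inclusive day interval of the moving window around ``day``.

    Day 4 with a 3-day half-width spans days 1-7; windows truncate at
    the start and end of the series rather than being dropped.
    """
    cfg = cfg or WindowConfig()
    if not 1 <= day <= last_day:
        raise ValueError(f"day {day} outside [1, {last_day}]")
    return max(1, day - cfg.half_width_days), min(last_day, day + cfg.half_width_days)


def _day_table(traj: Trajectory) -> tuple[np.ndarray, int]:
    days = traj.day_index()
    last = int(days.max()) if len(days) else 0
    return days, last


def windowed_ud_areas(
    traj: Trajectory,
    cfg: WindowConfig | None = None,
    dcfg: DBBMMConfig | None = None,
    profile: VarianceProfile | None = None,
    refit_per_window: bool = False,
) -> pd.DataFrame:
    """Daily dBBMM core/range areas over the 7-day moving window.

    The dynamic variance profile is estimated once over the whole
    monitoring period; each day's UD then integrates only the bridges
    whose fixes fall inside that day's window, reusing the global
    per-step variances (set ``refit_per_window`` to re-estimate the
    profile from each window's fixes alone instead). Days whose
    window holds fewer than ``dcfg.window_size`` fixes yield NaN.
    """
    cfg = cfg or WindowConfig()
    dcfg = dcfg or DBBMMConfig()
    days, last = _day_table(traj)
    last = min(last, cfg.horizon_days)
    rows = []
    spec = IsoplethSpec((0.50, 0.95))
    if profile is None and not refit_per_window and len(traj) >= 2:
        profile = dynamic_variance_profile(traj, dcfg)
    for d in range(1, last + 1):
        lo, hi = window_days(d, cfg, last)
        in_win = np.flatnonzero((days >= lo) & (days <= hi))
        core = rng = np.nan
        if len(in_win) >= dcfg.window_size:
            f0, f1 = int(in_win[0]), int(in_win[-1])
            if refit_per_window:
                sub = traj.with_fixes(traj.fixes.iloc[f0 : f1 + 1])
                ud = compute_ud(sub, dynamic_variance_profile(sub, dcfg), dcfg)
            else:
                ud = compute_ud(traj, profile, dcfg, step_slice=slice(f0, f1))
            areas = isopleth_area(ud, spec)
            core, rng = areas[0.50], areas[0.95]
        rows.append({"day": d, "core_area_ha": core, "range_area_ha": rng,
                     "n_fixes_window": len(in_win)})
    return pd.DataFrame(rows)


def distance_from_release(traj: Trajectory) -> pd.DataFrame:
    """Per-day mean Euclidean distance of fixes to the release site."""
    days, last = _day_table(traj)
    rx, ry = traj.meta.release_xy
    dist = np.hypot(traj.fixes["x"] - rx, traj.fixes["y"] - ry)
    df = pd.DataFrame({"day": days, "dist": dist})
    out = df.groupby("day").agg(mean_dist_release_m=("dist", "mean"), n_fixes=("dist", "size"))
    return out.reindex(range(1, last + 1)).rename_axis("day").reset_index()


def daily_distance(traj: Trajectory) -> pd.DataFrame:
    """Per-day distance travelled and end-of-day net squared displacement.

    Daily distance sums the lengths of steps whose terminal fix falls
    on that day, so the total over all days equals the total path
    length. NSD is the squared distance of the day's last fix from
    the release site.
    """
    days, last = _day_table(traj)
    steps = compute_steps(traj)
    lengths = np.array([s.length for s in steps])
    step_day = days[1:] if len(days) > 1 else np.array([], int)
    rx, ry = traj.meta.release_xy
    nsd_all = (traj.fixes["x"] - rx) ** 2 + (traj.fixes["y"] - ry) ** 2
    rows = []
    for d in range(1, last + 1):
        mask = step_day == d
        in_day = np.flatnonzero(days == d)
        nsd = float(nsd_all.iloc[in_day[-1]]) if len(in_day) else np.nan
        rows.append({
            "day": d,
            "daily_distance_m": float(lengths[mask].sum()) if mask.any() else (0.0 if len(in_day) else np.nan),
            "nsd_m2": nsd,
        })
    return pd.DataFrame(rows)


def daily_metrics(
    traj: Trajectory,
    cfg: WindowConfig | None = None,
    dcfg: DBBMMConfig | None = None,
) -> pd.DataFrame:
    """Full per-day metric table for one animal (the DailyMetrics series)."""
    cfg = cfg or WindowConfig()
    areas = windowed_ud_areas(traj, cfg, dcfg)
    dist = distance_from_release(traj)
    trav = daily_distance(traj)
    out = areas.merge(dist, on="day", how="outer").merge(trav, on="day", how="outer")
    out = out[out["day"] <= cfg.horizon_days].reset_index(drop=True)
    out.insert(0, "animal_id", traj.meta.animal_id)
    out.insert(1, "group", traj.meta.group)
    return out


def group_series(per_animal: list[tuple[Trajectory, pd.DataFrame]]) -> dict[str, pd.DataFrame]:
    """Group mean +/- SE series keyed by status x release habitat.

    Per day, the mean is over animals with data that day; SE = sd/sqrt(n)
    across animals, reported only when n >= 2. Animals leave the series
    when censored, so n can drop over time.
    """
    by_group: dict[str, list[pd.DataFrame]] = {}
    for traj, dm in per_animal:
        by_group.setdefault(traj.meta.group, []).append(dm)
    out = {}
    for group, dms in by_group.items():
        if not dms:
            logger.warning("group %s empty; omitted", group)
            continue
        long = pd.concat(dms, ignore_index=True)
        agg: dict[str, pd.Series] = {}
        g = long.groupby("day")
        for metric in METRICS:
            agg[f"mean_{metric}"] = g[metric].mean()
            sd = g[metric].std(ddof=1)
            n = g[metric].count()
            agg[f"se_{metric}"] = (sd / np.sqrt(n)).where(n >= 2)
            agg[f"n_{metric}"] = n
        out[group] = pd.DataFrame(agg).rename_axis("day").reset_index()
    return out


def detect_phase_transition(
    translocated: pd.DataFrame,
    resident: pd.DataFrame,
    group: str,
    cfg: WindowConfig | None = None,
) -> PhaseAssignment:
    """First day a translocated group's mean 95% area reaches resident level.

    The resident reference is the grand mean of the resident group's
    daily mean range areas over the horizon (or the day-matched daily
    mean under ``resident_reference='day_matched'``). Comparison
    starts at the first day the translocated series has data; if the
    level is never reached the assignment is flagged and every day
    stays exploration. The crossing day counts as the last
    exploration day, so a group crossing on day 29 has exploratory
    days 1-29 and exploitation days 30 onward.
    """
    cfg = cfg or WindowConfig()
    horizon = cfg.horizon_days
    ts = translocated.set_index("day")["mean_range_area_ha"]
    rs = resident.set_index("day")["mean_range_area_ha"]
    ref_grand = rs.dropna().mean()
    for d in range(1, horizon + 1):
        v = ts.get(d, np.nan)
        if np.isnan(v):
            continue
        ref = ref_grand if cfg.resident_reference == "grand_mean" else rs.get(d, np.nan)
        if np.isnan(ref):
            continue
        if v <= ref:
            return PhaseAssignment(group, d + 1, horizon, reached=True)
    logger.warning("group %s never reached the resident reference level", group)
    return PhaseAssignment(group, horizon + 1, horizon, reached=False)
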