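"""Trajectory data model, GPS CSV I/O, and preprocessing.

A :class:`Trajectory` holds one animal's time-ordered GPS fixes in a
projected metric coordinate system, together with its metadata
(resident vs. translocated status, release/capture coordinates, censor
windows). Preprocessing follows the standard telemetry cleaning
sequence: PDOP quality filter, thinning to a common 2-h cadence,
homing detection for translocated animals, censoring, and truncation
to a 90-day monitoring horizon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESIDENT = "resident"
TRANSLOCATED = "translocated"

_FIX_COLUMNS = ["t", "x", "y", "pdop"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning parameters for raw GPS fixes.

    target_interval_s
        Common cadence the data are thinned to (default 2 h). Finer
        schedules (15-min, 1-h) are subsampled, never interpolated.
    interval_tolerance_s
        How far from the nominal 2-h mark a fix may sit and still be
        kept (default +/- 15 min).
    pdop_max
        Fixes with PDOP strictly greater than this are discarded;
        fixes with no PDOP recorded are retained.
    truncate_days
        Monitoring horizon; fixes after this many days from the (possibly
        re-based) first fix are dropped.
    tz_offset_hours
        Offset applied before assigning fixes to calendar days, so that
        "a day" means local midnight to midnight at the study site.
    """

    target_interval_s: float = 7200.0
    interval_tolerance_s: float = 900.0
    pdop_max: float = 9.0
    truncate_days: int = 90
    homing_radius_m: float = 1600.0
    homing_window_days: int = 10
    tz_offset_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.target_interval_s <= 0:
            raise ValueError("target_interval_s must be > 0")
        if self.pdop_max <= 0:
            raise ValueError("pdop_max must be > 0")


@dataclass(frozen=True)
class AnimalMeta:
    """Per-animal study metadata.

    Residents are released at their capture site (release_xy ==
    capture_xy); translocated animals are moved to a novel release
    site. ``censor_windows`` are closed time intervals whose fixes are
    removed (e.g., periods travelling with another collared animal).
    """

    animal_id: str
    status: str
    release_habitat: str = "upland_pine"
    release_xy: tuple[float, float] = (0.0, 0.0)
    capture_xy: tuple[float, float] = (0.0, 0.0)
    censor_windows: tuple[tuple[pd.Timestamp, pd.Timestamp], ...] = ()

    def __post_init__(self) -> None:
        if self.status not in (RESIDENT, TRANSLOCATED):
            raise ValueError(f"status must be resident|translocated, got {self.status!r}")
        if self.status == RESIDENT and tuple(self.release_xy) != tuple(self.capture_xy):
            raise ValueError("residents must have release_xy == capture_xy")
        ws = sorted(self.censor_windows)
        for (a0, a1), (b0, b1) in zip(ws, ws[1:]):
            if b0 <= a1:
                raise ValueError("censor_windows must be non-overlapping")

    @property
    def group(self) -> str:
        """Analysis group key: status x release habitat."""
        return f"{self.status}_{self.release_habitat}"


class Trajectory:
    """One animal's time-ordered GPS fixes plus metadata.

    Fixes live in a DataFrame with columns ``t`` (tz-aware UTC
    timestamps), ``x``, ``y`` (projected meters) and ``pdop``
    (NaN when unrecorded). Timestamps are strictly increasing.
    """

    def __init__(self, meta: AnimalMeta, fixes: pd.DataFrame):
        fixes = fixes.loc[:, _FIX_COLUMNS].reset_index(drop=True)
        t = pd.to_datetime(fixes["t"], utc=True)
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("fixes must have strictly increasing timestamps")
        if not np.isfinite(fixes[["x", "y"]].to_numpy(float)).all():
            raise ValueError("fix coordinates must be finite")
        fixes = fixes.assign(t=t)
        self.meta = meta
        self.fixes = fixes

    def __len__(self) -> int:
        return len(self.fixes)

    def __repr__(self) -> str:
        return f"Trajectory({self.meta.animal_id!r}, n={len(self)}, status={self.meta.status})"

    @property
    def t_seconds(self) -> np.ndarray:
        """Fix times as POSIX seconds (float)."""
        return self.fixes["t"].astype("int64").to_numpy() / 1e9

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of projected coordinates in meters."""
        return self.fixes[["x", "y"]].to_numpy(float)

    def with_fixes(self, fixes: pd.DataFrame) -> "Trajectory":
        return Trajectory(self.meta, fixes)

    def day_index(self, cfg: PreprocessConfig | None = None) -> np.ndarray:
        """1-based day number of each fix, counted from the first fix's local day."""
        off = pd.Timedelta(hours=(cfg.tz_offset_hours if cfg else 0.0))
        local = self.fixes["t"] + off
        days = local.dt.floor("D")
        return (days - days.iloc[0]).dt.days.to_numpy() + 1


@dataclass(frozen=True)
class Step:
    """Geometry of one move between consecutive fixes.

    ``turning_angle`` is the signed change in heading, wrapped to
    (-pi, pi]; it is NaN for the first step of a trajectory and for
    steps following a zero-displacement step (the previous heading is
    undefined). ``heading`` is NaN for zero-length steps.
    """

    t0: pd.Timestamp
    t1: pd.Timestamp
    x0: float
    y0: float
    x1: float
    y1: float
    length: float
    heading: float
    turning_angle: float

    @property
    def duration_s(self) -> float:
        return (self.t1 - self.t0).total_seconds()


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to the interval (-pi, pi]."""
    w = np.remainder(np.asarray(a, float) + np.pi, 2 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return float(w) if np.isscalar(a) else w


def read_gps_csv(path, column_map: dict[str, str] | None = None) -> list[Trajectory]:
    """Read a GPS fix table into one Trajectory per animal.

    The CSV needs columns animal_id, timestamp (ISO-8601), x, y and
    optionally pdop; ``column_map`` renames nonstandard headers
    (e.g. ``{"id": "animal_id"}``). Rows are sorted by time within
    animal; duplicate (animal, timestamp) rows collapse to the first
    occurrence with a warning. Metadata is filled with resident
    placeholders; join real metadata via :func:`attach_metadata`.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"GPS CSV missing required column(s): {sorted(missing)}")
    try:
        df["t"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # locate the offending row for a useful error
        for i, v in enumerate(df["timestamp"]):
            try:
                pd.to_datetime(v, utc=True)
            except (ValueError, TypeError):
                raise ValueError(f"unparseable timestamp {v!r} at data row {i + 1}") from None
        raise
    if "pdop" not in df.columns:
        df["pdop"] = np.nan
    out: list[Trajectory] = []
    for aid, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("t", kind="mergesort")
        dup = g["t"].duplicated()
        if dup.any():
            logger.warning("animal %s: dropped %d duplicate-timestamp rows", aid, int(dup.sum()))
            g = g[~dup]
        meta = AnimalMeta(animal_id=str(aid), status=RESIDENT)
        out.append(Trajectory(meta, g[_FIX_COLUMNS]))
    return out


def read_metadata_csv(path) -> dict[str, AnimalMeta]:
    """Read animal metadata keyed by animal_id.

    Expected columns: animal_id, status, release_habitat, release_x,
    release_y, capture_x, capture_y. Optional censor windows come from
    a separate table via :func:`read_censor_csv`.
    """
    df = pd.read_csv(path)
    metas = {}
    for _, r in df.iterrows():
        metas[str(r["animal_id"])] = AnimalMeta(
            animal_id=str(r["animal_id"]),
            status=str(r["status"]),
            release_habitat=str(r["release_habitat"]),
            release_xy=(float(r["release_x"]), float(r["release_y"])),
            capture_xy=(float(r["capture_x"]), float(r["capture_y"])),
        )
    return metas


def read_censor_csv(path) -> dict[str, tuple[tuple[pd.Timestamp, pd.Timestamp], ...]]:
    """Read censor windows (animal_id, start, end) keyed by animal."""
    df = pd.read_csv(path)
    out: dict[str, list] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["animal_id"]), []).append(
            (pd.to_datetime(r["start"], utc=True), pd.to_datetime(r["end"], utc=True))
        )
    return {k: tuple(v) for k, v in out.items()}


def attach_metadata(
    trajs: list[Trajectory],
    metas: dict[str, AnimalMeta],
    censors: dict | None = None,
) -> list[Trajectory]:
    """Replace placeholder metadata with the study metadata table."""
    out = []
    for tr in trajs:
        meta = metas.get(tr.meta.animal_id)
        if meta is None:
            logger.warning("no metadata for animal %s; skipped", tr.meta.animal_id)
            continue
        if censors and tr.meta.animal_id in censors:
            meta = replace(meta, censor_windows=censors[tr.meta.animal_id])
        out.append(Trajectory(meta, tr.fixes))
    return out


def filter_pdop(traj: Trajectory, cfg: PreprocessConfig | None = None) -> Trajectory:
    """Drop fixes whose PDOP strictly exceeds the quality cutoff.

    Fixes with missing PDOP are kept: absence of the diagnostic is not
    evidence of a poor fix.
    """
    cfg = cfg or PreprocessConfig()
    pdop = traj.fixes["pdop"]
    keep = pdop.isna() | (pdop <= cfg.pdop_max)
    if not keep.any():
        logger.warning("animal %s: PDOP filter removed every fix", traj.meta.animal_id)
    return traj.with_fixes(traj.fixes[keep])


def resample_to_interval(traj: Trajectory, cfg: PreprocessConfig | None = None) -> Trajectory:
    """Thin fixes to the target cadence by greedy forward selection.

    Keeps the first fix, then repeatedly keeps the fix closest to
    (last kept time + target interval) among those within the
    tolerance band; if none falls in the band (a gap), the next
    available fix re-anchors the schedule. Fixes are only ever
    selected, never interpolated, so output fixes are a subset of the
    input. Already-2-h data pass through unchanged (idempotent).
    """
    cfg = cfg or PreprocessConfig()
    t = traj.t_seconds
    n = len(t)
    if n <= 1:
        return traj
    keep = [0]
    while True:
        target = t[keep[-1]] + cfg.target_interval_s
        lo = target - cfg.interval_tolerance_s
        hi = target + cfg.interval_tolerance_s
        j = np.searchsorted(t, lo, side="left")
        # skip anything at/before the last kept fix
        j = max(j, keep[-1] + 1)
        if j >= n:
            break
        cand = [k for k in range(j, n) if t[k] <= hi]
        if cand:
            best = min(cand, key=lambda k: abs(t[k] - target))
        else:
            best = j  # gap: first fix after the band re-anchors the cadence
        keep.append(best)
    return traj.with_fixes(traj.fixes.iloc[keep])


def compute_steps(traj: Trajectory) -> list[Step]:
    """Step geometry between consecutive fixes.

    n fixes yield n-1 steps. The turning angle of step i is the signed
    difference heading_i - heading_{i-1} wrapped to (-pi, pi]; it is
    undefined (NaN) for the first step and whenever the previous step
    had zero displacement.
    """
    n = len(traj)
    if n < 2:
        return []
    xy = traj.xy
    t = traj.fixes["t"]
    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    headings = np.where(lengths > 0, np.arctan2(d[:, 1], d[:, 0]), np.nan)
    turns = np.full(n - 1, np.nan)
    for i in range(1, n - 1):
        if np.isfinite(headings[i]) and np.isfinite(headings[i - 1]):
            turns[i] = wrap_angle(headings[i] - headings[i - 1])
    return [
        Step(
            t0=t.iloc[i], t1=t.iloc[i + 1],
            x0=xy[i, 0], y0=xy[i, 1], x1=xy[i + 1, 0], y1=xy[i + 1, 1],
            length=float(lengths[i]), heading=float(headings[i]),
            turning_angle=float(turns[i]),
        )
        for i in range(n - 1)
    ]


def detect_homing_return(traj: Trajectory, cfg: PreprocessConfig | None = None) -> pd.Timestamp | None:
    """First time a translocated animal re-enters its old home range.

    Returns the earliest timestamp at which the animal comes within
    ``homing_radius_m`` (default 1.6 km, the radius of an average
    resident home range) of its capture location during the first
    ``homing_window_days`` (default 10) after release, else None.
    Returns outside that window do not count as homing.
    """
    if traj.meta.status != TRANSLOCATED:
        raise ValueError("homing detection applies only to translocated animals")
    cfg = cfg or PreprocessConfig()
    if len(traj) == 0:
        return None
    t = traj.fixes["t"]
    cutoff = t.iloc[0] + pd.Timedelta(days=cfg.homing_window_days)
    cx, cy = traj.meta.capture_xy
    dist = np.hypot(traj.fixes["x"] - cx, traj.fixes["y"] - cy)
    hit = (dist <= cfg.homing_radius_m) & (t <= cutoff)
    if not hit.any():
        return None
    return t[hit].iloc[0]


def apply_censoring(
    traj: Trajectory,
    homing_time: pd.Timestamp | None = None,
    cfg: PreprocessConfig | None = None,
) -> Trajectory:
    """Apply censor windows, homing reclassification, and 90-day truncation.

    Fixes inside any metadata censor window are removed. If
    ``homing_time`` is given (a translocated animal returned home),
    fixes from release up to — but not including — the return are
    dropped and the animal is reclassified as a resident at its
    capture site. Finally the track is truncated ``truncate_days``
    after its (possibly re-based) first retained fix.
    """
    cfg = cfg or PreprocessConfig()
    fixes = traj.fixes
    meta = traj.meta
    keep = np.ones(len(fixes), bool)
    for w0, w1 in meta.censor_windows:
        keep &= ~((fixes["t"] >= w0) & (fixes["t"] <= w1)).to_numpy()
    if homing_time is not None:
        keep &= (fixes["t"] >= homing_time).to_numpy()
        meta = replace(
            meta,
            status=RESIDENT,
            release_xy=tuple(meta.capture_xy),
            censor_windows=meta.censor_windows,
        )
    fixes = fixes[keep]
    if len(fixes):
        end = fixes["t"].iloc[0] + pd.Timedelta(days=cfg.truncate_days)
        fixes = fixes[fixes["t"] <= end]
    return Trajectory(meta, fixes)


def preprocess(traj: Trajectory, cfg: PreprocessConfig | None = None) -> Trajectory:
    """Full cleaning sequence for one animal.

    PDOP filter -> 2-h thinning -> homing detection (translocated
    only) -> censoring and 90-day truncation.
    """
    cfg = cfg or PreprocessConfig()
    out = filter_pdop(traj, cfg)
    out = resample_to_interval(out, cfg)
    homing = None
    if out.meta.status == TRANSLOCATED and len(out):
        homing = detect_homing_return(out, cfg)
        if homing is not None:
            logger.info("animal %s homed at %s; reclassified resident", out.meta.animal_id, homing)
    return apply_censoring(out, homing, cfg)


def write_clean_csv(trajs: list[Trajectory], path) -> None:
    """Write cleaned fixes of a cohort to one CSV."""
    rows = []
    for tr in trajs:
        df = tr.fixes.copy()
        df.insert(0, "animal_id", tr.meta.animal_id)
        df["status"] = tr.meta.status
        rows.append(df)
    pd.concat(rows, ignore_index=True).rename(columns={"t": "timestamp"}).to_csv(path, index=False)
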