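"""Agent-based GPS telemetry simulator with known ground truth.

Generates the full input set the analysis consumes — GPS fix tables
at 2-h cadence with 15-m telemetry error, animal metadata, and a
patchy 3-class landcover raster — from a movement model whose
parameters (habitat selection strengths beta, exploration ->
exploitation switch day T*, movement kernels) are known exactly, so
phase detection and selection estimation can be scored against truth.

Movement is a discrete-choice (SSF-consistent) walk: at each 2-h
move the agent proposes K candidate steps from a phase-specific
parametric kernel (long, directionally persistent steps during
exploration; short steps with attraction to the range center during
exploitation) and picks one with probability proportional to
exp(beta_habitat + attraction). Residents start settled; translocated
agents explore until the programmed switch day and then settle at
their current position. A configurable fraction of translocated
agents instead walk home to their capture site within the first days,
exercising the homing/reclassification rule.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from translocmove.raster import (
    BOTTOMLAND,
    CLASS_CODES,
    EXCLUDED,
    GRASSLAND,
    LandscapeRaster,
    UPLAND_PINE,
)
from translocmove.trajectory import RESIDENT, TRANSLOCATED, AnimalMeta, Trajectory
from translocmove.windows import EXPLOITATION, EXPLORATION

logger = logging.getLogger(__name__)

_T0 = pd.Timestamp("2023-04-01 00:00:00", tz="UTC")


@dataclass(frozen=True)
class PhaseKernel:
    """Parametric proposal kernel for one behavioral phase.

    Step lengths are Gamma(shape, mean/shape); turning angles are
    centered normal with SD ``turn_sd`` (radians), wrapped.
    """

    step_mean_m: float
    step_shape: float
    turn_sd: float

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        lengths = rng.gamma(self.step_shape, self.step_mean_m / self.step_shape, n)
        angles = np.remainder(rng.normal(0.0, self.turn_sd, n) + np.pi, 2 * np.pi) - np.pi
        return lengths, angles


@dataclass(frozen=True)
class SimConfig:
    """Generative ground truth for a synthetic cohort.

    Defaults mirror the study conditions: 14 residents and 14
    translocated animals (8 released to upland pine, 6 to bottomland),
    90-day horizon at 2-h fixes, 15-m telemetry error, a 30-m 3-class
    landscape with ~26% bottomland / 44% upland pine, translocations
    of at least 8 km, and a programmed switch day T* = 25.

    true_beta
        Per-phase habitat selection strengths relative to upland pine.
    attraction_km
        Utility penalty per km of a candidate endpoint's distance to
        the range center, per phase (0 while exploring).
    homecoming_prob
        Fraction of translocated agents that home to their capture
        site within the first days instead of exploring.
    bottomland_ramp_per_week
        Optional linear increase of the exploitation-phase bottomland
        coefficient per week, for time-varying-selection experiments.
    """

    seed: int = 0
    n_resident: int = 14
    n_translocated: int = 14
    n_translocated_upland: int = 8
    horizon_days: int = 90
    fix_interval_s: float = 7200.0
    telemetry_error_sd: float = 15.0
    switch_day: int = 25
    homecoming_prob: float = 0.1
    n_candidates: int = 50
    true_beta: dict = field(default_factory=lambda: {
        EXPLORATION: {BOTTOMLAND: 0.5, GRASSLAND: -0.2},
        EXPLOITATION: {BOTTOMLAND: 1.0, GRASSLAND: -0.5},
    })
    attraction_km: dict = field(default_factory=lambda: {
        EXPLORATION: 0.0,
        EXPLOITATION: 3.0,
    })
    kernels: dict = field(default_factory=lambda: {
        EXPLORATION: PhaseKernel(step_mean_m=500.0, step_shape=1.8, turn_sd=0.4),
        EXPLOITATION: PhaseKernel(step_mean_m=160.0, step_shape=1.8, turn_sd=1.2),
    })
    bottomland_ramp_per_week: float = 0.0
    #: optional per-group overrides of the phase beta tables, keyed by
    #: group (e.g. "translocated_upland_pine") -> phase -> class -> beta;
    #: lets experiments generate selection that differs by status and
    #: release habitat
    group_beta: dict | None = None
    # landscape
    extent_m: float = 30_000.0
    cell_size: float = 30.0
    patch_scale_m: float = 900.0
    class_fractions: dict = field(default_factory=lambda: {
        BOTTOMLAND: 0.26, UPLAND_PINE: 0.44, GRASSLAND: 0.28,
    })
    min_translocation_m: float = 8_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.homecoming_prob <= 1.0:
            raise ValueError("homecoming_prob must be in [0, 1]")
        for k in self.kernels.values():
            if k.step_mean_m <= 0:
                raise ValueError("step scales must be > 0")


def generate_landscape(
    seed: int,
    extent_m: float = 30_000.0,
    patch_scale_m: float = 900.0,
    class_fractions: dict | None = None,
    cell_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandscapeRaster:
    """Patchy categorical landscape from a thresholded Gaussian field.

    Smooth noise (Gaussian filter with SD ``patch_scale_m``) is
    thresholded at the class-fraction quantiles, producing contiguous
    patches whose realized fractions match the targets to within the
    quantile discretization: low field values become bottomland
    (valleys), then upland pine, then grassland; any remainder is the
    excluded class.
    """
    fractions = dict(class_fractions or {BOTTOMLAND: 0.26, UPLAND_PINE: 0.44, GRASSLAND: 0.28})
    total = sum(fractions.values())
    if total > 1.0 + 1e-9:
        raise ValueError("class fractions must sum to <= 1")
    if patch_scale_m < 2 * cell_size:
        raise ValueError("patch_scale_m must be >= 2 cells (speckle, not patches)")
    n = int(round(extent_m / cell_size))
    rng = np.random.default_rng(seed)
    fld = gaussian_filter(rng.standard_normal((n, n)), sigma=patch_scale_m / cell_size)
    order = [BOTTOMLAND, UPLAND_PINE, GRASSLAND]
    qs = np.cumsum([fractions.get(c, 0.0) for c in order])
    cuts = np.quantile(fld, np.clip(qs, 0, 1))
    grid = np.full((n, n), CLASS_CODES[EXCLUDED], dtype=np.int16)
    prev = -np.inf
    for cls, cut in zip(order, cuts):
        grid[(fld > prev) & (fld <= cut)] = CLASS_CODES[cls]
        prev = cut
    return LandscapeRaster(origin=origin, cell_size=cell_size, grid=grid)


def _random_cell_of_class(
    landscape: LandscapeRaster, cls: str, rng: np.random.Generator,
    near: tuple[float, float] | None = None, min_dist: float = 0.0,
    margin_m: float = 2000.0,
) -> tuple[float, float]:
    """Center of a random cell of the given class, away from the border."""
    code = CLASS_CODES[cls]
    rows, cols = np.nonzero(landscape.grid == code)
    xs, ys = landscape.cell_centers()
    x = xs[cols]
    y = ys[rows]
    xmin, ymin, xmax, ymax = landscape.extent
    ok = (x > xmin + margin_m) & (x < xmax - margin_m) & (y > ymin + margin_m) & (y < ymax - margin_m)
    if near is not None:
        ok &= np.hypot(x - near[0], y - near[1]) >= min_dist
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        raise ValueError(f"no eligible {cls} cell (min_dist={min_dist})")
    j = idx[rng.integers(0, len(idx))]
    return float(x[j]), float(y[j])


def simulate_agent(
    landscape: LandscapeRaster,
    cfg: SimConfig,
    role: str,
    start_xy: tuple[float, float],
    rng: np.random.Generator,
    capture_xy: tuple[float, float] | None = None,
    homecomer: bool = False,
    beta_override: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Simulate one agent's true path at 2-h cadence.

    Returns ``(true_xy, info)`` where ``true_xy`` is the (n_fixes, 2)
    noise-free path (n_fixes = horizon_days * fixes/day + 1) and
    ``info`` records the switch step and homing arrival, if any.
    Residents start settled at ``start_xy``; translocated agents
    explore until the start of day ``switch_day + 1`` — the programmed
    crossing day T* = switch_day is their last exploration day — then
    settle where they stand. A homecomer instead walks toward
    ``capture_xy`` and settles there once within 1.6 km.
    """
    if landscape.class_at(*start_xy) in (None, EXCLUDED):
        raise ValueError("start position must be on a non-excluded cell")
    fixes_per_day = int(round(86400.0 / cfg.fix_interval_s))
    n_steps = cfg.horizon_days * fixes_per_day
    switch_step = cfg.switch_day * fixes_per_day  # first move of day T*+1
    pos = np.array(start_xy, float)
    heading = rng.uniform(-np.pi, np.pi)
    path = np.empty((n_steps + 1, 2))
    path[0] = pos
    if role == RESIDENT:
        phase = EXPLOITATION
        center = np.array(start_xy, float)
    else:
        phase = EXPLORATION
        center = None
    arrived_home = None
    homing_target = np.array(capture_xy, float) if homecomer else None
    for i in range(n_steps):
        day = i // fixes_per_day + 1
        week = (day - 1) // 7 + 1
        if role == TRANSLOCATED and not homecomer and phase == EXPLORATION and i >= switch_step:
            phase = EXPLOITATION
            center = pos.copy()
        if homecomer and arrived_home is None:
            d_home = float(np.hypot(*(homing_target - pos)))
            if d_home <= 1600.0:
                arrived_home = i
                phase = EXPLOITATION
                center = pos.copy()
            else:
                # directed walk home: long steps aimed at the capture site
                step = min(600.0 + rng.gamma(2.0, 100.0), d_home)
                ang = math.atan2(*(homing_target - pos)[::-1]) + rng.normal(0, 0.2)
                cand = pos + step * np.array([math.cos(ang), math.sin(ang)])
                if landscape.class_at(*cand) not in (None, EXCLUDED):
                    pos = cand
                    heading = ang
                path[i + 1] = pos
                continue
        kern = cfg.kernels[phase]
        beta_codes = _beta_by_code(cfg, phase, week, beta_override)
        lengths, turns = kern.sample(rng, cfg.n_candidates)
        angs = heading + turns
        cand = pos + np.column_stack([lengths * np.cos(angs), lengths * np.sin(angs)])
        codes = landscape.code_at(cand[:, 0], cand[:, 1])
        util = np.array([beta_codes.get(int(c), -np.inf) for c in codes])
        if center is not None:
            dist_km = np.hypot(cand[:, 0] - center[0], cand[:, 1] - center[1]) / 1000.0
            util = util - cfg.attraction_km[phase] * dist_km
        w = np.exp(util - util.max()) if np.isfinite(util).any() else None
        if w is None or w.sum() <= 0:
            path[i + 1] = pos  # boxed in: stay put
            continue
        j = rng.choice(cfg.n_candidates, p=w / w.sum())
        pos = cand[j]
        if lengths[j] > 0:
            heading = float(angs[j])
        path[i + 1] = pos
    return path, {
        "switch_step": None if role == RESIDENT or homecomer else switch_step,
        "arrived_home_step": arrived_home,
        "range_center": None if center is None else [float(center[0]), float(center[1])],
    }


def _beta_by_code(
    cfg: SimConfig, phase: str, week: int, override: dict | None = None
) -> dict[int, float]:
    table = override if override is not None else cfg.true_beta
    beta = dict(table[phase])
    if phase == EXPLOITATION and cfg.bottomland_ramp_per_week:
        beta[BOTTOMLAND] = beta.get(BOTTOMLAND, 0.0) + cfg.bottomland_ramp_per_week * (week - 1)
    out = {CLASS_CODES[UPLAND_PINE]: 0.0}
    for cls, b in beta.items():
        out[CLASS_CODES[cls]] = float(b)
    out[CLASS_CODES[EXCLUDED]] = -np.inf
    return out


@dataclass
class Cohort:
    """A simulated cohort: observed trajectories, landscape, truth."""

    trajectories: list[Trajectory]
    landscape: LandscapeRaster
    truth: dict
    true_paths: dict[str, np.ndarray]

    def write(self, outdir) -> dict[str, Path]:
        """Emit the pipeline's input files (GPS CSV, metadata CSV,
        ESRI ASCII raster, ground-truth JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gps": outdir / "gps.csv",
            "metadata": outdir / "metadata.csv",
            "landcover": outdir / "landcover.asc",
            "truth": outdir / "truth.json",
        }
        rows = []
        for tr in self.trajectories:
            df = tr.fixes.copy()
            df.insert(0, "animal_id", tr.meta.animal_id)
            rows.append(df)
        gps = pd.concat(rows, ignore_index=True).rename(columns={"t": "timestamp"})
        gps["timestamp"] = gps["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
        gps.to_csv(paths["gps"], index=False, float_format="%.3f")
        meta_rows = [
            {
                "animal_id": tr.meta.animal_id,
                "status": tr.meta.status,
                "release_habitat": tr.meta.release_habitat,
                "release_x": tr.meta.release_xy[0], "release_y": tr.meta.release_xy[1],
                "capture_x": tr.meta.capture_xy[0], "capture_y": tr.meta.capture_xy[1],
            }
            for tr in self.trajectories
        ]
        pd.DataFrame(meta_rows).to_csv(paths["metadata"], index=False, float_format="%.3f")
        self.landscape.write_ascii(paths["landcover"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)
        return paths


def simulate_cohort(cfg: SimConfig | None = None) -> Cohort:
    """Simulate a full study cohort on a fresh landscape.

    Residents start on bottomland or upland pine cells (split roughly
    as in the study, 10:4 bottomland:upland at the default sizes);
    translocated agents are captured in one habitat and released in
    the other at least ``min_translocation_m`` away. Observed fixes
    are the true path plus isotropic Gaussian telemetry noise, with
    plausible PDOP values (a few percent above the quality cutoff).
    """
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    land_seed, agents_seed = root.spawn(2)
    landscape = generate_landscape(
        int(land_seed.generate_state(1)[0] % (2**31)),
        cfg.extent_m, cfg.patch_scale_m, cfg.class_fractions, cfg.cell_size,
    )
    fixes_per_day = int(round(86400.0 / cfg.fix_interval_s))
    times = _T0 + pd.to_timedelta(
        np.arange(cfg.horizon_days * fixes_per_day + 1) * cfg.fix_interval_s, unit="s"
    )
    trajs: list[Trajectory] = []
    true_paths: dict[str, np.ndarray] = {}
    truth_agents = {}
    agent_rngs = agents_seed.spawn(cfg.n_resident + cfg.n_translocated)
    n_res_upland = max(1, round(cfg.n_resident * 4 / 14)) if cfg.n_resident > 1 else 1
    for i in range(cfg.n_resident + cfg.n_translocated):
        rng = np.random.default_rng(agent_rngs[i])
        if i < cfg.n_resident:
            role = RESIDENT
            habitat = UPLAND_PINE if i < n_res_upland else BOTTOMLAND
            start = _random_cell_of_class(landscape, habitat, rng)
            capture = release = start
            homecomer = False
            release_habitat = habitat
        else:
            role = TRANSLOCATED
            j = i - cfg.n_resident
            release_habitat = UPLAND_PINE if j < cfg.n_translocated_upland else BOTTOMLAND
            capture_habitat = BOTTOMLAND if release_habitat == UPLAND_PINE else UPLAND_PINE
            capture = _random_cell_of_class(landscape, capture_habitat, rng)
            release = _random_cell_of_class(
                landscape, release_habitat, rng, near=capture,
                min_dist=cfg.min_translocation_m,
            )
            start = release
            homecomer = bool(rng.random() < cfg.homecoming_prob)
        group = f"{role}_{release_habitat}"
        override = cfg.group_beta.get(group) if cfg.group_beta else None
        path, info = simulate_agent(
            landscape, cfg, role, start, rng,
            capture_xy=capture, homecomer=homecomer, beta_override=override,
        )
        noise = rng.normal(0.0, cfg.telemetry_error_sd, path.shape)
        obs = path + noise
        pdop = np.round(rng.gamma(3.0, 1.3, len(obs)), 1)  # ~3-4% exceed 9
        aid = f"{'R' if role == RESIDENT else 'T'}{i:03d}"
        meta = AnimalMeta(
            animal_id=aid, status=role, release_habitat=release_habitat,
            release_xy=release, capture_xy=capture,
        )
        fixes = pd.DataFrame({"t": times, "x": obs[:, 0], "y": obs[:, 1], "pdop": pdop})
        trajs.append(Trajectory(meta, fixes))
        true_paths[aid] = path
        truth_agents[aid] = {
            "role": role, "release_habitat": release_habitat,
            "homecomer": homecomer, **info,
        }
    truth = {
        "seed": cfg.seed,
        "switch_day": cfg.switch_day,
        "true_beta": {ph: dict(b) for ph, b in cfg.true_beta.items()},
        "bottomland_ramp_per_week": cfg.bottomland_ramp_per_week,
        "telemetry_error_sd": cfg.telemetry_error_sd,
        "agents": truth_agents,
        "class_fractions_realized": landscape.class_fractions(),
    }
    return Cohort(trajs, landscape, truth, true_paths)
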