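"""Brownian bridge and dynamic Brownian bridge movement models.

The Brownian bridge movement model treats the animal's position
between two known fixes as a Brownian bridge: conditioned on both
endpoints, the position at interpolation fraction ``alpha`` along the
bridge is bivariate normal with

    mean     = a + alpha * (b - a)
    variance = T*alpha*(1-alpha)*sigma_m2
               + (1-alpha)^2 * delta^2 + alpha^2 * delta^2

per coordinate (isotropic), where ``sigma_m2`` is the Brownian motion
variance (m^2/s), ``T`` the bridge duration and ``delta`` the
telemetry error SD. The *dynamic* variant lets sigma_m2 vary along
the path: a sliding window is moved along the track, a structural
break in sigma_m2 is allowed at candidate positions at least
``margin`` fixes from the window edges, the break / no-break decision
is made by BIC, and per-step estimates are averaged across windows.

The utilization distribution (UD) integrates the bridge densities
over time onto a grid; 50%/95% isopleths of the UD give the core and
range areas used throughout the moving-window analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from translocmove.raster import CODE_CLASSES, LandscapeRaster
from translocmove.trajectory import Trajectory

logger = logging.getLogger(__name__)

M2_PER_HA = 1e4


@dataclass(frozen=True)
class DBBMMConfig:
    """dBBMM fitting and rasterization parameters.

    window_size, margin
        Sliding-window extent in fixes (11 fixes = 22 h at 2-h
        cadence) and the margin kept free of breakpoints at each
        window edge (5 fixes).
    telemetry_error_sd
        Isotropic GPS error SD delta in meters (15 m, vendor estimate).
    cell_size
        UD grid resolution in meters (30 m, NLCD-like).
    grid_pad
        Grid padding as a multiple of the largest positional SD.
    substeps_per_bridge
        Number of interpolation fractions per bridge when integrating
        the UD.
    """

    window_size: int = 11
    margin: int = 5
    telemetry_error_sd: float = 15.0
    cell_size: float = 30.0
    grid_pad: float = 3.0
    substeps_per_bridge: int = 10

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0 or self.window_size <= 2 * self.margin:
            raise ValueError("window_size must be odd and > 2*margin")
        if self.telemetry_error_sd <= 0 or self.cell_size <= 0:
            raise ValueError("telemetry_error_sd and cell_size must be > 0")


@dataclass
class VarianceProfile:
    """Per-step Brownian motion variance along one track.

    ``sigma_m2[i]`` applies to the bridge between fixes i and i+1
    (m^2/s). ``breaks`` records, for each window start index, the
    chosen breakpoint (global fix index) or None when the single-
    variance model won the BIC comparison.
    """

    sigma_m2: np.ndarray
    breaks: dict[int, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sigma_m2 = np.asarray(self.sigma_m2, float)
        if (self.sigma_m2 < 0).any():
            raise ValueError("sigma_m2 must be >= 0")

    @property
    def break_fraction(self) -> float:
        """Fraction of windows in which the break model was selected."""
        if not self.breaks:
            return 0.0
        return sum(b is not None for b in self.breaks.values()) / len(self.breaks)


@dataclass
class UDGrid:
    """Gridded utilization distribution (probability mass per cell).

    ``values[iy, ix]`` is the mass of the cell whose lower-left corner
    is ``origin + (ix, iy) * cell_size`` (row 0 at the *bottom*;
    note this is flipped relative to ESRI ASCII row order).
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if (self.values < 0).any():
            raise ValueError("UD masses must be >= 0")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def write_ascii(self, path) -> None:
        """Export as ESRI ASCII (float mass per cell, top row first)."""
        ny, nx = self.values.shape
        with open(path, "w") as fh:
            fh.write(
                f"ncols {nx}\nnrows {ny}\n"
                f"xllcorner {self.origin[0]:.6f}\nyllcorner {self.origin[1]:.6f}\n"
                f"cellsize {self.cell_size:.6f}\nNODATA_value -9999\n"
            )
            np.savetxt(fh, self.values[::-1], fmt="%.8e")


@dataclass(frozen=True)
class IsoplethSpec:
    """UD probability levels at which to report areas (0.50 = core, 0.95 = range)."""

    levels: tuple[float, ...] = (0.50, 0.95)

    def __post_init__(self) -> None:
        for lv in self.levels:
            if not 0.0 < lv < 1.0:
                raise ValueError(f"isopleth level must be in (0,1), got {lv}")


def bridge_moments(a_xy, b_xy, T: float, alpha: float, sigma_m2: float, delta: float):
    """Mean and per-coordinate variance of a Brownian bridge position.

    Position at fraction ``alpha`` of a bridge of duration ``T``
    seconds between observed endpoints ``a_xy`` and ``b_xy``, with
    Brownian motion variance ``sigma_m2`` (m^2/s) and telemetry error
    SD ``delta`` on both endpoints. Returns ``(mean_xy, variance)``
    with the variance isotropic (same for x and y).
    """
    if T <= 0:
        raise ValueError("bridge duration T must be > 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    a = np.asarray(a_xy, float)
    b = np.asarray(b_xy, float)
    mean = a + alpha * (b - a)
    var = T * alpha * (1.0 - alpha) * sigma_m2 + (1.0 - alpha) ** 2 * delta**2 + alpha**2 * delta**2
    return mean, float(var)


def _loo_terms(t: np.ndarray, xy: np.ndarray, delta: float):
    """Precompute leave-one-out bridge likelihood terms.

    For each odd interior fix i, the observed position is scored
    against the bridge between fixes i-1 and i+1. The per-coordinate
    predictive variance is linear in sigma_m2:  v_i = a_i*sigma + c_i.
    Returns (a, c, r2) with r2 the squared residual from the bridge
    mean, so the bivariate log-likelihood is
    sum_i [ -log(2*pi*v_i) - r2_i / (2*v_i) ].
    """
    n = len(t)
    idx = np.arange(1, n - 1, 2)
    if len(idx) == 0:
        idx = np.array([1]) if n >= 3 else np.array([], dtype=int)
    T = t[idx + 1] - t[idx - 1]
    alpha = (t[idx] - t[idx - 1]) / T
    mean = xy[idx - 1] + alpha[:, None] * (xy[idx + 1] - xy[idx - 1])
    r2 = ((xy[idx] - mean) ** 2).sum(axis=1)
    a = T * alpha * (1.0 - alpha)
    c = ((1.0 - alpha) ** 2 + alpha**2) * delta**2
    return a, c, r2


def _loo_loglik(sigma_m2: float, a, c, r2) -> float:
    v = a * sigma_m2 + c
    return float(np.sum(-np.log(2.0 * np.pi * v) - r2 / (2.0 * v)))


def estimate_bm_variance(t: np.ndarray, xy: np.ndarray, delta: float) -> float:
    """Leave-one-out MLE of the Brownian motion variance (m^2/s).

    Maximizes the product over odd interior fixes of the bivariate
    normal density of each observed fix under the bridge between its
    temporal neighbours. 1-D bounded search on log sigma_m2; a track
    with no more apparent movement than telemetry error collapses to
    the lower bound 0.

    Parameters are raw arrays (times in seconds, positions in meters)
    so window sub-fits need no Trajectory slicing overhead.
    """
    t = np.asarray(t, float)
    xy = np.asarray(xy, float)
    if len(t) < 3:
        raise ValueError("need >= 3 fixes to estimate sigma_m2")
    a, c, r2 = _loo_terms(t, xy, delta)
    nll = lambda logs: -_loo_loglik(math.exp(logs), a, c, r2)
    res = minimize_scalar(nll, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    best = math.exp(res.x)
    # compare against the sigma = 0 boundary
    if _loo_loglik(0.0, a, c, r2) >= -res.fun:
        return 0.0
    return float(best)


def _fit_terms(a, c, r2):
    """(sigma_hat, loglik_at_hat) maximizing the precomputed LOO terms."""
    nll = lambda logs: -_loo_loglik(math.exp(logs), a, c, r2)
    res = minimize_scalar(nll, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    s = math.exp(res.x)
    ll = -res.fun
    ll0 = _loo_loglik(0.0, a, c, r2)
    if ll0 >= ll:
        s, ll = 0.0, ll0
    return s, ll


def dynamic_variance_profile(traj: Trajectory, cfg: DBBMMConfig | None = None) -> VarianceProfile:
    """Sliding-window breakpoint estimation of sigma_m2 along a track.

    For every window of ``window_size`` consecutive fixes the single-
    variance fit is compared by BIC against fits with one structural
    break at each candidate position at least ``margin`` fixes from
    both edges (k = 1 vs 2 variance parameters). Both models are
    scored on the identical leave-one-out terms (odd interior fixes of
    the window); under a break at fix b, a scored fix belongs to the
    left segment iff its index is < b. Each window contributes its
    (break-resolved) estimate to every step it contains — the margin
    only constrains where breaks may occur — and per-step estimates
    are the mean over all containing windows.

    Tracks shorter than the window fall back to one static sigma_m2.
    """
    cfg = cfg or DBBMMConfig()
    t = traj.t_seconds
    xy = traj.xy
    n = len(t)
    n_steps = n - 1
    if n_steps < 1:
        raise ValueError("need >= 2 fixes")
    delta = cfg.telemetry_error_sd
    W, m = cfg.window_size, cfg.margin

    if n < W:
        logger.info("track of %d fixes < window_size %d: static sigma_m2", n, W)
        if n >= 3:
            s = estimate_bm_variance(t, xy, delta)
        else:
            s = 0.0
        return VarianceProfile(np.full(n_steps, s))

    sums = np.zeros(n_steps)
    counts = np.zeros(n_steps, int)
    breaks: dict[int, int | None] = {}
    scored_local = np.arange(1, W - 1, 2)
    for i in range(n - W + 1):
        tw, xw = t[i : i + W], xy[i : i + W]
        a, c, r2 = _loo_terms(tw, xw, delta)
        ns = len(a)
        n_obs = 2 * ns  # each scored fix is a bivariate (2-scalar) observation
        s_full, ll_full = _fit_terms(a, c, r2)
        bic_full = -2.0 * ll_full + 1.0 * math.log(max(n_obs, 1))
        best = (bic_full, None, s_full, s_full)
        for b in range(m, W - m):  # local candidate breakpoints
            left = scored_local < b
            if not left.any() or left.all():
                continue
            s_l, ll_l = _fit_terms(a[left], c[left], r2[left])
            s_r, ll_r = _fit_terms(a[~left], c[~left], r2[~left])
            bic_b = -2.0 * (ll_l + ll_r) + 2.0 * math.log(max(n_obs, 1))
            if bic_b < best[0]:
                best = (bic_b, b, s_l, s_r)
        _, b_sel, s_l, s_r = best
        breaks[i] = None if b_sel is None else i + b_sel
        for j in range(W - 1):  # every step the window contains
            sig = s_l if (b_sel is None or j < b_sel) else s_r
            sums[i + j] += sig
            counts[i + j] += 1

    sigma = np.full(n_steps, np.nan)
    covered = counts > 0
    sigma[covered] = sums[covered] / counts[covered]
    if not covered.all():
        cov_idx = np.flatnonzero(covered)
        if len(cov_idx) == 0:
            sigma[:] = estimate_bm_variance(t, xy, delta)
        else:
            miss = np.flatnonzero(~covered)
            nearest = cov_idx[np.argmin(np.abs(miss[:, None] - cov_idx[None, :]), axis=1)]
            sigma[miss] = sigma[nearest]
    return VarianceProfile(sigma, breaks)


def _grid_for(xy: np.ndarray, max_sd: float, cfg: DBBMMConfig):
    """Grid origin and cell-center axes covering the track plus padding."""
    pad = cfg.grid_pad * max_sd
    xmin, ymin = xy.min(axis=0) - pad
    xmax, ymax = xy.max(axis=0) + pad
    cs = cfg.cell_size
    nx = max(int(math.ceil((xmax - xmin) / cs)), 10)
    ny = max(int(math.ceil((ymax - ymin) / cs)), 10)
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    x0 = cx - nx * cs / 2.0
    y0 = cy - ny * cs / 2.0
    xs = x0 + (np.arange(nx) + 0.5) * cs
    ys = y0 + (np.arange(ny) + 0.5) * cs
    return (x0, y0), xs, ys


def compute_ud(
    traj: Trajectory,
    profile: VarianceProfile | None = None,
    cfg: DBBMMConfig | None = None,
    step_slice: slice | None = None,
) -> UDGrid:
    """Integrate bridge densities into a gridded utilization distribution.

    Each inter-fix bridge is discretized at ``substeps_per_bridge``
    interpolation fractions; each position's isotropic bivariate
    normal density (from :func:`bridge_moments`) is evaluated at cell
    centers, weighted by the bridge duration, accumulated, and the
    grid normalized to total mass 1. ``step_slice`` restricts the
    integration to a contiguous run of steps (used by the moving-
    window analysis) while keeping the full profile's variances.

    A single-fix track yields the telemetry-error Gaussian around the
    point.
    """
    cfg = cfg or DBBMMConfig()
    t = traj.t_seconds
    xy = traj.xy
    delta = cfg.telemetry_error_sd
    n = len(t)
    if n == 0:
        raise ValueError("empty trajectory")
    if n == 1:
        (x0y0), xs, ys = _grid_for(xy, delta, cfg)
        gx = np.exp(-((xs - xy[0, 0]) ** 2) / (2 * delta**2))
        gy = np.exp(-((ys - xy[0, 1]) ** 2) / (2 * delta**2))
        vals = np.outer(gy, gx)
        return UDGrid(x0y0, cfg.cell_size, vals / vals.sum())

    if profile is None:
        profile = dynamic_variance_profile(traj, cfg)
    sig = profile.sigma_m2
    if len(sig) != n - 1:
        raise ValueError("profile length must equal step count")

    sl = step_slice if step_slice is not None else slice(0, n - 1)
    idx = np.arange(n - 1)[sl]
    if len(idx) == 0:
        raise ValueError("step_slice selects no steps")
    sub_xy = xy[idx[0] : idx[-1] + 2]

    T_all = t[idx + 1] - t[idx]
    mid_var = T_all / 4.0 * sig[idx] + delta**2
    max_sd = math.sqrt(max(float(mid_var.max()), delta**2))
    origin, xs, ys = _grid_for(sub_xy, max_sd, cfg)

    K = cfg.substeps_per_bridge
    alphas = (np.arange(K) + 0.5) / K
    vals = np.zeros((len(ys), len(xs)))
    for i in idx:
        a, b = xy[i], xy[i + 1]
        T = t[i + 1] - t[i]
        w = T / K
        for al in alphas:
            mean, v = bridge_moments(a, b, T, float(al), float(sig[i]), delta)
            gx = np.exp(-((xs - mean[0]) ** 2) / (2 * v))
            gy = np.exp(-((ys - mean[1]) ** 2) / (2 * v))
            vals += (w / (2 * np.pi * v)) * np.outer(gy, gx)
    total = vals.sum()
    if total <= 0:
        raise FloatingPointError("UD mass vanished; grid does not cover the track")
    return UDGrid(origin, cfg.cell_size, vals / total)


def isopleth_area(ud: UDGrid, spec: IsoplethSpec | None = None) -> dict[float, float]:
    """Isopleth areas (hectares) of a normalized UD.

    The level-p isopleth is the smallest set of cells whose cumulative
    mass reaches p, taking cells in decreasing mass order (ties broken
    by row-major index, deterministically). Area = cell count x cell
    area.
    """
    spec = spec or IsoplethSpec()
    flat = ud.values.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    cell_ha = ud.cell_size**2 / M2_PER_HA
    out = {}
    for lv in spec.levels:
        k = int(np.searchsorted(csum, lv * ud.total)) + 1
        k = min(k, len(flat))
        out[lv] = k * cell_ha
    return out


def isopleth_polygons(ud: UDGrid, spec: IsoplethSpec | None = None) -> dict:
    """Isopleth outlines as a GeoJSON FeatureCollection.

    Each feature is the union of the cells selected by
    :func:`isopleth_area` at one level (a Polygon or MultiPolygon in
    the UD's projected CRS) with ``level`` and ``area_ha``
    properties.
    """
    from shapely import unary_union
    from shapely.geometry import box, mapping

    spec = spec or IsoplethSpec()
    flat = ud.values.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    ny, nx = ud.values.shape
    cs = ud.cell_size
    x0, y0 = ud.origin
    features = []
    for lv in sorted(spec.levels):
        k = min(int(np.searchsorted(csum, lv * ud.total)) + 1, len(flat))
        iy, ix = np.unravel_index(order[:k], ud.values.shape)
        cells = [
            box(x0 + i * cs, y0 + j * cs, x0 + (i + 1) * cs, y0 + (j + 1) * cs)
            for j, i in zip(iy, ix)
        ]
        features.append({
            "type": "Feature",
            "geometry": mapping(unary_union(cells)),
            "properties": {"level": lv, "area_ha": k * cs**2 / M2_PER_HA},
        })
    return {"type": "FeatureCollection", "features": features}


def kde_home_range(
    traj: Trajectory,
    level: float = 0.95,
    cell_size: float | None = None,
) -> float:
    """Kernel-density home-range area (km^2) at the given isopleth.

    Bivariate normal kernel with the reference bandwidth
    h = sigma_hat * n^(-1/6), sigma_hat = sqrt((var_x + var_y)/2),
    evaluated on a grid and measured with the same smallest-cell-set
    isopleth rule as the dBBMM UD.
    """
    n = len(traj)
    if n < 30:
        raise ValueError(f"kde_home_range needs >= 30 fixes, got {n}")
    xy = traj.xy
    var = xy.var(axis=0, ddof=1)
    sigma_hat = math.sqrt((var[0] + var[1]) / 2.0)
    h = max(sigma_hat * n ** (-1.0 / 6.0), 1e-6)
    cs = cell_size if cell_size is not None else max(h / 3.0, 1e-6)
    pad = 4.0 * (sigma_hat + h)
    xmin, ymin = xy.min(axis=0) - pad
    xmax, ymax = xy.max(axis=0) + pad
    nx = max(int(math.ceil((xmax - xmin) / cs)), 10)
    ny = max(int(math.ceil((ymax - ymin) / cs)), 10)
    xs = xmin + (np.arange(nx) + 0.5) * cs
    ys = ymin + (np.arange(ny) + 0.5) * cs
    vals = np.zeros((ny, nx))
    for px, py in xy:
        gx = np.exp(-((xs - px) ** 2) / (2 * h**2))
        gy = np.exp(-((ys - py) ** 2) / (2 * h**2))
        vals += np.outer(gy, gx)
    ud = UDGrid((xmin, ymin), cs, vals / vals.sum())
    area_ha = isopleth_area(ud, IsoplethSpec((level,)))[level]
    return area_ha * M2_PER_HA / 1e6


def release_site_composition(
    release_xy: tuple[float, float],
    landcover: LandscapeRaster,
    mean_hr_area_km2: float = 8.3,
) -> dict[str, float]:
    """Habitat composition inside a home-range-sized buffer.

    The release site is buffered by a disc whose area equals the mean
    resident home range (8.3 km^2 -> radius ~1.63 km); fractions of
    raster cells whose centers fall inside are reported by class and
    sum to 1. Raises if the buffer is not fully covered by the raster.
    """
    r = math.sqrt(mean_hr_area_km2 * 1e6 / math.pi)
    x0, y0 = release_xy
    xmin, ymin, xmax, ymax = landcover.extent
    if x0 - r < xmin or x0 + r > xmax or y0 - r < ymin or y0 + r > ymax:
        dx = max(xmin - (x0 - r), (x0 + r) - xmax, 0.0)
        dy = max(ymin - (y0 - r), (y0 + r) - ymax, 0.0)
        frac = min(1.0, (dx + dy) / (2 * r))
        raise ValueError(
            f"buffer of radius {r:.0f} m exits the raster extent "
            f"(~{frac:.0%} of its bounding box uncovered)"
        )
    xs, ys = landcover.cell_centers()
    XX, YY = np.meshgrid(xs, ys)
    inside = (XX - x0) ** 2 + (YY - y0) ** 2 <= r**2
    codes = landcover.grid[inside]
    total = codes.size
    out = {}
    for code in np.unique(codes):
        name = CODE_CLASSES.get(int(code), str(int(code)))
        out[name] = float((codes == code).sum()) / total
    return out
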