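"""Phase-stratified step-selection functions.

Each observed ("used") step is paired with random alternative steps
drawn from empirical step-length and turning-angle distributions,
stratified by establishment phase (exploration vs. exploitation) and
release habitat for translocated animals, with a single pooled
distribution for residents; the focal animal's own steps are excluded
from the kernel applied to it. Habitat is recorded at step endpoints
from the landcover raster, and used-vs-available contrasts are fit by
conditional logistic regression (one conditional likelihood term per
choice set), with standard errors clustered by animal. A four-model
AIC comparison tests whether selection differs by translocation
status and release habitat, a diel post-hoc adds habitat x
day/night interactions to the top model, and weekly nocturnal fits
trace selection for bottomland habitat through time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from translocmove.raster import BOTTOMLAND, GRASSLAND, LandscapeRaster, UPLAND_PINE
from translocmove.trajectory import (
    RESIDENT,
    TRANSLOCATED,
    Trajectory,
    compute_steps,
)
from translocmove.windows import EXPLORATION, PhaseAssignment

logger = logging.getLogger(__name__)

DIURNAL = "diurnal"
NOCTURNAL = "nocturnal"

MODEL_NAMES = (
    "habitat",
    "habitat_x_status",
    "habitat_x_release",
    "habitat_x_status_plus_release",
)


@dataclass(frozen=True)
class SSFConfig:
    """Step-selection sampling and diel-classification parameters."""

    n_random_steps: int = 20
    reference_habitat: str = UPLAND_PINE
    diel_mode: str = "solar"  # "solar" | "fixed"
    fixed_day_window: tuple[float, float] = (6.0, 18.0)  # clock hours
    site_latlon: tuple[float, float] | None = (33.3, -81.7)
    min_kernel_steps: int = 30

    def __post_init__(self) -> None:
        if self.n_random_steps < 1:
            raise ValueError("n_random_steps must be >= 1")
        if self.diel_mode not in ("solar", "fixed"):
            raise ValueError("diel_mode must be solar|fixed")


@dataclass
class EmpiricalMoveKernel:
    """Empirical movement distributions for one stratum, minus one animal.

    Step lengths (m) and turning angles (radians, (-pi, pi]) are kept
    as separate samples and resampled independently, the standard SSF
    practice.
    """

    stratum: str
    excluded_animal: str
    lengths: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, float)
        self.angles = np.asarray(self.angles, float)
        if len(self.lengths) == 0 or len(self.angles) == 0:
            raise ValueError(f"empty kernel for stratum {self.stratum!r}")


def solar_altitude_deg(t: pd.Timestamp, lat: float, lon: float) -> float:
    """Sun altitude above the horizon (degrees) at a UTC time and site.

    NOAA's low-precision solar position algorithm: fractional-year
    Fourier series for declination and the equation of time, then the
    hour angle from true solar time. Adequate to a fraction of a
    degree, far below the day/night classification scale.
    """
    t = pd.Timestamp(t)
    if t.tzinfo is None:
        t = t.tz_localize("UTC")
    t = t.tz_convert("UTC")
    doy = t.dayofyear
    hour = t.hour + t.minute / 60.0 + t.second / 3600.0
    g = 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)
    decl = (
        0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g)
    )
    eqtime = 229.18 * (
        0.000075 + 0.001868 * math.cos(g) - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g) - 0.040849 * math.sin(2 * g)
    )
    tst = hour * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes
    ha = math.radians(tst / 4.0 - 180.0)
    latr = math.radians(lat)
    cos_zen = math.sin(latr) * math.sin(decl) + math.cos(latr) * math.cos(decl) * math.cos(ha)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    return 90.0 - math.degrees(math.acos(cos_zen))


def classify_diel(t: pd.Timestamp, cfg: SSFConfig | None = None) -> str:
    """Diurnal/nocturnal label for a fix time.

    Solar mode: diurnal iff the sun is strictly above the horizon at
    the study site. Fixed mode: diurnal iff the clock hour falls in
    ``fixed_day_window`` (half-open [start, end)).
    """
    cfg = cfg or SSFConfig()
    if cfg.diel_mode == "solar":
        if cfg.site_latlon is None:
            raise ValueError("solar diel mode requires site_latlon")
        lat, lon = cfg.site_latlon
        return DIURNAL if solar_altitude_deg(t, lat, lon) > 0.0 else NOCTURNAL
    t = pd.Timestamp(t)
    h = t.hour + t.minute / 60.0 + t.second / 3600.0
    lo, hi = cfg.fixed_day_window
    return DIURNAL if lo <= h < hi else NOCTURNAL


def _step_table(traj: Trajectory) -> pd.DataFrame:
    """Per-step records for one animal, with day and previous heading."""
    steps = compute_steps(traj)
    days = traj.day_index()
    rows = []
    for i, s in enumerate(steps):
        prev_heading = steps[i - 1].heading if i >= 1 else np.nan
        rows.append({
            "animal_id": traj.meta.animal_id,
            "status": traj.meta.status,
            "release_habitat": traj.meta.release_habitat,
            "step_index": i,
            "t1": s.t1,
            "day": int(days[i + 1]),
            "x0": s.x0, "y0": s.y0, "x1": s.x1, "y1": s.y1,
            "length": s.length,
            "turning_angle": s.turning_angle,
            "prev_heading": prev_heading,
        })
    return pd.DataFrame(rows)


def _kernel_stratum(status: str, release_habitat: str, phase: str | None) -> str:
    if status == RESIDENT:
        return RESIDENT
    return f"{TRANSLOCATED}_{release_habitat}_{phase}"


class KernelLibrary:
    """Per-stratum step samples with leave-one-animal-out access.

    Five strata: the pooled resident stratum (both habitats, whole
    horizon) and translocated x release habitat x phase. A kernel
    requested for animal i never contains i's own steps.
    """

    def __init__(self, cfg: SSFConfig | None = None):
        self.cfg = cfg or SSFConfig()
        self._samples: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    def add(self, stratum: str, animal_id: str, lengths: np.ndarray, angles: np.ndarray) -> None:
        self._samples.setdefault(stratum, {})[animal_id] = (
            np.asarray(lengths, float), np.asarray(angles, float),
        )

    @property
    def strata(self) -> list[str]:
        return sorted(self._samples)

    def kernel_for(self, stratum: str, animal_id: str) -> EmpiricalMoveKernel:
        if stratum not in self._samples:
            raise KeyError(f"no kernel stratum {stratum!r}")
        ls, as_ = [], []
        for aid, (l, a) in self._samples[stratum].items():
            if aid != animal_id:
                ls.append(l)
                as_.append(a)
        lengths = np.concatenate(ls) if ls else np.array([])
        angles = np.concatenate(as_) if as_ else np.array([])
        if len(lengths) < 2 or len(angles) < 2:
            raise ValueError(
                f"stratum {stratum!r} has < 2 steps after excluding {animal_id!r}"
            )
        if len(lengths) < self.cfg.min_kernel_steps:
            logger.warning(
                "stratum %s has only %d steps after excluding %s",
                stratum, len(lengths), animal_id,
            )
        return EmpiricalMoveKernel(stratum, animal_id, lengths, angles)


def build_kernels(
    trajs: list[Trajectory],
    phases: dict[str, PhaseAssignment],
    cfg: SSFConfig | None = None,
) -> KernelLibrary:
    """Empirical movement kernels from a preprocessed cohort.

    ``phases`` maps translocated group keys (e.g.
    ``translocated_upland_pine``) to their phase assignments; a
    translocated step's phase is that of the day of its terminal fix.
    Steps with undefined turning angles contribute their length only.
    """
    cfg = cfg or SSFConfig()
    lib = KernelLibrary(cfg)
    for traj in trajs:
        st = _step_table(traj)
        if st.empty:
            continue
        if traj.meta.status == RESIDENT:
            st["stratum"] = RESIDENT
        else:
            pa = phases[traj.meta.group]
            st["stratum"] = [
                _kernel_stratum(TRANSLOCATED, traj.meta.release_habitat, pa.phase_of(d))
                for d in st["day"]
            ]
        for stratum, g in st.groupby("stratum"):
            lib.add(
                stratum, traj.meta.animal_id,
                g["length"].to_numpy(),
                g["turning_angle"].dropna().to_numpy(),
            )
    return lib


def generate_random_steps(
    x0: float,
    y0: float,
    prev_heading: float,
    kernel: EmpiricalMoveKernel,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Endpoints of n random alternative steps from one origin.

    Lengths and turning angles are resampled independently and with
    replacement from the kernel; each alternative's heading is the
    previous observed heading plus the sampled turn. Returns an
    (n, 3) array of (x, y, length).
    """
    if not np.isfinite(prev_heading):
        raise ValueError("previous heading undefined; stratum must be skipped")
    lengths = kernel.lengths[rng.integers(0, len(kernel.lengths), n)]
    angles = kernel.angles[rng.integers(0, len(kernel.angles), n)]
    headings = prev_heading + angles
    return np.column_stack([
        x0 + lengths * np.cos(headings),
        y0 + lengths * np.sin(headings),
        lengths,
    ])


def annotate_habitat(df: pd.DataFrame, landcover: LandscapeRaster) -> pd.DataFrame:
    """Attach endpoint habitat classes and drop invalid strata.

    Alternatives whose endpoint falls off the raster or in an excluded
    class (developed, cultivated, open water, barren) are invalid; a
    stratum whose *used* step is invalid is dropped entirely, and so
    are strata left without any valid alternative.
    """
    hab = []
    for x, y in zip(df["x"], df["y"]):
        hab.append(landcover.class_at(float(x), float(y)))
    df = df.assign(habitat=hab)
    valid = df["habitat"].isin([BOTTOMLAND, UPLAND_PINE, GRASSLAND])
    bad_used = set(df.loc[(df["used"] == 1) & ~valid, "stratum_id"])
    n0 = df["stratum_id"].nunique()
    df = df[~df["stratum_id"].isin(bad_used) & valid]
    has_alt = df.groupby("stratum_id")["used"].agg(["sum", "count"])
    good = has_alt[(has_alt["sum"] == 1) & (has_alt["count"] >= 2)].index
    df = df[df["stratum_id"].isin(good)].reset_index(drop=True)
    dropped = n0 - df["stratum_id"].nunique()
    if dropped:
        logger.info("annotate_habitat: dropped %d strata (invalid used step or no valid alternative)", dropped)
    return df


def build_strata(
    trajs: list[Trajectory],
    phases: dict[str, PhaseAssignment],
    landcover: LandscapeRaster,
    cfg: SSFConfig | None = None,
    seed: int = 0,
    kernels: KernelLibrary | None = None,
) -> pd.DataFrame:
    """Full long-format choice-set table for a cohort.

    One row per alternative (1 used + ``n_random_steps`` random per
    stratum), with endpoint habitat, step length, diel period, week
    index and phase context. Random-step generation is seeded per
    stratum from (seed, animal index, step index), so results do not
    depend on iteration order. First steps (and steps following a
    zero-displacement step) have no previous heading and are skipped.
    """
    cfg = cfg or SSFConfig()
    kernels = kernels or build_kernels(trajs, phases, cfg)
    recs = []
    stratum_id = 0
    for ai, traj in enumerate(sorted(trajs, key=lambda t: t.meta.animal_id)):
        st = _step_table(traj)
        meta = traj.meta
        for _, row in st.iterrows():
            if not np.isfinite(row["prev_heading"]):
                continue
            day = int(row["day"])
            if meta.status == RESIDENT:
                phase = None
            else:
                phase = phases[meta.group].phase_of(day)
            stratum = _kernel_stratum(meta.status, meta.release_habitat, phase)
            try:
                kern = kernels.kernel_for(stratum, meta.animal_id)
            except (KeyError, ValueError) as exc:
                logger.warning("skipping stratum: %s", exc)
                continue
            rng = np.random.default_rng([seed, ai, int(row["step_index"])])
            alts = generate_random_steps(
                row["x0"], row["y0"], row["prev_heading"], kern, cfg.n_random_steps, rng
            )
            diel = classify_diel(row["t1"], cfg)
            week = (day - 1) // 7 + 1
            base = {
                "stratum_id": stratum_id,
                "animal_id": meta.animal_id,
                "status": meta.status,
                "release_habitat": meta.release_habitat,
                "group": meta.group,
                "phase": phase,
                "diel": diel,
                "day": day,
                "week_index": week,
            }
            recs.append({**base, "used": 1, "x": row["x1"], "y": row["y1"],
                         "step_length_m": row["length"]})
            for k in range(cfg.n_random_steps):
                recs.append({**base, "used": 0, "x": alts[k, 0], "y": alts[k, 1],
                             "step_length_m": alts[k, 2]})
            stratum_id += 1
    df = pd.DataFrame(recs)
    if df.empty:
        return df
    return annotate_habitat(df, landcover)


# ---------------------------------------------------------------------------
# conditional logistic regression


@dataclass
class FitResult:
    """Conditional-logit fit: coefficients, SEs, likelihood, AIC."""

    name: str
    params: pd.Series
    se: pd.Series
    se_cluster: pd.Series
    loglik: float
    n_strata: int
    converged: bool
    vcov_cluster: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.params)

    def summary(self) -> pd.DataFrame:
        z = self.params / self.se_cluster
        return pd.DataFrame({
            "coef": self.params,
            "se": self.se,
            "se_cluster": self.se_cluster,
            "ci_lo": self.params - 1.96 * self.se_cluster,
            "ci_hi": self.params + 1.96 * self.se_cluster,
            "z": z,
        })


def design_matrix(df: pd.DataFrame, model: str) -> pd.DataFrame:
    """Design matrix for one of the candidate SSF models.

    Habitat enters as bottomland/grassland dummies relative to upland
    pine; step length (km) is always retained. Status, release
    habitat and diel period are constant within a choice set, so they
    appear only through interactions with the habitat dummies — their
    main effects cancel from the conditional likelihood. ``model`` is
    one of MODEL_NAMES, optionally suffixed ``+diel`` for the
    post-hoc habitat x diel expansion.
    """
    base, _, extra = model.partition("+")
    bl = (df["habitat"] == BOTTOMLAND).astype(float).to_numpy()
    gl = (df["habitat"] == GRASSLAND).astype(float).to_numpy()
    tr = (df["status"] == TRANSLOCATED).astype(float).to_numpy()
    rb = (df["release_habitat"] == BOTTOMLAND).astype(float).to_numpy()
    cols: dict[str, np.ndarray] = {"bottomland": bl, "grassland": gl}
    if base in ("habitat_x_status", "habitat_x_status_plus_release"):
        cols["bottomland:translocated"] = bl * tr
        cols["grassland:translocated"] = gl * tr
    if base in ("habitat_x_release", "habitat_x_status_plus_release"):
        cols["bottomland:release_bottomland"] = bl * rb
        cols["grassland:release_bottomland"] = gl * rb
    if base not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    if extra == "diel":
        noct = (df["diel"] == NOCTURNAL).astype(float).to_numpy()
        for name, col in list(cols.items()):
            cols[f"{name}:nocturnal"] = col * noct
    cols["step_length_km"] = df["step_length_m"].to_numpy() / 1000.0
    # extra context covariates (columns named cov_*) enter every model;
    # recovery experiments use this to supply known generative terms
    for c in df.columns:
        if c.startswith("cov_"):
            cols[c.removeprefix("cov_")] = df[c].to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of linearly dependent columns (empty if full rank)."""
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    _, _, piv = qr(X, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[r:])]


def fit_conditional_logit(
    df: pd.DataFrame,
    model: str = "habitat",
    X: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    beta_bound: float = 15.0,
    on_singular: str = "error",
) -> FitResult:
    """Fit a conditional logit to a long-format choice-set table.

    Maximizes sum_s [ x_used.beta - log sum_alt exp(x_alt.beta) ] by
    Newton-Raphson with step halving. SEs come from the inverse
    observed information; cluster-robust (sandwich) SEs aggregate the
    per-stratum score contributions by animal. A coefficient walking
    past ``beta_bound`` in absolute value signals separation (a
    habitat used always or never within its strata); it is clamped at
    the bound with a warning. A rank-deficient design raises by
    default, naming the collinear columns; ``on_singular='drop'``
    instead removes the aliased columns with a warning (matching how
    clogit implementations handle data-dependent aliasing in small
    cohorts).
    """
    if on_singular not in ("error", "drop"):
        raise ValueError("on_singular must be error|drop")
    if len(df) == 0:
        raise ValueError("no strata to fit")
    if X is None:
        X = design_matrix(df, model)
    dead = [c for c in X.columns if not np.any(X[c].to_numpy())]
    if dead:
        # aliased terms (e.g. no translocated strata in a tiny cohort)
        logger.warning("dropping all-zero design column(s): %s", dead)
        X = X.drop(columns=dead)
    names = list(X.columns)
    order = np.argsort(df["stratum_id"].to_numpy(), kind="stable")
    sid = df["stratum_id"].to_numpy()[order]
    Xs = X.to_numpy()[order]
    y = df["used"].to_numpy()[order].astype(bool)
    animals = df["animal_id"].to_numpy()[order]
    starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    counts = np.diff(np.r_[starts, len(sid)])
    n_strata = len(starts)
    if not (np.add.reduceat(y.astype(int), starts) == 1).all():
        raise ValueError("every stratum must contain exactly one used alternative")
    aliased = _aliased_columns(Xs, names)
    if aliased:
        if on_singular == "error":
            raise np.linalg.LinAlgError(
                f"singular design; collinear column(s): {aliased}")
        logger.warning("dropping aliased design column(s): %s", aliased)
        keep = [j for j, n in enumerate(names) if n not in aliased]
        Xs = Xs[:, keep]
        names = [names[j] for j in keep]

    k = Xs.shape[1]
    beta = np.zeros(k)

    def ll_parts(beta):
        eta = Xs @ beta
        m = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - np.repeat(m, counts))
        denom = np.add.reduceat(ex, starts)
        p = ex / np.repeat(denom, counts)
        ll = float(eta[y].sum() - (np.log(denom) + m).sum())
        return ll, p

    ll, p = ll_parts(beta)
    converged = False
    clamped = False
    for _ in range(max_iter):
        grad = Xs[y].sum(axis=0) - Xs.T @ p
        pX = p[:, None] * Xs
        S = np.add.reduceat(pX, starts, axis=0)  # per-stratum mean covariate
        info = Xs.T @ pX - S.T @ S
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        scale = 1.0
        while scale > 1e-8:
            cand = beta + scale * step
            ll_new, p_new = ll_parts(cand)
            if ll_new >= ll - 1e-12:
                beta, ll, p = cand, ll_new, p_new
                break
            scale /= 2.0
        else:
            break
        if np.max(np.abs(beta)) > beta_bound:
            logger.warning(
                "separation suspected: coefficient(s) %s at bound %.0f",
                [names[j] for j in np.flatnonzero(np.abs(beta) > beta_bound)],
                beta_bound,
            )
            beta = np.clip(beta, -beta_bound, beta_bound)
            ll, p = ll_parts(beta)
            clamped = True
            break

    grad = Xs[y].sum(axis=0) - Xs.T @ p
    pX = p[:, None] * Xs
    S = np.add.reduceat(pX, starts, axis=0)
    info = Xs.T @ pX - S.T @ S
    bread = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(bread), 0, None))
    # per-stratum scores, summed within animal clusters
    g_s = Xs[y] - S
    stratum_animal = animals[starts]
    meat = np.zeros((k, k))
    for a in np.unique(stratum_animal):
        G = g_s[stratum_animal == a].sum(axis=0)
        meat += np.outer(G, G)
    n_cl = len(np.unique(stratum_animal))
    if n_cl > 1:
        meat *= n_cl / (n_cl - 1)
    vcov_cl = bread @ meat @ bread
    se_cl = np.sqrt(np.clip(np.diag(vcov_cl), 0, None))
    return FitResult(
        name=model,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        se_cluster=pd.Series(se_cl, index=names),
        loglik=ll,
        n_strata=n_strata,
        converged=converged and not clamped,
        vcov_cluster=vcov_cl,
    )


def clogit_loglik(df: pd.DataFrame, X: pd.DataFrame, beta: np.ndarray) -> float:
    """Conditional-logit log-likelihood at a fixed coefficient vector.

    sum over strata of [ x_used.beta - log sum_alt exp(x_alt.beta) ].
    """
    beta = np.asarray(beta, float)
    order = np.argsort(df["stratum_id"].to_numpy(), kind="stable")
    sid = df["stratum_id"].to_numpy()[order]
    Xs = X.to_numpy()[order]
    y = df["used"].to_numpy()[order].astype(bool)
    starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    counts = np.diff(np.r_[starts, len(sid)])
    eta = Xs @ beta
    m = np.maximum.reduceat(eta, starts)
    denom = np.add.reduceat(np.exp(eta - np.repeat(m, counts)), starts)
    return float(eta[y].sum() - (np.log(denom) + m).sum())


def model_set() -> tuple[str, ...]:
    """The four candidate model names, in the order they are compared."""
    return MODEL_NAMES


def rank_models_aic(
    df: pd.DataFrame,
    models: tuple[str, ...] | None = None,
    add_diel_posthoc: bool = True,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit the candidate models on identical strata and rank by AIC.

    All models see the same choice sets (an error otherwise). After
    ranking the base set, the diel post-hoc model — the top-ranked
    base model with every habitat term also interacted with the
    nocturnal indicator — is fit and enters the final ranking.
    Models within 2 AIC of the best are flagged equivalent.
    """
    models = models or MODEL_NAMES
    fits: dict[str, FitResult] = {}
    for m in models:
        fits[m] = fit_conditional_logit(df, m, on_singular="drop")
    ns = {f.n_strata for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"models fit on differing strata counts: {ns}")
    top_base = min(fits, key=lambda m: fits[m].aic)
    if add_diel_posthoc:
        ph = f"{top_base}+diel"
        fits[ph] = fit_conditional_logit(df, ph, on_singular="drop")
    tab = pd.DataFrame(
        {
            "model": list(fits),
            "k": [len(f.params) for f in fits.values()],
            "loglik": [f.loglik for f in fits.values()],
            "aic": [f.aic for f in fits.values()],
            "n_strata": [f.n_strata for f in fits.values()],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    tab["equivalent"] = tab["delta_aic"] <= 2.0
    return tab, fits


def weekly_selection_series(
    df: pd.DataFrame,
    group: str,
    n_weeks: int = 13,
) -> pd.DataFrame:
    """Weekly nocturnal selection coefficients for bottomland habitat.

    For one group's nocturnal strata, a single conditional logit is
    fit with a week-specific bottomland coefficient (bottomland dummy
    x week indicator), a grassland dummy and step length. Weeks whose
    strata show no within-stratum bottomland variation are reported
    as missing.
    """
    sub = df[(df["group"] == group) & (df["diel"] == NOCTURNAL)]
    out_idx = pd.RangeIndex(1, n_weeks + 1, name="week")
    empty = pd.DataFrame({"beta_bottomland": np.nan, "se": np.nan}, index=out_idx)
    if sub.empty:
        logger.warning("group %s: no nocturnal strata", group)
        return empty.reset_index()
    bl = (sub["habitat"] == BOTTOMLAND).astype(float)
    # identifiable weeks: bottomland varies within at least one stratum
    var_ok = (
        bl.groupby(sub["stratum_id"]).transform("nunique").gt(1)
        .groupby(sub["week_index"]).any()
    )
    weeks = [w for w in range(1, n_weeks + 1) if bool(var_ok.get(w, False))]
    if not weeks:
        logger.warning("group %s: no identifiable weeks", group)
        return empty.reset_index()
    keep = sub["week_index"].isin(weeks)
    sub = sub[keep]
    bl = bl[keep]
    cols = {}
    for w in weeks:
        cols[f"bottomland:w{w}"] = (bl * (sub["week_index"] == w)).to_numpy()
    cols["grassland"] = (sub["habitat"] == GRASSLAND).astype(float).to_numpy()
    cols["step_length_km"] = sub["step_length_m"].to_numpy() / 1000.0
    X = pd.DataFrame(cols, index=sub.index)
    # grassland column may be degenerate in small groups
    if X["grassland"].std() == 0:
        X = X.drop(columns=["grassland"])
    fit = fit_conditional_logit(sub, model=f"weekly_{group}", X=X)
    rows = []
    for w in range(1, n_weeks + 1):
        key = f"bottomland:w{w}"
        if key in fit.params.index:
            rows.append({"week": w, "beta_bottomland": fit.params[key],
                         "se": fit.se_cluster[key]})
        else:
            rows.append({"week": w, "beta_bottomland": np.nan, "se": np.nan})
    return pd.DataFrame(rows)
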