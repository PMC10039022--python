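"""End-to-end orchestration: preprocess -> space use -> phases -> SSF -> report.

``run_pipeline`` executes the whole analysis on either file inputs
(GPS CSV, metadata CSV, landcover ASCII grid) or a freshly simulated
demo cohort, writing every intermediate artifact (cleaned fixes,
per-animal daily metrics, group mean +/- SE series, phase
assignments, SSF strata, AIC ranking, weekly nocturnal selection
series), a four-figure report, and a manifest with a hash of the
numeric outputs so reruns can be checked for bit-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from translocmove.dbbmm import DBBMMConfig
from translocmove.raster import BOTTOMLAND, LandscapeRaster, UPLAND_PINE
from translocmove.ssf import (
    SSFConfig,
    build_kernels,
    build_strata,
    rank_models_aic,
    weekly_selection_series,
)
from translocmove.synthetic import Cohort, SimConfig, simulate_cohort
from translocmove.trajectory import (
    RESIDENT,
    TRANSLOCATED,
    PreprocessConfig,
    Trajectory,
    attach_metadata,
    preprocess,
    read_censor_csv,
    read_gps_csv,
    read_metadata_csv,
    write_clean_csv,
)
from translocmove.windows import (
    PhaseAssignment,
    WindowConfig,
    daily_metrics,
    detect_phase_transition,
    group_series,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, sub-configs and seed for one pipeline run."""

    outdir: str | Path = "run_output"
    gps_csv: str | Path | None = None
    metadata_csv: str | Path | None = None
    censor_csv: str | Path | None = None
    landcover_asc: str | Path | None = None
    seed: int = 0
    demo: bool = False
    sim: SimConfig | None = None
    pre: PreprocessConfig = field(default_factory=PreprocessConfig)
    dbb: DBBMMConfig = field(default_factory=DBBMMConfig)
    win: WindowConfig = field(default_factory=WindowConfig)
    ssf: SSFConfig = field(default_factory=SSFConfig)

    def validate(self) -> None:
        if not self.demo:
            for name in ("gps_csv", "metadata_csv", "landcover_asc"):
                if getattr(self, name) is None:
                    raise ValueError(f"RunConfig.{name} is required unless demo=True")


def load_inputs(cfg: RunConfig) -> tuple[list[Trajectory], LandscapeRaster]:
    """Read the GPS, metadata and landcover inputs (or simulate them)."""
    if cfg.demo:
        sim = cfg.sim or SimConfig(seed=cfg.seed)
        cohort = simulate_cohort(sim)
        return cohort.trajectories, cohort.landscape
    trajs = read_gps_csv(cfg.gps_csv)
    metas = read_metadata_csv(cfg.metadata_csv)
    censors = read_censor_csv(cfg.censor_csv) if cfg.censor_csv else None
    trajs = attach_metadata(trajs, metas, censors)
    landscape = LandscapeRaster.read_ascii(cfg.landcover_asc)
    return trajs, landscape


def detect_all_phases(
    groups: dict[str, pd.DataFrame], wcfg: WindowConfig
) -> dict[str, PhaseAssignment]:
    """Phase assignment for every translocated group.

    Each translocated group is compared against the resident group of
    its release habitat ("their respective resident group"); if that
    group is absent, the pooled resident series is used instead.
    """
    resident_groups = {g: s for g, s in groups.items() if g.startswith(RESIDENT)}
    if not resident_groups:
        raise ValueError("no resident group; cannot form a reference level")
    pooled = (
        pd.concat(resident_groups.values())
        .groupby("day", as_index=False)["mean_range_area_ha"].mean()
    )
    phases = {}
    for g, series in groups.items():
        if not g.startswith(TRANSLOCATED):
            continue
        habitat = g.removeprefix(f"{TRANSLOCATED}_")
        ref = resident_groups.get(f"{RESIDENT}_{habitat}")
        if ref is None:
            logger.warning("group %s: no matching resident group; using pooled residents", g)
            ref = pooled
        phases[g] = detect_phase_transition(series, ref, g, wcfg)
    return phases


def _hash_numeric_artifacts(outdir: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        if p.name == "manifest.json":
            continue
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts.

    Returns a dict of in-memory results (groups, phases, model table,
    weekly series, manifest). Any stage failure aborts with a
    stage-named error; artifacts written so far are left in place.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    timings: list[dict] = []

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                rec = {"stage": name, "seconds": round(time.perf_counter() - self.t0, 3),
                       "ok": exc is None}
                timings.append(rec)
                with open(log_path, "a") as fh:
                    fh.write(json.dumps(rec) + "\n")
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    log_path.write_text("")
    results: dict = {}

    with stage("load"):
        raw, landscape = load_inputs(cfg)

    with stage("preprocess"):
        trajs = [preprocess(tr, cfg.pre) for tr in raw]
        trajs = [tr for tr in trajs if len(tr) >= 2]
        write_clean_csv(trajs, outdir / "clean_fixes.csv")

    with stage("spaceuse"):
        per_animal = [(tr, daily_metrics(tr, cfg.win, cfg.dbb)) for tr in trajs]
        pd.concat([dm for _, dm in per_animal], ignore_index=True).to_csv(
            outdir / "daily_metrics.csv", index=False, float_format="%.6g"
        )
        groups = group_series(per_animal)
        gs = []
        for g, s in groups.items():
            s = s.copy()
            s.insert(0, "group", g)
            gs.append(s)
        pd.concat(gs, ignore_index=True).to_csv(
            outdir / "group_series.csv", index=False, float_format="%.6g"
        )
        results["groups"] = groups

    with stage("phases"):
        phases = detect_all_phases(groups, cfg.win)
        pd.DataFrame(
            [
                {"group": g, "crossing_day": p.crossing_day,
                 "transition_day": p.transition_day, "reached": p.reached}
                for g, p in phases.items()
            ]
        ).to_csv(outdir / "phases.csv", index=False)
        results["phases"] = phases

    with stage("ssf"):
        kernels = build_kernels(trajs, phases, cfg.ssf)
        strata = build_strata(trajs, phases, landscape, cfg.ssf, seed=cfg.seed,
                              kernels=kernels)
        strata.to_csv(outdir / "ssf_strata.csv", index=False, float_format="%.6g")
        table, fits = rank_models_aic(strata)
        table.to_csv(outdir / "model_ranking.csv", index=False, float_format="%.6g")
        fits_json = {
            name: {
                "coef": f.params.to_dict(),
                "se_cluster": f.se_cluster.to_dict(),
                "loglik": f.loglik, "aic": f.aic, "n_strata": f.n_strata,
                "converged": f.converged,
            }
            for name, f in fits.items()
        }
        (outdir / "ssf_fits.json").write_text(json.dumps(fits_json, indent=1))
        results["model_table"] = table
        results["fits"] = fits

    with stage("weekly"):
        n_weeks = max(1, cfg.win.horizon_days // 7)
        weekly = []
        for g in sorted(strata["group"].unique()) if len(strata) else []:
            w = weekly_selection_series(strata, g, n_weeks=n_weeks)
            w.insert(0, "group", g)
            weekly.append(w)
        weekly_df = (
            pd.concat(weekly, ignore_index=True)
            if weekly else pd.DataFrame(columns=["group", "week", "beta_bottomland", "se"])
        )
        weekly_df.to_csv(outdir / "weekly_selection.csv", index=False, float_format="%.6g")
        results["weekly"] = weekly_df

    with stage("report"):
        figures = make_report(outdir)
        results["figures"] = figures

    with stage("manifest"):
        manifest = {
            "seed": cfg.seed,
            "demo": cfg.demo,
            "config_hash": hashlib.sha256(
                json.dumps(_cfg_dict(cfg), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "numeric_hash": _hash_numeric_artifacts(outdir),
            "stages": timings,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        results["manifest"] = manifest
    return results


def _cfg_dict(cfg: RunConfig) -> dict:
    d = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            try:
                v = dataclasses.asdict(v)
            except TypeError:
                v = str(v)
        d[f.name] = v
    return d


def make_report(outdir: str | Path) -> list[str]:
    """Figures and summary tables from a completed run's artifacts.

    Produces the four standard panels: windowed core/range areas by
    group, distance from release by group, overall selection
    coefficients with 95% CIs from the top-ranked model (reference
    level at 0), and weekly nocturnal bottomland selection. Solid
    lines are group means, dashed lines +/- 1 SE (omitted for n < 2
    groups). Missing artifacts skip their figure with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    made = []

    def _plot_series(fname, metric, ylabel):
        path = outdir / "group_series.csv"
        if not path.exists():
            logger.warning("missing %s; figure %s skipped", path, fname)
            return
        df = pd.read_csv(path)
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for g, s in df.groupby("group"):
            line, = ax.plot(s["day"], s[f"mean_{metric}"], label=g)
            se = s[f"se_{metric}"]
            if se.notna().any():
                ax.plot(s["day"], s[f"mean_{metric}"] + se, "--", lw=0.8,
                        color=line.get_color())
                ax.plot(s["day"], s[f"mean_{metric}"] - se, "--", lw=0.8,
                        color=line.get_color())
        ax.set_xlabel("day post release")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=120)
        plt.close(fig)
        made.append(fname)

    _plot_series("fig1_window_areas.png", "range_area_ha", "95% dBBMM range area (ha)")
    _plot_series("fig2_distance_release.png", "mean_dist_release_m", "distance from release (m)")

    fits_path = outdir / "ssf_fits.json"
    rank_path = outdir / "model_ranking.csv"
    if fits_path.exists() and rank_path.exists():
        fits = json.loads(fits_path.read_text())
        top = pd.read_csv(rank_path)["model"].iloc[0]
        f = fits[top]
        names = [n for n in f["coef"] if n != "step_length_km"]
        coefs = np.array([f["coef"][n] for n in names])
        ses = np.array([f["se_cluster"][n] for n in names])
        fig, ax = plt.subplots(figsize=(7, 0.6 + 0.4 * len(names)))
        ypos = np.arange(len(names))[::-1]
        ax.errorbar(coefs, ypos, xerr=1.96 * ses, fmt="o", capsize=3)
        ax.axvline(0.0, color="k", lw=0.8)  # reference: neither selection nor avoidance
        ax.set_yticks(ypos)
        ax.set_yticklabels(names, fontsize=7)
        ax.set_xlabel(f"coefficient (top model: {top})")
        fig.tight_layout()
        fig.savefig(outdir / "fig3_selection_coefficients.png", dpi=120)
        plt.close(fig)
        made.append("fig3_selection_coefficients.png")
    else:
        logger.warning("missing SSF fits; figure 3 skipped")

    weekly_path = outdir / "weekly_selection.csv"
    if weekly_path.exists():
        df = pd.read_csv(weekly_path)
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for g, s in df.groupby("group"):
            ax.errorbar(s["week"], s["beta_bottomland"], yerr=1.96 * s["se"],
                        marker="o", capsize=2, label=g)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("week post release")
        ax.set_ylabel("nocturnal selection for bottomland (beta)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "fig4_weekly_selection.png", dpi=120)
        plt.close(fig)
        made.append("fig4_weekly_selection.png")
    else:
        logger.warning("missing weekly series; figure 4 skipped")
    return made
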