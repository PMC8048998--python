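"""End-to-end pipeline: zones -> series -> fit -> phases -> drivers.

All randomness fans out from the single config seed through named
per-stage ``SeedSequence`` spawns, so a re-run with the same config and
seed reproduces every deterministic output byte for byte.  Every output
file is listed in a manifest with its SHA-256 checksum.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, geometry, simulate
from .config import PipelineConfig
from .drivers import (
    build_driver_table, count_precip_events, event_overlay_export,
    fit_driver_regression, krill_buffer_catch, load_ssmus,
    tourism_window_count,
)
from .phases import friedman_test, phase_mortality, phase_rate_table
from .survival import ModelData, breeding_success, derive_total_chicks, fit_survival_model

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "validate_inputs", "PipelineStageError",
           "ValidationReport"]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {"ok": self.ok, "errors": self.errors,
                "warnings": self.warnings, "files": self.files}


def validate_inputs(paths) -> ValidationReport:
    """Schema/units checks for the file-based inputs.

    ``paths`` is an :class:`~nestcam.config.InputPaths` (or anything with
    its attributes).  Errors block the pipeline; warnings (capped counts,
    odd units) do not.
    """
    rep = ValidationReport()

    def check(name, path, required_cols, checker=None):
        if path is None:
            rep.files[name] = "absent (optional)"
            return None
        try:
            df = pd.read_csv(path)
        except Exception as e:
            rep.errors.append(f"{name}: unreadable ({e})")
            rep.files[name] = "unreadable"
            return None
        missing = [c for c in required_cols if c not in df.columns]
        if missing:
            rep.errors.append(f"{name}: missing columns {missing}")
            rep.files[name] = "schema error"
            return None
        rep.files[name] = f"ok ({len(df)} rows)"
        if checker:
            checker(df)
        return df

    check("annotations", getattr(paths, "annotations", None),
          ["site_id", "year_id", "nest_id", "x_px", "y_px", "frame_w", "frame_h"])
    check("detections", getattr(paths, "detections", None),
          ["site_id", "year_id", "timestamp", "x_px", "y_px"])

    def check_site_years(df):
        for r in df.itertuples():
            for col in ("creche_date", "first_chick_date"):
                v = getattr(r, col, None)
                if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "":
                    rep.errors.append(
                        f"site_years: missing {col} for site/year "
                        f"{r.site_id}/{r.year_id}")

    check("site_years", getattr(paths, "site_years", None),
          ["site_id", "year_id", "creche_date", "first_chick_date"],
          check_site_years)

    def check_precip(df):
        bad = df[~df["magnitude"].isin([1, 2, 3])]
        for r in bad.itertuples():
            rep.errors.append(
                f"precip: magnitude {r.magnitude} outside 1..3 "
                f"({r.site_id}/{r.year_id} {r.date})")

    check("precip", getattr(paths, "precip", None),
          ["site_id", "year_id", "date", "kind", "magnitude"], check_precip)
    check("tourism", getattr(paths, "tourism", None),
          ["site_id", "year_id", "date", "visitors"])
    check("krill_catch", getattr(paths, "krill_catch", None),
          ["ssmu_id", "year", "month", "tonnes"])

    obs = getattr(paths, "observations", None)
    if obs is not None:
        def check_obs(df):
            cnt = pd.to_numeric(df["count"], errors="coerce")
            over = int((cnt > geometry.CLUTCH_SIZE).sum())
            if over:
                rep.warnings.append(
                    f"observations: {over} counts above the clutch cap of "
                    f"{geometry.CLUTCH_SIZE}; they will be capped")
        check("observations", obs, ["site_id", "year_id", "nest_id", "t", "count"],
              check_obs)
    return rep


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write an artifact bundle.

    Returns the manifest (also written to ``manifest.json``): config echo,
    stage seeds and timings, convergence report, and a checksum for every
    output file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seeds": {},
        "stages": {},
        "outputs": {},
        "partial": False,
    }
    root_ss = np.random.SeedSequence(config.rng_seed)
    stage_seed = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ("simulate", "fit", "derive", "drivers"), root_ss.spawn(4))
    }
    manifest["seeds"] = stage_seed
    written: list[Path] = []

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3)}
                if exc is not None:
                    manifest["partial"] = True
                    _write_manifest()
                    raise PipelineStageError(name, exc) from exc
                logger.info("stage %s: done", name)
        return _Ctx()

    def emit(name: str, path: Path):
        written.append(path)
        manifest["outputs"][name] = {"path": str(path)}

    def _write_manifest():
        for name, info in manifest["outputs"].items():
            p = Path(info["path"])
            if p.exists():
                info["sha256"] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # ---- data stage: simulate or ingest --------------------------------
    site_meta = {}
    truth = None
    if config.simulation is not None:
        with stage("simulate"):
            sim_cfg = simulate.SimulationConfig(
                rng_seed=stage_seed["simulate"],
                **config.simulation.model_dump())
            sims = simulate.simulate_study(sim_cfg)
            series = [s.to_observation_series() for s in sims]
            truth = {
                f"{s.site_id}/{s.year_id}": {
                    "phi": s.params["phi"],
                    "breeding_success": s.true_breeding_success,
                }
                for s in sims
            }
            frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
            frame.to_csv(out / "observation_series.csv", index=False)
            emit("observation_series", out / "observation_series.csv")
            (out / "simulation_truth.json").write_text(json.dumps(truth, indent=2))
            emit("simulation_truth", out / "simulation_truth.json")
    else:
        with stage("validate"):
            rep = validate_inputs(config.inputs)
            (out / "validation.json").write_text(json.dumps(rep.to_dict(), indent=2))
            emit("validation", out / "validation.json")
            if not rep.ok:
                raise ValueError("; ".join(rep.errors))
        with stage("zones"):
            maps = geometry.read_annotations(config.inputs.annotations)
            for m in maps:
                p = out / f"zones_{m.site_id}_{m.year_id}.geojson"
                m.write_geojson(p)
                emit(f"zones_{m.site_id}_{m.year_id}", p)
        with stage("series"):
            detections = geometry.read_detections(config.inputs.detections)
            meta = pd.read_csv(config.inputs.site_years)
            series = []
            for m in maps:
                row = meta[(meta["site_id"].astype(str) == m.site_id)
                           & (meta["year_id"].astype(str) == m.year_id)]
                if row.empty:
                    raise ValueError(
                        f"no site_years metadata for {m.site_id}/{m.year_id}")
                row = row.iloc[0]
                daily = geometry.detections_to_daily(detections, m)
                s = geometry.build_observation_series(
                    daily,
                    creche_date=row["creche_date"],
                    first_chick_date=row["first_chick_date"],
                    nest_ids=m.nest_ids, site_id=m.site_id, year_id=m.year_id)
                series.append(s)
                site_meta[(m.site_id, m.year_id)] = row
            frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
            frame.to_csv(out / "observation_series.csv", index=False)
            emit("observation_series", out / "observation_series.csv")

    # ---- fit ------------------------------------------------------------
    with stage("fit"):
        data = ModelData(series)
        mcmc = config.mcmc_config()
        mcmc.rng_seed = stage_seed["fit"]
        post = fit_survival_model(data, priors=config.priors_config(), mcmc=mcmc)
        post.to_frame().to_csv(out / "posterior_draws.csv", index=False)
        emit("posterior_draws", out / "posterior_draws.csv")
        (out / "fit_report.json").write_text(json.dumps(post.fit_report(), indent=2))
        emit("fit_report", out / "fit_report.json")

    # ---- derived quantities ---------------------------------------------
    with stage("derive"):
        z_rows, bs_rows, phase_results = [], [], []
        for g, (site, year) in enumerate(data.labels):
            Z = derive_total_chicks(post, group=g, rng_seed=stage_seed["derive"])
            zm, zs = Z.mean(axis=0), Z.std(axis=0, ddof=1)
            for day in range(geometry.SEASON_LENGTH):
                z_rows.append({"site_id": site, "year_id": year, "day": day + 1,
                               "z_mean": zm[day], "z_sd": zs[day]})
            bs = breeding_success(post, group=g, rng_seed=stage_seed["derive"])
            bs_rows.append({"site_id": site, "year_id": year,
                            "n_nests": bs.n_nests, "bs_mean": bs.mean,
                            "bs_sd": bs.sd, "bs_lo95": bs.ci95[0],
                            "bs_hi95": bs.ci95[1]})
            phase_results.append(phase_mortality(
                zm, boundaries=config.phases.boundaries,
                site_id=site, year_id=year))
        pd.DataFrame(z_rows).to_csv(out / "z_trajectories.csv", index=False)
        emit("z_trajectories", out / "z_trajectories.csv")
        pd.DataFrame(bs_rows).to_csv(out / "breeding_success.csv", index=False)
        emit("breeding_success", out / "breeding_success.csv")
        rate_tab = phase_rate_table(phase_results)
        rate_tab.to_csv(out / "phase_rates.csv")
        emit("phase_rates", out / "phase_rates.csv")
        if len(phase_results) >= 2:
            fr = friedman_test(rate_tab[["egg", "young_chick", "old_chick"]].to_numpy())
            (out / "friedman.json").write_text(json.dumps({
                "statistic": fr.statistic, "df": fr.df, "p_value": fr.p_value,
                "n_blocks": fr.n_blocks, "k_treatments": fr.k_treatments,
                "tie_corrected": fr.tie_corrected}, indent=2))
            emit("friedman", out / "friedman.json")

    # ---- drivers --------------------------------------------------------
    with stage("drivers"):
        bs_df = pd.DataFrame(bs_rows)
        rows = []
        if config.simulation is not None:
            # plumbing covariates with no built-in effect on the simulated
            # survival process; effect-recovery is exercised by
            # simulate_drivers, not here
            drng = np.random.default_rng(stage_seed["drivers"])
            for r in bs_df.itertuples():
                rows.append({
                    "site_id": r.site_id, "year_id": r.year_id,
                    "bs_obs": r.bs_mean,
                    # a degenerate BS posterior (sd 0) still needs a positive
                    # known error in the errors-in-variables model
                    "sigma_bs": max(r.bs_sd, 1e-6),
                    "precip_events": int(drng.integers(0, 13)),
                    "krill_catch": float(drng.gamma(2.0, 500.0)),
                    "tourists": int(drng.integers(0, 3000)),
                })
        else:
            precip = (pd.read_csv(config.inputs.precip)
                      if config.inputs.precip else None)
            tourism = (pd.read_csv(config.inputs.tourism)
                       if config.inputs.tourism else None)
            ssmus = None
            if config.inputs.ssmu_geojson and config.inputs.krill_catch:
                gj = json.loads(Path(config.inputs.ssmu_geojson).read_text())
                ssmus = load_ssmus(gj, pd.read_csv(config.inputs.krill_catch))
            for r in bs_df.itertuples():
                meta_row = site_meta[(r.site_id, r.year_id)]
                creche = geometry._as_date(meta_row["creche_date"])
                lay = creche - dt.timedelta(days=geometry.SEASON_LENGTH)
                row = {"site_id": r.site_id, "year_id": r.year_id,
                       "bs_obs": r.bs_mean, "sigma_bs": max(r.bs_sd, 1e-6),
                       "precip_events": 0, "krill_catch": 0.0, "tourists": 0}
                if precip is not None:
                    sel = precip[(precip["site_id"].astype(str) == r.site_id)
                                 & (precip["year_id"].astype(str) == r.year_id)]
                    row["precip_events"] = count_precip_events(sel)
                if tourism is not None:
                    sel = tourism[(tourism["site_id"].astype(str) == r.site_id)
                                  & (tourism["year_id"].astype(str) == r.year_id)]
                    row["tourists"] = tourism_window_count(sel, lay, creche)
                if ssmus is not None:
                    row["krill_catch"] = krill_buffer_catch(
                        (float(meta_row["lon"]), float(meta_row["lat"])),
                        ssmus, season_end_year=creche.year,
                        radius_km=config.krill.radius_km)
                rows.append(row)
        table = build_driver_table(rows)
        table.to_csv(out / "driver_table.csv", index=False)
        emit("driver_table", out / "driver_table.csv")
        if len(table) >= 3:
            summaries, draw_frames = [], []
            for i, cov in enumerate(("precipitation", "krill", "tourism")):
                reg = fit_driver_regression(
                    table, cov, rng_seed=stage_seed["drivers"] + i)
                summaries.append(reg.summary())
                frame = reg.to_frame()
                frame.insert(0, "covariate", cov)
                draw_frames.append(frame)
            pd.DataFrame(summaries).to_csv(
                out / "driver_regressions.csv", index=False)
            emit("driver_regressions", out / "driver_regressions.csv")
            pd.concat(draw_frames, ignore_index=True).to_csv(
                out / "driver_regression_draws.csv", index=False)
            emit("driver_regression_draws", out / "driver_regression_draws.csv")
        # storm overlay for the first site/year (analysis aid)
        first = data.labels[0]
        zsel = pd.DataFrame(z_rows)
        zsel = zsel[(zsel["site_id"] == first[0]) & (zsel["year_id"] == first[1])]
        overlay = event_overlay_export(
            zsel["z_mean"].to_numpy(), zsel["z_sd"].to_numpy())
        overlay.to_csv(out / "event_overlay.csv", index=False)
        emit("event_overlay", out / "event_overlay.csv")

    _write_manifest()
    return manifest
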