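import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import nestcam as nc
from nestcam.cli import main as cli
from nestcam.config import (InputPaths, McmcSettings, PipelineConfig,
                            SimulationSettings)
from nestcam.pipeline import PipelineStageError, run_pipeline, validate_inputs

TINY_MCMC = McmcSettings(n_chains=2, n_warmup=250, n_samples=250)


class TestConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception, match="extra_forbidden|Extra"):
            PipelineConfig.model_validate(
                {"simulation": {}, "surprise": 1})

    def test_exactly_one_data_source(self):
        with pytest.raises(Exception, match="exactly one"):
            PipelineConfig.model_validate({})
        with pytest.raises(Exception, match="exactly one"):
            PipelineConfig.model_validate({
                "simulation": {},
                "inputs": {"annotations": "a", "detections": "b",
                           "site_years": "c"}})

    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(rng_seed=7, simulation=SimulationSettings(),
                             output_dir=tmp_path / "o")
        p = tmp_path / "cfg.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
        back = PipelineConfig.from_yaml(p)
        assert back == cfg

    def test_paper_preset_settings(self):
        cfg = PipelineConfig(simulation=SimulationSettings(),
                             mcmc=McmcSettings(preset="paper"))
        m = cfg.mcmc_config()
        assert (m.n_chains, m.n_warmup, m.n_samples, m.thin) == \
            (6, 400_000, 400_000, 100)


def _files_fixture(tmp_path):
    """Small but complete file-based input set, generated from the
    simulator so the survival signal is coherent."""
    cfg = nc.SimulationConfig(n_sites=1, n_years_per_site=1, n_nests=4,
                              theta_phi=6.0, sigma_mu_phi=0.0, mu_p=2.5,
                              sigma_nu_p=0.1, rng_seed=3)
    sim = nc.simulate_site_year(cfg, 0)
    site, year = "byers", "2014-15"
    seeds = [("1", 10, 10), ("2", 30, 10), ("3", 10, 30), ("4", 30, 30)]
    ann = pd.DataFrame([
        {"site_id": site, "year_id": year, "nest_id": nid, "x_px": x,
         "y_px": y, "frame_w": 40, "frame_h": 40} for nid, x, y in seeds])
    ann.to_csv(tmp_path / "annotations.csv", index=False)

    creche = sim.creche_date
    lay = creche - pd.Timedelta(days=60)
    det_rows = []
    for t in range(31, 61):
        date = lay + pd.Timedelta(days=t)
        for j, (nid, x, y) in enumerate(seeds):
            cnt = sim.y[t - 1, j]
            if np.isnan(cnt):
                continue
            for c in range(int(cnt)):
                det_rows.append({
                    "site_id": site, "year_id": year,
                    "timestamp": f"{date.isoformat()}T12:00:00",
                    "x_px": x + c, "y_px": y})
    pd.DataFrame(det_rows).to_csv(tmp_path / "detections.csv", index=False)

    pd.DataFrame([{
        "site_id": site, "year_id": year,
        "creche_date": creche.isoformat(),
        "first_chick_date": (lay + pd.Timedelta(days=31)).isoformat(),
        "lon": -61.0, "lat": -62.6, }]).to_csv(
            tmp_path / "site_years.csv", index=False)

    mid = (lay + pd.Timedelta(days=30)).isoformat()
    pd.DataFrame([
        {"site_id": site, "year_id": year, "date": mid,
         "kind": "snow", "magnitude": 3},
        {"site_id": site, "year_id": year, "date": mid,
         "kind": "rain", "magnitude": 1},
    ]).to_csv(tmp_path / "precip.csv", index=False)
    pd.DataFrame([
        {"site_id": site, "year_id": year, "date": mid, "visitors": 80},
    ]).to_csv(tmp_path / "tourism.csv", index=False)
    return InputPaths(
        annotations=tmp_path / "annotations.csv",
        detections=tmp_path / "detections.csv",
        site_years=tmp_path / "site_years.csv",
        precip=tmp_path / "precip.csv",
        tourism=tmp_path / "tourism.csv",
    ), sim


class TestValidateInputs:
    def test_well_formed_inputs_pass(self, tmp_path):
        paths, _ = _files_fixture(tmp_path)
        rep = validate_inputs(paths)
        assert rep.ok, rep.errors

    def test_missing_creche_date_names_site_year(self, tmp_path):
        paths, _ = _files_fixture(tmp_path)
        meta = pd.read_csv(paths.site_years)
        meta.loc[0, "creche_date"] = np.nan
        meta.to_csv(paths.site_years, index=False)
        rep = validate_inputs(paths)
        assert not rep.ok
        assert any("byers/2014-15" in e and "creche_date" in e
                   for e in rep.errors)

    def test_bad_precip_magnitude_is_schema_error(self, tmp_path):
        paths, _ = _files_fixture(tmp_path)
        pr = pd.read_csv(paths.precip)
        pr.loc[0, "magnitude"] = 4
        pr.to_csv(paths.precip, index=False)
        rep = validate_inputs(paths)
        assert any("magnitude 4" in e for e in rep.errors)

    def test_unreadable_file_reported(self, tmp_path):
        paths, _ = _files_fixture(tmp_path)
        rep = validate_inputs(paths.model_copy(
            update={"detections": tmp_path / "nope.csv"}))
        assert any("unreadable" in e for e in rep.errors)

    def test_capped_count_warning(self, tmp_path):
        obs = pd.DataFrame({"site_id": ["s"], "year_id": ["y"],
                            "nest_id": ["1"], "t": [40], "count": [3]})
        obs.to_csv(tmp_path / "obs.csv", index=False)

        class P:
            annotations = None
            detections = None
            site_years = None
            precip = None
            tourism = None
            krill_catch = None
            observations = tmp_path / "obs.csv"

        rep = validate_inputs(P())
        assert any("clutch cap" in w for w in rep.warnings)


class TestRunPipeline:
    def test_simulated_end_to_end_manifest_complete(self, tmp_path):
        cfg = PipelineConfig(
            rng_seed=5, output_dir=tmp_path / "out",
            simulation=SimulationSettings(n_sites=3, n_years_per_site=1,
                                          n_nests=6),
            mcmc=TINY_MCMC)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", nc.ConvergenceWarning)
            man = run_pipeline(cfg)
        for name, info in man["outputs"].items():
            p = Path(info["path"])
            assert p.exists(), name
            assert len(info["sha256"]) == 64
        report = json.loads((tmp_path / "out" / "fit_report.json").read_text())
        assert report["max_rhat"] > 0
        assert not man["partial"]

    def test_rerun_is_byte_identical(self, tmp_path):
        base = dict(rng_seed=11,
                    simulation=SimulationSettings(n_sites=3,
                                                  n_years_per_site=1,
                                                  n_nests=5),
                    mcmc=TINY_MCMC)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", nc.ConvergenceWarning)
            m1 = run_pipeline(PipelineConfig(output_dir=tmp_path / "a", **base))
            m2 = run_pipeline(PipelineConfig(output_dir=tmp_path / "b", **base))
        for name in m1["outputs"]:
            if name == "fit_report":  # carries wall-clock runtime
                continue
            assert m1["outputs"][name]["sha256"] == \
                m2["outputs"][name]["sha256"], name

    def test_files_mode_end_to_end(self, tmp_path):
        paths, sim = _files_fixture(tmp_path)
        cfg = PipelineConfig(rng_seed=2, output_dir=tmp_path / "out",
                             inputs=paths, mcmc=TINY_MCMC)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", nc.ConvergenceWarning)
            man = run_pipeline(cfg)
        series = pd.read_csv(tmp_path / "out" / "observation_series.csv")
        # observed counts should round-trip from the simulated truth
        got = nc.ObservationSeries.from_frame(series)
        np.testing.assert_array_equal(got.y, sim.y)
        table = pd.read_csv(tmp_path / "out" / "driver_table.csv")
        assert table.loc[0, "precip_events"] == 1  # only the S3 event counts
        assert table.loc[0, "tourists"] == 80

    def test_stage_failure_names_stage(self, tmp_path):
        paths, _ = _files_fixture(tmp_path)
        meta = pd.read_csv(paths.site_years)
        meta.loc[0, "first_chick_date"] = ""
        meta.to_csv(paths.site_years, index=False)
        cfg = PipelineConfig(rng_seed=2, output_dir=tmp_path / "out",
                             inputs=paths, mcmc=TINY_MCMC)
        with pytest.raises(PipelineStageError, match="validate"):
            run_pipeline(cfg)
        man = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert man["partial"]


class TestCli:
    def test_simulate_subcommand(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli, ["simulate", "--seed", "4",
                                  "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "observation_series.csv").exists()
        truth = json.loads((tmp_path / "simulation_truth.json").read_text())
        assert len(truth) == 3  # default simulate config: 3 site/years

    def test_phases_subcommand(self, tmp_path):
        rows = []
        for sy in ("a", "b", "c"):
            z = np.linspace(40, 25, 60) + (ord(sy) - 97)
            rows += [{"site_id": sy, "year_id": "2014-15", "day": d + 1,
                      "z_mean": z[d], "z_sd": 1.0} for d in range(60)]
        pd.DataFrame(rows).to_csv(tmp_path / "z.csv", index=False)
        runner = CliRunner()
        res = runner.invoke(cli, ["phases", "--z-trajectories",
                                  str(tmp_path / "z.csv"),
                                  "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert "Friedman" in res.output

    def test_drivers_subcommand(self, tmp_path):
        t = nc.simulate_drivers(12, 1.4, -0.02, 0.1, rng_seed=0)
        df = pd.DataFrame({
            "site_id": t["site_year"], "year_id": "2014-15",
            "bs_obs": t["bs_obs"], "sigma_bs": t["sigma_bs"],
            "precip_events": t["x"].astype(int),
            "krill_catch": np.linspace(100, 1000, 12),
            "tourists": np.arange(12) * 100})
        df.to_csv(tmp_path / "dt.csv", index=False)
        runner = CliRunner()
        res = runner.invoke(cli, ["drivers", "--driver-table",
                                  str(tmp_path / "dt.csv"),
                                  "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        out = pd.read_csv(tmp_path / "driver_regressions.csv")
        assert list(out["covariate"]) == ["precipitation", "krill", "tourism"]
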