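"""Pipeline configuration: schema-validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSettings(_Strict):
    n_sites: int = 3
    n_years_per_site: int = 1
    n_nests: int = 20
    theta_phi: float = 5.293304824724492       # logit(0.995)
    sigma_mu_phi: float = 0.6
    mu_p: float = 1.0
    mu_beta_p: float = 1.5
    sigma_beta_p: float = 0.5
    sigma_nu_p: float = 0.5
    hatch_day: int = 31
    outage_prob: float = 0.0


class InputPaths(_Strict):
    annotations: Path
    detections: Path
    site_years: Path                       # creche/first-chick dates, lon/lat
    precip: Optional[Path] = None
    tourism: Optional[Path] = None
    ssmu_geojson: Optional[Path] = None
    krill_catch: Optional[Path] = None


class PriorSettings(_Strict):
    theta_phi_sd: float = 1.5
    mu_p_sd: float = 1.5
    mu_beta_p_sd: float = 1.5
    sigma_mu_phi_scale: float = 1.0
    sigma_beta_p_scale: float = 1.0
    sigma_nu_p_scale: float = 1.0


class McmcSettings(_Strict):
    preset: Literal["desk", "paper"] = "desk"
    n_chains: Optional[int] = None
    n_warmup: Optional[int] = None
    n_samples: Optional[int] = None
    thin: Optional[int] = None
    rhat_threshold: float = 1.1
    min_ess_per_chain: float = 100.0


class PhaseSettings(_Strict):
    boundaries: tuple[int, int, int] = (30, 45, 60)


class KrillSettings(_Strict):
    radius_km: float = 150.0
    window_start_month: int = 3            # March of year t-1 ...
    window_end_month: int = 1              # ... through January of year t


class PipelineConfig(_Strict):
    """Top-level configuration; exactly one of ``simulation``/``inputs``."""

    rng_seed: int = 0
    output_dir: Path = Path("nestcam-out")
    simulation: Optional[SimulationSettings] = None
    inputs: Optional[InputPaths] = None
    priors: PriorSettings = Field(default_factory=PriorSettings)
    mcmc: McmcSettings = Field(default_factory=McmcSettings)
    phases: PhaseSettings = Field(default_factory=PhaseSettings)
    krill: KrillSettings = Field(default_factory=KrillSettings)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "configure exactly one data source: 'simulation' or 'inputs'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def mcmc_config(self):
        from .survival import PAPER_PRESET, McmcConfig

        base = PAPER_PRESET if self.mcmc.preset == "paper" else McmcConfig()
        kwargs = {
            "n_chains": self.mcmc.n_chains or base.n_chains,
            "n_warmup": self.mcmc.n_warmup or base.n_warmup,
            "n_samples": self.mcmc.n_samples or base.n_samples,
            "thin": self.mcmc.thin or base.thin,
            "rng_seed": self.rng_seed,
            "rhat_threshold": self.mcmc.rhat_threshold,
            "min_ess_per_chain": self.mcmc.min_ess_per_chain,
        }
        return McmcConfig(**kwargs)

    def priors_config(self):
        from .survival import Priors

        return Priors(**self.priors.model_dump())


def dump_yaml(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
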