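"""Pipeline configuration: strict schema, defaults, JSON round-trip."""

from __future__ import annotations

import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from boutonquant.errors import ConfigError
from boutonquant.protocols import StimulusProtocol, default_protocol
from boutonquant.synth.dataset import GeneratorConfig
from boutonquant.synth.models import InfluxModel, SilencingModel
from boutonquant.synth.render import RenderGeometry
from boutonquant.synth.traces import NoiseParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class InfluxSection(_Strict):
    intercept_ca_e: float = 0.47
    slope: float = 39.2
    residual: float = 1.6


class SilencingSection(_Strict):
    kd_sil: float = 25.0
    coeff: float = 1.79
    mode: Literal["probabilistic", "hard-threshold"] = "probabilistic"


class NoiseSection(_Strict):
    read_sd: float = 3.0
    shot_scale: float = 0.05


class RenderSection(_Strict):
    height: int = 96
    width: int = 96
    psf_sigma: float = 1.5
    min_separation: float = 4.0
    background: float = 20.0
    offset: float = 100.0
    edge_margin: int = 5


class ProtocolSection(_Strict):
    """Optional frame-window overrides applied to the modality default."""
    n_ap: Optional[int] = None
    ap_rate: Optional[float] = None
    frame_rate: Optional[float] = None
    baseline_frames: Optional[int] = None
    stim_frame: Optional[int] = None
    peak_start: Optional[int] = None
    peak_len: Optional[int] = None
    trial_frames: Optional[int] = None
    n_trials: Optional[int] = None
    calib_gap: Optional[int] = None
    calib_len: Optional[int] = None


class GeneratorSection(_Strict):
    n_neurons: int = 2
    n_terminals: int = 50
    ca_e_mm: list[float] = [2.0, 1.2, 0.8]
    modality: Literal["physin-gcamp", "vgph", "iglusnfr"] = "physin-gcamp"
    perturbation: float = 0.0
    influx: InfluxSection = InfluxSection()
    silencing: SilencingSection = SilencingSection()
    noise: NoiseSection = NoiseSection()
    protocol: ProtocolSection = ProtocolSection()
    resting_ca_um: float = 0.05
    f_max_mean: float = 2000.0
    f_max_cv: float = 0.25
    neuron_sigma: float = 0.2
    terminal_sigma: float = 0.25
    release_gain_per_nm: float = 0.005
    render: Optional[RenderSection] = None


class QuantificationSection(_Strict):
    low_sigma: float = 1.0
    high_sigma: float = 3.0
    threshold: Optional[float] = None
    min_separation: float = 4.0
    radius: float = 3.0
    max_bg_offset: float = 15.0
    fmax_k: int = 5
    saturation_guard: float = 0.995


class AnalysisSection(_Strict):
    linear_fit: bool = True
    hill_fit: bool = True


class PipelineConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    generator: GeneratorSection = GeneratorSection()
    quantification: QuantificationSection = QuantificationSection()
    analysis: AnalysisSection = AnalysisSection()

    # -- bridges to the runtime objects ---------------------------------------

    def resolved_protocol(self) -> StimulusProtocol:
        proto = default_protocol(self.generator.modality)
        overrides = {k: v for k, v in self.generator.protocol.model_dump().items()
                     if v is not None}
        return proto.with_overrides(**overrides) if overrides else proto

    def generator_config(self, seed: Optional[int] = None) -> GeneratorConfig:
        g = self.generator
        return GeneratorConfig(
            n_neurons=g.n_neurons,
            n_terminals=g.n_terminals,
            ca_e_mm=tuple(g.ca_e_mm),
            modality=g.modality,
            seed=self.seed if seed is None else seed,
            perturbation=g.perturbation,
            influx=InfluxModel(**g.influx.model_dump()),
            silencing=SilencingModel(**g.silencing.model_dump()),
            noise=NoiseParams(**g.noise.model_dump()),
            protocol=self.resolved_protocol(),
            resting_ca_um=g.resting_ca_um,
            f_max_mean=g.f_max_mean,
            f_max_cv=g.f_max_cv,
            neuron_sigma=g.neuron_sigma,
            terminal_sigma=g.terminal_sigma,
            release_gain_per_nm=g.release_gain_per_nm,
            render=RenderGeometry(**g.render.model_dump()) if g.render else None,
        )


def _format_pydantic_error(err: ValidationError) -> list[str]:
    out = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        out.append(f"{loc}: {e['msg']}")
    return out


def load_config(path) -> PipelineConfig:
    """Load, validate and default-fill a pipeline config; unknown keys are
    rejected with every offending field named."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(_format_pydantic_error(err)) from None


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.model_dump(), fh, indent=2, sort_keys=True)
        fh.write("\n")
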