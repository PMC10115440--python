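"""Parametric models underlying the synthetic data: sensor response,
external-Ca²⁺ → influx mapping, and influx → silencing probability."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from boutonquant.errors import ConfigError


@dataclass(frozen=True)
class SensorModel:
    """Fluorescent sensor parameters.

    For Ca²⁺ sensors, ``kd_um``/``rf``/``hill_n`` parameterize the
    equilibrium fluorescence↔concentration mapping
    ``F/F_max = 1/R_f + (1 - 1/R_f) · ca^n / (ca^n + K_d^n)``.
    For the release sensors (vGpH, iGluSnFR) those fields are ``None`` and
    only the kinetic time constants are used.
    """

    name: str
    kd_um: Optional[float]
    rf: Optional[float]
    hill_n: Optional[float]
    tau_rise_s: float
    tau_decay_s: float

    def __post_init__(self) -> None:
        problems = []
        if self.kd_um is not None and self.kd_um <= 0:
            problems.append("kd_um must be positive")
        if self.rf is not None and self.rf <= 1:
            problems.append("rf must exceed 1")
        if self.hill_n is not None and self.hill_n <= 0:
            problems.append("hill_n must be positive")
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            problems.append("time constants must be positive")
        if self.tau_rise_s >= self.tau_decay_s:
            problems.append("tau_rise must be smaller than tau_decay")
        if problems:
            raise ConfigError(problems)

    @property
    def is_calcium(self) -> bool:
        return self.kd_um is not None


# In-vitro GCaMP6f constants: K_d 0.38 µM, R_f 51.8, Hill n 2.3.
GCAMP6F = SensorModel("physin-gcamp", kd_um=0.38, rf=51.8, hill_n=2.3,
                      tau_rise_s=0.05, tau_decay_s=0.5)
# Exo/endocytosis reporter: slow rise over the 10 s train, slow retrieval.
VGPH = SensorModel("vgph", kd_um=None, rf=None, hill_n=None,
                   tau_rise_s=1.0, tau_decay_s=20.0)
# Fast single-AP glutamate transient.
IGLUSNFR = SensorModel("iglusnfr", kd_um=None, rf=None, hill_n=None,
                       tau_rise_s=0.005, tau_decay_s=0.05)

_SENSORS = {s.name: s for s in (GCAMP6F, VGPH, IGLUSNFR)}


def default_sensor(modality: str) -> SensorModel:
    try:
        return _SENSORS[modality]
    except KeyError:
        raise ConfigError([f"unknown modality {modality!r}"]) from None


@dataclass(frozen=True)
class InfluxModel:
    """Piecewise-linear evoked influx versus external Ca²⁺.

    ``delta_ca(ca_e) = max(slope · (ca_e − intercept_ca_e), residual)`` in nM.
    Defaults: x-intercept 0.47 mM, slope 39.2 nM/mM (≈60 nM at 2.0 mM) and a
    1.6 nM residual below the intercept.
    """

    intercept_ca_e: float = 0.47
    slope: float = 39.2
    residual: float = 1.6

    def __post_init__(self) -> None:
        problems = []
        if self.intercept_ca_e < 0:
            problems.append("intercept_ca_e must be non-negative")
        if self.slope <= 0:
            problems.append("slope must be positive")
        if self.residual < 0:
            problems.append("residual must be non-negative")
        elif self.residual > 0.1 * self.slope:
            problems.append("residual must be small relative to slope (< slope/10)")
        if problems:
            raise ConfigError(problems)


@dataclass(frozen=True)
class SilencingModel:
    """Probability of a terminal being silent as a function of influx.

    Decreasing Hill curve with unit maximum at zero influx:
    ``p(Δ) = kd^c / (kd^c + Δ^c)``.  In ``hard-threshold`` mode the draw is
    deterministic: silent iff ``Δ < kd``.
    """

    kd_sil: float = 25.0
    coeff: float = 1.79
    mode: str = "probabilistic"

    def __post_init__(self) -> None:
        problems = []
        if self.kd_sil <= 0:
            problems.append("kd_sil must be positive")
        if self.coeff <= 0:
            problems.append("coeff must be positive")
        if self.mode not in ("probabilistic", "hard-threshold"):
            problems.append("mode must be 'probabilistic' or 'hard-threshold'")
        if problems:
            raise ConfigError(problems)


def influx_at(ca_e, model: InfluxModel):
    """Evoked Δ[Ca²⁺]_i (nM) at external concentration ``ca_e`` (mM).

    Continuous, non-decreasing; raises on non-positive ``ca_e``.
    """
    ca_e = np.asarray(ca_e, dtype=float)
    if np.any(ca_e <= 0):
        raise ValueError("ca_e must be positive (mM)")
    out = np.maximum(model.slope * (ca_e - model.intercept_ca_e), model.residual)
    return out if out.ndim else float(out)


def silencing_probability(delta_ca, model: SilencingModel):
    """Probability that a terminal with influx ``delta_ca`` (nM) is silent."""
    delta = np.asarray(delta_ca, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta_ca must be non-negative (nM)")
    if model.mode == "hard-threshold":
        out = (delta < model.kd_sil).astype(float)
    else:
        with np.errstate(divide="ignore"):
            ratio = np.power(delta / model.kd_sil, model.coeff)
        out = 1.0 / (1.0 + ratio)
    return out if out.ndim else float(out)


def sensor_forward(ca, sensor: SensorModel):
    """Equilibrium fractional fluorescence ``F/F_max`` for free Ca²⁺ ``ca`` (µM).

    Exact algebraic inverse of :func:`boutonquant.metrics.convert_to_calcium`.
    """
    if not sensor.is_calcium:
        raise ValueError(f"{sensor.name} is not a Ca2+ sensor")
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca must be non-negative (µM)")
    inv_rf = 1.0 / sensor.rf
    can = np.power(ca, sensor.hill_n)
    kdn = sensor.kd_um ** sensor.hill_n
    sat = can / (can + kdn)
    out = inv_rf + (1.0 - inv_rf) * sat
    return out if out.ndim else float(out)
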