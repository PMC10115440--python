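"""Per-terminal trace metrics and the fluorescence→Ca²⁺ inversion.

Conventions (all configurable through :class:`StimulusProtocol`):

* baseline = mean of the 49 frames immediately preceding the first stimulus
  frame; sigma_baseline = sample SD (ddof=1) of the same frames;
* peak ΔF = mean of the modality-specific peak window minus the baseline
  (5 frames ending with the AP train for physin-GCaMP/vGpH, 3 frames
  starting at the AP for iGluSnFR);
* silent iff ΔF < sigma_baseline, strictly — equality counts as responding;
* F_max = best k-consecutive-frame mean inside the calibration window;
* [Ca²⁺]_i = K_d ((F/F_max − 1/R_f)/(1 − F/F_max))^(1/n), with a sub-floor
  clamp at F/F_max ≤ 1/R_f and a saturation guard at F/F_max ≥ 0.995.

All scalar operations accept stacked arrays along the leading axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from boutonquant.errors import BoutonQuantError
from boutonquant.protocols import StimulusProtocol
from boutonquant.synth.models import SensorModel

SATURATION_GUARD = 0.995


def _values(trace) -> np.ndarray:
    """Accept a Trace, an array, or a stack of traces (..., n_frames)."""
    return np.asarray(getattr(trace, "values", trace), dtype=float)


def baseline_stats(trace, protocol: StimulusProtocol):
    """Mean and sample SD (ddof=1) of the pre-stimulus baseline frames."""
    v = _values(trace)
    lo, hi = protocol.baseline_window
    if v.shape[-1] < hi:
        raise BoutonQuantError(
            f"trace has {v.shape[-1]} frames; baseline needs at least {hi}")
    win = v[..., lo:hi]
    mean = win.mean(axis=-1)
    sd = win.std(axis=-1, ddof=1) if win.shape[-1] > 1 else np.zeros_like(mean)
    if mean.ndim == 0:
        return float(mean), float(sd)
    return mean, sd


def peak_delta_f(trace, protocol: StimulusProtocol, f_baseline=None):
    """Peak window mean minus the baseline."""
    v = _values(trace)
    lo, hi = protocol.peak_window
    if v.shape[-1] < hi:
        raise BoutonQuantError("peak window extends beyond the trace")
    if f_baseline is None:
        f_baseline, _ = baseline_stats(v, protocol)
    out = v[..., lo:hi].mean(axis=-1) - f_baseline
    return float(out) if np.ndim(out) == 0 else out


def classify_silent(df_peak, sigma_baseline):
    """Silent iff ΔF < sigma_baseline (strict inequality)."""
    df_peak = np.asarray(df_peak, dtype=float)
    sigma = np.asarray(sigma_baseline, dtype=float)
    if np.any(sigma < 0):
        raise BoutonQuantError("sigma_baseline must be non-negative")
    out = df_peak < sigma
    return bool(out) if out.ndim == 0 else out


def estimate_fmax(trace, protocol: StimulusProtocol, k: int = 5):
    """Calibration plateau: maximal mean over k consecutive frames in the
    calibration window."""
    v = _values(trace)
    lo, hi = protocol.calibration_window
    if v.shape[-1] < hi:
        raise BoutonQuantError("calibration window extends beyond the trace")
    win = v[..., lo:hi]
    k = min(k, win.shape[-1])
    sw = np.lib.stride_tricks.sliding_window_view(win, k, axis=-1)
    out = sw.mean(axis=-1).max(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class ConversionResult:
    ca_um: float
    subfloor: bool = False
    saturated: bool = False


def convert_to_calcium(f, f_max, sensor: SensorModel,
                       saturation_guard: Optional[float] = SATURATION_GUARD) -> ConversionResult:
    """Invert the sensor response: fluorescence (a.u.) → [Ca²⁺]_i (µM).

    * ``f/f_max <= 1/R_f``: returns 0 µM with the sub-floor flag;
    * ``f/f_max >= saturation_guard``: returns NaN with the saturated flag
      (pass ``saturation_guard=None`` to disable the guard);
    * non-positive ``f_max`` is an error.
    """
    if not sensor.is_calcium:
        raise BoutonQuantError(f"{sensor.name} does not support Ca2+ conversion")
    if f_max <= 0:
        raise BoutonQuantError("f_max must be positive")
    x = f / f_max
    inv_rf = 1.0 / sensor.rf
    if x <= inv_rf:
        return ConversionResult(0.0, subfloor=True)
    if saturation_guard is not None and x >= saturation_guard:
        return ConversionResult(float("nan"), saturated=True)
    if x >= 1.0:
        return ConversionResult(float("nan"), saturated=True)
    ca = sensor.kd_um * ((x - inv_rf) / (1.0 - x)) ** (1.0 / sensor.hill_n)
    return ConversionResult(float(ca))


def delta_calcium(f_baseline, df_peak, f_max, sensor: SensorModel,
                  saturation_guard: Optional[float] = SATURATION_GUARD):
    """Evoked Δ[Ca²⁺]_i in nM from baseline and peak fluorescence.

    Returns ``(delta_nM, subfloor, saturated)``.  Saturation of the peak
    propagates; a sub-floor baseline clamps the baseline term at 0 µM.
    """
    base = convert_to_calcium(f_baseline, f_max, sensor, saturation_guard)
    peak = convert_to_calcium(f_baseline + df_peak, f_max, sensor, saturation_guard)
    if base.saturated or peak.saturated:
        return float("nan"), False, True
    return 1000.0 * (peak.ca_um - base.ca_um), base.subfloor or peak.subfloor, False


def normalize_response(df_peak, reference):
    """Dimensionless response: ΔF over the modality reference
    (ΔF_NH4Cl = F_max − F_baseline for vGpH; F_max for iGluSnFR)."""
    if reference <= 0:
        raise BoutonQuantError("normalization reference must be positive")
    return df_peak / reference


def split_trials(values: np.ndarray, protocol: StimulusProtocol) -> np.ndarray:
    """Reshape the trial portion of a full trace into (n_trials, trial_frames)."""
    v = np.asarray(values, dtype=float)
    n = protocol.n_trials * protocol.trial_frames
    if v.shape[-1] < n:
        raise BoutonQuantError("trace shorter than the trial block span")
    return v[..., :n].reshape(*v.shape[:-1], protocol.n_trials, protocol.trial_frames)


def quantify_traces(traces: np.ndarray, protocol: StimulusProtocol,
                    sensor: SensorModel, terminal_ids=None, neuron_id: str = "",
                    condition: float = float("nan"),
                    saturation_guard: Optional[float] = SATURATION_GUARD,
                    fmax_k: int = 5) -> pd.DataFrame:
    """Quantify a (n_terminals, total_frames) trace block into a measurement table.

    Multi-trial recordings are trial-averaged before baseline/peak metrics;
    F_max always comes from the calibration epoch of the full trace.  Columns
    follow the measurement-table interface; ``usable`` is False when
    F_max does not exceed the baseline or a normalization reference is
    non-positive.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[0]
    if terminal_ids is None:
        terminal_ids = [f"t{i:04d}" for i in range(n)]
    trial_avg = split_trials(traces, protocol).mean(axis=-2)
    f_base, sigma = baseline_stats(trial_avg, protocol)
    df_peak = peak_delta_f(trial_avg, protocol, f_baseline=f_base)
    f_max = estimate_fmax(traces, protocol, k=fmax_k)
    silent = classify_silent(df_peak, sigma)
    f_base, sigma, df_peak, f_max, silent = (
        np.atleast_1d(f_base), np.atleast_1d(sigma), np.atleast_1d(df_peak),
        np.atleast_1d(f_max), np.atleast_1d(silent))

    rows = []
    for i in range(n):
        usable = f_max[i] > f_base[i]
        resp_norm = np.nan
        delta = np.nan
        subfloor = False
        saturated = False
        if usable:
            if protocol.modality == "vgph":
                resp_norm = normalize_response(df_peak[i], f_max[i] - f_base[i])
            elif protocol.modality == "iglusnfr":
                resp_norm = normalize_response(df_peak[i], f_max[i])
            elif not silent[i]:
                delta, subfloor, saturated = delta_calcium(
                    f_base[i], df_peak[i], f_max[i], sensor, saturation_guard)
        rows.append({
            "neuron_id": neuron_id, "terminal_id": terminal_ids[i],
            "condition_mM": condition, "modality": protocol.modality,
            "f_baseline": f_base[i], "sigma_baseline": sigma[i],
            "df_peak": df_peak[i], "f_max": f_max[i],
            "silent": bool(silent[i]), "response_norm": resp_norm,
            "delta_ca_nM": delta, "saturated": saturated,
            "subfloor": subfloor, "usable": bool(usable),
        })
    return pd.DataFrame(rows)
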