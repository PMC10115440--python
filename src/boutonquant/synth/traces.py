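"""Forward simulation of per-terminal fluorescence traces.

The noiseless trace is built in units of ``F/F_max`` (fraction of the
terminal's saturated fluorescence) and then scaled by the terminal's
``f_max``.  Kinetics: a first-order saturating rise toward the evoked
plateau during the AP train and a single-exponential decay afterwards;
for the single-AP sensor, a normalized bi-exponential impulse response.
The calibration epoch ramps briefly and then sits exactly at ``F/F_max = 1``
(ionomycin / NH4Cl / saturating glutamate, depending on the modality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from boutonquant.errors import ConfigError
from boutonquant.protocols import StimulusProtocol
from boutonquant.synth.models import SensorModel, sensor_forward

# fraction of f_max at rest for the release sensors (surface/unquenched pool)
BASELINE_FRACTION = {"vgph": 0.05, "iglusnfr": 0.10}

_CAL_RAMP_FRAMES = 5


@dataclass(frozen=True)
class NoiseParams:
    """Additive read noise plus signal-scaled (shot-like) Gaussian noise.

    ``noisy = clean + N(0, read_sd) + N(0, sqrt(shot_scale * clean))``
    """

    read_sd: float = 3.0
    shot_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.read_sd < 0 or self.shot_scale < 0:
            raise ConfigError(["noise amplitudes must be non-negative"])


def transient_profile(protocol: StimulusProtocol, sensor: SensorModel,
                      n_extra_frames: int = 0) -> np.ndarray:
    """Unit-amplitude response profile over one trial block.

    Returns ``g`` sampled at frame centers, ``trial_frames + n_extra_frames``
    long (the extra frames continue the decay, used to fill the gap before
    the calibration epoch).  ``g`` peaks at 1 for the train-stimulated
    sensors and is normalized to unit peak for the impulse response.
    """
    n = protocol.trial_frames + n_extra_frames
    t = (np.arange(n) + 0.5) / protocol.frame_rate
    t0 = protocol.stim_frame / protocol.frame_rate
    g = np.zeros(n)
    if protocol.modality == "iglusnfr":
        dt = t - t0
        m = dt > 0
        tr, td = sensor.tau_rise_s, sensor.tau_decay_s
        tpk = tr * td / (td - tr) * np.log(td / tr)
        norm = np.exp(-tpk / td) - np.exp(-tpk / tr)
        g[m] = (np.exp(-dt[m] / td) - np.exp(-dt[m] / tr)) / norm
    else:
        t_end = t0 + protocol.train_duration
        rising = (t >= t0) & (t < t_end)
        g[rising] = 1.0 - np.exp(-(t[rising] - t0) / sensor.tau_rise_s)
        g_end = 1.0 - np.exp(-protocol.train_duration / sensor.tau_rise_s)
        falling = t >= t_end
        g[falling] = g_end * np.exp(-(t[falling] - t_end) / sensor.tau_decay_s)
    return g


def fluorescence_fraction(delta_ca_nm, resp_norm, silent, resting_ca_um,
                          protocol: StimulusProtocol, sensor: SensorModel) -> np.ndarray:
    """Noiseless ``F/F_max`` matrix, one row per terminal.

    ``delta_ca_nm``, ``resp_norm``, ``silent`` and ``resting_ca_um`` are
    broadcastable 1-D arrays.  Silent terminals evoke no transient.
    """
    delta = np.atleast_1d(np.asarray(delta_ca_nm, dtype=float)).copy()
    silent = np.atleast_1d(np.asarray(silent, dtype=bool))
    resting = np.broadcast_to(np.atleast_1d(np.asarray(resting_ca_um, dtype=float)),
                              delta.shape)
    delta[silent] = 0.0

    g_trial = transient_profile(protocol, sensor)
    g_last = transient_profile(protocol, sensor, n_extra_frames=protocol.calib_gap)
    g_full = np.concatenate([np.tile(g_trial, protocol.n_trials - 1), g_last])

    if protocol.modality == "physin-gcamp":
        ca = resting[:, None] + (delta[:, None] / 1000.0) * g_full[None, :]
        frac = sensor_forward(ca, sensor)
    else:
        base = BASELINE_FRACTION[protocol.modality]
        amp = np.atleast_1d(np.asarray(resp_norm, dtype=float)).copy()
        amp[silent] = 0.0
        frac = base + amp[:, None] * (1.0 - base) * g_full[None, :]

    # calibration epoch: short ramp to saturation, then exactly F/F_max = 1
    ramp = min(_CAL_RAMP_FRAMES, protocol.calib_len - 1)
    start_vals = frac[:, -1]
    plateau = np.ones((frac.shape[0], protocol.calib_len))
    if ramp > 0:
        plateau[:, :ramp] = np.linspace(start_vals, 1.0, ramp + 1, axis=1)[:, 1:]
    out = np.concatenate([frac, plateau], axis=1)
    assert out.shape[1] == protocol.total_frames
    return out


def add_noise(clean: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    """Apply the read + shot-like noise model; exact identity at zero amplitudes."""
    shot_sd = np.sqrt(noise.shot_scale * np.clip(clean, 0.0, None))
    return (clean
            + rng.standard_normal(clean.shape) * noise.read_sd
            + rng.standard_normal(clean.shape) * shot_sd)


def simulate_terminal_trace(terminal, condition: float, protocol: StimulusProtocol,
                            sensor: SensorModel, noise: NoiseParams = NoiseParams(),
                            rng: np.random.Generator | None = None):
    """Simulate one terminal at one external-Ca²⁺ condition.

    Returns ``(clean, noisy)`` traces in arbitrary fluorescence units.
    ``condition`` must be one of the terminal's keyed conditions
    (raises ``KeyError`` otherwise).
    """
    delta = terminal.delta_ca_true[condition]
    silent = terminal.silent_true[condition]
    resp = terminal.resp_norm_true[condition]
    frac = fluorescence_fraction([delta], [resp], [silent],
                                 [terminal.resting_ca_um], protocol, sensor)
    clean = terminal.f_max * frac[0]
    if rng is None:
        rng = np.random.default_rng()
    noisy = add_noise(clean, noise, rng)
    return clean, noisy
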