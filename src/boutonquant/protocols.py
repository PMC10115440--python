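"""Stimulus/epoch protocols for the three sensor modalities.

A recording is laid out as ``n_trials`` identical trial blocks followed by a
gap and a saturating-calibration epoch::

    [trial 0][trial 1]...[trial n-1][gap][calibration]

Each trial block holds a pre-stimulus baseline, the AP train and a recovery
tail.  Frames are 0-based; frame ``i`` spans ``[i/frame_rate, (i+1)/frame_rate)``
and trace values are sampled at frame centers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

from boutonquant.errors import ConfigError

MODALITIES = ("physin-gcamp", "vgph", "iglusnfr")


@dataclass(frozen=True)
class StimulusProtocol:
    """Frame-window definitions for one sensor modality.

    Parameters
    ----------
    modality:
        One of ``physin-gcamp``, ``vgph``, ``iglusnfr``.
    n_ap, ap_rate:
        Action-potential count and train frequency (Hz).
    frame_rate:
        Acquisition rate (Hz); defaults are 50, 5 and 100 Hz for the three
        modalities respectively.
    baseline_frames:
        Pre-stimulus frames used for baseline mean/SD (default 49).
    stim_frame:
        0-based index of the first stimulus frame within a trial.
    peak_start, peak_len:
        Peak window within a trial: 5 frames ending with the AP train for
        the train-stimulated sensors, 3 frames starting at the AP for the
        single-AP sensor.
    trial_frames:
        Total frames per trial block.
    n_trials:
        Number of repeated trial blocks (averaged downstream).
    calib_gap, calib_len:
        Frames between the last trial and the calibration window, and the
        calibration window length.
    """

    modality: str
    n_ap: int
    ap_rate: float
    frame_rate: float
    baseline_frames: int
    stim_frame: int
    peak_start: int
    peak_len: int
    trial_frames: int
    n_trials: int
    calib_gap: int
    calib_len: int

    def __post_init__(self) -> None:
        problems = []
        if self.modality not in MODALITIES:
            problems.append(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.frame_rate <= 0:
            problems.append("frame_rate must be positive")
        if self.n_ap < 1 or self.ap_rate <= 0:
            problems.append("n_ap >= 1 and ap_rate > 0 required")
        if not (0 < self.baseline_frames <= self.stim_frame):
            problems.append("baseline must fit before the first stimulus frame")
        if self.peak_start < self.stim_frame:
            problems.append("peak window must not precede the stimulus")
        if self.peak_start + self.peak_len > self.trial_frames:
            problems.append("peak window must lie within the trial")
        if self.n_trials < 1 or self.calib_len < 1 or self.calib_gap < 0:
            problems.append("n_trials >= 1, calib_len >= 1, calib_gap >= 0 required")
        if problems:
            raise ConfigError(problems)

    # -- derived frame spans -------------------------------------------------

    @property
    def total_frames(self) -> int:
        return self.n_trials * self.trial_frames + self.calib_gap + self.calib_len

    @property
    def baseline_window(self) -> tuple[int, int]:
        """(start, stop) of the baseline frames within a trial."""
        return (self.stim_frame - self.baseline_frames, self.stim_frame)

    @property
    def peak_window(self) -> tuple[int, int]:
        return (self.peak_start, self.peak_start + self.peak_len)

    @property
    def calibration_window(self) -> tuple[int, int]:
        start = self.n_trials * self.trial_frames + self.calib_gap
        return (start, start + self.calib_len)

    @property
    def train_duration(self) -> float:
        """AP train duration in seconds."""
        return self.n_ap / self.ap_rate

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def with_overrides(self, **kwargs) -> "StimulusProtocol":
        return replace(self, **kwargs)


def default_protocol(modality: str) -> StimulusProtocol:
    """Default frame-window layout for one modality.

    physin-GCaMP: 20 AP at 20 Hz, 50 Hz frames, ionomycin calibration.
    vGpH: 200 AP at 20 Hz, 5 Hz frames, NH4Cl calibration.
    iGluSnFR: 1 AP x 15 trials, 100 Hz frames, glutamate calibration.
    """
    if modality == "physin-gcamp":
        # train covers frames 49..98 (1 s at 50 Hz); peak = last 5 train frames
        return StimulusProtocol(
            modality=modality, n_ap=20, ap_rate=20.0, frame_rate=50.0,
            baseline_frames=49, stim_frame=49, peak_start=94, peak_len=5,
            trial_frames=150, n_trials=1, calib_gap=10, calib_len=40,
        )
    if modality == "vgph":
        # train covers frames 49..98 (10 s at 5 Hz); peak = last 5 train frames
        return StimulusProtocol(
            modality=modality, n_ap=200, ap_rate=20.0, frame_rate=5.0,
            baseline_frames=49, stim_frame=49, peak_start=94, peak_len=5,
            trial_frames=125, n_trials=1, calib_gap=5, calib_len=20,
        )
    if modality == "iglusnfr":
        # single AP per trial; peak = 3 frames starting at the AP frame
        return StimulusProtocol(
            modality=modality, n_ap=1, ap_rate=20.0, frame_rate=100.0,
            baseline_frames=49, stim_frame=49, peak_start=49, peak_len=3,
            trial_frames=100, n_trials=15, calib_gap=20, calib_len=80,
        )
    raise ConfigError([f"unknown modality {modality!r}"])
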