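"""Assembly of complete ground-truth datasets.

``generate_dataset`` draws per-neuron and per-terminal heterogeneity,
computes per-condition influx, applies the (optionally perturbed) silencing
model with a single uniform draw per terminal reused across conditions (so a
terminal silent at one concentration stays silent at every lower one),
simulates sensor traces, and optionally renders movies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from boutonquant.errors import ConfigError, GenerationError
from boutonquant.protocols import StimulusProtocol, default_protocol, MODALITIES
from boutonquant.synth.models import (
    InfluxModel,
    SensorModel,
    SilencingModel,
    default_sensor,
    influx_at,
    silencing_probability,
)
from boutonquant.synth.render import RenderGeometry, render_movie
from boutonquant.synth.traces import NoiseParams, add_noise, fluorescence_fraction

# spawn-key name spaces for child RNG streams (stable across config changes)
_STREAM_TERMINALS = 1
_STREAM_TRACES = 2
_STREAM_RENDER = 3

# cap on the fraction of the vesicle pool / sensor range a response may occupy
_MAX_RESP_FRACTION = 0.95


@dataclass
class GroundTruthTerminal:
    """Ground truth for one terminal: geometry, calibration and per-condition
    influx / silencing / normalized-response values keyed by [Ca²⁺]_e (mM)."""

    terminal_id: str
    neuron_id: str
    position: Optional[tuple[float, float]]  # (x, y) pixels, None for trace-only
    f_max: float
    resting_ca_um: float
    delta_ca_true: dict[float, float]
    silent_true: dict[float, bool]
    resp_norm_true: dict[float, float]
    u_sil: float = float("nan")  # the reused silencing draw (diagnostics)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate a dataset reproducibly."""

    n_neurons: int = 9
    n_terminals: int = 200
    ca_e_mm: tuple[float, ...] = (2.0, 1.2, 0.8, 0.4)
    modality: str = "physin-gcamp"
    seed: int = 0
    perturbation: float = 0.0  # fractional influx reduction (GPCR agonism emulation)
    influx: InfluxModel = field(default_factory=InfluxModel)
    silencing: SilencingModel = field(default_factory=SilencingModel)
    noise: NoiseParams = field(default_factory=NoiseParams)
    sensor: Optional[SensorModel] = None
    protocol: Optional[StimulusProtocol] = None
    resting_ca_um: float = 0.05
    f_max_mean: float = 2000.0
    f_max_cv: float = 0.25
    neuron_sigma: float = 0.2       # lognormal sigma of per-neuron influx factor
    terminal_sigma: float = 0.25    # lognormal sigma of per-terminal influx factor
    release_gain_per_nm: float = 0.005  # pool fraction released per nM influx
    render: Optional[RenderGeometry] = None  # None => trace-only fast path

    def validate(self) -> None:
        problems = []
        if self.n_neurons < 1:
            problems.append("n_neurons must be >= 1")
        if self.n_terminals < 1:
            problems.append("n_terminals must be >= 1")
        if len(self.ca_e_mm) == 0 or any(c <= 0 for c in self.ca_e_mm):
            problems.append("ca_e_mm must be non-empty with positive concentrations")
        if len(set(self.ca_e_mm)) != len(self.ca_e_mm):
            problems.append("ca_e_mm conditions must be distinct")
        if not (0.0 <= self.perturbation < 1.0):
            problems.append("perturbation must lie in [0, 1)")
        if self.modality not in MODALITIES:
            problems.append(f"modality must be one of {MODALITIES}")
        if self.resting_ca_um <= 0:
            problems.append("resting_ca_um must be positive")
        if self.f_max_mean <= 0 or self.f_max_cv < 0:
            problems.append("f_max_mean must be positive and f_max_cv non-negative")
        if self.neuron_sigma < 0 or self.terminal_sigma < 0:
            problems.append("heterogeneity sigmas must be non-negative")
        if self.release_gain_per_nm <= 0:
            problems.append("release_gain_per_nm must be positive")
        if self.protocol is not None and self.protocol.modality != self.modality:
            problems.append("protocol modality does not match config modality")
        if self.sensor is not None and self.sensor.name != self.modality:
            problems.append("sensor does not match config modality")
        if problems:
            raise ConfigError(problems)

    def resolved_protocol(self) -> StimulusProtocol:
        return self.protocol or default_protocol(self.modality)

    def resolved_sensor(self) -> SensorModel:
        return self.sensor or default_sensor(self.modality)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ca_e_mm"] = list(self.ca_e_mm)
        d["protocol"] = self.resolved_protocol().to_dict()
        d["sensor"] = dataclasses.asdict(self.resolved_sensor())
        return d


@dataclass
class SyntheticRecording:
    """One neuron at one condition: per-terminal traces and/or a movie."""

    neuron_id: str
    condition: float
    terminal_ids: list[str]
    clean: np.ndarray              # (n_terminals, n_frames) noiseless a.u.
    noisy: np.ndarray              # (n_terminals, n_frames) with noise
    movie: Optional[np.ndarray] = None  # (n_frames, H, W) uint16
    positions: Optional[np.ndarray] = None  # (n_terminals, 2) as (x, y)


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    protocol: StimulusProtocol
    sensor: SensorModel
    terminals: list[GroundTruthTerminal]
    ground_truth: pd.DataFrame
    recordings: list[SyntheticRecording]
    manifest: dict


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _lognormal_unit_mean(rng, sigma: float, size=None):
    """Lognormal factor with mean exactly 1."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def _place_positions(rng: np.random.Generator, geom: RenderGeometry, n: int) -> np.ndarray:
    """Jittered-grid spot placement honoring the minimum separation."""
    spacing = geom.min_separation + 1.0
    m = geom.edge_margin + 0.5  # jitter is +-0.5, keep inside the render margin
    xs = np.arange(m, geom.width - 1 - m + 1e-9, spacing)
    ys = np.arange(m, geom.height - 1 - m + 1e-9, spacing)
    if len(xs) * len(ys) < n:
        raise GenerationError(
            f"cannot place {n} spots with separation {geom.min_separation} "
            f"in a {geom.height}x{geom.width} image")
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    idx = rng.choice(len(grid), size=n, replace=False)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    return grid[idx] + jitter


def generate_dataset(config: GeneratorConfig, truth_only: bool = False) -> SyntheticDataset:
    """Generate a complete synthetic dataset.

    Child RNG streams are spawned per neuron (and per neuron x condition for
    trace noise) from the global seed, so increasing ``n_neurons`` leaves
    earlier neurons' data unchanged.  With ``truth_only`` no traces or movies
    are simulated (cheap structural checks).
    """
    config.validate()
    protocol = config.resolved_protocol()
    sensor = config.resolved_sensor()
    conditions = list(config.ca_e_mm)
    pert_factor = 1.0 - config.perturbation
    fmax_sigma = float(np.sqrt(np.log1p(config.f_max_cv ** 2)))

    terminals: list[GroundTruthTerminal] = []
    recordings: list[SyntheticRecording] = []
    rows = []
    for i in range(config.n_neurons):
        neuron_id = f"n{i:03d}"
        rng = _child_rng(config.seed, _STREAM_TERMINALS, i)
        nf = _lognormal_unit_mean(rng, config.neuron_sigma)
        tf = _lognormal_unit_mean(rng, config.terminal_sigma, config.n_terminals)
        f_max = config.f_max_mean * _lognormal_unit_mean(rng, fmax_sigma, config.n_terminals)
        u = rng.uniform(size=config.n_terminals)
        positions = None
        if config.render is not None:
            positions = _place_positions(rng, config.render, config.n_terminals)

        delta_by_cond, silent_by_cond, resp_by_cond = {}, {}, {}
        for c in conditions:
            delta = influx_at(c, config.influx) * nf * tf * pert_factor
            if config.silencing.mode == "hard-threshold":
                silent = delta < config.silencing.kd_sil
            else:
                silent = u < silencing_probability(delta, config.silencing)
            resp = np.clip(config.release_gain_per_nm * delta, 0.0, _MAX_RESP_FRACTION)
            delta_by_cond[c], silent_by_cond[c], resp_by_cond[c] = delta, silent, resp

        neuron_terminals = []
        for j in range(config.n_terminals):
            term = GroundTruthTerminal(
                terminal_id=f"{neuron_id}_t{j:04d}",
                neuron_id=neuron_id,
                position=tuple(positions[j]) if positions is not None else None,
                f_max=float(f_max[j]),
                resting_ca_um=config.resting_ca_um,
                delta_ca_true={c: float(delta_by_cond[c][j]) for c in conditions},
                silent_true={c: bool(silent_by_cond[c][j]) for c in conditions},
                resp_norm_true={c: float(resp_by_cond[c][j]) for c in conditions},
                u_sil=float(u[j]),
            )
            neuron_terminals.append(term)
            for c in conditions:
                rows.append({
                    "terminal_id": term.terminal_id,
                    "neuron_id": neuron_id,
                    "x": term.position[0] if term.position else np.nan,
                    "y": term.position[1] if term.position else np.nan,
                    "f_max": term.f_max,
                    "condition_mM": c,
                    "delta_ca_true_nM": term.delta_ca_true[c],
                    "silent_true": term.silent_true[c],
                    "resp_norm_true": term.resp_norm_true[c],
                })
        terminals.extend(neuron_terminals)

        if truth_only:
            continue
        for ci, c in enumerate(conditions):
            frac = fluorescence_fraction(
                delta_by_cond[c], resp_by_cond[c], silent_by_cond[c],
                np.full(config.n_terminals, config.resting_ca_um), protocol, sensor)
            clean = f_max[:, None] * frac
            rng_tr = _child_rng(config.seed, _STREAM_TRACES, i, ci)
            rec = SyntheticRecording(
                neuron_id=neuron_id, condition=c,
                terminal_ids=[t.terminal_id for t in neuron_terminals],
                clean=clean, noisy=add_noise(clean, config.noise, rng_tr),
                positions=positions,
            )
            if config.render is not None:
                rng_mv = _child_rng(config.seed, _STREAM_RENDER, i, ci)
                rec.movie = render_movie(positions, clean, config.render,
                                         noise=config.noise, rng=rng_mv)
            recordings.append(rec)

    ground_truth = pd.DataFrame(rows)
    manifest = {"generator": config.to_dict(), "seed": config.seed,
                "n_recordings": len(recordings), "truth_only": truth_only}
    return SyntheticDataset(config=config, protocol=protocol, sensor=sensor,
                            terminals=terminals, ground_truth=ground_truth,
                            recordings=recordings, manifest=manifest)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write a dataset to disk (TIFF movies or per-recording trace CSVs,
    ground-truth CSV, protocol and manifest JSON).  Returns a file map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    files = {}
    gt_path = os.path.join(outdir, "ground_truth.csv")
    ds.ground_truth.to_csv(gt_path, index=False)
    files["ground_truth"] = gt_path

    index = []
    for rec in ds.recordings:
        ci = list(ds.config.ca_e_mm).index(rec.condition)
        stem = f"{rec.neuron_id}_c{ci}"
        if rec.movie is not None:
            import tifffile

            path = os.path.join(outdir, f"movie_{stem}.tif")
            tifffile.imwrite(path, rec.movie)
        else:
            path = os.path.join(outdir, f"traces_{stem}.csv")
            df = pd.DataFrame(rec.noisy.T, columns=rec.terminal_ids)
            df.insert(0, "frame", np.arange(rec.noisy.shape[1]))
            df.to_csv(path, index=False)
        index.append({"neuron_id": rec.neuron_id, "condition_mM": rec.condition,
                      "file": os.path.basename(path),
                      "kind": "movie" if rec.movie is not None else "traces"})

    ds.protocol.to_json(os.path.join(outdir, "protocol.json"))
    files["protocol"] = os.path.join(outdir, "protocol.json")
    manifest = dict(ds.manifest)
    manifest["recordings"] = index
    man_path = os.path.join(outdir, "dataset_manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = man_path
    return files
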