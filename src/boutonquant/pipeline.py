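"""Stage orchestration: simulate → quantify → analyze.

Each stage writes its outputs atomically (staged in a temporary directory,
moved into place on success), records a deterministic manifest (tool
version, config hash, seed, input/output digests) and logs every excluded
terminal with a machine-readable reason code.  Wall-clock timestamps go to
the log only, so identical config + seed reproduce bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
import tempfile

import numpy as np
import pandas as pd

from boutonquant._version import __version__
from boutonquant.config import PipelineConfig, save_config
from boutonquant.errors import BoutonQuantError, FitError, MissingArtifactError
from boutonquant.protocols import StimulusProtocol
from boutonquant.report import dump_json, silent_fraction_recovery, write_report
from boutonquant import dose, metrics, roi as roi_mod
from boutonquant.synth.dataset import generate_dataset, write_dataset
from boutonquant.synth.models import default_sensor

log = logging.getLogger("boutonquant")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_manifest(outdir: str, stage: str, cfg: PipelineConfig, seed: int,
                    inputs: dict[str, str]) -> dict:
    outputs = {}
    for name in sorted(os.listdir(outdir)):
        p = os.path.join(outdir, name)
        if os.path.isfile(p) and name != "stage_manifest.json":
            outputs[name] = _sha256(p)
    manifest = {
        "stage": stage, "tool_version": __version__, "seed": seed,
        "config_sha256": _config_hash(cfg), "inputs": inputs, "outputs": outputs,
    }
    dump_json(manifest, os.path.join(outdir, "stage_manifest.json"))
    return manifest


class _atomic_stage:
    """Stage outputs land in a temp dir and move into place only on success."""

    def __init__(self, outdir: str):
        self.outdir = outdir

    def __enter__(self) -> str:
        parent = os.path.dirname(os.path.abspath(self.outdir)) or "."
        os.makedirs(parent, exist_ok=True)
        self.tmp = tempfile.mkdtemp(prefix=".stage-", dir=parent)
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> bool:
        if exc_type is not None:
            shutil.rmtree(self.tmp, ignore_errors=True)
            return False
        os.makedirs(self.outdir, exist_ok=True)
        for name in os.listdir(self.tmp):
            os.replace(os.path.join(self.tmp, name), os.path.join(self.outdir, name))
        os.rmdir(self.tmp)
        return False


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig, outdir: str, seed: int | None = None,
                 traces_only: bool = False) -> dict:
    seed = cfg.seed if seed is None else seed
    gen_cfg = cfg.generator_config(seed=seed)
    if traces_only and gen_cfg.render is not None:
        gen_cfg = dataclasses.replace(gen_cfg, render=None)
    log.info("simulate: %d neurons x %d terminals x %d conditions (%s)",
             gen_cfg.n_neurons, gen_cfg.n_terminals, len(gen_cfg.ca_e_mm),
             "traces-only" if gen_cfg.render is None else "movies")
    with _atomic_stage(outdir) as tmp:
        ds = generate_dataset(gen_cfg)
        write_dataset(ds, tmp)
        save_config(cfg, os.path.join(tmp, "resolved_config.json"))
        manifest = _write_manifest(tmp, "simulate", cfg, seed, inputs={})
    return manifest


# ---------------------------------------------------------------------------
# quantify
# ---------------------------------------------------------------------------

def _require(path: str) -> str:
    if not os.path.exists(path):
        raise MissingArtifactError(f"expected upstream artifact missing: {path}")
    return path


def _quantify_movie(movie: np.ndarray, protocol: StimulusProtocol, sensor,
                    q, neuron_id: str, condition: float):
    """Detect ROIs on the baseline-epoch mean image and quantify all traces."""
    lo, hi = protocol.baseline_window
    reference = movie[lo:hi].astype(float).mean(axis=0)
    terminals = roi_mod.detect_puncta(
        reference, low_sigma=q.low_sigma, high_sigma=q.high_sigma,
        threshold=q.threshold, min_separation=q.min_separation, radius=q.radius)
    terminals, backgrounds, excluded = roi_mod.place_background_rois(
        terminals, reference.shape, max_offset=q.max_bg_offset)
    bg_by_id = {b.roi_id: b for b in backgrounds}
    corrected, ids = [], []
    exclusions = [{"neuron_id": neuron_id, "condition_mM": condition,
                   "roi_id": rid, "reason": "no_background_position"}
                  for rid in excluded]
    for r in terminals:
        if r.partner is None:
            continue
        t_tr = roi_mod.extract_trace(movie, r, protocol.frame_rate)
        b_tr = roi_mod.extract_trace(movie, bg_by_id[r.partner], protocol.frame_rate)
        corrected.append(roi_mod.background_correct(t_tr, b_tr).values)
        ids.append(r.roi_id)
    if not corrected:
        return pd.DataFrame(), roi_mod.rois_to_frame(terminals + backgrounds), exclusions
    meas = metrics.quantify_traces(
        np.asarray(corrected), protocol, sensor, terminal_ids=ids,
        neuron_id=neuron_id, condition=condition,
        saturation_guard=q.saturation_guard, fmax_k=q.fmax_k)
    return meas, roi_mod.rois_to_frame(terminals + backgrounds), exclusions


def run_quantify(indir: str, cfg: PipelineConfig, outdir: str) -> dict:
    man_path = _require(os.path.join(indir, "dataset_manifest.json"))
    with open(man_path) as fh:
        ds_manifest = json.load(fh)
    protocol = StimulusProtocol.from_json(_require(os.path.join(indir, "protocol.json")))
    sensor = default_sensor(protocol.modality)
    q = cfg.quantification
    inputs = {"dataset_manifest.json": _sha256(man_path)}

    with _atomic_stage(outdir) as tmp:
        all_meas, all_rois, exclusions = [], [], []
        for rec in ds_manifest["recordings"]:
            path = _require(os.path.join(indir, rec["file"]))
            nid, cond = rec["neuron_id"], float(rec["condition_mM"])
            if rec["kind"] == "movie":
                import tifffile

                movie = tifffile.imread(path)
                meas, rois_df, excl = _quantify_movie(movie, protocol, sensor,
                                                      q, nid, cond)
                rois_df.insert(0, "neuron_id", nid)
                rois_df.insert(1, "condition_mM", cond)
                all_rois.append(rois_df)
                exclusions.extend(excl)
            else:
                df = pd.read_csv(path)
                ids = [c for c in df.columns if c != "frame"]
                traces = df[ids].to_numpy(dtype=float).T
                meas = metrics.quantify_traces(
                    traces, protocol, sensor, terminal_ids=ids, neuron_id=nid,
                    condition=cond, saturation_guard=q.saturation_guard,
                    fmax_k=q.fmax_k)
            if not meas.empty:
                for _, row in meas[~meas["usable"]].iterrows():
                    exclusions.append({"neuron_id": nid, "condition_mM": cond,
                                       "roi_id": row["terminal_id"],
                                       "reason": "fmax_not_above_baseline"})
                all_meas.append(meas)
        measurements = (pd.concat(all_meas, ignore_index=True)
                        if all_meas else pd.DataFrame())
        measurements.to_csv(os.path.join(tmp, "measurements.csv"), index=False)
        if all_rois:
            pd.concat(all_rois, ignore_index=True).to_csv(
                os.path.join(tmp, "rois.csv"), index=False)
        pd.DataFrame(exclusions, columns=["neuron_id", "condition_mM", "roi_id",
                                          "reason"]).to_csv(
            os.path.join(tmp, "exclusions.csv"), index=False)
        for rid in exclusions:
            log.warning("excluded %s (%s)", rid["roi_id"], rid["reason"])
        gt = os.path.join(indir, "ground_truth.csv")
        if os.path.exists(gt):
            shutil.copyfile(gt, os.path.join(tmp, "ground_truth.csv"))
        save_config(cfg, os.path.join(tmp, "resolved_config.json"))
        manifest = _write_manifest(tmp, "quantify", cfg, cfg.seed, inputs)
    return manifest


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def run_analyze(indir: str, cfg: PipelineConfig, outdir: str) -> dict:
    meas_path = _require(os.path.join(indir, "measurements.csv"))
    try:
        measurements = pd.read_csv(meas_path)
    except pd.errors.EmptyDataError:
        raise BoutonQuantError("measurement table is empty; nothing to analyze") from None
    if measurements.empty:
        raise BoutonQuantError("measurement table is empty; nothing to analyze")
    inputs = {"measurements.csv": _sha256(meas_path)}

    with _atomic_stage(outdir) as tmp:
        per_neuron, across = dose.summarize_condition(measurements)
        per_neuron.to_csv(os.path.join(tmp, "summary_per_neuron.csv"), index=False)
        across.to_csv(os.path.join(tmp, "summary_across_neurons.csv"), index=False)
        dose.ecdf_by_class(measurements).to_csv(
            os.path.join(tmp, "ecdf_by_class.csv"), index=False)

        conds = sorted(across["condition_mM"], reverse=True)
        slopes = []
        for hi_c, lo_c in zip(conds, conds[1:]):
            f_hi = 100.0 * float(across.loc[across["condition_mM"] == hi_c,
                                            "silent_fraction_mean"].iloc[0])
            f_lo = 100.0 * float(across.loc[across["condition_mM"] == lo_c,
                                            "silent_fraction_mean"].iloc[0])
            slopes.append({"ca_low_mM": lo_c, "ca_high_mM": hi_c,
                           "slope_pct_per_mM": dose.silencing_slope(
                               f_lo, f_hi, lo_c, hi_c)})

        fits = None
        if cfg.analysis.linear_fit or cfg.analysis.hill_fit:
            fits = {"linear": None, "hill": None}
            pts = per_neuron.dropna(subset=["responder_mean_delta_ca"])
            if cfg.analysis.linear_fit and len(pts["condition_mM"].unique()) >= 2:
                try:
                    lin = dose.fit_linear_intercept(
                        pts[["condition_mM", "responder_mean_delta_ca"]].to_numpy())
                    fits["linear"] = dataclasses.asdict(lin)
                except FitError as err:
                    log.warning("linear fit skipped: %s", err)
            if cfg.analysis.hill_fit and len(pts) >= 3:
                try:
                    hill = dose.fit_hill_silencing(np.column_stack([
                        pts["responder_mean_delta_ca"].to_numpy(),
                        100.0 * pts["silent_fraction"].to_numpy()]))
                    d = dataclasses.asdict(hill)
                    d["signed_coeff"] = hill.signed_coeff
                    fits["hill"] = d
                except FitError as err:
                    log.warning("Hill fit skipped: %s", err)

        recovery = None
        gt_path = os.path.join(indir, "ground_truth.csv")
        if os.path.exists(gt_path):
            recovery = silent_fraction_recovery(measurements, pd.read_csv(gt_path))
        write_report(across, slopes, fits, recovery,
                     path=os.path.join(tmp, "report.json"))
        save_config(cfg, os.path.join(tmp, "resolved_config.json"))
        manifest = _write_manifest(tmp, "analyze", cfg, cfg.seed, inputs)
    return manifest


def run_all(cfg: PipelineConfig, outdir: str, seed: int | None = None,
            traces_only: bool = False) -> dict:
    sim_dir = os.path.join(outdir, "simulate")
    quant_dir = os.path.join(outdir, "quantify")
    ana_dir = os.path.join(outdir, "analyze")
    manifests = {"simulate": run_simulate(cfg, sim_dir, seed=seed,
                                          traces_only=traces_only)}
    manifests["quantify"] = run_quantify(sim_dir, cfg, quant_dir)
    manifests["analyze"] = run_analyze(quant_dir, cfg, ana_dir)
    return manifests
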