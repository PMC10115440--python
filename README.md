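# boutonquant

Single-bouton fluorescence quantification and synaptic-silencing analysis,
with a ground-truth synthetic-data generator so every stage is verifiable
offline.

The pipeline takes time-lapse fluorescence recordings of presynaptic
boutons — rendered 16-bit multi-page TIFF movies or per-terminal trace
tables — for three sensor modalities (`physin-gcamp`, `vgph`, `iglusnfr`)
and produces:

* per-terminal measurements: baseline mean/SD, peak ΔF, calibration F_max,
  silent/responding calls (ΔF < σ_baseline), absolute Δ[Ca²⁺]_i via the
  GCaMP conversion equation (K_d 0.38 µM, R_f 51.8, n 2.3), and
  NH₄Cl / saturating-glutamate normalized responses;
* per-neuron and across-neuron summaries: silent fractions (mean, SEM, CoV),
  responder means, silencing-per-mM slopes, ΔF ECDFs by class, paired
  perturbation effects;
* population fits: OLS x-intercept extrapolation of influx versus external
  Ca²⁺, and a constrained Hill fit of silent percentage versus influx with
  the maximum pinned at 100% for zero influx.

The generator renders punctate boutons (Gaussian spots over background +
camera offset, read/shot noise) with per-terminal influx drawn from a
piecewise-linear influx model (default x-intercept 0.47 mM), probabilistic
all-or-none silencing from a decreasing Hill model (default K_d 25 nM,
coefficient 1.79), sensor saturation nonlinearity, calibration epochs, and
an optional fractional influx reduction emulating GPCR agonism.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (conversion
round-trip, classifier-oracle equivalence, end-to-end silent-fraction
recovery, Hill/linear fit recovery, perturbation monotonicity, stage
determinism).

## CLI

Configuration is a strict JSON file (unknown keys rejected); all defaults
are filled in, so `{"seed": 1}` is a valid config.

```sh
boutonquant simulate --config cfg.json --out run/sim [--seed 7] [--traces-only]
boutonquant quantify --in run/sim --config cfg.json --out run/quant
boutonquant analyze  --in run/quant --config cfg.json --out run/analysis
boutonquant all      --config cfg.json --out run [--seed 7] [--traces-only]
```

Example config:

```json
{
  "seed": 7,
  "generator": {
    "n_neurons": 9,
    "n_terminals": 200,
    "ca_e_mm": [2.0, 1.2, 0.8, 0.4],
    "modality": "physin-gcamp",
    "perturbation": 0.0,
    "render": {"height": 96, "width": 96}
  }
}
```

Omit `generator.render` (or pass `--traces-only`) to skip movie rendering
and emit per-terminal trace CSVs directly.  Stage outputs are written
atomically with deterministic manifests (config hash + artifact digests);
identical config and seed reproduce bit-identical artifacts.

Outputs: `measurements.csv` (per-terminal), `summary_per_neuron.csv`,
`summary_across_neurons.csv`, `ecdf_by_class.csv`, `report.json`
(conditions, slopes, fits with the negative-exponent reporting convention
for the Hill coefficient, and — when ground truth is available —
silent-fraction recovery errors).

## Layout

```
src/boutonquant/
  synth/        generator: models, traces, movie rendering, dataset assembly
  roi.py        punctum detection, background ROIs, trace extraction
  metrics.py    baseline/peak/silent/F_max/Ca2+ conversion per terminal
  dose.py       population summaries, slopes, ECDFs, linear + Hill fits
  protocols.py  frame-window protocols per sensor modality
  config.py     strict pipeline configuration schema
  pipeline.py   stage orchestration, manifests, atomic outputs
  cli.py        click CLI
tests/          pytest suite (unit, property, acceptance)
scripts/        acceptance.py
```
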