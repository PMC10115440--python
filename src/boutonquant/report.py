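"""Deterministic JSON reporting.

Floats are rounded to 9 significant digits and keys sorted so regenerating a
report from identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd


def _canon(obj):
    if isinstance(obj, dict):
        return {str(k): _canon(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canon(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "Infinity" if f > 0 else "-Infinity"
        return float(f"{f:.9g}")
    return obj


def dump_json(obj, path=None) -> str:
    """Serialize with sorted keys and 9-significant-digit floats."""
    text = json.dumps(_canon(obj), indent=2, sort_keys=True, allow_nan=False) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_report(across: pd.DataFrame, slopes: list[dict], fits: dict | None,
                 recovery: dict | None = None, path=None) -> dict:
    """Assemble the analysis report.

    ``fits`` may be None (serialized as an explicit null) or a dict with
    ``linear``/``hill`` entries, themselves possibly null.  When ground truth
    was available, ``recovery`` carries per-condition silent-fraction
    recovery errors.
    """
    report = {
        "conditions": across.to_dict(orient="records"),
        "slopes_pct_per_mm": slopes,
        "fits": fits,
        "recovery": recovery,
    }
    if path is not None:
        dump_json(report, path)
    return report


def silent_fraction_recovery(measurements: pd.DataFrame,
                             ground_truth: pd.DataFrame) -> dict:
    """Per-condition comparison of measured vs ground-truth silent fractions."""
    out = {}
    meas = measurements[measurements["usable"]]
    for cond in sorted(meas["condition_mM"].unique()):
        m = meas[meas["condition_mM"] == cond]
        g = ground_truth[ground_truth["condition_mM"] == cond]
        measured = float(m["silent"].mean())
        true = float(g["silent_true"].mean())
        out[f"{cond:g}"] = {
            "measured_silent_fraction": measured,
            "true_silent_fraction": true,
            "abs_error": abs(measured - true),
            "n_terminals": int(len(m)),
        }
    return out
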