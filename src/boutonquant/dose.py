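"""Population-level analyses.

Per-neuron/per-condition summaries (silent fraction, responder means),
across-neuron statistics (mean, SEM, CoV), linear x-intercept extrapolation
of influx versus external Ca²⁺, silencing-per-mM slopes, ΔF ECDFs by class,
paired perturbation effects, and the constrained Hill fit of silent fraction
versus absolute influx (maximum pinned at 100% for zero influx).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from boutonquant.errors import FitError, PairingError

# multi-start grid for the Hill fit; ties in SSE break toward the smallest kd
_HILL_KD_STARTS = (5.0, 15.0, 45.0, 135.0)
_HILL_C_STARTS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class LinearFit:
    slope: float          # nM per mM
    intercept_y: float    # nM at ca_e = 0
    intercept_x: float    # mM where influx extrapolates to zero
    r2: float
    slope_nonpositive: bool = False


@dataclass(frozen=True)
class HillFit:
    kd: float             # nM at half-maximal silencing
    coeff: float          # positive steepness exponent
    r2: float
    n_points: int
    max_constrained: float = 100.0

    @property
    def signed_coeff(self) -> float:
        """Reporting convention: negative exponent for the decreasing curve."""
        return -self.coeff


def expected_proportional_delta(delta_ref: float, ca_ref: float, ca_target: float) -> float:
    """Influx expected at ``ca_target`` if it scaled 1:1 with external Ca²⁺."""
    if ca_ref <= 0:
        raise ValueError("ca_ref must be positive")
    return delta_ref * (ca_target / ca_ref)


def fit_linear_intercept(points) -> LinearFit:
    """OLS line through (ca_e mM, mean Δ[Ca²⁺]_i nM) points; x-intercept = −b/m."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 2:
        raise FitError("fit_linear_intercept needs >= 2 distinct ca_e values",
                       {"n_points": len(x), "n_abscissae": len(np.unique(x))})
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(slope=float(slope), intercept_y=float(intercept),
                     intercept_x=float(-intercept / slope), r2=float(r2),
                     slope_nonpositive=bool(slope <= 0))


def silencing_slope(frac_low: float, frac_high: float,
                    ca_low: float, ca_high: float) -> float:
    """Change in silent percentage per mM over a concentration step.

    ``frac_low``/``frac_high`` are silent percentages at the lower/higher
    concentration; positive when silencing rises as Ca²⁺ falls.
    """
    if not ca_low < ca_high:
        raise ValueError("requires ca_low < ca_high")
    return (frac_low - frac_high) / (ca_high - ca_low)


def hill_silencing(delta_ca, kd: float, coeff: float, maximum: float = 100.0):
    """Decreasing Hill curve with fixed maximum at zero influx."""
    delta = np.asarray(delta_ca, dtype=float)
    # log-space ratio keeps extreme exploratory (kd, coeff) finite-safe
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.exp(coeff * (np.log(delta) - np.log(kd)))
    return maximum / (1.0 + ratio)


def fit_hill_silencing(points, weights=None, maximum: float = 100.0) -> HillFit:
    """Least-squares fit of silent % versus influx with the maximum constrained.

    ``points`` are (Δ[Ca²⁺]_i nM, silent %) pairs — per-neuron means by
    convention.  Multi-start over a fixed kd x coeff grid; deterministic; SSE
    ties break toward the smallest kd.  Raises :class:`FitError` when fewer
    than 3 points with spread in positive influx are supplied or no start
    converges.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    delta, frac = pts[:, 0], pts[:, 1]
    if np.any(delta < 0):
        raise FitError("influx values must be non-negative", {"min_delta": delta.min()})
    pos = delta[delta > 0]
    if len(pts) < 3 or len(np.unique(pos)) < 2:
        raise FitError("fit_hill_silencing needs >= 3 points with spread in "
                       "positive influx",
                       {"n_points": len(pts), "n_positive_abscissae": len(np.unique(pos))})
    w = np.ones(len(pts)) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    def residuals(theta):
        log_kd, log_c = theta
        return w * (hill_silencing(delta, np.exp(log_kd), np.exp(log_c), maximum) - frac)

    best = None
    for kd0 in _HILL_KD_STARTS:
        for c0 in _HILL_C_STARTS:
            try:
                sol = least_squares(residuals, x0=[np.log(kd0), np.log(c0)],
                                    method="lm", max_nfev=2000)
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            sse = float(np.sum(sol.fun ** 2))
            kd = float(np.exp(sol.x[0]))
            if best is None or sse < best[0] - 1e-12 or (
                    abs(sse - best[0]) <= 1e-12 and kd < best[1]):
                best = (sse, kd, float(np.exp(sol.x[1])))
    if best is None:
        raise FitError("Hill fit failed to converge from every start",
                       {"starts": len(_HILL_KD_STARTS) * len(_HILL_C_STARTS)})
    sse, kd, coeff = best
    pred = hill_silencing(delta, kd, coeff, maximum)
    ss_tot = float(np.sum((frac - frac.mean()) ** 2))
    r2 = 1.0 - float(np.sum((frac - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return HillFit(kd=kd, coeff=coeff, r2=r2, n_points=len(pts), max_constrained=maximum)


def summarize_condition(measurements: pd.DataFrame):
    """Per-neuron x per-condition summaries plus across-neuron statistics.

    Responder means are taken over non-silent, usable, non-saturated,
    non-subfloor terminals.  Returns ``(per_neuron, across)`` DataFrames; the
    across-neuron table carries mean, SEM (ddof=1) and CoV (SD/mean) of the
    silent fractions per condition.
    """
    if measurements.empty:
        raise ValueError("measurement table is empty")
    df = measurements[measurements["usable"]].copy()
    if df.empty:
        raise ValueError("no usable terminals in the measurement table")
    rows = []
    for (nid, cond), grp in df.groupby(["neuron_id", "condition_mM"], sort=True):
        responders = grp[~grp["silent"] & ~grp["saturated"] & ~grp["subfloor"]]
        rows.append({
            "neuron_id": nid, "condition_mM": cond,
            "modality": grp["modality"].iloc[0],
            "n_terminals": len(grp),
            "n_responding": len(responders),
            "silent_fraction": grp["silent"].mean(),
            "responder_mean_delta_ca": responders["delta_ca_nM"].mean()
            if len(responders) else np.nan,
            "responder_mean_response_norm": responders["response_norm"].mean()
            if len(responders) else np.nan,
        })
    per_neuron = pd.DataFrame(rows)

    across_rows = []
    for cond, grp in per_neuron.groupby("condition_mM", sort=True):
        frac = grp["silent_fraction"].to_numpy(dtype=float)
        sd = frac.std(ddof=1) if len(frac) > 1 else 0.0
        across_rows.append({
            "condition_mM": cond, "n_neurons": len(frac),
            "silent_fraction_mean": frac.mean(),
            "silent_fraction_sem": sd / np.sqrt(len(frac)) if len(frac) > 1 else 0.0,
            "silent_fraction_cov_pct": 100.0 * sd / frac.mean() if frac.mean() > 0 else np.nan,
            "responder_mean_delta_ca": grp["responder_mean_delta_ca"].mean(),
            "responder_mean_response_norm": grp["responder_mean_response_norm"].mean(),
        })
    return per_neuron, pd.DataFrame(across_rows)


def ecdf_by_class(measurements: pd.DataFrame, conditions=None) -> pd.DataFrame:
    """ECDF points of ΔF for silent versus responding terminals per condition."""
    df = measurements
    if conditions is not None:
        df = df[df["condition_mM"].isin(conditions)]
    parts = []
    for (cond, silent), grp in df.groupby(["condition_mM", "silent"], sort=True):
        v = np.sort(grp["df_peak"].to_numpy(dtype=float))
        if len(v) == 0:
            continue
        parts.append(pd.DataFrame({
            "condition_mM": cond,
            "class": "silent" if silent else "responding",
            "df_peak": v,
            "ecdf": np.arange(1, len(v) + 1) / len(v),
        }))
    if not parts:
        return pd.DataFrame(columns=["condition_mM", "class", "df_peak", "ecdf"])
    return pd.concat(parts, ignore_index=True)


def paired_effect(pre: pd.DataFrame, post: pd.DataFrame):
    """Per-neuron post − pre differences of silent fraction and responder mean.

    Both inputs are per-neuron summary tables (as from
    :func:`summarize_condition`); neuron ids must match exactly, otherwise a
    :class:`PairingError` lists the offenders.  Returns ``(per_neuron_deltas,
    across_stats_dict)``; no hypothesis test is performed.
    """
    pre_ids = set(pre["neuron_id"])
    post_ids = set(post["neuron_id"])
    if pre_ids != post_ids:
        raise PairingError("unmatched neuron ids", pre_ids ^ post_ids)
    cols = ["silent_fraction", "responder_mean_delta_ca", "responder_mean_response_norm"]
    p0 = pre.groupby("neuron_id")[cols].mean()
    p1 = post.groupby("neuron_id")[cols].mean()
    deltas = (p1 - p0).reset_index().rename(
        columns={c: f"delta_{c}" for c in cols})
    stats = {}
    for c in cols:
        v = deltas[f"delta_{c}"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        stats[f"delta_{c}_mean"] = float(v.mean()) if len(v) else float("nan")
        stats[f"delta_{c}_sem"] = (float(v.std(ddof=1) / np.sqrt(len(v)))
                                   if len(v) > 1 else float("nan"))
    stats["n_neurons"] = int(len(deltas))
    return deltas, stats
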