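import numpy as np
import pandas as pd
import pytest

from boutonquant import dose
from boutonquant.errors import FitError, PairingError


class TestExpectedProportionalDelta:
    def test_identity_ratio(self):
        assert dose.expected_proportional_delta(55.0, 1.2, 1.2) == 55.0

    def test_physiologic_factor(self):
        # 1.2 / 2.0 -> factor 0.6
        assert dose.expected_proportional_delta(100.0, 2.0, 1.2) == pytest.approx(60.0)

    def test_arithmetic(self):
        assert dose.expected_proportional_delta(60.0, 2.0, 0.8) == pytest.approx(24.0)

    def test_nonpositive_reference_error(self):
        with pytest.raises(ValueError):
            dose.expected_proportional_delta(10.0, 0.0, 1.2)


class TestLinearIntercept:
    def test_exact_recovery_on_noiseless_line(self):
        xs = np.array([0.8, 1.2, 2.0])
        pts = np.column_stack([xs, 39.2 * (xs - 0.47)])
        fit = dose.fit_linear_intercept(pts)
        assert fit.intercept_x == pytest.approx(0.47, rel=1e-12)
        assert fit.slope == pytest.approx(39.2, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_scale_invariance_of_root(self):
        xs = np.array([0.8, 1.2, 2.0])
        pts = np.column_stack([xs, 39.2 * (xs - 0.47)])
        doubled = pts * [1.0, 2.0]
        assert dose.fit_linear_intercept(doubled).intercept_x == pytest.approx(0.47, rel=1e-12)

    def test_single_abscissa_error(self):
        with pytest.raises(FitError):
            dose.fit_linear_intercept([(1.2, 10.0), (1.2, 12.0)])

    def test_nonpositive_slope_flagged(self):
        fit = dose.fit_linear_intercept([(0.8, 30.0), (1.2, 20.0), (2.0, 5.0)])
        assert fit.slope_nonpositive

    def test_noisy_recovery(self, rng):
        # 9 neurons x 3 conditions, noise SD 3 nM
        xs = np.tile([0.8, 1.2, 2.0], 9)
        errs = []
        for _ in range(100):
            ys = 39.2 * (xs - 0.47) + rng.normal(0, 3.0, xs.size)
            errs.append(dose.fit_linear_intercept(np.column_stack([xs, ys])).intercept_x - 0.47)
        assert abs(np.mean(errs)) < 0.05


class TestSilencingSlope:
    def test_flat(self):
        assert dose.silencing_slope(40.0, 40.0, 0.8, 1.2) == 0.0

    def test_printed_slope_reconstruction(self):
        # values consistent with the printed 48.9 % / mM over 1.2 -> 0.8
        assert dose.silencing_slope(60.0, 40.44, 0.8, 1.2) == pytest.approx(48.9)

    def test_low_transition_value(self):
        assert dose.silencing_slope(93.0, 93.0 - 29.32, 0.4, 0.8) == pytest.approx(73.3)

    def test_equal_concentration_error(self):
        with pytest.raises(ValueError):
            dose.silencing_slope(60.0, 40.0, 1.2, 1.2)


class TestHillFit:
    def test_noiseless_self_consistency(self):
        deltas = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
        fracs = dose.hill_silencing(deltas, kd=23.0, coeff=1.46)
        fit = dose.fit_hill_silencing(np.column_stack([deltas, fracs]))
        assert fit.kd == pytest.approx(23.0, rel=1e-6)
        assert fit.coeff == pytest.approx(1.46, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.signed_coeff == pytest.approx(-1.46, rel=1e-6)

    def test_constrained_maximum_at_zero(self):
        deltas = np.array([0.0, 10.0, 30.0, 90.0])
        fracs = dose.hill_silencing(deltas, kd=25.0, coeff=1.79)
        fit = dose.fit_hill_silencing(np.column_stack([deltas, fracs]))
        assert dose.hill_silencing(0.0, fit.kd, fit.coeff) == 100.0

    def test_degenerate_single_abscissa(self):
        with pytest.raises(FitError):
            dose.fit_hill_silencing([(25.0, 50.0)] * 5)

    def test_noisy_recovery_tolerances(self):
        rng = np.random.default_rng(77)
        deltas = np.repeat([5.0, 12.0, 25.0, 45.0, 70.0, 110.0, 160.0], 4)
        fracs = dose.hill_silencing(deltas, kd=25.0, coeff=1.79) + rng.normal(0, 5, deltas.size)
        fit = dose.fit_hill_silencing(np.column_stack([deltas, fracs]))
        assert fit.kd == pytest.approx(25.0, rel=0.20)
        assert fit.coeff == pytest.approx(1.79, rel=0.25)


def _measurements(rows):
    df = pd.DataFrame(rows)
    defaults = {"modality": "physin-gcamp", "usable": True, "saturated": False,
                "subfloor": False, "response_norm": np.nan}
    for k, v in defaults.items():
        if k not in df:
            df[k] = v
        elif isinstance(v, bool):
            df[k] = df[k].map(lambda x: v if pd.isna(x) else bool(x)).astype(bool)
    return df


class TestSummarizeCondition:
    def test_all_silent_flags_responder_mean(self):
        m = _measurements([{"neuron_id": "n0", "condition_mM": 1.2, "terminal_id": f"t{i}",
                            "silent": True, "df_peak": 0.0, "delta_ca_nM": np.nan}
                           for i in range(5)])
        per, across = dose.summarize_condition(m)
        assert per["silent_fraction"].iloc[0] == 1.0
        assert np.isnan(per["responder_mean_delta_ca"].iloc[0])

    def test_cov_zero_for_equal_fractions(self):
        rows = []
        for n in range(3):
            for i in range(4):
                rows.append({"neuron_id": f"n{n}", "condition_mM": 1.2,
                             "terminal_id": f"t{n}_{i}", "silent": i < 2,
                             "df_peak": 1.0, "delta_ca_nM": 10.0})
        _, across = dose.summarize_condition(_measurements(rows))
        assert across["silent_fraction_cov_pct"].iloc[0] == pytest.approx(0.0)

    def test_cov_derived_value(self):
        # fractions {0.4, 0.6}: SD(ddof=1)=0.14142, mean 0.5 -> CoV 28.28%
        rows = []
        for n, frac in enumerate([0.4, 0.6]):
            for i in range(10):
                rows.append({"neuron_id": f"n{n}", "condition_mM": 1.2,
                             "terminal_id": f"t{n}_{i}", "silent": i < frac * 10,
                             "df_peak": 1.0, "delta_ca_nM": 10.0})
        _, across = dose.summarize_condition(_measurements(rows))
        assert across["silent_fraction_cov_pct"].iloc[0] == pytest.approx(28.2843, abs=1e-3)

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            dose.summarize_condition(pd.DataFrame())

    def test_responders_exclude_saturated_and_subfloor(self):
        m = _measurements([
            {"neuron_id": "n0", "condition_mM": 1.2, "terminal_id": "a",
             "silent": False, "df_peak": 5.0, "delta_ca_nM": 50.0},
            {"neuron_id": "n0", "condition_mM": 1.2, "terminal_id": "b",
             "silent": False, "df_peak": 5.0, "delta_ca_nM": 999.0, "saturated": True},
        ])
        per, _ = dose.summarize_condition(m)
        assert per["responder_mean_delta_ca"].iloc[0] == 50.0
        assert per["n_responding"].iloc[0] == 1


class TestEcdf:
    def test_single_value_step(self):
        m = _measurements([{"neuron_id": "n0", "condition_mM": 1.2, "terminal_id": "a",
                            "silent": False, "df_peak": 3.5, "delta_ca_nM": 1.0}])
        tab = dose.ecdf_by_class(m)
        assert len(tab) == 1
        assert tab["ecdf"].iloc[0] == 1.0 and tab["df_peak"].iloc[0] == 3.5

    def test_empty_class_empty_table(self):
        m = _measurements([{"neuron_id": "n0", "condition_mM": 1.2, "terminal_id": "a",
                            "silent": False, "df_peak": 3.5, "delta_ca_nM": 1.0}])
        tab = dose.ecdf_by_class(m)
        assert not (tab["class"] == "silent").any()

    def test_silent_distribution_invariant_across_conditions(self, small_dataset):
        """Silent-terminal dF distributions barely move with [Ca2+]_e
        (two-sample KS distance below 0.15 at these sample sizes)."""
        from boutonquant import metrics

        ds = small_dataset
        frames = [metrics.quantify_traces(r.noisy, ds.protocol, ds.sensor,
                                          terminal_ids=r.terminal_ids,
                                          neuron_id=r.neuron_id, condition=r.condition)
                  for r in ds.recordings]
        meas = pd.concat(frames, ignore_index=True)
        gt = ds.ground_truth
        mm = meas.merge(gt, on=["terminal_id", "condition_mM"])
        sil = mm[mm["silent_true"]]
        a = np.sort(sil.loc[sil["condition_mM"] == 2.0, "df_peak"] /
                    sil.loc[sil["condition_mM"] == 2.0, "sigma_baseline"])
        b = np.sort(sil.loc[sil["condition_mM"] == 0.8, "df_peak"] /
                    sil.loc[sil["condition_mM"] == 0.8, "sigma_baseline"])
        from scipy.stats import ks_2samp

        assert ks_2samp(a, b).statistic < 0.2


class TestPairedEffect:
    def _summary(self, fracs, delta=30.0):
        return pd.DataFrame([{"neuron_id": f"n{i}", "condition_mM": 1.2,
                              "silent_fraction": f, "responder_mean_delta_ca": delta,
                              "responder_mean_response_norm": np.nan}
                             for i, f in enumerate(fracs)])

    def test_null_perturbation(self):
        pre = self._summary([0.4, 0.5, 0.6])
        deltas, stats = dose.paired_effect(pre, pre.copy())
        assert np.allclose(deltas["delta_silent_fraction"], 0.0)
        assert stats["delta_silent_fraction_mean"] == 0.0

    def test_missing_neuron_error_names_id(self):
        pre = self._summary([0.4, 0.5])
        post = self._summary([0.4])
        with pytest.raises(PairingError) as err:
            dose.paired_effect(pre, post)
        assert "n1" in str(err.value)

    def test_reports_mean_and_sem(self):
        pre = self._summary([0.4, 0.5, 0.6])
        post = self._summary([0.5, 0.7, 0.6])
        deltas, stats = dose.paired_effect(pre, post)
        vals = np.array([0.1, 0.2, 0.0])
        assert stats["delta_silent_fraction_mean"] == pytest.approx(vals.mean())
        assert stats["delta_silent_fraction_sem"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(3))
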