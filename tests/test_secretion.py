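"""Calibration fitting, secretion-rate estimation, gating and ROS slope."""

import numpy as np
import pandas as pd
import pytest

from dropsecr.config import AcquisitionSpec, AssayConstants, ChamberSpec, PhenotypeSpec
from dropsecr.secretion import (
    GATE_ABOVE_RANGE,
    GATE_BELOW_LOD,
    GATE_EXCLUDED_MULTICELL,
    GATE_IGG_SC,
    GATE_IGG_UNINTERPRETABLE,
    GATE_IN_RANGE,
    CalibrationCurve,
    default_igg_curve,
    default_lactate_curve,
    fit_igg_calibration,
    fit_lactate_calibration,
    igg_gate,
    igg_molecules,
    igg_secretion_rate,
    joint_phenotype_table,
    lactate_gate,
    lactate_secretion_rate,
    ros_slope,
)
from dropsecr.synthgen import generate_calibration_standards, generate_trace_set


def trace_for(traces, droplet_id, channel):
    sub = traces[(traces["droplet_id"] == droplet_id) & (traces["channel"] == channel)]
    return sub.sort_values("frame")


class TestUnitChain:
    def test_one_pm_step_per_interval_is_30_molecules(self, constants):
        # 1 pM in 50 pL: c * V * N_A = 30.1 molecules -> 0.050 molecules/s over 600 s
        molecules = igg_molecules(1e-3, constants)  # 1 pM = 1e-3 nM
        assert molecules == pytest.approx(30.11, abs=0.01)
        assert molecules / 600.0 == pytest.approx(0.0502, abs=0.0005)


class TestCalibration:
    def test_saturating_exponential_parameters_recovered(self):
        true = CalibrationCurve("igg_relocation", (1.2, 3.5, 12.0))
        standards = generate_calibration_standards(
            true, [0, 2, 5, 10, 20, 40], replicates=2, noise_sd=0.0, seed=0
        )
        fit = fit_igg_calibration(standards)
        for a, b in zip(fit.params, true.params):
            assert a == pytest.approx(b, rel=1e-6)

    def test_inverse_forward_round_trip(self):
        curve = default_igg_curve()
        for c in [0.0, 0.5, 3.0, 10.0, 45.0]:
            conc, clamped = curve.inverse(curve.forward(c))
            assert conc == pytest.approx(c, abs=1e-9)
            assert not clamped or c == 0.0

    def test_readout_below_baseline_clamps_to_zero_with_flag(self):
        curve = default_igg_curve()
        conc, clamped = curve.inverse(curve.params[0] - 0.5)
        assert conc == 0.0 and clamped

    def test_zero_concentration_readout_is_baseline(self):
        curve = default_igg_curve()
        standards = generate_calibration_standards(curve, [0.0], replicates=1)
        assert standards["readout"].iloc[0] == pytest.approx(curve.params[0])

    def test_saturation_scale_closed_form(self):
        baseline, span, c0 = default_igg_curve().params
        standards = generate_calibration_standards(default_igg_curve(), [c0], replicates=1)
        assert standards["readout"].iloc[0] == pytest.approx(
            baseline + span * (1 - np.exp(-1.0))
        )

    def test_standards_deterministic_under_seed(self):
        a = generate_calibration_standards(default_igg_curve(), [0, 5, 10], 3, 0.2, seed=4)
        b = generate_calibration_standards(default_igg_curve(), [0, 5, 10], 3, 0.2, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_standards(default_igg_curve(), [])

    def test_lactate_intercept_fixed_from_zero_standards(self):
        true = default_lactate_curve()
        standards = generate_calibration_standards(true, [0, 0, 10, 50, 100], 1, 0.0, 0)
        fit = fit_lactate_calibration(standards)
        assert fit.params[0] == pytest.approx(true.params[0])
        assert fit.params[1] == pytest.approx(true.params[1], rel=1e-9)


class TestIgGRate:
    def test_planted_rate_recovered_noiseless(self, small_noiseless_chamber, constants):
        _, _, traces, truth = small_noiseless_chamber
        series = trace_for(traces, "d000001", "a647")
        est = igg_secretion_rate(series, default_igg_curve(), constants)
        assert est.rate == pytest.approx(50.0, rel=0.02)
        assert est.gate == GATE_IGG_SC

    def test_constant_relocation_gates_below_lod(self, constants):
        series = pd.DataFrame(
            {"droplet_id": "d0", "time_s": np.arange(6) * 600.0,
             "droplet_mean": 200.0, "beadline_mean": 200.0}
        )
        est = igg_secretion_rate(series, default_igg_curve(), constants)
        assert est.rate == 0.0
        assert est.gate == GATE_BELOW_LOD

    @pytest.mark.parametrize(
        "rate,gate",
        [(8.99, GATE_BELOW_LOD), (9.0, GATE_IGG_SC), (284.99, GATE_IGG_SC),
         (285.0, GATE_ABOVE_RANGE)],
    )
    def test_gate_boundaries_inclusive_at_lod(self, rate, gate, constants):
        assert igg_gate(rate, constants) == gate

    def test_alternative_published_upper_bound_configurable(self):
        constants = AssayConstants(igg_upper=258.0)
        assert igg_gate(258.0, constants) == GATE_ABOVE_RANGE
        assert igg_gate(257.0, constants) == GATE_IGG_SC

    def test_nox_positive_droplet_uninterpretable(self, small_noiseless_chamber, constants):
        _, _, traces, _ = small_noiseless_chamber
        series = trace_for(traces, "d000000", "a647")
        est = igg_secretion_rate(series, default_igg_curve(), constants,
                                 nox_label="NOX_drop_pos")
        assert est.gate == GATE_IGG_UNINTERPRETABLE
        assert np.isnan(est.rate)

    def test_monotone_recovery_noiseless(self, noiseless_acq, constants):
        rates = [5.0, 20.0, 80.0, 200.0, 300.0]
        estimates = []
        for r in rates:
            phens = [PhenotypeSpec("c0", igg_rate=r, n_cells_in_droplet=1)]
            traces, _ = generate_trace_set(
                ChamberSpec(n_droplets=1), noiseless_acq, phens, seed=0
            )
            series = trace_for(traces, "d000000", "a647")
            estimates.append(igg_secretion_rate(series, default_igg_curve(), constants).rate)
        assert all(b > a for a, b in zip(estimates, estimates[1:]))


class TestLactateRate:
    def test_planted_rate_recovered_noiseless(self, small_noiseless_chamber, constants):
        _, _, traces, _ = small_noiseless_chamber
        series = trace_for(traces, "d000002", "lactate_probe")
        est = lactate_secretion_rate(series, default_lactate_curve(), constants)
        assert est.rate == pytest.approx(0.4, rel=0.02)
        assert est.gate == GATE_IN_RANGE
        assert est.in_quant_range

    def test_flat_trace_is_zero(self, constants):
        series = pd.DataFrame(
            {"droplet_id": "d0", "time_s": np.arange(6) * 600.0, "droplet_mean": 80.0}
        )
        est = lactate_secretion_rate(series, default_lactate_curve(), constants)
        assert est.rate == 0.0
        assert est.gate == GATE_BELOW_LOD

    def test_multicell_droplets_excluded(self, constants):
        series = pd.DataFrame(
            {"droplet_id": "d0", "time_s": np.arange(6) * 600.0, "droplet_mean": 80.0}
        )
        est = lactate_secretion_rate(series, default_lactate_curve(), constants, n_cells=2)
        assert est.gate == GATE_EXCLUDED_MULTICELL
        assert np.isnan(est.rate)

    @pytest.mark.parametrize(
        "rate,gate",
        [(0.05, GATE_BELOW_LOD), (0.1, GATE_IN_RANGE), (0.79, GATE_IN_RANGE),
         (0.8, GATE_ABOVE_RANGE)],
    )
    def test_gate_boundaries(self, rate, gate, constants):
        assert lactate_gate(rate, constants) == gate


class TestParameterRecovery:
    def test_median_relative_error_with_noise(self, constants):
        """500 single-cell droplets, rates uniform over the quantitative
        ranges, realistic frame noise: median relative error <= 15%."""
        from dropsecr.synthgen import REALISTIC_NOISE_SD

        n = 500
        rng = np.random.default_rng(21)
        igg_true = rng.uniform(9, 285, n)
        lac_true = rng.uniform(0.1, 0.8, n)
        phens = [
            PhenotypeSpec(f"c{i}", igg_rate=igg_true[i], lactate_rate=lac_true[i],
                          n_cells_in_droplet=1)
            for i in range(n)
        ]
        traces, _ = generate_trace_set(
            ChamberSpec(n_droplets=n),
            AcquisitionSpec(noise_sd=REALISTIC_NOISE_SD),
            phens, seed=22,
        )
        igg_curve, lac_curve = default_igg_curve(), default_lactate_curve()
        igg_err, lac_err = [], []
        a647 = traces[traces["channel"] == "a647"]
        lact = traces[traces["channel"] == "lactate_probe"]
        for i, (did, grp) in enumerate(a647.groupby("droplet_id", sort=True)):
            est = igg_secretion_rate(grp.sort_values("frame"), igg_curve, constants)
            igg_err.append(abs(est.rate - igg_true[i]) / igg_true[i])
        for i, (did, grp) in enumerate(lact.groupby("droplet_id", sort=True)):
            est = lactate_secretion_rate(grp.sort_values("frame"), lac_curve, constants)
            lac_err.append(abs(est.rate - lac_true[i]) / lac_true[i])
        assert np.median(igg_err) <= 0.15
        assert np.median(lac_err) <= 0.15


class TestRosSlope:
    def test_flat_trace_zero(self):
        assert ros_slope([50, 50, 50], [0, 600, 1200]) == 0.0

    def test_linear_rise_recovers_slope(self):
        y = 30 + 30 * np.arange(6)  # +30 a.u. per 10-min frame, max at last
        assert ros_slope(y, np.arange(6) * 600.0) == pytest.approx(30.0)

    def test_intervals_after_maximum_ignored(self):
        y = [10, 40, 70, 100, 60, 20]  # max at frame 3
        t = np.arange(6) * 600.0
        assert ros_slope(y, t) == pytest.approx(30.0)

    def test_maximum_at_first_frame_gives_zero(self):
        assert ros_slope([100, 60, 20], [0, 600, 1200]) == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            ros_slope([10], [0])


class TestJointTable:
    def _df(self, ids, **cols):
        return pd.DataFrame({"droplet_id": ids, **cols})

    def test_disjoint_ids_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no shared"):
            out = joint_phenotype_table(
                self._df(["a"], label=["NOX_drop_neg"]),
                self._df(["b"], rate=[1.0]),
                self._df(["b"], rate=[0.2]),
            )
        assert out.empty

    def test_planted_difference_detected_downstream(self):
        from dropsecr.stats import compare_distributions

        rng = np.random.default_rng(3)
        pos = rng.normal(0.6, 0.05, 200)
        neg = rng.normal(0.3, 0.05, 200)
        res = compare_distributions(pos, neg)
        assert res.p < 1e-10

    def test_nox_positive_rows_carry_no_igg_rate(self, constants):
        calls = self._df(["a", "b"], label=["NOX_drop_pos", "NOX_drop_neg"])
        series = pd.DataFrame(
            {"droplet_id": "a", "time_s": np.arange(6) * 600.0,
             "droplet_mean": 200.0, "beadline_mean": 200.0}
        )
        est_pos = igg_secretion_rate(series, default_igg_curve(), constants,
                                     nox_label="NOX_drop_pos")
        igg = self._df(["a", "b"], rate=[est_pos.rate, 50.0])
        out = joint_phenotype_table(calls, igg, self._df(["a", "b"], rate=[0.2, 0.3]))
        assert np.isnan(out.loc[out["droplet_id"] == "a", "igg_rate"].iloc[0])
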