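"""Take-off estimation, Pfaffl ratios, normalizer combination, plate QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from septiclass import (
    AmplificationCurve,
    CurveModel,
    LOGISTIC_TAKEOFF_OFFSET,
    NOT_DETECTED,
    PanelSpec,
    PlateQCError,
    SampleUnquantifiableError,
    WellRole,
    WellSpec,
    combine_normalizers,
    pfaffl_fold_change,
    plate_qc,
    quantify_sample,
    simulate_amplification_curves,
    takeoff_cycle,
)


def logistic_curve(c0=25.0, k=0.8, step=0.1, f_max=100.0, baseline=2.0, n_cycles=40):
    cycles = np.arange(1.0, n_cycles + step, step)
    fluo = baseline + f_max / (1.0 + np.exp(-k * (cycles - c0)))
    return AmplificationCurve("w", "M01", WellRole.TARGET, cycles, fluo)


class TestTakeoffCycle:
    def test_dense_logistic_matches_analytic_peak(self):
        # closed-form oracle: second derivative of the logistic is maximal
        # at c0 - ln(2 + sqrt(3)) / k
        k, c0 = 0.8, 25.0
        expected = c0 - math.log(2.0 + math.sqrt(3.0)) / k
        assert expected == pytest.approx(25.0 - 1.6463, abs=5e-4)
        est = takeoff_cycle(logistic_curve(c0=c0, k=k, step=0.1))
        assert est == pytest.approx(expected, abs=0.25)

    def test_integer_cycle_sampling_within_tolerance(self):
        model = CurveModel()
        for true_takeoff in (21.3, 24.0, 26.7):
            (curve,) = simulate_amplification_curves(
                [WellSpec("w", "M01", WellRole.TARGET, takeoff=true_takeoff)], model, 0
            )
            assert takeoff_cycle(curve) == pytest.approx(true_takeoff, abs=0.25)

    def test_flat_trace_not_detected(self):
        cycles = np.arange(1.0, 41.0)
        flat = AmplificationCurve("w", "M01", WellRole.TARGET, cycles, np.full(40, 2.0))
        assert takeoff_cycle(flat) is NOT_DETECTED

    def test_noisy_flat_trace_not_detected(self, rng):
        cycles = np.arange(1.0, 41.0)
        noisy = AmplificationCurve(
            "w", "M01", WellRole.TARGET, cycles, 2.0 + rng.normal(0, 0.3, 40)
        )
        assert takeoff_cycle(noisy) is NOT_DETECTED

    def test_translation_equivariance(self):
        base = takeoff_cycle(logistic_curve(c0=23.0, step=1.0))
        shifted = takeoff_cycle(logistic_curve(c0=26.0, step=1.0))
        assert shifted - base == pytest.approx(3.0, abs=1e-6)

    def test_fractional_shift_tracked(self):
        base = takeoff_cycle(logistic_curve(c0=23.0, step=1.0))
        shifted = takeoff_cycle(logistic_curve(c0=24.4, step=1.0))
        assert shifted - base == pytest.approx(1.4, abs=0.1)

    def test_short_trace_rejected(self):
        cycles = np.arange(1.0, 9.0)
        short = AmplificationCurve("w", "M01", WellRole.TARGET, cycles, np.ones(8))
        with pytest.raises(ValueError):
            takeoff_cycle(short)

    def test_smoothing_tolerates_noise(self, rng):
        k, c0 = 0.6, 25.0
        cycles = np.arange(1.0, 41.0)
        fluo = 2.0 + 100.0 / (1.0 + np.exp(-k * (cycles - c0))) + rng.normal(0, 0.5, 40)
        curve = AmplificationCurve("w", "M01", WellRole.TARGET, cycles, fluo)
        est = takeoff_cycle(curve, smoothing_window=3)
        expected = c0 - LOGISTIC_TAKEOFF_OFFSET / k
        assert est == pytest.approx(expected, abs=1.5)


class TestPfafflFoldChange:
    def test_no_change_is_unity(self):
        assert pfaffl_fold_change(0.0, 0.0, 1.8, 1.95) == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        assert pfaffl_fold_change(1.0, 0.0, 2.0, 2.0) == pytest.approx(2.0)

    def test_efficiency_corrected_ratio(self):
        # 1.9^2.5 / 2^0.5
        expected = 1.9**2.5 / 2.0**0.5
        assert pfaffl_fold_change(2.5, 0.5, 1.9, 2.0) == pytest.approx(expected)
        assert expected == pytest.approx(3.519, abs=1e-3)

    def test_invalid_efficiency_rejected(self):
        for bad in (1.0, 0.5, 2.1):
            with pytest.raises(ValueError):
                pfaffl_fold_change(1.0, 1.0, bad, 2.0)
            with pytest.raises(ValueError):
                pfaffl_fold_change(1.0, 1.0, 2.0, bad)

    @given(
        dct_t=st.floats(-6, 6),
        dct_n=st.floats(-6, 6),
    )
    @settings(max_examples=50, deadline=None)
    def test_reduces_to_two_power_neg_ddct_at_perfect_efficiency(self, dct_t, dct_n):
        assert pfaffl_fold_change(dct_t, dct_n, 2.0, 2.0) == pytest.approx(
            2.0 ** (dct_t - dct_n)
        )


class TestCombineNormalizers:
    def test_geometric_mean(self):
        assert combine_normalizers([1.0, 1.0, 8.0]) == pytest.approx(2.0)

    def test_idempotent_on_equal_values(self):
        assert combine_normalizers([1.7, 1.7, 1.7]) == pytest.approx(1.7)

    def test_log_domain_oracle(self):
        vals = [1.2, 0.9, 1.5]
        expected = math.exp(np.mean(np.log(vals)))
        assert combine_normalizers(vals) == pytest.approx(expected)
        assert expected == pytest.approx(1.1737, abs=1e-3)

    @given(st.permutations([0.8, 1.3, 2.4]))
    @settings(max_examples=6, deadline=None)
    def test_permutation_invariant(self, vals):
        assert combine_normalizers(list(vals)) == pytest.approx(
            combine_normalizers([0.8, 1.3, 2.4])
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            combine_normalizers([])
        with pytest.raises(ValueError):
            combine_normalizers([1.0, -2.0])


def make_plate(n_neg=5, n_pos=5, contaminated_neg=0, failed_pos=0):
    wells = []
    for i in range(n_neg):
        role = WellRole.NEGATIVE_CONTROL
        if i < contaminated_neg:
            wells.append(WellSpec(f"n{i}", "CTRL", WellRole.POSITIVE_CONTROL, takeoff=24.0))
        else:
            wells.append(WellSpec(f"n{i}", "CTRL", role))
    for i in range(n_pos):
        if i < failed_pos:
            wells.append(WellSpec(f"p{i}", "CTRL", WellRole.NEGATIVE_CONTROL))
        else:
            wells.append(WellSpec(f"p{i}", "CTRL", WellRole.POSITIVE_CONTROL, takeoff=24.0))
    curves = simulate_amplification_curves(wells, CurveModel(), seed=0)
    # restore the intended declared roles (amplifying negatives emulate
    # contamination; flat positives emulate reaction failure)
    fixed = []
    for i, c in enumerate(curves):
        declared = WellRole.NEGATIVE_CONTROL if c.well_id.startswith("n") else WellRole.POSITIVE_CONTROL
        fixed.append(
            AmplificationCurve(c.well_id, c.marker_id, declared, c.cycles, c.fluorescence)
        )
    return fixed


class TestPlateQC:
    def test_clean_plate_passes(self):
        qc = plate_qc(make_plate())
        assert qc.negative_pass and qc.positive_pass and qc.passed

    def test_contaminated_negative_fails(self):
        qc = plate_qc(make_plate(contaminated_neg=1))
        assert not qc.negative_pass
        assert qc.positive_pass
        assert any("contamination" in r for r in qc.reasons)

    def test_flat_positive_fails(self):
        qc = plate_qc(make_plate(failed_pos=1))
        assert not qc.positive_pass
        assert any("failed to amplify" in r for r in qc.reasons)

    def test_wrong_control_count_is_reported_not_raised(self):
        qc = plate_qc(make_plate(n_neg=3))
        assert not qc.passed
        assert any("expected 5 negative controls" in r for r in qc.reasons)


def sample_wells(panel, true_log2fc, ref_takeoff=24.0, sample_id="S1"):
    wells = []
    for marker in panel.marker_ids:
        wells.append(
            WellSpec(
                f"{sample_id}:{marker}", marker, WellRole.TARGET,
                takeoff=ref_takeoff - true_log2fc.get(marker, 0.0), sample_id=sample_id,
            )
        )
    for norm in panel.normalizer_ids:
        wells.append(
            WellSpec(f"{sample_id}:{norm}", norm, WellRole.NORMALIZER,
                     takeoff=ref_takeoff, sample_id=sample_id)
        )
    return wells


@pytest.fixture
def tiny_panel():
    return PanelSpec(marker_ids=("M01", "M02", "M03"), normalizer_ids=("N1", "N2", "N3"))


class TestQuantifySample:
    def test_sample_identical_to_reference_gives_unit_fold_changes(self, tiny_panel):
        ref = {m: 24.0 for m in (*tiny_panel.marker_ids, *tiny_panel.normalizer_ids)}
        curves = simulate_amplification_curves(sample_wells(tiny_panel, {}), CurveModel(), 0)
        # reference take-offs estimated from identical reference curves, so
        # estimator bias cancels exactly
        est_ref = {c.marker_id: takeoff_cycle(c) for c in curves}
        results = quantify_sample(curves, est_ref, tiny_panel, "S1")
        assert len(results) == 3
        for r in results:
            assert r.fold_change == pytest.approx(1.0, abs=1e-9)
            assert r.log2_fold_change == pytest.approx(0.0, abs=1e-9)

    def test_known_fold_change_recovered(self, tiny_panel):
        curves = simulate_amplification_curves(
            sample_wells(tiny_panel, {"M02": 2.0}), CurveModel(), 0
        )
        ref_curves = simulate_amplification_curves(sample_wells(tiny_panel, {}), CurveModel(), 0)
        est_ref = {c.marker_id: takeoff_cycle(c) for c in ref_curves}
        results = {r.marker_id: r for r in quantify_sample(curves, est_ref, tiny_panel, "S1")}
        assert results["M02"].log2_fold_change == pytest.approx(2.0, abs=0.2)
        assert results["M01"].log2_fold_change == pytest.approx(0.0, abs=0.1)

    def test_log2_consistency_invariant(self, tiny_panel):
        curves = simulate_amplification_curves(
            sample_wells(tiny_panel, {"M01": -1.3}), CurveModel(), 0
        )
        ref = {m: 24.0 for m in (*tiny_panel.marker_ids, *tiny_panel.normalizer_ids)}
        for r in quantify_sample(curves, ref, tiny_panel, "S1"):
            assert r.fold_change > 0
            assert r.log2_fold_change == pytest.approx(math.log2(r.fold_change))

    def test_failed_qc_blocks_quantification(self, tiny_panel):
        curves = simulate_amplification_curves(sample_wells(tiny_panel, {}), CurveModel(), 0)
        qc = plate_qc(make_plate(contaminated_neg=1))
        ref = {m: 24.0 for m in (*tiny_panel.marker_ids, *tiny_panel.normalizer_ids)}
        with pytest.raises(PlateQCError):
            quantify_sample(curves, ref, tiny_panel, "S1", qc=qc)

    def test_undetected_normalizer_flags_sample(self, tiny_panel):
        wells = sample_wells(tiny_panel, {})
        curves = simulate_amplification_curves(wells, CurveModel(), 0)
        # flatten one normalizer trace: reaction failure in a reference gene
        flat = [
            AmplificationCurve(c.well_id, c.marker_id, c.role, c.cycles,
                               np.full_like(c.fluorescence, 2.0))
            if c.marker_id == "N2" else c
            for c in curves
        ]
        ref = {m: 24.0 for m in (*tiny_panel.marker_ids, *tiny_panel.normalizer_ids)}
        with pytest.raises(SampleUnquantifiableError, match="N2"):
            quantify_sample(flat, ref, tiny_panel, "S1")

    def test_normalizer_scale_consistency(self, tiny_panel):
        """Multiplying all normalizer ratios by kappa divides every marker
        fold change by kappa (here via a uniform +1-cycle normalizer shift,
        i.e. kappa = 2 at efficiency 2)."""
        ref = {m: 24.0 for m in (*tiny_panel.marker_ids, *tiny_panel.normalizer_ids)}
        base_wells = sample_wells(tiny_panel, {"M03": 1.0})
        shifted_wells = [
            WellSpec(w.well_id, w.marker_id, w.role, w.takeoff - 1.0, w.sample_id)
            if w.role is WellRole.NORMALIZER else w
            for w in base_wells
        ]
        base = {
            r.marker_id: r.fold_change
            for r in quantify_sample(
                simulate_amplification_curves(base_wells, CurveModel(), 0), ref, tiny_panel, "S1"
            )
        }
        shifted = {
            r.marker_id: r.fold_change
            for r in quantify_sample(
                simulate_amplification_curves(shifted_wells, CurveModel(), 0), ref, tiny_panel, "S1"
            )
        }
        for marker in tiny_panel.marker_ids:
            assert shifted[marker] == pytest.approx(base[marker] / 2.0, rel=0.02)
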