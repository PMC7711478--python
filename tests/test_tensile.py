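import numpy as np
import pytest

from enterospring.errors import (
    DegenerateSpecimenError,
    EmptyAfterTrimError,
    LabellingError,
)
from enterospring.synthetic_data import (
    SyntheticCurveParams,
    TensileSpecimenSpec,
    generate_tensile_curve,
)
from enterospring.tensile import (
    LabelledEstimate,
    ModulusEstimate,
    TensileCurve,
    aggregate_moduli,
    estimate_modulus,
    trim_curve,
)

SPEC = TensileSpecimenSpec(gauge_length=20.0, width=5.0, thickness=2.0)


def make_linear_curve(slope, n=50, offset=0.0, d_max=5.0):
    d = np.linspace(0.1, d_max, n)
    return TensileCurve(displacement=d, force=offset + slope * d, specimen=SPEC)


class TestTrimCurve:
    def test_removes_toe_below_preload(self):
        curve = generate_tensile_curve(
            SPEC, SyntheticCurveParams(true_modulus=1.5, noise_sd=0.0))
        trimmed = trim_curve(curve, preload=2.0)
        assert np.all(trimmed.force > 2.0)

    def test_removes_failure_tail(self):
        params = SyntheticCurveParams(true_modulus=1.5, noise_sd=0.0, n_points=300)
        curve = generate_tensile_curve(SPEC, params)
        k_fail = np.argmax(curve.force)  # failure index by construction
        trimmed = trim_curve(curve)
        assert trimmed.displacement[-1] < curve.displacement[k_fail]

    def test_monotone_curve_keeps_tail(self):
        curve = make_linear_curve(2.0)
        trimmed = trim_curve(curve, preload=2.0)
        assert trimmed.displacement[-1] == curve.displacement[-1]

    def test_idempotent(self):
        curve = generate_tensile_curve(
            SPEC, SyntheticCurveParams(true_modulus=1.5, noise_sd=0.03, seed=9))
        once = trim_curve(curve)
        twice = trim_curve(once)
        np.testing.assert_array_equal(once.force, twice.force)

    def test_all_below_preload_raises(self):
        curve = make_linear_curve(0.01)  # max force 0.05 N
        with pytest.raises(EmptyAfterTrimError):
            trim_curve(curve, preload=2.0)


class TestEstimateModulus:
    def test_exact_slope_conversion(self):
        # slope 5 N/mm, L0=20 mm, A=10 mm^2 -> E = 10 MPa
        est = estimate_modulus(make_linear_curve(5.0, offset=2.5))
        assert est.young_modulus == pytest.approx(10.0, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_noiseless(self):
        params = SyntheticCurveParams(true_modulus=1.56, noise_sd=0.0)
        curve = trim_curve(generate_tensile_curve(SPEC, params))
        est = estimate_modulus(curve)
        assert est.young_modulus == pytest.approx(1.56, rel=0.005)

    def test_force_scaling_doubles_modulus(self):
        base = make_linear_curve(3.0, offset=2.5)
        doubled = TensileCurve(displacement=base.displacement,
                               force=2 * base.force, specimen=SPEC)
        assert estimate_modulus(doubled).young_modulus == pytest.approx(
            2 * estimate_modulus(base).young_modulus, rel=1e-12)

    def test_subsampling_invariance(self):
        params = SyntheticCurveParams(true_modulus=2.0, noise_sd=0.0, n_points=400)
        curve = trim_curve(generate_tensile_curve(SPEC, params))
        full = estimate_modulus(curve).young_modulus
        sub = TensileCurve(displacement=curve.displacement[::4],
                           force=curve.force[::4], specimen=SPEC)
        assert estimate_modulus(sub).young_modulus == pytest.approx(full, rel=0.01)

    def test_negative_slope_rejected(self):
        d = np.linspace(0.1, 5, 30)
        curve = TensileCurve(displacement=d, force=10 - d, specimen=SPEC)
        with pytest.raises(DegenerateSpecimenError):
            estimate_modulus(curve)

    def test_noisy_recovery_median_under_5pct(self):
        errs = []
        for seed in range(50):
            params = SyntheticCurveParams(
                true_modulus=1.56, noise_sd=0.02 * 9.0, seed=seed)
            curve = trim_curve(generate_tensile_curve(SPEC, params))
            est = estimate_modulus(curve)
            errs.append(abs(est.young_modulus - 1.56) / 1.56)
        assert np.median(errs) < 0.05


def _est(E):
    return ModulusEstimate(young_modulus=E, slope=1.0, fit_window=(0, 5),
                           r_squared=1.0)


class TestAggregateModuli:
    def test_single_estimate(self):
        df = aggregate_moduli([LabelledEstimate(_est(1.5), "s1", "P-intact")])
        row = df.iloc[0]
        assert row.specimen_mean_MPa == 1.5
        assert row.subject_mean_MPa == 1.5
        assert row.n_specimens == 1 and row.n_subjects == 1

    def test_specimen_vs_subject_hierarchy(self):
        rows = [
            LabelledEstimate(_est(1.0), "s1", "P-sm"),
            LabelledEstimate(_est(2.0), "s1", "P-sm"),
            LabelledEstimate(_est(4.0), "s2", "P-sm"),
        ]
        df = aggregate_moduli(rows)
        row = df.iloc[0]
        assert row.specimen_mean_MPa == pytest.approx(7.0 / 3)
        # subject means: s1 -> 1.5, s2 -> 4.0
        assert row.subject_mean_MPa == pytest.approx(2.75)
        assert row.n_specimens == 3 and row.n_subjects == 2

    def test_unknown_group_rejected(self):
        with pytest.raises(LabellingError):
            aggregate_moduli([LabelledEstimate(_est(1.0), "s1", "cat")])

    def test_synthetic_cohort_mean_near_truth(self):
        # specimens drawn around a 1.01 MPa population mean
        rng = np.random.default_rng(11)
        sd = 0.1
        n = 40
        rows = [
            LabelledEstimate(_est(rng.normal(1.01, sd)), f"s{i % 5}", "P-(mu+sm)")
            for i in range(n)
        ]
        df = aggregate_moduli(rows)
        assert abs(df.iloc[0].specimen_mean_MPa - 1.01) < 2 * sd / np.sqrt(n)
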