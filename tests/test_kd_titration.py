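import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from raseff.errors import DegenerateDataError, InsufficientDataError
from raseff.kd_titration import (
    BindingFit,
    TitrationCurve,
    fit_titration,
    fraction_bound,
    model_signal,
    replicate_summary,
)
from raseff.reference_data import titration_design
from raseff.synthetic_data import TitrationSpec, make_titration


def bisection_fraction(rt: float, et: float, kd: float) -> float:
    """Independent oracle: root of K_d·x = (R_t−x)(E_t−x) by bracketing."""
    if et == 0:
        return 0.0
    if kd == 0:
        return min(rt, et) / rt

    def f(x):
        return (rt - x) * (et - x) - kd * x

    x = brentq(f, 0.0, min(rt, et), xtol=1e-15)
    return x / rt


class TestFractionBound:
    def test_stoichiometric_limit(self):
        assert fraction_bound(1.0, 0.5, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_no_ligand(self):
        assert fraction_bound(1.0, 0.0, 3.7) == 0.0

    def test_matches_bisection_oracle_at_unit_point(self):
        # closed form: (3 − √5)/2
        assert fraction_bound(1.0, 1.0, 1.0) == pytest.approx(
            (3.0 - np.sqrt(5.0)) / 2.0, abs=1e-12
        )
        assert fraction_bound(1.0, 1.0, 1.0) == pytest.approx(
            bisection_fraction(1.0, 1.0, 1.0), abs=1e-9
        )

    @given(
        rt=st.floats(0.01, 10.0),
        et=st.floats(0.0, 200.0),
        kd=st.floats(0.0, 500.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bisection_oracle_everywhere(self, rt, et, kd):
        assert fraction_bound(rt, et, kd) == pytest.approx(
            bisection_fraction(rt, et, kd), abs=1e-8
        )

    @given(kd=st.floats(0.001, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ligand_and_bounded(self, kd):
        et = titration_design()
        frac = fraction_bound(1.0, et, kd)
        assert np.all(np.diff(frac) >= -1e-12)
        assert np.all(frac >= 0)
        assert np.all(frac <= np.minimum(1.0, et / 1.0) + 1e-12)

    def test_monotone_decreasing_in_kd(self):
        kds = np.geomspace(1e-3, 1e3, 25)
        vals = [fraction_bound(1.0, 5.0, k) for k in kds]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_hyperbolic_limit_when_receptor_negligible(self):
        # R_t ≤ K_d/100 ⇒ ligand depletion vanishes and the quadratic
        # solution approaches E_t/(E_t + K_d)
        kd = 10.0
        rt = kd / 100.0
        for et in (0.1, 1.0, 10.0, 100.0):
            hyper = et / (et + kd)
            assert fraction_bound(rt, et, kd) == pytest.approx(hyper, rel=0.01)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fraction_bound(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            fraction_bound(1.0, 1.0, -1.0)
        with pytest.raises(ValueError):
            fraction_bound(0.0, 1.0, 1.0)


class TestModelSignal:
    def design(self):
        return TitrationCurve(receptor_total=1.0, ligand_totals=titration_design())

    def test_no_binding_limit_is_flat_at_p_free(self):
        signals = model_signal(self.design(), kd=1e9, p_free=0.0, p_bound=1.0)
        assert np.all(np.abs(signals) < 1e-4)

    def test_saturation_at_zero_kd(self):
        curve = TitrationCurve(receptor_total=1.0, ligand_totals=np.array([1.0, 2.0, 5.0]))
        signals = model_signal(curve, kd=0.0, p_free=0.2, p_bound=0.9)
        assert signals == pytest.approx([0.9, 0.9, 0.9])

    def test_unit_point_value(self):
        curve = TitrationCurve(receptor_total=1.0, ligand_totals=np.array([0.5, 1.0]))
        signals = model_signal(curve, kd=1.0, p_free=0.0, p_bound=1.0)
        assert signals[1] == pytest.approx((3.0 - np.sqrt(5.0)) / 2.0, abs=1e-9)


class TestFitTitration:
    @pytest.mark.parametrize("kd_true", [0.05, 0.5, 5.0, 50.0, 200.0])
    def test_noise_free_recovery_across_regimes(self, kd_true):
        curve = make_titration(TitrationSpec(kd_true=kd_true))
        fit = fit_titration(curve)
        assert fit.converged
        assert fit.kd == pytest.approx(kd_true, rel=1e-2)

    def test_tight_binder_recovered_to_per_mil(self):
        curve = make_titration(TitrationSpec(kd_true=0.094))
        assert fit_titration(curve).kd == pytest.approx(0.094, rel=1e-3)

    def test_weak_binder_recovered(self):
        curve = make_titration(TitrationSpec(kd_true=204.7))
        assert fit_titration(curve).kd == pytest.approx(204.7, rel=1e-2)

    def test_roundtrip_recovers_all_three_parameters(self):
        curve = make_titration(TitrationSpec(kd_true=2.5), p_free=0.13, p_bound=0.47)
        fit = fit_titration(curve)
        assert fit.kd == pytest.approx(2.5, rel=1e-3)
        assert fit.p_free == pytest.approx(0.13, abs=1e-4)
        assert fit.p_bound == pytest.approx(0.47, abs=1e-3)
        assert fit.residual_norm < 1e-12

    def test_flat_signals_degenerate(self):
        curve = TitrationCurve(
            receptor_total=1.0,
            ligand_totals=titration_design(),
            signals=np.full(24, 0.5),
        )
        with pytest.raises(DegenerateDataError):
            fit_titration(curve)

    def test_too_few_points_rejected(self):
        curve = TitrationCurve(
            receptor_total=1.0,
            ligand_totals=np.array([0.1, 1.0, 10.0]),
            signals=np.array([0.1, 0.5, 0.9]),
        )
        with pytest.raises(InsufficientDataError):
            fit_titration(curve)

    def test_noisy_fit_has_finite_stderr(self):
        curve = make_titration(TitrationSpec(kd_true=1.0, noise_sd=0.02, seed=7))
        fit = fit_titration(curve)
        assert np.isfinite(fit.stderr_kd) and fit.stderr_kd > 0


class TestReplicateSummary:
    def test_identical_fits(self):
        fits = [BindingFit(1.0, 0, 1, 0.0, 0.0, True) for _ in range(3)]
        assert replicate_summary(fits) == (1.0, 0.0)

    def test_hand_computed_sem(self):
        fits = [BindingFit(0.9, 0, 1, 0.0, 0.0, True),
                BindingFit(1.1, 0, 1, 0.0, 0.0, True)]
        mean, sem = replicate_summary(fits)
        assert mean == pytest.approx(1.0)
        assert sem == pytest.approx(0.1)

    def test_single_fit_rejected(self):
        with pytest.raises(InsufficientDataError):
            replicate_summary([BindingFit(1.0, 0, 1, 0.0, 0.0, True)])
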