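"""Eddy-current and resonant-coupling model: closed forms, LTI contract,
trajectory errors, and the two-parameter residual analysis."""

import numpy as np
import pytest
from scipy.integrate import cumulative_simpson

from epighost.imperfections import (
    EddyTerm,
    ImperfectionModel,
    ResonantTerm,
    actual_trajectory,
    delta_k_dense,
    eddy_response,
    residual_after_linear_correction,
    resonant_response,
    tuneup_delay_us,
)
from epighost.presets import default_model, ripple_protocol, tuned
from epighost.units import K_PER_AREA
from epighost.waveforms import GradientWaveform, build_epi_train, integrate_trajectory


def _wf(g):
    t = np.arange(len(g), dtype=float)
    return GradientWaveform(axis="read", t_us=t, g_mT_per_m=np.asarray(g, float),
                            segment_marks=(0, len(g) - 1))


def _step(height=10.0, at=100, total=2000):
    g = np.zeros(total)
    g[at:] = height
    return _wf(g)


class TestEddyResponse:
    def test_no_terms_gives_zero(self):
        assert np.all(eddy_response(_step(), []).g_mT_per_m == 0.0)

    def test_step_response_matches_closed_form(self):
        a, tau, dG = 0.01, 70.0, 10.0
        at = 100
        wf = _step(dG, at=at)
        p = eddy_response(wf, [EddyTerm(a, tau)]).g_mT_per_m
        # the discrete step is a 1-sample ramp ending at t=at; afterwards
        # p(t) = -a dG (tau/dt)(1 - e^{-dt/tau}) e^{-(t-at)/tau} exactly
        t = wf.t_us
        amp = -a * dG * tau * (1.0 - np.exp(-1.0 / tau))
        expect = np.where(t >= at, amp * np.exp(-(t - at) / tau), 0.0)
        sel = t >= at
        assert np.max(np.abs(p[sel] - expect[sel])) < 1e-9 * abs(amp)

    def test_causality(self):
        p = eddy_response(_step(at=500), [EddyTerm(0.01, 120.0)]).g_mT_per_m
        assert np.all(p[:500] == 0.0)

    def test_lti_contract(self, rng):
        terms = [EddyTerm(0.004, 55.0), EddyTerm(-0.002, 240.0)]
        g1, g2 = rng.normal(size=300), rng.normal(size=300)
        a, b = 1.7, -0.6
        lhs = eddy_response(_wf(a * g1 + b * g2), terms).g_mT_per_m
        rhs = (a * eddy_response(_wf(g1), terms).g_mT_per_m
               + b * eddy_response(_wf(g2), terms).g_mT_per_m)
        assert np.max(np.abs(lhs - rhs)) < 1e-9 * np.max(np.abs(lhs))

    def test_negation_antisymmetry(self, rng):
        terms = [EddyTerm(0.003, 80.0)]
        g = rng.normal(size=200)
        assert np.array_equal(
            eddy_response(_wf(-g), terms).g_mT_per_m,
            -eddy_response(_wf(g), terms).g_mT_per_m,
        )


class TestResonantResponse:
    def test_zero_coupling_or_disabled(self):
        wf = _step()
        for term in (ResonantTerm(coupling=0.0), ResonantTerm(coupling=0.5, enabled=False)):
            assert np.all(resonant_response(wf, term).g_mT_per_m == 0.0)

    def test_on_resonance_steady_state_gain(self):
        f0, c = 1100.0, 0.2
        term = ResonantTerm(f0_Hz=f0, q_width_Hz=150.0, coupling=c)
        t = np.arange(40000, dtype=float)
        g = np.sin(2 * np.pi * f0 * t * 1e-6)
        p = resonant_response(_wf(g), term).g_mT_per_m
        mid = slice(15000, 25000)  # past the ring-in transient
        gain = np.max(np.abs(p[mid]))
        assert gain == pytest.approx(c, rel=0.02)

    def test_notch_rolloff_far_from_resonance(self):
        f0, c = 1100.0, 0.2
        term = ResonantTerm(f0_Hz=f0, q_width_Hz=150.0, coupling=c)
        t = np.arange(40000, dtype=float)
        g = np.sin(2 * np.pi * 10 * f0 * t * 1e-6)
        p = resonant_response(_wf(g), term).g_mT_per_m
        assert np.max(np.abs(p[15000:25000])) < 0.05 * c

    def test_output_is_real_and_same_length(self):
        wf = _step()
        p = resonant_response(wf, ResonantTerm(coupling=0.1)).g_mT_per_m
        assert p.dtype.kind == "f" and len(p) == len(wf.g_mT_per_m)


class TestActualTrajectory:
    def test_empty_model_is_nominal(self, ripple96):
        train = build_epi_train(ripple96, +1)
        nom = integrate_trajectory(train)
        act = actual_trajectory(train, ImperfectionModel())
        assert np.array_equal(act.kx, nom.kx)

    def test_delta_k_matches_dense_simpson_oracle(self, ripple96):
        train = build_epi_train(ripple96, +1)
        model = ImperfectionModel(eddy_terms=(EddyTerm(0.005, 120.0),))
        t_grid, dk = delta_k_dense(train, model)
        # independent oracle: Simpson integration of the sampled
        # perturbation on a 10x oversampled grid
        from epighost.imperfections import _eddy_state

        _, g = train.gradient_dense()
        t_fine = np.linspace(t_grid[0], t_grid[-1], (len(t_grid) - 1) * 10 + 1)
        g_fine = np.interp(t_fine, t_grid, g)
        p_fine = _eddy_state(g_fine, 0.1, model.eddy_terms[0])
        dk_oracle = K_PER_AREA * cumulative_simpson(p_fine, x=t_fine, initial=0.0)
        dk_oracle_at = np.interp(t_grid, t_fine, dk_oracle)
        assert np.max(np.abs(dk - dk_oracle_at)) < 1e-8 * np.max(np.abs(dk))

    def test_polarity_antisymmetry_exact(self, ripple96):
        model = default_model()
        tp = build_epi_train(ripple96, +1)
        tm = build_epi_train(ripple96, -1)
        dkp = actual_trajectory(tp, model).kx - integrate_trajectory(tp).kx
        dkm = actual_trajectory(tm, model).kx - integrate_trajectory(tm).kx
        assert np.array_equal(dkp, -dkm)

    def test_error_peaks_near_trapezoid_corners(self, ripple96):
        train = build_epi_train(ripple96, +1)
        model = ImperfectionModel(eddy_terms=(EddyTerm(0.01, 70.0),))
        nom = integrate_trajectory(train)
        act = actual_trajectory(train, model)
        dk = np.abs(act.kx - nom.kx)
        t_adc = train.sample_times_lobe_us
        marks_t = [train.lobe.t_us[m] for m in train.lobe.segment_marks] + [
            train.lobe.t_us[0], train.lobe.t_us[-1]
        ]
        mark_idx = np.array([np.argmin(np.abs(t_adc - mt)) for mt in marks_t])
        for l in range(4, train.n_lines):  # skip the train-onset transient
            peak = int(np.argmax(dk[l]))
            assert np.min(np.abs(peak - mark_idx)) <= 10

    def test_delay_model_shifts_trajectory(self, ripple96):
        train = build_epi_train(ripple96, +1)
        delay = 2.0
        act = actual_trajectory(train, ImperfectionModel(delay_us=delay))
        nom = integrate_trajectory(train)
        # on the flat top the shift is -delay * gamma * g * sign
        l = 10
        i, j = train.lobe.segment_marks
        flat = (train.sample_times_lobe_us > train.lobe.t_us[i] + 1) & (
            train.sample_times_lobe_us < train.lobe.t_us[j] - 1
        )
        expect = -delay * K_PER_AREA * train.lobe.amplitude * train.lobe_signs[l]
        assert np.allclose((act.kx - nom.kx)[l, flat], expect, rtol=1e-9)

    def test_disabling_resonance_reduces_error_energy(self, ripple96):
        train = build_epi_train(ripple96, +1)
        model = default_model(shim_connected=True)
        nom = integrate_trajectory(train)
        on = actual_trajectory(train, model).kx - nom.kx
        off = actual_trajectory(train, model.without_resonance()).kx - nom.kx
        assert np.sum(off**2) < np.sum(on**2)


class TestTwoParamResidual:
    def test_uniform_shift_fully_removed(self, ripple96):
        train = build_epi_train(ripple96, +1)
        nom = integrate_trajectory(train)
        act_kx = nom.kx.copy()
        act_kx[train.line_parity == 1] += 3e-4
        from epighost.waveforms import Trajectory

        act = Trajectory(kx=act_kx, ky=nom.ky, t_us=nom.t_us, ky_indices=nom.ky_indices)
        resid, fits = residual_after_linear_correction(nom, act, train)
        assert np.max(np.abs(resid)) < 1e-10

    def test_zero_perturbation_zero_residual(self, ripple96):
        train = build_epi_train(ripple96, +1)
        nom = integrate_trajectory(train)
        resid, fits = residual_after_linear_correction(nom, nom, train)
        assert np.max(np.abs(resid)) == 0.0

    def test_corner_eddy_residual_localized_at_segment_marks(self):
        # a lobe whose segments are long relative to tau shows the
        # transients as sharp corner features the linear fit cannot absorb
        from epighost.presets import factorial_protocol

        train = build_epi_train(factorial_protocol(N=96), +1)
        model = ImperfectionModel(eddy_terms=(EddyTerm(0.01, 70.0),))
        nom = integrate_trajectory(train)
        act = actual_trajectory(train, model)
        resid, _ = residual_after_linear_correction(nom, act, train)
        t_adc = train.sample_times_lobe_us
        marks_t = [train.lobe.t_us[m] for m in train.lobe.segment_marks] + [
            train.lobe.t_us[0], train.lobe.t_us[-1]
        ]
        near = np.zeros(len(t_adc), dtype=bool)
        for mt in marks_t:
            idx = np.argmin(np.abs(t_adc - mt))
            near[max(0, idx - 10) : idx + 11] = True
        steady = resid[4:]
        frac = np.sum(steady[:, near] ** 2) / np.sum(steady**2)
        assert frac > 0.5

    def test_recovers_injected_delay(self, ripple96):
        train = build_epi_train(ripple96, +1)
        nom = integrate_trajectory(train)
        act = actual_trajectory(train, ImperfectionModel(delay_us=1.5))
        resid, fits = residual_after_linear_correction(nom, act, train)
        for parity, (delay, off) in fits.items():
            assert delay == pytest.approx(-1.5, rel=1e-3)
        # residual is second order in the delay (true shift vs linear fit)
        assert np.max(np.abs(resid)) < 5e-3 * np.max(np.abs(act.kx - nom.kx))


def test_tuneup_nulls_center_error(ripple96):
    model = default_model()
    mt = tuned(model, ripple96)
    train = build_epi_train(ripple96, +1)
    nom = integrate_trajectory(train)
    act = actual_trajectory(train, mt)
    dk = act.kx - nom.kx
    rows = np.nonzero(train.line_parity == 0)[0]
    line = rows[len(rows) // 2]
    s = int(np.argmin(np.abs(nom.kx[line])))
    assert abs(dk[line, s]) < 1e-9 * np.max(np.abs(dk))


def test_term_validation():
    with pytest.raises(ValueError):
        EddyTerm(0.5, -1.0)
    with pytest.raises(ValueError):
        EddyTerm(1.5, 100.0)
    with pytest.raises(ValueError):
        ResonantTerm(f0_Hz=-5.0)
    with pytest.raises(ValueError):
        ResonantTerm(coupling=-0.1)
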