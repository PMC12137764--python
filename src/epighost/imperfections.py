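"""Linear time-invariant gradient imperfection model.

Two mechanisms perturb the demanded readout gradient:

* short-term eddy currents -- each gradient switching event couples a
  fraction ``a`` of the slew into a decaying field with time constant
  ``tau`` (50-500 us for the uncorrected short-term regime), modeled as
  the derivative of the waveform convolved with a causal exponential;
* resonant coupling -- inductive coupling between the readout gradient
  and a high-order shim circuit carves a complex Lorentzian notch of depth
  ``coupling`` into the gradient transfer function around the mechanical
  resonance f0 (1100 +- 150 Hz for the gradient set emulated here).

Both are linear and time-invariant, so the perturbation -- and hence the
trajectory error Delta-kx -- flips sign exactly when the readout polarity
is inverted. That antisymmetry is what makes the ghosts of opposite-
polarity acquisitions opposite in phase and cancellable by complex
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy.fft import next_fast_len, rfft, irfft
from scipy.interpolate import CubicHermiteSpline

from .units import K_PER_AREA
from .waveforms import EpiTrain, GradientWaveform, Trajectory, integrate_trajectory

__all__ = [
    "EddyTerm",
    "ResonantTerm",
    "ImperfectionModel",
    "eddy_response",
    "resonant_response",
    "actual_trajectory",
    "residual_after_linear_correction",
]


@dataclass(frozen=True)
class EddyTerm:
    """One exponential eddy-current mode: amplitude fraction and decay."""

    amplitude_fraction: float
    time_constant_us: float

    def __post_init__(self) -> None:
        if self.time_constant_us <= 0:
            raise ValueError("time_constant_us must be positive")
        if not abs(self.amplitude_fraction) < 1:
            raise ValueError("|amplitude_fraction| must be < 1")


@dataclass(frozen=True)
class ResonantTerm:
    """Resonant gradient-shim coupling: a Lorentzian notch in the GIRF.

    ``enabled=False`` represents the mitigation of physically
    disconnecting the coupled shim circuit.
    """

    f0_Hz: float = 1100.0
    q_width_Hz: float = 150.0
    coupling: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.f0_Hz <= 0 or self.q_width_Hz <= 0:
            raise ValueError("f0_Hz and q_width_Hz must be positive")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")


@dataclass(frozen=True)
class ImperfectionModel:
    """LTI perturbation model applied to the readout axis.

    ``delay_us`` is a pure timing delay of the realized gradient -- the
    classic global odd-even mismatch: the actual trajectory is the
    nominal one evaluated at t - delay. Like the other terms it is LTI,
    so its trajectory error flips sign under polarity inversion.
    """

    eddy_terms: tuple[EddyTerm, ...] = ()
    resonant: ResonantTerm | None = None
    delay_us: float = 0.0

    @property
    def is_empty(self) -> bool:
        res_off = (
            self.resonant is None
            or not self.resonant.enabled
            or self.resonant.coupling == 0
        )
        return not self.eddy_terms and res_off and self.delay_us == 0.0

    def scaled(self, factor: float) -> "ImperfectionModel":
        """Model with all perturbation amplitudes scaled by ``factor``."""
        terms = tuple(
            EddyTerm(t.amplitude_fraction * factor, t.time_constant_us)
            for t in self.eddy_terms
        )
        res = self.resonant
        if res is not None:
            res = ResonantTerm(res.f0_Hz, res.q_width_Hz, res.coupling * factor, res.enabled)
        return ImperfectionModel(
            eddy_terms=terms, resonant=res, delay_us=self.delay_us * factor
        )

    def without_resonance(self) -> "ImperfectionModel":
        res = self.resonant
        if res is not None:
            res = ResonantTerm(res.f0_Hz, res.q_width_Hz, res.coupling, enabled=False)
        return ImperfectionModel(
            eddy_terms=self.eddy_terms, resonant=res, delay_us=self.delay_us
        )


def _eddy_state(g: np.ndarray, dt: float, term: EddyTerm) -> np.ndarray:
    """Perturbation p(t) at the grid nodes for one eddy term.

    Within each cell the demanded slew is constant, so the convolution of
    dG/dt with a*exp(-t/tau) obeys an exact one-pole recursion
    p_{i+1} = E p_i - a m_i tau (1 - E), E = exp(-dt/tau), evaluated with
    scipy.signal.lfilter. No quadrature error is incurred.
    """
    a, tau = term.amplitude_fraction, term.time_constant_us
    E = np.exp(-dt / tau)
    m = np.diff(g) / dt
    y = scipy.signal.lfilter([-a * tau * (1.0 - E)], [1.0, -E], m)
    return np.concatenate([[0.0], y])


def _eddy_cumint(g: np.ndarray, dt: float, term: EddyTerm) -> np.ndarray:
    """Exact running integral of the eddy perturbation at the grid nodes."""
    a, tau = term.amplitude_fraction, term.time_constant_us
    E = np.exp(-dt / tau)
    m = np.diff(g) / dt
    p = _eddy_state(g, dt, term)
    # integral over cell i: p_i tau (1-E) - a m_i tau (dt - tau (1-E))
    cell = p[:-1] * tau * (1.0 - E) - a * m * tau * (dt - tau * (1.0 - E))
    return np.concatenate([[0.0], np.cumsum(cell)])


def eddy_response(
    waveform: GradientWaveform, terms: list[EddyTerm] | tuple[EddyTerm, ...]
) -> GradientWaveform:
    """Eddy-current perturbation of a waveform, on the same time base."""
    t, g = waveform.t_us, waveform.g_mT_per_m
    dts = np.diff(t)
    if dts.size and not np.allclose(dts, dts[0]):
        raise ValueError("waveform must be uniformly sampled")
    dt = float(dts[0]) if dts.size else 1.0
    p = np.zeros_like(g)
    for term in terms:
        p = p + _eddy_state(g, dt, term)
    return GradientWaveform(
        axis=waveform.axis, t_us=t.copy(), g_mT_per_m=p,
        segment_marks=waveform.segment_marks,
    )


def _lorentzian_notch_pert(f: np.ndarray, term: ResonantTerm) -> np.ndarray:
    """Perturbation transfer function P(f) = H(f) - 1 = -c (L(f-f0)+L(f+f0)),
    with L(x) = (w/2) / (w/2 + i x); Hermitian-symmetric, so the filtered
    output of a real waveform is real."""
    hw = term.q_width_Hz / 2.0

    def L(x):
        return hw / (hw + 1j * x)

    return -term.coupling * (L(f - term.f0_Hz) + L(f + term.f0_Hz))


def resonant_response(waveform: GradientWaveform, term: ResonantTerm) -> GradientWaveform:
    """Resonant-coupling perturbation of a waveform (zero when disabled)."""
    t, g = waveform.t_us, waveform.g_mT_per_m
    if not term.enabled or term.coupling == 0:
        p = np.zeros_like(g)
    else:
        dts = np.diff(t)
        dt_s = float(dts[0]) * 1e-6
        # pad beyond the resonance ring-down so the circular FFT does not wrap
        ring = int(np.ceil(5.0 / (np.pi * term.q_width_Hz) / dt_s))
        n = next_fast_len(len(g) + ring)
        f = np.fft.rfftfreq(n, d=dt_s)
        P = _lorentzian_notch_pert(f, term)
        p = irfft(rfft(g, n) * P, n)[: len(g)]
    return GradientWaveform(
        axis=waveform.axis, t_us=t.copy(), g_mT_per_m=p,
        segment_marks=waveform.segment_marks,
    )


def perturbation_dense(train: EpiTrain, model: ImperfectionModel) -> np.ndarray:
    """Total gradient perturbation of the train on its dense 1 us grid."""
    t, g = train.gradient_dense()
    wf = GradientWaveform(axis="read", t_us=t, g_mT_per_m=g, segment_marks=(0, len(t) - 1))
    p = np.zeros_like(g)
    if model.eddy_terms:
        p += eddy_response(wf, model.eddy_terms).g_mT_per_m
    if model.resonant is not None:
        p += resonant_response(wf, model.resonant).g_mT_per_m
    return p


def delta_k_dense(train: EpiTrain, model: ImperfectionModel) -> tuple[np.ndarray, np.ndarray]:
    """(t_grid, Delta-kx) of the perturbation on the dense grid, cycles/mm.

    Eddy contributions are integrated with the exact per-cell exponential
    quadrature; the resonant contribution (band-limited around f0) with
    the trapezoid rule on the 1 us grid.
    """
    t, g = train.gradient_dense()
    dt = 1.0
    C = np.zeros_like(g)
    for term in model.eddy_terms:
        C += _eddy_cumint(g, dt, term)
    if model.resonant is not None and model.resonant.enabled and model.resonant.coupling:
        wf = GradientWaveform(axis="read", t_us=t, g_mT_per_m=g, segment_marks=(0, len(t) - 1))
        pr = resonant_response(wf, model.resonant).g_mT_per_m
        C += np.concatenate([[0.0], np.cumsum(0.5 * (pr[1:] + pr[:-1]) * dt)])
    return t, K_PER_AREA * C


def actual_trajectory(train: EpiTrain, model: ImperfectionModel | None) -> Trajectory:
    """Trajectory actually traversed under the imperfection model.

    Equals the nominal trajectory plus the integral of the gradient
    perturbation; with short-tau eddy terms the largest |Delta-kx| on each
    line sits at the ramp/flat transitions of the trapezoid.
    """
    nominal = integrate_trajectory(train)
    if model is None or model.is_empty:
        return nominal
    t_samples = train.sample_times_us()
    kx = nominal.kx.copy()
    if model.delay_us:
        # delayed gradient: k_actual(t) = k_nominal(t - delay), evaluated
        # exactly from the piecewise-linear dense waveform
        t_grid, g = train.gradient_dense()
        k_nodes = np.concatenate(
            [[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(t_grid))]
        )
        from .waveforms import _integral_at

        shifted = np.clip(t_samples.ravel() - model.delay_us, t_grid[0], t_grid[-1])
        kx = train.prephase_kx + K_PER_AREA * _integral_at(
            t_grid, g, k_nodes, shifted
        ).reshape(t_samples.shape)
    if model.eddy_terms or (
        model.resonant is not None and model.resonant.enabled and model.resonant.coupling
    ):
        t_grid, dk = delta_k_dense(train, model)
        p = perturbation_dense(train, model) * K_PER_AREA  # derivative of dk
        spline = CubicHermiteSpline(t_grid, dk, p)
        kx = kx + spline(t_samples.ravel()).reshape(t_samples.shape)
    return Trajectory(kx=kx, ky=nominal.ky, t_us=nominal.t_us,
                      ky_indices=nominal.ky_indices)


def tuneup_delay_us(train: EpiTrain, model: ImperfectionModel) -> float:
    """Compensating gradient delay that zeroes the center-of-k-space
    trajectory error, emulating the scanner's delay tune-up.

    Production systems null the global readout delay during calibration;
    what remains afterwards is the kx-structured short-term error this
    package studies. The returned value (us) can be placed in
    ``ImperfectionModel.delay_us`` alongside the other terms so that the
    modeled hardware is delay-compensated at the echo center.
    """
    traj = actual_trajectory(train, model)
    nominal = integrate_trajectory(train)
    dk = traj.kx - nominal.kx
    # steady-state parity-0 line, sample nearest kx = 0
    rows = np.nonzero(train.line_parity == 0)[0]
    line = rows[len(rows) // 2]
    s = int(np.argmin(np.abs(nominal.kx[line])))
    g_flat = train.lobe.amplitude * float(train.lobe_signs[line])
    if g_flat == 0:
        raise ValueError("flat-top amplitude is zero")
    return float(dk[line, s] / (K_PER_AREA * g_flat))


def residual_after_linear_correction(
    nominal: Trajectory, actual: Trajectory, train: EpiTrain
) -> tuple[np.ndarray, dict[int, tuple[float, float]]]:
    """Trajectory error that no line-wise two-parameter correction removes.

    Per line parity, fits Delta-kx(t) ~ c + delta * dkx/dt (a constant kx
    offset plus a global gradient delay) by least squares over all samples
    of that parity and subtracts the fit. Returns (residual [n_lines,
    n_adc], {parity: (delay_us, offset_cycles_per_mm)}).

    When dkx/dt is constant over the ADC window (flat-top-only sampling)
    the delay is indistinguishable from the offset; the fit then reduces
    to offset-only with delay reported as 0. A zero-gradient window raises.
    """
    dk = actual.kx - nominal.kx
    # nominal dkx/dt at each ADC sample, from the template lobe
    t_lobe = train.sample_times_lobe_us
    g_lobe = np.interp(t_lobe, train.lobe.t_us, train.lobe.g_mT_per_m)
    parities = train.line_parity
    residual = np.empty_like(dk)
    fits: dict[int, tuple[float, float]] = {}
    for parity in (0, 1):
        rows = np.nonzero(parities == parity)[0]
        if rows.size == 0:
            continue
        sign = float(train.lobe_signs[rows[0]])
        slope = K_PER_AREA * sign * g_lobe  # cycles/mm per us, per sample
        y = dk[rows].ravel()
        A = np.column_stack(
            [np.ones(rows.size * t_lobe.size), np.tile(slope, rows.size)]
        )
        if np.allclose(g_lobe, 0.0):
            raise ValueError("singular fit: zero readout gradient over the ADC window")
        if np.ptp(slope) < 1e-12 * np.max(np.abs(slope)):
            c = float(np.mean(y))
            fits[parity] = (0.0, c)
            residual[rows] = dk[rows] - c
            continue
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        c, delay = float(coef[0]), float(coef[1])
        fits[parity] = (delay, c)
        residual[rows] = dk[rows] - (c + delay * slope)[None, :]
    return residual, fits
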