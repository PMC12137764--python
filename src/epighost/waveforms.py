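"""Trapezoidal EPI readout synthesis and nominal trajectory integration.

The readout train is a sequence of sign-alternating trapezoidal gradient
lobes played back-to-back, one lobe per echo spacing, with instantaneous
phase-encode blips at the lobe transitions. Two ADC modes are supported:

* ramp sampling on  -- the ADC covers the whole lobe and the full lobe area
  equals the prescribed kx width N/FOV, so samples on the ramps encode the
  outer *and* a sizeable inner portion of kx and must be regridded;
* ramp sampling off -- the ADC covers the flat top only, whose area alone
  equals N/FOV, so samples are already uniform in kx.

Lobe design fixes the lobe duration to the echo spacing and minimizes the
amplitude subject to the slew limit (slew at its limit on the ramps up to
1 us quantization), which is how encoding-limited EPI readouts are run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import K_PER_AREA

__all__ = [
    "ProtocolSpec",
    "GradientWaveform",
    "EpiTrain",
    "Trajectory",
    "InfeasibleProtocolError",
    "design_readout_lobe",
    "ramp_sampling_fraction",
    "build_epi_train",
    "integrate_trajectory",
    "harmonic_frequencies",
]


class InfeasibleProtocolError(ValueError):
    """No gradient lobe under (gmax, smax) realizes the protocol."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition prescription for one 2D EPI slice/partition.

    Parameters
    ----------
    matrix_size : int
        Image matrix N (isotropic, even).
    fov_mm : float
        Field of view in mm.
    echo_spacing_ms : float
        Time between consecutive gradient-echo centers; one readout lobe
        occupies exactly one echo spacing.
    dwell_us : float
        ADC sample interval in microseconds.
    gmax_mT_per_m, smax_T_per_m_per_s : float
        Gradient amplitude and slew-rate limits.
    ramp_sampling : bool
        Acquire on the ramps (True) or flat top only (False).
    grappa_factor : int
        Phase-encode undersampling factor R.
    acs_lines : int
        Fully sampled autocalibration lines at the ky center (even).
    train_polarity : int
        Sign of the first readout lobe, +1 or -1.
    te_ms : float or None
        Echo time: excitation to the center-of-k-space sample. None means
        the minimum feasible TE.
    """

    matrix_size: int
    fov_mm: float
    echo_spacing_ms: float
    dwell_us: float = 5.0
    gmax_mT_per_m: float = 40.0
    smax_T_per_m_per_s: float = 90.0
    ramp_sampling: bool = True
    grappa_factor: int = 1
    acs_lines: int = 24
    train_polarity: int = 1
    te_ms: float | None = None

    def __post_init__(self) -> None:
        N = self.matrix_size
        if N <= 0 or N % 2:
            raise ValueError(f"matrix_size must be positive and even, got {N}")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if self.echo_spacing_ms <= 0:
            raise ValueError("echo_spacing_ms must be positive")
        if self.dwell_us <= 0:
            raise ValueError("dwell_us must be positive")
        if self.grappa_factor < 1:
            raise ValueError("grappa_factor must be >= 1")
        if self.acs_lines % 2 or not (0 <= self.acs_lines <= N):
            raise ValueError("acs_lines must be even and within [0, N]")
        if self.train_polarity not in (+1, -1):
            raise ValueError("train_polarity must be +1 or -1")

    @property
    def kx_width(self) -> float:
        """Prescribed kx coverage N/FOV in cycles/mm."""
        return self.matrix_size / self.fov_mm

    @property
    def delta_k(self) -> float:
        """k-space grid spacing 1/FOV in cycles/mm."""
        return 1.0 / self.fov_mm

    def acquired_ky_indices(self) -> np.ndarray:
        """Sorted ky indices covered by the train: every R-th line plus a
        contiguous ACS center block (when R > 1)."""
        N, R = self.matrix_size, self.grappa_factor
        lines = set(range(0, N, R))
        if R > 1 and self.acs_lines:
            lo = N // 2 - self.acs_lines // 2
            lines.update(range(lo, lo + self.acs_lines))
        return np.array(sorted(lines), dtype=int)


@dataclass
class GradientWaveform:
    """One gradient waveform sampled on a uniform 1 us grid.

    ``segment_marks = (ramp_up_end, flat_end)`` are indices into ``t_us``;
    a rectangle has marks (0, n-1) and a triangle (n//2, n//2).
    """

    axis: str
    t_us: np.ndarray
    g_mT_per_m: np.ndarray
    segment_marks: tuple[int, int]

    @property
    def duration_us(self) -> float:
        return float(self.t_us[-1] - self.t_us[0])

    @property
    def amplitude(self) -> float:
        return float(np.max(np.abs(self.g_mT_per_m)))

    @property
    def ramp_up_us(self) -> float:
        return float(self.t_us[self.segment_marks[0]] - self.t_us[0])

    @property
    def flat_top_us(self) -> float:
        i, j = self.segment_marks
        return float(self.t_us[j] - self.t_us[i])

    def area(self) -> float:
        """Trapezoid-rule area in mT/m * us (exact for piecewise-linear g
        with breakpoints on the grid)."""
        return float(np.trapezoid(self.g_mT_per_m, self.t_us))

    def flat_area(self) -> float:
        i, j = self.segment_marks
        return float(np.trapezoid(self.g_mT_per_m[i : j + 1], self.t_us[i : j + 1]))

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.t_us, self.g_mT_per_m]),
            fmt="%.6f",
            delimiter="\t",
            header="time_us\tg_mT_per_m",
            comments="",
        )


def _trapezoid_waveform(ramp_us: int, flat_us: int, amp: float) -> GradientWaveform:
    """Symmetric trapezoid on the integer-us grid (exact breakpoints)."""
    total = 2 * ramp_us + flat_us
    t = np.arange(total + 1, dtype=float)
    g = np.empty_like(t)
    r = max(ramp_us, 1)
    g[: ramp_us + 1] = amp * t[: ramp_us + 1] / r if ramp_us else amp
    g[ramp_us : ramp_us + flat_us + 1] = amp
    g[ramp_us + flat_us :] = amp * (total - t[ramp_us + flat_us :]) / r if ramp_us else amp
    g[0] = 0.0 if ramp_us else g[0]
    if ramp_us == 0:  # rectangle: starts/ends at amplitude by convention
        g[:] = amp
    return GradientWaveform(
        axis="read",
        t_us=t,
        g_mT_per_m=g,
        segment_marks=(ramp_us, ramp_us + flat_us),
    )


def design_readout_lobe(protocol: ProtocolSpec) -> GradientWaveform:
    """Design the trapezoidal readout lobe for one echo spacing.

    The lobe duration is fixed at the echo spacing; ramps run at the slew
    limit (up to 1 us quantization) and the amplitude is the minimum that
    realizes the required kx area: the *total* lobe area N/FOV with ramp
    sampling, the *flat-top* area alone N/FOV without.

    Raises
    ------
    InfeasibleProtocolError
        If no trapezoid under (gmax, smax) achieves the area in time.
    """
    T = int(round(protocol.echo_spacing_ms * 1000.0))
    area_needed = protocol.kx_width / K_PER_AREA  # mT/m * us
    s = protocol.smax_T_per_m_per_s * 1e-3  # mT/m per us
    gmax = protocol.gmax_mT_per_m

    if protocol.ramp_sampling:
        # g*(T - r) = A with g = s*r  ->  r^2 - T r + A/s = 0
        disc = T * T - 4.0 * area_needed / s
        if disc < 0:
            raise InfeasibleProtocolError(
                f"kx area {area_needed:.1f} mT/m*us not reachable in "
                f"{T} us at smax={protocol.smax_T_per_m_per_s} T/m/s"
            )
        r = int(math.ceil((T - math.sqrt(disc)) / 2.0))
        r = min(max(r, 1), T // 2)
        amp = area_needed / (T - r)
    else:
        # flat-top area g*(T - 2r) = A with g = s*r -> 2r^2 - T r + A/s = 0
        disc = T * T - 8.0 * area_needed / s
        if disc < 0:
            raise InfeasibleProtocolError(
                f"flat-top kx area {area_needed:.1f} mT/m*us not reachable "
                f"in {T} us at smax={protocol.smax_T_per_m_per_s} T/m/s "
                "(ramp_sampling=False needs extra headroom)"
            )
        r = int(math.ceil((T - math.sqrt(disc)) / 4.0))
        r = min(max(r, 1), (T - 1) // 2)
        amp = area_needed / (T - 2 * r)

    if amp > gmax * (1 + 1e-12):
        raise InfeasibleProtocolError(
            f"required amplitude {amp:.2f} mT/m exceeds gmax={gmax} mT/m"
        )
    if amp / r > s * (1 + 1e-9):
        raise InfeasibleProtocolError(
            f"required slew {amp / r * 1e3:.1f} T/m/s exceeds "
            f"smax={protocol.smax_T_per_m_per_s} T/m/s"
        )
    return _trapezoid_waveform(r, T - 2 * r, amp)


def adc_times(lobe: GradientWaveform, dwell_us: float, ramp_sampling: bool) -> np.ndarray:
    """ADC sample times relative to lobe start.

    With ramp sampling the window is the whole lobe starting at t=0 (the
    first sample sits exactly on the -kmax edge of the grid); without, the
    window is the flat top starting at its first instant.
    """
    if ramp_sampling:
        t0, t1 = float(lobe.t_us[0]), float(lobe.t_us[-1])
    else:
        i, j = lobe.segment_marks
        t0, t1 = float(lobe.t_us[i]), float(lobe.t_us[j])
    n = int(math.floor((t1 - t0) / dwell_us)) + 1
    return t0 + dwell_us * np.arange(n)


def ramp_sampling_fraction(lobe: GradientWaveform, dwell_us: float) -> float:
    """Fraction of ADC samples falling on the lobe ramps.

    The ADC window spans the whole lobe. A rectangle gives 0.0, a triangle
    1.0; the submillimeter protocols this package emulates run up to ~0.78.
    """
    t = adc_times(lobe, dwell_us, ramp_sampling=True)
    i, j = lobe.segment_marks
    ramp_up_end = float(lobe.t_us[i])
    flat_end = float(lobe.t_us[j])
    on_flat = (t >= ramp_up_end) & (t <= flat_end) & (flat_end > ramp_up_end)
    return 1.0 - float(np.count_nonzero(on_flat)) / float(t.size)


@dataclass
class EpiTrain:
    """A full EPI readout train: one template lobe replayed with
    alternating sign, plus the ky schedule realized by the blips."""

    protocol: ProtocolSpec
    lobe: GradientWaveform
    lobe_signs: np.ndarray  # per line, +-1
    ky_indices: np.ndarray  # per line, 0..N-1
    sample_times_lobe_us: np.ndarray  # ADC times relative to lobe start
    start_time_us: float  # excitation -> first lobe start
    prephase_kx: float  # kx at the start of the first lobe, cycles/mm

    @property
    def n_lines(self) -> int:
        return len(self.ky_indices)

    @property
    def line_parity(self) -> np.ndarray:
        """0 for lines sharing the first lobe's sign, 1 otherwise."""
        return (np.arange(self.n_lines) % 2).astype(int)

    @property
    def echo_spacing_us(self) -> float:
        return self.protocol.echo_spacing_ms * 1000.0

    @property
    def blips_delta_ky(self) -> np.ndarray:
        """Instantaneous Delta-ky at each lobe transition, cycles/mm."""
        return np.diff(self.ky_indices) * self.protocol.delta_k

    def sample_times_us(self) -> np.ndarray:
        """Absolute ADC times from excitation, [n_lines, n_adc]."""
        esp = self.echo_spacing_us
        line_starts = self.start_time_us + esp * np.arange(self.n_lines)
        return line_starts[:, None] + self.sample_times_lobe_us[None, :]

    def gradient_dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Readout gradient of the whole train on the uniform 1 us grid,
        from excitation (zero before the train starts)."""
        esp = int(round(self.echo_spacing_us))
        n_pre = int(round(self.start_time_us))
        total = n_pre + esp * (self.n_lines - 1) + len(self.lobe.t_us)
        g = np.zeros(total, dtype=float)
        for i, sign in enumerate(self.lobe_signs):
            a = n_pre + i * esp
            seg = g[a : a + len(self.lobe.t_us)]
            seg += sign * self.lobe.g_mT_per_m[: len(seg)]
        t = np.arange(total, dtype=float)
        return t, g


def build_epi_train(protocol: ProtocolSpec, polarity: int | None = None) -> EpiTrain:
    """Assemble the EPI train for a protocol.

    The prephaser puts the first sample of the first lobe at
    (-N/(2 FOV) * polarity, ky of the first acquired line); blips are
    instantaneous; the center-of-k-space sample of the DC line lands on TE.
    """
    if polarity is None:
        polarity = protocol.train_polarity
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    lobe = design_readout_lobe(protocol)
    ky = protocol.acquired_ky_indices()
    n_lines = len(ky)
    signs = polarity * (-1) ** np.arange(n_lines)
    t_adc = adc_times(lobe, protocol.dwell_us, protocol.ramp_sampling)

    # enough ADC coverage for regridding onto all N grid points
    span = (t_adc[-1] - t_adc[0]) if protocol.ramp_sampling else lobe.flat_top_us
    if not protocol.ramp_sampling:
        covered = (t_adc[-1] - t_adc[0]) / span
        if covered < 1.0 - 1.0 / protocol.matrix_size:
            raise InfeasibleProtocolError(
                "dwell too coarse: flat-top ADC window does not cover the "
                "outermost kx grid point"
            )

    # TE: center sample of the DC line (ky index N/2) at te_ms
    dc_pos = int(np.searchsorted(ky, protocol.matrix_size // 2))
    if dc_pos >= n_lines or ky[dc_pos] != protocol.matrix_size // 2:
        raise InfeasibleProtocolError("ky schedule does not contain the DC line")
    esp = protocol.echo_spacing_ms * 1000.0
    t_center_in_train = dc_pos * esp + lobe.duration_us / 2.0
    if protocol.te_ms is None:
        start = 0.0
    else:
        start = protocol.te_ms * 1000.0 - t_center_in_train
        if start < -1e-9:
            raise InfeasibleProtocolError(
                f"TE {protocol.te_ms} ms infeasible: center of k-space is "
                f"reached {t_center_in_train / 1000.0:.3f} ms into the train"
            )
        # snap to the 1 us waveform grid so dense integration and ADC
        # timestamps share the same time base
        start = float(round(max(start, 0.0)))

    prephase = -np.sign(signs[0]) * lobe.area() / 2.0 * K_PER_AREA
    return EpiTrain(
        protocol=protocol,
        lobe=lobe,
        lobe_signs=signs.astype(int),
        ky_indices=ky,
        sample_times_lobe_us=t_adc,
        start_time_us=float(start),
        prephase_kx=float(prephase),
    )


@dataclass
class Trajectory:
    """Per-sample k-space coordinates of a train, cycles/mm."""

    kx: np.ndarray  # [n_lines, n_adc]
    ky: np.ndarray  # [n_lines]
    t_us: np.ndarray  # [n_lines, n_adc], from excitation
    ky_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_lines(self) -> int:
        return self.kx.shape[0]


def _integral_at(t_grid: np.ndarray, g: np.ndarray, k_nodes: np.ndarray,
                 t_query: np.ndarray) -> np.ndarray:
    """Evaluate the running integral of a piecewise-linear g at arbitrary
    times: exact in-cell quadrature k(t) = k_i + (g_i + g(t))/2 * (t - t_i)."""
    idx = np.clip(np.searchsorted(t_grid, t_query, side="right") - 1, 0, len(t_grid) - 2)
    t0 = t_grid[idx]
    dt = t_query - t0
    h = t_grid[idx + 1] - t_grid[idx]
    g_t = g[idx] + (g[idx + 1] - g[idx]) * (dt / h)
    return k_nodes[idx] + 0.5 * (g[idx] + g_t) * dt


def integrate_trajectory(train: EpiTrain, g_dense: np.ndarray | None = None) -> Trajectory:
    """Time-integrate the (nominal) readout gradient into per-sample kx.

    The dense 1 us waveform is integrated with the trapezoid rule -- exact
    for the piecewise-linear nominal lobes -- and evaluated at the ADC
    times with exact in-cell quadrature. ``g_dense`` substitutes a
    perturbed waveform on the same grid.
    """
    t_grid, g_nom = train.gradient_dense()
    g = g_nom if g_dense is None else g_dense
    if len(g) != len(t_grid):
        raise ValueError("g_dense must match the train's dense time grid")
    k_nodes = np.concatenate(
        [[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(t_grid))]
    )
    t_samples = train.sample_times_us()
    kx = train.prephase_kx + K_PER_AREA * _integral_at(
        t_grid, g, k_nodes, t_samples.ravel()
    ).reshape(t_samples.shape)
    ky = (train.ky_indices - train.protocol.matrix_size // 2) * train.protocol.delta_k
    return Trajectory(kx=kx, ky=ky, t_us=t_samples, ky_indices=train.ky_indices.copy())


def harmonic_frequencies(echo_spacing_ms: float, n: int) -> np.ndarray:
    """Harmonics of the EPI readout waveform in Hz.

    The alternating-lobe gradient waveform is periodic with period two echo
    spacings, so harmonic m sits at m / (2 esp); at esp = 1.26 ms the third
    harmonic is ~1190 Hz, coincident with typical gradient-coil mechanical
    resonances.
    """
    if echo_spacing_ms <= 0:
        raise ValueError("echo_spacing_ms must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    m = np.arange(1, n + 1)
    return m / (2.0 * echo_spacing_ms * 1e-3)
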