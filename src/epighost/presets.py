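"""Default desk-scale protocols, imperfection models, and phantoms.

Matrix sizes are deliberately smaller than in-vivo submillimeter
protocols (which run matrices of 200-300); gradient limits are derived so
the designed readout lobes land in the same qualitative regimes:

* ``ripple_protocol`` -- encoding-limited lobe whose ramps occupy ~78% of
  its duration (the regime reported for submillimeter EPI), placing the
  trapezoid-corner trajectory errors at low-to-mid |kx|;
* ``factorial_protocol`` -- enough slew headroom that the same
  prescription is feasible with ramp sampling on *and* off (flat-top-only
  sampling needs the full kx area on the flat top);
* ``sweep_protocol`` -- feasible across the 0.9-1.5 ms echo-spacing range
  used for the resonance sweep.

The imperfection fixtures are built from short-term eddy modes inside the
50-500 us band and a resonant shim-coupling notch at 1100 Hz of width
150 Hz. Mode amplitudes and the coupling depth are simulation
calibration constants chosen so the single-polarity ghost-to-signal
ratio of the full fixture lands at a few percent, the severity seen on
affected scanners. Fixtures are used *delay-compensated* (see
:func:`tuned`): the scanner's tune-up nulls the trajectory error at the
echo center, so what remains is the kx-structured residue that survives
line-wise correction.

Two phantom presets exist because desk-scale matrices put the spectral
band cutoff (structures of 5% FOV) at only ~40% of kmax: ghost-ratio
fixtures use :func:`default_phantom` (one pixel of edge smoothing, so
truncation ringing does not pollute the ghost region), while spectral
band-split fixtures use :func:`band_phantom` (0.8 mm edges, so edge
ghosts retain power above the cutoff).
"""

from __future__ import annotations

from dataclasses import replace

from .imperfections import EddyTerm, ImperfectionModel, ResonantTerm, tuneup_delay_us
from .phantoms import EllipsePhantom, make_shepp_logan
from .waveforms import ProtocolSpec, build_epi_train
from .units import K_PER_AREA

__all__ = [
    "ripple_protocol",
    "factorial_protocol",
    "sweep_protocol",
    "eddy_only_model",
    "short_eddy_model",
    "resonance_model",
    "default_model",
    "delay_model",
    "tuned",
    "default_phantom",
    "band_phantom",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20250402

#: short-term eddy modes (amplitude fraction, time constant us)
EDDY_TERMS = (EddyTerm(0.003, 70.0), EddyTerm(0.002, 300.0))

#: single fast eddy mode used for the ramp-sampling factorial arms; its
#: time constant is well below the flat-top duration of the no-ramp lobe,
#: which is the premise of flat-top-only sampling escaping corner errors
SHORT_EDDY_A = 0.05
SHORT_EDDY_TAU_US = 70.0

#: resonant shim-coupling defaults: center and width of the emulated
#: gradient set's mechanical resonance; depth is a calibration constant
RESONANCE_F0_HZ = 1100.0
RESONANCE_WIDTH_HZ = 150.0
RESONANCE_COUPLING = 0.15

#: edge smoothing (mm) of the band-split phantom
BAND_EDGE_SMOOTH_MM = 0.8


def ripple_protocol(
    N: int = 128,
    fov_mm: float = 175.0,
    echo_spacing_ms: float = 1.26,
    grappa_factor: int = 1,
    ramp_time_fraction: float = 0.78,
    **kwargs,
) -> ProtocolSpec:
    """High ramp-sampling-fraction protocol (the artifact fixture).

    The slew limit is derived so the designed lobe spends
    ``ramp_time_fraction`` of its duration on the ramps.
    """
    T = round(echo_spacing_ms * 1000.0)
    r = round(ramp_time_fraction * T / 2.0)
    area = (N / fov_mm) / K_PER_AREA  # mT/m * us
    amp = area / (T - r)
    kwargs.setdefault("smax_T_per_m_per_s", amp / r * 1e3 * (1 + 1e-6))
    kwargs.setdefault("gmax_mT_per_m", max(40.0, amp * 1.05))
    kwargs.setdefault("dwell_us", 5.0)
    return ProtocolSpec(
        matrix_size=N, fov_mm=fov_mm, echo_spacing_ms=echo_spacing_ms,
        grappa_factor=grappa_factor, **kwargs,
    )


def factorial_protocol(
    N: int = 128,
    fov_mm: float = 175.0,
    echo_spacing_ms: float = 1.26,
    ramp_sampling: bool = True,
    grappa_factor: int = 1,
    **kwargs,
) -> ProtocolSpec:
    """Slew-generous protocol feasible with and without ramp sampling."""
    kwargs.setdefault("smax_T_per_m_per_s", 90.0)
    kwargs.setdefault("gmax_mT_per_m", 40.0)
    kwargs.setdefault("dwell_us", 5.0)
    return ProtocolSpec(
        matrix_size=N, fov_mm=fov_mm, echo_spacing_ms=echo_spacing_ms,
        ramp_sampling=ramp_sampling, grappa_factor=grappa_factor, **kwargs,
    )


def sweep_protocol(
    echo_spacing_ms: float, N: int = 96, fov_mm: float = 175.0, **kwargs
) -> ProtocolSpec:
    """Protocol family for the echo-spacing sweep (feasible 0.9-1.5 ms)."""
    kwargs.setdefault("smax_T_per_m_per_s", 70.0)
    kwargs.setdefault("gmax_mT_per_m", 40.0)
    kwargs.setdefault("dwell_us", 5.0)
    return ProtocolSpec(
        matrix_size=N, fov_mm=fov_mm, echo_spacing_ms=echo_spacing_ms, **kwargs
    )


def eddy_only_model(scale: float = 1.0) -> ImperfectionModel:
    """The two default short-term eddy modes, no resonance."""
    return ImperfectionModel(eddy_terms=EDDY_TERMS).scaled(scale)


def short_eddy_model(scale: float = 1.0) -> ImperfectionModel:
    """Single fast eddy mode for the ramp-sampling comparison arms."""
    return ImperfectionModel(
        eddy_terms=(EddyTerm(SHORT_EDDY_A, SHORT_EDDY_TAU_US),)
    ).scaled(scale)


def resonance_model(coupling: float = RESONANCE_COUPLING, enabled: bool = True) -> ImperfectionModel:
    """Resonant shim-coupling corruption only."""
    return ImperfectionModel(
        resonant=ResonantTerm(RESONANCE_F0_HZ, RESONANCE_WIDTH_HZ, coupling, enabled)
    )


def default_model(shim_connected: bool = True) -> ImperfectionModel:
    """Eddy terms plus the shim-coupling resonance (the full fixture);
    ``shim_connected=False`` represents unplugging the coupled shim."""
    return ImperfectionModel(
        eddy_terms=EDDY_TERMS,
        resonant=ResonantTerm(
            RESONANCE_F0_HZ, RESONANCE_WIDTH_HZ, RESONANCE_COUPLING, shim_connected
        ),
    )


def delay_model(delay_us: float = 2.0) -> ImperfectionModel:
    """Pure readout-timing delay: the classic global odd-even mismatch
    that line-wise two-parameter correction fully removes."""
    return ImperfectionModel(delay_us=delay_us)


def tuned(model: ImperfectionModel, protocol: ProtocolSpec) -> ImperfectionModel:
    """Model with the scanner's delay tune-up applied: a compensating
    gradient delay nulls the trajectory error at the echo center, leaving
    only the kx-structured residue of the eddy/resonance terms."""
    train = build_epi_train(protocol, +1)
    return replace(model, delay_us=model.delay_us + tuneup_delay_us(train, model))


def default_phantom(N: int, fov_mm: float = 175.0) -> tuple[EllipsePhantom, "object"]:
    """Head phantom for ghost-ratio fixtures: scaled to keep the FOV/2
    ghost on background, with one pixel of Gaussian edge smoothing so
    truncation ringing does not set the ghost-region floor."""
    return make_shepp_logan(N, fov_mm, edge_smooth_mm=fov_mm / N)


def band_phantom(N: int, fov_mm: float = 175.0) -> tuple[EllipsePhantom, "object"]:
    """Head phantom for spectral band-split fixtures: 0.8 mm edges keep
    edge-ghost power above the 5%-FOV band cutoff at desk-scale N."""
    return make_shepp_logan(N, fov_mm, edge_smooth_mm=BAND_EDGE_SMOOTH_MM)
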