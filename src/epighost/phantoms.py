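"""Analytic ellipse phantoms, off-resonance maps, and coil sensitivities.

The ellipse phantom plays the role of the imaged brain: its Fourier
transform is known in closed form (Bessel-J1 "jinc" radial profile per
ellipse), so the EPI forward model can be evaluated at *arbitrary*
k-space points. Simulated data therefore never come from the same N x N
DFT used by the reconstruction, avoiding the inverse crime.

By default the head ellipse is scaled well below half the FOV in the
phase-encode direction -- the deliberately generous FOV prescription used
to observe Nyquist ghosts separated from the object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import j1

__all__ = [
    "EllipsePhantom",
    "FieldMap",
    "CoilSet",
    "make_shepp_logan",
    "analytic_kspace",
    "make_fieldmap",
    "make_coils",
]

# (intensity, semi-x, semi-y, x0, y0, rotation-deg) in units of the unit
# disk; the classic head phantom with high-contrast intensities.
_SHEPP_LOGAN = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


@dataclass(frozen=True)
class Ellipse:
    intensity: float
    semi_axes_mm: tuple[float, float]
    center_mm: tuple[float, float]
    rotation_deg: float


@dataclass
class EllipsePhantom:
    """Sum of rotated, shifted ellipses with additive intensities.

    ``edge_smooth_mm`` applies a Gaussian apodization of that standard
    deviation to the object's edges (a k-space Gaussian envelope),
    emulating the finite edge sharpness of real objects; without it the
    band-limited phantom's truncation ringing dominates the ghost-region
    background and masks the artifacts under study.
    """

    ellipses: list[Ellipse]
    fov_mm: float
    edge_smooth_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.ellipses:
            raise ValueError("phantom needs at least one ellipse")

    def total_intensity_area(self) -> float:
        """Sum over ellipses of pi*a*b*intensity (the k=0 signal)."""
        return float(
            sum(np.pi * e.semi_axes_mm[0] * e.semi_axes_mm[1] * e.intensity
                for e in self.ellipses)
        )

    def raster(self, N: int, oversample: int = 1) -> np.ndarray:
        """Rasterize by per-pixel membership on an N x N grid over the FOV
        (image axes [y, x]); oversample > 1 anti-aliases by box averaging
        on a grid aligned so block centers coincide with the coarse pixel
        centers. Gaussian edge smoothing, when set, is applied on the
        sampling grid before any downsampling.
        """
        n = N * oversample
        c = grid_coords_mm(n, self.fov_mm)
        if oversample > 1:
            # align fine-block centers with coarse pixel centers
            c = c + (0.5 - oversample / 2.0) * (self.fov_mm / n)
        X, Y = np.meshgrid(c, c, indexing="xy")
        img = np.zeros((n, n))
        for e in self.ellipses:
            phi = np.deg2rad(e.rotation_deg)
            xr = (X - e.center_mm[0]) * np.cos(phi) + (Y - e.center_mm[1]) * np.sin(phi)
            yr = -(X - e.center_mm[0]) * np.sin(phi) + (Y - e.center_mm[1]) * np.cos(phi)
            img += e.intensity * (
                (xr / e.semi_axes_mm[0]) ** 2 + (yr / e.semi_axes_mm[1]) ** 2 <= 1.0
            )
        if self.edge_smooth_mm:
            from scipy.ndimage import gaussian_filter

            img = gaussian_filter(img, self.edge_smooth_mm / (self.fov_mm / n))
        if oversample > 1:
            img = img.reshape(N, oversample, N, oversample).mean(axis=(1, 3))
        return img

    def support_mask(self, N: int) -> np.ndarray:
        """Boolean support of the outermost ellipse on the N-grid."""
        e = self.ellipses[0]
        c = grid_coords_mm(N, self.fov_mm)
        X, Y = np.meshgrid(c, c, indexing="xy")
        phi = np.deg2rad(e.rotation_deg)
        xr = (X - e.center_mm[0]) * np.cos(phi) + (Y - e.center_mm[1]) * np.sin(phi)
        yr = -(X - e.center_mm[0]) * np.sin(phi) + (Y - e.center_mm[1]) * np.cos(phi)
        return (xr / e.semi_axes_mm[0]) ** 2 + (yr / e.semi_axes_mm[1]) ** 2 <= 1.0


def grid_coords_mm(N: int, fov_mm: float) -> np.ndarray:
    """Pixel-center coordinates with DC at index N//2 (even N)."""
    return (np.arange(N) - N // 2) * (fov_mm / N)


def make_shepp_logan(
    N: int,
    fov_mm: float,
    scale: float = 0.45,
    oversample: int = 1,
    edge_smooth_mm: float = 0.0,
) -> tuple[EllipsePhantom, np.ndarray]:
    """Head phantom scaled to ``scale`` of the FOV, plus its raster.

    The default scale keeps the object inside the central band of the FOV
    so that the FOV/2 Nyquist ghost lands on background -- the generous
    FOV prescription used to observe peripheral ghosts in isolation.
    """
    if N % 2:
        raise ValueError("N must be even")
    half = fov_mm / 2.0 * scale
    ells = [
        Ellipse(
            intensity=v,
            semi_axes_mm=(a * half, b * half),
            center_mm=(x0 * half, y0 * half),
            rotation_deg=ang,
        )
        for v, a, b, x0, y0, ang in _SHEPP_LOGAN
    ]
    phantom = EllipsePhantom(ellipses=ells, fov_mm=fov_mm, edge_smooth_mm=edge_smooth_mm)
    return phantom, phantom.raster(N, oversample=oversample)


def analytic_kspace(
    phantom: EllipsePhantom, kx: np.ndarray, ky: np.ndarray
) -> np.ndarray:
    """Closed-form Fourier transform of the phantom at (kx, ky) points.

    Per ellipse: intensity * pi a b * 2 J1(2 pi u)/(2 pi u) with
    u = sqrt((a kx')^2 + (b ky')^2) in rotated coordinates, times the
    center-shift phase. Linear in intensities; Hermitian for real
    phantoms.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    out = np.zeros(np.broadcast(kx, ky).shape, dtype=complex)
    for e in phantom.ellipses:
        a, b = e.semi_axes_mm
        phi = np.deg2rad(e.rotation_deg)
        kxr = kx * np.cos(phi) + ky * np.sin(phi)
        kyr = -kx * np.sin(phi) + ky * np.cos(phi)
        u = np.sqrt((a * kxr) ** 2 + (b * kyr) ** 2)
        x = 2.0 * np.pi * u
        with np.errstate(invalid="ignore", divide="ignore"):
            jinc = np.where(x > 1e-12, 2.0 * j1(np.maximum(x, 1e-300)) / np.maximum(x, 1e-300), 1.0)
        phase = np.exp(-2j * np.pi * (kx * e.center_mm[0] + ky * e.center_mm[1]))
        out += e.intensity * np.pi * a * b * jinc * phase
    if phantom.edge_smooth_mm:
        s = phantom.edge_smooth_mm
        out = out * np.exp(-2.0 * np.pi**2 * s**2 * (kx**2 + ky**2))
    return out


@dataclass
class FieldMap:
    """Static off-resonance in Hz on the image grid (axes [y, x])."""

    delta_f_Hz: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.delta_f_Hz)):
            raise ValueError("field map must be finite everywhere")

    @property
    def peak_Hz(self) -> float:
        return float(np.max(np.abs(self.delta_f_Hz)))


def make_fieldmap(
    N: int, fov_mm: float, severity: str = "good", peak_Hz: float | None = None
) -> FieldMap:
    """Second-order polynomial off-resonance map.

    ``good`` peaks at 10 Hz (a well-shimmed slab), ``bad`` at 150 Hz (a
    deliberately degraded shim). ``peak_Hz`` overrides the peak magnitude.
    """
    peaks = {"good": 10.0, "bad": 150.0}
    if severity not in peaks:
        raise ValueError(f"severity must be one of {sorted(peaks)}")
    peak = peaks[severity] if peak_Hz is None else float(peak_Hz)
    c = grid_coords_mm(N, fov_mm) / (fov_mm / 2.0)  # normalized [-1, 1)
    X, Y = np.meshgrid(c, c, indexing="xy")
    poly = 0.35 * (X**2 - 0.5) + 0.25 * X * Y + 0.3 * X + 0.2 * Y + 0.15 * (Y**2 - 0.3)
    m = np.max(np.abs(poly))
    f = peak * poly / m if m > 0 else poly
    return FieldMap(
        delta_f_Hz=f,
        description=f"2nd-order polynomial, severity={severity}, peak={peak:g} Hz",
    )


@dataclass
class CoilSet:
    """Smooth Gaussian-profile receive sensitivities around the FOV.

    Parameterized (not gridded) so maps can be sampled on any grid size,
    including the oversampled forward-model raster.
    """

    n_coils: int
    fov_mm: float
    centers_mm: np.ndarray  # [n_coils, 2]
    sigma_mm: float
    phase_grad_per_mm: np.ndarray  # [n_coils, 2], linear phase, rad/mm
    phase0_rad: np.ndarray  # [n_coils]

    def maps(self, N: int) -> np.ndarray:
        """Complex sensitivities [n_coils, N, N] (axes [y, x])."""
        if self.n_coils == 1:
            return np.ones((1, N, N), dtype=complex)
        c = grid_coords_mm(N, self.fov_mm)
        X, Y = np.meshgrid(c, c, indexing="xy")
        out = np.empty((self.n_coils, N, N), dtype=complex)
        for i in range(self.n_coils):
            dx = X - self.centers_mm[i, 0]
            dy = Y - self.centers_mm[i, 1]
            mag = np.exp(-(dx**2 + dy**2) / (2.0 * self.sigma_mm**2))
            ph = (
                self.phase0_rad[i]
                + self.phase_grad_per_mm[i, 0] * X
                + self.phase_grad_per_mm[i, 1] * Y
            )
            out[i] = mag * np.exp(1j * ph)
        return out

    def rss(self, N: int) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps(N)) ** 2, axis=0))


def make_coils(N: int, n_coils: int, fov_mm: float, seed: int = 20250402) -> CoilSet:
    """Deterministic ring of Gaussian coil profiles; n_coils=1 is uniform."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    ang = 2.0 * np.pi * np.arange(n_coils) / max(n_coils, 1) + rng.uniform(0, 0.2)
    radius = 0.55 * fov_mm / 2.0
    centers = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    phase_grad = rng.normal(0.0, 0.015, size=(n_coils, 2))
    phase0 = rng.uniform(-np.pi, np.pi, size=n_coils)
    return CoilSet(
        n_coils=n_coils,
        fov_mm=fov_mm,
        centers_mm=centers,
        sigma_mm=0.45 * fov_mm,
        phase_grad_per_mm=phase_grad,
        phase0_rad=phase0,
    )
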