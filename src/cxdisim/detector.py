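"""Detector geometry, reciprocal-space pixel maps and detector-side noise.

Geometry convention: the interaction point is the lab-frame origin, the beam
travels along +z, the detector plane sits at ``distance`` metres downstream,
the fast axis is x (columns) and the slow axis y (rows).  Even-sized arrays
place the nominal beam centre between the two central pixels.  The direct-beam
position may be offset from the nominal centre (``center_offset_m``), which is
how per-shot beam miscentering enters: pixels keep their lab positions, the
scattering origin moves, so the reciprocal-space map shifts.

For each pixel at lab position p the outgoing unit vector is u = p/|p| and

    q = (2 pi / lambda) (u - z_hat),        |q| = 4 pi sin(theta) / lambda,
    solid angle = pixel_area * cos(theta_inc) / |p|^2,
    polarization in [0, 1] per the Thomson-scattering factor.

Auto-ranging digitisation mimics ePix10k/Jungfrau-style detectors: each pixel
independently selects the finest gain range whose switching threshold its
deposited energy does not exceed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorGeometry",
    "PixelMaps",
    "NoiseConfig",
    "DigitizedImage",
    "pixel_maps",
    "resolution_at_edge",
    "distance_for_resolution",
    "sample_miscenter",
    "apply_dark_noise",
    "apply_static_background",
    "digitize",
]


@dataclass
class DetectorGeometry:
    """Square-pixel detector: monolithic or two panels with a central gap."""

    shape: tuple[int, int]          # (ny, nx)
    pixel_size_m: float
    distance_m: float
    center_offset_m: tuple[float, float] = (0.0, 0.0)
    gap_m: float = 0.0              # physical gap splitting rows into two panels
    mask: np.ndarray | None = None  # True = live

    def __post_init__(self):
        if self.distance_m <= 0 or self.pixel_size_m <= 0:
            raise ValueError("distance and pixel size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape mismatch")

    @classmethod
    def monolithic(cls, n_pixels: int, pixel_size_m: float, distance_m: float,
                   **kw) -> "DetectorGeometry":
        return cls((n_pixels, n_pixels), pixel_size_m, distance_m, **kw)

    @classmethod
    def two_panel(cls, n_pixels: int, pixel_size_m: float, distance_m: float,
                  gap_m: float, **kw) -> "DetectorGeometry":
        """pnccd-like layout: two half panels separated by a central gap."""
        return cls((n_pixels, n_pixels), pixel_size_m, distance_m, gap_m=gap_m, **kw)

    def pixel_xy_m(self) -> tuple[np.ndarray, np.ndarray]:
        """Lab-frame transverse pixel-centre coordinates (nominal centre at 0)."""
        ny, nx = self.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_size_m
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_size_m
        if self.gap_m > 0:
            y = np.where(np.arange(ny) < ny / 2, y - self.gap_m / 2, y + self.gap_m / 2)
        return np.meshgrid(x, y)  # each (ny, nx)

    def with_center_offset(self, offset_m) -> "DetectorGeometry":
        off = (float(offset_m[0]), float(offset_m[1]))
        return DetectorGeometry(
            self.shape, self.pixel_size_m, self.distance_m,
            center_offset_m=(self.center_offset_m[0] + off[0],
                             self.center_offset_m[1] + off[1]),
            gap_m=self.gap_m, mask=self.mask,
        )


@dataclass
class PixelMaps:
    """Per-pixel reciprocal vectors and geometric correction factors."""

    q_vectors: np.ndarray    # (ny, nx, 3) Å⁻¹
    q_mag: np.ndarray        # (ny, nx) Å⁻¹
    solid_angle: np.ndarray  # (ny, nx) sr
    polarization: np.ndarray  # (ny, nx) in [0, 1]
    mask: np.ndarray         # (ny, nx) bool, True = live
    wavelength_A: float

    @property
    def shape(self):
        return self.q_mag.shape


def pixel_maps(geometry: DetectorGeometry, wavelength_A: float,
               polarization: str = "horizontal") -> PixelMaps:
    """Map every pixel to q-space and compute solid angle and polarization."""
    if wavelength_A <= 0:
        raise ValueError("wavelength must be positive")
    x, y = geometry.pixel_xy_m()
    cx, cy = geometry.center_offset_m
    x = x - cx
    y = y - cy
    z = np.full_like(x, geometry.distance_m)
    norm = np.sqrt(x * x + y * y + z * z)
    if np.any(norm == 0):
        raise ValueError("pixel at the interaction point")
    ux, uy, uz = x / norm, y / norm, z / norm
    k = 2 * np.pi / wavelength_A
    q = np.stack([k * ux, k * uy, k * (uz - 1.0)], axis=-1)
    q_mag = np.linalg.norm(q, axis=-1)
    area = geometry.pixel_size_m**2
    solid_angle = area * uz / norm**2  # cos(theta_inc) = uz for a flat normal-z panel
    if polarization == "horizontal":
        pol = 1.0 - ux**2
    elif polarization == "vertical":
        pol = 1.0 - uy**2
    elif polarization == "unpolarized":
        cos2t = uz  # cos(2 theta) between u and the beam axis
        pol = 0.5 * (1.0 + cos2t**2)
    else:
        raise ValueError(f"unknown polarization {polarization!r}")
    return PixelMaps(
        q_vectors=q,
        q_mag=q_mag,
        solid_angle=solid_angle,
        polarization=pol,
        mask=geometry.mask.copy(),
        wavelength_A=wavelength_A,
    )


def resolution_at_edge(geometry: DetectorGeometry, wavelength_A: float,
                       at: str = "edge") -> float:
    """Resolution d = 2 pi / |q| (Å) at the detector edge midpoint.

    ``at='corner'`` instead returns d at the highest-|q| live pixel.
    """
    if at == "corner":
        maps = pixel_maps(geometry, wavelength_A)
        return float(2 * np.pi / maps.q_mag[maps.mask].max())
    ny, nx = geometry.shape
    half = min(nx, ny) / 2.0 * geometry.pixel_size_m
    two_theta = np.arctan2(half, geometry.distance_m)
    q = 4 * np.pi / wavelength_A * np.sin(two_theta / 2.0)
    return float(2 * np.pi / q)


def distance_for_resolution(d_target_A: float, wavelength_A: float,
                            half_width_m: float) -> float:
    """Detector distance placing resolution ``d_target_A`` at the edge midpoint."""
    s = wavelength_A / (2 * d_target_A)  # sin(theta)
    if not 0 < s < 1:
        raise ValueError("requested resolution unreachable at this wavelength")
    return float(half_width_m / np.tan(2 * np.arcsin(s)))


@dataclass
class NoiseConfig:
    """Detector-side noise switches.

    ``adu_per_kev`` lists the auto-ranging gain levels, finest first
    (strictly descending detector gain in ADU per keV); each range switches
    to the next at ``switch_fraction`` of its full well (``adu_max`` ADU).
    """

    miscenter_sigma_m: tuple[float, float] = (0.0, 0.0)
    dark_frames: np.ndarray | None = None   # (n_frames, ny, nx) ADU
    dark_sigma_adu: float = 0.0
    static_background: np.ndarray | None = None  # (ny, nx) photons
    gain_mode: str = "photon_counting"      # or 'autoranging'
    adu_per_kev: tuple[float, ...] = (100.0, 100.0 / 6.7, 1.0)
    adu_max: float = 16384.0
    switch_fraction: float = 0.8

    def __post_init__(self):
        if np.isscalar(self.miscenter_sigma_m):
            self.miscenter_sigma_m = (float(self.miscenter_sigma_m),) * 2
        if any(s < 0 for s in self.miscenter_sigma_m):
            raise ValueError("miscenter_sigma_m must be nonnegative")
        if self.dark_sigma_adu < 0:
            raise ValueError("dark_sigma_adu must be nonnegative")
        if self.static_background is not None:
            self.static_background = np.asarray(self.static_background, dtype=float)
            if np.any(self.static_background < 0):
                raise ValueError("static background must be nonnegative")
        if self.gain_mode not in ("photon_counting", "autoranging"):
            raise ValueError(f"unknown gain mode {self.gain_mode!r}")
        g = np.asarray(self.adu_per_kev, dtype=float)
        if np.any(g <= 0) or np.any(np.diff(g) >= 0):
            raise ValueError("gain levels must be positive and strictly descending")

    @property
    def switch_thresholds_kev(self) -> np.ndarray:
        """Max deposited energy of each range (ascending, keV)."""
        return self.switch_fraction * self.adu_max / np.asarray(self.adu_per_kev)


def sample_miscenter(noise: NoiseConfig,
                     seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Per-shot direct-beam displacement: independent Gaussians per axis (m)."""
    sx, sy = noise.miscenter_sigma_m
    if sx == 0 and sy == 0:
        return (0.0, 0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (float(rng.normal(0, sx)) if sx else 0.0,
            float(rng.normal(0, sy)) if sy else 0.0)


def apply_dark_noise(image_adu: np.ndarray, noise: NoiseConfig,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add fluctuating dark noise in ADU (incoherent, post-digitisation).

    A randomly selected supplied dark frame is added when frames exist;
    otherwise per-pixel Normal(0, dark_sigma^2).
    """
    image_adu = np.asarray(image_adu, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise.dark_frames is not None:
        frames = np.asarray(noise.dark_frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.shape[1:] != image_adu.shape:
            raise ValueError("dark frame shape mismatch")
        return image_adu + frames[rng.integers(len(frames))]
    if noise.dark_sigma_adu == 0:
        return image_adu.copy()
    return image_adu + rng.normal(0.0, noise.dark_sigma_adu, size=image_adu.shape)


def apply_static_background(image_photons: np.ndarray,
                            background_photons: np.ndarray) -> np.ndarray:
    """Add a static background in photon units, before Poisson quantisation."""
    image = np.asarray(image_photons, dtype=float)
    bg = np.asarray(background_photons, dtype=float)
    if bg.shape != image.shape:
        raise ValueError("background shape mismatch")
    if np.any(bg < 0):
        raise ValueError("background must be nonnegative")
    return image + bg


@dataclass
class DigitizedImage:
    adu: np.ndarray
    gain_index: np.ndarray
    saturated: np.ndarray


def digitize(photons: np.ndarray, noise: NoiseConfig,
             photon_energy_kev: float = 1.0) -> DigitizedImage:
    """Convert photon counts to ADU.

    ``photon_counting`` mode returns the counts unchanged (finest gain
    everywhere).  ``autoranging`` mode converts counts to deposited energy,
    selects per pixel the finest gain range whose switching threshold the
    energy does not exceed, and reports ADU = energy * gain.  Energies beyond
    the coarsest range are clamped at full well and flagged saturated.
    """
    photons = np.asarray(photons, dtype=float)
    if np.any(photons < 0):
        raise ValueError("photon counts must be nonnegative")
    if noise.gain_mode == "photon_counting":
        return DigitizedImage(
            adu=photons.copy(),
            gain_index=np.zeros(photons.shape, dtype=int),
            saturated=np.zeros(photons.shape, dtype=bool),
        )
    energy = photons * photon_energy_kev
    thresholds = noise.switch_thresholds_kev
    gains = np.asarray(noise.adu_per_kev)
    idx = np.searchsorted(thresholds, energy, side="left")
    saturated = idx >= len(gains)
    idx = np.minimum(idx, len(gains) - 1)
    adu = energy * gains[idx]
    adu = np.minimum(adu, noise.adu_max)
    return DigitizedImage(adu=adu, gain_index=idx, saturated=saturated)


def decode_adu(image: DigitizedImage, noise: NoiseConfig) -> np.ndarray:
    """Recover deposited energy (keV) from a noise-free auto-ranged image."""
    gains = np.asarray(noise.adu_per_kev)
    return image.adu / gains[image.gain_index]
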