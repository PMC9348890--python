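"""The X-ray pulse: spectrum, fluence, spatial profile and jitter.

The simplest beam is a monochromatic spike of spatially uniform fluence.  A
SASE (self-amplified spontaneous emission) pulse is modelled as a train of
mutually uncorrelated spikes: spike centre energies are Gaussian about the
central photon energy, spike heights are random, and a Gaussian kernel density
estimate over the spikes approximates the pulse's energy distribution.  A
polychromatic pattern is the incoherent, weight-summed stack of monochromatic
patterns, one per spectral sample.

Shot-to-shot fluence jitter multiplies the pulse photon count by
``max(0, 1 + eps)`` with ``eps ~ N(0, jitter_fraction^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import HC_EV_A

__all__ = ["Beam", "Spectrum", "wavelength", "sase_spectrum", "shot_fluence", "fluence_at"]


@dataclass
class Beam:
    """Pulse parameters.

    ``focus_radius_m`` defines a circular focus for the uniform profile; the
    Gaussian profile uses ``profile_sigma_m`` (x, y).  ``jitter_fraction`` is
    the relative sigma of shot-to-shot total-fluence variation.
    """

    photon_energy_ev: float
    photons_per_pulse: float = 1e12
    focus_radius_m: float = 1e-7
    polarization: str = "horizontal"
    jitter_fraction: float = 0.0
    profile: str = "uniform"  # 'uniform' | 'gaussian'
    profile_sigma_m: tuple[float, float] | None = None

    def __post_init__(self):
        if self.photon_energy_ev <= 0:
            raise ValueError("photon_energy_ev must be positive")
        if self.photons_per_pulse < 0 or self.jitter_fraction < 0:
            raise ValueError("photons_per_pulse and jitter_fraction must be >= 0")
        if self.polarization not in ("horizontal", "vertical", "unpolarized"):
            raise ValueError(f"unknown polarization {self.polarization!r}")
        if self.profile not in ("uniform", "gaussian"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "gaussian" and self.profile_sigma_m is None:
            # default: sigma such that the Gaussian FWHM matches the focus diameter
            s = 2 * self.focus_radius_m / 2.3548200450309493
            self.profile_sigma_m = (s, s)

    @property
    def wavelength_A(self) -> float:
        return HC_EV_A / self.photon_energy_ev


def wavelength(beam: Beam) -> float:
    """Wavelength in Å: lambda = 12398.42 / E[eV]."""
    return beam.wavelength_A


@dataclass
class Spectrum:
    """Normalised wavelength spectrum: samples (wavelength Å, weight)."""

    wavelengths_A: np.ndarray
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths_A = np.atleast_1d(np.asarray(self.wavelengths_A, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if np.any(self.weights < 0):
            raise ValueError("spectral weights must be nonnegative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total weight")
        self.weights = self.weights / total

    @classmethod
    def monochromatic(cls, wavelength_A: float) -> "Spectrum":
        return cls(
            wavelengths_A=np.array([wavelength_A]),
            weights=np.array([1.0]),
            provenance={"type": "monochromatic"},
        )

    @property
    def is_monochromatic(self) -> bool:
        return len(self.weights) == 1


def sase_spectrum(
    beam: Beam,
    n_spikes: int = 100,
    bandwidth_fraction: float = 1e-3,
    n_samples: int = 101,
    seed: int | np.random.Generator = 0,
    spike_height_range: tuple[float, float] = (0.5, 1.5),
) -> Spectrum:
    """Draw one SASE pulse spectrum as a Gaussian KDE over random spikes.

    Spike centre energies ~ N(E0, (bandwidth_fraction * E0)^2), spike heights
    uniform in ``spike_height_range``; the height-weighted KDE (Scott-rule
    bandwidth over the spike centres) is evaluated on ``n_samples`` energies
    spanning E0 +/- 4 sigma and returned as normalised wavelength samples.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if bandwidth_fraction <= 0:
        raise ValueError("bandwidth_fraction must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e0 = beam.photon_energy_ev
    sigma = bandwidth_fraction * e0
    centers = rng.normal(e0, sigma, size=n_spikes)
    heights = rng.uniform(*spike_height_range, size=n_spikes)
    spread = np.std(centers, ddof=1) if n_spikes > 1 else 0.0
    h = spread * n_spikes ** (-1 / 5)  # Scott's rule in 1D
    if h <= 0:
        # degenerate train (one spike / coincident spikes): a delta line
        return Spectrum(
            wavelengths_A=np.array([HC_EV_A / centers[0]]),
            weights=np.array([1.0]),
            provenance={
                "type": "sase",
                "n_spikes": n_spikes,
                "bandwidth_fraction": bandwidth_fraction,
                "degenerate": True,
            },
        )
    grid = np.linspace(e0 - 4 * sigma, e0 + 4 * sigma, n_samples)
    density = np.sum(
        heights[:, None] * np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / h) ** 2),
        axis=0,
    )
    return Spectrum(
        wavelengths_A=HC_EV_A / grid,
        weights=density,
        provenance={
            "type": "sase",
            "n_spikes": n_spikes,
            "bandwidth_fraction": bandwidth_fraction,
        },
    )


def shot_fluence(beam: Beam, seed: int | np.random.Generator = 0) -> float:
    """Photon count of one shot: nominal count with Gaussian jitter, clipped at 0."""
    if beam.jitter_fraction == 0:
        return float(beam.photons_per_pulse)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, beam.jitter_fraction)
    return float(beam.photons_per_pulse * max(0.0, 1.0 + eps))


def fluence_at(
    beam: Beam,
    transverse_offset_m=(0.0, 0.0),
    photons: float | None = None,
) -> float:
    """Fluence (photons / m^2) at a transverse position in the focal plane.

    Uniform profile: ``photons / (pi focus_radius^2)`` inside the focus, 0
    outside.  Gaussian profile: a 2D Gaussian whose integral over the plane is
    the photon count.  ``photons`` overrides the nominal pulse count (used to
    feed in a jittered per-shot count).
    """
    n = beam.photons_per_pulse if photons is None else photons
    x, y = np.asarray(transverse_offset_m, dtype=float)[:2]
    if beam.profile == "uniform":
        r2 = x * x + y * y
        if r2 > beam.focus_radius_m**2:
            return 0.0
        return float(n / (np.pi * beam.focus_radius_m**2))
    sx, sy = beam.profile_sigma_m
    return float(
        n / (2 * np.pi * sx * sy) * np.exp(-0.5 * ((x / sx) ** 2 + (y / sy) ** 2))
    )
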