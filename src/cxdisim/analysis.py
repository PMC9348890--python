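"""Validation utilities: Fourier shell correlation and toy fixture particles.

The Fourier shell correlation between two real 3D density maps is, per shell
of spatial frequency k,

    FSC(k) = Re( sum F1 F2* ) / sqrt( sum |F1|^2 * sum |F2|^2 ),

with sums over Fourier voxels in the shell.  The spatial frequency at which
the FSC against a noise-free reference falls to 0.5 is the conventional
resolution estimate; the reported resolution is d = 1/k (map-frequency
convention, cycles per unit length), alongside the 2*pi/q convention used by
the diffraction modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .particle import FormFactorRecord, Particle

__all__ = ["FSCCurve", "fsc", "resolution_at_threshold", "make_fixture"]


@dataclass
class FSCCurve:
    """Shell-wise correlation curve; k in cycles per unit length."""

    shell_centers: np.ndarray
    values: np.ndarray
    shell_width: float
    voxel_size: float = 1.0

    def __len__(self):
        return len(self.values)


def fsc(map1: np.ndarray, map2: np.ndarray, n_shells: int | None = None,
        voxel_size: float = 1.0) -> FSCCurve:
    """Fourier shell correlation of two equal-shape cubic real maps."""
    m1 = np.asarray(map1, dtype=float)
    m2 = np.asarray(map2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("maps must have equal shapes")
    if m1.ndim != 3 or len(set(m1.shape)) != 1:
        raise ValueError("maps must be cubic 3D arrays")
    n = m1.shape[0]
    if n_shells is None:
        n_shells = n // 2
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    f1 = np.fft.fftn(m1)
    f2 = np.fft.fftn(m2)
    freq = np.fft.fftfreq(n)  # cycles per voxel
    r = np.sqrt(
        freq[:, None, None] ** 2 + freq[None, :, None] ** 2 + freq[None, None, :] ** 2
    )
    nyquist = 0.5
    width = nyquist / n_shells
    shell = np.minimum((r / width).astype(int), n_shells)  # last bin catches corners
    num = np.real(f1 * np.conj(f2)).ravel()
    p1 = (np.abs(f1) ** 2).ravel()
    p2 = (np.abs(f2) ** 2).ravel()
    s = shell.ravel()
    num_s = np.bincount(s, weights=num, minlength=n_shells + 1)[:n_shells]
    p1_s = np.bincount(s, weights=p1, minlength=n_shells + 1)[:n_shells]
    p2_s = np.bincount(s, weights=p2, minlength=n_shells + 1)[:n_shells]
    counts = np.bincount(s, minlength=n_shells + 1)[:n_shells]
    if np.any(counts == 0):
        raise ValueError("empty FSC shell; reduce n_shells")
    denom = np.sqrt(p1_s * p2_s)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, num_s / denom, 0.0)
    centers = (np.arange(n_shells) + 0.5) * width / voxel_size
    return FSCCurve(
        shell_centers=centers,
        values=values,
        shell_width=width / voxel_size,
        voxel_size=voxel_size,
    )


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.5) -> float:
    """Resolution d = 1/k (same length unit as ``voxel_size``) at the first
    crossing of the FSC below ``threshold``, linearly interpolated between
    shells.  Returns ``inf`` ("beyond Nyquist") if the curve never crosses.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    v = np.asarray(curve.values)
    k = np.asarray(curve.shell_centers)
    if len(v) == 0:
        raise ValueError("empty FSC curve")
    if v[0] < threshold:
        raise ValueError(
            f"FSC starts below threshold ({v[0]:.3f} < {threshold}); "
            "maps do not agree even at low resolution"
        )
    for i in range(len(v) - 1):
        if v[i] >= threshold > v[i + 1]:
            frac = (v[i] - threshold) / (v[i] - v[i + 1])
            k_cross = k[i] + frac * (k[i + 1] - k[i])
            return float(1.0 / k_cross)
    return math.inf


def _unit_record(amplitude: float = 1.0, label: str = "unit") -> FormFactorRecord:
    """q-independent point scatterer of fixed amplitude (electrons)."""
    return FormFactorRecord(a=(0.0, 0.0, 0.0, 0.0), b=(0.0,) * 4, c=amplitude, label=label)


def make_fixture(name: str, **params) -> Particle:
    """Deterministic toy particles used across the test and example suite.

    ``two_atom(d, element)``     — two atoms d Å apart along x;
    ``shell(radius, thickness, spacing)`` — hollow shell of unit pseudo-atoms;
    ``ball(radius, density, voxel)``      — uniform solvent ball (continuum
                                            points of amplitude density*voxel^3,
                                            anchored by one zero-amplitude
                                            scatterer at the origin);
    ``random_coil(n, seed, bond)``        — seeded self-avoiding-ish random
                                            walk of carbon pseudo-atoms.
    """
    if name == "two_atom":
        d = float(params.get("d", 10.0))
        element = params.get("element", "C")
        return Particle(
            positions=np.array([[-d / 2, 0, 0], [d / 2, 0, 0]]),
            species=np.array([element, element], dtype=object),
            registry={},
            label=f"two_atom(d={d})",
        )
    if name == "shell":
        radius = float(params.get("radius", 20.0))
        thickness = float(params.get("thickness", 4.0))
        spacing = float(params.get("spacing", 2.0))
        ax = np.arange(-radius - thickness, radius + thickness + spacing, spacing)
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
        r = np.linalg.norm(pts, axis=1)
        keep = (r >= radius - thickness / 2) & (r <= radius + thickness / 2)
        pts = pts[keep]
        rec = _unit_record()
        return Particle(
            positions=pts,
            species=np.array(["unit"] * len(pts), dtype=object),
            registry={"unit": rec},
            label=f"shell(R={radius})",
        )
    if name == "ball":
        radius = float(params.get("radius", 20.0))
        density = float(params.get("density", 0.334))
        voxel = float(params.get("voxel", 1.5))
        ax = np.arange(-radius, radius + voxel, voxel)
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
        rec = _unit_record(0.0, label="anchor")
        return Particle(
            positions=np.zeros((1, 3)),
            species=np.array(["anchor"], dtype=object),
            registry={"anchor": rec},
            solvent_points=pts,
            solvent_amplitudes=np.full(len(pts), density * voxel**3),
            label=f"ball(R={radius})",
        )
    if name == "random_coil":
        n = int(params.get("n", 50))
        seed = int(params.get("seed", 0))
        bond = float(params.get("bond", 3.8))
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n - 1, 3))
        steps = bond * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        return Particle(
            positions=pos,
            species=np.array(["C"] * n, dtype=object),
            registry={},
            label=f"random_coil(n={n},seed={seed})",
        )
    raise ValueError(f"unknown fixture {name!r}")
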