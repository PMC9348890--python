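"""Diffraction engine: direct summation, 3D volumes, Ewald slicing, photons.

The exact structure factor of a particle is the direct sum

    F(q) = sum_j occ_j f_j(|q|) exp(i q . r_j) + sum_k A_k exp(i q . r_k)

over scatterers j (form factors f_j) and continuum-solvent points k (fixed
amplitudes A_k in electrons).  Direct summation at arbitrary q-points is the
oracle for everything downstream and scales linearly in the number of
scatterers.

For single-particle work, |F|^2 is evaluated once on a cubic reciprocal grid
(:func:`build_volume`); per-shot patterns are then produced at a cost
independent of the atom count by trilinear interpolation of the volume on the
rotated Ewald sphere of the detector (:func:`slice_pattern`).

Orientation convention: the stored unit quaternion rotates the PARTICLE, so a
pattern is the volume sampled at R(q_orient)^T q_pixel.  Multi-particle
coherent sums use the same convention with per-particle phase factors
exp(i q . d_k), evaluated by direct summation because a |F|^2 volume carries
no phase.

Expected photon counts per pixel follow Thomson scattering:

    lambda_p = fluence * r_e^2 * Omega_p * P_p * |F(q_p)|^2

with fluence in photons/m^2, r_e the classical electron radius, Omega_p the
pixel solid angle and P_p the polarization factor; measured photons are
independent Poisson draws of lambda_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .constants import R_ELECTRON_M
from .detector import PixelMaps
from .particle import Particle
from .rotation import normalize_quaternion, quat_to_matrix, random_quaternion

__all__ = [
    "DiffractionVolume",
    "structure_factor_direct",
    "build_volume",
    "default_n_grid",
    "slice_pattern",
    "multi_particle_pattern",
    "expected_photons",
    "pattern_to_photons",
    "random_quaternion",
]

_CHUNK = 4096  # q-points per direct-summation block, bounds peak memory


def structure_factor_direct(particle: Particle, q_points: np.ndarray) -> np.ndarray:
    """Exact complex structure factor (electrons) at arbitrary q-points (Å⁻¹).

    ``q_points`` has shape (..., 3); the result has the leading shape.
    """
    q = np.asarray(q_points, dtype=float)
    lead_shape = q.shape[:-1]
    q = q.reshape(-1, 3)
    q_mag = np.linalg.norm(q, axis=1)
    out = np.zeros(len(q), dtype=complex)
    # group scatterers by species so each form factor is evaluated once per q
    species = particle.species
    for sp in sorted(set(species.tolist())):
        sel = species == sp
        f = particle.registry[sp](q_mag)
        r = particle.positions[sel]
        occ = particle.occupancy[sel]
        acc = np.zeros(len(q), dtype=complex)
        for lo in range(0, len(q), _CHUNK):
            block = q[lo : lo + _CHUNK] @ r.T  # (chunk, n_sp)
            acc[lo : lo + _CHUNK] = np.exp(1j * block) @ occ
        out += f * acc
    if len(particle.solvent_points):
        r = particle.solvent_points
        amps = particle.solvent_amplitudes
        for lo in range(0, len(q), _CHUNK):
            block = q[lo : lo + _CHUNK] @ r.T
            out[lo : lo + _CHUNK] += np.exp(1j * block) @ amps
    return out.reshape(lead_shape)


@dataclass
class DiffractionVolume:
    """|F|^2 (electrons^2) on a cubic grid spanning [-q_max, q_max]^3."""

    grid: np.ndarray       # (n, n, n), axis order (qx, qy, qz)
    q_max: float           # Å⁻¹ half-extent per axis
    particle_label: str = ""

    @property
    def n_grid(self) -> int:
        return self.grid.shape[0]

    @property
    def voxel(self) -> float:
        return 2 * self.q_max / (self.n_grid - 1)

    def save(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("volume", data=self.grid)
            f.attrs["q_max"] = self.q_max
            f.attrs["n_grid"] = self.n_grid
            f.attrs["particle_label"] = self.particle_label

    @classmethod
    def load(cls, path) -> "DiffractionVolume":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                grid=np.asarray(f["volume"]),
                q_max=float(f.attrs["q_max"]),
                particle_label=str(f.attrs.get("particle_label", "")),
            )


def _particle_diameter(particle: Particle) -> float:
    pts = particle.positions
    if len(particle.solvent_points):
        pts = np.vstack([pts, particle.solvent_points])
    c = pts.mean(axis=0)
    return 2.0 * float(np.max(np.linalg.norm(pts - c, axis=1)))


def default_n_grid(particle: Particle, q_max: float, oversampling: int = 4) -> int:
    """Grid size giving >= `oversampling` voxels per Shannon interval.

    The intensity autocorrelation of a particle of diameter D has support 2D,
    so Shannon sampling of |F|^2 requires a grid spacing of pi/D; the default
    refines this by `oversampling` so trilinear slicing error stays well below
    the percent level.
    """
    d = max(_particle_diameter(particle), 1e-6)
    dq = np.pi / (oversampling * d)
    n = 2 * int(np.ceil(q_max / dq)) + 1
    return max(n, 9)


def build_volume(
    particle: Particle,
    q_max: float,
    n_grid: int | None = None,
    oversampling: int = 4,
) -> DiffractionVolume:
    """Evaluate |F|^2 on the cubic grid by exact direct summation.

    This is the one-time per-particle cost of an experiment; patterns are then
    sliced from the volume at a rate independent of the atom count.
    """
    if n_grid is None:
        n_grid = default_n_grid(particle, q_max, oversampling)
    if n_grid < 9 or n_grid % 2 == 0:
        raise ValueError("n_grid must be odd and >= 9")
    axis = np.linspace(-q_max, q_max, n_grid)
    grid = np.empty((n_grid, n_grid, n_grid))
    qy, qz = np.meshgrid(axis, axis, indexing="ij")
    plane = np.empty((n_grid * n_grid, 3))
    plane[:, 1] = qy.ravel()
    plane[:, 2] = qz.ravel()
    for ix, qx in enumerate(axis):  # slab-wise to bound memory
        plane[:, 0] = qx
        f = structure_factor_direct(particle, plane)
        grid[ix] = (f.real**2 + f.imag**2).reshape(n_grid, n_grid)
    return DiffractionVolume(grid=grid, q_max=q_max, particle_label=particle.label)


def slice_pattern(
    volume: DiffractionVolume,
    orientation,
    maps: PixelMaps,
    return_mask: bool = False,
):
    """Trilinear slice of the volume on the detector's (rotated) Ewald sphere.

    ``orientation`` is the particle's unit quaternion (w, x, y, z); the volume
    is sampled at R^T q_pixel.  Out-of-volume pixels are set to 0 and reported
    in the optional mask; if every pixel falls outside, an error is raised.
    """
    q = np.asarray(orientation, dtype=float)
    rot = quat_to_matrix(normalize_quaternion(q))
    qpix = maps.q_vectors.reshape(-1, 3) @ rot  # == (R^T q) for each row
    inside = np.all(np.abs(qpix) <= volume.q_max * (1 + 1e-12), axis=1)
    if not np.any(inside):
        raise ValueError("all pixels fall outside the diffraction volume")
    coords = (qpix.T + volume.q_max) / volume.voxel  # (3, npix) fractional indices
    vals = map_coordinates(volume.grid, coords, order=1, mode="nearest")
    vals[~inside] = 0.0
    pattern = vals.reshape(maps.shape)
    if return_mask:
        return pattern, inside.reshape(maps.shape)
    return pattern


def multi_particle_pattern(
    states,
    maps: PixelMaps,
    coherent: bool = True,
):
    """|F_total|^2 for several particles in the beam.

    ``states`` is a list of (particle_or_volume, orientation, offset_Å)
    triples.  Coherent mode computes |sum_k exp(i q . d_k) F_k(R_k^T q)|^2 by
    per-particle direct summation (phases require complex amplitudes, which a
    |F|^2 volume cannot supply); a single-particle volume state reduces to
    :func:`slice_pattern`.  Incoherent mode sums the member intensities.
    """
    if len(states) == 0:
        raise ValueError("need at least one particle state")
    if len(states) == 1 and isinstance(states[0][0], DiffractionVolume):
        return slice_pattern(states[0][0], states[0][1], maps)
    qpix = maps.q_vectors.reshape(-1, 3)
    if coherent:
        total = np.zeros(len(qpix), dtype=complex)
        for obj, orientation, offset in states:
            if isinstance(obj, DiffractionVolume):
                raise TypeError(
                    "coherent multi-particle sums need Particle states "
                    "(a |F|^2 volume carries no phase)"
                )
            rot = quat_to_matrix(normalize_quaternion(np.asarray(orientation, float)))
            centered = obj.transformed(rotation=rot)
            amp = structure_factor_direct(centered, qpix)
            phase = np.exp(1j * (qpix @ np.asarray(offset, dtype=float)))
            total += phase * amp
        return (total.real**2 + total.imag**2).reshape(maps.shape)
    out = np.zeros(maps.shape)
    for obj, orientation, offset in states:
        if isinstance(obj, DiffractionVolume):
            out += slice_pattern(obj, orientation, maps)
        else:
            rot = quat_to_matrix(normalize_quaternion(np.asarray(orientation, float)))
            centered = obj.transformed(rotation=rot)
            amp = structure_factor_direct(centered, qpix)
            out += (amp.real**2 + amp.imag**2).reshape(maps.shape)
    return out


def expected_photons(pattern: np.ndarray, maps: PixelMaps, fluence: float) -> np.ndarray:
    """Expected photon count per pixel (the Poisson rate lambda_p).

    ``fluence`` in photons/m^2; ``pattern`` is |F|^2 in electrons^2.
    """
    pattern = np.asarray(pattern, dtype=float)
    if np.any(pattern < 0):
        raise ValueError("pattern intensities must be nonnegative")
    return fluence * R_ELECTRON_M**2 * maps.solid_angle * maps.polarization * pattern


def pattern_to_photons(
    pattern: np.ndarray,
    maps: PixelMaps,
    fluence: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Quantise a pattern into integer photon counts (independent Poisson draws)."""
    lam = expected_photons(pattern, maps, fluence)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(lam)
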