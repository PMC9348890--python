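"""Particles: scatterer positions, form factors, solvent decoration.

A :class:`Particle` is the sample-side object of a diffraction simulation: a
set of point scatterers (atoms or coarse-grained pseudo-atoms), each resolving
to a form-factor evaluator, plus an optional cloud of continuum-solvent sample
points carrying fixed scattering amplitudes in electrons.

Atomic form factors use the standard International Tables four-Gaussian
parameterisation

    f(s) = sum_i a_i exp(-b_i s^2) + c,   s = sin(theta)/lambda = |q|/(4 pi),

with coefficients taken from gemmi's element tables, so ``f(0)`` equals the
element's electron count.  Coarse-grained particles loaded from HDF5 may carry
explicit per-scatterer coefficient records instead of element symbols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .constants import WATER_DENSITY_E_A3

__all__ = [
    "FormFactorRecord",
    "Particle",
    "form_factor",
    "load_pdb",
    "load_particle_h5",
    "save_particle_h5",
    "add_hydration_layer",
    "fill_cavity",
    "gold_reference",
]

#: Generic heavy-atom van der Waals radius (Å) used for the particle envelope.
DEFAULT_PROBE_RADIUS = 1.7


@dataclass(frozen=True)
class FormFactorRecord:
    """Sum-of-Gaussians form factor: ``f(s) = sum a_i exp(-b_i s^2) + c``.

    ``a`` in electrons, ``b`` in Å², ``s = |q|/(4 pi)`` in Å⁻¹.
    """

    a: tuple[float, ...]
    b: tuple[float, ...]
    c: float
    label: str = ""

    def __call__(self, q_mag: np.ndarray | float) -> np.ndarray | float:
        s2 = np.square(np.asarray(q_mag, dtype=float) / (4.0 * np.pi))
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        return np.sum(a * np.exp(-np.multiply.outer(s2, b)), axis=-1) + self.c

    @property
    def f0(self) -> float:
        """Forward-scattering value, i.e. the electron count of the species."""
        return float(sum(self.a) + self.c)


def _element_record(symbol: str) -> FormFactorRecord:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    it = el.it92
    if it is None:
        raise ValueError(f"no form-factor coefficients for element {symbol!r}")
    return FormFactorRecord(a=tuple(it.a), b=tuple(it.b), c=float(it.c), label=el.name)


_RECORD_CACHE: dict[str, FormFactorRecord] = {}


def element_form_factor_record(symbol: str) -> FormFactorRecord:
    """Four-Gaussian record for an element symbol (case-insensitive)."""
    key = symbol.strip().capitalize()
    if key not in _RECORD_CACHE:
        _RECORD_CACHE[key] = _element_record(key)
    return _RECORD_CACHE[key]


def form_factor(kind: str | FormFactorRecord, q_mag) -> np.ndarray | float:
    """Evaluate a form factor at |q| (Å⁻¹), vectorised over arrays.

    ``kind`` is an element symbol or an explicit :class:`FormFactorRecord`.
    """
    q_mag = np.asarray(q_mag, dtype=float)
    if np.any(q_mag < 0):
        raise ValueError("q_mag must be nonnegative")
    rec = kind if isinstance(kind, FormFactorRecord) else element_form_factor_record(kind)
    return rec(q_mag)


@dataclass
class Particle:
    """Point scatterers plus optional continuum-solvent sample points.

    Attributes
    ----------
    positions : (N, 3) float array, Å
    species : (N,) array of str
        Keys into ``registry``; for atomic particles these are element symbols.
    registry : dict mapping species key -> FormFactorRecord
    occupancy : (N,) float array, unitless weights (default 1)
    solvent_points : (M, 3) float array, Å
    solvent_amplitudes : (M,) float array, electrons (nonnegative)
    atom_names : optional (N,) array of str (PDB atom names, e.g. ``CA``)
    label : free-text state identifier
    """

    positions: np.ndarray
    species: np.ndarray
    registry: dict[str, FormFactorRecord]
    occupancy: np.ndarray | None = None
    solvent_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    solvent_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    atom_names: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.species = np.asarray(self.species, dtype=object)
        if self.occupancy is None:
            self.occupancy = np.ones(len(self.positions))
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.solvent_points = np.asarray(self.solvent_points, dtype=float).reshape(-1, 3)
        self.solvent_amplitudes = np.asarray(self.solvent_amplitudes, dtype=float)
        if self.positions.shape[0] == 0:
            raise ValueError("particle must contain at least one scatterer")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("scatterer positions must be finite")
        if self.positions.shape != (len(self.species), 3):
            raise ValueError("positions and species length mismatch")
        if len(self.occupancy) != len(self.species):
            raise ValueError("occupancy length mismatch")
        if len(self.solvent_amplitudes) != len(self.solvent_points):
            raise ValueError("solvent points/amplitudes length mismatch")
        if np.any(self.solvent_amplitudes < 0):
            raise ValueError("solvent amplitudes must be nonnegative")
        for sp in set(self.species.tolist()):
            if sp not in self.registry:
                # element symbols resolve lazily against the standard table
                self.registry[sp] = element_form_factor_record(sp)

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def total_electrons(self) -> float:
        """f(0)-weighted electron count including solvent amplitudes."""
        tot = sum(
            self.registry[sp].f0 * occ
            for sp, occ in zip(self.species, self.occupancy)
        )
        return float(tot + self.solvent_amplitudes.sum())

    def copy(self, **changes) -> "Particle":
        defaults = dict(
            positions=self.positions.copy(),
            species=self.species.copy(),
            registry=dict(self.registry),
            occupancy=self.occupancy.copy(),
            solvent_points=self.solvent_points.copy(),
            solvent_amplitudes=self.solvent_amplitudes.copy(),
            atom_names=None if self.atom_names is None else self.atom_names.copy(),
            label=self.label,
        )
        defaults.update(changes)
        return Particle(**defaults)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Particle":
        """Rigid transform (rotate about the centroid, then translate)."""
        pos = self.positions
        sol = self.solvent_points
        if rotation is not None:
            c = self.centroid()
            pos = (pos - c) @ rotation.T
            sol = (sol - c) @ rotation.T if len(sol) else sol
        else:
            c = np.zeros(3)
            pos = pos - c
            sol = sol - c if len(sol) else sol
        if translation is not None:
            t = np.asarray(translation, dtype=float)
            pos = pos + t
            sol = sol + t if len(sol) else sol
        return self.copy(positions=pos, solvent_points=sol)


def load_pdb(path, exclude_water: bool = True) -> Particle:
    """Read a PDB file into a :class:`Particle` (one scatterer per atom).

    The element is taken from the element column when present, with gemmi's
    atom-name fallback otherwise.  Waters (HOH/WAT/DOD) are excluded by
    default; hydrogens present in the file are kept.  Alternate locations:
    only blank or 'A' altlocs are retained.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    water_names = {"HOH", "WAT", "DOD"}
    positions, species, occ, names = [], [], [], []
    if len(st) == 0:
        raise ValueError(f"no models in PDB file {path}")
    model = st[0]
    for chain in model:
        for residue in chain:
            if exclude_water and residue.name.strip() in water_names:
                continue
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                if atom.element.atomic_number == 0:
                    raise ValueError(
                        f"unknown element for atom {atom.name!r} in {residue.name!r}"
                    )
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                species.append(atom.element.name)
                occ.append(atom.occ)
                names.append(atom.name)
    if not positions:
        raise ValueError(f"no atoms left after filtering in {path}")
    return Particle(
        positions=np.array(positions),
        species=np.array(species, dtype=object),
        registry={},
        occupancy=np.array(occ),
        atom_names=np.array(names, dtype=object),
        label=str(path),
    )


def save_particle_h5(path, particle: Particle, explicit_form_factors: bool = False):
    """Write the HDF5 particle layout.

    Datasets: ``positions`` [N x 3, Å] plus either ``elements`` [N] or the
    explicit ``form_factors/{a,b,c}`` records; attribute ``units='angstrom'``.
    """
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("positions", data=particle.positions)
        f.attrs["units"] = "angstrom"
        if explicit_form_factors:
            recs = [particle.registry[sp] for sp in particle.species]
            g = f.create_group("form_factors")
            g.create_dataset("a", data=np.array([r.a for r in recs]))
            g.create_dataset("b", data=np.array([r.b for r in recs]))
            g.create_dataset("c", data=np.array([r.c for r in recs]))
        else:
            f.create_dataset(
                "elements",
                data=np.array([s.encode() for s in particle.species]),
            )
        if particle.occupancy is not None:
            f.create_dataset("occupancy", data=particle.occupancy)
        del d


def load_particle_h5(path) -> Particle:
    """Read the HDF5 particle layout written by :func:`save_particle_h5`.

    Explicit ``form_factors`` records, when present, are used verbatim (one
    record per scatterer); otherwise ``elements`` labels resolve against the
    standard table.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if "positions" not in f:
            raise ValueError(f"{path}: missing required dataset 'positions'")
        positions = np.asarray(f["positions"])
        n = len(positions)
        occupancy = np.asarray(f["occupancy"]) if "occupancy" in f else None
        if "form_factors" in f:
            g = f["form_factors"]
            for key in ("a", "b", "c"):
                if key not in g:
                    raise ValueError(f"{path}: missing dataset form_factors/{key}")
            a = np.atleast_2d(np.asarray(g["a"]))
            b = np.atleast_2d(np.asarray(g["b"]))
            c = np.asarray(g["c"]).reshape(-1)
            if not (len(a) == len(b) == len(c) == n):
                raise ValueError(f"{path}: form-factor record count != positions")
            registry = {}
            species = []
            for i in range(n):
                key = f"rec{i}"
                registry[key] = FormFactorRecord(
                    a=tuple(a[i]), b=tuple(b[i]), c=float(c[i]), label=key
                )
                species.append(key)
            return Particle(
                positions=positions,
                species=np.array(species, dtype=object),
                registry=registry,
                occupancy=occupancy,
                label=str(path),
            )
        if "elements" not in f:
            raise ValueError(f"{path}: need either 'elements' or 'form_factors'")
        elements = [s.decode() if isinstance(s, bytes) else str(s) for s in f["elements"]]
        if len(elements) != n:
            raise ValueError(f"{path}: elements length != positions length")
        return Particle(
            positions=positions,
            species=np.array(elements, dtype=object),
            registry={},
            occupancy=occupancy,
            label=str(path),
        )


def _shell_lattice(particle: Particle, pad: float, voxel: float):
    """Centroid-anchored cubic lattice of spacing `voxel` covering the
    particle's padded bounding box (the centroid is a lattice point)."""
    c = particle.centroid()
    half = np.max(np.abs(particle.positions - c), axis=0) + pad
    axes = []
    for i in range(3):
        n = int(np.ceil(half[i] / voxel))
        axes.append(c[i] + np.arange(-n, n + 1) * voxel)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return axes, grid.reshape(-1, 3)


def add_hydration_layer(
    particle: Particle,
    thickness: float,
    density: float = WATER_DENSITY_E_A3,
    voxel: float = 2.0,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> Particle:
    """Decorate a particle with a continuum-water shell following its contour.

    The particle envelope is the union of spheres of ``probe_radius`` around
    the scatterers; lattice points (spacing ``voxel``) outside the envelope
    but within ``thickness`` of its surface become solvent sample points of
    amplitude ``density * voxel**3`` electrons each.
    """
    if thickness <= 0 or density <= 0 or voxel <= 0:
        raise ValueError("thickness, density and voxel must be positive")
    _, pts = _shell_lattice(particle, probe_radius + thickness + voxel, voxel)
    d = cKDTree(particle.positions).query(pts, k=1)[0]
    surface = d - probe_radius  # signed distance to the envelope surface
    in_shell = (surface > 0) & (surface <= thickness)
    if not np.any(in_shell):
        raise ValueError(
            f"empty hydration shell: thickness {thickness} Å < lattice spacing {voxel} Å"
        )
    shell_pts = pts[in_shell]
    amps = np.full(len(shell_pts), density * voxel**3)
    return particle.copy(
        solvent_points=np.vstack([particle.solvent_points, shell_pts]),
        solvent_amplitudes=np.concatenate([particle.solvent_amplitudes, amps]),
    )


def fill_cavity(
    particle: Particle,
    density: float,
    voxel: float = 2.0,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> Particle:
    """Fill interior voids of the particle envelope with uniform density.

    Voxels outside every scatterer sphere but not connected to the exterior
    (flood fill from the bounding-box boundary) are interior voids; each gets
    a solvent point of amplitude ``density * voxel**3``.  Voxels already
    claimed by an existing solvent shell are skipped.  If no void exists a
    warning is issued and an unchanged copy returned.
    """
    if density < 0 or voxel <= 0:
        raise ValueError("voxel must be positive and density nonnegative")
    axes, pts = _shell_lattice(particle, probe_radius + voxel, voxel)
    shape = tuple(len(ax) for ax in axes)
    d = cKDTree(particle.positions).query(pts, k=1)[0]
    empty = (d > probe_radius).reshape(shape)
    # flood the exterior from the box boundary through empty voxels
    border = np.zeros(shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    exterior = ndimage.binary_propagation(border & empty, mask=empty)
    void = empty & ~exterior
    void_pts = pts[void.reshape(-1)]
    if len(particle.solvent_points):
        d_sol = cKDTree(particle.solvent_points).query(void_pts, k=1)[0]
        void_pts = void_pts[d_sol > 0.5 * voxel]
    if len(void_pts) == 0:
        warnings.warn("no interior void found; particle returned unchanged")
        return particle.copy()
    amps = np.full(len(void_pts), density * voxel**3)
    return particle.copy(
        solvent_points=np.vstack([particle.solvent_points, void_pts]),
        solvent_amplitudes=np.concatenate([particle.solvent_amplitudes, amps]),
    )


def gold_reference(radius: float, lattice_constant: float = 4.08) -> Particle:
    """Spherical FCC gold nanoparticle, centred at the origin.

    Serves as the reference scatterer of a holography experiment.  Lattice
    sites of the conventional FCC cell (corner + three face centres) are
    generated on an origin-anchored lattice and clipped to ``|r| <= radius``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if radius < lattice_constant / 2:
        raise ValueError(
            f"radius {radius} Å smaller than half a lattice cell "
            f"({lattice_constant} Å); no meaningful nanoparticle"
        )
    a = lattice_constant
    n = int(np.ceil(radius / a)) + 1
    cells = np.arange(-n, n + 1)
    corners = np.stack(np.meshgrid(cells, cells, cells, indexing="ij"), axis=-1)
    corners = corners.reshape(-1, 3).astype(float) * a
    basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]) * a
    sites = (corners[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    keep = np.linalg.norm(sites, axis=1) <= radius
    sites = sites[keep]
    if len(sites) == 0:
        raise ValueError(
            f"radius {radius} Å too small for lattice constant {lattice_constant} Å"
        )
    # canonical ordering for determinism independent of meshgrid layout
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
    sites = sites[order]
    return Particle(
        positions=sites,
        species=np.array(["Au"] * len(sites), dtype=object),
        registry={},
        label=f"gold_reference(r={radius})",
    )
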