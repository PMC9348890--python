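"""Conformational heterogeneity via anisotropic-network-model normal modes.

An elastic network is built over a node subset of the particle (Cα atoms when
atom names are available, else a uniform spatial subsample), with a uniform
spring constant between nodes within a distance cutoff.  The ANM Hessian is
the standard 3N x 3N super-element matrix with off-diagonal blocks
``-gamma * (dr dr^T) / |dr|^2`` and diagonal blocks closing each row to zero.
Its eigenvectors are collective displacement fields; a connected network has
exactly six zero modes (rigid translations and rotations).

Conformer libraries are drawn by displacing nodes along selected non-rigid
modes with zero-mean Gaussian coefficients scaled so the signed per-state
RMSD contribution of mode m has standard deviation ``amplitudes[m]``;
scatterers that are not nodes ride along with their nearest node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .particle import Particle, save_particle_h5

__all__ = ["NormalModeSet", "build_anm", "sample_conformers", "write_conformer_library"]

ZERO_MODE_TOL = 1e-8


@dataclass
class NormalModeSet:
    """ANM eigen-decomposition over a node subset of a particle."""

    node_positions: np.ndarray     # (N, 3) Å
    node_indices: np.ndarray       # (N,) indices into the particle's scatterers
    eigenvalues: np.ndarray        # (3N,) ascending, spring-constant scaled
    eigenvectors: np.ndarray       # (3N, 3N), columns unit-norm
    cutoff: float                  # Å

    @property
    def num_zero_modes(self) -> int:
        scale = self.eigenvalues[-1] if self.eigenvalues[-1] > 0 else 1.0
        return int(np.sum(self.eigenvalues < ZERO_MODE_TOL * scale))

    def mode(self, index: int) -> np.ndarray:
        """Displacement field of one mode, shape (N, 3)."""
        return self.eigenvectors[:, index].reshape(-1, 3)


def _select_nodes(particle: Particle, node_budget: int) -> np.ndarray:
    if particle.atom_names is not None:
        ca = np.array([str(n).strip() == "CA" for n in particle.atom_names])
        if ca.sum() >= 3:
            idx = np.flatnonzero(ca)
            if len(idx) > node_budget:
                idx = idx[np.linspace(0, len(idx) - 1, node_budget).astype(int)]
            return idx
    n = particle.n_scatterers
    if n <= node_budget:
        return np.arange(n)
    return np.linspace(0, n - 1, node_budget).astype(int)


def build_anm(
    particle: Particle,
    cutoff: float = 15.0,
    node_budget: int = 500,
    spring_constant: float = 1.0,
) -> NormalModeSet:
    """Build and diagonalise the ANM Hessian over the selected nodes.

    Raises if fewer than 3 nodes are selected or the contact network is
    disconnected at the cutoff (which would yield more than six zero modes).
    """
    idx = _select_nodes(particle, node_budget)
    if len(idx) < 3:
        raise ValueError("need at least 3 network nodes")
    pos = particle.positions[idx]
    n = len(pos)
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp = connected_components(adj, directed=False)[0]
    else:
        n_comp = n
    if n_comp > 1:
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} Å "
            f"({n_comp} components); increase the cutoff"
        )
    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        dr = pos[j] - pos[i]
        block = -spring_constant * np.outer(dr, dr) / (dr @ dr)
        hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    vals, vecs = eigh(hess)
    vals = np.clip(vals, 0.0, None)  # numerical negatives in the null space
    # note: degenerate geometries (e.g. collinear chains) can carry more than
    # six zero modes while still being connected; connectivity is checked on
    # the contact graph above, which is the actual disconnection criterion.
    return NormalModeSet(
        node_positions=pos,
        node_indices=idx,
        eigenvalues=vals,
        eigenvectors=vecs,
        cutoff=cutoff,
    )


def sample_conformers(
    particle: Particle,
    modes: NormalModeSet,
    mode_indices,
    amplitudes,
    n_states: int,
    seed: int | np.random.Generator = 0,
) -> list[Particle]:
    """Draw a library of displaced conformations along the given modes.

    ``amplitudes[m]`` (Å) is the standard deviation of the signed per-state
    RMSD along mode ``mode_indices[m]``; coefficients are zero-mean Gaussian.
    Non-node scatterers are displaced with their nearest node.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    mode_indices = list(mode_indices)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(amplitudes) != len(mode_indices):
        raise ValueError("one amplitude per mode index required")
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be nonnegative")
    nz = modes.num_zero_modes
    for m in mode_indices:
        if m < nz:
            raise ValueError(f"mode {m} is a rigid-body (zero) mode; pick index >= {nz}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = len(modes.node_positions)
    # map every scatterer to its nearest node
    nearest = cKDTree(modes.node_positions).query(particle.positions, k=1)[1]
    states = []
    for s in range(n_states):
        node_disp = np.zeros((n_nodes, 3))
        for m, a in zip(mode_indices, amplitudes):
            c = rng.normal(0.0, a * np.sqrt(n_nodes))
            node_disp += c * modes.mode(m)
        new = particle.copy(
            positions=particle.positions + node_disp[nearest],
            label=f"{particle.label or 'particle'}/state{s:04d}",
        )
        states.append(new)
    return states


def write_conformer_library(directory, states: list[Particle], manifest_extra=None):
    """Write a conformer library: one particle HDF5 per state plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"states": {}, **(manifest_extra or {})}
    for i, st in enumerate(states):
        fname = f"state{i:04d}.h5"
        save_particle_h5(directory / fname, st)
        manifest["states"][st.label or f"state{i:04d}"] = fname
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return directory / "manifest.json"
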