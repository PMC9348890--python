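"""Ballistic hit-and-stick particle–cluster aggregation.

Aggregates form by a sequence of collisions between a growing cluster and one
incoming particle at a time.  Each incoming particle is randomly oriented,
launched from outside the cluster with a random impact parameter, and
translated along a straight line aimed at the cluster centre of mass until its
bounding sphere first touches any member's bounding sphere.  On contact it
freezes ("hit and stick"): no re-orientation, compression or fragmentation.
Collision detection is at the bounding-sphere level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .particle import Particle
from .rotation import quat_to_matrix, random_quaternion

__all__ = ["ClusterLayout", "bounding_radius", "build_cluster", "realize_cluster"]

CONTACT_RTOL = 1e-6


def bounding_radius(particle: Particle) -> float:
    """Radius of the smallest centroid-centred sphere containing all scatterers."""
    c = particle.centroid()
    return float(np.max(np.linalg.norm(particle.positions - c, axis=1)))


@dataclass
class ClusterLayout:
    """Rigid placement of cluster members (orientation + centre offset each)."""

    particles: list
    quaternions: np.ndarray        # (K, 4), (w, x, y, z), unit norm
    offsets: np.ndarray            # (K, 3) Å, member centre positions
    radii: np.ndarray              # (K,) Å bounding radii
    contact_edges: list = field(default_factory=list)
    seed: int | None = None

    @property
    def n_members(self) -> int:
        return len(self.particles)

    def to_json(self) -> str:
        return json.dumps(
            {
                "quaternions": self.quaternions.tolist(),
                "offsets": self.offsets.tolist(),
                "radii": self.radii.tolist(),
                "contact_edges": [list(e) for e in self.contact_edges],
                "seed": self.seed,
            }
        )

    def is_connected(self) -> bool:
        k = self.n_members
        if k <= 1:
            return True
        adj = {i: set() for i in range(k)}
        for i, j in self.contact_edges:
            adj[i].add(j)
            adj[j].add(i)
        seen, stack = {0}, [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == k


def _first_contact_distance(launch, direction, centers, radii, r_new):
    """Smallest travel distance along `direction` to sphere contact, or None."""
    best = None
    for c, r in zip(centers, radii):
        p = c - launch
        proj = p @ direction
        rr = r + r_new
        disc = proj * proj - p @ p + rr * rr
        if disc < 0:
            continue
        t = proj - np.sqrt(disc)  # first touching point
        if t >= 0 and (best is None or t < best):
            best = t
    return best


def build_cluster(
    particles: list,
    seed: int | np.random.Generator = 0,
    margin: float = 1.0,
    max_retries: int = 200,
) -> ClusterLayout:
    """Aggregate particles one by one into a single hit-and-stick cluster.

    The first member sits at the origin with a random orientation.  Each later
    member is launched from a sphere of radius (cluster extent + its own
    radius + ``margin``) with a transverse offset uniform in the disk of the
    cluster's projected radius, and slides toward the centre of mass until
    bounding spheres touch.  Trajectories that miss are resampled, up to
    ``max_retries`` per member.
    """
    if len(particles) < 1:
        raise ValueError("need at least one particle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radii = np.array([bounding_radius(p) for p in particles])
    weights = np.array([p.n_scatterers for p in particles], dtype=float)
    quats = [random_quaternion(rng)]
    centers = [np.zeros(3)]
    edges: list[tuple[int, int]] = []
    for k in range(1, len(particles)):
        placed = np.array(centers)
        com = np.average(placed, axis=0, weights=weights[:k])
        extent = np.max(np.linalg.norm(placed - com, axis=1) + radii[:k])
        r_new = radii[k]
        quat = random_quaternion(rng)
        contact_t = None
        for _ in range(max_retries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            launch0 = com + u * (extent + r_new + margin)
            direction = (com - launch0)
            direction /= np.linalg.norm(direction)
            # transverse offset uniform in the disk of the projected cluster radius
            t1 = np.cross(direction, [0.0, 0.0, 1.0])
            if np.linalg.norm(t1) < 1e-12:
                t1 = np.cross(direction, [0.0, 1.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(direction, t1)
            rho = extent * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            launch = launch0 + rho * (np.cos(phi) * t1 + np.sin(phi) * t2)
            contact_t = _first_contact_distance(
                launch, direction, placed, radii[:k], r_new
            )
            if contact_t is not None:
                break
        if contact_t is None:
            raise RuntimeError(
                f"ballistic trajectory missed the cluster {max_retries} times "
                f"while placing member {k}"
            )
        new_center = launch + contact_t * direction
        centers.append(new_center)
        quats.append(quat)
        for i in range(k):
            d = np.linalg.norm(new_center - centers[i])
            rr = radii[i] + r_new
            if d <= rr * (1 + CONTACT_RTOL) + 1e-9:
                edges.append((i, k))
    return ClusterLayout(
        particles=list(particles),
        quaternions=np.array(quats),
        offsets=np.array(centers),
        radii=radii,
        contact_edges=edges,
        seed=seed if isinstance(seed, int) else None,
    )


def realize_cluster(layout: ClusterLayout) -> Particle:
    """Merge the layout into one Particle (members rotated about their
    centroids, then offset; solvent points transformed identically)."""
    positions, species, occ, solv_pts, solv_amp = [], [], [], [], []
    registry: dict = {}
    names = []
    have_names = all(p.atom_names is not None for p in layout.particles)
    for p, q, off in zip(layout.particles, layout.quaternions, layout.offsets):
        rot = quat_to_matrix(q)
        c = p.centroid()
        positions.append((p.positions - c) @ rot.T + off)
        species.append(p.species)
        occ.append(p.occupancy)
        if len(p.solvent_points):
            solv_pts.append((p.solvent_points - c) @ rot.T + off)
            solv_amp.append(p.solvent_amplitudes)
        registry.update(p.registry)
        if have_names:
            names.append(p.atom_names)
    return Particle(
        positions=np.vstack(positions),
        species=np.concatenate(species),
        registry=registry,
        occupancy=np.concatenate(occ),
        solvent_points=np.vstack(solv_pts) if solv_pts else np.empty((0, 3)),
        solvent_amplitudes=np.concatenate(solv_amp) if solv_amp else np.empty(0),
        atom_names=np.concatenate(names) if have_names else None,
        label="cluster[" + "+".join(p.label or "particle" for p in layout.particles) + "]",
    )
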