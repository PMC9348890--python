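"""Experiment orchestration: SPI / SPI-aggregate / FXS / FTH over many shots.

The four experiment kinds share one engine and differ only in the number,
type and relative placement of particles in the beam:

* ``spi``            — one particle per shot, random orientation;
* ``spi_aggregate``  — K particles aggregated into a hit-and-stick cluster;
* ``fxs``            — K particles (fixed or Poisson-distributed count)
                        dispersed independently in the interaction volume;
* ``fth``            — one target particle plus a reference scatterer at a
                        fixed in-plane separation; their interference encodes
                        the hologram.

Per shot, the noise stack is applied in a fixed order:
spectrum -> slice/coherent sum -> static background -> Poisson quantisation
-> gain digitisation -> dark noise.  Disabling every noise source leaves the
ideal expected-photon map untouched.

Reproducibility: shot ``i`` of an experiment with root seed ``s`` draws all
randomness from ``numpy``'s ``SeedSequence([s, i])`` stream, so any shot can
be regenerated independently of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregate import build_cluster, realize_cluster
from .beam import Beam, Spectrum, fluence_at, sase_spectrum, shot_fluence
from .detector import (
    DetectorGeometry,
    NoiseConfig,
    apply_dark_noise,
    apply_static_background,
    digitize,
    pixel_maps,
)
from .diffraction import (
    DiffractionVolume,
    build_volume,
    expected_photons,
    multi_particle_pattern,
    slice_pattern,
)
from .particle import Particle
from .rotation import random_quaternion

__all__ = [
    "ExperimentConfig",
    "ShotRecord",
    "Experiment",
    "simulate_shot",
    "run_experiment",
    "read_dataset",
    "radial_profile",
]

M_TO_A = 1e10

KINDS = ("spi", "spi_aggregate", "fxs", "fth")


@dataclass
class ExperimentConfig:
    """Everything needed to simulate a dataset.

    ``particles`` is the state library: (Particle, weight) pairs sampled per
    shot.  ``particles_per_shot`` is an int (fixed count) or, when
    ``poisson_particles`` is set, the mean of a Poisson draw (clipped to at
    least 1).  ``interaction_volume_m`` gives box extents of the jet-beam
    overlap region in which particles are displaced.
    """

    kind: str
    beam: Beam
    geometry: DetectorGeometry
    particles: list  # [(Particle, weight), ...]
    n_shots: int = 1
    particles_per_shot: float = 1
    poisson_particles: bool = False
    interaction_volume_m: tuple[float, float, float] = (1e-7, 1e-7, 1e-7)
    reference: Particle | None = None
    reference_offset_A: np.ndarray | None = None
    outputs: str = "photons"  # 'ideal' | 'photons' | 'both'
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    spectrum: dict = field(default_factory=lambda: {"type": "monochromatic"})
    n_grid: int | None = None
    oversampling: int = 4
    q_max_factor: float = 1.02

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.n_shots < 1:
            raise ValueError("n_shots must be >= 1")
        if not self.particles:
            raise ValueError("at least one particle source required")
        w = np.array([float(w) for _, w in self.particles])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("particle weights must be nonnegative with positive sum")
        self.particles = [(p, wi / w.sum()) for (p, _), wi in zip(self.particles, w)]
        if self.kind == "spi" and not (
            self.particles_per_shot == 1 and not self.poisson_particles
        ):
            raise ValueError("spi experiments have exactly one particle per shot")
        if self.kind == "fth":
            if self.reference is None:
                raise ValueError("fth requires a reference particle")
            if len(self.particles) != 1:
                raise ValueError("fth takes exactly one target source")
        if self.outputs not in ("ideal", "photons", "both"):
            raise ValueError(f"unknown outputs mode {self.outputs!r}")


@dataclass
class ShotRecord:
    """One simulated pattern plus its complete ground truth."""

    index: int
    ideal: np.ndarray | None          # expected photons per pixel
    photons: np.ndarray | None        # Poisson-quantised counts
    adu: np.ndarray | None            # digitised + dark, when enabled
    n_particles: int
    orientations: np.ndarray          # (K, 4) quaternions (w, x, y, z)
    positions_A: np.ndarray           # (K, 3) Å
    state_labels: list
    fluence_photons: float            # jittered photon count of this pulse
    fluence_per_m2: float             # fluence at the shot's centre of mass
    miscenter_m: tuple[float, float]
    spectrum: Spectrum


def _default_reference_offset(target: Particle, reference: Particle) -> np.ndarray:
    from .aggregate import bounding_radius

    sep = 2.5 * 2.0 * (bounding_radius(target) + bounding_radius(reference))
    return np.array([sep, 0.0, 0.0])


class Experiment:
    """Precomputes per-state diffraction volumes and simulates shots."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.maps0 = pixel_maps(
            config.geometry, config.beam.wavelength_A, config.beam.polarization
        )
        bw = 0.0
        if config.spectrum.get("type") == "sase":
            bw = config.spectrum.get("bandwidth_fraction", 1e-3)
        self.q_max = (
            config.q_max_factor
            * (1.0 + 5.0 * bw)
            * float(self.maps0.q_mag[self.maps0.mask].max())
        )
        self.volumes: list[DiffractionVolume | None] = []
        if config.kind == "spi":
            # the one-time cost: one |F|^2 volume per library state
            for p, _ in config.particles:
                self.volumes.append(
                    build_volume(
                        p, self.q_max, config.n_grid, config.oversampling
                    )
                )
        else:
            self.volumes = [None] * len(config.particles)

    # -- per-shot sampling helpers -------------------------------------------

    def _sample_state_indices(self, rng: np.random.Generator, k: int) -> np.ndarray:
        w = np.array([w for _, w in self.config.particles])
        return rng.choice(len(w), size=k, p=w)

    def _sample_count(self, rng: np.random.Generator) -> int:
        cfg = self.config
        if cfg.kind in ("spi", "fth"):
            return 1
        if cfg.poisson_particles:
            return max(1, int(rng.poisson(cfg.particles_per_shot)))
        return int(cfg.particles_per_shot)

    def _shot_rng(self, shot_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.config.seed), int(shot_index)])
        )

    # -- the shot ------------------------------------------------------------

    def simulate_shot(self, shot_index: int) -> ShotRecord:
        cfg = self.config
        rng = self._shot_rng(shot_index)
        box = np.asarray(cfg.interaction_volume_m, dtype=float)

        k = self._sample_count(rng)
        state_idx = self._sample_state_indices(rng, k)
        members = [cfg.particles[i][0] for i in state_idx]
        labels = [p.label or f"state{i}" for p, i in zip(members, state_idx)]
        orientations = np.array([random_quaternion(rng) for _ in range(k)])

        if cfg.kind == "fxs":
            positions_m = rng.uniform(-box / 2, box / 2, size=(k, 3))
        else:
            # one rigid body (particle, cluster or target+reference): one draw
            positions_m = np.tile(rng.uniform(-box / 2, box / 2, size=3), (k, 1))

        # beam-side randomness
        photons = shot_fluence(cfg.beam, rng)
        com_m = positions_m.mean(axis=0)
        if cfg.beam.profile == "gaussian":
            fluence = fluence_at(cfg.beam, com_m[:2], photons=photons)
        else:
            # uniform focus: the interaction volume is assumed inside the focus
            fluence = photons / (np.pi * cfg.beam.focus_radius_m**2)

        if cfg.spectrum.get("type") == "sase":
            spectrum = sase_spectrum(
                cfg.beam,
                n_spikes=cfg.spectrum.get("n_spikes", 100),
                bandwidth_fraction=cfg.spectrum.get("bandwidth_fraction", 1e-3),
                n_samples=cfg.spectrum.get("n_samples", 21),
                seed=rng,
            )
        else:
            spectrum = Spectrum.monochromatic(cfg.beam.wavelength_A)

        # detector-side geometry jitter
        miscenter = (0.0, 0.0)
        geometry = cfg.geometry
        if any(s > 0 for s in cfg.noise.miscenter_sigma_m):
            from .detector import sample_miscenter

            miscenter = sample_miscenter(cfg.noise, rng)
            geometry = geometry.with_center_offset(miscenter)

        # assemble the per-shot particle states (positions in Å)
        positions_A = positions_m * M_TO_A
        if cfg.kind == "spi":
            states = [(self.volumes[state_idx[0]], orientations[0], positions_A[0])]
        elif cfg.kind == "spi_aggregate":
            layout = build_cluster(members, seed=rng)
            merged = realize_cluster(layout)
            # the cluster is one rigid body: one orientation, one displacement
            cluster_q = random_quaternion(rng)
            states = [(merged, cluster_q, positions_A[0])]
            # ground truth per member: composed orientation + lab-frame centre
            from .rotation import quat_multiply, quat_to_matrix

            rot = quat_to_matrix(cluster_q)
            c = merged.centroid()
            positions_A = (layout.offsets - c) @ rot.T + positions_A[0]
            orientations = np.array(
                [quat_multiply(cluster_q, qm) for qm in layout.quaternions]
            )
            labels = [merged.label]
            k = len(members)
        elif cfg.kind == "fxs":
            states = [
                (members[j], orientations[j], positions_A[j]) for j in range(k)
            ]
        else:  # fth
            offset = (
                np.asarray(cfg.reference_offset_A, dtype=float)
                if cfg.reference_offset_A is not None
                else _default_reference_offset(members[0], cfg.reference)
            )
            ref_orientation = random_quaternion(rng)
            states = [
                (members[0], orientations[0], positions_A[0]),
                (cfg.reference, ref_orientation, positions_A[0] + offset),
            ]
            orientations = np.vstack([orientations, ref_orientation[None]])
            positions_A = np.vstack([positions_A, positions_A[0] + offset])
            labels = labels + [cfg.reference.label or "reference"]
            k = 2

        # spectrum -> slice/sum: incoherent weighted stack of expected photons
        lam = np.zeros(self.maps0.shape)
        for wl, weight in zip(spectrum.wavelengths_A, spectrum.weights):
            if weight == 0:
                continue
            maps = pixel_maps(geometry, wl, cfg.beam.polarization)
            if len(states) == 1 and isinstance(states[0][0], DiffractionVolume):
                pattern = slice_pattern(states[0][0], states[0][1], maps)
            else:
                pattern = multi_particle_pattern(states, maps, coherent=True)
            lam += weight * expected_photons(pattern, maps, fluence)

        if cfg.noise.static_background is not None:
            lam_obs = apply_static_background(lam, cfg.noise.static_background)
        else:
            lam_obs = lam

        photons_img = None
        adu = None
        if cfg.outputs in ("photons", "both"):
            photons_img = rng.poisson(lam_obs)
            digitized = digitize(
                photons_img, cfg.noise, cfg.beam.photon_energy_ev / 1000.0
            )
            dark_on = (
                cfg.noise.dark_frames is not None or cfg.noise.dark_sigma_adu > 0
            )
            if cfg.noise.gain_mode != "photon_counting" or dark_on:
                adu = apply_dark_noise(digitized.adu, cfg.noise, rng)

        return ShotRecord(
            index=shot_index,
            ideal=lam if cfg.outputs in ("ideal", "both") else None,
            photons=photons_img,
            adu=adu,
            n_particles=k,
            orientations=orientations,
            positions_A=positions_A,
            state_labels=labels,
            fluence_photons=photons,
            fluence_per_m2=fluence,
            miscenter_m=miscenter,
            spectrum=spectrum,
        )

    # -- dataset writing -----------------------------------------------------

    def run(self, out_path, progress: bool = False):
        """Simulate all shots and stream them into a CXI-flavoured HDF5 file."""
        import h5py

        cfg = self.config
        ny, nx = cfg.geometry.shape
        max_k = 1
        records_meta = []
        with h5py.File(out_path, "w") as f:
            opts = dict(track_times=False)
            data_grp = f.create_group("entry_1/data_1")
            det_grp = f.create_group("entry_1/instrument_1/detector_1")
            det_grp.create_dataset("distance", data=cfg.geometry.distance_m, **opts)
            det_grp.create_dataset("x_pixel_size", data=cfg.geometry.pixel_size_m, **opts)
            det_grp.create_dataset("y_pixel_size", data=cfg.geometry.pixel_size_m, **opts)
            det_grp.create_dataset("mask", data=cfg.geometry.mask, **opts)
            if cfg.outputs in ("photons", "both"):
                d_photons = data_grp.create_dataset(
                    "data", shape=(cfg.n_shots, ny, nx), dtype="int32", **opts
                )
            if cfg.outputs in ("ideal", "both"):
                d_ideal = data_grp.create_dataset(
                    "ideal", shape=(cfg.n_shots, ny, nx), dtype="float64", **opts
                )
            d_adu = None
            shots = []
            for i in range(cfg.n_shots):
                rec = self.simulate_shot(i)
                shots.append(rec)
                max_k = max(max_k, rec.n_particles)
                if rec.photons is not None:
                    d_photons[i] = rec.photons
                if rec.ideal is not None:
                    d_ideal[i] = rec.ideal
                if rec.adu is not None:
                    if d_adu is None:
                        d_adu = data_grp.create_dataset(
                            "adu", shape=(cfg.n_shots, ny, nx), dtype="float64", **opts
                        )
                    d_adu[i] = rec.adu
                records_meta.append(rec)
                if progress and (i + 1) % 10 == 0:
                    print(f"  shot {i + 1}/{cfg.n_shots}", flush=True)

            geo = f.create_group("entry_1/sample_1/geometry")
            orientations = np.full((cfg.n_shots, max_k, 4), np.nan)
            positions = np.full((cfg.n_shots, max_k, 3), np.nan)
            for i, rec in enumerate(shots):
                orientations[i, : len(rec.orientations)] = rec.orientations
                positions[i, : rec.positions_A.shape[0]] = rec.positions_A
            geo.create_dataset("orientations", data=orientations, **opts)
            geo.create_dataset("positions", data=positions, **opts)

            gt = f.create_group("ground_truth")
            gt.create_dataset(
                "n_particles",
                data=np.array([r.n_particles for r in shots], dtype=int),
                **opts,
            )
            gt.create_dataset(
                "fluence_photons",
                data=np.array([r.fluence_photons for r in shots]),
                **opts,
            )
            gt.create_dataset(
                "fluence_per_m2",
                data=np.array([r.fluence_per_m2 for r in shots]),
                **opts,
            )
            gt.create_dataset(
                "miscenter_m",
                data=np.array([r.miscenter_m for r in shots]),
                **opts,
            )
            labels = np.array(
                ["|".join(r.state_labels).encode() for r in shots]
            )
            gt.create_dataset("state_labels", data=labels, **opts)
            gt.create_dataset("seed", data=int(cfg.seed), **opts)
        return out_path


def simulate_shot(config: ExperimentConfig, shot_index: int) -> ShotRecord:
    """One-off shot simulation (builds volumes; prefer Experiment for many)."""
    return Experiment(config).simulate_shot(shot_index)


def run_experiment(config: ExperimentConfig, out_path, progress: bool = False):
    """Simulate the full dataset into ``out_path`` (CXI-flavoured HDF5)."""
    return Experiment(config).run(out_path, progress=progress)


def read_dataset(path) -> dict:
    """Read back a dataset file into plain arrays (round-trip helper)."""
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        data = f["entry_1/data_1"]
        for key in ("data", "ideal", "adu"):
            if key in data:
                out[key] = np.asarray(data[key])
        out["orientations"] = np.asarray(f["entry_1/sample_1/geometry/orientations"])
        out["positions"] = np.asarray(f["entry_1/sample_1/geometry/positions"])
        gt = f["ground_truth"]
        for key in (
            "n_particles",
            "fluence_photons",
            "fluence_per_m2",
            "miscenter_m",
            "state_labels",
            "seed",
        ):
            out[key] = np.asarray(gt[key])
        det = f["entry_1/instrument_1/detector_1"]
        out["distance"] = float(np.asarray(det["distance"]))
        out["x_pixel_size"] = float(np.asarray(det["x_pixel_size"]))
        out["mask"] = np.asarray(det["mask"])
    return out


def radial_profile(pattern: np.ndarray, maps, n_bins: int = 100,
                   extra_mask: np.ndarray | None = None):
    """Radially averaged profile: mean intensity in equal-width |q| bins.

    Returns (bin centres Å⁻¹, mean intensity); empty bins hold NaN.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    live = maps.mask.copy()
    if extra_mask is not None:
        live &= np.asarray(extra_mask, dtype=bool)
    q = maps.q_mag[live]
    v = np.asarray(pattern, dtype=float)[live]
    q_max = maps.q_mag[maps.mask].max()
    edges = np.linspace(0.0, q_max * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(q, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, means
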