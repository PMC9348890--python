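"""YAML experiment configuration.

Schema (all keys under one document)::

    experiment:
      kind: spi | spi_aggregate | fxs | fth
      n_shots: 100
      particles_per_shot: 3          # fxs / spi_aggregate
      poisson_particles: false
      outputs: photons | ideal | both
      seed: 0
      interaction_volume_m: [1.0e-7, 1.0e-7, 1.0e-7]
    beam:
      photon_energy_ev: 4000.0
      photons_per_pulse: 1.0e12
      focus_radius_m: 1.0e-7
      polarization: horizontal
      jitter_fraction: 0.0
      profile: uniform | gaussian
      spectrum: {type: monochromatic}   # or {type: sase, n_spikes: …,
                                        #     bandwidth_fraction: …, n_samples: …}
    detector:
      n_pixels: 256
      pixel_size_m: 75.0e-6
      distance_m: 0.2                # or edge_resolution_A: 14.0
      gap_m: 0.0
    particles:
      - {fixture: {name: random_coil, n: 60, seed: 7}, weight: 1.0}
      - {pdb: path/to.pdb, weight: 1.0}
      - {h5: path/to.h5, weight: 1.0}
      reference: {gold: {radius: 10.0}}   # fth only (sibling of the list form)
    noise:
      miscenter_sigma_m: [0.0, 0.0]
      dark_sigma_adu: 0.0
      gain_mode: photon_counting | autoranging
      static_background: {slope_photons: 0.0}  # linear ramp across the panel
"""

from __future__ import annotations

import numpy as np
import yaml

from .analysis import make_fixture
from .beam import Beam
from .detector import DetectorGeometry, NoiseConfig, distance_for_resolution
from .experiment import ExperimentConfig
from .particle import gold_reference, load_particle_h5, load_pdb

__all__ = ["config_from_yaml", "config_from_dict"]


def _load_particle_entry(entry: dict):
    if "fixture" in entry:
        spec = dict(entry["fixture"])
        return make_fixture(spec.pop("name"), **spec)
    if "pdb" in entry:
        return load_pdb(entry["pdb"])
    if "h5" in entry:
        return load_particle_h5(entry["h5"])
    if "gold" in entry:
        return gold_reference(**entry["gold"])
    raise ValueError(f"cannot interpret particle source {entry!r}")


def _ramp_background(shape, slope: float) -> np.ndarray:
    ny, nx = shape
    ramp = np.linspace(0.0, 1.0, nx)[None, :] * np.ones((ny, 1))
    return slope * ramp


def config_from_dict(cfg: dict) -> ExperimentConfig:
    exp = cfg.get("experiment", {})
    beam_cfg = dict(cfg.get("beam", {}))
    spectrum = beam_cfg.pop("spectrum", {"type": "monochromatic"})
    beam = Beam(**beam_cfg)

    det = dict(cfg.get("detector", {}))
    n_pixels = int(det.pop("n_pixels"))
    pixel_size = float(det.pop("pixel_size_m"))
    if "edge_resolution_A" in det:
        half = n_pixels / 2 * pixel_size
        distance = distance_for_resolution(
            float(det.pop("edge_resolution_A")), beam.wavelength_A, half
        )
        det.pop("distance_m", None)
    else:
        distance = float(det.pop("distance_m"))
    geometry = DetectorGeometry(
        (n_pixels, n_pixels), pixel_size, distance, gap_m=float(det.pop("gap_m", 0.0))
    )

    part_cfg = cfg.get("particles", [])
    reference = None
    if isinstance(part_cfg, dict):
        reference = (
            _load_particle_entry(part_cfg["reference"])
            if "reference" in part_cfg
            else None
        )
        part_cfg = part_cfg.get("sources", [])
    particles = [
        (_load_particle_entry(e), float(e.get("weight", 1.0))) for e in part_cfg
    ]

    noise_cfg = dict(cfg.get("noise", {}))
    bg = noise_cfg.pop("static_background", None)
    if bg is not None and "slope_photons" in bg:
        noise_cfg["static_background"] = _ramp_background(
            geometry.shape, float(bg["slope_photons"])
        )
    if "miscenter_sigma_m" in noise_cfg:
        noise_cfg["miscenter_sigma_m"] = tuple(
            np.atleast_1d(noise_cfg["miscenter_sigma_m"]).astype(float)
        )
    noise = NoiseConfig(**noise_cfg)

    return ExperimentConfig(
        kind=exp.get("kind", "spi"),
        beam=beam,
        geometry=geometry,
        particles=particles,
        n_shots=int(exp.get("n_shots", 1)),
        particles_per_shot=exp.get("particles_per_shot", 1),
        poisson_particles=bool(exp.get("poisson_particles", False)),
        interaction_volume_m=tuple(exp.get("interaction_volume_m", (1e-7,) * 3)),
        reference=reference,
        outputs=exp.get("outputs", "photons"),
        seed=int(exp.get("seed", 0)),
        noise=noise,
        spectrum=spectrum,
        n_grid=exp.get("n_grid"),
        oversampling=int(exp.get("oversampling", 4)),
    )


def config_from_yaml(path) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
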