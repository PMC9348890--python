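# cxdisim

Simulation of coherent X-ray diffractive imaging (CXDI) of noncrystalline
biological particles at X-ray free-electron laser (XFEL) sources.

CXDI experiments on single particles remain data-starved: real datasets are
rare, noisy and hard to label, which makes it difficult to develop and
benchmark hit-finding, classification, background-subtraction and
reconstruction algorithms. `cxdisim` generates realistic synthetic datasets
with complete per-shot ground truth for the four principal experiment
geometries:

* **SPI** — single-particle imaging: one particle per shot at a random
  unknown orientation;
* **SPI aggregates** — several particles fused by ballistic hit-and-stick
  aggregation, for training single-hit classifiers;
* **FXS** — fluctuation X-ray scattering: several identical particles
  dispersed in the beam;
* **FTH** — Fourier-transform holography: a target particle interfering with
  a gold-nanoparticle reference.

## Model

A particle is a set of point scatterers with International-Tables
four-Gaussian atomic form factors f(s) (so f(0) equals the electron count),
optionally decorated with a continuum hydration shell and interior cavity
fill sampled on a lattice. The exact far-field structure factor is the
direct sum

```
F(q) = Σ_j occ_j f_j(|q|) exp(i q·r_j) + Σ_k A_k exp(i q·r_k)
```

over scatterers j and solvent sample points k, with the physics convention
q = k_out − k_in, |q| = 4π sin θ/λ and resolution d = 2π/|q|.

For SPI, |F|² is evaluated once per particle state on a cubic reciprocal grid
(cost linear in the atom count); each shot then slices this volume on the
detector's rotated Ewald sphere by trilinear interpolation, at a cost
independent of the atom count. Multi-particle patterns (aggregates, FXS,
FTH) are coherent sums |Σ_k exp(i q·d_k) F_k(R_kᵀ q)|² by per-particle direct
summation. Expected photon counts follow Thomson scattering,

```
λ_p = fluence · r_e² · Ω_p · P_p · |F(q_p)|² ,
```

with pixel solid angle Ω and polarization factor P, and measured photons are
independent Poisson draws.

The configurable noise stack covers all the error sources that typify real
CXDI data: Poisson counting noise, conformational heterogeneity (anisotropic
network-model conformer libraries), hydration-shell variation, particle
aggregation, SASE spectral structure (Gaussian-KDE spike trains), fluence
jitter, Gaussian beam miscentering, auto-ranging gain digitisation, dark
noise and a static sloped background. Fourier shell correlation utilities
(`fsc`, `resolution_at_threshold`) support downstream reconstruction
validation.

## Worked example

Twenty SPI shots of a hydrated 60-residue random coil on a 128×128 detector
with 10 % fluence jitter:

```python
import cxdisim as cx
from cxdisim.experiment import Experiment, ExperimentConfig, read_dataset

particle = cx.add_hydration_layer(
    cx.make_fixture("random_coil", n=60, seed=21), thickness=3.0, voxel=3.0
)
cfg = ExperimentConfig(
    kind="spi",
    beam=cx.Beam(photon_energy_ev=4000.0, photons_per_pulse=1e13,
                 focus_radius_m=1e-7, jitter_fraction=0.1),
    geometry=cx.DetectorGeometry.monolithic(128, 75e-6, 0.1),
    particles=[(particle, 1.0)],
    n_shots=20, outputs="both", seed=0,
)
out = Experiment(cfg).run("example.cxi")
d = read_dataset(out)
print("patterns:", d["data"].shape)
print("mean photons/pixel:", round(float(d["data"].mean()), 4))
```

prints

```
patterns: (20, 128, 128)
mean photons/pixel: 0.0078
```

— sparse single-photon patterns, as real SPI data are: at this fluence a
small protein scatters a few thousandths of a photon per pixel, which is why
thousands of shots must be merged for reconstruction. The dataset file is
CXI-flavoured HDF5 carrying the patterns (quantised photons, ideal
intensities and, when gain/dark noise is on, ADU), per-shot quaternions,
positions, particle counts, fluences and beam-center offsets — the ground
truth a classification or orientation-recovery algorithm trains against.

The same run from the shell:

```
cxdisim run --config cfg.yaml --out example.cxi --seed 0
cxdisim profile --dataset example.cxi --bins 200 --wavelength-a 3.1
cxdisim fixtures --name two_atom --out two.h5
```

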