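# Methods

This note records the physical model, the numerical choices and the design
decisions behind `cxdisim`, and what the test suite does and does not
demonstrate.

## Scattering model

Particles are collections of point scatterers. Atomic species use the
International Tables four-Gaussian form-factor parameterisation
f(s) = Σᵢ aᵢ exp(−bᵢ s²) + c with s = |q|/4π, taken from gemmi's element
tables; coarse-grained particles loaded from HDF5 may instead carry one
explicit coefficient record per scatterer, used verbatim. All reciprocal
quantities use the physics convention q = k_out − k_in with |k| = 2π/λ, so
|q| = 4π sin θ/λ and d = 2π/|q|; the analysis module's FSC resolution is
additionally reported in the map-frequency convention d = 1/k to avoid the
2π ambiguity common between crystallographic and imaging communities.

The exact structure factor is direct summation over scatterers and
continuum-solvent points. This O(N·M) sum is the package's oracle: every
faster path (volume slicing) is tested against it. Solvent points are
q-independent point amplitudes (density × voxel³ electrons); aliasing is
controlled by the lattice spacing, which should stay below
1/(2·q_max·oversampling) for quantitative work beyond the detector edge.

## Hydration layer and cavity fill

The particle envelope is the union of spheres of a configurable probe radius
(default 1.7 Å, a generic heavy-atom van der Waals radius) around the
scatterers. The hydration shell consists of the points of a
centroid-anchored cubic lattice lying outside the envelope but within the
shell thickness of its surface; each carries density × voxel³ electrons,
default density 0.334 e Å⁻³ (bulk water), default voxel 2 Å. Interior
cavities are the empty lattice voxels not reachable from the bounding-box
boundary (binary flood fill); filling them with a uniform density models
e.g. the nucleic-acid interior of a virus capsid at low resolution. On a
spherical test particle the summed shell electrons converge to ρ × the
analytic shell volume as the voxel is refined (verified to 2 % at 0.4 Å).

## Conformational heterogeneity

The anisotropic network model is built over Cα atoms when atom names are
available, otherwise over a uniform spatial subsample (default budget 500
nodes): uniform springs between nodes within a 15 Å cutoff, the standard
super-element Hessian, dense symmetric eigendecomposition. A connected
network has six rigid-body zero modes; disconnection is detected on the
contact graph (degenerate geometries such as collinear chains legitimately
carry extra zero modes, so the graph — not the zero-mode count — is the
criterion). Conformers displace nodes along selected non-rigid modes with
zero-mean Gaussian coefficients; the coefficient scale is chosen so the
signed per-state RMSD along mode m has standard deviation `amplitudes[m]`
(the sampling rule is deliberately stated in terms of a signed projection,
since an unsigned RMSD has no zero-mean distribution). Non-node scatterers
ride with their nearest node — adequate for the large-scale collective
motions normal modes describe, wrong for side-chain-level detail, which is
out of scope.

## Aggregation

Hit-and-stick ballistic particle–cluster aggregation at bounding-sphere
resolution: each incoming member is randomly oriented, launched from a
sphere enclosing the cluster with a transverse impact offset uniform in the
disk of the cluster's projected radius, and translated toward the cluster
centre of mass until its bounding sphere first touches any member's.
Contact is frozen — no re-orientation, compression or fragmentation — and
misses are resampled (bounded retries). Consequences worth knowing:
member-centre separations at insertion equal the sum of bounding radii
exactly; clusters are connected by construction; contact directions are
isotropic. Atom-level contact refinement is deliberately not attempted —
the model is a schematic of injector aggregation, not a physical collision
simulation.

## Beam

Wavelength λ[Å] = 12398.42/E[eV]. SASE pulses: spike centre energies
Gaussian about the central energy with σ = bandwidth_fraction × E₀, spike
heights uniform(0.5, 1.5), and a height-weighted Gaussian KDE with Scott's
bandwidth over the spike centres evaluated on a ±4σ grid (a degenerate
single-spike train collapses to an exact single line). The KDE is
hand-evaluated (ten lines) rather than delegated, because the degenerate
limit must return a delta line where a generic KDE errors on singular
covariance. Polychromatic patterns are incoherent weighted sums over the
spectral samples, each with its own Ewald mapping — SASE spikes are mutually
incoherent. Fluence jitter multiplies the pulse photon count by
max(0, 1 + ε), ε ~ N(0, jitter²). Spatial profiles: uniform over a circular
focus, or a normalised 2D Gaussian. In an experiment the per-shot fluence is
evaluated at the shot's transverse centre of mass for the Gaussian profile;
the uniform profile assumes the interaction volume sits inside the focus.

## Detector

Flat square-pixel geometry normal to the beam; even-sized arrays put the
beam centre between the two central pixels; a pnccd-like two-panel variant
adds a physical central gap between the row halves. Per pixel:
q = (2π/λ)(u − ẑ), Ω = area·cos θ/|p|², and the Thomson polarization factor
(horizontal: 1 − (u·x̂)²; unpolarized: (1 + cos² 2θ)/2; horizontal is the
default, the XFEL standard). Beam miscentering displaces the direct-beam
position by independent per-axis Gaussians and re-derives the q map — a
one-pixel offset shifts the map by exactly one pixel index.

Auto-ranging digitisation (ePix10k/Jungfrau-style): three gain ranges with
relative gains 100 : 100/6.7 : 1 ADU/keV, 16384-ADU full well, switching at
80 % of each range; each pixel selects the finest range whose threshold its
deposited energy does not exceed; energies beyond the coarsest range clamp
at full well and are flagged saturated. These defaults are plausible
placeholders, not a calibration of any real detector. Dark noise is added
in ADU after digitisation — either a randomly chosen user-supplied
pedestal-subtracted dark frame or per-pixel Gaussian noise. The static
background (photons) is added *before* Poisson quantisation, so it is
Poisson-sampled along with the signal, as a physical parasitic-scattering
source would be.

## Diffraction volume and slicing

The |F|² volume spans [−q_max, q_max]³ with q_max = 1.02 × the detector's
maximum |q| (widened by 5 × the bandwidth fraction for SASE runs). The
default grid size places `oversampling` (default 4) voxels per Shannon
interval π/D of the particle's intensity autocorrelation (D = bounding
diameter including solvent). This particle-based sizing keeps trilinear
slicing error below 1 % relative RMS — verified against direct summation —
at bounded memory; sizing the grid from the detector pixel count alone would
demand gigabyte-scale volumes on megapixel detectors without improving
accuracy for compact particles. Out-of-volume pixels are masked, never
extrapolated.

Orientation convention, fixed package-wide: the stored unit quaternion
(w, x, y, z) rotates the **particle**; a pattern therefore samples the volume
at Rᵀq_pixel, and the multi-particle direct-summation path applies the same
convention with phase factors exp(i q·d). Ground truth plus this stated
convention reproduces any pattern bitwise. Orientations are uniform over
SO(3) (Shoemake construction); q and −q act identically.

Coherent multi-particle sums require complex amplitudes, which a |F|² volume
cannot supply, so they use per-particle direct summation at the pixel
q-vectors. This is exact but scales with the per-shot atom count; a
complex-amplitude volume variant would trade memory for speed at large
particle counts and is a known extension, not implemented.

## Experiments, noise order, reproducibility

Per shot: sample states, orientations and positions → draw jittered fluence
→ draw the spectrum → (miscenter the geometry) → slice/sum per spectral
sample into an expected-photon map → add static background → Poisson draw →
digitise → add dark noise. Disabling every source reduces the pipeline to
the pure ideal-intensity path bitwise. All randomness of shot i comes from
`SeedSequence([seed, i])`, so any shot is reproducible independently of
execution order, and identical configurations produce byte-identical HDF5
files (datasets are written with `track_times=False`).

SPI positional displacement is recorded as ground truth but does not alter
the recorded intensity (the pattern of a single particle is
translation-invariant; distance-dependent solid-angle changes over a
sub-micron interaction volume are orders of magnitude below the other noise
sources). For FXS and FTH the relative positions enter the coherent phases
exactly. The FTH reference sits at a fixed in-plane offset from the target,
default 2.5 × the summed diameters. The FXS per-shot particle count is fixed
or Poisson with a configured mean (clipped to ≥ 1); real counts depend on
injector concentration, which is not modelled.

## Fourier shell correlation

FSC(k) = Re(Σ F₁F₂*) / sqrt(Σ|F₁|² Σ|F₂|²) per shell of integer-frequency
width; the real part is taken in the numerator (the raw ratio is complex for
finite shells; the real part is the community convention). With the default
shell count the zeroth shell holds only the DC term. Resolution is the
linearly interpolated first crossing below the threshold (default 0.5); a
curve that never crosses reports infinity ("beyond Nyquist"), and a curve
already below threshold at low frequency is rejected as a flag that the maps
disagree globally. No masking or apodization is applied.

## What the synthetic data do and do not show

The toy fixtures (two-atom pairs, hollow shells, uniform solvent balls,
random coils, FCC gold spheres) exercise every code path against closed-form
or brute-force oracles, and the default study conditions (4 keV photons,
10¹³ photons/pulse, 0.1 µm focus, 10 % jitter, 10⁻³ SASE bandwidth,
pixel-scale miscentering) produce the sparse sub-photon-per-pixel patterns
characteristic of real SPI. Passing tests demonstrate the correctness of the
scattering mathematics, the noise statistics and the reproducibility
contracts on these conditions. They do not demonstrate fidelity to any
specific facility: detector gain values are placeholders, no
radiation damage, charge sharing, incoherent scattering or detector
point-spread is modelled, and hydration defaults are literature bulk values
rather than fits. Problem sizes in the tests (≤ 200-scatterer oracles,
64–256-pixel detectors, 100-shot productions, 10⁴–10⁵-draw Monte Carlo) were
chosen as the smallest sizes at which the statistical assertions have
conventional 3σ power.

## Numerical notes

* Direct summation is chunked (4096 q-points) to bound peak memory; BLAS
  batch-shape differences make equal values differ in the last bit between
  batch sizes, so bitwise comparisons are only meaningful at equal shapes.
* ANM eigenvalues are clipped at zero (the null space produces ~−10⁻¹⁴
  numerical negatives).
* The empty-bin convention is NaN in radial profiles; FSC raises on empty
  shells instead, since a shell with no voxels means the shell count is
  wrong.
* Gold nanoparticles below half a lattice cell in radius are rejected rather
  than returning a bare handful of atoms.
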