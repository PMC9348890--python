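"""Physical constants shared across the package.

Unit conventions, fixed once for every module:

* lengths in real space: angstrom (Å) unless a variable is suffixed ``_m``;
* reciprocal space: the physics convention ``q = k_out - k_in`` with
  ``|k| = 2*pi/lambda``, so ``|q| = 4*pi*sin(theta)/lambda`` in Å⁻¹ and the
  resolution of a reflection is ``d = 2*pi/|q|``;
* detector geometry (pixel pitch, distance, beam offsets, focus): metres;
* photon energies: eV (keV only inside the gain/digitisation code);
* form factors and structure factors: electrons.
"""

#: hc in eV·Å — converts photon energy to wavelength, lambda = HC_EV_A / E.
HC_EV_A = 12398.42

#: Classical electron radius in metres (Thomson scattering length).
R_ELECTRON_M = 2.8179403e-15

#: Bulk water electron density in e·Å⁻³ (hydration-layer default).
WATER_DENSITY_E_A3 = 0.334
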