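"""Förster theory on a B-DNA helix: efficiency vs base-pair separation.

Rigid internal labelling means dye separation *and* dipole orientation are
set by the helix geometry (0.34 nm rise, 36 deg twist per bp).  The script
computes the Förster radius for a synthetic donor/acceptor spectral pair,
then fits the helix dipole geometry (radial offset, tilt, azimuthal
disorder) to measured signal-rise efficiencies and prints the predicted
curve, alongside the hypothetical freely rotating (kappa^2 = 2/3) dye limit.
"""

import numpy as np

import ixflim

# Förster radius from a synthetic overlap (Gaussian spectra, n = 1.33)
lam = np.linspace(500.0, 700.0, 801)
ctx = ixflim.ForsterContext(
    wavelength_grid=lam,
    acceptor_absorption=250_000.0 * np.exp(-0.5 * ((lam - 650) / 20.0) ** 2),
    donor_emission=np.exp(-0.5 * ((lam - 600) / 18.0) ** 2),
    refractive_index=1.33)
r0 = ixflim.forster_radius(ctx)
print(f"Förster radius of the synthetic pair: R0 = {r0:.2f} nm "
      f"(E = 0.5 at that distance)")

# helix-geometry fit to measured rise efficiencies (bp, E, sigma)
measured = [(4, 0.91, 0.07), (12, 0.81, 0.03), (13, 0.73, 0.05),
            (20, 0.68, 0.06)]
model = ixflim.HelixModel(mc_samples=20_000)
fitted, info = ixflim.fit_helix_model(
    measured, model, r0_nm=7.1,
    free_parameters=("dipole_radial_offset", "dipole_tilt",
                     "helical_angle_sigma"))
print("fitted geometry: "
      f"radial offset {fitted.dipole_radial_offset:.2f} nm, "
      f"tilt {fitted.dipole_tilt:.0f} deg, "
      f"azimuthal disorder {fitted.helical_angle_sigma:.0f} deg")

bps = [4, 8, 12, 13, 16, 20]
helix_curve = ixflim.helix_fret_curve(fitted, 7.1, bps)
iso_curve = [ixflim.efficiency_from_distance(bp * 0.34, 7.1) for bp in bps]
print(" bp   helix-E   isotropic-E")
for bp, eh, ei in zip(bps, helix_curve, iso_curve):
    print(f"{bp:3d}    {eh:.2f}      {ei:.2f}")
print("Deviations of the helix curve from the isotropic one are pure "
      "orientation effects: at 20 bp (two full turns) the dipoles realign "
      "and transfer is enhanced relative to intermediate separations.")
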