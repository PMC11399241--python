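"""Simulate a two-capillary dye sample and image it by mean lifetime and
mean excitation wavelength.

One capillary holds free dye (90 ps, excitation peaking at 595 nm), the
other protein-bound dye (0.5 ns / 620 nm and 1.5 ns / 632 nm).  After the
Fourier reconstruction, the two regions separate cleanly in *both* derived
images: lifetime contrast (0.1 ns vs ~1 ns) and spectral contrast
(~600 nm vs ~626 nm centre of mass), without any model fitting.
"""

import numpy as np

import ixflim

scene, laser, truth = ixflim.make_fixture(
    "oxonol_capillaries", {"shape": (32, 32), "n_delays": 64})
t_axis = ixflim.default_t_axis()
irf = ixflim.default_irf()

stack = ixflim.simulate_stack(scene, laser, t_axis, irf,
                              photon_budget=1e6, seed=1)
print(f"simulated stack: {stack.counts.shape} [tau, t, y, x], "
      f"{stack.counts.sum():,} photons")

cube = ixflim.reconstruct(stack, mask_threshold=0.05, normalize=False)
print(f"hypercube: {cube.values.shape} [lambda, t, y, x], "
      f"{cube.valid_mask.sum()} valid wavelengths")

tau_img = ixflim.moment_image(cube, "mean_lifetime", t0=irf.t0,
                              threshold=0.05)
lam_img = ixflim.moment_image(cube, "mean_wavelength",
                              wavelength_range=(540.0, 690.0),
                              threshold=0.05)
for name, rois in [("free", truth["rois"]["free"]),
                   ("bound", truth["rois"]["bound"])]:
    tau_med = np.nanmedian(tau_img.values[rois])
    lam_med = np.nanmedian(lam_img.values[rois])
    print(f"{name:>5} capillary: mean lifetime {tau_med:.3f} ns, "
          f"mean excitation wavelength {lam_med:.1f} nm")
print("The bound region shows the longer lifetime and red-shifted "
      "excitation expected from protein binding; dark pixels are NaN.")
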