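"""Decompose a transient excitation map into decay-associated spectra.

The bound-dye capillary hosts two binding sites with different lifetimes
and slightly shifted excitation spectra.  Global analysis fits all
wavelengths simultaneously with shared rates (variable projection), and
the information criterion confirms that exactly two components are needed.
"""

import numpy as np

import ixflim

scene, laser, truth = ixflim.make_fixture(
    "oxonol_capillaries", {"shape": (32, 32), "n_delays": 64})
irf = ixflim.default_irf()
stack = ixflim.simulate_stack(scene, laser, ixflim.default_t_axis(), irf,
                              1e6, seed=2)
cube = ixflim.reconstruct(stack, normalize=False)
tmap = ixflim.roi_transient_map(cube, truth["rois"]["bound"])

selection = ixflim.select_n_components(tmap, n_max=3, irf=irf, seed=0)
print(f"components chosen by BIC: {selection.chosen_n} (truth: 2)")

fit = selection.best
for tau, err, spec in zip(fit.lifetimes, fit.lifetime_stderr, fit.spectra):
    peak = fit.lambda_axis[np.argmax(spec)]
    print(f"  lifetime {1e3 * tau:6.0f} +/- {1e3 * err:.0f} ps, "
          f"spectrum peaking near {peak:.0f} nm")
print("Ground truth: 500 ps @ 620 nm and 1500 ps @ 632 nm -- the two "
      "binding sites are separated by lifetime even though their spectra "
      "overlap within the spectral resolution of the short delay scan.")
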