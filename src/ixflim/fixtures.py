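"""Scene presets emulating the three published demonstration samples.

* ``oxonol_capillaries`` — two adjacent microcapillaries: one filled with
  free Oxonol VI (single 90 ps species, excitation peaking at 595 nm), the
  other with albumin-bound Oxonol VI (two binding sites: 0.5 ns at 620 nm
  and 1.5 ns at 632 nm).
* ``cy3cy5_beads`` — streptavidin beads carrying doubly labelled dsDNA with
  a Cy3 donor and Cy5 acceptor at a fixed base-pair separation, detected in
  the acceptor channel (donor lifetime 0.75 ns, acceptor 1.34 ns; the
  transfer rate is set by the per-separation target efficiency).  ``bp``
  may be a list to lay out a bead mixture.
* ``npm_nucleus`` — a cell nucleus with a brighter nucleolus, containing
  free mVenus donor (2.9 ns), mRFP1 acceptor (1.5 ns), and a bound
  donor-acceptor fraction with a 0.18 ns donor-fed rise; the bound-donor
  amplitude (relative to the acceptor) is twice as large in the nucleolus
  as in the nucleoplasm.

Every preset returns the scene, the matching broadband laser, and a
machine-readable ground-truth record for assertions.  Defaults mirror a
full acquisition (256 x 256 pixels, 301 delay steps of 0.75 fs, 50 ps
Gaussian IRF); tests and the acceptance runs pass overrides for reduced
problem sizes (32 x 32, 64 delays).
"""

from __future__ import annotations

import numpy as np

from .kernels import Irf
from .simulate import FretScheme, LaserField, Scene, Species, gaussian_band

__all__ = ["PRESETS", "make_fixture", "default_t_axis", "default_irf",
           "TABLE_RISE_EFFICIENCY", "RISE_PER_BP_NM"]

#: measured signal-rise FRET efficiencies per base-pair separation; used as
#: the simulation ground truth of the bead scenes
TABLE_RISE_EFFICIENCY = {4: 0.91, 12: 0.81, 13: 0.73, 20: 0.68}

#: B-DNA axial rise per base pair in nm
RISE_PER_BP_NM = 0.34

#: donor (Cy3) and acceptor (Cy5-on-bead) lifetimes in ns
CY3_LIFETIME_NS = 0.75
CY5_LIFETIME_NS = 1.34

PRESETS = ("oxonol_capillaries", "cy3cy5_beads", "npm_nucleus")


def default_t_axis(n_bins: int = 512, window_ns: float = 10.0) -> np.ndarray:
    """TCSPC time axis: left bin edges in ns."""
    return np.arange(n_bins) * (window_ns / n_bins)


def default_irf() -> Irf:
    return Irf(fwhm=50.0, t0=0.5)


def _rect(shape, row_frac, col_frac=(0.1, 0.9)) -> np.ndarray:
    ny, nx = shape
    m = np.zeros(shape)
    r0, r1 = int(row_frac[0] * ny), int(row_frac[1] * ny)
    c0, c1 = int(col_frac[0] * nx), int(col_frac[1] * nx)
    m[r0:r1, c0:c1] = 1.0
    return m


def _disk(shape, center_frac, radius_frac) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = center_frac[0] * ny, center_frac[1] * nx
    r = radius_frac * min(ny, nx)
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(float)


def _oxonol(shape, laser: LaserField):
    grid = laser.wavelength_grid
    free = Species("oxo_free", gaussian_band(grid, 595.0, 45.0),
                   decay_rate=1.0 / 0.090)
    bound1 = Species("oxo_bound_site1", gaussian_band(grid, 620.0, 45.0),
                     decay_rate=1.0 / 0.5)
    bound2 = Species("oxo_bound_site2", gaussian_band(grid, 632.0, 45.0),
                     decay_rate=1.0 / 1.5)
    free_map = _rect(shape, (0.58, 0.86))
    bound_map = _rect(shape, (0.14, 0.42))
    scene = Scene(shape, [(free, free_map), (bound1, bound_map),
                          (bound2, bound_map)])
    rois = {"free": free_map > 0, "bound": bound_map > 0}
    truth = {
        "species": [
            {"name": "oxo_free", "lifetime_ns": 0.090, "peak_nm": 595.0,
             "region": "free"},
            {"name": "oxo_bound_site1", "lifetime_ns": 0.5, "peak_nm": 620.0,
             "region": "bound"},
            {"name": "oxo_bound_site2", "lifetime_ns": 1.5, "peak_nm": 632.0,
             "region": "bound"},
        ],
        "rois": rois,
    }
    return scene, truth


def _cy3cy5(shape, laser: LaserField, bp):
    grid = laser.wavelength_grid
    bp_list = [int(b) for b in (bp if isinstance(bp, (list, tuple)) else [bp])]
    k_d = 1.0 / CY3_LIFETIME_NS
    components = []
    rois = {}
    truth_pairs = []
    # beads laid out on a coarse grid, cycling through the requested
    # separations
    ny, nx = shape
    n_side = max(1, int(np.ceil(np.sqrt(len(bp_list) * 2))))
    centers = [((i + 0.5) / n_side, (j + 0.5) / n_side)
               for i in range(n_side) for j in range(n_side)]
    radius = 0.5 / n_side * 0.6
    for idx, bp_i in enumerate(bp_list * ((len(centers) // len(bp_list)) or 1)):
        if idx >= len(centers):
            break
        e_target = TABLE_RISE_EFFICIENCY[bp_i]
        k_t = k_d * e_target / (1.0 - e_target)
        donor = Species("cy3", gaussian_band(grid, 550.0, 40.0),
                        decay_rate=k_d, quantum_yield=0.25,
                        detection_efficiency=0.0)  # 700 nm-filtered channel
        acceptor = Species("cy5", gaussian_band(grid, 650.0, 45.0),
                           decay_rate=1.0 / CY5_LIFETIME_NS,
                           quantum_yield=0.25, detection_efficiency=1.0)
        scheme = FretScheme(donor=donor, acceptor=acceptor, transfer_rate=k_t,
                            c_acceptor=1.0, c_donor_bound=1.0,
                            c_donor_free=0.0)
        bead = _disk(shape, centers[idx], radius)
        components.append((scheme, bead))
        rois.setdefault(f"bp{bp_i:02d}", np.zeros(shape, dtype=bool))
        rois[f"bp{bp_i:02d}"] |= bead > 0
        truth_pairs.append({
            "bp": bp_i,
            "efficiency": e_target,
            "transfer_rate_ns": k_t,
            "rise_time_ns": 1.0 / (k_t + k_d),
            "donor_lifetime_ns": CY3_LIFETIME_NS,
            "acceptor_lifetime_ns": CY5_LIFETIME_NS,
            "axial_separation_nm": round(bp_i * RISE_PER_BP_NM, 3),
        })
    scene = Scene(shape, components)
    truth = {"pairs": truth_pairs, "rois": rois,
             "donor_peak_nm": 550.0, "acceptor_peak_nm": 650.0}
    return scene, truth


def _npm(shape, laser: LaserField):
    grid = laser.wavelength_grid
    tau_d, tau_a, tau_rise = 2.9, 1.5, 0.18
    k_d, k_a = 1.0 / tau_d, 1.0 / tau_a
    k_t = 1.0 / tau_rise - k_d
    donor = Species("mVenus", gaussian_band(grid, 515.0, 40.0),
                    decay_rate=k_d, quantum_yield=0.64,
                    detection_efficiency=0.1)
    acceptor = Species("mRFP1", gaussian_band(grid, 585.0, 40.0),
                       decay_rate=k_a, quantum_yield=0.25,
                       detection_efficiency=1.0)
    # nucleoplasm: ellipse; nucleolus: brighter disk with twice the bound
    # donor fraction (relative to the acceptor component)
    nucleus = _disk(shape, (0.5, 0.5), 0.42)
    nucleolus = _disk(shape, (0.42, 0.58), 0.15)
    nucleoplasm = np.clip(nucleus - nucleolus, 0.0, 1.0)
    plasm = FretScheme(donor, acceptor, transfer_rate=k_t, c_acceptor=1.0,
                       c_donor_bound=0.5, c_donor_free=2.0)
    olus = FretScheme(donor, acceptor, transfer_rate=k_t, c_acceptor=2.0,
                      c_donor_bound=2.0, c_donor_free=4.0)
    scene = Scene(shape, [(plasm, nucleoplasm), (olus, nucleolus)])
    rois = {"nucleolus": nucleolus > 0, "nucleoplasm": nucleoplasm > 0,
            "nucleus": nucleus > 0}
    bound_ratio = (olus.c_donor_bound / olus.c_acceptor) / \
        (plasm.c_donor_bound / plasm.c_acceptor)
    truth = {
        "lifetimes_ns": [tau_rise, tau_a, tau_d],
        "transfer_rate_ns": k_t,
        "efficiency": k_t / (k_t + k_d),
        "donor_peak_nm": 515.0,
        "acceptor_peak_nm": 585.0,
        "bound_donor_amplitude_ratio": bound_ratio,
        "rois": rois,
    }
    return scene, truth


_LASER_DEFAULTS = {
    "oxonol_capillaries": dict(center=610.0, fwhm=120.0, lam_min=520.0,
                               lam_max=700.0),
    "cy3cy5_beads": dict(center=590.0, fwhm=160.0, lam_min=480.0,
                         lam_max=700.0),
    "npm_nucleus": dict(center=560.0, fwhm=140.0, lam_min=460.0,
                        lam_max=660.0),
}


def make_fixture(preset: str, overrides: dict | None = None, seed: int = 0
                 ) -> tuple[Scene, LaserField, dict]:
    """Build a preset scene with its laser and ground-truth record.

    ``overrides`` may set ``shape``, ``n_delays``, ``delay_step``,
    ``visibility``, ``delay_offset``, ``lam_step`` and, for the bead
    preset, ``bp`` (an int or list of base-pair separations).  The
    ground-truth dict lists every rate, spectral peak and concentration
    used, plus boolean ROI masks per region.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    ov = dict(overrides or {})
    shape = tuple(ov.pop("shape", (256, 256)))
    laser_kw = dict(_LASER_DEFAULTS[preset])
    laser_kw["lam_step"] = ov.pop("lam_step", 2.0)
    laser = LaserField.gaussian(
        laser_kw.pop("center"), laser_kw.pop("fwhm"),
        laser_kw.pop("lam_min"), laser_kw.pop("lam_max"),
        lam_step=laser_kw.pop("lam_step"),
        n_delays=int(ov.pop("n_delays", 301)),
        delay_step=float(ov.pop("delay_step", 0.75)),
        visibility=float(ov.pop("visibility", 1.0)),
        delay_offset=float(ov.pop("delay_offset", 0.0)))
    if preset == "oxonol_capillaries":
        scene, truth = _oxonol(shape, laser)
    elif preset == "cy3cy5_beads":
        scene, truth = _cy3cy5(shape, laser, ov.pop("bp", 20))
    else:
        scene, truth = _npm(shape, laser)
    if ov:
        raise ValueError(f"unknown overrides: {sorted(ov)}")
    truth.update({"preset": preset, "seed": int(seed),
                  "shape": list(shape)})
    return scene, laser, truth
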