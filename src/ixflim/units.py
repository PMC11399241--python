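"""Unit conventions and converters.

The package uses a fixed internal unit system:

* wavelengths ``lambda`` in nanometres (nm),
* optical (angular) frequencies ``omega`` in rad/fs,
* interferometer delays ``tau`` in femtoseconds (fs),
* TCSPC arrival times ``t`` in nanoseconds (ns),
* kinetic rates ``k`` in ns^-1,
* instrument-response widths in picoseconds (ps).

With these choices the vacuum speed of light is ``C_NM_PER_FS`` and the
optical frequency of light of wavelength ``lam`` nm is
``omega = 2 pi C_NM_PER_FS / lam`` rad/fs, e.g. ~3.14 rad/fs at 600 nm.
"""

from __future__ import annotations

import numpy as np

#: speed of light in nm/fs (= m/s * 1e-6)
C_NM_PER_FS: float = 299.792458

#: conversion factor FWHM -> Gaussian sigma
FWHM_TO_SIGMA: float = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def omega_from_wavelength(lam_nm):
    """Angular frequency (rad/fs) of light with vacuum wavelength ``lam_nm``."""
    lam_nm = np.asarray(lam_nm, dtype=float)
    return 2.0 * np.pi * C_NM_PER_FS / lam_nm


def wavelength_from_omega(omega_rad_fs):
    """Vacuum wavelength (nm) for angular frequency ``omega_rad_fs`` (rad/fs)."""
    omega_rad_fs = np.asarray(omega_rad_fs, dtype=float)
    return 2.0 * np.pi * C_NM_PER_FS / omega_rad_fs


def ps_to_ns(t_ps):
    return np.asarray(t_ps, dtype=float) * 1e-3


def ns_to_ps(t_ns):
    return np.asarray(t_ns, dtype=float) * 1e3


def fwhm_ps_to_sigma_ns(fwhm_ps: float) -> float:
    """Gaussian sigma in ns for an IRF full width at half maximum in ps."""
    return float(fwhm_ps) * 1e-3 * FWHM_TO_SIGMA
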