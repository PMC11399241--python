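"""Quantitative FRET from ixFLIM data, and Förster theory.

Three complementary estimators of the transfer efficiency
``E = kT / (kT + kD)`` are implemented:

* **rise time** — in acceptor-detected data the donor band rises with rate
  ``kT + kD``, so ``E = 1 - tau_rise / tau_D`` once the free-donor lifetime
  is known;
* **spectral decomposition** — the time-integrated excitation spectrum is
  ``phi_A eta_A c_A {eps_A + eps_D E}`` for equal donor/acceptor
  concentrations, so a linear fit of the donor and acceptor reference
  spectra yields ``E`` as the donor/acceptor weight ratio, with an optional
  correction for donor emission leaking through the detection filter;
* **donor quench** — the classical ``E = 1 - tau_DA / tau_D`` from the
  shortening of the donor lifetime in presence of the acceptor.

Förster theory ties ``E`` to the donor-acceptor distance through the
Förster radius ``R0`` (overlap integral, orientation factor kappa,
refractive index); the helix submodule places dye dipoles on a B-DNA
geometry with orientational disorder to predict ``E`` versus base-pair
separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .helix import HelixModel, fit_helix_model, helix_fret_curve

__all__ = [
    "EfficiencyResult",
    "ForsterContext",
    "HelixModel",
    "efficiency_from_rise",
    "efficiency_from_spectrum",
    "efficiency_map",
    "kappa_bracket",
    "forster_radius",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "transfer_rate",
    "efficiency_from_donor_quench",
    "helix_fret_curve",
    "fit_helix_model",
]


@dataclass
class EfficiencyResult:
    """A FRET efficiency estimate.

    ``efficiency`` is clipped to [0, 1]; ``raw_efficiency`` retains the
    pre-clip value (a negative value signals no transfer, or a mis-assigned
    component).  ``stderr`` is the first-order propagated uncertainty and
    ``auxiliaries`` the fitted weights/rates behind the estimate.
    """

    efficiency: float
    raw_efficiency: float
    method: str
    stderr: float = np.nan
    auxiliaries: dict = field(default_factory=dict)


def efficiency_from_rise(tau_rise: float, tau_donor: float,
                         tau_rise_err: float = 0.0,
                         tau_donor_err: float = 0.0) -> EfficiencyResult:
    """Efficiency from the acceptor-detected signal rise time.

    The donor-band signal rises with ``kT + kD = 1/tau_rise``; with the
    independently known donor lifetime ``tau_D = 1/kD``,

        E = 1 - kD / (kT + kD) = 1 - tau_rise / tau_D.

    Uncertainties are propagated to first order.  A rise time exceeding the
    donor lifetime yields a negative raw efficiency with a warning.
    """
    if not (tau_rise > 0 and tau_donor > 0):
        raise ValueError("tau_rise and tau_donor must be positive")
    raw = 1.0 - tau_rise / tau_donor
    if raw < 0:
        warnings.warn(
            "rise time exceeds the donor lifetime: negative efficiency "
            "(no transfer, or mis-assigned component)", RuntimeWarning,
            stacklevel=2)
    stderr = np.hypot(tau_rise_err / tau_donor,
                      tau_rise * tau_donor_err / tau_donor**2)
    return EfficiencyResult(efficiency=float(np.clip(raw, 0.0, 1.0)),
                            raw_efficiency=float(raw), method="rise",
                            stderr=float(stderr),
                            auxiliaries={"tau_rise": tau_rise,
                                         "tau_donor": tau_donor})


def efficiency_from_donor_quench(donor_lifetime_with_acceptor: float,
                                 donor_lifetime_alone: float,
                                 err_with: float = 0.0,
                                 err_alone: float = 0.0) -> EfficiencyResult:
    """Classical donor-quench efficiency ``E = 1 - tau_DA / tau_D``.

    For multi-exponential donors the caller supplies amplitude-weighted
    mean lifetimes.
    """
    if not (donor_lifetime_with_acceptor > 0 and donor_lifetime_alone > 0):
        raise ValueError("lifetimes must be positive")
    raw = 1.0 - donor_lifetime_with_acceptor / donor_lifetime_alone
    if raw < 0:
        warnings.warn("donor lifetime longer with acceptor than alone: "
                      "negative efficiency", RuntimeWarning, stacklevel=2)
    stderr = np.hypot(err_with / donor_lifetime_alone,
                      donor_lifetime_with_acceptor * err_alone
                      / donor_lifetime_alone**2)
    return EfficiencyResult(efficiency=float(np.clip(raw, 0.0, 1.0)),
                            raw_efficiency=float(raw), method="donor_quench",
                            stderr=float(stderr),
                            auxiliaries={"tau_da": donor_lifetime_with_acceptor,
                                         "tau_d": donor_lifetime_alone})


def efficiency_from_spectrum(raw_spectrum: np.ndarray,
                             donor_reference: np.ndarray,
                             acceptor_reference: np.ndarray,
                             laser: np.ndarray,
                             leak_ratio: float = 0.0,
                             equal_concentrations: bool = True
                             ) -> EfficiencyResult:
    """Efficiency from a linear decomposition of the excitation spectrum.

    The *raw* (laser-weighted, non-normalized) time-integrated spectrum is
    fitted as ``w_A eps_A(lambda) Spec(lambda) + w_D eps_D(lambda)
    Spec(lambda)``; working on the raw product avoids amplifying noise at
    the laser-spectrum edges.  Under equal donor and acceptor
    concentrations the apparent efficiency is ``E_app = w_D / w_A``.  When
    a fraction of the donor emission leaks through the detection filter the
    donor weight becomes ``E + r (1 - E)`` with ``r = leak_ratio`` (the
    quantum-yield/detection factor multiplying the leak term), so the
    corrected value is ``E = (E_app - r) / (1 - r)``.
    """
    if leak_ratio < 0 or leak_ratio >= 1:
        raise ValueError("leak_ratio must lie in [0, 1)")
    y = np.asarray(raw_spectrum, dtype=float)
    basis = np.stack([np.asarray(acceptor_reference, dtype=float) * laser,
                      np.asarray(donor_reference, dtype=float) * laser], axis=1)
    if basis.shape[0] != y.size:
        raise ValueError("spectrum and references must share the wavelength grid")
    cond = np.linalg.cond(basis)
    if cond > 1e8:
        raise ValueError(
            "donor and acceptor references are collinear on this grid; the "
            "decomposition is not identifiable")
    coef, res, _, _ = np.linalg.lstsq(basis, y, rcond=None)
    w_a, w_d = float(coef[0]), float(coef[1])
    if w_a <= 0:
        warnings.warn("non-positive acceptor weight in the spectral fit",
                      RuntimeWarning, stacklevel=2)
    dof = max(y.size - 2, 1)
    rss = float(res[0]) if res.size else float(np.sum((y - basis @ coef) ** 2))
    cov = np.linalg.inv(basis.T @ basis) * rss / dof
    e_app = w_d / w_a if w_a != 0 else np.inf
    # var(w_D/w_A) to first order
    if w_a != 0:
        g = np.array([-w_d / w_a**2, 1.0 / w_a])
        e_app_err = float(np.sqrt(g @ cov @ g))
    else:
        e_app_err = np.nan
    raw_e = (e_app - leak_ratio) / (1.0 - leak_ratio)
    stderr = e_app_err / (1.0 - leak_ratio)
    if not equal_concentrations:
        warnings.warn(
            "unequal concentrations: returned value is c_D E / c_A, not E",
            RuntimeWarning, stacklevel=2)
    return EfficiencyResult(
        efficiency=float(np.clip(raw_e, 0.0, 1.0)), raw_efficiency=float(raw_e),
        method="spectral", stderr=float(stderr),
        auxiliaries={"w_acceptor": w_a, "w_donor": w_d,
                     "apparent_efficiency": float(e_app),
                     "leak_ratio": float(leak_ratio),
                     "residual_rss": rss})


def efficiency_map(ixfim: np.ndarray, lambda_axis: np.ndarray,
                   donor_band: tuple[float, float],
                   acceptor_band: tuple[float, float],
                   donor_reference: np.ndarray,
                   acceptor_reference: np.ndarray,
                   threshold: float = 0.05):
    """Per-pixel FRET efficiency image from band-integrated spectra.

    Integrates the donor and acceptor spectral bands of the time-integrated
    excitation-spectrum image, unmixes the reference-spectrum cross-talk
    between the two bands with a 2x2 matrix of reference band integrals,
    and reports ``E = w_D / w_A`` per pixel (clipped to [0, 1]).  Pixels
    below ``threshold`` times the maximum integrated intensity are
    undefined (NaN).

    Returns a :class:`~ixflim.reconstruct.MomentImage`-like object with
    ``kind="fret_efficiency"``.
    """
    from .reconstruct import MomentImage

    lam = np.asarray(lambda_axis, dtype=float)
    d_lo, d_hi = donor_band
    a_lo, a_hi = acceptor_band
    if not (d_hi <= a_lo or a_hi <= d_lo):
        raise ValueError("donor and acceptor bands must be disjoint")
    if d_lo < lam[0] or a_hi > lam[-1] or a_lo < lam[0] or d_hi > lam[-1]:
        raise ValueError("bands must lie inside the wavelength axis")
    sel_d = (lam >= d_lo) & (lam <= d_hi)
    sel_a = (lam >= a_lo) & (lam <= a_hi)
    eps_d = np.asarray(donor_reference, dtype=float)
    eps_a = np.asarray(acceptor_reference, dtype=float)
    # rows: (acceptor band, donor band); columns: (eps_A, eps_D)
    mix = np.array([
        [np.trapezoid(eps_a[sel_a], lam[sel_a]), np.trapezoid(eps_d[sel_a], lam[sel_a])],
        [np.trapezoid(eps_a[sel_d], lam[sel_d]), np.trapezoid(eps_d[sel_d], lam[sel_d])],
    ])
    if abs(np.linalg.det(mix)) < 1e-12 * np.abs(mix).max() ** 2:
        raise ValueError("singular band-unmixing matrix: bands do not "
                         "separate the reference spectra")
    i_a = np.trapezoid(ixfim[sel_a], lam[sel_a], axis=0)
    i_d = np.trapezoid(ixfim[sel_d], lam[sel_d], axis=0)
    w = np.linalg.solve(mix, np.stack([i_a.ravel(), i_d.ravel()]))
    w_a = w[0].reshape(i_a.shape)
    w_d = w[1].reshape(i_d.shape)
    intensity = i_a + i_d
    ok = intensity > threshold * intensity.max()
    values = np.full(intensity.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.clip(w_d / w_a, 0.0, 1.0)
    good = ok & np.isfinite(e)
    values[good] = e[good]
    return MomentImage(values=values, mask=good, kind="fret_efficiency")


def kappa_bracket(mu_a: np.ndarray, mu_d: np.ndarray,
                  r_hat: np.ndarray) -> float | np.ndarray:
    """Orientation factor ``mu_a . mu_d - 3 (mu_a . R)(mu_d . R)``.

    Its square is kappa^2 (isotropic average 2/3).  Inputs are expected
    unit-norm; non-unit vectors are normalized with a warning.  Accepts
    arrays of vectors in the last axis for vectorized Monte-Carlo use.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_d = np.asarray(mu_d, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    vecs = []
    for v in (mu_a, mu_d, r_hat):
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        if np.any(np.abs(norm - 1.0) > 1e-9):
            warnings.warn("non-unit vector passed to kappa_bracket; "
                          "normalizing", RuntimeWarning, stacklevel=2)
            v = v / norm
        vecs.append(v)
    mu_a, mu_d, r_hat = vecs
    out = (np.sum(mu_a * mu_d, axis=-1)
           - 3.0 * np.sum(mu_a * r_hat, axis=-1) * np.sum(mu_d * r_hat, axis=-1))
    return float(out) if out.ndim == 0 else out


@dataclass
class ForsterContext:
    """Inputs of the Förster-radius calculation.

    ``acceptor_absorption`` is the molar absorption spectrum in
    M^-1 cm^-1 on ``wavelength_grid`` (nm); ``donor_emission`` is
    normalized to unit area on the same grid.  ``orientation`` is either
    the string ``"isotropic"`` (kappa^2 = 2/3) or a (mu_a, mu_d, R_hat)
    triple of unit vectors.  The printed prefactor convention absorbs the
    donor quantum yield; pass ``donor_quantum_yield`` to include it as an
    explicit factor (default 1).
    """

    wavelength_grid: np.ndarray
    acceptor_absorption: np.ndarray
    donor_emission: np.ndarray
    refractive_index: float = 1.33
    donor_quantum_yield: float = 1.0
    orientation: object = "isotropic"

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelength_grid, dtype=float)
        fl = np.asarray(self.donor_emission, dtype=float)
        area = np.trapezoid(fl, lam)
        if area <= 0:
            raise ValueError("donor emission spectrum is empty")
        if abs(area - 1.0) > 1e-6:
            fl = fl / area
        self.wavelength_grid = lam
        self.donor_emission = fl
        self.acceptor_absorption = np.asarray(self.acceptor_absorption,
                                              dtype=float)
        if isinstance(self.orientation, str):
            if self.orientation != "isotropic":
                raise ValueError("orientation must be 'isotropic' or a "
                                 "(mu_a, mu_d, R_hat) triple")
        else:
            for v in self.orientation:
                if abs(np.linalg.norm(np.asarray(v, dtype=float)) - 1.0) > 1e-12:
                    raise ValueError("orientation vectors must be unit-norm")

    @property
    def kappa_squared(self) -> float:
        if isinstance(self.orientation, str):
            return 2.0 / 3.0
        mu_a, mu_d, r_hat = (np.asarray(v, dtype=float)
                             for v in self.orientation)
        return float(kappa_bracket(mu_a, mu_d, r_hat) ** 2)


def forster_radius(ctx: ForsterContext) -> float:
    """Förster radius in nm.

    ``R0^6 [Å^6] = 8.79e-5 kappa^2 n^-4 phi_D J`` with the overlap integral
    ``J = integral alpha_a(lambda) FL_d(lambda) lambda^4 d lambda`` in
    M^-1 cm^-1 nm^4 (trapezoid rule).  Non-overlapping spectra give
    ``R0 = 0`` with a warning.
    """
    lam = ctx.wavelength_grid
    overlap = np.trapezoid(ctx.acceptor_absorption * ctx.donor_emission
                           * lam**4, lam)
    if overlap <= 0:
        warnings.warn("donor emission and acceptor absorption do not "
                      "overlap; R0 = 0", RuntimeWarning, stacklevel=2)
        return 0.0
    r0_aa6 = (8.79e-5 * ctx.kappa_squared * ctx.refractive_index**-4
              * ctx.donor_quantum_yield * overlap)
    return float(r0_aa6 ** (1.0 / 6.0) / 10.0)  # Å -> nm


def efficiency_from_distance(distance: float, r0: float) -> float:
    """``E = kT/(kT + kD)`` with ``kT = kD (R0/R)^6``, i.e.
    ``E = 1 / (1 + (R/R0)^6)``; E = 1/2 at R = R0."""
    if not (distance > 0 and r0 > 0):
        raise ValueError("distance and r0 must be positive")
    return float(1.0 / (1.0 + (distance / r0) ** 6))


def distance_from_efficiency(efficiency: float, r0: float) -> float:
    """Invert the efficiency-distance relation:
    ``R = R0 ((1 - E) / E)^(1/6)``; undefined at E = 0 or 1."""
    if not r0 > 0:
        raise ValueError("r0 must be positive")
    if not 0.0 < efficiency < 1.0:
        raise ValueError("distance is defined only for 0 < E < 1")
    return float(r0 * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0))


def transfer_rate(k_d: float, r0: float, distance: float) -> float:
    """Förster transfer rate ``kT = kD (R0/R)^6`` in ns^-1."""
    if not (k_d > 0 and r0 > 0 and distance > 0):
        raise ValueError("k_d, r0 and distance must be positive")
    return float(k_d * (r0 / distance) ** 6)
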