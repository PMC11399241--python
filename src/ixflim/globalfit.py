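"""Global multi-exponential analysis of transient excitation maps.

A transient map ``S(t, lambda_tau)`` is decomposed into decay-associated
spectra (DAS),

    S(t, lambda) = sum_i S_i(lambda) exp(-k_i t) (x) irf(t),

with a shared Gaussian IRF.  The fit is separable: for fixed rates the
spectra ``S_i(lambda)`` enter linearly and are solved per wavelength by
weighted least squares (variable projection); only the (few) rates are
iterated nonlinearly, parameterized by their logarithm to keep them
positive.  Spectra are unconstrained in sign, so a delayed signal rise —
the fingerprint of energy transfer feeding the emitting state — appears as
a component with negative amplitude.

Model selection fits an increasing number of components and picks the
smallest model after which the Bayesian information criterion stops
improving; an F-test alternative is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .kernels import Irf, exp_gauss_kernel
from .reconstruct import TransientMap

__all__ = ["DasFit", "ModelSelection", "exp_gauss_kernel", "fit_global",
           "select_n_components"]

#: components whose lifetimes differ by less than this fraction and whose
#: spectra are proportional are merged after convergence
_MERGE_RTOL = 0.05


@dataclass
class DasFit:
    """Result of a global multi-exponential fit.

    ``rates`` (ns^-1) are sorted descending (fastest component first) with
    ``spectra[i]`` the decay-associated spectrum of ``rates[i]`` on
    ``lambda_axis`` (may be negative: rise component).  ``rate_stderr``
    contains first-order uncertainty estimates from the Jacobian at the
    optimum; ``chi2_reduced`` is the weighted residual sum of squares per
    degree of freedom.
    """

    rates: np.ndarray
    spectra: np.ndarray
    lambda_axis: np.ndarray
    irf: Irf
    residual_norm: float
    chi2_reduced: float
    rate_stderr: np.ndarray
    covariance: np.ndarray
    n_data: int
    success: bool
    message: str = ""
    merged: bool = False

    @property
    def lifetimes(self) -> np.ndarray:
        return 1.0 / self.rates

    @property
    def lifetime_stderr(self) -> np.ndarray:
        return self.rate_stderr / self.rates**2

    @property
    def n_components(self) -> int:
        return self.rates.size

    @property
    def n_parameters(self) -> int:
        return self.rates.size * (1 + self.spectra.shape[1])


@dataclass
class ModelSelection:
    """Candidate fits for n = 1..n_max and the chosen component count."""

    fits: list = field(default_factory=list)
    criterion: str = "bic"
    criterion_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    chosen_n: int = 1

    @property
    def best(self) -> DasFit:
        return self.fits[self.chosen_n - 1]


def _map_data_weights(tmap: TransientMap, weights: str):
    """Valid-wavelength data block and per-bin inverse standard deviations.

    ``weights="poisson"`` assumes raw photon counts per bin (variance =
    max(counts, 1)); ``"propagated"`` uses the per-bin variance carried by
    Fourier-reconstructed maps (Poisson noise pushed through the linear
    transform); ``"none"`` assumes homoscedastic noise.  ``"auto"``
    prefers the propagated variance when present, Poisson for maps
    flagged as raw counts, unit weights otherwise.
    """
    data = np.asarray(tmap.values, dtype=float)[tmap.valid_mask]
    if weights == "auto":
        if tmap.variance is not None:
            weights = "propagated"
        elif tmap.roi.get("raw_counts", False):
            weights = "poisson"
        else:
            weights = "none"
    if weights == "poisson":
        w = 1.0 / np.sqrt(np.maximum(data, 1.0))
    elif weights == "propagated":
        if tmap.variance is None:
            raise ValueError("map carries no propagated variance")
        var = np.asarray(tmap.variance, dtype=float)[tmap.valid_mask]
        floor = max(var.max() * 1e-12, np.finfo(float).tiny)
        w = 1.0 / np.sqrt(np.maximum(var, floor))
    elif weights == "none":
        w = np.ones_like(data)
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    return data, w


def _solve_spectra(data: np.ndarray, w: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-wavelength weighted linear solve of the spectra.

    ``data``/``w`` have shape (n_lambda, n_t); ``c`` is the (n_t, n_comp)
    kernel matrix.  Returns spectra of shape (n_lambda, n_comp).
    """
    w2 = w * w
    a = np.einsum("ti,lt,tj->lij", c, w2, c)
    b = np.einsum("ti,lt,lt->li", c, w2, data)
    try:
        return np.linalg.solve(a, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        # rank-deficient kernel (e.g. two rates collapsed): fall back to the
        # minimum-norm solution per wavelength
        warnings.warn("rank-deficient linear step in variable projection; "
                      "using pseudo-inverse", RuntimeWarning, stacklevel=2)
        return np.stack([np.linalg.lstsq(a[i], b[i], rcond=None)[0]
                         for i in range(a.shape[0])])


def _residuals(log_rates: np.ndarray, data, w, irf, t_axis):
    rates = np.exp(log_rates)
    c = np.stack([exp_gauss_kernel(k, irf, t_axis) for k in rates], axis=1)
    s = _solve_spectra(data, w, c)
    model = s @ c.T
    return ((data - model) * w).ravel()


def _initial_rate_sets(t_axis: np.ndarray, n: int, n_starts: int,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Log-spaced initial rates between the bin rate and the window rate,
    plus seeded log-normal perturbations for the multi-start."""
    t_bin = float(t_axis[1] - t_axis[0])
    window = float(t_axis[-1] - t_axis[0])
    k_hi = 1.0 / max(t_bin, 1e-6)
    k_lo = 1.0 / window
    base = np.geomspace(k_lo * 3.0, k_hi / 3.0, n + 2)[1:-1] if n > 1 else \
        np.array([np.sqrt(k_lo * k_hi)])
    sets = [base]
    for _ in range(n_starts - 1):
        sets.append(np.clip(base * np.exp(rng.normal(0.0, 0.8, size=n)),
                            k_lo / 10.0, k_hi * 10.0))
    return sets


def fit_global(tmap: TransientMap, n_components: int, irf: Irf,
               init_rates: np.ndarray | None = None,
               weights: str = "auto", n_starts: int = 8,
               seed: int = 0) -> DasFit:
    """Fit ``n_components`` IRF-convolved exponentials to a transient map.

    Variable-projection least squares: the nonlinear search runs over the
    log rates only, the spectra being re-solved linearly (sign-free) at
    every step.  Without ``init_rates`` a multi-start over log-spaced and
    seeded randomized rate sets is used and the best converged candidate
    kept; the procedure is deterministic for a given (map, init, seed).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    data, w = _map_data_weights(tmap, weights)
    lam = np.asarray(tmap.lambda_axis)[tmap.valid_mask]
    t_axis = np.asarray(tmap.t_axis, dtype=float)
    rng = np.random.default_rng(seed)

    if init_rates is not None:
        starts = [np.asarray(init_rates, dtype=float)]
        if len(starts[0]) != n_components:
            raise ValueError("init_rates length must equal n_components")
    else:
        starts = _initial_rate_sets(t_axis, n_components, n_starts, rng)

    best = None
    for x0 in starts:
        try:
            res = least_squares(_residuals, np.log(x0),
                                args=(data, w, irf, t_axis),
                                method="trf", x_scale="jac", ftol=1e-12,
                                xtol=1e-12, gtol=1e-12, max_nfev=400)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("global fit failed for every initialization")

    rates = np.exp(best.x)
    order = np.argsort(rates)[::-1]
    rates = rates[order]
    c = np.stack([exp_gauss_kernel(k, irf, t_axis) for k in rates], axis=1)
    spectra = _solve_spectra(data, w, c)[:, :].T  # (n_comp, n_lambda)

    n_data = data.size
    dof = max(n_data - n_components * (1 + lam.size), 1)
    wrss = 2.0 * best.cost
    chi2_red = wrss / dof

    # covariance of the log rates from the Gauss-Newton approximation
    jac = best.jac[:, order]
    try:
        cov_log = np.linalg.inv(jac.T @ jac) * max(chi2_red, np.finfo(float).tiny)
        rate_stderr = np.sqrt(np.maximum(np.diag(cov_log), 0.0)) * rates
    except np.linalg.LinAlgError:
        cov_log = np.full((n_components, n_components), np.nan)
        rate_stderr = np.full(n_components, np.nan)

    fit = DasFit(rates=rates, spectra=spectra, lambda_axis=lam, irf=irf,
                 residual_norm=float(np.sqrt(wrss)), chi2_reduced=float(chi2_red),
                 rate_stderr=rate_stderr, covariance=cov_log, n_data=n_data,
                 success=bool(best.success), message=str(best.message))
    return _merge_degenerate(fit, data, w, t_axis)


def _merge_degenerate(fit: DasFit, data, w, t_axis) -> DasFit:
    """Merge components whose lifetimes agree within ``_MERGE_RTOL`` and
    whose spectra are proportional (cosine similarity > 0.99)."""
    if fit.n_components < 2:
        return fit
    keep = np.ones(fit.n_components, dtype=bool)
    for i in range(fit.n_components - 1):
        if not keep[i]:
            continue
        j = i + 1
        if not keep[j]:
            continue
        ti, tj = 1.0 / fit.rates[i], 1.0 / fit.rates[j]
        if abs(ti - tj) / max(ti, tj) < _MERGE_RTOL:
            si, sj = fit.spectra[i], fit.spectra[j]
            ni, nj = np.linalg.norm(si), np.linalg.norm(sj)
            if ni > 0 and nj > 0 and abs(si @ sj) / (ni * nj) > 0.99:
                keep[j] = False
    if keep.all():
        return fit
    rates = fit.rates[keep]
    c = np.stack([exp_gauss_kernel(k, fit.irf, t_axis) for k in rates], axis=1)
    spectra = _solve_spectra(data, w, c).T
    fit.rates = rates
    fit.spectra = spectra
    fit.rate_stderr = fit.rate_stderr[keep]
    fit.covariance = fit.covariance[np.ix_(keep, keep)]
    fit.merged = True
    model = (c @ spectra).T
    fit.residual_norm = float(np.sqrt(np.sum(((data - model) * w) ** 2)))
    return fit


def select_n_components(tmap: TransientMap, n_max: int, irf: Irf,
                        criterion: str = "bic", alpha: float = 0.05,
                        weights: str = "auto", seed: int = 0,
                        n_starts: int = 8) -> ModelSelection:
    """Choose the minimal number of exponential components.

    Fits n = 1..n_max and keeps the smallest model after which the
    criterion shows no significant improvement.  The default BIC,
    ``N ln(wRSS/N) + p ln N``, is robust at typical photon budgets and
    needs no significance level; ``criterion="ftest"`` instead accepts a
    larger model only while the nested F-test is significant at ``alpha``.
    Residual improvements below numerical noise (relative change < 1e-9,
    e.g. on noiseless data) never justify an extra component.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    fits: list[DasFit] = []
    wrss: list[float] = []
    for n in range(1, n_max + 1):
        fit = fit_global(tmap, n, irf, weights=weights, seed=seed,
                         n_starts=n_starts)
        fits.append(fit)
        wrss.append(fit.residual_norm**2)

    n_data = fits[0].n_data
    floor = n_data * np.finfo(float).eps**2
    values = np.empty(n_max)
    effective_max = n_max
    for i, fit in enumerate(fits):
        rss = max(wrss[i], floor)
        if criterion == "bic":
            values[i] = n_data * np.log(rss / n_data) + \
                fit.n_parameters * np.log(n_data)
        elif criterion == "ftest":
            values[i] = rss
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        # an essentially-zero improvement (noiseless data at machine
        # precision) caps the model size; a *negative* one just means the
        # larger fit found a worse local optimum and loses on its own BIC
        improvement = wrss[i - 1] - wrss[i] if i > 0 else np.inf
        if 0 <= improvement < 1e-9 * max(wrss[i - 1], floor):
            effective_max = min(effective_max, i)

    if criterion == "bic":
        chosen = int(np.argmin(values[:effective_max])) + 1
    else:
        chosen = 1
        for i in range(1, effective_max):
            p_small = fits[i - 1].n_parameters
            p_big = fits[i].n_parameters
            dof_big = max(n_data - p_big, 1)
            f_val = ((wrss[i - 1] - wrss[i]) / max(p_big - p_small, 1)) / \
                max(wrss[i] / dof_big, np.finfo(float).tiny)
            p_value = stats.f.sf(f_val, p_big - p_small, dof_big)
            if p_value < alpha:
                chosen = i + 1
            else:
                break
    return ModelSelection(fits=fits, criterion=criterion,
                          criterion_values=values, chosen_n=chosen)
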