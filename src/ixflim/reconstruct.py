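"""Fourier reconstruction of ixFLIM hypercubes from delay-scanned stacks.

The raw stack ``counts[tau, t, y, x]`` carries the excitation spectrum in
its fringe pattern along the interferometer delay ``tau``.  Reconstruction
proceeds per (t, y, x):

1. locate zero delay and calibrate the true delay step from the recorded
   reference laser spectra ``Spec(lambda, tau)``;
2. subtract the mean along ``tau`` (suppresses the unmodulated background /
   zero-frequency peak);
3. take the real part of the discrete Fourier transform along ``tau``,
   evaluated on the zero-padded frequency grid
   ``omega_k = 2 pi k / (N_pad dtau)`` — with the transform origin at the
   calibrated tau = 0 sample the fringe phase is zero and the real part
   carries the full amplitude;
4. convert frequency to wavelength ``lambda = 2 pi c / omega`` including the
   Jacobian ``d omega = (2 pi c / lambda^2) d lambda`` so spectral integrals
   are preserved, and resample onto a uniform wavelength grid;
5. optionally divide by the excitation laser spectrum, itself obtained by
   pushing the spectrally integrated reference interferogram through the
   *same* transform, so that all scan-length, visibility and windowing
   factors cancel.  Wavelengths where the laser reference falls below a
   threshold fraction of its maximum are masked as undefined.

The reconstructed hypercube ``ixFLIM(lambda_tau, t, y, x)`` contains the
ordinary FLIM image as its wavelength marginal and the excitation-spectrum
image (ixFIM) as its time marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .simulate import RawStack
from .units import C_NM_PER_FS, omega_from_wavelength, wavelength_from_omega

__all__ = [
    "CalibrationError",
    "Calibration",
    "Hypercube",
    "TransientMap",
    "MomentImage",
    "find_tau_zero_and_calibrate",
    "reconstruct",
    "marginals",
    "moment_image",
    "roi_transient_map",
]


class CalibrationError(RuntimeError):
    """Raised when the reference interferogram carries no usable fringes."""


@dataclass(frozen=True)
class Calibration:
    """Zero-delay position and delay-step rescaling from the laser reference.

    ``tau_zero_index`` is the scan index of the interferogram's
    constructive-interference (envelope-maximum) position;
    ``step_scale`` multiplies the nominal delay step so that the fringe
    frequency observed at ``ref_wavelength`` maps onto ``2 pi c / lambda``.
    """

    tau_zero_index: int
    step_scale: float
    ref_wavelength: float
    fringe_contrast: float


def find_tau_zero_and_calibrate(reference_spectra: np.ndarray,
                                wavelength_grid: np.ndarray,
                                delay_step: float,
                                ref_wavelength: float | None = None,
                                ) -> Calibration:
    """Locate tau = 0 and calibrate the delay step from reference spectra.

    Parameters
    ----------
    reference_spectra : array, shape (n_tau, n_lambda)
        Modulated laser spectra recorded per delay step.
    wavelength_grid : array
        Spectrometer wavelengths in nm.
    delay_step : float
        Nominal delay increment in fs.
    ref_wavelength : float, optional
        Wavelength at which the fringe frequency is measured; defaults to
        the intensity centre of mass of the mean laser spectrum.

    Notes
    -----
    Zero delay is the maximum of the fringe envelope of the spectrally
    integrated interferogram: for a broadband field all wavelengths
    interfere constructively only at tau = 0.  The true delay step follows
    from the fringe frequency at ``ref_wavelength``: with samples
    ``cos(omega_ref dtau_true j)`` the measured phase advance per sample
    ``phi`` gives ``step_scale = phi / (omega_ref delay_step)``.
    """
    refs = np.asarray(reference_spectra, dtype=float)
    lam = np.asarray(wavelength_grid, dtype=float)
    if refs.ndim != 2 or refs.shape[1] != lam.size:
        raise ValueError("reference_spectra must have shape (n_tau, n_lambda)")
    n_tau = refs.shape[0]
    mean_spec = refs.mean(axis=0)
    if ref_wavelength is None:
        if mean_spec.sum() <= 0:
            raise CalibrationError("reference spectra are empty")
        ref_wavelength = float(np.sum(lam * mean_spec) / np.sum(mean_spec))

    # zero delay: envelope maximum of the spectrally integrated interferogram
    interferogram = np.trapezoid(refs, lam, axis=1)
    dev = interferogram - interferogram.mean()
    scale = np.max(np.abs(interferogram))
    if scale <= 0 or np.max(np.abs(dev)) < 1e-9 * scale:
        raise CalibrationError(
            "reference interferogram shows no delay modulation; cannot "
            "locate tau = 0 (is the interferometer scanning?)")
    envelope = np.abs(hilbert(dev))
    tau_zero_index = int(np.argmax(envelope))
    # prefer the raw constructive-interference maximum when it agrees with
    # the envelope to within a sample (robust to Hilbert edge effects)
    j_max = int(np.argmax(dev))
    if abs(j_max - tau_zero_index) <= 1:
        tau_zero_index = j_max

    # fringe frequency at the reference wavelength
    i_ref = int(np.argmin(np.abs(lam - ref_wavelength)))
    sig = refs[:, i_ref] - refs[:, i_ref].mean()
    contrast = 0.0
    if mean_spec[i_ref] > 0:
        contrast = float(0.5 * (sig.max() - sig.min()) / mean_spec[i_ref])
    n_pad = 16 * n_tau
    amp = np.abs(np.fft.rfft(sig, n_pad))
    k_peak = int(np.argmax(amp[1:]) + 1)
    if amp[k_peak] < 3.0 * np.median(amp[1:]) + 1e-300:
        raise CalibrationError(
            "no clear fringe peak at the reference wavelength; reference "
            "appears unmodulated")
    # parabolic interpolation of the peak position
    if 1 <= k_peak < amp.size - 1:
        a, b, c = amp[k_peak - 1], amp[k_peak], amp[k_peak + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    else:
        delta = 0.0
    phase_per_sample = 2.0 * np.pi * (k_peak + delta) / n_pad
    omega_ref = omega_from_wavelength(ref_wavelength)
    step_scale = float(phase_per_sample / (omega_ref * delay_step))
    return Calibration(tau_zero_index=tau_zero_index, step_scale=step_scale,
                       ref_wavelength=float(ref_wavelength),
                       fringe_contrast=contrast)


@dataclass
class Hypercube:
    """Reconstructed ixFLIM hypercube ``values[lambda_tau, t, y, x]``.

    ``laser_reference`` is the excitation laser spectrum on ``lambda_axis``
    recovered from the reference interferogram through the same transform;
    ``valid_mask`` flags wavelengths where it exceeds the mask threshold.
    Values at masked-out wavelengths are set to zero and carry no signal
    information.
    """

    values: np.ndarray
    lambda_axis: np.ndarray
    t_axis: np.ndarray
    laser_reference: np.ndarray
    valid_mask: np.ndarray
    normalized: bool
    variance: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambda_axis) <= 0):
            raise ValueError("lambda_axis must be strictly increasing")


@dataclass
class TransientMap:
    """ROI-integrated transient excitation map ``values[lambda_tau, t]``."""

    values: np.ndarray
    lambda_axis: np.ndarray
    t_axis: np.ndarray
    valid_mask: np.ndarray
    normalized: bool = False
    variance: np.ndarray | None = None
    roi: dict = field(default_factory=dict)


@dataclass
class MomentImage:
    """Per-pixel scalar image (mean lifetime in ns or mean wavelength in nm).

    Undefined pixels (below the intensity threshold, or zero denominator)
    are NaN in ``values`` and False in ``mask``.
    """

    values: np.ndarray
    mask: np.ndarray
    kind: str


def _transform_matrix(tau_rel: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """One-sided cosine-transform matrix; the tau = 0 sample has trapezoid
    weight 1/2 so it does not bias all frequency bins equally."""
    m = np.cos(np.outer(omega, tau_rel))
    m[:, 0] *= 0.5
    return m


def reconstruct(stack: RawStack, mask_threshold: float = 0.05,
                normalize: bool = True, pad_factor: int = 4,
                window: str | None = None,
                calibration: Calibration | None = None,
                lambda_axis: np.ndarray | None = None) -> Hypercube:
    """Reconstruct the excitation-resolved hypercube from a raw stack.

    Parameters
    ----------
    stack : RawStack
        Delay-scanned photon-count stack with per-delay reference spectra.
    mask_threshold : float
        Fraction of the laser-reference maximum below which a wavelength is
        flagged undefined (default 0.05).
    normalize : bool
        Divide by the reconstructed laser spectrum (where valid).  With
        ``False`` the raw laser-weighted product is returned, which is what
        direct spectral decomposition fits operate on.
    pad_factor : int
        Zero-padding factor of the delay-axis transform (default 4); pads
        the frequency sampling for smooth resampling, not the resolution.
    window : {"hann", None}
        Optional apodization of the delay scan.  Default none, preserving
        component amplitudes; the mean along tau is always subtracted.
    calibration : Calibration, optional
        Precomputed zero-delay/step calibration; computed from the stack's
        reference spectra when absent.
    lambda_axis : array, optional
        Uniform target wavelength grid; defaults to the grid of the
        reference spectrometer.
    """
    if calibration is None:
        calibration = find_tau_zero_and_calibrate(
            stack.reference_spectra, stack.wavelength_grid, stack.delay_step)
    j0 = calibration.tau_zero_index
    dtau = stack.delay_step * calibration.step_scale
    n_used = stack.counts.shape[0] - j0
    if n_used < 2:
        raise CalibrationError("fewer than two delay samples after tau = 0")

    if lambda_axis is None:
        lam_grid = stack.wavelength_grid
        lam_target = np.linspace(lam_grid[0], lam_grid[-1], lam_grid.size)
    else:
        lam_target = np.asarray(lambda_axis, dtype=float)

    # frequency grid of the zero-padded transform, restricted to the band
    # that maps into the target wavelength range
    n_pad = pad_factor * n_used
    omega_all = 2.0 * np.pi * np.arange(1, n_pad // 2 + 1) / (n_pad * dtau)
    lam_all = wavelength_from_omega(omega_all)
    in_band = (lam_all >= lam_target[0] * 0.98) & (lam_all <= lam_target[-1] * 1.02)
    if not np.any(in_band):
        raise CalibrationError(
            "no transform frequencies fall inside the requested wavelength "
            "range; delay scan too coarse for this band")
    omega = omega_all[in_band]

    tau_rel = np.arange(n_used) * dtau
    win = np.ones(n_used)
    if window == "hann":
        win = np.hanning(2 * n_used)[n_used:]
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    m = _transform_matrix(tau_rel, omega) * win[None, :]

    # assemble the whole pipeline (mean subtraction, cosine transform,
    # Jacobian, wavelength resampling) as one explicit linear operator
    # A[lambda, tau]; counts are Poisson, so per-bin output variance is
    # exactly (A*A) @ counts
    lam_of_omega = wavelength_from_omega(omega)
    jac = (2.0 * np.pi * C_NM_PER_FS) / lam_of_omega**2  # d omega / d lambda
    order = np.argsort(lam_of_omega)
    src = lam_of_omega[order]
    scaled = (jac[:, None] * m)[order]  # (n_k, n_used), sorted by lambda
    interp = np.zeros((lam_target.size, src.size))
    idx = np.clip(np.searchsorted(src, lam_target), 1, src.size - 1)
    inside = (lam_target >= src[0]) & (lam_target <= src[-1])
    frac = (lam_target - src[idx - 1]) / (src[idx] - src[idx - 1])
    rows = np.arange(lam_target.size)[inside]
    interp[rows, idx[inside] - 1] = 1.0 - frac[inside]
    interp[rows, idx[inside]] = frac[inside]
    a_band = interp @ scaled                      # (n_lambda, n_used)
    a_full = a_band - a_band.mean(axis=1, keepdims=True)  # mean subtraction

    counts = np.asarray(stack.counts, dtype=float)[j0:]
    flat = counts.reshape(n_used, -1)
    out_shape = (lam_target.size,) + counts.shape[1:]
    values = (a_full @ flat).reshape(out_shape)
    variance = ((a_full * a_full) @ flat).reshape(out_shape)
    # one-photon variance floor per wavelength (the counterpart of the
    # max(counts, 1) Poisson floor): empty bins are uninformative, not
    # infinitely precise
    one_photon = (a_full * a_full).mean(axis=1)
    variance += one_photon.reshape((-1,) + (1,) * (variance.ndim - 1))

    ref_interf = np.trapezoid(stack.reference_spectra, stack.wavelength_grid,
                              axis=1)[j0:]
    laser_ref = a_full @ ref_interf

    ref_max = laser_ref.max()
    if ref_max <= 0:
        raise CalibrationError("reconstructed laser reference is empty")
    valid = laser_ref > mask_threshold * ref_max
    if not np.any(valid):
        raise CalibrationError("all wavelengths fall below the laser mask")

    if normalize:
        scale = laser_ref[valid][:, None, None, None]
        values[valid] /= scale
        variance[valid] /= scale * scale
    values[~valid] = 0.0
    variance[~valid] = 0.0

    meta = dict(stack.metadata)
    meta.update({
        "mask_threshold": float(mask_threshold),
        "normalized": bool(normalize),
        "pad_factor": int(pad_factor),
        "window": window,
        "tau_zero_index": int(j0),
        "step_scale": float(calibration.step_scale),
    })
    return Hypercube(values=values, lambda_axis=lam_target,
                     t_axis=stack.t_axis, laser_reference=laser_ref,
                     valid_mask=valid, normalized=bool(normalize),
                     variance=variance, metadata=meta)


def marginals(cube: Hypercube) -> tuple[np.ndarray, np.ndarray]:
    """FLIM and ixFIM marginals of the hypercube.

    Returns ``flim[t, y, x]`` (sum over valid excitation wavelengths) and
    ``ixfim[lambda_tau, y, x]`` (sum over emission time).  Both marginals
    sum the same cube, so their grand totals coincide.
    """
    flim = cube.values[cube.valid_mask].sum(axis=0)
    ixfim = cube.values.sum(axis=1)
    return flim, ixfim


def moment_image(cube: Hypercube, kind: str, t0: float = 0.0,
                 wavelength_range: tuple[float, float] | None = None,
                 threshold: float = 0.05) -> MomentImage:
    """First-moment image of a hypercube.

    ``kind="mean_lifetime"`` computes the intensity-weighted first moment
    ``<t> = sum (t - t0) FLIM(t) / sum FLIM(t)`` per pixel;
    ``kind="mean_wavelength"`` the spectral centre of mass of the ixFIM
    marginal, restricted to ``wavelength_range``.  Pixels whose integrated
    intensity falls below ``threshold`` times the image maximum — or whose
    denominator vanishes — are flagged undefined (NaN), not raised.
    """
    flim, ixfim = marginals(cube)
    if kind == "mean_lifetime":
        t = cube.t_axis
        if not (t[0] <= t0 <= t[-1]):
            raise ValueError(f"t0={t0} lies outside the time axis")
        weight = flim
        denom = weight.sum(axis=0)
        numer = ((t - t0)[:, None, None] * weight).sum(axis=0)
    elif kind == "mean_wavelength":
        lam = cube.lambda_axis
        if wavelength_range is None:
            sel = cube.valid_mask
        else:
            lo, hi = wavelength_range
            if lo < lam[0] or hi > lam[-1]:
                raise ValueError("wavelength_range lies outside lambda_axis")
            sel = (lam >= lo) & (lam <= hi) & cube.valid_mask
        weight = ixfim[sel]
        denom = weight.sum(axis=0)
        numer = (lam[sel][:, None, None] * weight).sum(axis=0)
    else:
        raise ValueError(f"unknown moment kind {kind!r}")
    intensity = denom
    limit = threshold * intensity.max() if intensity.size else 0.0
    ok = (intensity > limit) & (denom != 0)
    values = np.full(denom.shape, np.nan)
    values[ok] = numer[ok] / denom[ok]
    return MomentImage(values=values, mask=ok, kind=kind)


def roi_transient_map(cube: Hypercube, roi: np.ndarray) -> TransientMap:
    """Sum the hypercube over a pixel mask, yielding a transient map."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != cube.values.shape[2:]:
        raise ValueError("roi mask shape does not match the image")
    n_px = int(roi.sum())
    if n_px == 0:
        raise ValueError("roi is empty")
    values = cube.values[:, :, roi].sum(axis=2)
    variance = None
    if cube.variance is not None:
        variance = cube.variance[:, :, roi].sum(axis=2)
    return TransientMap(values=values, lambda_axis=cube.lambda_axis,
                        t_axis=cube.t_axis, valid_mask=cube.valid_mask,
                        normalized=cube.normalized, variance=variance,
                        roi={"n_pixels": n_px})
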