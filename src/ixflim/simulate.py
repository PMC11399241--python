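"""Forward simulation of interferometric-excitation FLIM acquisitions.

An ixFLIM measurement excites the sample with a phase-stable pair of
broadband pulses delayed by ``tau``.  Their spectral interference modulates
the excitation spectrum,

    Spec(lambda, tau) = Spec(lambda) (1 + V cos(omega(lambda) tau)),
    omega(lambda) = 2 pi c / lambda,

and one TCSPC FLIM frame is recorded per delay, producing a 4-D photon-count
stack ``counts[tau, t, y, x]``.  Because photon detection is linear in the
excitation intensity, the expected signal of every fluorescent component is
a *separable* sum of products

    E[counts](tau, t, y, x) = sum_terms  W(tau) * K(t) * C(y, x),

where ``W(tau)`` is the overlap of the component's excitation spectrum with
the modulated laser spectrum, ``K(t)`` its IRF-convolved emission kinetics
and ``C(y, x)`` its concentration map.  Plain species contribute a single
exponential; a donor-acceptor FRET pair detected through the acceptor
channel contributes the sequential-kinetics terms (acceptor decay, delayed
donor-fed rise with rate ``kT + kD``, and optional donor emission leaking
through the detection filter).  Photon noise is independent Poisson per 4-D
bin.  Pulse pile-up is not modelled: real acquisitions keep the count rate
well below the pulse repetition rate, so the detection stays linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kernels import Irf, exp_gauss_kernel, exp_gauss_kernel_t
from .units import omega_from_wavelength

__all__ = [
    "LaserField",
    "Irf",
    "Species",
    "FretScheme",
    "Scene",
    "RawStack",
    "gaussian_band",
    "modulated_excitation",
    "fret_populations",
    "simulate_stack",
]

#: relative rate difference below which the sequential-transfer kinetics are
#: evaluated by the analytic degenerate limit  t exp(-kA t)
_DEGENERACY_RTOL = 1e-9


def gaussian_band(wavelength_grid: np.ndarray, center: float, fwhm: float,
                  amplitude: float = 1.0) -> np.ndarray:
    """Gaussian spectral band on a wavelength grid (nm); peak = ``amplitude``."""
    lam = np.asarray(wavelength_grid, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((lam - center) / sigma) ** 2)


@dataclass(frozen=True)
class LaserField:
    """Broadband two-pulse excitation field and its delay scan.

    Parameters
    ----------
    wavelength_grid : array
        Strictly increasing, uniformly spaced wavelengths in nm.
    base_spectrum : array
        Single-pulse laser intensity spectrum ``Spec(lambda)`` (>= 0).
    delay_step : float
        Interferometer delay increment in fs (default 0.75 fs).
    n_delays : int
        Number of delay steps per scan (default 301).
    visibility : float
        Interference fringe visibility V in [0, 1]; 1 for an ideal
        phase-stable interferometer.
    delay_offset : float
        Position of zero delay within the scan, in fs; the scanned delays
        are ``tau_j = j * delay_step - delay_offset``.
    """

    wavelength_grid: np.ndarray
    base_spectrum: np.ndarray
    delay_step: float = 0.75
    n_delays: int = 301
    visibility: float = 1.0
    delay_offset: float = 0.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelength_grid, dtype=float)
        spec = np.asarray(self.base_spectrum, dtype=float)
        object.__setattr__(self, "wavelength_grid", lam)
        object.__setattr__(self, "base_spectrum", spec)
        if lam.ndim != 1 or lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength_grid must be 1-D and strictly increasing")
        if spec.shape != lam.shape:
            raise ValueError("base_spectrum must match wavelength_grid")
        if np.any(spec < 0):
            raise ValueError("base_spectrum must be non-negative")
        if self.n_delays < 2:
            raise ValueError("n_delays must be >= 2")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValueError("visibility must lie in [0, 1]")
        if not self.delay_step > 0:
            raise ValueError("delay_step must be positive")

    @property
    def tau_axis(self) -> np.ndarray:
        """Scanned delays in fs; tau = 0 lies at ``delay_offset``."""
        return np.arange(self.n_delays) * self.delay_step - self.delay_offset

    @classmethod
    def gaussian(cls, center: float, fwhm: float, lam_min: float, lam_max: float,
                 lam_step: float = 2.0, **kwargs) -> "LaserField":
        """Convenience constructor: Gaussian spectrum on a uniform nm grid."""
        grid = np.arange(lam_min, lam_max + 0.5 * lam_step, lam_step)
        return cls(grid, gaussian_band(grid, center, fwhm), **kwargs)


@dataclass(frozen=True)
class Species:
    """A single fluorescent species.

    ``excitation_spectrum`` is the unitless excitation efficiency
    ``epsilon(lambda)`` sampled on the laser wavelength grid;
    ``decay_rate`` is ``k`` in ns^-1, ``quantum_yield`` the fluorescence
    quantum yield ``phi`` and ``detection_efficiency`` the fraction ``eta``
    of its emission passing the detection filter.
    """

    name: str
    excitation_spectrum: np.ndarray
    decay_rate: float
    quantum_yield: float = 1.0
    detection_efficiency: float = 1.0

    def __post_init__(self) -> None:
        eps = np.asarray(self.excitation_spectrum, dtype=float)
        object.__setattr__(self, "excitation_spectrum", eps)
        if np.any(eps < 0):
            raise ValueError("excitation_spectrum must be non-negative")
        if not self.decay_rate > 0:
            raise ValueError("decay_rate must be positive")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum_yield must lie in [0, 1]")
        if not 0.0 <= self.detection_efficiency <= 1.0:
            raise ValueError("detection_efficiency must lie in [0, 1]")

    @property
    def lifetime(self) -> float:
        return 1.0 / self.decay_rate


@dataclass(frozen=True)
class FretScheme:
    """Donor-acceptor pair with Förster transfer, detected in the acceptor
    channel, plus optional free-donor and donor-leak contributions.

    ``transfer_rate`` is ``kT`` (ns^-1).  ``c_acceptor`` and
    ``c_donor_bound`` are the relative concentrations of acceptors and of
    donors engaged in transfer (equal for stoichiometric constructs such as
    doubly labelled DNA); ``c_donor_free`` is non-interacting donor.  Donor
    emission reaches the detector only through the donor's
    ``detection_efficiency`` (the filter leak).
    """

    donor: Species
    acceptor: Species
    transfer_rate: float
    c_acceptor: float = 1.0
    c_donor_bound: float = 1.0
    c_donor_free: float = 0.0

    def __post_init__(self) -> None:
        if self.transfer_rate < 0:
            raise ValueError("transfer_rate must be >= 0")
        for c in (self.c_acceptor, self.c_donor_bound, self.c_donor_free):
            if c < 0:
                raise ValueError("concentrations must be >= 0")

    @property
    def efficiency(self) -> float:
        """Transfer efficiency E = kT / (kT + kD)."""
        kd = self.donor.decay_rate
        return self.transfer_rate / (self.transfer_rate + kd)

    @property
    def rise_rate(self) -> float:
        """Observed donor-fed rise rate kT + kD (ns^-1)."""
        return self.transfer_rate + self.donor.decay_rate


@dataclass(frozen=True)
class Scene:
    """Image geometry: components with per-pixel concentration maps."""

    shape: tuple[int, int]
    components: Sequence[tuple[object, np.ndarray]]

    def __post_init__(self) -> None:
        comps = []
        for entity, conc in self.components:
            conc = np.asarray(conc, dtype=float)
            if conc.shape != tuple(self.shape):
                raise ValueError(
                    f"concentration map shape {conc.shape} does not match "
                    f"scene shape {tuple(self.shape)}")
            if np.any(conc < 0):
                raise ValueError("concentration maps must be >= 0")
            comps.append((entity, conc))
        object.__setattr__(self, "components", tuple(comps))
        object.__setattr__(self, "shape", tuple(self.shape))


@dataclass
class RawStack:
    """Measured or simulated 4-D photon-count stack ``counts[tau, t, y, x]``.

    ``reference_spectra`` holds the modulated laser spectrum
    ``Spec(lambda, tau)`` recorded per delay, shape ``(n_tau, n_lambda)`` on
    ``wavelength_grid``; it drives zero-delay finding, delay-step
    calibration and laser normalization in reconstruction.
    """

    counts: np.ndarray
    t_axis: np.ndarray
    tau_axis: np.ndarray
    wavelength_grid: np.ndarray
    reference_spectra: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        self.tau_axis = np.asarray(self.tau_axis, dtype=float)
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        self.reference_spectra = np.asarray(self.reference_spectra, dtype=float)
        if self.counts.ndim != 4:
            raise ValueError("counts must be 4-D [tau, t, y, x]")
        n_tau, n_t = self.counts.shape[:2]
        if self.tau_axis.shape != (n_tau,):
            raise ValueError("tau_axis length does not match counts")
        if self.t_axis.shape != (n_t,):
            raise ValueError("t_axis length does not match counts")
        if self.reference_spectra.shape != (n_tau, self.wavelength_grid.size):
            raise ValueError("reference_spectra must have shape (n_tau, n_lambda)")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")

    @property
    def t_bin(self) -> float:
        """TCSPC bin width in ns (t_axis entries are left bin edges)."""
        return float(self.t_axis[1] - self.t_axis[0])

    @property
    def delay_step(self) -> float:
        """Nominal delay step in fs."""
        return float(self.tau_axis[1] - self.tau_axis[0])


def modulated_excitation(laser: LaserField, tau: float) -> np.ndarray:
    """Two-pulse interference spectrum ``Spec(lambda)(1 + V cos(omega tau))``.

    At tau = 0 all wavelengths interfere constructively (factor 1 + V); a
    wavelength with ``omega(lambda) tau = pi`` is fully suppressed at V = 1.
    Averaged over a full fringe period the single-pulse spectrum is
    recovered.
    """
    if not np.isfinite(tau):
        raise ValueError(f"tau must be finite, got {tau}")
    omega = omega_from_wavelength(laser.wavelength_grid)
    return laser.base_spectrum * (1.0 + laser.visibility * np.cos(omega * float(tau)))


def fret_populations(scheme: FretScheme, t_axis: np.ndarray,
                     p_d0: float = 1.0, p_a0: float = 0.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Excited-state populations of a donor-acceptor pair under rate kinetics.

    Solves  dP_D/dt = -(kD + kT) P_D,  dP_A/dt = kT P_D - kA P_A  with the
    given initial populations:

        P_D(t) = P_D(0) exp(-(kD + kT) t)
        P_A(t) = P_A(0) exp(-kA t)
                 + P_D(0) kT/(kT + kD - kA) (exp(-kA t) - exp(-(kT+kD) t)).

    The degenerate case kT + kD = kA is evaluated by its analytic limit
    ``P_D(0) kT t exp(-kA t)``.
    """
    t = np.asarray(t_axis, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_axis must be non-negative")
    kd = scheme.donor.decay_rate
    ka = scheme.acceptor.decay_rate
    kt = scheme.transfer_rate
    krise = kd + kt
    p_d = p_d0 * np.exp(-krise * t)
    p_a = p_a0 * np.exp(-ka * t)
    if kt > 0:
        if abs(krise - ka) <= _DEGENERACY_RTOL * max(krise, ka):
            p_a = p_a + p_d0 * kt * t * np.exp(-ka * t)
        else:
            p_a = p_a + p_d0 * kt / (krise - ka) * (
                np.exp(-ka * t) - np.exp(-krise * t))
    return p_d, p_a


def _component_terms(entity, irf: Irf, t_axis: np.ndarray
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Decompose a scene component into separable (spectrum, time-kernel)
    terms; kernels are IRF-convolved and carry the emission prefactors
    ``k phi eta``."""
    if isinstance(entity, Species):
        s = entity
        kern = (s.decay_rate * s.quantum_yield * s.detection_efficiency
                * exp_gauss_kernel(s.decay_rate, irf, t_axis))
        return [(s.excitation_spectrum, kern)]
    if isinstance(entity, FretScheme):
        d, a = entity.donor, entity.acceptor
        kt = entity.transfer_rate
        ka, kd = a.decay_rate, d.decay_rate
        krise = kt + kd
        pref_a = ka * a.quantum_yield * a.detection_efficiency
        pref_d = kd * d.quantum_yield * d.detection_efficiency
        terms: list[tuple[np.ndarray, np.ndarray]] = []
        # acceptor directly excited, decaying with kA
        if entity.c_acceptor > 0:
            terms.append((a.excitation_spectrum,
                          entity.c_acceptor * pref_a
                          * exp_gauss_kernel(ka, irf, t_axis)))
        # donor-fed acceptor emission: delayed rise with rate kT + kD
        if kt > 0 and entity.c_donor_bound > 0:
            if abs(krise - ka) <= _DEGENERACY_RTOL * max(krise, ka):
                fed = kt * exp_gauss_kernel_t(ka, irf, t_axis)
            else:
                fed = kt / (krise - ka) * (exp_gauss_kernel(ka, irf, t_axis)
                                           - exp_gauss_kernel(krise, irf, t_axis))
            terms.append((d.excitation_spectrum,
                          entity.c_donor_bound * pref_a * fed))
        # donor emission leaking through the acceptor detection filter
        if pref_d > 0:
            leak = np.zeros_like(np.asarray(t_axis, dtype=float))
            if entity.c_donor_free > 0:
                leak = leak + entity.c_donor_free * exp_gauss_kernel(kd, irf, t_axis)
            if entity.c_donor_bound > 0:
                leak = leak + entity.c_donor_bound * exp_gauss_kernel(krise, irf, t_axis)
            if np.any(leak):
                terms.append((d.excitation_spectrum, pref_d * leak))
        return terms
    raise TypeError(f"unsupported scene component: {type(entity).__name__}")


def expected_stack(scene: Scene, laser: LaserField, t_axis: np.ndarray,
                   irf: Irf, photon_budget: float | None) -> np.ndarray:
    """Expected (noise-free) counts per 4-D bin, scaled so the total over
    the whole stack equals ``photon_budget`` (``None`` leaves the raw,
    unscaled expectation).  Linear in the scene: the expectation of a
    two-component scene is the sum of the single-component expectations."""
    if photon_budget is not None and photon_budget < 0:
        raise ValueError("photon_budget must be >= 0")
    t = np.asarray(t_axis, dtype=float)
    tau = laser.tau_axis
    lam = laser.wavelength_grid
    n_tau, n_t = tau.size, t.size
    ny, nx = scene.shape
    omega = omega_from_wavelength(lam)
    # modulated spectra for all delays: (n_tau, n_lambda)
    mod = laser.base_spectrum[None, :] * (
        1.0 + laser.visibility * np.cos(omega[None, :] * tau[:, None]))
    expected = np.zeros((n_tau, n_t, ny, nx))
    for entity, conc in scene.components:
        for eps, kern in _component_terms(entity, irf, t):
            if np.asarray(eps).shape != lam.shape:
                raise ValueError(
                    "component excitation spectrum does not match the laser "
                    "wavelength grid")
            w_tau = np.trapezoid(mod * eps[None, :], lam, axis=1)
            expected += (w_tau[:, None, None, None]
                         * kern[None, :, None, None]
                         * conc[None, None, :, :])
    total = expected.sum()
    if photon_budget is not None and total > 0:
        expected *= photon_budget / total
    return expected


def simulate_stack(scene: Scene, laser: LaserField, t_axis: np.ndarray,
                   irf: Irf, photon_budget: float, seed: int,
                   noiseless: bool = False) -> RawStack:
    """Simulate one ixFLIM acquisition of ``scene``.

    Builds the expected separable signal, rescales it to ``photon_budget``
    expected photons in total, and draws independent Poisson counts per
    (tau, t, y, x) bin with the given integer ``seed`` (recorded in the
    stack metadata; identical seeds give identical stacks).  With
    ``noiseless=True`` the expectation itself is returned as the count
    array, which is convenient for oracle tests.
    """
    expected = expected_stack(scene, laser, t_axis, irf, photon_budget)
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.int64)
    tau = laser.tau_axis
    refs = np.stack([modulated_excitation(laser, tv) for tv in tau])
    meta = {
        "provenance": "ixflim.simulate.simulate_stack",
        "seed": int(seed),
        "noiseless": bool(noiseless),
        "photon_budget": float(photon_budget),
        "irf_fwhm_ps": float(irf.fwhm),
        "irf_t0_ns": float(irf.t0),
        "visibility": float(laser.visibility),
    }
    return RawStack(counts=counts, t_axis=np.asarray(t_axis, dtype=float),
                    tau_axis=tau, wavelength_grid=laser.wavelength_grid,
                    reference_spectra=refs, metadata=meta)
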