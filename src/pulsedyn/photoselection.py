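"""Photoselection and finite-bleach theory for polarised pump(-dump)-probe work.

A polarised pulse preferentially excites molecules whose transition dipole is
aligned with its field: for a linear absorber the photolysed fraction at
orientation p = cosθ is

    f(p, x) = 1 − exp(−3 x p²),        x = I·σ·Φ,

with I the photon flux density (photons/cm²), σ the absorption cross-section
(cm²/molecule) and Φ the reaction quantum yield; the factor 3 normalises the
orientational cross-section 3σcos²θ to σ on an isotropic ensemble.  A circular
(in-plane degenerate) absorber has f(p, x) = 1 − exp(−(3/2)·x·(1 − p²)).

All ensemble averages are over p uniform on [0, 1] (isotropy + up/down
symmetry).  The optical anisotropy factor is the saturation-weighted second
Legendre moment r_opt(x) = ⟨f·P₂(p)⟩ / ⟨f⟩, which starts at 2/5 for x → 0 and
falls as intense pulses flatten the orientational selectivity.  The measured
anisotropy of a probed transition at angle β from the photoselected dipole is

    r = r_opt(x) · P₂(cos β).

The module also covers Gaussian beam profiles (peak photon density from the
two-dimensional integral equality with a top-hat of equal energy), the
pump/probe beam-ratio correction, decadic depth attenuation in optically thick
samples, and double-pulse (finite ground-state recovery) generalisations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, simpson
from scipy.special import erf

__all__ = [
    "CONSTANTS",
    "PulseParameters",
    "OrientationDistribution",
    "SampleGeometry",
    "MultipulseSchedule",
    "AnisotropySet",
    "InfeasibleAnisotropyError",
    "excitation_strength",
    "orientational_fraction",
    "ensemble_fraction",
    "ensemble_fraction_p2",
    "beam_profile_fraction",
    "anisotropy_factor",
    "measured_anisotropy",
    "anisotropy_degenerate",
    "extract_dipole_angle",
    "beam_ratio_correction",
    "depth_average_anisotropy",
    "multipulse_fraction",
    "multipulse_anisotropy",
    "multipulse_weights",
    "pure_intermediate_signal",
]

PLANCK = 6.62607015e-34  # J s
C_LIGHT = 2.99792458e8  # m/s

#: Single home for every numeric factor of the saturation model, so a revised
#: convention propagates everywhere at once.
CONSTANTS = {
    # exponent factor of the linear-absorber saturation: f = 1 - exp(-LINEAR x p^2)
    "orient_linear": 3.0,
    # circular absorber: f = 1 - exp(-CIRCULAR x (1 - p^2))
    "orient_circular": 1.5,
    # Gaussian peak flux = factor x top-hat flux at equal pulse energy and
    # FWHM = top-hat diameter D: peak = N/(2 pi s^2), s = D/(2 sqrt(2 ln 2)),
    # versus top-hat N/(pi D^2/4)  =>  factor = ln 2.
    "tophat_to_gaussian_peak": math.log(2.0),
}

TAYLOR_RADIUS = 1.0  # series in x converge fast below this; warn + fall back beyond


class InfeasibleAnisotropyError(ValueError):
    """Measured anisotropy outside what the optical anisotropy factor allows."""


@dataclass
class PulseParameters:
    """Photophysical and geometric description of one laser pulse.

    energy in J, wavelength in m, beam_size in m (top-hat diameter or Gaussian
    FWHM), cross_section in cm²/molecule, quantum_yield dimensionless.
    """

    energy: float
    wavelength: float
    beam_size: float
    cross_section: float
    quantum_yield: float
    profile: str = "top-hat"
    absorber: str = "linear"

    def __post_init__(self) -> None:
        for name in ("energy", "wavelength", "beam_size", "cross_section", "quantum_yield"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.quantum_yield > 1:
            raise ValueError("quantum_yield must be <= 1")
        if self.profile not in ("top-hat", "gaussian"):
            raise ValueError("profile must be 'top-hat' or 'gaussian'")
        if self.absorber not in ("linear", "circular"):
            raise ValueError("absorber must be 'linear' or 'circular'")

    @property
    def photon_energy(self) -> float:
        return PLANCK * C_LIGHT / self.wavelength

    @property
    def n_photons(self) -> float:
        return self.energy / self.photon_energy

    @property
    def sigma_beam(self) -> float:
        """Gaussian standard deviation (m) when beam_size is read as FWHM."""
        return self.beam_size / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class OrientationDistribution:
    """Photolysed fraction per orientation p = cosθ."""

    p_grid: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.p_grid = np.asarray(self.p_grid, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any((self.p_grid < 0) | (self.p_grid > 1)):
            raise ValueError("p values must lie in [0, 1]")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SampleGeometry:
    """Sample absorbance (decadic OD at the pump wavelength), thickness, layers."""

    absorbance: float
    thickness: float
    n_layers: int = 200

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if not self.thickness > 0:
            raise ValueError("thickness must be > 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass
class MultipulseSchedule:
    """Two-pulse schedule: excitation strengths, delay, ground-state recovery G(Δt)."""

    x1: float
    x2: float
    delay: float = 0.0
    recovery: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("excitation strengths must be >= 0")
        if not 0.0 <= self.recovery <= 1.0:
            raise ValueError("recovery must lie in [0, 1]")


@dataclass
class AnisotropySet:
    """Polarised absorbance changes with the derived anisotropy quantities."""

    dA_parallel: float
    dA_perpendicular: float
    r: float
    r_optical: float
    beta: float  # degrees between optical and probed transition dipole


# -- excitation strength and orientational photolysis -------------------------


def excitation_strength(pulse: PulseParameters) -> float:
    """Dimensionless saturation parameter x = I·σ·Φ of a pulse.

    I is the photon flux density in photons/cm²: pulse energy divided by the
    photon energy hc/λ and by the beam area.  For a Gaussian profile the PEAK
    flux is used — the top-hat flux at equal energy and width times the
    two-dimensional integral-equality factor ln 2.
    """
    area_cm2 = math.pi * (pulse.beam_size * 100.0 / 2.0) ** 2  # top-hat, D -> cm
    if area_cm2 == 0:
        raise ValueError("beam area is zero")
    flux = pulse.n_photons / area_cm2
    if pulse.profile == "gaussian":
        flux *= CONSTANTS["tophat_to_gaussian_peak"]
    return flux * pulse.cross_section * pulse.quantum_yield


def orientational_fraction(x: float, p, absorber: str = "linear"):
    """Photolysed fraction at orientation(s) p = cosθ for excitation strength x."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if x < 0:
        raise ValueError("x must be >= 0")
    if absorber == "linear":
        out = -np.expm1(-CONSTANTS["orient_linear"] * x * p**2)
    elif absorber == "circular":
        out = -np.expm1(-CONSTANTS["orient_circular"] * x * (1.0 - p**2))
    else:
        raise ValueError("absorber must be 'linear' or 'circular'")
    return out if out.shape else float(out)


# -- closed forms and power series for the isotropic averages ------------------
#
# F(x)  = <f(p, x)>           (ensemble photolysed fraction)
# Q(x)  = <f(p, x) P2(p)>     (second-Legendre-weighted average)
# Series coefficients follow from term-wise integration of the exponential
# series; the quotient series for r_opt = Q/F is built by the Cauchy rule.


def _F_linear(x: float) -> float:
    a = CONSTANTS["orient_linear"] * x
    if a == 0.0:
        return 0.0
    if a < 1e-4:  # cancellation guard
        return a / 3.0 - a**2 / 10.0 + a**3 / 42.0
    return 1.0 - math.sqrt(math.pi / (4.0 * a)) * erf(math.sqrt(a))


def _Q_linear(x: float) -> float:
    # <P2(p)> = 0 on [0,1], so Q = -<exp(-a p^2) P2(p)>
    a = CONSTANTS["orient_linear"] * x
    if a == 0.0:
        return 0.0
    if a < 1e-3:
        # Q = sum_{n>=1} (-1)^{n+1} a^n/n! * 2n/((2n+1)(2n+3))
        return (2.0 / 15.0) * a - (2.0 / 35.0) * a**2 + (1.0 / 63.0) * a**3
    s = math.sqrt(a)
    g0 = math.sqrt(math.pi / (4.0 * a)) * erf(s)  # ∫ exp(-a p^2) dp
    g2 = (g0 - math.exp(-a)) / (2.0 * a)  # ∫ p^2 exp(-a p^2) dp
    return -(3.0 * g2 - g0) / 2.0


def _F_series_coeffs(n_terms: int) -> np.ndarray:
    """Coefficients of F(x) = sum c_n x^n for the linear absorber."""
    lam = CONSTANTS["orient_linear"]
    c = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        c[n] = -((-lam) ** n) / (math.factorial(n) * (2 * n + 1))
    return c


def _Q_series_coeffs(n_terms: int) -> np.ndarray:
    lam = CONSTANTS["orient_linear"]
    c = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        moment = 2.0 * n / ((2 * n + 1) * (2 * n + 3))  # ∫ p^{2n} P2(p) dp
        c[n] = -((-lam) ** n) / math.factorial(n) * moment
    return c


def _series_eval(coeffs: np.ndarray, x: float) -> float:
    return float(np.polyval(coeffs[::-1], x))


def _quotient_series(num: np.ndarray, den: np.ndarray, n_terms: int) -> np.ndarray:
    """Cauchy-rule division of two power series that both start at order 1."""
    # r(x) = (n1 x + n2 x^2 + ...) / (d1 x + d2 x^2 + ...) = q0 + q1 x + ...
    n_shift = num[1:]
    d_shift = den[1:]
    q = np.zeros(n_terms)
    for k in range(n_terms):
        acc = n_shift[k] if k < n_shift.size else 0.0
        for j in range(k):
            dk = d_shift[k - j] if (k - j) < d_shift.size else 0.0
            acc -= q[j] * dk
        q[k] = acc / d_shift[0]
    return q


def ensemble_fraction(x: float, absorber: str = "linear", method: str = "quadrature",
                      order: int | None = None) -> float:
    """Isotropic average ⟨f⟩ of the photolysed fraction at excitation strength x.

    method="quadrature" integrates adaptively over p ∈ [0, 1];
    method="taylor" sums the power series in x (by default to machine
    convergence, or truncated after ``order`` terms as in the low-power
    approximation).  The series is used only for x ≤ 1; beyond that radius a
    warning is issued and quadrature takes over.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if method == "taylor":
        if x > TAYLOR_RADIUS:
            warnings.warn("x beyond the Taylor radius; falling back to quadrature")
            return ensemble_fraction(x, absorber, "quadrature")
        if absorber == "linear":
            n_terms = order if order is not None else 30
            return _series_eval(_F_series_coeffs(n_terms), x)
        # circular: <(1-p^2)^n> obeys I_n = 2n/(2n+1) I_{n-1}
        lam = CONSTANTS["orient_circular"]
        n_terms = order if order is not None else 30
        total, moment = 0.0, 1.0
        for n in range(1, n_terms + 1):
            moment *= 2.0 * n / (2.0 * n + 1.0)
            total += -((-lam * x) ** n) / math.factorial(n) * moment
        return total
    if method != "quadrature":
        raise ValueError("method must be 'quadrature' or 'taylor'")
    val, _ = quad(lambda p: orientational_fraction(x, p, absorber), 0.0, 1.0,
                  epsabs=1e-13, epsrel=1e-13)
    return float(val)


def ensemble_fraction_p2(x: float, absorber: str = "linear") -> float:
    """Second-Legendre-weighted average ⟨f·P₂(p)⟩ (closed form)."""
    if absorber == "linear":
        return _Q_linear(x)
    val, _ = quad(
        lambda p: orientational_fraction(x, p, absorber) * 0.5 * (3 * p**2 - 1),
        0.0, 1.0, epsabs=1e-13, epsrel=1e-13,
    )
    return float(val)


def beam_profile_fraction(pulse: PulseParameters, radial_points) -> np.ndarray:
    """Ensemble photolysed fraction at each distance r from the beam centre.

    A top-hat profile gives a constant fraction inside the beam radius and 0
    outside; a Gaussian profile decays with the local flux exp(−r²/2σ²).
    """
    r = np.asarray(radial_points, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial points must be >= 0")
    x0 = excitation_strength(pulse)
    out = np.empty(r.shape)
    if pulse.profile == "top-hat":
        inside = r <= pulse.beam_size / 2.0
        f_in = ensemble_fraction(x0, pulse.absorber)
        out[...] = np.where(inside, f_in, 0.0)
    else:
        s = pulse.sigma_beam
        for i, ri in np.ndenumerate(r):
            out[i] = ensemble_fraction(x0 * math.exp(-(ri**2) / (2 * s**2)), pulse.absorber)
    return out


# -- anisotropy ----------------------------------------------------------------


def anisotropy_factor(x: float, method: str = "quadrature", order: int | None = None) -> float:
    """Optical anisotropy factor r_opt(x) = ⟨f P₂⟩/⟨f⟩ of a linear absorber.

    Limits to 2/5 as x → 0 and decreases strictly with x (finite bleach).
    method="taylor" evaluates the quotient power series (Cauchy-rule
    coefficients; leading terms 2/5 − (27/175)x + (57/1750)x²); ``order``
    truncates it (order=3 reproduces the low-power three-term form).
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if method == "taylor":
        if x > TAYLOR_RADIUS:
            warnings.warn("x beyond the Taylor radius; falling back to quadrature")
            return anisotropy_factor(x, "quadrature")
        n_terms = order if order is not None else 30
        q = _quotient_series(_Q_series_coeffs(n_terms + 1), _F_series_coeffs(n_terms + 1), n_terms)
        return float(np.polyval(q[::-1], x))
    if method != "quadrature":
        raise ValueError("method must be 'quadrature' or 'taylor'")
    if x == 0.0:
        return 0.4
    num, _ = quad(lambda p: orientational_fraction(x, p) * 0.5 * (3 * p**2 - 1),
                  0.0, 1.0, epsabs=1e-13, epsrel=1e-13)
    den, _ = quad(lambda p: orientational_fraction(x, p), 0.0, 1.0,
                  epsabs=1e-13, epsrel=1e-13)
    return float(num / den)


def measured_anisotropy(dA_par: float, dA_perp: float) -> tuple[float, float]:
    """Anisotropy r = (ΔA∥ − ΔA⊥)/(ΔA∥ + 2ΔA⊥) and the magic-angle signal.

    The magic-angle (isotropic) signal is (ΔA∥ + 2ΔA⊥)/3.
    """
    if not (math.isfinite(dA_par) and math.isfinite(dA_perp)):
        raise ValueError("absorbance changes must be finite")
    denom = dA_par + 2.0 * dA_perp
    if denom == 0.0:
        raise InfeasibleAnisotropyError("ΔA∥ + 2ΔA⊥ = 0: anisotropy undefined")
    return (dA_par - dA_perp) / denom, denom / 3.0


def anisotropy_degenerate(plane_angle: float) -> float:
    """Anisotropy for a degenerate (circular) transition probed by a linear one.

    ``plane_angle`` is the angle (degrees, 0–90) between the probed linear
    transition and the plane of the degenerate transition:
    r = (3 cos²α − 2)/10, running from 0.1 (in plane) to −0.2 (perpendicular).
    Rotational relaxation is ignored.
    """
    if not 0.0 <= plane_angle <= 90.0:
        raise ValueError("plane_angle must be in [0, 90] degrees")
    ca = math.cos(math.radians(plane_angle))
    return (3.0 * ca * ca - 2.0) / 10.0


def extract_dipole_angle(r_measured: float, r_optical: float) -> float:
    """Angle β (degrees) between photoselected and probed dipole.

    Solves r_measured = r_optical · P₂(cos β) for the principal value in
    [0°, 90°]; the cos² degeneracy means ±β (and 180° − β) are equivalent.
    """
    if not r_optical > 0:
        raise ValueError("r_optical must be > 0")
    p2 = r_measured / r_optical
    if not -0.5 - 1e-12 <= p2 <= 1.0 + 1e-12:
        raise InfeasibleAnisotropyError(
            f"r_measured/r_optical = {p2:.4g} outside [-1/2, 1]: check power, beam-ratio "
            "and depth corrections"
        )
    p2 = min(max(p2, -0.5), 1.0)
    cos_b = math.sqrt((2.0 * p2 + 1.0) / 3.0)
    return math.degrees(math.acos(cos_b))


def beam_ratio_correction(R: float) -> float:
    """Probe-weighted excitation correction for pump/probe FWHM ratio R.

    The product of two centred Gaussians of widths σ_pu = R·σ_pr and σ_pr is a
    new Gaussian; averaging the pump profile over the probe along a transverse
    axis gives R/√(1 + R²): 0.71, 0.89, 0.95 at R = 1, 2, 3, tending to 1 for
    a pump much wider than the probe.
    """
    if not R > 0:
        raise ValueError("R must be > 0")
    return R / math.sqrt(1.0 + R * R)


def depth_average_anisotropy(pulse: PulseParameters, geometry: SampleGeometry) -> float:
    """Depth-averaged optical anisotropy of an absorbing sample.

    The pump flux decays decadically with depth, I(z) = I₀·10^(−A·z/d); each
    of ``n_layers`` uniform layers contributes its local optical anisotropy
    weighted by its local photolysed fraction (polarised signals add in
    proportion to the locally excited population).  A = 0 reduces exactly to
    the surface value.
    """
    x0 = excitation_strength(pulse)
    if geometry.absorbance == 0.0 or x0 == 0.0:
        return anisotropy_factor(x0)
    # uniform slicing in z/d; composite-Simpson weights over the layer edges
    # keep the discretisation error negligible already at the default count
    z = np.linspace(0.0, 1.0, geometry.n_layers + 1)
    xs = x0 * 10.0 ** (-geometry.absorbance * z)
    F = np.array([_F_linear(x) for x in xs])
    Q = np.array([_Q_linear(x) for x in xs])
    return float(simpson(Q, x=z) / simpson(F, x=z))


# -- multipulse (finite ground-state recovery) ---------------------------------


def multipulse_fraction(schedule: MultipulseSchedule, p=None, which: str = "second"):
    """Photolysed fraction in a two-pulse experiment with ground-state recovery G.

    Pulse I photolyses f₁(p) = 1 − exp(−3x₁p²); by the time pulse II arrives a
    fraction G of that has recovered, so the available (orientationally
    non-random) ground state is 1 − (1−G)·f₁(p) and

        f_II(p) = [1 − (1−G)·f₁(p)] · (1 − exp(−3x₂p²)).

    ``which`` selects the pulse-II fraction ("second") or the total excited
    population (1−G)·f₁ + f_II ("total").  With p=None the ensemble average is
    returned, computed per orientation first and then averaged (the pulse-II
    distribution is non-random, so the order matters):

        ⟨f_II⟩ = G·F(x₂) + (1−G)·[F(x₁+x₂) − F(x₁)].

    G = 1 reduces to the single-pulse expressions; G = 0 at equal strengths
    makes the total identical to one pulse of doubled power.
    """
    G, x1, x2 = schedule.recovery, schedule.x1, schedule.x2
    if p is not None:
        f1 = orientational_fraction(x1, p)
        f2 = orientational_fraction(x2, p)
        avail = 1.0 - (1.0 - G) * f1
        f_ii = avail * f2
        if which == "second":
            return f_ii
        if which == "total":
            return (1.0 - G) * f1 + f_ii
        raise ValueError("which must be 'second' or 'total'")
    f_ii = G * _F_linear(x2) + (1.0 - G) * (_F_linear(x1 + x2) - _F_linear(x1))
    if which == "second":
        return f_ii
    if which == "total":
        return (1.0 - G) * _F_linear(x1) + f_ii
    raise ValueError("which must be 'second' or 'total'")


def multipulse_anisotropy(schedule: MultipulseSchedule, method: str = "quadrature",
                          order: int | None = None) -> float:
    """Optical anisotropy of the pulse-II excited population.

    r_II = ⟨f_II·P₂⟩/⟨f_II⟩ over the pre-oriented ground state; decomposes as
    [G·Q(x₂) + (1−G)(Q(x₁+x₂) − Q(x₁))] / [G·F(x₂) + (1−G)(F(x₁+x₂) − F(x₁))].
    With G = 1 and x₁ → 0 this is the single-pulse anisotropy_factor(x₂).
    """
    G, x1, x2 = schedule.recovery, schedule.x1, schedule.x2
    if method == "taylor":
        if max(x1, x2) > TAYLOR_RADIUS:
            warnings.warn("x beyond the Taylor radius; falling back to quadrature")
            return multipulse_anisotropy(schedule, "quadrature")
        n_terms = order if order is not None else 30
        cf, cq = _F_series_coeffs(n_terms), _Q_series_coeffs(n_terms)

        def F(x):
            return _series_eval(cf, x)

        def Q(x):
            return _series_eval(cq, x)
    elif method == "quadrature":
        F, Q = _F_linear, _Q_linear
    else:
        raise ValueError("method must be 'quadrature' or 'taylor'")
    num = G * Q(x2) + (1.0 - G) * (Q(x1 + x2) - Q(x1))
    den = G * F(x2) + (1.0 - G) * (F(x1 + x2) - F(x1))
    if den == 0.0:
        return 0.4  # x2 -> 0 limit
    return float(num / den)


def multipulse_weights(schedule: MultipulseSchedule) -> dict[str, float]:
    """Linear weights of the pump-dump-probe signal decomposition.

    ``ground_state``: pulse-II ground-state excitation relative to a
    dump-probe-only experiment, ⟨f_II⟩ / F(x₂); ``intermediate``: the pumped
    population still in the transient phase when pulse II arrives,
    (1 − G)·F(x₁).
    """
    f2_alone = _F_linear(schedule.x2)
    f_ii = multipulse_fraction(schedule, which="second")
    w_gs = f_ii / f2_alone if f2_alone > 0 else 1.0
    w_int = (1.0 - schedule.recovery) * _F_linear(schedule.x1)
    return {"ground_state": w_gs, "intermediate": w_int}


def pure_intermediate_signal(S_pp, S_dp, S_pdp, fractions: dict[str, float]):
    """Extract the pure-intermediate signal from three polarised experiments.

    The pump-dump-probe matrix is modelled as the linear combination

        S_pdp = S_pp + w_gs·S_dp + w_int·I,

    with the weights of :func:`multipulse_weights`; solving for I gives the
    time-resolved signal of the transient intermediate alone, ready for global
    fitting.  All three matrices must share both axes.
    """
    from .io import DataMatrix

    for other in (S_dp, S_pdp):
        if not (np.array_equal(S_pp.times, other.times)
                and np.array_equal(S_pp.channels, other.channels)):
            raise ValueError("experiments must share time and channel axes")
    w_int = fractions["intermediate"]
    if w_int == 0:
        raise ValueError("intermediate weight is zero; nothing to extract")
    vals = (S_pdp.values - S_pp.values - fractions["ground_state"] * S_dp.values) / w_int
    return DataMatrix(S_pp.times.copy(), S_pp.channels.copy(), vals,
                      {**S_pp.metadata, "signal": "pure intermediate"})
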