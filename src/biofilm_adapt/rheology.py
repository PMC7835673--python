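"""Oscillatory-shear viscoelastic analysis.

Operators shared by simulated and synthetic stress records: Fourier
(first-harmonic) extraction of the storage and loss moduli from a
stress response to a sinusoidal strain, the loss-modulus route to the
shear viscosity, and yield-strain detection on amplitude-sweep
stress-strain curves.

For a drive ``gamma(t) = gamma_0 * sin(omega * t)`` a linear
viscoelastic material responds with
``sigma(t) = gamma_0 * (G' sin(omega t) + G'' cos(omega t))``;
projecting the recorded stress onto the in-phase and quadrature
components over whole cycles recovers G' (storage) and G'' (loss).
The shear viscosity follows as ``eta = G'' / omega``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViscoelasticModuli",
    "YieldAnalysis",
    "StressStrainCurve",
    "extract_moduli",
    "extract_moduli_from_strain",
    "viscosity",
    "detect_yield",
    "synthesize_stress",
]


@dataclass(frozen=True)
class ViscoelasticModuli:
    """Storage/loss moduli and derived viscosity at one drive point.

    ``G_prime`` and ``G_double_prime`` are in the stress units of the
    input (Pa for experimental records, reduced units for simulation),
    ``omega`` in rad/s, ``eta = G_double_prime / omega`` in Pa s.
    """

    G_prime: float
    G_double_prime: float
    eta: float
    omega: float
    gamma_0: float


@dataclass(frozen=True)
class YieldAnalysis:
    """Result of yield-point detection on an amplitude sweep."""

    gamma_Y: float | None
    linear_slope: float
    detected: bool


@dataclass
class StressStrainCurve:
    """Amplitude-sweep record: peak (or first-harmonic) stress per amplitude.

    ``gamma_0`` must be strictly increasing.  Optional raw per-amplitude
    time series may be attached in ``raw`` as (sigma_t, gamma_t) pairs.
    """

    gamma_0: np.ndarray
    stress: np.ndarray
    raw: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gamma_0 = np.asarray(self.gamma_0, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.gamma_0.shape != self.stress.shape or self.gamma_0.ndim != 1:
            raise ValueError("gamma_0 and stress must be 1-d arrays of equal length")
        if np.any(np.diff(self.gamma_0) <= 0):
            raise ValueError("amplitudes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.gamma_0)


def synthesize_stress(
    t: np.ndarray,
    G_prime: float,
    G_double_prime: float,
    gamma_0: float,
    omega: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal linear-viscoelastic (sigma(t), gamma(t)) for given moduli."""
    t = np.asarray(t, dtype=float)
    gamma = gamma_0 * np.sin(omega * t)
    sigma = gamma_0 * (G_prime * np.sin(omega * t) + G_double_prime * np.cos(omega * t))
    return sigma, gamma


def extract_moduli(
    sigma_t: np.ndarray,
    t: np.ndarray,
    omega: float,
    gamma_0: float,
    discard_cycles: int = 0,
) -> ViscoelasticModuli:
    """First-harmonic storage and loss moduli from a stress record.

    Parameters
    ----------
    sigma_t:
        Stress samples at the times ``t``; the strain is assumed to be
        ``gamma_0 * sin(omega * t)`` (t measured from the start of the
        drive).
    t:
        Uniformly spaced sample times covering at least two whole drive
        cycles (after ``discard_cycles`` are dropped).
    omega:
        Angular drive frequency (rad per time unit of ``t``).
    gamma_0:
        Strain amplitude; must be nonzero.
    discard_cycles:
        Initial whole cycles dropped as transient.

    The projections are computed with the trapezoidal rule over the
    largest whole number of cycles available:
    ``G' = 2/(gamma_0 T n) * int sigma sin(omega t) dt`` and
    ``G'' = 2/(gamma_0 T n) * int sigma cos(omega t) dt``.
    """
    sigma_t = np.asarray(sigma_t, dtype=float)
    t = np.asarray(t, dtype=float)
    if sigma_t.shape != t.shape or t.ndim != 1:
        raise ValueError("sigma_t and t must be 1-d arrays of equal length")
    if gamma_0 == 0:
        raise ValueError("gamma_0 must be nonzero")
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    period = 2.0 * np.pi / omega
    span = t[-1] - t[0]
    n_cycles = int(np.floor(span / period + 1e-9))
    if n_cycles - discard_cycles < 2:
        raise ValueError(
            f"need >= 2 whole cycles after discarding {discard_cycles}; "
            f"record spans {span / period:.3f} periods"
        )
    t0 = t[0] + discard_cycles * period
    t1 = t0 + (n_cycles - discard_cycles) * period
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    tt = t[mask]
    ss = sigma_t[mask]
    n = n_cycles - discard_cycles
    norm = 2.0 / (gamma_0 * n * period)
    g1 = norm * np.trapezoid(ss * np.sin(omega * tt), tt)
    g2 = norm * np.trapezoid(ss * np.cos(omega * tt), tt)
    return ViscoelasticModuli(
        G_prime=g1, G_double_prime=g2, eta=g2 / omega, omega=omega, gamma_0=gamma_0
    )


def extract_moduli_from_strain(
    sigma_t: np.ndarray,
    gamma_t: np.ndarray,
    t: np.ndarray,
    omega: float,
    discard_cycles: int = 0,
) -> ViscoelasticModuli:
    """Moduli from paired stress and strain records.

    Unlike :func:`extract_moduli` this does not assume the strain is
    phase-aligned with ``t = 0``: both signals are projected onto the
    first harmonic and the complex modulus is their ratio, so an
    arbitrary drive phase cancels.
    """
    gamma_t = np.asarray(gamma_t, dtype=float)
    t = np.asarray(t, dtype=float)
    if gamma_t.shape != t.shape:
        raise ValueError("gamma_t and t must have equal length")
    period = 2.0 * np.pi / omega
    span = t[-1] - t[0]
    n_cycles = int(np.floor(span / period + 1e-9))
    if n_cycles - discard_cycles < 2:
        raise ValueError("need >= 2 whole cycles after discarding the transient")
    t0 = t[0] + discard_cycles * period
    t1 = t0 + (n_cycles - discard_cycles) * period
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    tt = t[mask]
    basis = np.exp(-1j * omega * tt)
    sig = np.trapezoid(np.asarray(sigma_t, dtype=float)[mask] * basis, tt)
    gam = np.trapezoid(gamma_t[mask] * basis, tt)
    gamma_0 = 2.0 * np.abs(gam) / ((n_cycles - discard_cycles) * period)
    if gamma_0 == 0:
        raise ValueError("strain record has zero first-harmonic amplitude")
    g_star = sig / gam  # complex modulus; drive phase cancels in the ratio
    g1, g2 = float(np.real(g_star)), float(np.imag(g_star))
    return ViscoelasticModuli(
        G_prime=g1, G_double_prime=g2, eta=g2 / omega, omega=omega, gamma_0=gamma_0
    )


def viscosity(G_double_prime: float, omega: float) -> float:
    """Shear viscosity ``eta = G'' / omega`` (Pa s for Pa and rad/s)."""
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return G_double_prime / omega


def detect_yield(
    curve: StressStrainCurve,
    threshold: float = 0.10,
    n_linear: int = 3,
) -> YieldAnalysis:
    """Yield strain as the first departure from the low-amplitude linear fit.

    A zero-intercept line is fitted to the ``n_linear`` smallest
    amplitudes (the Hookean regime); ``gamma_Y`` is the smallest
    amplitude whose stress deviates from that line by more than
    ``threshold`` (relative).  If no amplitude deviates the curve is
    reported as linear throughout (``detected=False``).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if n_linear < 3:
        raise ValueError("need at least 3 points in the candidate linear regime")
    if len(curve) < max(5, n_linear + 1):
        raise ValueError(
            f"need >= {max(5, n_linear + 1)} amplitudes spanning both regimes, "
            f"got {len(curve)}"
        )
    g = curve.gamma_0
    s = curve.stress
    # least-squares slope through the origin on the candidate linear points
    slope = float(np.dot(g[:n_linear], s[:n_linear]) / np.dot(g[:n_linear], g[:n_linear]))
    predicted = slope * g
    with np.errstate(divide="ignore", invalid="ignore"):
        deviation = np.abs(s - predicted) / np.abs(predicted)
    beyond = np.flatnonzero(deviation > threshold)
    if beyond.size == 0:
        return YieldAnalysis(gamma_Y=None, linear_slope=slope, detected=False)
    return YieldAnalysis(gamma_Y=float(g[beyond[0]]), linear_slope=slope, detected=True)
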