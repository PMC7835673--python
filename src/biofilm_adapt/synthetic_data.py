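"""Synthetic observation sets with the statistical structure of the study.

Three generators emulate the measured observables so that inference and
the rheology operators can be exercised end-to-end without any external
data:

* :func:`gen_counts` — plate-count growth curves: the population model
  sampled at the harvest grid (24, 48, 72, 96 h by default), with
  multiplicative (lognormal) plate-count noise applied as additive
  Gaussian noise on log10 counts.
* :func:`gen_coverage` — surface-coverage percentages bounded in
  [0, 100]: a saturating rise to a sub-100% cap peaking in a configured
  window, with truncated-Gaussian noise.
* :func:`gen_stress_strain` — amplitude-sweep stress-strain curves with
  a Hookean regime, a yield strain and a mildly softening plastic
  plateau, at the moduli magnitudes of the two growth conditions
  (storage modulus ~1 kPa when shaken, ~10 Pa static).

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import TimeSeriesTable
from .ode_model import DEFAULT_INITIAL, PopulationParams, preset, simulate
from .rheology import StressStrainCurve

__all__ = ["GeneratorSpec", "gen_counts", "gen_coverage", "gen_stress_strain"]

#: Linear-regime modulus (Pa) and yield strain per condition; the shaken
#: biofilm is ~2 decades stiffer and yields at ~20% strain, the static
#: one near 100%.
DEFAULT_RHEO_TARGETS = {
    "shaking": {"G_prime": 1000.0, "G_double_prime": 100.0, "gamma_Y": 0.2},
    "static": {"G_prime": 10.0, "G_double_prime": 10.0, "gamma_Y": 1.0},
}

DEFAULT_COVERAGE_PARAMS = {
    "cap_pct": 55.0,  # peak coverage (between 50 and 60% when shaken)
    "t_mid_h": 30.0,  # logistic midpoint of the rise
    "rate_per_h": 0.15,  # logistic steepness
    "t_peak_h": 60.0,  # peak inside the 48-72 h window
    "decline_pct_per_h": 0.3,  # late detachment
    "noise_sd_pct": 3.0,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and observation design for the generators."""

    condition: str = "shaking"
    true_params: PopulationParams | None = None
    time_grid_h: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0)
    n_replicates: int = 10
    noise_sd_log10: float = 0.1
    cfu_scale: float = 1e8  # CFU per model density unit at the 24-h count
    coverage_params: dict = field(default_factory=dict)
    rheo_targets: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(t < 0 for t in self.time_grid_h):
            raise ValueError("time grid must be non-negative")

    def resolved_params(self) -> PopulationParams:
        return self.true_params if self.true_params is not None else preset(self.condition)

    def resolved_coverage(self) -> dict:
        out = dict(DEFAULT_COVERAGE_PARAMS)
        out.update(self.coverage_params)
        return out

    def resolved_rheo(self) -> dict:
        out = dict(DEFAULT_RHEO_TARGETS[self.condition])
        out.update(self.rheo_targets)
        return out


def gen_counts(spec: GeneratorSpec, dt: float = 0.01) -> TimeSeriesTable:
    """Plate-count observations from the population model.

    The noiseless trajectory is sampled at the harvest grid; each
    replicate observes ``log10(cfu_scale * rho) + N(0, noise_sd_log10)``
    for both the biofilm and the planktonic compartment.
    """
    params = spec.resolved_params()
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.time_grid_h, dtype=float)
    t_end = max(float(grid.max()), 24.0)
    traj = simulate(params, DEFAULT_INITIAL, t_end, dt=dt, condition=spec.condition)
    rows = []
    for var, attr in (
        ("log10_cfu_biofilm", "rho_b"),
        ("log10_cfu_plankton", "rho_p"),
    ):
        clean = np.log10(np.maximum(traj.interp(grid, attr) * spec.cfu_scale, 1e-300))
        for rep in range(1, spec.n_replicates + 1):
            noisy = clean + rng.normal(0.0, spec.noise_sd_log10, len(grid))
            for t, v in zip(grid, noisy):
                rows.append((t, spec.condition, rep, var, v))
    return TimeSeriesTable(
        pd.DataFrame(rows, columns=["time_h", "condition", "replicate", "variable", "value"])
    )


def coverage_curve(t_h: np.ndarray, params: dict) -> np.ndarray:
    """Noiseless coverage model: logistic rise to a cap, late mild decline."""
    t_h = np.asarray(t_h, dtype=float)
    p = params
    rise = p["cap_pct"] / (1.0 + np.exp(-p["rate_per_h"] * (t_h - p["t_mid_h"])))
    peak_val = p["cap_pct"] / (1.0 + np.exp(-p["rate_per_h"] * (p["t_peak_h"] - p["t_mid_h"])))
    after = peak_val - p["decline_pct_per_h"] * (t_h - p["t_peak_h"])
    out = np.where(t_h <= p["t_peak_h"], rise, after)
    return np.clip(out, 0.0, 100.0)


def gen_coverage(spec: GeneratorSpec) -> TimeSeriesTable:
    """Surface-coverage observations (percent of the coupon colonized)."""
    p = spec.resolved_coverage()
    rng = np.random.default_rng(spec.seed + 1)
    grid = np.asarray(spec.time_grid_h, dtype=float)
    clean = coverage_curve(grid, p)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        noisy = np.clip(clean + rng.normal(0.0, p["noise_sd_pct"], len(grid)), 0.0, 100.0)
        for t, v in zip(grid, noisy):
            rows.append((t, spec.condition, rep, "coverage_pct", v))
    return TimeSeriesTable(
        pd.DataFrame(rows, columns=["time_h", "condition", "replicate", "variable", "value"])
    )


def stress_strain_model(
    gamma_0: np.ndarray, G: float, gamma_Y: float, softening: float = 0.15
) -> np.ndarray:
    """Hookean branch up to the yield strain, then a softening plateau.

    Beyond yield the stress decays logarithmically from the yield stress
    (``softening`` per decade of strain), the mild stress softening seen
    past the yield point.
    """
    gamma_0 = np.asarray(gamma_0, dtype=float)
    sigma_y = G * gamma_Y
    plastic = sigma_y * (1.0 - softening * np.log10(np.maximum(gamma_0 / gamma_Y, 1.0)))
    return np.where(gamma_0 <= gamma_Y, G * gamma_0, np.maximum(plastic, 0.0))


def gen_stress_strain(
    condition: str,
    spec: GeneratorSpec | None = None,
    amplitudes: np.ndarray | None = None,
    noise_rel: float = 0.02,
) -> StressStrainCurve:
    """Synthetic amplitude-sweep stress-strain record for one condition.

    Amplitudes default to a geometric sweep from 1% to 400% strain
    (ratio ~1.25 per step); stress carries multiplicative lognormal
    noise of relative s.d. ``noise_rel``.
    """
    spec = spec if spec is not None else GeneratorSpec(condition=condition)
    spec = replace(spec, condition=condition)
    targets = spec.resolved_rheo()
    rng = np.random.default_rng(spec.seed + 2)
    if amplitudes is None:
        amplitudes = np.geomspace(0.01, 4.0, 28)
    amplitudes = np.asarray(amplitudes, dtype=float)
    clean = stress_strain_model(amplitudes, targets["G_prime"], targets["gamma_Y"])
    noisy = clean * np.exp(rng.normal(0.0, noise_rel, len(amplitudes)))
    return StressStrainCurve(gamma_0=amplitudes, stress=noisy)
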