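"""Local-population energy use from composed allometries.

A guild's individual metabolic rate scales as ``R = a * M**b`` and its
local population density as ``D = c * M**d``; the energy used by a local
population is their product ``E = R * D = a*c * M**(b + d)``, a straight
line on log10-log10 axes with intercept ``alpha = log10(a) + log10(c)``
and slope ``beta = b + d``.  Comparing two guilds' lines gives

* the equilibrial mass ``M*`` where the lines cross (above it the
  steeper-declining guild uses less energy per local population and is
  predicted competitively inferior), and
* the energy-equivalent mass: the mass at which one guild's local
  population uses exactly as much energy as the other guild's does at a
  reference mass.

Uncertainty on both quantities is propagated to first order (delta
method) from the intercept/slope covariances of the underlying GLS fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError, NoIntersectionError, UnsolvableError
from .phylo_gls import AllometricFit

__all__ = [
    "EnergyLine",
    "compose_energy_line",
    "equilibrial_mass",
    "equilibrial_mass_se_log10",
    "energy_equivalent_mass",
    "energy_equivalent_log10",
    "energy_equivalent_se_log10",
]


@dataclass(frozen=True)
class EnergyLine:
    """log10 E(M) = alpha + beta * log10 M, with propagated uncertainty."""

    alpha: float
    beta: float
    alpha_var: float = 0.0
    beta_var: float = 0.0
    alpha_beta_cov: float = 0.0
    guild: str = ""

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.alpha_var, self.beta_var,
                self.alpha_beta_cov)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidArgumentError("EnergyLine fields must be finite")

    def log10_energy(self, log10_mass):
        return self.alpha + self.beta * np.asarray(log10_mass, dtype=float)

    def log10_energy_var(self, log10_mass):
        """Delta-method variance of the line value at log10 M."""
        x = np.asarray(log10_mass, dtype=float)
        return self.alpha_var + 2 * x * self.alpha_beta_cov + x**2 * self.beta_var


def compose_energy_line(fit_R: AllometricFit, fit_D: AllometricFit,
                        guild: str = "") -> EnergyLine:
    """Compose metabolic-rate and density allometries into an energy line.

    ``alpha`` is the sum of the two intercepts and ``beta`` the sum of the
    two slopes; variances add, treating the two fits as independent (they
    come from different trait compilations).
    """
    cov_R = np.asarray(fit_R.param_cov, dtype=float)
    cov_D = np.asarray(fit_D.param_cov, dtype=float)
    return EnergyLine(
        alpha=fit_R.intercept + fit_D.intercept,
        beta=fit_R.slope + fit_D.slope,
        alpha_var=float(cov_R[0, 0] + cov_D[0, 0]),
        beta_var=float(cov_R[1, 1] + cov_D[1, 1]),
        alpha_beta_cov=float(cov_R[0, 1] + cov_D[0, 1]),
        guild=guild,
    )


def equilibrial_mass(line_a: EnergyLine, line_b: EnergyLine) -> float:
    """Mass (kg) at which the two energy lines intersect.

    ``log10 M* = (alpha_b - alpha_a) / (beta_a - beta_b)``.
    """
    dbeta = line_a.beta - line_b.beta
    if dbeta == 0.0:
        raise NoIntersectionError("energy lines have equal slopes")
    return float(10.0 ** ((line_b.alpha - line_a.alpha) / dbeta))


def equilibrial_mass_se_log10(line_a: EnergyLine, line_b: EnergyLine) -> float:
    """Delta-method standard error of log10 M* (lines independent)."""
    dbeta = line_a.beta - line_b.beta
    if dbeta == 0.0:
        raise NoIntersectionError("energy lines have equal slopes")
    m = (line_b.alpha - line_a.alpha) / dbeta
    # gradients wrt (alpha_a, beta_a) and (alpha_b, beta_b)
    g_aa, g_ba = -1.0 / dbeta, -m / dbeta
    g_ab, g_bb = 1.0 / dbeta, m / dbeta
    var = (g_aa**2 * line_a.alpha_var + g_ba**2 * line_a.beta_var
           + 2 * g_aa * g_ba * line_a.alpha_beta_cov
           + g_ab**2 * line_b.alpha_var + g_bb**2 * line_b.beta_var
           + 2 * g_ab * g_bb * line_b.alpha_beta_cov)
    return float(np.sqrt(max(var, 0.0)))


def energy_equivalent_log10(line_target: EnergyLine, line_ref: EnergyLine,
                            log10_m_ref):
    """log10 mass at which ``line_target`` matches ``line_ref``'s energy use
    at ``log10_m_ref``:
    ``(alpha_ref + beta_ref * x_ref - alpha_target) / beta_target``.
    """
    if line_target.beta == 0.0:
        raise UnsolvableError("target energy line has zero slope")
    x = np.asarray(log10_m_ref, dtype=float)
    return (line_ref.alpha + line_ref.beta * x - line_target.alpha) / line_target.beta


def energy_equivalent_mass(line_target: EnergyLine, line_ref: EnergyLine,
                           m_ref: float) -> float:
    """Mass (kg) at which the target guild's local-population energy use
    equals the reference guild's at mass ``m_ref`` (kg)."""
    if m_ref <= 0:
        raise InvalidArgumentError(f"reference mass must be positive, got {m_ref}")
    return float(10.0 ** energy_equivalent_log10(line_target, line_ref,
                                                 np.log10(m_ref)))


def energy_equivalent_se_log10(line_target: EnergyLine, line_ref: EnergyLine,
                               log10_m_ref: float) -> float:
    """Delta-method standard error of the energy-equivalent log10 mass."""
    bt = line_target.beta
    if bt == 0.0:
        raise UnsolvableError("target energy line has zero slope")
    x = float(log10_m_ref)
    m_eq = (line_ref.alpha + line_ref.beta * x - line_target.alpha) / bt
    g_ar, g_br = 1.0 / bt, x / bt          # wrt reference (alpha, beta)
    g_at, g_bt = -1.0 / bt, -m_eq / bt     # wrt target (alpha, beta)
    var = (g_ar**2 * line_ref.alpha_var + g_br**2 * line_ref.beta_var
           + 2 * g_ar * g_br * line_ref.alpha_beta_cov
           + g_at**2 * line_target.alpha_var + g_bt**2 * line_target.beta_var
           + 2 * g_at * g_bt * line_target.alpha_beta_cov)
    return float(np.sqrt(max(var, 0.0)))
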