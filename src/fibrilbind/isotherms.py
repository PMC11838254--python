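"""Closed-form binding isotherms for ligands stacking on symmetric fibril sites.

A protein fibril (e.g. a tau paired helical filament) presents thousands of
equivalent binding sites in a 1-D array.  Ligands bind each site with a
per-site dissociation constant and gain an extra stacking energy ``C`` when
two ligands occupy adjacent sites; the corresponding Boltzmann factor is
``alpha = exp(-C / kB T)``.  In the infinite-lattice limit the transfer
matrix gives closed-form saturation and (saturated) competition isotherms,
which this module implements together with their midpoint relations and
the energy/Boltzmann-factor conversions.

All isotherms are expressed in dimensionless concentration ratios
(``c = [L]/KD`` for saturation, ``x = [I]/IC50`` for competition); molar
wrappers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BOLTZMANN_KCAL",
    "ROOM_TEMPERATURE",
    "ThermoContext",
    "SaturationParams",
    "CompetitionParams",
    "factor_from_energy",
    "energy_from_factor",
    "langmuir_fraction",
    "saturation_fraction",
    "ec50_saturation",
    "competition_fraction",
    "ic50_saturated",
    "cheng_prusoff_ic50",
    "hot_cold_fraction",
    "beta_from_factors",
    "midpoint_log_derivative",
    "critical_beta",
]

#: Boltzmann (gas) constant in kcal/(mol K).
BOLTZMANN_KCAL = 1.987204259e-3

#: Default "room temperature" in kelvin.
ROOM_TEMPERATURE = 298.15


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and energy-unit convention for energy <-> factor conversions.

    Energies are in kcal/mol throughout; ``boltzmann_constant`` is in
    kcal/(mol K) so that ``kB * T`` is an energy per mole.
    """

    temperature: float = ROOM_TEMPERATURE
    boltzmann_constant: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not (self.boltzmann_constant > 0):
            raise ValueError(
                f"boltzmann_constant must be positive, got {self.boltzmann_constant}"
            )

    @property
    def kt(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return self.boltzmann_constant * self.temperature


@dataclass(frozen=True)
class SaturationParams:
    """Per-site dissociation constant and self-cooperativity of a radioligand.

    ``alpha_l = 1`` recovers the non-cooperative (Langmuir) model;
    ``alpha_l > 1`` means favorable ligand-ligand stacking.
    """

    kd: float
    alpha_l: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kd > 0):
            raise ValueError(f"kd must be positive, got {self.kd}")
        if not (self.alpha_l >= 0):
            raise ValueError(f"alpha_l must be non-negative, got {self.alpha_l}")

    @property
    def ec50(self) -> float:
        return ec50_saturation(self.kd, self.alpha_l)


@dataclass(frozen=True)
class CompetitionParams:
    """Standalone midpoints of radioligand and inhibitor plus the shape parameter.

    ``ec50_l = KD/alpha_L`` and ``ec50_i = KI/alpha_I`` are the midpoints each
    species would show in its own saturation assay; ``beta = chi**2/(alpha_L
    alpha_I)`` is the relative cross-cooperativity that sets the steepness of
    the saturated competition curve (beta = 1 non-steep, beta < 1 steep,
    beta > 3 biphasic plateau).
    """

    ec50_l: float
    ec50_i: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ec50_l > 0):
            raise ValueError(f"ec50_l must be positive, got {self.ec50_l}")
        if not (self.ec50_i > 0):
            raise ValueError(f"ec50_i must be positive, got {self.ec50_i}")
        if not (self.beta >= 0):
            raise ValueError(f"beta must be non-negative, got {self.beta}")

    @classmethod
    def from_factors(
        cls, kd: float, ki: float, alpha_l: float, alpha_i: float, chi: float
    ) -> "CompetitionParams":
        return cls(
            ec50_l=ec50_saturation(kd, alpha_l),
            ec50_i=ec50_saturation(ki, alpha_i),
            beta=beta_from_factors(alpha_l, alpha_i, chi),
        )

    def ic50(self, conc_l: float) -> float:
        return ic50_saturated(self.ec50_i, conc_l, self.ec50_l)


def factor_from_energy(c: float, thermo: ThermoContext | None = None) -> float:
    """Boltzmann factor ``alpha = exp(-C/(kB T))`` of a cooperativity energy.

    Parameters
    ----------
    c : float
        Cooperativity energy in kcal/mol (negative = favorable stacking).
    thermo : ThermoContext, optional
        Temperature convention; defaults to 298.15 K.
    """
    if thermo is None:
        thermo = ThermoContext()
    c = float(c)
    if not np.isfinite(c):
        raise ValueError(f"energy must be finite, got {c}")
    return float(np.exp(-c / thermo.kt))


def energy_from_factor(alpha: float, thermo: ThermoContext | None = None) -> float:
    """Cooperativity energy ``C = -kB T ln(alpha)`` in kcal/mol (inverse of
    :func:`factor_from_energy`)."""
    if thermo is None:
        thermo = ThermoContext()
    alpha = float(alpha)
    if not (alpha > 0) or not np.isfinite(alpha):
        raise ValueError(f"Boltzmann factor must be positive and finite, got {alpha}")
    return float(-thermo.kt * np.log(alpha))


def langmuir_fraction(conc_ratio):
    """Non-cooperative bound fraction ``c/(1+c)`` with ``c = [L]/KD``."""
    c = np.asarray(conc_ratio, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration ratio must be non-negative")
    out = c / (1.0 + c)
    return float(out) if np.isscalar(conc_ratio) or out.ndim == 0 else out


def saturation_fraction(conc_ratio, alpha_l):
    """Infinite-lattice bound fraction for a cooperative saturation assay.

    ``f = [(a c - 1) + sqrt((a c - 1)^2 + 4 c)] / (2 sqrt((a c - 1)^2 + 4 c))``
    with ``c = [L]/KD`` and ``a = alpha_l``; the largest-eigenvalue result of
    the 2-state (ligand/empty) transfer matrix.  Reduces exactly to
    :func:`langmuir_fraction` at ``alpha_l = 1`` and obeys particle-hole
    symmetry ``f(c) + f(1/(a^2 c)) = 1``.
    """
    c = np.asarray(conc_ratio, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration ratio must be non-negative")
    if not (alpha_l >= 0):
        raise ValueError(f"alpha_l must be non-negative, got {alpha_l}")
    t = alpha_l * c - 1.0
    disc = np.sqrt(t * t + 4.0 * c)
    # disc = 0 only at c = 0 with alpha*c = 1, which cannot happen; c = 0 gives
    # disc = 1 and f = 0 as the continuous limit.
    out = np.where(disc > 0, (t + disc) / (2.0 * np.where(disc > 0, disc, 1.0)), 0.0)
    return float(out) if np.isscalar(conc_ratio) or out.ndim == 0 else out


def ec50_saturation(kd: float, alpha_l: float) -> float:
    """Saturation-curve midpoint ``EC50 = KD / alpha_L``.

    Cooperativity shifts the apparent affinity left of the per-site KD:
    ``saturation_fraction(ec50/kd, alpha_l) == 1/2`` exactly.
    """
    if not (kd > 0):
        raise ValueError(f"kd must be positive, got {kd}")
    if not (alpha_l > 0):
        raise ValueError(f"alpha_l must be positive, got {alpha_l}")
    return kd / alpha_l


def competition_fraction(x, beta):
    """Radioligand-bound fraction in a saturated competition assay.

    ``f = [(1-x) + sqrt((1-x)^2 + 4 beta x)] / (2 sqrt((1-x)^2 + 4 beta x))``
    with ``x = [I]/IC50``.  ``beta`` is a pure shape parameter: ``beta = 1``
    gives the non-steep hyperbola ``IC50/(IC50+[I])``, ``beta < 1`` a steep
    transition, ``beta > 3`` a biphasic plateau around f = 1/2.  The curve is
    log-symmetric: ``f(x) + f(1/x) = 1``.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("inhibitor ratio must be non-negative")
    if not (beta >= 0):
        raise ValueError(f"beta must be non-negative, got {beta}")
    t = 1.0 - xa
    disc = np.sqrt(t * t + 4.0 * beta * xa)
    # beta = 0, x = 1 makes disc = 0; the continuous limit through x = 1 is 1/2.
    safe = np.where(disc > 0, disc, 1.0)
    out = np.where(disc > 0, (t + disc) / (2.0 * safe), 0.5)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def ic50_saturated(ec50_i: float, conc_l: float, ec50_l: float) -> float:
    """Competition midpoint ``IC50 = EC50_I [L] / EC50_L`` for the saturated
    fibril (cf. Cheng-Prusoff without the ``+1``: no empty sites remain)."""
    for name, v in (("ec50_i", ec50_i), ("conc_l", conc_l), ("ec50_l", ec50_l)):
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v}")
    return ec50_i * conc_l / ec50_l


def cheng_prusoff_ic50(ki: float, conc_l: float, kd: float) -> float:
    """Classical Cheng-Prusoff ``IC50 = KI (1 + [L]/KD)`` for independent
    receptors, provided for comparison with :func:`ic50_saturated`."""
    for name, v in (("ki", ki), ("conc_l", conc_l), ("kd", kd)):
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v}")
    return ki * (1.0 + conc_l / kd)


def hot_cold_fraction(conc_l: float, conc_i: float) -> float:
    """Bound fraction when the inhibitor is the unlabeled ("cold") form of the
    radioligand: just the hot mole fraction ``[L]/([L]+[I])``."""
    if conc_l < 0 or conc_i < 0:
        raise ValueError("concentrations must be non-negative")
    total = conc_l + conc_i
    if total <= 0:
        raise ValueError("at least one concentration must be positive")
    return conc_l / total


def beta_from_factors(alpha_l: float, alpha_i: float, chi: float) -> float:
    """Relative cross-cooperativity ``beta = chi^2 / (alpha_L alpha_I)``.

    Equals 1 when the cross-stacking energy is the arithmetic mean of the two
    self-stacking energies.
    """
    if not (alpha_l > 0):
        raise ValueError(f"alpha_l must be positive, got {alpha_l}")
    if not (alpha_i > 0):
        raise ValueError(f"alpha_i must be positive, got {alpha_i}")
    if not (chi >= 0):
        raise ValueError(f"chi must be non-negative, got {chi}")
    return chi * chi / (alpha_l * alpha_i)


def midpoint_log_derivative(beta: float, order: int = 1, step: float = 1e-2) -> float:
    """Derivative of the competition isotherm w.r.t. ``ln x`` at the midpoint.

    Central differences with one Richardson extrapolation step evaluate
    ``d^order f / d(ln x)^order`` at ``x = 1``.  The order-1 value has the
    closed form ``-1/(4 sqrt(beta))``; the order-3 value is
    ``-(beta-3)/(16 beta^{3/2})`` and changes sign at ``beta = 3``, the onset
    of the biphasic plateau.

    Parameters
    ----------
    beta : float
        Shape parameter, must be positive.
    order : {1, 3}
        Derivative order; even orders vanish by log-symmetry.
    step : float
        Base step in ln x for the finite differences.
    """
    if not (beta > 0):
        raise ValueError(f"beta must be positive, got {beta}")
    if order not in (1, 3):
        raise ValueError(f"order must be 1 or 3, got {order}")

    def f(u: float) -> float:
        return float(competition_fraction(np.exp(u), beta))

    def central(h: float) -> float:
        if order == 1:
            return (f(h) - f(-h)) / (2.0 * h)
        return (f(2 * h) - 2 * f(h) + 2 * f(-h) - f(-2 * h)) / (2.0 * h**3)

    # Richardson: both stencils have O(h^2) error.
    d_h = central(step)
    d_h2 = central(step / 2.0)
    return (4.0 * d_h2 - d_h) / 3.0


def critical_beta(bracket: tuple[float, float] = (1.5, 9.0)) -> float:
    """Shape-parameter value where the midpoint third log-derivative changes
    sign — the onset of the mid-curve plateau in competition assays.

    Root-finds :func:`midpoint_log_derivative` of order 3 over ``bracket``;
    the analytic answer is ``beta = 3``.
    """
    lo, hi = bracket
    return float(
        brentq(lambda b: midpoint_log_derivative(b, order=3), lo, hi, xtol=1e-10)
    )
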