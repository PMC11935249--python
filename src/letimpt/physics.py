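"""Proton-in-water physics shared by both dose engines.

The beam model is deliberately minimal: a two-parameter Bragg-Kleeman
range-energy closure, Gaussian range straggling with a fixed relative
width, Highland multiple Coulomb scattering in the small-angle Gaussian
approximation, and an unrestricted-stopping-power LET table for primary
protons in water.  All constants are configurable so measured tables can
be substituted.

Units: energy MeV, lengths cm unless a function says mm, mass density
g/cc, stopping power MeV/cm, LET keV/um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTON_MASS_MEV = 938.272
HIGHLAND_CONSTANT_MEV = 14.1
#: radiation length of water, cm (density 1 g/cc)
RADIATION_LENGTH_WATER_CM = 36.08


@dataclass
class PhysicsTables:
    """Physical constants and the LET-vs-residual-range table.

    Parameters
    ----------
    alpha : Bragg-Kleeman coefficient, cm/MeV**p (range = alpha * E**p).
    p : Bragg-Kleeman exponent, dimensionless, in (1, 2).
    straggling_fraction : sigma_R / R, the relative Gaussian range
        straggling width.
    let_table_residual_cm, let_table_kev_um : tabulated LET of a primary
        proton vs its residual range in water, strictly decreasing with
        residual range; built from the stopping power by unit conversion
        unless supplied.
    """

    alpha: float = 2.2e-3
    p: float = 1.77
    straggling_fraction: float = 0.012
    let_table_residual_cm: np.ndarray | None = None
    let_table_kev_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 1.0 < self.p < 2.0:
            raise ValueError("p must lie in (1, 2)")
        if not 0.0 < self.straggling_fraction < 0.05:
            raise ValueError("straggling_fraction must lie in (0, 0.05)")
        if self.let_table_residual_cm is None:
            r, let = _build_let_table(self)
            self.let_table_residual_cm = r
            self.let_table_kev_um = let
        self.let_table_residual_cm = np.asarray(self.let_table_residual_cm, float)
        self.let_table_kev_um = np.asarray(self.let_table_kev_um, float)
        if np.any(self.let_table_kev_um <= 0):
            raise ValueError("LET table must be strictly positive")
        if np.any(np.diff(self.let_table_kev_um) >= 0):
            raise ValueError("LET table must decrease with residual range")

    # -- CSV round trip (energy MeV, range cm, stopping MeV/cm, LET keV/um)
    def to_frame(self, energies: np.ndarray | None = None) -> pd.DataFrame:
        if energies is None:
            energies = np.linspace(5.0, 250.0, 50)
        energies = np.asarray(energies, float)
        r = range_from_energy(energies, self)
        return pd.DataFrame(
            {
                "energy_mev": energies,
                "range_cm": r,
                "stopping_mev_cm": stopping_power(energies, self),
                "let_kev_um": let_vs_residual_range(r, self),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def range_from_energy(energy_mev, tables: PhysicsTables):
    """CSDA range in water, cm: R = alpha * E**p (strictly increasing)."""
    e = np.asarray(energy_mev, float)
    if np.any(e < 0):
        raise ValueError("energy must be nonnegative")
    return tables.alpha * e**tables.p


def energy_from_range(range_cm, tables: PhysicsTables):
    """Inverse of :func:`range_from_energy`: E = (R/alpha)**(1/p)."""
    r = np.asarray(range_cm, float)
    if np.any(r < 0):
        raise ValueError("range must be nonnegative")
    return (r / tables.alpha) ** (1.0 / tables.p)


def stopping_power(energy_mev, tables: PhysicsTables):
    """Stopping power in water, MeV/cm: S = 1/(dR/dE) = E**(1-p)/(alpha p)."""
    e = np.asarray(energy_mev, float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    return e ** (1.0 - tables.p) / (tables.alpha * tables.p)


def sigma_range(energy_mev, tables: PhysicsTables):
    """Gaussian range-straggling width sigma_R = fraction * R(E), cm."""
    return tables.straggling_fraction * range_from_energy(energy_mev, tables)


def momentum_velocity_mev(energy_mev):
    """Relativistic p*v for a proton of kinetic energy T: T(T+2m)/(T+m)."""
    t = np.asarray(energy_mev, float)
    m = PROTON_MASS_MEV
    return t * (t + 2.0 * m) / (t + m)


def scattering_power(energy_mev, density_g_cc=1.0):
    """Highland scattering power d<theta^2>/dz in rad^2/cm.

    Small-angle Gaussian form (14.1 MeV / pv)^2 / X0 with the water
    radiation length scaled by the local mass density; the slowly varying
    logarithmic thickness correction of the full Highland formula is
    dropped so that the same scattering power can be accumulated step by
    step (Monte Carlo) and integrated in closed form (Fermi-Eyges),
    keeping the two engines' lateral models consistent by construction.
    """
    pv = momentum_velocity_mev(energy_mev)
    x0 = RADIATION_LENGTH_WATER_CM / np.maximum(np.asarray(density_g_cc, float), 1e-12)
    return (HIGHLAND_CONSTANT_MEV / pv) ** 2 / x0


def let_from_stopping(stopping_mev_cm):
    """Convert stopping power MeV/cm to LET keV/um (water, 1 g/cc)."""
    return 0.1 * np.asarray(stopping_mev_cm, float)


def _build_let_table(tables: PhysicsTables, r_min_cm: float = 0.01,
                     r_max_cm: float = 45.0, n: int = 400):
    r = np.geomspace(r_min_cm, r_max_cm, n)
    e = energy_from_range(r, tables)
    return r, let_from_stopping(stopping_power(e, tables))


def let_vs_residual_range(residual_cm, tables: PhysicsTables):
    """LET of a primary proton at a given residual range, keV/um.

    Linear interpolation in the table, clamped at both ends (residual
    ranges below the first node return the tabulated maximum; beyond the
    last node the plateau value).
    """
    r = np.asarray(residual_cm, float)
    if np.any(r < 0):
        raise ValueError("residual range must be nonnegative")
    return np.interp(r, tables.let_table_residual_cm, tables.let_table_kev_um)
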