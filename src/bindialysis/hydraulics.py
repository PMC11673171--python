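"""Axial pressure/flow/ultrafiltration profiles and the hydraulic-
permeability bench calculation.

The axial model couples lumen-side and shell-side Poiseuille flow
through the local transmembrane (Starling, osmosis neglected) flux::

    dPb/dz = -a Qb          a = 8 mu_b / (n pi ri^4)
    dPd/dz = +b Qd          b = 8 mu_d (Rm^2 + n ro^2) / (pi (Rm^2 - n ro^2)^3)
    dQb/dz = dQd/dz = -gamma (Pb - Pd)     gamma = 2 n pi ri Lp

with z from the blood inlet (z=0) to the blood outlet (z=L); the
dialysate flows counter-current (its inlet is at z=L) and its flow rate
is carried as a positive magnitude, so dPd/dz > 0.  The shell-side
resistance ``b`` follows the annular-bundle form above; it can be
overridden if an independently measured value is available.

Because the system is linear it has a closed form: with zero net
ultrafiltration the transmembrane pressure is an odd hyperbolic sine
about the dialyzer midpoint,

    u(z) = Pb - Pd = D sinh(k (z - L/2)),   k^2 = gamma (a + b),

with D fixed by du/dz(0) = -(a Qb_in + b Qd_in).  The unknown blood
inlet pressure (the dialysate outlet is the gauge reference, Pd(0)=0)
is whatever value makes the net ultrafiltration over the full length
vanish, which is how the bench circuits are pressure-clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DialyzerGeometry, FluidProperties, ValidationError

__all__ = [
    "AxialProfile",
    "HydraulicField",
    "PermeabilityMeasurement",
    "solve_axial_hydraulics",
    "hydraulic_permeability",
    "fiber_lumen_area",
]

M3S_TO_MLMIN = 6.0e7  # 1 m^3/s = 6e7 mL/min


class InvalidGeometryError(ValidationError):
    """Fiber bundle leaves no dialysate flow annulus."""


@dataclass(frozen=True)
class HydraulicField:
    """Closed-form axial hydraulic solution, evaluable at any z in [0, L].

    Internal SI units: z in m, pressures in Pa, flows in m^3/s.
    ``u(z) = Pb - Pd``; for ``Lp = 0`` the field degenerates to a linear
    transmembrane pressure with constant flows.
    """

    L: float
    a: float  # blood-side resistance per unit length per unit flow
    b: float  # dialysate-side resistance per unit length per unit flow
    gamma: float  # 2 n pi ri Lp
    k: float  # sqrt(gamma (a + b)), 0 when Lp = 0
    D: float  # amplitude of sinh transmembrane pressure
    Qb_in: float  # m^3/s
    Qd_in: float  # m^3/s

    def u(self, z):
        """Transmembrane pressure Pb - Pd (Pa); odd about z = L/2."""
        z = np.asarray(z, dtype=float)
        if self.k > 0:
            return self.D * np.sinh(self.k * (self.L / 2 - z))
        return self.D * (self.L / 2 - z)

    def Qd(self, z):
        """Dialysate flow magnitude (m^3/s); Qd(0) = Qd(L) = Qd_in."""
        z = np.asarray(z, dtype=float)
        if self.k > 0:
            # Qd(z) = Qd_in - gamma * int_0^z u dz'
            integral = (self.D / self.k) * (
                np.cosh(self.k * self.L / 2) - np.cosh(self.k * (self.L / 2 - z))
            )
            return self.Qd_in - self.gamma * integral
        return self.Qd_in + np.zeros_like(z)

    def Qb(self, z):
        return self.Qd(z) + (self.Qb_in - self.Qd_in)

    def Pd(self, z):
        """Dialysate pressure (Pa), gauge Pd(0) = 0; Pd = b int_0^z Qd."""
        z = np.asarray(z, dtype=float)
        if self.k > 0:
            inner = (self.D / self.k) * (
                z * np.cosh(self.k * self.L / 2)
                - (np.sinh(self.k * self.L / 2) - np.sinh(self.k * (self.L / 2 - z)))
                / self.k
            )
            return self.b * (self.Qd_in * z - self.gamma * inner)
        return self.b * self.Qd_in * z

    def Pb(self, z):
        return self.Pd(z) + self.u(z)

    def Jv(self, z):
        """Local ultrafiltration flux per unit length (m^3 s^-1 m^-1)."""
        return self.gamma * self.u(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class AxialProfile:
    """Discretized axial hydraulic state (clinical-facing units).

    z in m; pressures in Pa; flows in mL/min; Jv in mL min^-1 mm^-1.
    The continuous solution is retained as ``field`` (SI units).
    """

    z: np.ndarray
    Pb: np.ndarray
    Pd: np.ndarray
    Qb: np.ndarray
    Qd: np.ndarray
    Jv: np.ndarray
    field: HydraulicField

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_m": self.z,
                "Pb_Pa": self.Pb,
                "Pd_Pa": self.Pd,
                "Qb_mL_min": self.Qb,
                "Qd_mL_min": self.Qd,
                "Jv_mL_min_mm": self.Jv,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def shell_resistance(geom: DialyzerGeometry, mu_dialysate: float) -> float:
    """Shell-side Poiseuille resistance per unit length per unit flow.

    Adopted form: 8 mu_d (Rm^2 + n ro^2) / (pi (Rm^2 - n ro^2)^3) -- the
    annular-bundle expression; this is the only dimensionally coherent
    reading of the printed source formula (which drops the exponent on
    the first Rm).  Pass ``b_override`` to :func:`solve_axial_hydraulics`
    to substitute a measured value.
    """
    n, ro, Rm = geom.n_fibers, geom.r_outer, geom.housing_radius
    annulus = Rm**2 - n * ro**2
    if annulus <= 0:
        raise InvalidGeometryError(
            "housing leaves no dialysate annulus (Rm^2 <= n ro^2)"
        )
    return 8.0 * mu_dialysate * (Rm**2 + n * ro**2) / (math.pi * annulus**3)


def solve_axial_hydraulics(
    geom: DialyzerGeometry,
    fluids: FluidProperties,
    Qb_in: float,
    Qd_in: float,
    n_z: int = 201,
    b_override: float | None = None,
) -> AxialProfile:
    """Closed-form axial hydraulics under zero net ultrafiltration.

    Parameters
    ----------
    Qb_in, Qd_in : inlet flow rates in mL/min (positive magnitudes; the
        dialysate flows from z=L toward z=0).
    n_z : number of grid points for the returned discretized profile.
    b_override : replace the computed shell-side resistance
        (Pa s^-1 m^-4 per unit length) with a measured value.
    """
    if Qb_in <= 0 or Qd_in <= 0:
        raise ValidationError("flow rates must be positive")
    L = geom.fiber_length
    a = 8.0 * fluids.mu_blood / (geom.n_fibers * math.pi * geom.r_inner**4)
    b = shell_resistance(geom, fluids.mu_dialysate) if b_override is None else b_override
    gamma = 2.0 * geom.n_fibers * math.pi * geom.r_inner * geom.Lp

    qb = Qb_in / M3S_TO_MLMIN
    qd = Qd_in / M3S_TO_MLMIN
    slope0 = a * qb + b * qd  # -du/dz at z=0
    if gamma > 0:
        k = math.sqrt(gamma * (a + b))
        D = slope0 / (k * math.cosh(k * L / 2))  # from du/dz(0) = -slope0
    else:
        k = 0.0
        D = slope0  # u = D (L/2 - z), linear Lp=0 limit
    field = HydraulicField(L=L, a=a, b=b, gamma=gamma, k=k, D=D, Qb_in=qb, Qd_in=qd)

    z = np.linspace(0.0, L, n_z)
    return AxialProfile(
        z=z,
        Pb=field.Pb(z),
        Pd=field.Pd(z),
        Qb=field.Qb(z) * M3S_TO_MLMIN,
        Qd=field.Qd(z) * M3S_TO_MLMIN,
        Jv=field.Jv(z) * M3S_TO_MLMIN * 1e-3,  # per mm
        field=field,
    )


@dataclass(frozen=True)
class PermeabilityMeasurement:
    """One bench ultrafiltration run on a mini-module."""

    dV: float  # mL ultrafiltrate collected
    dt: float  # min
    Pb_in: float  # Pa
    Pb_out: float  # Pa
    Pd_in: float  # Pa
    Pd_out: float  # Pa
    area: float  # m^2

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.area <= 0:
            raise ValidationError("area must be positive")

    @property
    def mean_pressure(self) -> float:
        """Mean transmembrane pressure (Pa)."""
        return (self.Pb_in + self.Pb_out) / 2 - (self.Pd_in + self.Pd_out) / 2


class DegeneratePressureError(ValidationError):
    """No transmembrane driving pressure."""


def hydraulic_permeability(m: PermeabilityMeasurement) -> float:
    """Hydraulic permeability Lp = (dV/dt) / (P * A) in m s^-1 Pa^-1.

    ``dV/dt`` is converted from mL/min to m^3/s; P is the mean
    transmembrane pressure.
    """
    P = m.mean_pressure
    if P <= 0:
        raise DegeneratePressureError(
            f"mean transmembrane pressure must be positive, got {P} Pa"
        )
    flux_si = (m.dV / m.dt) / M3S_TO_MLMIN  # m^3/s
    return flux_si / (P * m.area)


def fiber_lumen_area(n: int, ri: float, L: float) -> float:
    """Geometric lumen membrane area 2 pi ri L n (m^2)."""
    if n <= 0 or ri <= 0 or L <= 0:
        raise ValidationError("n, ri and L must be positive")
    return 2.0 * math.pi * ri * L * n
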