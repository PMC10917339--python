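"""Closed-form electrical model of a double-barrel nanopipette.

Each barrel is approximated as a truncated hollow cone of electrolyte:
inner tip radius ``r_tip``, inner half-cone angle with tangent ``taper``
and filled length ``length``.  The series resistance of such a cone filled
with a solution of conductivity ``kappa`` is

    R = L / (pi * kappa * r_tip * r_back),      r_back = r_tip + L * taper,

the exact value of the integral ``int_0^L dx / (kappa * pi * r(x)^2)``.

After electrowetting draws a cytoplasm column of length ``ell`` into the
organic barrel, the barrel becomes a two-segment conical resistor
(cytoplasm from the tip to ``ell``, organic solvent above), whose
resistance decreases monotonically with ``ell`` because cytoplasm
(~0.35-0.5 S/m) conducts far better than the organic phase (~0.01 S/m).
Measuring the resistance change therefore gives the ingress length and,
through the frustum volume, the extracted cytoplasm volume.

Near a surface the ion current through the aqueous barrel drops because of
the access resistance between tip and sample; it is modelled as ``alpha/z``
with ``alpha`` fixed operationally so that the current falls to the scanning
set point (99.5% of baseline) at a configurable set-point distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "PipetteGeometry",
    "BarrelElectrics",
    "PlugState",
    "cone_resistance",
    "calibrate_taper",
    "access_coefficient",
    "approach_current",
    "plug_resistance",
    "invert_ingress",
    "plug_volume",
    "M3_TO_FL",
    "DEFAULT_R_TIP_M",
    "DEFAULT_LENGTH_M",
    "DEFAULT_KAPPA_AQ",
    "DEFAULT_KAPPA_ORG",
    "DEFAULT_KAPPA_CYT",
]

# 1 m^3 = 1e18 femtoliters
M3_TO_FL = 1e18

# Defaults drawn from the platform description: ~150 nm pore diameter
# (read as diameter, so r_tip = 75 nm), barrel length 5 mm (enters only
# weakly through r_back), kappa_aq = 1.30 S/m, kappa_org = 0.01 S/m (the
# Methods also quote 0.011; the main-text value is the default), and
# cytoplasm conductivity at the midpoint of the quoted 0.35-0.5 S/m range.
DEFAULT_R_TIP_M = 75e-9
DEFAULT_LENGTH_M = 5e-3
DEFAULT_KAPPA_AQ = 1.30
DEFAULT_KAPPA_ORG = 0.01
DEFAULT_KAPPA_CYT = 0.425


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class CalibrationError(ValueError):
    """A calibration target cannot be met by any admissible parameter."""


@dataclass(frozen=True)
class PipetteGeometry:
    """Truncated-hollow-cone barrel geometry.

    Parameters
    ----------
    r_tip : float
        Inner tip radius in metres.
    taper : float
        Tangent of the inner half-cone angle (dimensionless, >= 0;
        0 is the cylinder limit).
    length : float
        Filled barrel length in metres.
    """

    r_tip: float = DEFAULT_R_TIP_M
    taper: float = 0.0714
    length: float = DEFAULT_LENGTH_M

    def __post_init__(self) -> None:
        if not (self.r_tip > 0):
            raise InvalidParameterError(f"r_tip must be > 0, got {self.r_tip}")
        if self.taper < 0:
            raise InvalidParameterError(f"taper must be >= 0, got {self.taper}")
        if not (self.length > 0):
            raise InvalidParameterError(f"length must be > 0, got {self.length}")

    @property
    def r_back(self) -> float:
        """Inner radius at the back of the filled column (m)."""
        return self.r_tip + self.length * self.taper

    def radius_at(self, x: float) -> float:
        """Inner radius at axial distance ``x`` from the tip (m)."""
        return self.r_tip + x * self.taper

    def with_taper(self, taper: float) -> "PipetteGeometry":
        return replace(self, taper=taper)


@dataclass(frozen=True)
class BarrelElectrics:
    """Electrical state of one barrel far from / near a surface.

    ``bulk_resistance`` is the barrel resistance far from any surface;
    ``access_coeff`` (ohm*m) sets the distance-dependent access
    resistance ``access_coeff / z``.
    """

    conductivity: float
    bias: float
    bulk_resistance: float
    access_coeff: float = 0.0

    def __post_init__(self) -> None:
        if not (self.conductivity > 0):
            raise InvalidParameterError("conductivity must be > 0")
        if not (self.bulk_resistance > 0):
            raise InvalidParameterError("bulk_resistance must be > 0")
        if self.access_coeff < 0:
            raise InvalidParameterError("access_coeff must be >= 0")


@dataclass(frozen=True)
class PlugState:
    """Cytoplasm column drawn into the organic barrel.

    ``ingress_length`` is the column length from the tip (m);
    ``cyt_conductivity`` the cytoplasm conductivity (S/m).
    """

    ingress_length: float
    cyt_conductivity: float = DEFAULT_KAPPA_CYT

    def __post_init__(self) -> None:
        if self.ingress_length < 0:
            raise InvalidParameterError("ingress_length must be >= 0")
        if not (self.cyt_conductivity > 0):
            raise InvalidParameterError("cyt_conductivity must be > 0")


def cone_resistance(geometry: PipetteGeometry, conductivity: float) -> float:
    """Series resistance (ohm) of a conductivity-``kappa`` filled cone.

    Exact closed form ``L / (pi * kappa * r_tip * r_back)``; reduces to the
    cylinder formula ``L / (kappa * pi * r_tip**2)`` at taper = 0.
    """
    if not (conductivity > 0):
        raise InvalidParameterError(f"conductivity must be > 0, got {conductivity}")
    return geometry.length / (math.pi * conductivity * geometry.r_tip * geometry.r_back)


def calibrate_taper(
    target_resistance: float,
    r_tip: float,
    conductivity: float,
    length: float,
) -> float:
    """Taper that makes ``cone_resistance`` match ``target_resistance``.

    The cone resistance decreases monotonically with taper, so the root is
    unique; it is solved in closed form from r_back and refined/validated
    against the forward model to relative tolerance 1e-9.

    Raises
    ------
    CalibrationError
        If the target exceeds the cylinder-limit resistance (taper = 0).
    """
    cylinder = cone_resistance(PipetteGeometry(r_tip, 0.0, length), conductivity)
    if not (0 < target_resistance <= cylinder):
        raise CalibrationError(
            f"target resistance {target_resistance:.4g} ohm not attainable; "
            f"feasible range is (0, {cylinder:.4g}] ohm at taper >= 0"
        )
    # R = L / (pi k r_tip r_back)  =>  r_back = L / (pi k r_tip R)
    r_back = length / (math.pi * conductivity * r_tip * target_resistance)
    taper = max((r_back - r_tip) / length, 0.0)
    achieved = cone_resistance(PipetteGeometry(r_tip, taper, length), conductivity)
    assert abs(achieved - target_resistance) <= 1e-9 * target_resistance
    return taper


def access_coefficient(bulk_resistance: float, z_setpoint: float, setpoint_fraction: float = 0.995) -> float:
    """Access-resistance coefficient alpha (ohm*m).

    Fixed by requiring the current magnitude to fall to
    ``setpoint_fraction`` of the bulk value at tip-surface distance
    ``z_setpoint``:  ``alpha = (1 - f)/f * R_bulk * z_sp``.
    """
    if not (0 < setpoint_fraction < 1):
        raise InvalidParameterError("setpoint_fraction must be in (0, 1)")
    return (1.0 - setpoint_fraction) / setpoint_fraction * bulk_resistance * z_setpoint


def approach_current(z: float, electrics: BarrelElectrics) -> float:
    """Ion current (A) at tip-surface distance ``z`` (m).

    ``i(z) = bias / (R_bulk + alpha / z)``: magnitude increases with z and
    tends to the bulk value ``bias / R_bulk`` far from the surface.
    """
    if not (z > 0):
        raise InvalidParameterError(f"tip-surface distance must be > 0, got {z}")
    return electrics.bias / (electrics.bulk_resistance + electrics.access_coeff / z)


def plug_resistance(
    plug: PlugState,
    geometry: PipetteGeometry,
    organic_conductivity: float = DEFAULT_KAPPA_ORG,
) -> float:
    """Resistance (ohm) of the organic barrel holding a cytoplasm plug.

    Two conical segments in series: cytoplasm (kappa_cyt) from the tip to
    ingress length ``ell``, organic solvent (kappa_org) from ``ell`` to the
    back.  Strictly decreasing in ``ell`` whenever kappa_cyt > kappa_org;
    equals ``cone_resistance(kappa_org)`` at ``ell = 0``.
    """
    if not (organic_conductivity > 0):
        raise InvalidParameterError("organic conductivity must be > 0")
    if plug.cyt_conductivity <= organic_conductivity:
        raise InvalidParameterError(
            "cytoplasm conductivity must exceed the organic conductivity "
            f"({plug.cyt_conductivity} <= {organic_conductivity})"
        )
    ell = plug.ingress_length
    if ell > geometry.length:
        raise InvalidParameterError("ingress_length exceeds barrel length")
    r_tip, t = geometry.r_tip, geometry.taper
    if t == 0.0:
        area = math.pi * r_tip**2
        return ell / (plug.cyt_conductivity * area) + (geometry.length - ell) / (
            organic_conductivity * area
        )
    r_ell = geometry.radius_at(ell)
    r_back = geometry.r_back
    return (1.0 / (math.pi * t)) * (
        (1.0 / plug.cyt_conductivity) * (1.0 / r_tip - 1.0 / r_ell)
        + (1.0 / organic_conductivity) * (1.0 / r_ell - 1.0 / r_back)
    )


def invert_ingress(
    post_extraction_resistance: float,
    geometry: PipetteGeometry,
    cyt_conductivity: float = DEFAULT_KAPPA_CYT,
    organic_conductivity: float = DEFAULT_KAPPA_ORG,
) -> float:
    """Ingress length ``ell`` (m) with the given plug resistance.

    Bisection (Brent) on the strictly monotone forward model, to absolute
    tolerance 1 nm.

    Raises
    ------
    InvalidParameterError
        If the resistance lies outside the attainable interval
        ``[R(ell = L), R(ell = 0)]``.
    """

    def resistance(ell: float) -> float:
        return plug_resistance(PlugState(ell, cyt_conductivity), geometry, organic_conductivity)

    r_full, r_empty = resistance(geometry.length), resistance(0.0)
    if not (r_full <= post_extraction_resistance <= r_empty):
        raise InvalidParameterError(
            f"resistance {post_extraction_resistance:.4g} ohm outside attainable "
            f"interval [{r_full:.4g}, {r_empty:.4g}] ohm"
        )

    def objective(ell: float) -> float:
        return resistance(ell) - post_extraction_resistance

    return float(brentq(objective, 0.0, geometry.length, xtol=1e-12))


def plug_volume(ingress_length: float, geometry: PipetteGeometry) -> float:
    """Volume (femtoliters) of the cytoplasm frustum of length ``ell``.

    Conical frustum: ``(pi * ell / 3) (r_tip^2 + r_tip r_ell + r_ell^2)``,
    reducing to the cylinder ``pi r_tip^2 ell`` at taper = 0.
    """
    if not (0 <= ingress_length <= geometry.length):
        raise InvalidParameterError(
            f"ingress_length must lie in [0, {geometry.length}], got {ingress_length}"
        )
    r0 = geometry.r_tip
    r1 = geometry.radius_at(ingress_length)
    return (math.pi * ingress_length / 3.0) * (r0 * r0 + r0 * r1 + r1 * r1) * M3_TO_FL
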