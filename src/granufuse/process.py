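"""Scale-independent process descriptors for high-shear wet granulation.

Literature granulation runs report agitation and liquid addition in
heterogeneous units (rpm or tip speed; water volume, mass, or rate x time)
on granulators from fractions of a litre to hundreds of litres.  This module
reduces every run to three unified variables:

* ``w``      -- liquid-to-solid mass ratio (g water / g dry solids);
* ``Fr``     -- impeller Froude number, Fr = omega^2 * 2R / g, the ratio of
  centrifugal to gravitational acceleration at the bowl wall (omega in
  revolutions per second, R the bowl inner radius in metres);
* ``S'max``  -- theoretical maximum pore saturation (%): the fraction of the
  tapped powder bed's pore volume the added liquid would fill, ignoring
  granule consolidation.  Values above 100% predict over-wetting (slurry).

The minimum bed porosity entering S'max is estimated from the mixture's
tapped and true densities: eps_min = 1 - rho_tapped / rho_true.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .material_db import PROPERTY_COLUMNS

#: Standard gravity (m/s^2), configurable in every formula that uses it.
G_DEFAULT = 9.81

#: Density of water (g/mL), the only binder liquid considered.
RHO_WATER = 1.0

#: Liquid-to-solid ratio range spanned by the literature runs (g/g); values
#: outside it are flagged, not rejected.
LS_LITERATURE_RANGE = (0.025, 1.8)

#: Pore saturation (%) above which a run is predicted to turn to slurry.
SLURRY_THRESHOLD = 100.0

#: Canonical 21-column feature order: 18 mixture properties, then process.
PROCESS_COLUMNS = ("LS", "Fr", "Smax")
FEATURE_COLUMNS = PROPERTY_COLUMNS + PROCESS_COLUMNS


class ProcessSpecError(ValueError):
    """An agitation or liquid-addition description is invalid."""


@dataclass(frozen=True)
class GranulatorGeometry:
    """Bowl scale and (optionally measured) inner radius."""

    volume_l: float
    radius_m: float | None = None

    def __post_init__(self):
        if not self.volume_l > 0:
            raise ProcessSpecError(f"granulator scale must be > 0 L, got "
                                   f"{self.volume_l}")
        if self.radius_m is not None and not self.radius_m > 0:
            raise ProcessSpecError(f"radius must be > 0 m, got {self.radius_m}")

    @property
    def radius_source(self) -> str:
        return "measured" if self.radius_m is not None else "derived-from-volume"

    def radius(self) -> float:
        """Measured radius when available, else derived from the volume."""
        if self.radius_m is not None:
            return self.radius_m
        return radius_from_volume(self.volume_l)


@dataclass(frozen=True)
class AgitationSpec:
    """Exactly one of impeller speed (rpm) or blade tip speed (m/s)."""

    impeller_rpm: float | None = None
    tip_speed_ms: float | None = None

    def __post_init__(self):
        given = [v for v in (self.impeller_rpm, self.tip_speed_ms) if v is not None]
        if len(given) != 1:
            raise ProcessSpecError(
                "exactly one of impeller_rpm / tip_speed_ms must be given"
            )
        if given[0] < 0:
            raise ProcessSpecError("agitation must be non-negative")

    def rpm(self, radius_m: float) -> float:
        if self.impeller_rpm is not None:
            return self.impeller_rpm
        return omega_from_tip_speed(self.tip_speed_ms, radius_m) * 60.0


@dataclass(frozen=True)
class LiquidAdditionSpec:
    """One liquid-addition description plus the dry solids mass.

    Exactly one of: total water volume (mL), total water mass (g), or an
    (addition rate mL/min, duration min) pair.
    """

    solids_g: float
    water_ml: float | None = None
    water_g: float | None = None
    rate_ml_min: float | None = None
    duration_min: float | None = None
    rho_l: float = RHO_WATER

    def __post_init__(self):
        if not self.solids_g > 0:
            raise ProcessSpecError(f"solids mass must be > 0 g, got {self.solids_g}")
        forms = [
            self.water_ml is not None,
            self.water_g is not None,
            self.rate_ml_min is not None or self.duration_min is not None,
        ]
        if sum(forms) != 1:
            raise ProcessSpecError(
                "exactly one liquid description (volume | mass | rate+duration) "
                "must be populated"
            )
        if forms[2] and (self.rate_ml_min is None or self.duration_min is None):
            raise ProcessSpecError("rate form needs both rate_ml_min and "
                                   "duration_min")
        for v in (self.water_ml, self.water_g, self.rate_ml_min,
                  self.duration_min):
            if v is not None and v < 0:
                raise ProcessSpecError("liquid quantities must be non-negative")
        if not self.rho_l > 0:
            raise ProcessSpecError("liquid density must be > 0")

    def water_mass_g(self) -> float:
        if self.water_g is not None:
            return self.water_g
        if self.water_ml is not None:
            return self.water_ml * self.rho_l
        return self.rate_ml_min * self.duration_min * self.rho_l


@dataclass(frozen=True)
class DimensionlessProcess:
    """The unified (L/S, Fr, S'max) process triple for one run."""

    ls: float           # g/g
    fr: float           # dimensionless
    smax: float         # percent
    eps_min: float      # fraction in (0, 1)
    g: float = G_DEFAULT

    def __post_init__(self):
        for label, v in (("ls", self.ls), ("fr", self.fr), ("smax", self.smax)):
            if v < 0:
                raise ProcessSpecError(f"{label} must be >= 0, got {v}")
        if not 0 < self.eps_min < 1:
            raise ProcessSpecError(f"eps_min must be in (0, 1), got "
                                   f"{self.eps_min}")

    @property
    def slurry(self) -> bool:
        """True when the pore saturation predicts over-wetting."""
        return self.smax > SLURRY_THRESHOLD


def radius_from_volume(volume_l: float) -> float:
    """Bowl inner radius (m) from its volume, assuming a cylinder with H = R.

    V = pi R^2 H with H = R gives R = (V / pi)^(1/3), V in m^3.
    """
    if not volume_l > 0:
        raise ProcessSpecError(f"volume must be > 0 L, got {volume_l}")
    v_si = volume_l * 1e-3
    return (v_si / math.pi) ** (1.0 / 3.0)


def omega_from_tip_speed(tip_speed_ms: float, radius_m: float) -> float:
    """Impeller speed (rev/s) from blade tip speed: v = 2 pi R omega."""
    if not radius_m > 0:
        raise ProcessSpecError(f"radius must be > 0 m, got {radius_m}")
    return tip_speed_ms / (2.0 * math.pi * radius_m)


def tip_speed(omega_rps: float, radius_m: float) -> float:
    """Blade tip speed (m/s) from impeller speed in rev/s."""
    return 2.0 * math.pi * radius_m * omega_rps


def froude(omega_rpm: float, radius_m: float, g: float = G_DEFAULT) -> float:
    """Impeller Froude number Fr = omega^2 * (2R) / g, omega in rev/s.

    The impeller speed is passed in rpm (as tabulated) and converted
    internally.
    """
    if not radius_m > 0:
        raise ProcessSpecError(f"radius must be > 0 m, got {radius_m}")
    if not g > 0:
        raise ProcessSpecError(f"g must be > 0, got {g}")
    omega_rps = omega_rpm / 60.0
    return omega_rps ** 2 * (2.0 * radius_m) / g


def liquid_to_solid(liq: LiquidAdditionSpec) -> float:
    """Liquid-to-solid mass ratio w (g/g) from any addition description."""
    return liq.water_mass_g() / liq.solids_g


def epsilon_min(tapped_density: float, true_density: float) -> float:
    """Minimum bed porosity eps_min = 1 - rho_tapped / rho_true.

    The tapped density of the mixture stands in for the envelope density of
    ungranulated particles.
    """
    if not 0 < tapped_density < true_density:
        raise ProcessSpecError(
            f"need 0 < tapped ({tapped_density}) < true ({true_density}); "
            "porosity would fall outside (0, 1)"
        )
    return 1.0 - tapped_density / true_density


def smax(w: float, rho_solid: float, eps_min: float,
         rho_l: float = RHO_WATER) -> float:
    """Theoretical maximum pore saturation S'max (%).

    S'max = 100 * w * rho_solid * (1 - eps_min) / (rho_l * eps_min).
    ``rho_solid`` is the mixture density on the scale chosen by the caller
    (true density by default throughout this package, since pore volume is
    referenced to fully dense solid).
    """
    if not 0 < eps_min < 1:
        raise ProcessSpecError(f"eps_min must be in (0, 1), got {eps_min}")
    if w < 0 or not rho_solid > 0 or not rho_l > 0:
        raise ProcessSpecError("w must be >= 0 and densities > 0")
    return 100.0 * w * rho_solid * (1.0 - eps_min) / (rho_l * eps_min)


def dimensionless_process(
    mixture_props: pd.Series,
    geometry: GranulatorGeometry,
    agitation: AgitationSpec,
    liquid: LiquidAdditionSpec,
    g: float = G_DEFAULT,
    density: str = "true",
) -> DimensionlessProcess:
    """Assemble the (L/S, Fr, S'max) triple for one run.

    ``density`` selects the solid density entering S'max: ``"true"`` (the
    default, consistent with printed saturation magnitudes) or ``"bulk"``.
    """
    if density not in ("true", "bulk"):
        raise ProcessSpecError("density must be 'true' or 'bulk'")
    radius = geometry.radius()
    w = liquid_to_solid(liquid)
    fr = froude(agitation.rpm(radius), radius, g=g)
    eps = epsilon_min(float(mixture_props["Dc"]), float(mixture_props["Dt"]))
    rho_solid = float(mixture_props["Dt" if density == "true" else "Da"])
    s = smax(w, rho_solid, eps, rho_l=liquid.rho_l)
    return DimensionlessProcess(ls=w, fr=fr, smax=s, eps_min=eps, g=g)


def build_feature_row(mixture_props: pd.Series,
                      dp: DimensionlessProcess) -> pd.Series:
    """The 21-entry model input row: 18 properties then L/S, Fr, S'max."""
    props = pd.Series(mixture_props, dtype=float).reindex(list(PROPERTY_COLUMNS))
    if props.isna().any():
        missing = list(props.index[props.isna()])
        raise ProcessSpecError(f"mixture properties incomplete: {missing}")
    row = pd.concat([props, pd.Series({"LS": dp.ls, "Fr": dp.fr,
                                       "Smax": dp.smax})])
    return row.reindex(list(FEATURE_COLUMNS)).astype(float)
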