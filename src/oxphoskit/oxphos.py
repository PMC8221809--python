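"""Derived OXPHOS statistics from steady-state rates and clamp forces.

Landmarks: ``jh_total`` is the maximal uncoupler-supported proton current,
``jh_oxphos`` the respiration at the minimal clamp force (default
-54.16 kJ/mol), ``fractional_oxphos`` their ratio, and ``fccp_effect`` the
ratio of post-oligomycin uncoupled flux at the final clamp force to
``jh_oxphos``.  P/O and power output convert oxygen flux to ATP flux and
watts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "DEFAULT_CLAMP_FORCES",
    "JH_OXPHOS_FORCE",
    "OxphosKinetics",
    "OxphosSummary",
    "POResult",
    "PowerPoint",
    "RelativeChange",
    "MetricsError",
    "BasisMismatchError",
    "jh_total",
    "jh_oxphos",
    "fractional_oxphos",
    "fccp_effect",
    "relative_inhibition",
    "po_ratio",
    "energy_factor_j_per_pmol",
    "power_output",
    "summarize",
]

#: Protocol-standard clamp forces (kJ/mol) for PCr = 1, 6, 15 and 21 mM.
DEFAULT_CLAMP_FORCES: tuple[float, ...] = (-54.16, -58.93, -60.64, -61.49)

#: Minimal clamp force defining jh_oxphos (maximal ATP-coupled respiration).
JH_OXPHOS_FORCE: float = -54.16


class MetricsError(ValueError):
    pass


class BasisMismatchError(MetricsError):
    pass


@dataclass
class OxphosKinetics:
    """(dG_ATP, JO2) titration curve, forces strictly decreasing."""

    points: list[tuple[float, float]]
    fccp_dgatp: float | None = None  # uncoupled rate at the final clamp force
    assay_id: str = ""
    basis: str | None = None

    def __post_init__(self) -> None:
        forces = [p[0] for p in self.points]
        if any(b >= a for a, b in zip(forces, forces[1:])):
            raise MetricsError("dg_atp values must be strictly decreasing")
        if any(p[1] < 0 for p in self.points):
            raise MetricsError("rates must be >= 0")
        if self.fccp_dgatp is not None and self.fccp_dgatp < 0:
            raise MetricsError("fccp_dgatp must be >= 0")

    @property
    def forces(self) -> list[float]:
        return [p[0] for p in self.points]

    @property
    def rates(self) -> list[float]:
        return [p[1] for p in self.points]


@dataclass
class OxphosSummary:
    jh_oxphos: float
    jh_total: float
    fractional_oxphos: float
    fccp_effect: float | None
    jh_total_source: str = "ets_permeabilized"


@dataclass
class POResult:
    jatp: float
    jo2_ss: float
    po_ratio: float


@dataclass
class PowerPoint:
    dg_atp: float  # kJ/mol
    jatp: float  # pmol ATP/s (per million cells)
    power_uw: float  # uW (per million cells)


@dataclass
class RelativeChange:
    dg_atp: float
    percent: float
    defined: bool = True


def jh_total(ets_rates: Sequence[float], source: str = "ets_permeabilized") -> float:
    """Maximal uncoupler-supported rate of an FCCP titration (adenylate-free)."""
    rates = list(ets_rates)
    if not rates:
        raise MetricsError("jh_total requires at least one FCCP-titration rate")
    return max(rates)


def jh_oxphos(
    kin: OxphosKinetics, force: float = JH_OXPHOS_FORCE, tol: float = 0.05
) -> float:
    """Rate at the designated minimal clamp force (matched within ``tol``)."""
    for f, rate in kin.points:
        if abs(f - force) <= tol:
            return rate
    raise MetricsError(
        f"no kinetics point at force {force} kJ/mol (+/-{tol}); "
        f"available: {kin.forces}"
    )


def fractional_oxphos(jh_ox: float, jh_tot: float) -> float:
    """Fraction of the total proton current usable for ATP synthesis."""
    if jh_tot <= 0:
        raise MetricsError("jh_total must be > 0")
    return jh_ox / jh_tot


def fccp_effect(fccp_dgatp: float, jh_ox: float) -> float:
    """Ratio of uncoupled flux at the final clamp force to jh_oxphos."""
    if jh_ox <= 0:
        raise MetricsError("jh_oxphos must be > 0")
    return fccp_dgatp / jh_ox


def relative_inhibition(
    treated: OxphosKinetics, vehicle: OxphosKinetics, tol: float = 0.05
) -> list[RelativeChange]:
    """Per-force percent change of treated vs vehicle on a shared force grid."""
    if len(treated.points) != len(vehicle.points):
        raise MetricsError("force grids differ in length")
    out = []
    for (ft, rt), (fv, rv) in zip(treated.points, vehicle.points):
        if abs(ft - fv) > tol:
            raise MetricsError(f"force grid mismatch: {ft} vs {fv} kJ/mol")
        if rv == 0.0:
            out.append(RelativeChange(ft, math.nan, defined=False))
        else:
            out.append(RelativeChange(ft, 100.0 * (rt - rv) / rv))
    return out


def po_ratio(
    jatp: float,
    jo2_ss: float,
    jatp_basis: str | None = None,
    jo2_basis: str | None = None,
) -> float:
    """P/O = JATP / (2 * JO2); both rates must share a normalization basis."""
    if jo2_ss <= 0:
        raise MetricsError("jo2_ss must be > 0")
    if jatp_basis is not None and jo2_basis is not None and jatp_basis != jo2_basis:
        raise BasisMismatchError(
            f"normalization basis mismatch: {jatp_basis!r} vs {jo2_basis!r}"
        )
    return jatp / (2.0 * jo2_ss)


def energy_factor_j_per_pmol(dg_atp: float) -> float:
    """|dG_ATP| as J per pmol ATP (e.g. -54.16 kJ/mol -> 5.416e-8 J/pmol)."""
    return abs(dg_atp) * 1e3 * 1e-12


def power_output(kin: OxphosKinetics, po: float) -> list[PowerPoint]:
    """ATP flux and power at each clamp force.

    jatp = jo2 * po * 2 (pmol ATP/s), power = jatp * |dG| J/pmol in uW.
    """
    if po < 0:
        raise MetricsError("po must be >= 0")
    out = []
    for dg, jo2 in kin.points:
        jatp = jo2 * po * 2.0
        power_w = jatp * energy_factor_j_per_pmol(dg)
        out.append(PowerPoint(dg_atp=dg, jatp=jatp, power_uw=power_w * 1e6))
    return out


def summarize(
    kin: OxphosKinetics,
    ets_rates: Sequence[float],
    force: float = JH_OXPHOS_FORCE,
    jh_total_source: str = "ets_permeabilized",
) -> OxphosSummary:
    """Convenience: landmark rates and both ratios from one kinetics assay."""
    jt = jh_total(ets_rates, source=jh_total_source)
    jo = jh_oxphos(kin, force=force)
    eff = fccp_effect(kin.fccp_dgatp, jo) if kin.fccp_dgatp is not None else None
    return OxphosSummary(
        jh_oxphos=jo,
        jh_total=jt,
        fractional_oxphos=fractional_oxphos(jo, jt),
        fccp_effect=eff,
        jh_total_source=jh_total_source,
    )
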