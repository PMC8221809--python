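"""Creatine-kinase clamp thermodynamics.

The CK clamp pins the extramitochondrial free energy of ATP hydrolysis by
holding the reaction

    PCr2- + ADP3- + H+  <=>  ATP4- + Cr

at equilibrium with excess creatine kinase.  Given an assay composition
(total ATP, Cr, PCr, Pi, Mg and pH) the module speciates magnesium, adjusts
the apparent equilibrium constants to the assay pH/pMg via proton and
magnesium binding polynomials, solves for free ADP and evaluates

    dG_ATP = dG0'(pH, pMg, T) + RT ln([ADP][Pi]/[ATP])

in kJ/mol.  The binding-constant parameterization follows the
Teague/Golding pH-pMg adjustment lineage; reference constants carry an
explicit ``source_label`` because the literature offers several sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "GAS_CONSTANT_KJ",
    "ClampComposition",
    "ThermoParameterSet",
    "ClampPoint",
    "ValidationError",
    "EquilibriumError",
    "DEFAULT_PARAMS",
    "binding_polynomial",
    "apparent_ck_constant",
    "delta_g0_atp",
    "solve_free_mg",
    "solve_adp",
    "delta_g_atp",
    "titration_curve",
]

GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ mol^-1 K^-1


class ValidationError(ValueError):
    """An input field is outside its validated range."""


class EquilibriumError(ValueError):
    """The clamp equilibrium is undefined for the given composition."""


@dataclass(frozen=True)
class ClampComposition:
    """Assay mixture defining the clamp, concentrations in mol/L."""

    atp_total: float
    pcr: float
    cr: float
    pi_total: float
    mg_total: float
    ph: float = 7.2
    temperature: float = 310.15
    ionic_strength: float | None = None
    ck_units: float | None = None  # U/mL, informational

    def __post_init__(self) -> None:
        for name in ("atp_total", "pcr", "cr", "pi_total", "mg_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 5.0 < self.ph < 9.0:
            raise ValidationError(f"ph must be in (5, 9), got {self.ph}")
        if not 273.0 < self.temperature < 330.0:
            raise ValidationError(
                f"temperature must be in (273, 330) K, got {self.temperature}"
            )
        if self.ck_units is not None and self.ck_units <= 0:
            raise ValidationError(f"ck_units must be > 0, got {self.ck_units}")

    @classmethod
    def from_millimolar(
        cls,
        atp_total: float,
        pcr: float,
        cr: float,
        pi_total: float,
        mg_total: float,
        **kwargs,
    ) -> "ClampComposition":
        """Build a composition from concentrations given in mmol/L."""
        return cls(
            atp_total=atp_total * 1e-3,
            pcr=pcr * 1e-3,
            cr=cr * 1e-3,
            pi_total=pi_total * 1e-3,
            mg_total=mg_total * 1e-3,
            **kwargs,
        )


#: log10 association constants (M^-1) at 310.15 K, Teague/Golding-style set.
#: Keys: "<ligand>_<species>", ligand bound to the fully deprotonated anion,
#: except mg_hatp / mg_hadp which are Mg binding to the monoprotonated form.
DEFAULT_BINDING_LOG10: Mapping[str, float] = {
    "h_atp": 6.494,
    "h_adp": 6.349,
    "h_pi": 6.75,
    "h_pcr": 4.5,
    "mg_atp": 4.19,
    "mg_adp": 3.25,
    "mg_pi": 1.81,
    "mg_pcr": 1.6,
    "mg_hatp": 2.32,
    "mg_hadp": 1.96,
}


@dataclass(frozen=True)
class ThermoParameterSet:
    """Reference constants and binding constants for clamp thermodynamics.

    ``k_ck_ref`` is the apparent CK equilibrium constant
    [ATP][Cr]/([PCr][ADP]) and ``dg0_atp_ref`` the apparent standard
    transformed Gibbs energy of ATP hydrolysis (kJ/mol), both at the
    reference conditions ``(ref_ph, ref_mg_free, ref_temperature)``.
    Binding constants are log10 association constants (M^-1).
    """

    k_ck_ref: float = 177.0
    dg0_atp_ref: float = -33.187
    binding_log10: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINDING_LOG10)
    )
    ref_ph: float = 7.0
    ref_mg_free: float = 1e-3
    ref_temperature: float = 310.15
    dh_ck: float | None = None  # kJ/mol, van 't Hoff enthalpy; None = no T adjustment
    dh_atp: float | None = None
    source_label: str = (
        "Teague/Golding-lineage pH-pMg binding polynomials at 310.15 K; "
        "dG0'_ATP anchored to the CK-clamp PCr titration forces"
    )

    def __post_init__(self) -> None:
        if self.k_ck_ref <= 0:
            raise ValidationError("k_ck_ref must be > 0")
        if not self.source_label:
            raise ValidationError("source_label must be non-empty (provenance)")
        for key, val in self.binding_log10.items():
            if 10.0**val <= 0:
                raise ValidationError(f"binding constant {key} must be > 0")


DEFAULT_PARAMS = ThermoParameterSet()


def _validate_conditions(ph: float, mg_free: float, temperature: float) -> None:
    if not 5.0 < ph < 9.0:
        raise ValidationError(f"ph out of range (5, 9): {ph}")
    if not 0.0 <= mg_free < 0.2:
        raise ValidationError(f"mg_free out of range [0, 0.2) mol/L: {mg_free}")
    if not 273.0 < temperature < 330.0:
        raise ValidationError(f"temperature out of range (273, 330) K: {temperature}")


def binding_polynomial(
    species: str, h: float, mg: float, params: ThermoParameterSet
) -> float:
    """Binding polynomial of a reactant relative to its base (unbound) anion.

    species is one of "atp", "adp", "pi", "pcr", "cr".
    """
    b = {k: 10.0**v for k, v in params.binding_log10.items()}
    if species == "atp":
        return 1.0 + h * b["h_atp"] + mg * b["mg_atp"] + h * mg * b["h_atp"] * b["mg_hatp"]
    if species == "adp":
        return 1.0 + h * b["h_adp"] + mg * b["mg_adp"] + h * mg * b["h_adp"] * b["mg_hadp"]
    if species == "pi":
        return 1.0 + h * b["h_pi"] + mg * b["mg_pi"]
    if species == "pcr":
        return 1.0 + h * b["h_pcr"] + mg * b["mg_pcr"]
    if species == "cr":
        return 1.0
    raise ValueError(f"unknown species {species!r}")


def _ck_adjustment(h: float, mg: float, params: ThermoParameterSet) -> float:
    # K'_CK = K_ionic * [H+] * P_ATP / (P_ADP * P_PCr); only the ratio to the
    # reference conditions is needed.
    return (
        h
        * binding_polynomial("atp", h, mg, params)
        / (
            binding_polynomial("adp", h, mg, params)
            * binding_polynomial("pcr", h, mg, params)
        )
    )


def _hyd_adjustment(h: float, mg: float, params: ThermoParameterSet) -> float:
    # K'_hyd = K_ionic * P_ADP * P_Pi / (P_ATP * [H+])
    return (
        binding_polynomial("adp", h, mg, params)
        * binding_polynomial("pi", h, mg, params)
        / (binding_polynomial("atp", h, mg, params) * h)
    )


def apparent_ck_constant(
    params: ThermoParameterSet, ph: float, mg_free: float, temperature: float
) -> float:
    """Apparent CK equilibrium constant [ATP][Cr]/([PCr][ADP]) at conditions.

    Returns ``params.k_ck_ref`` exactly at the reference conditions.
    """
    _validate_conditions(ph, mg_free, temperature)
    h = 10.0**-ph
    href = 10.0**-params.ref_ph
    k = params.k_ck_ref
    if temperature != params.ref_temperature and params.dh_ck is not None:
        k *= math.exp(
            -params.dh_ck
            / GAS_CONSTANT_KJ
            * (1.0 / temperature - 1.0 / params.ref_temperature)
        )
    return k * _ck_adjustment(h, mg_free, params) / _ck_adjustment(
        href, params.ref_mg_free, params
    )


def delta_g0_atp(
    params: ThermoParameterSet, ph: float, mg_free: float, temperature: float
) -> float:
    """Apparent standard transformed Gibbs energy of ATP hydrolysis, kJ/mol."""
    _validate_conditions(ph, mg_free, temperature)
    h = 10.0**-ph
    href = 10.0**-params.ref_ph
    rt = GAS_CONSTANT_KJ * temperature
    dg0 = params.dg0_atp_ref
    if temperature != params.ref_temperature and params.dh_atp is not None:
        # Gibbs-Helmholtz with temperature-independent enthalpy
        tr = params.ref_temperature
        dg0 = dg0 * temperature / tr + params.dh_atp * (1.0 - temperature / tr)
    return dg0 - rt * math.log(
        _hyd_adjustment(h, mg_free, params)
        / _hyd_adjustment(href, params.ref_mg_free, params)
    )


def solve_free_mg(
    comp: ClampComposition,
    params: ThermoParameterSet = DEFAULT_PARAMS,
    adp_total: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Free Mg2+ from total Mg by fixed-point iteration over binding polynomials.

    Conservation: mg_total = mg_free * (1 + sum_X T_X * w_X(mg_free)) where
    w_X is the Mg-bound weight of reactant X divided by its polynomial.
    """
    if comp.mg_total == 0.0:
        return 0.0
    h = 10.0**-comp.ph
    b = {k: 10.0**v for k, v in params.binding_log10.items()}

    totals = (
        ("atp", comp.atp_total, lambda m: b["mg_atp"] + h * b["h_atp"] * b["mg_hatp"]),
        ("adp", adp_total, lambda m: b["mg_adp"] + h * b["h_adp"] * b["mg_hadp"]),
        ("pi", comp.pi_total, lambda m: b["mg_pi"]),
        ("pcr", comp.pcr, lambda m: b["mg_pcr"]),
    )

    def bound_weight(m: float) -> float:
        g = 0.0
        for species, total, kfun in totals:
            if total > 0:
                g += total * kfun(m) / binding_polynomial(species, h, m, params)
        return g

    m = comp.mg_total / 2.0
    for _ in range(max_iter):
        m_new = comp.mg_total / (1.0 + bound_weight(m))
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    raise EquilibriumError(
        f"free-Mg fixed point did not converge within {max_iter} iterations"
    )


def solve_adp(
    comp: ClampComposition,
    params: ThermoParameterSet = DEFAULT_PARAMS,
    mg_free_override: float | None = None,
) -> float:
    """Free (total) ADP imposed by the CK equilibrium, mol/L.

    [ADP] = [ATP][Cr] / (K'_CK [PCr]); the apparent constant is evaluated at
    the assay pH and the self-consistently speciated free Mg (or at a
    user-supplied free-Mg override).
    """
    if comp.pcr == 0.0:
        raise EquilibriumError("PCr = 0: CK equilibrium undefined")
    if comp.cr == 0.0:
        return 0.0
    if comp.atp_total == 0.0:
        return 0.0

    adp = 0.0
    for _ in range(50):
        mg = (
            mg_free_override
            if mg_free_override is not None
            else solve_free_mg(comp, params, adp_total=adp, tol=1e-12)
        )
        k = apparent_ck_constant(params, comp.ph, mg, comp.temperature)
        adp_new = comp.atp_total * comp.cr / (k * comp.pcr)
        if abs(adp_new - adp) < 1e-15:
            adp = adp_new
            break
        adp = adp_new
    return adp


def delta_g_atp(
    comp: ClampComposition,
    params: ThermoParameterSet = DEFAULT_PARAMS,
    mg_free_override: float | None = None,
) -> float:
    """Clamped free energy of ATP hydrolysis, kJ/mol (more negative = stiffer)."""
    if comp.atp_total == 0.0:
        raise EquilibriumError("ATP = 0: dG_ATP undefined")
    if comp.pi_total == 0.0:
        raise EquilibriumError("Pi = 0: dG_ATP undefined")
    adp = solve_adp(comp, params, mg_free_override=mg_free_override)
    if adp == 0.0:
        raise EquilibriumError("free ADP = 0 (Cr = 0?): dG_ATP diverges")
    mg = (
        mg_free_override
        if mg_free_override is not None
        else solve_free_mg(comp, params, adp_total=adp, tol=1e-12)
    )
    rt = GAS_CONSTANT_KJ * comp.temperature
    dg0 = delta_g0_atp(params, comp.ph, mg, comp.temperature)
    return dg0 + rt * math.log(adp * comp.pi_total / comp.atp_total)


@dataclass(frozen=True)
class ClampPoint:
    """One PCr step of a titration."""

    pcr_added: float  # mol/L
    adp_free: float  # mol/L
    atp_adp_ratio: float
    dg_atp: float  # kJ/mol
    source_label: str = ""


def titration_curve(
    comp: ClampComposition,
    pcr_levels: Sequence[float],
    params: ThermoParameterSet = DEFAULT_PARAMS,
) -> list[ClampPoint]:
    """Evaluate the clamp across a strictly increasing PCr series."""
    levels = list(pcr_levels)
    if not levels:
        raise ValidationError("pcr_levels must be non-empty")
    if any(p <= 0 for p in levels):
        raise ValidationError("pcr_levels must all be > 0")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValidationError("pcr_levels must be strictly increasing")
    points = []
    for pcr in levels:
        c = replace(comp, pcr=pcr)
        adp = solve_adp(c, params)
        points.append(
            ClampPoint(
                pcr_added=pcr,
                adp_free=adp,
                atp_adp_ratio=c.atp_total / adp if adp > 0 else math.inf,
                dg_atp=delta_g_atp(c, params),
                source_label=params.source_label,
            )
        )
    return points
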