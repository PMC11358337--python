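"""Dissolved-gas saturations, acid-base kinetics and charge-balance pH.

The SAB water phase exchanges CO2 and O2 with the atmosphere fast enough
(micron-scale film) that their dissolved concentrations sit at Henry-law
saturation at the interface temperature.  Bicarbonate and the organic-acid
anion are kinetic states relaxing toward acid-base equilibrium; the
hydrogen-ion concentration is algebraic, recomputed at every instant from
electroneutrality

    S_H + S_Cat = Kw/S_H + S_HCO3 + S_OA- + S_An,

which has the closed-form positive root S_H = (B + sqrt(B^2 + 4*Kw))/2 with
B = S_HCO3 + S_OA- + S_An - S_Cat.  Carbonate (CO3^2-) is neglected: it
matters only above pH ~10.

Concentrations are mol m^-3 throughout; pH is reported on the conventional
mol L^-1 scale (factor 1000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ChemistryParams:
    """Carbonate/organic-acid chemistry constants.

    Defaults: CO2/HCO3- pKa 6.36 and glycolic-acid pKa 3.83 on the molar
    scale (converted to mol m^-3); Henry constants and van 't Hoff slopes
    are standard freshwater values; acid-base rate constants are set fast
    relative to biology so speciation is near-equilibrium.
    """

    KH_CO2_ref: float = 34.0        # [mol m-3 atm-1] at T_ref
    KH_O2_ref: float = 1.3          # [mol m-3 atm-1] at T_ref
    vantHoff_CO2: float = 2400.0    # [K]
    vantHoff_O2: float = 1700.0     # [K]
    T_ref: float = 298.15           # [K]
    pCO2: float = 4.15e-4           # [atm]
    pO2: float = 0.209              # [atm]
    Ka_CO2: float = 1e3 * 10.0 ** (-6.36)   # [mol m-3] (pKa 6.36 molar)
    k_AB_CO2: float = 1e3           # [h-1]
    Ka_OA: float = 1e3 * 10.0 ** (-3.83)    # [mol m-3] (glycolic acid)
    k_AB_OA: float = 1e3            # [m3 mol-1 h-1]
    Kw: float = 1e-8                # [(mol m-3)^2], i.e. 1e-14 M^2
    S_An: float = 0.0               # inert anions [mol m-3]
    S_Cat: float = 0.0              # inert cations [mol m-3]

    def __post_init__(self) -> None:
        positive = ("KH_CO2_ref", "KH_O2_ref", "T_ref", "pCO2", "pO2",
                    "Ka_CO2", "k_AB_CO2", "Ka_OA", "k_AB_OA", "Kw")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.S_An < 0 or self.S_Cat < 0:
            raise ValueError("inert ion concentrations must be >= 0")


@dataclass(frozen=True)
class DerivedChemistry:
    """Instantaneous chemistry derived from state + forcing."""

    S_CO2: float     # dissolved CO2 at saturation [mol C m-3]
    S_O2: float      # dissolved O2 at saturation [mol m-3]
    S_HCO3: float    # bicarbonate [mol C m-3]
    S_DIC: float     # S_CO2 + S_HCO3 [mol C m-3]
    S_H: float       # hydrogen ion [mol m-3]
    pH: float        # -log10(S_H / 1000)
    a_w: float
    T_star: float    # [degC]


def henry_saturation(T_C: float, gas: str,
                     p: ChemistryParams = ChemistryParams()) -> float:
    """Henry-law saturation concentration [mol m-3] at temperature T [degC].

    KH(T) = KH_ref * exp(vantHoff * (1/T_K - 1/T_ref)); solubility falls
    with temperature for both gases.
    """
    if T_C <= -273.15:
        raise ValueError("temperature below absolute zero")
    if gas == "CO2":
        kh_ref, vh, pp = p.KH_CO2_ref, p.vantHoff_CO2, p.pCO2
    elif gas == "O2":
        kh_ref, vh, pp = p.KH_O2_ref, p.vantHoff_O2, p.pO2
    else:
        raise ValueError(f"unknown gas {gas!r}")
    T_K = T_C + 273.15
    return kh_ref * math.exp(vh * (1.0 / T_K - 1.0 / p.T_ref)) * pp


def solve_hydrogen(S_HCO3: float, S_OAminus: float,
                   p: ChemistryParams = ChemistryParams()) -> tuple[float, float]:
    """Closed-form hydrogen-ion concentration and pH from electroneutrality.

    Returns ``(S_H [mol m-3], pH)``.  The positive root always exists; the
    electroneutrality residual is at rounding level.
    """
    if S_HCO3 < 0 or S_OAminus < 0:
        raise ValueError("ionic concentrations must be >= 0")
    B = S_HCO3 + S_OAminus + p.S_An - p.S_Cat
    root = math.sqrt(B * B + 4.0 * p.Kw)
    # rationalized form for B < 0 avoids catastrophic cancellation
    S_H = 0.5 * (B + root) if B >= 0.0 else 2.0 * p.Kw / (root - B)
    return S_H, -math.log10(S_H / 1000.0)


def co2_hydration_rate(CO2_sat: float, S_H: float, S_HCO3: float,
                       p: ChemistryParams = ChemistryParams()) -> float:
    """Net CO2 hydration rate [mol m-3 h-1]; positive produces HCO3-.

    r = k_AB_CO2 * (CO2_sat - S_H*S_HCO3/Ka_CO2): dissolved CO2 (held at
    saturation) hydrates toward the equilibrium bicarbonate level set by
    the current pH.
    """
    return p.k_AB_CO2 * (CO2_sat - S_H * S_HCO3 / p.Ka_CO2)


def oa_dissociation_rate(S_TOA: float, S_OAminus: float, S_H: float,
                         p: ChemistryParams = ChemistryParams()) -> float:
    """Net organic-acid association rate [mol m-3 h-1].

    r = k_AB_OA * (S_OA- * (Ka_OA + S_H) - Ka_OA * S_TOA); positive r
    consumes the anion (association), negative r is net dissociation of the
    undissociated acid S_TOA - S_OA-.
    """
    if S_OAminus > S_TOA:
        raise ValueError("anion concentration cannot exceed total organic acid")
    return p.k_AB_OA * (S_OAminus * (p.Ka_OA + S_H) - p.Ka_OA * S_TOA)


def derive_chemistry(S_HCO3: float, S_OAminus: float, a_w: float, T_star: float,
                     p: ChemistryParams = ChemistryParams()) -> DerivedChemistry:
    """Assemble the instantaneous chemistry snapshot used by the metabolism."""
    S_CO2 = henry_saturation(T_star, "CO2", p)
    S_O2 = henry_saturation(T_star, "O2", p)
    S_H, pH = solve_hydrogen(S_HCO3, S_OAminus, p)
    return DerivedChemistry(S_CO2=S_CO2, S_O2=S_O2, S_HCO3=S_HCO3,
                            S_DIC=S_CO2 + S_HCO3, S_H=S_H, pH=pH,
                            a_w=a_w, T_star=T_star)
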