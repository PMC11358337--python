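"""Limitation factors and metabolic process rates for both guilds.

Every biological process rate has the Liebig form

    r_i = k_i * M_i * f_i,    f_i = min(phi_1, ..., phi_k),

where each limitation factor phi lies in [0, 1] and only the single most
limiting factor acts.  Cyanobacteria run non-cyclic and cyclic electron
transport, carbon fixation in competition with photorespiration (branching
function g_fix), nitrogen fixation, growth, polysaccharide secretion,
nighttime respiration and organic-acid reuptake.  Heterotrophs scavenge
polysaccharides and decayed biomass, take up dissolved organic acids, and
respire/grow on their stored-carbon quota with no light dependence.

Maintenance is an ATP drain that rises linearly as water activity falls;
when ATP production and reserves cannot cover it, decay is triggered in
proportion to the unmet fraction.  Decay moves functional biomass and its
quota cargo into the decayed-biomass pools.

All rate constants are per hour; intracellular reserves are Droop quotas
(mol per mol biomass carbon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chemistry import DerivedChemistry

# Process order shared with the stoichiometric matrix.  The *_d_* entries
# are the decay-cargo processes draining each quota pool of dying cells.
CYANO_PROCESSES = (
    "nc", "cy", "fix", "fix_co2", "photo", "photo_co2", "Nfix",
    "C_growth", "POLprod", "C_resp", "C_uptake", "C_main", "C_d",
    "C_d_soc", "C_d_n", "C_d_atp", "C_d_nadph",
)
HETERO_PROCESSES = (
    "POL_scav", "CDB_scav", "NDB_scav", "H_uptake",
    "H_resp", "H_growth", "H_main", "H_d",
    "H_d_soc", "H_d_n", "H_d_atp",
)
ABIOTIC_PROCESSES = ("co2_hydration", "oa_association")
PROCESS_ORDER = CYANO_PROCESSES + HETERO_PROCESSES + ABIOTIC_PROCESSES


@dataclass
class CyanoState:
    """Cyanobacterial functional biomass and intracellular quotas."""

    M_C: float            # functional biomass [mol C]
    Q_SOC: float          # stored organic carbon [mol C / mol C]
    Q_N: float            # bound nitrogen [mol N / mol C]
    Q_ATP: float          # [mol ATP / mol C]
    Q_NADPH: float        # [mol NADPH / mol C]

    def validate(self) -> None:
        if self.M_C < 0 or min(self.Q_SOC, self.Q_N, self.Q_ATP, self.Q_NADPH) < 0:
            raise ValueError("cyanobacterial state must be non-negative")


@dataclass
class HeteroState:
    """Heterotroph functional biomass and intracellular quotas."""

    M_H: float
    Q_SOC: float
    Q_N: float
    Q_ATP: float

    def validate(self) -> None:
        if self.M_H < 0 or min(self.Q_SOC, self.Q_N, self.Q_ATP) < 0:
            raise ValueError("heterotroph state must be non-negative")


@dataclass
class ExtracellularState:
    """Shared extracellular pools (amounts) and dissolved species."""

    M_POL: float          # polysaccharides [mol C]
    M_CDB: float          # carbon decayed biomass [mol C]
    M_NDB: float          # nitrogen decayed biomass [mol N]
    S_TOA: float          # total organic acids [mol C m-3]
    S_OAminus: float      # organic-acid anion [mol C m-3]
    S_HCO3: float         # bicarbonate [mol C m-3]

    def validate(self) -> None:
        if min(self.M_POL, self.M_CDB, self.M_NDB,
               self.S_TOA, self.S_OAminus, self.S_HCO3) < 0:
            raise ValueError("extracellular state must be non-negative")
        if self.S_OAminus > self.S_TOA * (1 + 1e-9) + 1e-12:
            raise ValueError("organic-acid anion cannot exceed total organic acid")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic, quota, yield and environmental-window parameters.

    Maximum rates are per hour in the currency of each process (see yield
    fields for the ATP/NADPH bookkeeping).  Defaults are order-of-magnitude
    choices producing day-scale dynamics; every value is configurable.
    """

    # maximum specific rates [currency (mol C biomass)-1 h-1]
    k_nc: float = 1.0             # non-cyclic ETC [mol NADPH]
    k_cy: float = 0.2             # basal cyclic ETC [mol ATP]
    dk_cy: float = 0.8            # stress increment of cyclic ETC [mol ATP]
    k_fix: float = 0.2            # carbon fixation + photorespiration [mol C]
    k_Nfix: float = 0.02          # nitrogen fixation [mol N]
    k_growth_C: float = 0.05      # cyanobacterial biosynthesis [mol C]
    k_pol: float = 0.02           # polysaccharide secretion [mol C]
    k_resp: float = 0.05          # respiration, both guilds [mol C]
    k_uptake: float = 1.0         # organic-acid uptake, both guilds [mol C]
    k_scav: float = 0.1           # heterotroph scavenging [mol C or mol N]
    k_growth_H: float = 0.05      # heterotroph biosynthesis [mol C]

    # photorespiration branching
    gamma_spec: float = 0.02      # inverse Rubisco specificity [-]

    # light response [uE m-2 s-1]
    K_I: float = 100.0
    K_I_inh: float = 3000.0       # photoinhibition constant (non-cyclic only)
    K_I_dark: float = 1.0         # darkness gate for respiration/OA reuptake

    # substrate half-saturations
    K_DIC: float = 0.005          # [mol m-3]
    K_TOA: float = 0.05           # [mol m-3]
    K_POL: float = 100.0          # [mol C m-3]
    K_CDB: float = 100.0          # [mol C m-3]
    K_NDB: float = 10.0           # [mol N m-3]

    # quota bounds and half-saturations
    Q_SOC_min: float = 0.05
    Q_SOC_max: float = 0.5
    Q_N_min: float = 0.02
    Q_N_max: float = 0.2
    Q_ATP_max: float = 0.1
    Q_NADPH_max: float = 0.1
    K_ATP: float = 0.01
    K_NADPH: float = 0.01

    # environmental windows
    a_w_min: float = 0.6          # metabolic suppression threshold
    a_w_peak: float = 0.8         # peak of osmotic-stress responses
    pH_L: float = 4.5
    pH_U: float = 9.5

    # maintenance and decay
    m0: float = 0.01              # baseline maintenance [mol ATP (mol C)-1 h-1]
    m1: float = 0.2               # maintenance slope vs (1 - a_w)
    k_d: float = 0.005            # maximum decay rate [h-1]

    # biofilm density
    rho: float = 4000.0           # [mol C m-3]

    # stoichiometric yields (energy currencies per process currency)
    y_ATP_nc: float = 1.3         # ATP per NADPH, non-cyclic ETC
    y_ATP_fix: float = 3.0        # ATP per C fixed (also photorespiration)
    y_NADPH_fix: float = 2.0
    y_ATP_Nfix: float = 2.0       # ATP per N fixed
    y_NADPH_Nfix: float = 1.0
    y_ATP_growth: float = 2.0     # ATP per C of new biomass
    y_NADPH_growth: float = 1.0   # cyanobacteria only
    y_ATP_pol: float = 0.2        # ATP per C secreted
    y_ATP_resp: float = 4.0       # ATP per C respired
    n_CN: float = 0.1             # N content of functional biomass [mol N / mol C]

    # strict-paper alternatives (see methods note)
    strict_decay_gamma: bool = False       # decay proportional to omega/f*_main
    strict_hetero_decay_mass: bool = False  # heterotroph decay scaled by M_C

    def __post_init__(self) -> None:
        for name in ("k_nc", "k_cy", "dk_cy", "k_fix", "k_Nfix", "k_growth_C",
                     "k_pol", "k_resp", "k_uptake", "k_scav", "k_growth_H",
                     "gamma_spec", "K_I", "K_I_inh", "K_I_dark", "K_DIC", "K_TOA", "K_POL",
                     "K_CDB", "K_NDB", "K_ATP", "K_NADPH", "m0", "m1", "k_d",
                     "rho", "n_CN"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.a_w_min < self.a_w_peak < 1.0:
            raise ValueError("require 0 < a_w_min < a_w_peak < 1")
        if self.pH_L >= self.pH_U:
            raise ValueError("require pH_L < pH_U")
        if not (0 < self.Q_SOC_min < self.Q_SOC_max
                and 0 < self.Q_N_min < self.Q_N_max):
            raise ValueError("quota minima must be below maxima")

    @property
    def max_rates(self) -> dict[str, float]:
        """Upper bound k_i for each bounded biological process."""
        return {
            "nc": self.k_nc, "cy": self.k_cy + self.dk_cy, "fix": self.k_fix,
            "photo": self.k_fix, "Nfix": self.k_Nfix,
            "C_growth": self.k_growth_C, "POLprod": self.k_pol,
            "C_resp": self.k_resp, "C_uptake": self.k_uptake,
            "POL_scav": self.k_scav, "CDB_scav": self.k_scav,
            "NDB_scav": self.k_scav, "H_uptake": self.k_uptake,
            "H_resp": self.k_resp, "H_growth": self.k_growth_H,
        }


@dataclass
class ProcessRates:
    """All process rates plus per-process limitation diagnostics."""

    rates: dict[str, float] = field(default_factory=dict)
    limiting: dict[str, str] = field(default_factory=dict)   # argmin factor name
    f: dict[str, float] = field(default_factory=dict)        # combined factor


# ---------------------------------------------------------------------------
# limitation primitives
# ---------------------------------------------------------------------------

def combine_limitations(phis: dict[str, float]) -> tuple[float, str]:
    """Liebig combination: the minimum factor and its name."""
    if not phis:
        raise ValueError("need at least one limitation factor")
    for name, phi in phis.items():
        if not 0.0 <= phi <= 1.0:
            raise ValueError(f"limitation factor {name} = {phi} outside [0, 1]")
    name = min(phis, key=phis.get)
    return phis[name], name


def aw_ramp(a_w: float, a_w_min: float) -> float:
    """Linear rise from 0 at the suppression threshold to 1 at a_w = 1."""
    return min(max((a_w - a_w_min) / (1.0 - a_w_min), 0.0), 1.0)


def aw_tent(a_w: float, a_w_min: float, a_w_peak: float) -> float:
    """Osmotic-stress response: 0 at the threshold, 1 at the peak, 0 at 1."""
    if a_w <= a_w_min:
        return 0.0
    if a_w <= a_w_peak:
        return (a_w - a_w_min) / (a_w_peak - a_w_min)
    return max((1.0 - a_w) / (1.0 - a_w_peak), 0.0)


def light_response(I: float, K_I: float, K_I_inh: float | None = None) -> float:
    """Light limitation: Monod, or normalized Haldane with photoinhibition."""
    if I < 0:
        raise ValueError("light intensity must be >= 0")
    if K_I_inh is None:
        return I / (K_I + I)
    I_opt = math.sqrt(K_I * K_I_inh)
    peak = I_opt / (2.0 * K_I + I_opt)
    return (I / (K_I + I + I * I / K_I_inh)) / peak


def darkness(I: float, K_I: float) -> float:
    """Night-activation factor for respiration and organic-acid reuptake."""
    return K_I / (K_I + I)


def ph_window(pH: float, pH_L: float, pH_U: float) -> float:
    """Cardinal pH bump: 0 outside [pH_L, pH_U], 1 at the midpoint."""
    if pH_L >= pH_U:
        raise ValueError("require pH_L < pH_U")
    half = 0.5 * (pH_U - pH_L)
    val = (pH - pH_L) * (pH_U - pH) / (half * half)
    return min(max(val, 0.0), 1.0)


def monod(x: float, K: float) -> float:
    return max(x, 0.0) / (K + max(x, 0.0))


def droop(Q: float, Q_min: float) -> float:
    """Droop quota factor clip(1 - Q_min/Q, 0, 1)."""
    if Q <= 0.0:
        return 0.0
    return min(max(1.0 - Q_min / Q, 0.0), 1.0)


def room(Q: float, Q_max: float) -> float:
    """Remaining storage capacity clip(1 - Q/Q_max, 0, 1)."""
    return min(max(1.0 - Q / Q_max, 0.0), 1.0)


def branching_fraction(S_O2: float, S_DIC: float, gamma_spec: float) -> float:
    """Photorespiration branching g_fix = 1/(1 + gamma*S_O2/S_DIC)."""
    if S_DIC <= 0.0:
        return 0.0
    if S_O2 < 0.0:
        raise ValueError("S_O2 must be >= 0")
    return 1.0 / (1.0 + gamma_spec * S_O2 / S_DIC)


def maintenance_requirement(a_w: float, m0: float, m1: float) -> float:
    """Total maintenance demand f*_main = m0 + m1*(1 - a_w) [mol ATP/mol C/h]."""
    return m0 + m1 * (1.0 - a_w)


def maintenance_and_decay(omega: float, f_star_main: float, Q_ATP: float,
                          k_d: float, K_ATP: float,
                          strict_gamma: bool = False) -> tuple[float, float]:
    """Realized maintenance rate and specific decay rate.

    Sufficiency s = min(1, (omega/f*_main) * Q_ATP/(K_ATP + Q_ATP)) gates on
    both ATP production and the stored pool.  When maintenance is fully met
    (s = 1) there is no decay; otherwise maintenance falls back to the
    ATP-gated production rate and decay is proportional to the unmet
    fraction, f_d = k_d*(1 - s).  With ``strict_gamma`` the decay factor is
    instead proportional to omega/f*_main itself (the form as printed).
    """
    if min(omega, f_star_main, Q_ATP, k_d, K_ATP) < 0:
        raise ValueError("maintenance inputs must be >= 0")
    if f_star_main == 0.0:
        return 0.0, 0.0
    sigma = Q_ATP / (K_ATP + Q_ATP)
    s = min(1.0, (omega / f_star_main) * sigma)
    f_main = f_star_main if s >= 1.0 else omega * sigma
    if strict_gamma:
        f_d = k_d * min(omega / f_star_main, 1.0)
    else:
        f_d = k_d * (1.0 - s)
    return f_main, f_d


# ---------------------------------------------------------------------------
# guild rate evaluation
# ---------------------------------------------------------------------------

def cyano_rates(cy: CyanoState, ex: ExtracellularState, chem: DerivedChemistry,
                I: float, p: KineticParams,
                out: ProcessRates | None = None) -> ProcessRates:
    """All cyanobacterial process rates (Liebig-limited) plus diagnostics."""
    pr = out if out is not None else ProcessRates()
    M = cy.M_C
    if M <= 0.0:
        for name in CYANO_PROCESSES:
            pr.rates[name] = 0.0
        return pr

    a_w = chem.a_w
    ramp = aw_ramp(a_w, p.a_w_min)
    tent = aw_tent(a_w, p.a_w_min, p.a_w_peak)
    l_monod = light_response(I, p.K_I)
    l_haldane = light_response(I, p.K_I, p.K_I_inh)
    dark = darkness(I, p.K_I_dark)
    atp_room = room(cy.Q_ATP, p.Q_ATP_max)
    nadph_room = room(cy.Q_NADPH, p.Q_NADPH_max)
    soc_room = room(cy.Q_SOC, p.Q_SOC_max)

    def rate(name: str, k: float, phis: dict[str, float]) -> float:
        f, argmin = combine_limitations(phis)
        r = k * M * f
        pr.rates[name] = r
        pr.limiting[name] = argmin
        pr.f[name] = f
        return r

    # light-dependent phase
    r_nc = rate("nc", p.k_nc, {
        "a_w": ramp, "light": l_haldane, "ATP_room": atp_room,
        "NADPH_room": nadph_room,
    })
    f_cy1, arg1 = combine_limitations(
        {"a_w": ramp, "light": l_monod, "ATP_room": atp_room})
    f_cy2, arg2 = combine_limitations(
        {"a_w_stress": tent, "light": l_monod, "ATP_room": atp_room})
    r_cy = p.k_cy * M * f_cy1 + p.dk_cy * M * f_cy2
    pr.rates["cy"] = r_cy
    pr.limiting["cy"] = arg1 if p.k_cy * f_cy1 >= p.dk_cy * f_cy2 else arg2
    pr.f["cy"] = r_cy / ((p.k_cy + p.dk_cy) * M)

    # light-independent phase: fixation vs photorespiration share one factor;
    # inorganic carbon is drawn from bicarbonate and dissolved CO2 in
    # proportion to their shares of DIC (CO2 is atmosphere-replenished)
    g_fix = branching_fraction(chem.S_O2, chem.S_DIC, p.gamma_spec)
    f_fix, arg_fix = combine_limitations({
        "a_w": ramp, "light": l_monod, "DIC": monod(chem.S_DIC, p.K_DIC),
        "ATP": monod(cy.Q_ATP, p.K_ATP), "NADPH": monod(cy.Q_NADPH, p.K_NADPH),
        "SOC_room": soc_room, "pH": ph_window(chem.pH, p.pH_L, p.pH_U),
    })
    hco3_share = chem.S_HCO3 / chem.S_DIC if chem.S_DIC > 0.0 else 0.0
    hco3_share = min(max(hco3_share, 0.0), 1.0)
    r_fix_tot = g_fix * p.k_fix * M * f_fix
    r_photo_tot = (1.0 - g_fix) * p.k_fix * M * f_fix
    pr.rates["fix"] = hco3_share * r_fix_tot
    pr.rates["fix_co2"] = (1.0 - hco3_share) * r_fix_tot
    pr.rates["photo"] = hco3_share * r_photo_tot
    pr.rates["photo_co2"] = (1.0 - hco3_share) * r_photo_tot
    for name in ("fix", "fix_co2", "photo", "photo_co2"):
        pr.limiting[name] = arg_fix
        pr.f[name] = f_fix

    rate("Nfix", p.k_Nfix, {
        "a_w": ramp, "ATP": monod(cy.Q_ATP, p.K_ATP),
        "NADPH": monod(cy.Q_NADPH, p.K_NADPH), "N_room": room(cy.Q_N, p.Q_N_max),
    })
    rate("C_growth", p.k_growth_C, {
        "SOC": droop(cy.Q_SOC, p.Q_SOC_min), "N": droop(cy.Q_N, p.Q_N_min),
        "ATP": monod(cy.Q_ATP, p.K_ATP), "NADPH": monod(cy.Q_NADPH, p.K_NADPH),
        "light": l_monod, "a_w": ramp,
    })
    rate("POLprod", p.k_pol, {
        "a_w_stress": tent, "SOC": droop(cy.Q_SOC, p.Q_SOC_min),
    })
    r_resp = rate("C_resp", p.k_resp, {
        "a_w": ramp, "darkness": dark, "SOC": droop(cy.Q_SOC, p.Q_SOC_min),
        "ATP_room": atp_room,
    })
    rate("C_uptake", p.k_uptake, {
        "a_w": ramp, "darkness": dark, "TOA": monod(ex.S_TOA, p.K_TOA),
        "SOC_room": soc_room,
    })

    # maintenance and decay from the ATP budget
    omega = (p.y_ATP_nc * r_nc + r_cy + p.y_ATP_resp * r_resp) / M
    f_star = maintenance_requirement(a_w, p.m0, p.m1)
    f_main, f_d = maintenance_and_decay(omega, f_star, cy.Q_ATP, p.k_d, p.K_ATP,
                                        p.strict_decay_gamma)
    pr.rates["C_main"] = M * f_main
    r_d = M * f_d
    pr.rates["C_d"] = r_d
    pr.rates["C_d_soc"] = cy.Q_SOC * r_d
    pr.rates["C_d_n"] = cy.Q_N * r_d
    pr.rates["C_d_atp"] = cy.Q_ATP * r_d
    pr.rates["C_d_nadph"] = cy.Q_NADPH * r_d
    return pr


def hetero_rates(h: HeteroState, ex: ExtracellularState, chem: DerivedChemistry,
                 I: float, V: float, p: KineticParams,
                 out: ProcessRates | None = None,
                 M_C: float | None = None) -> ProcessRates:
    """All heterotroph process rates; light-independent throughout."""
    pr = out if out is not None else ProcessRates()
    M = h.M_H
    if M <= 0.0:
        for name in HETERO_PROCESSES:
            pr.rates[name] = 0.0
        return pr
    if V <= 0.0:
        raise ValueError("SAB volume must be positive")

    a_w = chem.a_w
    ramp = aw_ramp(a_w, p.a_w_min)
    atp_room = room(h.Q_ATP, p.Q_ATP_max)
    soc_room = room(h.Q_SOC, p.Q_SOC_max)

    def rate(name: str, k: float, phis: dict[str, float]) -> float:
        f, argmin = combine_limitations(phis)
        r = k * M * f
        pr.rates[name] = r
        pr.limiting[name] = argmin
        pr.f[name] = f
        return r

    rate("POL_scav", p.k_scav, {
        "a_w": ramp, "POL": monod(ex.M_POL / V, p.K_POL), "SOC_room": soc_room,
    })
    rate("CDB_scav", p.k_scav, {
        "a_w": ramp, "CDB": monod(ex.M_CDB / V, p.K_CDB), "SOC_room": soc_room,
    })
    rate("NDB_scav", p.k_scav, {
        "a_w": ramp, "NDB": monod(ex.M_NDB / V, p.K_NDB),
        "N_room": room(h.Q_N, p.Q_N_max),
    })
    rate("H_uptake", p.k_uptake, {
        "a_w": ramp, "TOA": monod(ex.S_TOA, p.K_TOA), "SOC_room": soc_room,
    })
    r_resp = rate("H_resp", p.k_resp, {
        "a_w": ramp, "SOC": droop(h.Q_SOC, p.Q_SOC_min), "ATP_room": atp_room,
    })
    rate("H_growth", p.k_growth_H, {
        "SOC": droop(h.Q_SOC, p.Q_SOC_min), "N": droop(h.Q_N, p.Q_N_min),
        "ATP": monod(h.Q_ATP, p.K_ATP), "a_w": ramp,
    })

    omega = p.y_ATP_resp * r_resp / M
    f_star = maintenance_requirement(a_w, p.m0, p.m1)
    f_main, f_d = maintenance_and_decay(omega, f_star, h.Q_ATP, p.k_d, p.K_ATP,
                                        p.strict_decay_gamma)
    pr.rates["H_main"] = M * f_main
    # Heterotroph decay is printed scaled by the cyanobacterial mass; the
    # default uses M_H (presumed typo).  The printed form needs a depletion
    # gate: a flux independent of M_H would push the pool through zero.
    if p.strict_hetero_decay_mass and M_C is not None:
        mass_d = M_C * M / (M + 1e-6 * max(M_C, 1e-300))
    else:
        mass_d = M
    r_d = mass_d * f_d
    pr.rates["H_d"] = r_d
    pr.rates["H_d_soc"] = h.Q_SOC * r_d
    pr.rates["H_d_n"] = h.Q_N * r_d
    pr.rates["H_d_atp"] = h.Q_ATP * r_d
    return pr
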