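# Methods

## Scope and state

`sabsim` models a thin subaerial biofilm (SAB) as a spatially homogeneous
biofilm–water layer of constant thickness λ on impermeable stone.  The
state vector holds 15 extensive quantities: cyanobacterial functional
biomass M_C with four quota pools in product form (E = M·Q for stored
organic carbon, bound nitrogen, ATP, NADPH), heterotroph biomass M_H with
three quota pools, the shared solid pools (polysaccharides M_POL, carbon
and nitrogen decayed biomass M_CDB/M_NDB) and dissolved amounts
A = V·S for total organic acid, its anion, and bicarbonate.  The water
volume is V = M/ρ with M the total solid mass and ρ a constant biofilm
density (default 4000 mol C m⁻³, i.e. roughly 5 % dry carbon at unit
specific gravity); growth therefore expands the colonized area, not the
thickness.

Integrating extensive variables rather than quotas/concentrations makes
elemental bookkeeping exact and absorbs volume change without explicit
dilution terms; quotas (Q = E/M, with a 10⁻¹² mass guard) and
concentrations (S = A/V) are derived outputs.

## Process kinetics

Every biological rate is Liebig-limited, `r_i = k_i·M_i·min(φ_1…φ_k)`:
only the single scarcest factor acts, so simultaneous mild limitations do
not compound.  The factor library is:

* `aw_ramp` — linear from 0 at a_w_min (default 0.6, the experimentally
  motivated suppression threshold) to 1 at a_w = 1; used by all
  "ordinary" metabolism.
* `aw_tent` — 0 at a_w_min, peak 1 at a_w_peak (default 0.8), back to 0
  at pure water; used for the osmotic-stress responses (the increment of
  cyclic electron transport, polysaccharide secretion).
* light — Monod in intensity (half-saturation K_I = 100 µE m⁻² s⁻¹); the
  non-cyclic chain uses a Haldane form normalized to peak 1 at
  I = √(K_I·K_I_inh) to represent PSII photoinhibition
  (K_I_inh = 3000 µE m⁻² s⁻¹).
* `darkness` — K_I_dark/(K_I_dark + I) with K_I_dark = 1 µE m⁻² s⁻¹,
  gating respiration and organic-acid re-uptake by cyanobacteria.  The
  gate is deliberately much sharper than the photosynthetic light
  response: these are nighttime processes, and a loose gate would let
  cyanobacteria re-absorb photorespiratory acids in daylight, erasing the
  daytime acid accumulation that drives the ecosystem's pH dynamics.
* quota factors — Droop `1 − Q_min/Q` for consuming a reserve, Monod in
  Q for energy carriers, and "room" factors `1 − Q/Q_max` that stop
  production when a pool is full (these keep all quotas inside their
  configured bounds by construction).
* `ph_window` — a normalized parabolic bump on [pH_L, pH_U] (default
  4.5–9.5), applied to carbon fixation.

Carbon fixation and photorespiration share one limitation evaluation and
are split by the branching function g_fix = 1/(1 + γ·S_O2/S_DIC) with
γ = 0.02 (the inverse of a Rubisco-like specificity of ~50), giving
roughly three quarters of the flux to fixation at air-equilibrated
oxygen.

### Maintenance and decay

The maintenance ATP demand per unit biomass is f*_main = m0 + m1·(1−a_w)
(defaults 0.01 and 0.2 mol ATP (mol C)⁻¹ h⁻¹).  With ω the guild's total
specific ATP production rate and σ = Q_ATP/(K_ATP+Q_ATP) a gate on the
stored pool, sufficiency is s = min(1, (ω/f*_main)·σ).  Maintenance
proceeds at f*_main when s = 1, otherwise at ω·σ, and decay runs at
k_d·(1−s): decay is proportional to the *unmet* fraction of the demand.
The source equations label ω/f*_main itself the "missing energy rate";
read literally that would make decay largest when maintenance is best
covered, so the complementary form is the default and the literal form
is available behind `strict_decay_gamma`.  Similarly the printed
heterotroph decay rate is scaled by the cyanobacterial mass; the default
uses the heterotroph's own mass (`strict_hetero_decay_mass` restores the
printed form, with a smooth depletion gate — a decay flux independent of
M_H would otherwise push the pool through zero and stall the stiff
solver).

Decay moves functional biomass into M_CDB with its structural nitrogen
(n_CN = 0.1 mol N per mol C) into M_NDB.  Because a dying cell also
carries its reserves, four "cargo" processes per guild drain each quota
pool at Q·r_d (SOC→CDB, N→NDB; ATP and NADPH are lost).  Cargo processes
have unit stoichiometric coefficients and state-dependent rates, keeping
the stoichiometric matrix constant.

## Stoichiometry and conservation

One matrix column per process; ATP/NADPH rows carry no elemental content
(pure energy currencies), and the organic-acid-anion row carries none
because its carbon is already counted in the total-organic-acid row
(S_OA = S_TOA − S_OA⁻ is speciation, not a separate pool).  Functional
biomass carries 1 C and n_CN N per mole.  Virtual CO₂, O₂ and N₂ gas
rows are appended; the CO₂ and N₂ entries of every column are *solved*
from its carbon and nitrogen balance at build time, so per-column closure
is exact by construction and `elemental_audit` residuals are zero.
Trajectory-level conservation is then a real test: integrating the
virtual-row fluxes as quadrature states alongside the ODEs, the change
in tracked carbon (nitrogen) matches the accumulated CO₂ (N₂) exchange
to solver tolerance.

### Inorganic-carbon routing

Respiration releases its carbon as bicarbonate (charge-coupled to
nighttime acid re-uptake), while fixation and photorespiration draw
inorganic carbon from dissolved CO₂ and bicarbonate *in proportion to
their instantaneous shares of DIC* — implemented as paired processes
(`fix`/`fix_co2`, `photo`/`photo_co2`) with constant coefficients and a
state-dependent split.  Routing all fixation through the bicarbonate
state alone would overdraw a pool that holds only ~10⁻⁶ of the daily
biological flux; the proportional split keeps the pool non-negative
while preserving the morning pH rise from bicarbonate drawdown.
Dissolved CO₂ and O₂ themselves are algebraic, pinned at Henry-law
saturation at the interface temperature (van 't Hoff temperature
dependence; defaults are standard freshwater values: 34 mol m⁻³ atm⁻¹ /
2400 K for CO₂, 1.3 mol m⁻³ atm⁻¹ / 1700 K for O₂, pCO₂ = 415 µatm).

## Chemistry and pH

Bicarbonate relaxes toward equilibrium with saturated CO₂ at rate
k_AB_CO2·(CO2_sat − S_H·S_HCO3/Ka_CO2); the organic acid (glycolic,
pKa 3.83) speciates analogously.  Both rate constants default to
10³ h⁻¹-scale so speciation is fast relative to biology — in the large
k_AB limit the simulated bicarbonate tracks its equilibrium value to
well under 1 %.  H⁺ is not a state: electroneutrality is solved in
closed form at every right-hand-side evaluation,
S_H = (B + √(B²+4K_w))/2 with B the net non-water anion excess, using
the rationalized form when B < 0 to avoid cancellation.  Concentrations
are mol m⁻³ throughout; pH is reported on the conventional molar scale
(Ka values are entered as molar pKa and converted).  Carbonate ion is
neglected (relevant only above pH ~10); inert ions S_An/S_Cat default to
zero.

## Microclimate

T* = (T_a·k_a·λ + T_s·δ·k_b)/(λ·k_a + δ·k_b) from matching steady
diffusive heat flux across the boundary layer (δ = 1 mm, k_a = 0.026)
and the film (λ = 15 µm, k_b = 0.6, water-like).  Only the ratio of the
transport coefficients matters; with the default geometry T* is within
a millikelvin of the stone temperature.  Water activity uses the Magnus
saturation curve (b = 17.62, c = 243.12 °C) and is clipped to [0, 1];
both quantities are evaluated quasi-statically, assuming heat and vapor
exchange are fast relative to biology.  Transient evaporation/
condensation, EPS water retention and stone water storage are out of
scope.

## Forcing

A forcing is one 24 h-periodic day (time, air and stone temperature, air
relative humidity, light), sampled by piecewise-linear interpolation
with periodic wrap — a measured day that does not close on itself keeps
its wrap-point jump, which the stiff integrator smooths.  The synthetic
generator emulates a clear-sky day on insolated stone: sinusoidal air
temperature with minimum at 05:00 and maximum at 17:00, half-sine light
between sunrise and sunset, stone temperature blending from
T_a − night_offset to T_a + day_offset with insolation, and humidity
from a fixed dewpoint.  The four presets (summer 20–33 °C / 2000 µE,
spring 10–24 °C / 1600 µE, autumn 8–18 °C / 1000 µE, winter 0–8 °C /
700 µE, with matching dewpoints and stone offsets) produce mean daily
water activity increasing monotonically from summer to winter, with
summer/spring showing deep midday suppression and winter remaining
above the viability threshold all day.

What the generator does **not** emulate: weather variability between
days, cloud cover, rain and dew deposition events, wind-driven changes
in the boundary layer, or seasonal day-length asymmetry beyond the
sunrise/sunset parameters.  Tests passing on synthetic forcing therefore
demonstrate the model's mechanisms (activity windows, acid/pH coupling,
seasonal ordering), not quantitative agreement with any field site.

## Integration and the periodic state

`scipy.integrate.solve_ivp` with LSODA (BDF available), rtol 10⁻⁶ and
per-state atol 10⁻⁹·scale; the forcing is evaluated inside the RHS (no
operator splitting), and small solver-induced negative excursions are
clipped only for rate evaluation.  Output is sampled on a fixed 6-minute
grid.  Under periodic forcing the intensive sub-state (all quotas and
concentrations) converges to a 24 h orbit while total biomass changes by
a constant daily factor; `detect_periodic_state` declares periodicity
when consecutive daily profiles agree within a relative L∞ tolerance
(default 10⁻³), excluding biomasses, whose daily multiplicative
increment is reported as the growth factor.  On the default summer
preset the orbit is reached after roughly 70 simulated days (the
approach is slow because the community is near-marginal); the default
horizon is 60 days and scenario tests use 15–80 days, sizes chosen to
pass the periodicity/ordering checks while keeping a full suite run in
minutes.

Extinction is flagged when living functional biomass M_C + M_H falls
below 10⁻⁶ of its initial value.  Total solid mass is *not* used: dead
material and polysaccharides have no abiotic sink and can outlast the
community, so a total-mass criterion could never fire exactly when the
living film dies.

## Numerical studies

Three scenario runners mirror the model's intended experiments:
`single_day` (one forcing to approximate periodic state), `ablation`
(identical configuration with the heterotroph inoculum M_H,0 = 0.008·M_0
versus 0) and `seasons` (the four presets).  With the default
parameterization the ablation reproduces the expected ecology: without
heterotrophs, photorespiratory acids accumulate through the morning
until the pH window throttles fixation (minimum pH ≈ 4.5 versus ≈ 5.1
with heterotrophs), mean dissolved acid is an order of magnitude higher,
more polysaccharide and decayed material accumulates, and daily growth
is lower — heterotrophs act as a pH-stabilizing waste-removal guild.

## Parameter provenance and limitations

Chemistry, microclimate and the two printed anchors (carbonate pKa 6.36;
a_w suppression threshold 0.6) are fixed by standard constants or the
source narrative.  The kinetic maxima, half-saturations, quota bounds
and yields are order-of-magnitude defaults chosen to produce day-scale
dynamics (growth ~0.05 h⁻¹, fixation ~0.2 h⁻¹, decay 0.005 h⁻¹, fast
small-molecule uptake ~1 h⁻¹); they are exposed in the `[kinetics]`
config block and none is claimed as a measured value.  There is no
direct temperature dependence of metabolic rates (temperature acts only
through water activity and gas solubility), no photoacclimation or
PSII damage–repair kinetics, no spatial structure or thickness
dynamics, no stone chemistry, and no stochasticity — the model is fully
deterministic.
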