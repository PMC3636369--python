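# Methods

This note records the model equations as implemented, the defaults and
units of the parameters that matter, the numerical scheme, what the
synthetic fixture does and does not emulate, and the design choices made
where the design was genuinely open.

## Compartment model

Every biosphere object is a set of ten internally homogeneous
compartments (lower regolith; aquatic and terrestrial mid/upper regolith;
litter; surface water; aquatic and terrestrial primary producers;
atmosphere). All state is total activity per compartment (Bq); time is in
years (calendar years CE, negative = BC); all transfers are first-order
rates (a⁻¹) on total inventories. The model is strictly linear: doses
scale exactly with the release, which is what makes unit-release dose
conversion factors meaningful.

**Sorption.** Each solid-bearing compartment partitions its inventory
between pore water and solids at equilibrium: dissolved fraction
`V_w / (V_w + K_d M)` with `K_d` in m³ kg⁻¹ dw. The surface-water
compartment uses suspended solids (`c_ss · V_w`) as its solid phase.
Consequences: a water flux `Q` leaving a compartment moves only the
dissolved share (`k = Q / (V_w + K_d M)` — sorption retards transport);
diffusion acts on pore-water concentration differences with conductance
`G = D_e A / L` (rates `G/cap` on each side, zero net flux at equal
pore-water concentrations); sedimentation removes the sorbed share of the
water column (`k_sed = F_sed A K_d,w / cap_w`) and resuspension returns
the sorbed share of the upper sediment.

**Biota.** Uptake is production-driven: newly produced biomass
equilibrates with its medium (upper terrestrial regolith for plants,
water for aquatic producers) at concentration ratio CR, giving an uptake
flux `P · CR · C_medium` and a turnover return `P / B` (to litter on
land; split between water and upper sediment in the aquatic food web,
default 0.5/0.5, configurable). Producer compartments are carried in
kg C; at steady state the producer concentration approaches
`CR · C_medium / (1 + λB/P)`, i.e. the CR equilibrium whenever turnover
is fast against decay.

**Decay chains.** Chains are solved jointly. In activity units the
daughter gains `b · λ_d` per unit parent activity in the same
compartment (`b` = branching fraction). Cumulative decayed, ingrown and
exported activities are integrated as auxiliary linear states, so the
balance *injected + ingrown = inventory + decayed + exported* holds to
integrator precision at every output time and the audit is exact rather
than post hoc.

**Landscape coupling.** Inter-object transport couples only the WATER
compartments. Outflowing surface water carries the total water-column
concentration (dissolved plus suspended-particle-bound), so the edge rate
is `Q / V_w`; this equals the retarded advective form when the outflow
carries suspended solids at the water-column concentration. While an
object is a sea basin (stage weight `w_sea`) it exchanges bidirectionally
with the coastal basin, scaled by `w_sea`; its downstream drainage edges
are scaled by `1 − w_sea`; edges into the outlet sink are always active.
The outlet is an absorbing external sink tracked in the export ledger, as
is each object's atmospheric vent. Deep groundwater does not flow between
objects: each release enters its target object's lower regolith directly.

## Succession

A `SuccessionSchedule` gives each object an isolation window
(`isolation_start → isolation_end`, default width 500 a), a wetland
completion time `wetland_by` (default `isolation_end + 1000 a`; the field
is needed to pin the lake→wetland ramp and is a package addition), and an
optional agricultural conversion time (1-a ramp, so weights stay
continuous). Stage weights are piecewise linear, non-negative and sum to
one. Geometry follows the same ramps: the aquatic area shrinks from the
whole object (submerged) to a lake and then a residual stream; the
terrestrial area is the complement. A fully submerged object has
zero-size terrestrial compartments, which are decoupled from the matrix;
the entire deep-regolith flux then feeds the aquatic sediments. Wetland
growth transfers inventory from the aquatic mid/upper regolith to the
terrestrial counterparts at `max(0, −dA_aq/dt)/A_aq`; the shrinking water
volume itself is handled by the water-balance fluxes, not by this term.

Climate periods default to a temperate (interglacial) period of 18 400 a
(−9000 to 9400) followed by 50 200 a of periglacial conditions. Glacial
exposure re-uses the submerged-stage doses of the temperate run (sea-food
ingestion under maximum dilution). During periglacial conditions the
release to the biosphere is scaled by a configurable factor (default 0 —
deep permafrost blocks discharge; a scenario choice, not physics), and
the periglacial LDF derives from the residual inventory carried over from
the temperate period.

## Dose assessment

The representative individual of the most exposed group lives on one
object with full occupancy and takes all water and food from it. Defaults
(adult, annual): drinking water 0.6 m³, diet 110 kg C split
crops 0.6 / game 0.1 / fish 0.3, breathing 8100 m³, dust load 5×10⁻⁸
kg m⁻³, water occupancy 0.02. Foods exist only in the stages that produce
them (fish: sea+lake; game: wetland; crops: agricultural); the diet
renormalises toward available foods, and intake of any food is capped by
the object's production times an edible fraction (crops 0.5, game 0.02,
fish 0.1 of net primary production) — if all substitutes are exhausted
the total intake is reduced and a warning logged. Drinking water comes
from the object's surface water; a drilled-well pathway is not modelled.
Doses sum over all chain members and are attributed to the released
parent. Dose coefficients are constants (never sampled).

The LDF of a period is the maximum of the total annual dose over all
objects and output times in that period for a unit constant release; the
pulse LDF normalises by a unit pulse (default 1 Bq over 1 a, starting at
the beginning of the temperate period unless specified). The output grid
(default every 10 a) is the sampling resolution of that maximum; the
transport integration itself is refreshed at least yearly wherever
anything varies.

## Numerics

The system `dA/dt = K(t)A + S(t)` is propagated over segments on which
`K` and `S` are frozen at the segment midpoint and advanced exactly via
`expm` of the augmented matrix `[[K, S], [0, 0]]`. Segments are at most
one year long inside any interval where a parameter series or stage
weight changes (all series are piecewise linear, so constancy is decided
between global breakpoints) and span whole constant stretches otherwise,
with repeated exponentials cached. Because `K` is a proper rate matrix
(non-negative off-diagonal, column sums = −(decay + exports)), the
propagator is non-negative and the scheme is unconditionally stable for
the ~10-orders-of-magnitude rate spread (deep-till residence vs water
turnover); non-negativity is enforced with a clip tolerance of 1e-12 of
the state norm, and any larger negativity raises. Midpoint freezing is
second-order in the segment length; against the analytic Bateman chain
the integrator agrees to ~1e-10, and a frozen-parameter run converges to
the direct linear steady-state solve to ~1e-10. Near-equal decay
constants in the Bateman oracle are perturbed by 1 part in 1e9. Singular
steady-state systems report the trap compartments by name; structurally
absent compartments (all-zero rows/columns) are excluded from the solve.

## Synthetic fixture

The generator builds a drainage chain of 1–n objects (areas drawn
log-uniformly from 1–3×10⁵ m², seed-controlled), staggered isolation
times (1500 a apart from −8000), each draining into the next and finally
through a 10⁷ m² coastal basin to the outlet. Regolith: 4 m till
(ρ 2000 kg m⁻³, porosity 0.25), 1.5 m clay/gyttja (500, 0.7), 0.3 m
peat/active layer (150, 0.85). Hydrology: vertical deep-regolith flux
0.03 m a⁻¹ under terrestrial conditions, ×10⁻³ while submerged (vertical
fluxes under sea basins are minute), specific runoff 0.2 m a⁻¹, effective
diffusivity 0.01 m² a⁻¹. Particles: sedimentation 0.5→0.2 kg m⁻² a⁻¹
(sea→lake), resuspension 0.1→0.02, suspended solids 0.01→0.005 kg m⁻³.
Ecology: NPP 0.2 (terrestrial) and 0.05 (aquatic) kg C m⁻² a⁻¹, standing
biomass 1.0 and 0.1 kg C m⁻². The two reference nuclides keep realistic
half-life orders (1.57×10⁷ a and 1600 a) but **all chemistry and dose
coefficients are synthetic** order-of-magnitude values (e.g. Ra-like till
K_d 0.5 m³ kg⁻¹ vs I-like 10⁻³).

These conditions reproduce the structural behaviour the model is built
for — continuous succession without inventory jumps, retention and decay
losses of sorbing nuclides in the deep regolith (the fixture gives a
~10³ surface-water concentration ratio between the mobile and sorbing
reference nuclides), peat/soil accumulation, Kd-dominated sensitivity —
but they are not site data: absolute LDF values from the fixture
characterise the fixture, not any real site, and passing tests show
correctness of the mechanisms and bookkeeping, not predictive accuracy
for a licensed assessment.

## Problem sizes used in the shipped checks

The end-to-end checks run the three-object fixture over the full
18 400-a temperate period (output every 20 a plus yearly samples across
each isolation window and ±10⁻⁴ a straddles of every succession
breakpoint), a 10⁴-a decay-chain comparison at 201 points, and Monte
Carlo with n = 200 end-to-end LDF evaluations on the one-object fixture
at 50-a output resolution. These sizes were chosen as the smallest that
exercise every mechanism; all scale linearly if enlarged.

## Known limitations

- No spatial sub-gridding within a compartment and no nonlinear sorption
  isotherms; strictly first-order kinetics.
- The atmosphere is per-object and vents to an external sink; objects do
  not share air.
- Litter carries the upper-regolith K_d (its own sorption behaviour is
  not separately parameterised).
- No non-human biota dose, collective dose, or risk conversion.
- The landscape geometry (areas, depths, isolation times) is consumed as
  input, never predicted; no shoreline-displacement modelling.
- Sensitivity is sampling-based: simple random sampling by default (with
  the stream-prefix reproducibility property) or Latin hypercube, and
  Spearman rank correlation as the primary metric (robust to the
  log-scale spread of Kd/CR) with standardized rank regression
  coefficients as an option. No variance-based indices and no Bayesian
  parameter calibration.
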