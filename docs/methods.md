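# Methods

## Rule-based representation

Molecules are typed objects with named sites; each site carries exactly one
internal state drawn from its type's allowed list and at most one bond.
Localization is an ordinary site state (`IR.loc ~ mem/cyt`,
`GLUT4.loc ~ cyt/mem`). A chemical species is a connected site-graph taken
up to isomorphism; identity is decided by a canonical label computed by
iterative colour refinement (initial colour = molecule type + site states,
refined by the multiset of bonded-neighbour colours) followed by a
lexicographic tie-break over the orderings of each remaining colour class.
The tie-break enumerates automorphic orderings exhaustively, which is exact
and cheap for the complexes that arise here (at most three molecules); a
cap guards against pathological inputs.

Patterns are partial site-graphs with "don't care, don't write" semantics:
an unmentioned site matches any state and any bond; a mentioned site with
no bond mark must be unbound; `!+` means bound to an unspecified partner
and `!?` leaves the bond unconstrained. A rule aligns its reactant and
product pattern molecules positionally; aligned molecules of the same type
are edited (state set, bond add/delete), a type change or an unmatched
molecule means deletion/synthesis, and consumed or created molecules are
written last on their side. Reversible rules are single rules carrying a
second rate law and count once toward the rule total (this is the only way
42 rules can carry 101 parameters at ~2.4 parameters per rule).

Network generation applies every rule (both directions) to the growing
species set until a fixed point, with configurable caps (10,000 species /
50 sweeps by default) that raise an explicit closure error for
non-terminating rule sets such as unbounded polymerization. The species
order is seeds first, then discovery order; the canonical species *set* is
independent of rule order.

### Statistical factors

Deterministic reaction rates follow the BioNetGen convention. For each
ordered assignment of species to reactant slots, every embedding
combination is applied; outcomes with identical reactant and product
multisets are merged with their embedding count, then divided by (i) the
number of orderings of identical pattern slots and (ii) the automorphism
count of each reactant pattern. This yields the textbook results: a
homodimerization `A + A -> A2` carries flux `(k/2)·A²`, the dissociation of
a symmetric dimer carries `k·[A2]`, and a rule matching twice on a
symmetric substrate carries twice the single-site flux. The equality of
compiled ODEs with hand-written ones is asserted on every fixture.

## Rate laws

Two kinds only. Mass action multiplies a constant (possibly a product of
parameter symbols) by the reactant copy numbers and the statistical factor.
The Hill form multiplies the same mass-action core by
`X^n/(Kd^n + X^n)` — or `Kd^n/(Kd^n + X^n)` for inhibitory modulation —
where `X` is the copy number of a named observable (a pattern-defined sum
over species weighted by embedding multiplicity). Reading the modifier as
an observable rather than a single species keeps feedback strength
well-defined across complexes: the p70S6K feedback, for instance, reads
every Thr389-phosphorylated p70S6K copy regardless of context. `n` may be
a parameter or a structural literal; steps modelled as simple saturating
catalysis fix `n = 1` structurally, while steps with known or plausible
cooperativity (the IRS1 serine feedbacks, the AKT-phosphatase modulation,
the MAPK tier) expose the exponent as a parameter.

## The insulin-pathway model

The model integrates the three classical sub-models of insulin signalling
— receptor/PI3K/AKT/GLUT4, the amino-acid-gated TSC1/2-mTOR branch, and
the RAS-MAPK cascade — into one rule set of 42 rules, 101 parameters and
61 generated species. Structural choices worth recording:

* **Insulin and amino acids are constant (clamped) species.** The dose is
  set by the protocol (`nM × NA·V` molecules); zero dose leaves every
  trajectory flat because the listed initial conditions are the resting
  state (below).
* **IRS1** carries one Tyr site (gating PI3K/GRB2/SOS/SHP2 recruitment),
  one Ser site (the inhibitory integrator: phosphorylated basally, by PKC,
  and by p70S6K), and three binding sites. GRB2/SOS and SHP2 exclude each
  other; PI3K binds alongside GRB2/SOS; PI3K and SHP2 are kept exclusive.
  Binding requires Tyr-P and Ser-0; dissociation is state-agnostic, and
  serine phosphorylation additionally ejects GRB2/SOS and SHP2 (`k41`).
  Tyr dephosphorylation acts on fully unbound IRS1 only (bound partners
  shield the phosphotyrosine).
* **PDK1, PTP1B, SHIP2 and PTEN are implicit.** PDK1 is lumped into the
  PIP3-dependent AKT-Thr phosphorylation (PIP3 is the membrane docking
  site recruiting both kinase and substrate); the phosphatases appear as
  AKT-modulated inhibitory Hill factors on IRS1-Tyr and PIP3
  dephosphorylation. This keeps the phosphatase modulation mechanism while
  closing the network at exactly 61 species. For the same reason the
  lipid pool is two-state (PI(4,5)P2 / PI(3,4,5)P3), with the PI(3,4)P2
  intermediate folded into the degradation flux, and RAS deactivation by
  RASGAP is a first-order constant (`kcat27`).
* **AKT multi-site logic.** AKT phosphorylated at Thr (alone or doubly)
  acts on TSC1/2; AKT phosphorylated at Ser (alone or doubly) inactivates
  c-RAF; either site drives GLUT4 translocation. The "either site"
  semantics is an observable listing the patterns `AKT(T~P)` and
  `AKT(T~0,S~P)`, which counts the doubly phosphorylated form exactly
  once.
* **The ERK1/2→GRB2/SOS feedback is catalytic-arm inhibition.** Doubly
  phosphorylated ERK switches the GRB2/SOS `cat` site off (and `k_39`
  switches it back); binding to IRS1 is unaffected by the `cat` state, and
  RAS activation reads only `cat~on` complexes. Because the feedback
  never touches binding occupancy — and because nothing the PI3K-AKT
  branch reads depends on the GRB2/SOS or SHP2 state — removing this
  feedback leaves the GLUT4 trajectory identical to solver tolerance, a
  structural property the tests assert at 1e-6 relative. The p70S6K
  feedback, acting on IRS1 itself, reaches both endpoints.
* **Feedback removal** deletes the loop's rule(s); an alternative route
  zeroes the loop-specific rate constants, and the equality of the two is
  itself a test. Enhancement scales `k15` (p70S6K route) or `kcat39`
  (ERK route, with the ×10 variant exposed as a named perturbation rather
  than a default change).

### Units, pools and initial conditions

All amounts are molecules/cell. Molar values are multiplied by
`NA·V = 6.02214076e23 × 3e-12`; arbitrary units are anchored on IRS1
(1e5 molecules ≡ 100 AU, so 1 AU = 1000 molecules — mTORC2's 18.8 AU
becomes 18,800 copies); percentage concentrations map onto a total pool:
total GLUT4 and total lipids equal total IRS1, total PKC equals total AKT
(GLUT4 rests at 96 % cytosol / 4 % membrane). Receptor, IRS1 and PI3K
pools are set at 1e5 copies — the molecule-inventory scale — because
converting the historical sub-micromolar literature values through `NA·V`
would leave fewer than one molecule per cell.

The listed initial conditions are the insulin-free resting state of the
model with amino acids present, computed by relaxing the system to steady
state and frozen into the seed list. At rest, AMPK and TSC1/2 are fully
active, amino acids alone sustain ~10 % mTORC1 and ~14 % p70S6K activity,
and basal serine-kinase tone holds ~42 % of IRS1 Ser-phosphorylated.
Starting from rest means a zero-dose protocol produces flat trajectories
(verified to ~3e-5 relative over 60 min) and no simulation begins
mid-transient; an optional pre-equilibration flag re-derives the resting
state at run time and is a no-op by construction.

### Parameter values

Rate constants are expressed in 1/min (first order) and 1/(molecules·min)
(second order). Insulin binding uses the classical receptor association
rate (6e7 M⁻¹min⁻¹, i.e. 3.32e-5 after unit conversion) with a
nanomolar-scale dissociation constant; the remaining constants were chosen
once, at physiologically sensible orders of magnitude, and calibrated so
the model reproduces the established dynamic signatures of the pathway:
pAKT-S473 at steady state within 2–5 min; pmTOR-S2448 approaching steady
state on the 20–30 min scale; a ppERK1/2 transient peaking near 10 min and
relaxing most of the way back to baseline by 60 min (a behaviour that
requires both negative feedback loops); IRS1-proximal activities fast,
endpoint activities slow; and a monotone GLUT4 dose–response on
0.1–100 nM that the enhanced p70S6K feedback shifts downward everywhere.
Hill half-saturation constants sit inside the dynamic range of their
modifier observables — in particular `Kd_p70` lies below the stimulated
p70S6K level, so the serine feedback operates above half-saturation and a
steeper `n_p70` strengthens it. Calibration used only these qualitative
signatures; no parameter is fitted to quantitative trace data, and
parameter estimation is deliberately out of scope.

## Simulation and numerics

The network compiles to index arrays (stoichiometry matrix, reactant
indices, Hill tables); the right-hand side is evaluated vectorized and
integrated with LSODA at rtol 1e-8 / atol 1e-4 molecules on a 0.1 min
output grid over [0, 60] min by default. Copy numbers are clipped at zero
inside rate evaluations so transient solver undershoot cannot feed
negative amounts into fractional powers. Convergence is property-tested:
halving the tolerances changes the main observables by < 0.1 %, conserved
pools stay constant to 1e-6 relative, and trajectories stay above −atol.

## Sensitivity analysis

`s_i(t) = (∂y/∂λ_i)·λ_i/y(t)` is estimated with a one-sided forward
difference at `+0.1 %` of the parameter value (a central difference is
available and agrees within 1 % on the nonlinear fixtures — the
step-size robustness test). The overall coefficient averages the trapezoid
integral of `s_i` over the window and is reported in percent; averaging by
window length makes the constant-trace identity exact (`s ≡ c` gives
`S = c`) and puts coefficients on the percent scale of the ranked tables.
Grid points where the baseline output is below one molecule are masked and
excluded from the average rather than silently dropped. Report tables rank
parameters by |S| in the complete model (ties broken by name), drop rows
below 0.1 % absolute in every variant, and show a null marker where a
variant no longer contains a parameter because its rules were removed.
On the linear production–degradation fixture the numerical coefficient
matches the closed form to better than four significant digits.

## The toy-fixture generator

Four fixtures ship with hand-derived reference answers and serve as the
oracles for the engine: reversible binding (3 species, 2 reactions,
closed-form equilibrium), a two-site phosphoprotein (2² = 4 species,
8 reactions), linear production–degradation (`y' = k − d·y`, closed-form
trajectory and sensitivity), and a positive Hill-feedback switch
(modifier-observable rate law). They emulate the structural ingredients of
the pathway model — binding, multi-site states, turnover, Hill modulation
— but not its scale or stiffness; passing them certifies the engine's
bookkeeping (species enumeration, statistical factors, compiled ODEs), not
the biological adequacy of any particular parameterization.

## SBML export

The generated network exports as SBML Level 3: one compartment of
3e-12 l, species as molecule counts (`hasOnlySubstanceUnits`), clamped
inputs as boundary species, and one kinetic law per directed reaction with
the Hill modifier expanded into an explicit weighted sum of species
references. The writer uses the standard library's XML tools; tests
validate the document structurally and re-integrate the exported kinetic
laws with an independent evaluator, recovering the native trajectories.

## Known limitations

* The parameterization is a literature-scale reconstruction calibrated to
  qualitative dynamic signatures; printed sensitivity magnitudes from any
  specific historical parameterization are not expected to be reproduced
  numerically, although the sign structure, rankings and the
  feedback-ablation patterns are.
* Stochastic (particle-based) simulation is out of scope; amounts are in
  copies per cell specifically so it could be added.
* One cell volume; no compartment-size dynamics, receptor synthesis, or
  insulin washout. IRS1 serine biology is compressed into a single site
  class.
* The dynamic-behaviour classifier encodes the four response classes with
  fixed, configurable thresholds (overshoot index 0.05, 5 % settling band,
  5 min fast/slow cut); an unsupervised 4-means mode on normalized traces
  is provided for comparison, not as the reference.
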