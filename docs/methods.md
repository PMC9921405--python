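# Methods

## Model form

Every pathway is a reaction network over named species with
concentrations in nM and time in seconds. A model compiles to
`dy/dt = N·v(y)` where `N` is the integer net-stoichiometry matrix and
`v(y)` the vector of reaction fluxes. Two base rate laws are supported:

* **mass action** — `k · Π reactant^stoich`, with the effective constant
  optionally the product of several named parameters (this keeps e.g. a
  basal rate constant and a condition-scaling factor separately named);
* **Michaelis–Menten** — `kcat·[E]·S/(Km+S)` with a designated catalytic
  enzyme species, or `Vmax·S/(Km+S)` without one. The enzyme-scaled form
  exists because the deconjugation flux must track the β-glucuronidase
  concentration: in the coupled integrated model the synthesis cascade's
  enzyme output is what drives deconjugation.

Either base law may be multiplied by Hill factors,
`IC50ⁿ/(IC50ⁿ + [I]ⁿ)` for inhibitors and `[A]ⁿ/(EC50ⁿ + [A]ⁿ)` for
activators (n ≥ 1). Every Hill effector must be declared as a reaction
modifier and vice versa; the validator enforces this, along with species
reference integrity, nonnegative initials, and finite nonnegative
parameters.

**Boundary species** (clamped: GA, the stressors, ethanol, the
mitochondrial cytochrome-c store, the toxin supply) are excluded from the
stoichiometry matrix rows, so their zero time derivative is structural
rather than numerical. Concentrations are floored at zero inside flux
evaluation — stiff cascades can transiently undershoot — and fluxes are
therefore nonnegative for any input the solver produces.

Units: first-order constants s⁻¹, second-order nM⁻¹s⁻¹, zeroth-order
(synthesis) nM·s⁻¹, Km/IC50/EC50 nM, Hill exponents dimensionless.

## The four pathway networks

The network topologies follow the mechanism descriptions for each
pathway; kinetic forms are deliberately minimal (mass action for
binding/activation/cleavage, Michaelis–Menten for enzymatic turnover,
multiplicative Hill factors for modifier effects), because the rate
constants are obtained by calibration rather than taken from literature.
Strictly parallel branches are collapsed to keep the calibration
identifiable — caspase-8/10 into one initiator pool, caspase-3/7 into one
effector pool, the MyD88/TIRAP/TRIF/TRAM adaptors into one complex,
IRAK1/2/4 into one kinase complex — since only one biomarker per pathway
is observed and extra unobserved states would be pure degrees of freedom.

Signalling intermediates use a synthesis/decay ("activation/deactivation")
pattern with catalytic drivers, so each intermediate's steady state is
proportional to its upstream signal; downstream species do not feed back
on the biomarker-producing fluxes. This keeps every steady state
well-defined and the calibration problems smooth and monotone.

* **ROS production.** Ethanol induces CYP2E1; LPS activates TLR4, which
  activates NADPH oxidase. Both enzymes produce ROS; both production
  fluxes carry the oxidative-injury scaling (`injury_fold`, default 10,
  expressed as an explicit multiplier on the production rate constants
  relative to the basal parameterization) and a shared GA Hill-inhibition
  factor representing Fe³⁺ chelation (Fenton suppression). A
  Fenton-independent basal production flux carries the injury scaling but
  no GA factor — it is what leaves the residual ~16 nM ROS floor at
  saturating GA. ROS is cleared first-order and drives NF-κB/STAT3
  activation while suppressing AMPK and Nrf2 synthesis through Hill
  inhibition (downstream only; no feedback onto ROS).
* **Deconjugation.** UDPGT conjugates a clamped toxin supply with
  glucuronic acid; the conjugate is predominantly excreted to bile (and
  cleared), while β-glucuronidase catalyses deconjugation to the
  glucuronide-deconjugate biomarker, which is removed by reabsorption. GA
  inhibits the enzymatic deconjugation flux (see "GA attachment" below);
  a slow spontaneous-hydrolysis route is GA-insensitive. β-glucuronidase
  is maintained by an endotoxin-driven synthesis/turnover pair
  (`bgluc_source="intrinsic"`), or supplied externally by the merged
  synthesis model (`"external"`, used for the coupled integrated model).
* **Apoptosis.** TNF-α ligates the death receptor; FADD recruitment
  activates the initiator caspase pool (a FADD-dependent route plus a
  small basal route); caspase-8 truncates Bid; tBid triggers
  cytochrome-c release from the clamped mitochondrial store, gated by
  Bcl-2 (Hill inhibition) and Bax (Hill activation), alongside a basal
  leak; cytosolic cytochrome c and Apaf-1 form the apoptosome, which
  activates caspase-9 and then the effector caspase pool; effector
  caspases cleave PARP. PARP + cPARP is a conserved 2000 nM pool with a
  slow repair reaction returning cPARP to PARP, so the steady-state
  cleaved fraction tracks effector-caspase activity instead of running to
  completion.
* **β-glucuronidase synthesis.** LPS activates TLR4; TLR4 dimerises; the
  dimer recruits the adaptor complex, which activates the IRAK complex;
  IRAK activates TRAF6; active TRAF6 activates NF-κB (GA-inhibited Hill
  factor), with a small TRAF6-independent basal NF-κB activity; NF-κB
  drives c-Myc, c-Myc drives β-glucuronidase expression; the enzyme turns
  over first-order.

## GA dosing

Supplementation is labelled in mg per 100 mL. Serum concentration is
1.5 µM per mg/100 mL — the constant ratio induced from the printed dose
table (2.7/39/78/180 µM for 1.8/26/52/120 mg), which it reproduces with
zero residual — and liver GA is taken equal to serum GA. The model input
is therefore `1500 × dose` nM, set at t = 0 and clamped for the whole
run (GA is a boundary species). Time-varying pharmacokinetics are out of
scope.

## GA attachment points and why they have the shapes they do

* **ROS:** a single Hill-inhibition factor (n = 2, IC50 ≈ 100 nM after
  calibration) on both enzymatic production routes. The factor is ~0 at
  every dose on the grid (≥ 2.7 µM), which yields the observed step from
  70 nM to the 16 nM floor at the lowest dose and saturation above it.
* **Deconjugation:** GA competitively inhibits β-glucuronidase. The pure
  textbook competitive form `Km → Km(1+[GA]/Ki)` cannot satisfy the
  printed values simultaneously: in the linear substrate regime it gives
  a flux factor `1/(1 + a·GA/Ki)`, and matching the 26 and 52 mg values
  forces a Ki that produces a ~20-fold flux drop already at 1.8 mg,
  contradicting the reported absence of an effect there. The package
  therefore uses the cooperative competitive form
  `Km(1 + ([GA]/Ki)ⁿ)` — algebraically a multiplicative Hill factor in
  the linear regime — with n calibrated in [1, 6] (n ≈ 5 accepted), plus
  the spontaneous-hydrolysis floor. This reproduces the sharp
  threshold between 2.7 and 39 µM together with the ~2× step between 39
  and 78 µM.
* **Apoptosis:** the reported mechanism is a raised Bcl-2:Bax ratio
  downregulating caspase-8 activation. A single Hill site (n ≥ 1, with
  floor) cannot reproduce all four printed cPARP values within ±1 nM:
  the printed inhibition depths (0.49%, 0.74%, 1.23% at 39/78/180 µM)
  grow like dose^0.6, shallower than any single-site isotherm. Two Hill
  sites with well-separated half-saturations — one on FADD-dependent
  caspase-8 activation (IC50 ≈ 3.9 µM), one on the Bcl-2/Bax-gated
  cytochrome-c release (IC50 ≈ 460 µM), both expressions of the same
  Bcl-2/Bax mechanism and both paired with GA-insensitive basal routes —
  compose to exactly this sub-linear shape.
* **Synthesis:** one Hill factor (n = 2, IC50 ≈ 2 µM) on the
  TRAF6-dependent NF-κB activation step; the basal NF-κB activity sets
  the 1.19/4.75 ≈ 25% floor, and the factor is nearly exhausted at 39 µM,
  giving the reported "no further decrease" at 52 mg. (The source text's
  sentence about 52 mg says "ROS levels" inside the β-glucuronidase
  section; it is read as a typo for β-glucuronidase levels.)

The 16 nM ROS value at 1.8 mg is read as the *final level* (not a
decrease *by* 16 nM), by analogy with the phrasing used for the other
pathways ("to 1.7 × 10⁻⁵", "to 1.19").

## Simulation and steady-state detection

LSODA with rtol 1e-8 and atol 1e-12 nM (both configurable); the tight
atol is needed because steady states span ~10⁻⁶–10³ nM. Time courses are
sampled at 201 uniform points over 172,800 s; the calibration path
integrates straight to the final time. Steadiness is an RHS criterion at
the final state — `max |dX/dt|·t_final / max(|X|, 10⁻⁶ nM) < 10⁻⁴` —
rather than trajectory flatness, because slow transients can look flat on
a coarse output grid. The slowest mode in any shipped model has a time
constant below ~4,000 s, so two days is > 40 relaxation times and the
criterion is met with large margin. Halving both solver tolerances moves
every reported steady state by far less than 0.1% (tested).

## Calibration

Free parameters (2–5 per pathway: the biomarker-scale rate constants,
the GA half-saturations, and where relevant the Hill exponent or basal
floor) are fitted in log10 space with `scipy.optimize.least_squares`
(TRF, bounds). Residuals are `(ln y_sim − ln y_target)/ln(1+tol)` with
tol the target's tolerance (1–2% relative; ±1 nM absolute for cPARP,
whose printed effects are sub-percent and would be untestable under a
relative band), so |residual| ≤ 1 means "within tolerance". Violated
qualitative constraints contribute weighted hinge residuals. Multi-start
uses the model's current parameter values plus 19 seeded Latin-hypercube
draws over the bounds; starts are polished in order of initial loss and
polishing stops at the first accepted result (all targets within
tolerance, all constraints passing). Identical seeds give identical
results.

The builders ship with the *reference calibrated parameterization*:
values derived analytically from each network's steady-state design
equations and refined by this same calibration procedure. Re-running
`calibrate` from any seed reproduces an accepted result; the parameters
are not claimed to be unique, only consistent with all printed outputs.

Calibration is per-pathway; the integrated model is a verification
artifact (shared GA, optionally shared β-glucuronidase between the
synthesis and deconjugation networks via the `coupled` flag, since the
source material does not state whether the integrated system couples
them — both modes are supported).

## Synthetic data

The generator provides (a) fixture networks with closed-form steady
states — production/degradation (X_ss = k_p/k_d), closed isomerization
(conservation), a three-step cascade with one Hill-inhibited step
(analytic fixed point: downstream steady state exactly halves when the
inhibitor sits at its IC50 with n = 1) — and (b) seeded observation sets:
steady states per dose with multiplicative log-normal noise.
Multiplicative noise is the right family here because biomarkers span
many orders of magnitude; additive noise would swamp the small targets.
Noise-free observations equal the generating steady states exactly, which
is what the parameter-recovery tests exploit.

What the generator does *not* emulate: measurement error structure of
real assays (western blots, enzyme activity), cell-to-cell variability,
or any dynamics absent from the generating models. Passing recovery tests
therefore demonstrates that the calibration machinery inverts the models'
own dose-response maps, not that the models are identified by real data.

## Numerical and design choices

* Stoichiometry is integer and exact; conserved moieties come from the
  exact (rational) left null space of the non-boundary stoichiometry
  matrix, rescaled to primitive integer vectors, with pairwise
  combination to find nonnegative representatives. For the shipped
  networks the null spaces are at most one-dimensional with a nonnegative
  basis (the apoptosis PARP pool), so the heuristic is complete here.
* Integration namespaces species/reactions/parameters by model name;
  only canonical shared ids (GA, and β-glucuronidase when coupled) merge.
  Merged species must agree on initial value and boundary flag.
* SBML L3V1 export writes standard structure with kinetic laws as MathML
  for interoperability; the reader reconstructs models from a structured
  annotation carried alongside (generic MathML→rate-law inference is out
  of scope), which makes the round trip exact.
* Determinism: no randomness anywhere except the seeded calibration
  multi-start and the seeded noise generator; repeated runs are
  bit-identical.

## Problem sizes

The shipped networks have 9–18 species and 10–30 reactions; the
integrated model has 45 species. A two-day stiff integration takes
~10 ms, a full pathway calibration seconds; the whole experiment set
(four calibrations plus all dose-response tables) completes in well under
a minute on one CPU.

## Known limitations

* Rate constants are calibrated, not measured; they are one consistent
  parameterization among many (no identifiability analysis is attempted,
  and none is claimed).
* The cPARP pool total (2000 nM) is a design choice; the source values
  (~1217 nM cleaved) come with no per-cell scaling rationale.
* No stochastic simulation, no spatial effects, no time-varying
  pharmacokinetics, no DSL (the GA lactone derivative) as a distinct
  species, no mitochondrial-dysfunction pathway.
* The steadiness criterion is asymptotic, not a proof of uniqueness;
  the shipped networks are designed to have single stable fixed points,
  but arbitrary user-built networks may not.
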