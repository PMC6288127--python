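# Methods

This note documents the model, its parameters, the numerical choices, what
the toy networks emulate, and the known limitations of the package.

## Growth model

Fitness is proxied by the growth rate µ predicted by an
enzyme-cost-constrained LP (the MOMENT formulation). Variables are the
fluxes (reversible reactions split into non-negative forward/backward
halves) and one concentration variable `g_j ≥ 0` per gene, shared across
every reaction that gene catalyzes. Constraints:

- steady state `S v = 0` and the model's flux bounds;
- per-reaction capacity `v_f + v_r ≤ 3600 · κ_i · f(GPR_i, g)`. The 3600
  converts κ (s⁻¹) into h⁻¹ so fluxes stay in mmol gDW⁻¹ h⁻¹ and `g` in
  mmol gDW⁻¹. Bounding the *sum* of the two half-fluxes by one κ·g term
  implements the Haldane coupling of forward and backward rates: a single
  κ per reaction, mutated as a unit;
- a proteome budget `Σ g_j MW_j ≤ C` with C = 0.32 g gDW⁻¹, the measured
  metabolic protein fraction of *E. coli* across growth conditions.

The GPR capacity recursion maps a gene leaf to its concentration and an OR
node (isozymes) to the sum of its children. AND nodes (complexes) are
genuinely ambiguous in the field's descriptions, so the semantics is a
mode switch (`gpr_and_mode`):

- `max` (default): capacity is the maximum of the children. This is
  non-convex (a disjunction), and is solved exactly as a MILP via
  `scipy.optimize.milp` whenever true AND nodes are present. The bundled
  toy networks contain no AND nodes, so at desk scale every solve is a
  pure LP (HiGHS through `scipy.optimize.linprog`).
- `min`: capacity limited by the scarcest subunit — the classic convex
  choice; encoded as one auxiliary variable with `a ≤ g_child` rows.
- `sum_mw`: one concentration variable per complex whose molecular weight
  is the sum of its subunits' weights.

Non-enzymatic reactions (no GPR: exchanges, biomass, spontaneous) carry no
capacity constraint and no cost. Every analysis states the mode it used;
tests on AND semantics pin all three against closed forms.

Plain FBA is the same problem without enzyme constraints. FVA fixes the
biomass flux at its optimum (relative slack 1e-9) and minimizes/maximizes
each net flux; a reaction "contributes to growth in silico" when its
maximal or absolute minimal flux at the optimum exceeds
1e-6 mmol gDW⁻¹ h⁻¹. pFBA minimizes the summed absolute flux at fixed
optimal growth, using the same forward/backward splitting.

## Evolutionary dynamics

The population is genetically homogeneous (strong selection, weak
mutation). One iteration:

1. choose a reaction uniformly among *unconstrained enzymatic* reactions
   (constrained reactions cannot change, so proposing them would only
   rescale time);
2. draw α from a lognormal with log-mean log(3/2) and log-sd 0.3; draw the
   direction with P(decrease) = 100/101; the proposal is κ·α for an
   increase and κ/α for a decrease. The reciprocal of a lognormal is the
   mirrored lognormal, so decrease magnitudes are symmetric to increase
   magnitudes in log space — "divide by α" and "mirrored distribution" are
   the same choice, which is why no extra switch exists. Note a decrease
   draw with α < 1 (about 9% of decrease draws) raises κ; direction labels
   record the draw, analyses of realized decreases compare κ before/after;
3. solve the mutant LP; s = 1 − µ/µ_mut (s = −∞ for a lethal mutant,
   s = 0 when both rates are 0); infeasible mutant LPs are treated as
   lethal with π = 0, which equals the formula's s → −∞ limit without
   overflow;
4. fix with the Kimura probability π (Nₑ = 2.5e7), evaluated via `expm1`
   and, for strongly deleterious mutations, in log space; probabilities
   below double precision underflow to exactly 0;
5. on fixation, update κ and reuse µ_mut as the next µ (the pre-mutation
   growth rate is cached between fixations — valid under SSWM — and
   invalidated on environment switches).

The RNG draw order per iteration is: environment draws when due, reaction
index, α, direction, fixation uniform. The fixation uniform is drawn even
when π = 0, so optional optimizations cannot shift the stream. One seeded
`numpy` generator drives a replicate; identical (model, config, seed)
reproduce the trajectory bit-for-bit (tested, and re-verified by replaying
fixed events through fresh LP solves).

`reuse_mutant_cache` (off by default) memoizes mutant growth rates keyed by
(reaction, proposed κ, environment). Because the LP is deterministic and
the RNG stream is untouched, trajectories with the cache on and off are
identical (tested). This realizes the "evaluate a deleterious mutant once,
sample its fixation many times" speed-up as an exact equivalence rather
than an approximation.

Ancestral state: unconstrained κ = 1e-3 s⁻¹ (the scale of today's slowest
enzymes); constrained κ = 13.7 s⁻¹ (the in vitro median). The constrained
set is built from EC top-level classes: oxidoreductases (1), hydrolases
(3) and isomerases (5) evolve freely; everything else is capped; reactions
with experimental kcat data are always unconstrained so that comparisons
with data are not circular; missing EC numbers default to constrained.

Environment sampling (diverse mode, every 1000 iterations): oxygen with
probability ½; one uniformly chosen exchange per element C, N, S, P
(classified from metabolite formulas by a Hill-notation parser; charge or
polymeric R/X groups exclude an exchange with a warning); Binomial(2, ½)
extra sources uniform over all classified exchanges; resampled until FBA
growth exceeds 1e-6 h⁻¹ (capped at 1e4 attempts). The uptake bound of an
opened exchange is 10 mmol gDW⁻¹ h⁻¹, the standard glucose-uptake scale;
it is a config field.

The greedy search doubles the κ with the largest s each step (ties broken
by reaction id) and halts when even the best doubling has s < 1/Nₑ — the
drift barrier below which selection cannot distinguish beneficial from
neutral.

One property worth flagging: the *overall* best-s sequence of the greedy
walk is not monotone. Early in adaptation, fixing a mutation shrinks the
total proteome denominator, so the next reaction's s can exceed the
previous one (verifiable on the linear-chain closed form). What does
decrease monotonically — and what the tests assert — is the per-reaction
sequence: successive doublings of the *same* reaction yield strictly
smaller s as the background growth rate rises. That is diminishing-returns
epistasis.

## Toy networks

Every generator emits a model that passes validation and grows under its
default environment; all are deterministic given a seed.

- **Linear pathway**: chain EX → A0 → … → An → biomass, one single-gene
  reaction per step; biomass may drain intermediates. With b_i the flux
  reaction i carries per unit growth (the cumulative biomass coefficients
  downstream of it), the optimum has the closed form
  µ* = 3600·C / Σ b_i·MW_i/κ_i — the oracle used throughout the tests.
- **Standard fixture** (convergence experiments): six steps; step 1 is a
  constrained energy-generation analog with biomass coefficient 2e4 (an
  ATP-demand analog; it ultimately caps growth the way ATP synthase's
  biophysics would), and the five evolving steps spread the selection
  pressure b_i·MW_i over ~3 decades. That spread stratifies evolved kcats
  strongly enough that replicate walks correlate at R ≥ 0.9 after 2e4
  iterations.
- **Trajectory toy**: three steps, two evolving. Small enough that 2e4
  iterations carry the walk to the drift barrier, so the growth trajectory
  visibly saturates strictly below the fast-enzyme (1e5 s⁻¹) maximum.
- **Diminishing-returns fixture**: four steps, one high-demand constrained
  reaction (biomass coefficient 3e4). Derived from the closed form: the
  constrained proteome term must dominate by ~1e7× for the greedy walk to
  hit the drift barrier while evolving κs are still below 1e5 s⁻¹ — i.e.
  strictly below the theoretical maximum.
- **Multifunctional enzyme**: one gene appears on two reactions of the
  same chain (two active sites, separate κs, one shared concentration and
  cost). Improving a single site cannot reduce the pathway's protein cost
  while the other site is limiting, so single-site mutations are exactly
  neutral — synergistic epistasis.
- **Isozyme branch**: two single-gene reactions bridging the same
  metabolites; FVA gives each branch the full (0, total) range and
  replicate evolution may diverge between branches.
- **Mixed multi-source network**: three carbon sources (glucose via two
  isozymes, fructose, acetate requiring oxygen), single N/S/P sources, one
  constrained downstream step; used for environment sampling and
  diverse-mode evolution.
- **Perturbation fixture**: a chain whose selection pressures step by only
  ~2×, so lognormal(0, 0.5) noise on stoichiometric coefficients and
  enzyme weights reorders them — the desk-scale expression of "perturbing
  the network abolishes agreement". The standard fixture's decade-wide
  ladder is robust to that noise, which would mask the effect.

What the toys do *not* emulate: alternate optimal flux distributions at
genome scale, realistic pathway redundancy, cofactor coupling, or the
absolute growth-rate scale (fixture growth rates are of order 1e-5 h⁻¹
because the energy-demand analogs are large). Passing tests therefore show
the mechanisms — shared-cost epistasis, drift barriers, convergence driven
by flux·MW selection pressure — not genome-scale numbers.

Growth rates in the walks are tiny in absolute terms; the LP is solved at
HiGHS default tolerances (~1e-9 feasibility/optimality), and closed-form
agreement at 1e-6 relative holds across the tested κ ranges.

## Desk-scale experiment sizes

The bundled experiments use: 2e4 MCMC iterations for trajectory-shape and
convergence runs (3 replicate seeds), 1e4 iterations for the
perturbation-sensitivity protocol (one reference, three control, three
perturbed runs), 1e5 draws for mutation-sampler moments, and 1e4 samples
for environment-distribution checks. These sizes put each claim's test
statistic well inside its acceptance band on the fixtures while keeping a
full run of suite plus acceptance script within tens of minutes on one
CPU.

Analyses that are stochastic contrasts (perturbation sensitivity,
adaptation speed) are asserted on means across seeds, not on single
replicates; per-seed overlap is expected at these run lengths.

## Statistics

Correlations between kcat sets are Pearson on log10 values over the
intersection of positive entries, with a two-sided t-test
(t = R√(n−2)/√(1−R²), n−2 df); fewer than 3 shared values or zero variance
raise errors rather than returning NaN. The Wilcoxon rank-sum test is
exact by full enumeration of rank assignments (midranks for ties) when
both groups have ≤ 8 observations — scipy's exact method does not handle
ties — and a normal approximation otherwise. Identical groups give the
ties-averaged exact p of 1.

Jump detection flags fixed events whose growth gain exceeds
`threshold_factor` (default 10) times the median gain — an
operationalization of "unusually high fitness gains" exposed as a
parameter, not a constant. Adaptation speed is the first iteration at
which growth reaches half its endpoint value. Pairwise endpoint averaging
uses the geometric mean (the arithmetic mean of the multiplicative
mutation model's log scale); an arithmetic mode exists. The per-reaction
enzyme MW used in selection-pressure correlates is the cheapest satisfying
assignment of the GPR: OR takes the lightest branch; AND follows the
capacity mode (max → lightest subunit pool, min/sum_mw → subunit sum).

## Limitations

- No clonal interference or explicit Wright–Fisher dynamics: mutations
  arise and resolve one at a time (SSWM).
- No K_m/saturation, thermodynamic driving-force or allosteric effects;
  enzymes are assumed substrate-saturated.
- Gene expression is re-optimized by the LP at every step (growth-optimal
  expression), so expression evolution is not modeled.
- Intragenic epistasis is absent: mutation effects are independent draws.
- The verbatim `max` AND semantics is exact but becomes a MILP on models
  with complexes; genome-scale runs in that mode would be expensive, and
  `min`/`sum_mw` are the practical convex alternatives there.
- Whether GPR-less reactions should carry any protein cost is unresolved;
  they are costless here.
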