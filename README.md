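# kcatevo

Simulating genome-wide evolution of enzyme turnover numbers (*k*cat) on
constraint-based metabolic models.

## The problem

Most enzymes are far slower than the fastest known catalysts, even in
pathways that have been under selection for billions of years. `kcatevo`
asks why, by simulating how turnover numbers evolve when fitness is the
growth rate an organism can achieve with a *finite proteome*: a slow enzyme
forces the cell to spend more protein mass on that reaction, which is
protein it cannot spend elsewhere. The package is aimed at systems and
evolutionary biologists who want to explore how network context —
shared proteome costs, isozymes, multifunctional enzymes, biophysically
capped reactions — shapes the evolution of kinetic parameters.

## The model

Growth is predicted by an enzyme-cost-constrained linear program (the
MOMENT formulation). With stoichiometric matrix **S**, fluxes **v**
(mmol gDW⁻¹ h⁻¹), enzyme concentrations *g* (mmol gDW⁻¹) and turnover
numbers κ (s⁻¹):

```
max  v_z                      (flux into the biomass reaction = growth µ)
s.t. S v = 0
     v_min ≤ v ≤ v_max
     v_i  ≤ 3600 κ_i f(GPR_i, g)   for enzymatic reactions
     Σ_j g_j MW_j ≤ C              (metabolic proteome budget, 0.32 g gDW⁻¹)
```

The gene–protein–reaction capacity *f* is evaluated recursively: OR
(isozymes) sums the children, AND (complexes) defaults to the maximum of
the children (with `min` and summed-molecular-weight modes selectable).
Reversible reactions are split into two non-negative half-reactions whose
*sum* is capacity-bounded by a single κ·*g* term, so mutations change
forward and backward rates together (Haldane coupling).

Evolution proceeds in a strong-selection weak-mutation regime: each
iteration multiplies the κ of one random unconstrained reaction by a
lognormal factor α (log-mean log 3/2, log-sd 0.3; decreasing mutations
proposed 100× more often than increasing ones), solves the mutant growth
problem, computes the selection coefficient `s = 1 − µ/µ_mut`, and fixes
the mutation with the Kimura probability

```
π = 1/N            if s = 0
π = (1 − e⁻²ˢ) / (1 − e⁻²ᴺˢ)   otherwise,     N = Nₑ = 2.5·10⁷
```

Ancestral unconstrained enzymes start at 10⁻³ s⁻¹; reactions whose EC class
is not oxidoreductase/hydrolase/isomerase are treated as biophysically
constrained and fixed at the in vitro median of 13.7 s⁻¹. In "diverse"
mode a random growth-sustaining environment (one carbon, nitrogen, sulfur
and phosphate source each, oxygen with probability ½, plus Binomial(2, ½)
extra sources) is resampled every 1000 iterations.

The package also provides plain FBA, flux-variability analysis (growth
relevance at the 10⁻⁶ mmol gDW⁻¹ h⁻¹ threshold), parsimonious FBA, a
greedy κ-doubling search to the drift barrier (s < 1/Nₑ), and analysis
tools: endpoint convergence correlations, comparison with experimental
kcat tables, epistasis diagnostics, fitness-jump gene detection,
adaptation-speed tests, and selection-pressure correlates.

## Worked example

```python
from kcatevo import EvolutionConfig, solve_moment, theoretical_max_growth
from kcatevo.evolution import build_constrained_set, initial_kcats, run_evolution
from kcatevo.fixtures import make_trajectory_toy

model, spec = make_trajectory_toy()          # 3-step pathway, 1 constrained
flags = build_constrained_set(model)         # EC-based constrained set
kcats = initial_kcats(model, flags)          # ancestral state

print(solve_moment(model, kcats).growth_rate)        # 1.141e-05 h^-1
print(theoretical_max_growth(model, kcats))          # 1.052e-04 h^-1

traj = run_evolution(model, EvolutionConfig(n_iterations=20_000, rng_seed=7),
                     flags=flags)
print(len(traj.fixed_events()), traj.mu_end)         # 35   1.006e-04 h^-1
```

The ancestral pathway grows at 1.14·10⁻⁵ h⁻¹ because its two evolving
enzymes are slow (10⁻³ s⁻¹) and soak up nearly the whole proteome budget.
After 2·10⁴ proposed mutations, 35 have fixed and growth has saturated at
1.006·10⁻⁴ h⁻¹ — close to, but strictly below, the 1.052·10⁻⁴ h⁻¹ the
network could reach with fast (10⁵ s⁻¹) enzymes: the biophysically
constrained step (κ fixed at 13.7 s⁻¹) dominates the proteome at the end,
so further improvements of the evolving enzymes (endpoint κ of 0.28 and
0.11 s⁻¹) are effectively neutral and drift cannot fix them — diminishing
returns epistasis halts adaptation far from the optimum.

The same machinery is available from a shell:

```bash
kcatevo fixtures --topology linear --n 5 --out model.json
kcatevo run --model model.json --seed 1 --iterations 20000 --out results/
kcatevo greedy --model model.json --out greedy/
kcatevo envs --model mixed.json --sample 10 --seed 0
```

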