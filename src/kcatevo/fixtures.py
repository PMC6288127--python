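"""Programmatic toy metabolic models for desk-scale experiments.

These generators build the minimal networks on which the evolutionary
mechanisms can be studied exactly: linear pathways (closed-form growth
optimum, diminishing-returns epistasis), a multifunctional enzyme whose two
active sites sit in the same linear pathway (synergistic epistasis), an
isozyme branch (divergent evolution of redundant routes), and a "mixed"
multi-source network for environment sampling.  Biomass is a single
pseudo-reaction consuming pathway metabolites with configurable
coefficients, the simplest structure under which flux is proportional to
growth and the closed form

    mu* = 3600 C / sum_i (b_i MW_i / kappa_i)

holds on linear pathways (b_i: flux carried by reaction i per unit growth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import ExperimentalKcatSet
from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, Reaction
from .moment import KcatVector

__all__ = [
    "FixtureSpec",
    "make_linear_pathway",
    "make_multifunctional_model",
    "make_isozyme_branch",
    "make_mixed_model",
    "make_dre_fixture",
    "make_standard_fixture",
    "linear_pathway_growth_rate",
    "perturb_model",
    "synthetic_kcat_data",
]

# EC classes used to tag fixture reactions so the same EC rule that is used
# at genome scale reproduces the intended constrained set on toys
_EC_UNCONSTRAINED = "1.1.1.1"
_EC_CONSTRAINED = "2.7.1.1"

_SUGAR = "C6H12O6"


@dataclass
class FixtureSpec:
    """Blueprint for a toy pathway model."""

    topology: str = "linear"
    n_reactions: int = 5
    gene_mws: list[float] | None = None  # g mmol^-1, one per reaction step
    biomass_coefficients: dict[int, float] | None = None  # metabolite index -> coeff
    constrained: frozenset[int] = frozenset()  # reaction step indices (1-based)
    uptake: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if self.gene_mws is not None:
            if len(self.gene_mws) != self.n_reactions:
                raise ValueError("gene_mws must have one entry per reaction")
            if any(mw <= 0 for mw in self.gene_mws):
                raise ValueError("gene molecular weights must be positive")
        if self.biomass_coefficients is not None:
            if any(c <= 0 for c in self.biomass_coefficients.values()):
                raise ValueError("biomass coefficients must be positive")

    def resolved_mws(self) -> list[float]:
        if self.gene_mws is not None:
            return list(self.gene_mws)
        # default span 10-100 kDa
        return list(np.logspace(4, 5, self.n_reactions))

    def resolved_biomass(self) -> dict[int, float]:
        if self.biomass_coefficients is not None:
            return dict(self.biomass_coefficients)
        return {self.n_reactions: 1.0}


def make_linear_pathway(spec: FixtureSpec | None = None, **kwargs) -> MetabolicModel:
    """Chain EX -> A0 -> A1 -> ... -> An -> biomass, one gene per step.

    Reaction i (1-based) converts A_{i-1} to A_i and is catalyzed by gene
    g{i}; biomass consumes metabolite A_k with coefficient c_k per
    ``biomass_coefficients`` (default: terminal metabolite, coefficient 1).
    """
    if spec is None:
        spec = FixtureSpec(**kwargs)
    n = spec.n_reactions
    mws = spec.resolved_mws()
    bio = spec.resolved_biomass()
    if not bio.get(n):
        raise ValueError("biomass must consume the terminal metabolite")
    metabolites = [Metabolite(f"A{i}", formula=_SUGAR, compartment="c") for i in range(n + 1)]
    reactions = [
        Reaction("EX_A0", {"A0": -1.0}, lower_bound=-spec.uptake, upper_bound=1000.0)
    ]
    gene_weights = {}
    for i in range(1, n + 1):
        gene = f"g{i}"
        gene_weights[gene] = mws[i - 1]
        reactions.append(
            Reaction(
                f"R{i}", {f"A{i-1}": -1.0, f"A{i}": 1.0},
                lower_bound=0.0, upper_bound=1e6,
                gpr=parse_gpr(gene),
                ec_number=_EC_CONSTRAINED if i in spec.constrained else _EC_UNCONSTRAINED,
            )
        )
    reactions.append(
        Reaction("BIOMASS", {f"A{k}": -c for k, c in bio.items()},
                 lower_bound=0.0, upper_bound=1000.0)
    )
    model = MetabolicModel(
        id=f"linear_{n}", metabolites=metabolites, reactions=reactions,
        gene_weights=gene_weights, biomass_reaction_id="BIOMASS",
        declared_genes=frozenset(gene_weights),
    )
    model.validate()
    return model


def linear_pathway_growth_rate(
    spec: FixtureSpec, kcats: dict[str, float], C: float = 0.32
) -> float:
    """Closed-form growth optimum of a linear-pathway fixture.

    Reaction i carries flux b_i = sum_{k >= i} c_k per unit growth, needs
    g_i = b_i mu / (3600 kappa_i) of its enzyme, and the proteome budget
    binds: mu* = 3600 C / sum_i (b_i MW_i / kappa_i).
    """
    mws = spec.resolved_mws()
    bio = spec.resolved_biomass()
    total = 0.0
    for i in range(1, spec.n_reactions + 1):
        b_i = sum(c for k, c in bio.items() if k >= i)
        total += b_i * mws[i - 1] / kcats[f"R{i}"]
    return 3600.0 * C / total


def make_multifunctional_model(
    n_reactions: int = 3, shared_steps: tuple[int, int] = (1, 2),
    gene_mws: list[float] | None = None, uptake: float = 1000.0,
) -> MetabolicModel:
    """Linear pathway where one gene catalyzes two of its reactions.

    The two shared steps model the two active sites of a multifunctional
    enzyme: each has its own kcat, but one shared concentration variable
    (and cost).  Improving a single site cannot reduce the protein cost of
    the pathway while the other site remains limiting.
    """
    i, j = shared_steps
    if not (1 <= i < j <= n_reactions):
        raise ValueError("shared steps must be distinct reactions of the chain")
    spec = FixtureSpec(topology="multifunctional", n_reactions=n_reactions,
                       gene_mws=gene_mws, uptake=uptake)
    model = make_linear_pathway(spec)
    shared_gene = f"g{i}"
    old_gene = f"g{j}"
    model.reaction(f"R{j}").gpr = parse_gpr(shared_gene)
    model.gene_weights.pop(old_gene, None)
    model = MetabolicModel(
        id=f"multifunctional_{n_reactions}", metabolites=model.metabolites,
        reactions=model.reactions, gene_weights=model.gene_weights,
        biomass_reaction_id="BIOMASS", declared_genes=frozenset(model.gene_weights),
    )
    model.validate()
    return model


def make_isozyme_branch(
    gene_mws: tuple[float, float, float] = (4e4, 4e4, 4e4), uptake: float = 1000.0
) -> MetabolicModel:
    """Two parallel reactions (distinct genes) bridging the same metabolites.

    EX -> A0, then A0 -> A1 via R1a or R1b (redundant routes), then
    A1 -> A2 -> biomass.  The branches are symmetric when their gene MWs
    are equal, in which case flux variability spans (0, full) on each.
    """
    metabolites = [Metabolite(f"A{i}", formula=_SUGAR, compartment="c") for i in range(3)]
    gene_weights = {"ga": gene_mws[0], "gb": gene_mws[1], "g2": gene_mws[2]}
    reactions = [
        Reaction("EX_A0", {"A0": -1.0}, lower_bound=-uptake, upper_bound=1000.0),
        Reaction("R1a", {"A0": -1.0, "A1": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("ga"), ec_number=_EC_UNCONSTRAINED),
        Reaction("R1b", {"A0": -1.0, "A1": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("gb"), ec_number=_EC_UNCONSTRAINED),
        Reaction("R2", {"A1": -1.0, "A2": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("g2"), ec_number=_EC_UNCONSTRAINED),
        Reaction("BIOMASS", {"A2": -1.0}, upper_bound=1000.0),
    ]
    model = MetabolicModel(
        id="isozyme_branch", metabolites=metabolites, reactions=reactions,
        gene_weights=gene_weights, biomass_reaction_id="BIOMASS",
        declared_genes=frozenset(gene_weights),
    )
    model.validate()
    return model


def make_mixed_model(uptake_default: float = 0.0) -> MetabolicModel:
    """Multi-source network for environment sampling and diverse evolution.

    Three carbon sources (glucose via two isozymes, fructose, acetate which
    additionally requires oxygen), single nitrogen/sulfur/phosphate
    sources, and a short downstream chain with one biophysically
    constrained step.  All exchanges are closed by default
    (``uptake_default`` = 0); environments open them.
    """
    mets = [
        Metabolite("glc", formula="C6H12O6", compartment="e"),
        Metabolite("fru", formula="C6H12O6", compartment="e"),
        Metabolite("ac", formula="C2H4O2", compartment="e"),
        Metabolite("nh4", formula="H4N", compartment="e"),
        Metabolite("so4", formula="O4S", compartment="e"),
        Metabolite("pi", formula="HO4P", compartment="e"),
        Metabolite("o2", formula="O2", compartment="e"),
        Metabolite("A", formula="C6H12O6", compartment="c"),
        Metabolite("B", formula="C6H12O6", compartment="c"),
    ]
    lb = -abs(uptake_default)
    gene_weights = {
        "g_glc_a": 3e4, "g_glc_b": 5e4, "g_fru": 4e4, "g_ac": 6e4,
        "g_ab": 4.5e4,
    }
    reactions = [
        Reaction("EX_glc", {"glc": -1.0}, lower_bound=lb),
        Reaction("EX_fru", {"fru": -1.0}, lower_bound=lb),
        Reaction("EX_ac", {"ac": -1.0}, lower_bound=lb),
        Reaction("EX_nh4", {"nh4": -1.0}, lower_bound=lb),
        Reaction("EX_so4", {"so4": -1.0}, lower_bound=lb),
        Reaction("EX_pi", {"pi": -1.0}, lower_bound=lb),
        Reaction("EX_o2", {"o2": -1.0}, lower_bound=lb),
        Reaction("CONV_glc_a", {"glc": -1.0, "A": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("g_glc_a"), ec_number=_EC_UNCONSTRAINED),
        Reaction("CONV_glc_b", {"glc": -1.0, "A": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("g_glc_b"), ec_number=_EC_UNCONSTRAINED),
        Reaction("CONV_fru", {"fru": -1.0, "A": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("g_fru"), ec_number=_EC_UNCONSTRAINED),
        Reaction("CONV_ac", {"ac": -3.0, "o2": -1.0, "A": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("g_ac"), ec_number=_EC_UNCONSTRAINED),
        Reaction("R_AB", {"A": -1.0, "B": 1.0}, upper_bound=1e6,
                 gpr=parse_gpr("g_ab"), ec_number=_EC_CONSTRAINED),
        Reaction("BIOMASS", {"B": -1.0, "nh4": -0.5, "so4": -0.05, "pi": -0.1},
                 upper_bound=1000.0),
    ]
    model = MetabolicModel(
        id="mixed_sources", metabolites=mets, reactions=reactions,
        gene_weights=gene_weights, biomass_reaction_id="BIOMASS",
        declared_genes=frozenset(gene_weights),
    )
    model.validate()
    return model


def make_dre_fixture() -> tuple[MetabolicModel, FixtureSpec]:
    """Linear chain with one essential high-demand constrained reaction.

    The constrained first step (an energy-generation analog, biomass
    coefficient 3e4) dominates the proteome once the three downstream
    unconstrained enzymes have improved, so a greedy walk of kcat doublings
    reaches the drift barrier (s < 1/N_e) while the unconstrained kcats are
    still far below the fast-enzyme scale of 1e5 s^-1.
    """
    spec = FixtureSpec(
        topology="linear", n_reactions=4,
        gene_mws=[5e4, 4e4, 4e4, 4e4],
        biomass_coefficients={1: 3e4, 4: 1.0},
        constrained=frozenset({1}),
    )
    return make_linear_pathway(spec), spec


def make_standard_fixture() -> tuple[MetabolicModel, FixtureSpec]:
    """The default desk-scale chain for adaptive-walk experiments.

    Six steps: one constrained energy-generation analog (step 1, biomass
    coefficient 2e4, the ATP-demand analog that ultimately caps growth) and
    five unconstrained steps whose per-unit-growth flux (biomass drains
    every intermediate) and molecular weights spread the selection pressure
    b_i * MW_i over ~1000x.  That spread is the mechanism that stratifies
    evolved kcats, so replicate walks converge to correlated endpoints.
    """
    spec = FixtureSpec(
        topology="linear", n_reactions=6,
        gene_mws=[5e4, 1e5, 5.6e4, 3.2e4, 1.8e4, 1e4],
        biomass_coefficients={1: 2e4, 2: 81.0, 3: 27.0, 4: 9.0, 5: 3.0, 6: 1.0},
        constrained=frozenset({1}),
    )
    return make_linear_pathway(spec), spec


def make_trajectory_toy() -> tuple[MetabolicModel, FixtureSpec]:
    """Minimal adaptive-walk chain: two evolving steps, one constrained.

    Small enough that 2e4 iterations carry the walk all the way to the
    drift barrier, so the growth trajectory visibly saturates strictly
    below the fast-enzyme theoretical maximum.
    """
    spec = FixtureSpec(
        topology="linear", n_reactions=3,
        gene_mws=[5e4, 6e4, 3e4],
        biomass_coefficients={1: 3e3, 3: 1.0},
        constrained=frozenset({1}),
    )
    return make_linear_pathway(spec), spec


def make_perturbation_fixture() -> tuple[MetabolicModel, FixtureSpec]:
    """Chain with moderately spread selection pressures (~2x steps).

    Designed for stoichiometry/molecular-weight sensitivity experiments:
    lognormal coefficient noise of sd 0.5 is enough to reorder adjacent
    reactions' selection pressures here, whereas the standard fixture's
    decade-wide ladder is robust to it.
    """
    spec = FixtureSpec(
        topology="linear", n_reactions=6,
        gene_mws=[5e4, 4.5e4, 3.8e4, 3.2e4, 2.6e4, 2.2e4],
        biomass_coefficients={1: 2e4, 2: 8.0, 3: 4.0, 4: 2.0, 5: 1.5, 6: 1.0},
        constrained=frozenset({1}),
    )
    return make_linear_pathway(spec), spec


def fixture_flags(model: MetabolicModel) -> dict[str, str]:
    """Constrained/unconstrained flags as encoded in fixture EC numbers."""
    from .evolution import build_constrained_set

    return build_constrained_set(model)


def perturb_model(
    model: MetabolicModel, rng: np.random.Generator, magnitude: float,
    perturb_gene_mws: bool = False,
) -> MetabolicModel:
    """Randomly perturb stoichiometric and biomass coefficients.

    Every non-zero coefficient of non-exchange reactions (biomass included)
    is multiplied by an independent lognormal(0, magnitude) factor, which
    preserves signs so the network stays structurally valid.
    """
    if not magnitude > 0:
        raise ValueError("perturbation magnitude must be positive")
    out = model.copy()
    exchanges = set(out.exchange_reaction_ids)
    for rxn in out.reactions:
        if rxn.id in exchanges:
            continue
        for mid in sorted(rxn.metabolites):
            factor = float(np.exp(rng.normal(0.0, magnitude)))
            rxn.metabolites[mid] *= factor
    if perturb_gene_mws:
        for gene in sorted(out.gene_weights):
            out.gene_weights[gene] *= float(np.exp(rng.normal(0.0, magnitude)))
    out.validate()
    return out


def synthetic_kcat_data(
    true_kcats: KcatVector | dict[str, float],
    noise_sdlog: float,
    rng: np.random.Generator,
    coverage_fraction: float = 1.0,
) -> ExperimentalKcatSet:
    """Noisy subsample emulating an experimental kcat table.

    Values are true kcats times lognormal(0, noise_sdlog) noise;
    ``coverage_fraction`` of reactions (rounded) are retained.
    """
    if noise_sdlog < 0:
        raise ValueError("noise_sdlog must be >= 0")
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    values = true_kcats.values if isinstance(true_kcats, KcatVector) else dict(true_kcats)
    rids = sorted(values)
    n_keep = int(round(coverage_fraction * len(rids)))
    if n_keep == 0:
        raise ValueError("coverage yields an empty dataset")
    keep = sorted(rng.choice(rids, size=n_keep, replace=False))
    noisy = {
        rid: values[rid] * float(np.exp(rng.normal(0.0, noise_sdlog))) for rid in keep
    }
    return ExperimentalKcatSet(values=noisy, provenance="synthetic")
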