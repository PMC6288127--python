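"""Adaptive-walk simulation of kcat evolution under drift and selection.

The population is genetically homogeneous (strong selection, weak
mutation): one mutation at a time multiplies a random unconstrained
reaction's turnover number by a lognormal factor, the mutant growth rate
is predicted by the proteome-constrained growth problem, and fixation is
decided by the Kimura diffusion probability at effective population size
N_e.  Decreasing mutations are proposed 100x more often than increasing
ones, mirroring the mutational bias towards degrading catalysis.  In
"diverse" mode the growth environment is resampled every 1000 iterations
from random combinations of carbon/nitrogen/sulfur/phosphate sources with
oxygen available half of the time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import Environment, MetabolicModel
from .model_io import classify_exchange_sources
from .moment import (
    CONSTRAINED,
    DEFAULT_PROTEOME_BUDGET,
    NON_ENZYMATIC,
    UNCONSTRAINED,
    KcatVector,
    MomentProblem,
    solve_fba,
)

__all__ = [
    "EvolutionConfig",
    "MutationEvent",
    "Trajectory",
    "build_constrained_set",
    "initial_kcats",
    "propose_mutation",
    "selection_coefficient",
    "fixation_probability",
    "draw_candidate_environment",
    "sample_environment",
    "run_evolution",
    "replay_growth",
    "greedy_adaptation",
]

# EC top-level classes with high median in vitro kcat: oxidoreductases (1),
# hydrolases (3), isomerases (5) evolve without a biophysical ceiling
UNCONSTRAINED_EC_CLASSES = ("1", "3", "5")


@dataclass
class EvolutionConfig:
    """Parameters of the adaptive walk.

    Defaults are the study conditions: E. coli effective population size
    2.5e7, metabolic proteome budget 0.32 g/gDW, lognormal mutation factor
    with log-scale mean log(3/2) and SD 0.3, 100:1 decreasing:increasing
    proposal ratio, environment switch every 1000 iterations, ancestral
    kcat 1e-3 s^-1 for evolving reactions, and 13.7 s^-1 (the in vitro
    median) for biophysically constrained ones.
    """

    n_iterations: int = 20_000
    rng_seed: int = 0
    N_e: float = 2.5e7
    C: float = DEFAULT_PROTEOME_BUDGET
    mut_meanlog: float = math.log(3.0 / 2.0)
    mut_sdlog: float = 0.3
    deleterious_ratio: float = 100.0
    env_switch_period: int = 1000
    initial_unconstrained_kcat: float = 1e-3
    constrained_kcat: float = 13.7
    gpr_and_mode: str = "max"
    environment_uptake: float = 10.0
    record_all_proposals: bool = True
    reuse_mutant_cache: bool = False
    checkpoint_every: int = 10_000
    max_env_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.N_e < 1:
            raise ValueError("N_e must be >= 1")
        if self.C <= 0 or self.initial_unconstrained_kcat <= 0 or self.constrained_kcat <= 0:
            raise ValueError("rates and budgets must be positive")
        if self.deleterious_ratio < 0:
            raise ValueError("deleterious_ratio must be >= 0")
        if self.env_switch_period < 1:
            raise ValueError("env_switch_period must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MutationEvent:
    iteration: int
    reaction_id: str
    alpha: float
    direction: str  # "increase" or "decrease"
    kcat_before: float
    kcat_after: float
    mu_before: float
    mu_after: float
    s: float
    pi: float
    fixed: bool
    environment_id: str | None = None


@dataclass
class Trajectory:
    """Ordered record of an adaptive walk."""

    events: list[MutationEvent]
    endpoint: KcatVector
    mu_end: float
    initial: KcatVector
    snapshots: list[tuple[int, KcatVector]] = field(default_factory=list)
    environments: list[tuple[int, Environment]] = field(default_factory=list)
    config: EvolutionConfig | None = None

    def fixed_events(self) -> list[MutationEvent]:
        return [e for e in self.events if e.fixed]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.events])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def endpoint_table(self) -> pd.DataFrame:
        rows = [
            {"reaction_id": r, "kcat_per_s": self.endpoint.values[r],
             "flag": self.endpoint.flags.get(r, "")}
            for r in sorted(self.endpoint.values)
        ]
        return pd.DataFrame(rows)


def build_constrained_set(
    model: MetabolicModel, kcat_data_reaction_ids: set[str] | None = None
) -> dict[str, str]:
    """Classify reactions by whether their kcat can evolve upward.

    A reaction is unconstrained when its EC top-level class is 1, 3, or 5
    (oxidoreductases, hydrolases, isomerases: the classes with the highest
    median in vitro kcat) OR when experimental kcat data exist for it (to
    keep comparisons with data non-circular).  Every other enzymatic
    reaction is constrained; reactions without a GPR are non-enzymatic.
    Missing EC numbers default to constrained.
    """
    data_ids = kcat_data_reaction_ids or set()
    flags: dict[str, str] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            flags[rxn.id] = NON_ENZYMATIC
            continue
        ec_class = rxn.ec_number.split(".")[0].strip() if rxn.ec_number else None
        if rxn.id in data_ids or ec_class in UNCONSTRAINED_EC_CLASSES:
            flags[rxn.id] = UNCONSTRAINED
        else:
            flags[rxn.id] = CONSTRAINED
    return flags


def initial_kcats(
    model: MetabolicModel, flags: dict[str, str], config: EvolutionConfig | None = None
) -> KcatVector:
    """Ancestral kcat vector: slow unconstrained, fixed constrained."""
    config = config or EvolutionConfig()
    values = {}
    for rxn in model.reactions:
        f = flags.get(rxn.id, NON_ENZYMATIC if rxn.gpr is None else UNCONSTRAINED)
        if f == NON_ENZYMATIC:
            continue
        values[rxn.id] = (
            config.constrained_kcat if f == CONSTRAINED else config.initial_unconstrained_kcat
        )
    return KcatVector(values, {r: f for r, f in flags.items()})


def selection_coefficient(mu: float, mu_mut: float) -> float:
    """s = 1 - mu/mu_mut, with growth rate as fitness proxy.

    A lethal mutant (mu_mut = 0 while mu > 0) returns -inf; two dead
    strains (mu = mu_mut = 0) are selectively equivalent (s = 0).
    """
    if mu < 0 or mu_mut < 0:
        raise ValueError("growth rates must be non-negative")
    if mu_mut == 0.0:
        return 0.0 if mu == 0.0 else float("-inf")
    return 1.0 - mu / mu_mut


def fixation_probability(s: float, N: float) -> float:
    """Kimura fixation probability of a new mutation.

    pi = 1/N for s = 0, else (1 - exp(-2s)) / (1 - exp(-2Ns)); evaluated
    stably for large N|s| (strongly deleterious mutations underflow to 0,
    strongly beneficial ones approach 1 - exp(-2s) ~ 2s for small s).
    """
    if N < 1:
        raise ValueError("population size must be >= 1")
    if s == 0.0:
        return 1.0 / N
    if math.isinf(s) and s < 0:
        return 0.0
    two_s = 2.0 * s
    two_ns = 2.0 * N * s
    if s > 0:
        num = -math.expm1(-two_s)
        den = -math.expm1(-two_ns) if two_ns < 700 else 1.0
        return num / den
    # s < 0: pi = (exp(-2s) - 1) / (exp(-2Ns) - 1), both positive
    if -two_ns > 700:
        # log-space: log pi = log(expm1(-2s)) - log(expm1(-2Ns)) ~ ... + 2Ns
        log_num = math.log(math.expm1(-two_s)) if -two_s < 700 else -two_s
        log_pi = log_num + two_ns  # log(expm1(-2Ns)) ~ -2Ns for large -2Ns
        return math.exp(log_pi) if log_pi > -745 else 0.0
    return math.expm1(-two_s) / math.expm1(-two_ns)


def propose_mutation(
    kcats: KcatVector, rng: np.random.Generator, config: EvolutionConfig
) -> tuple[str, float, str, float]:
    """Draw (reaction, alpha, direction, proposed kcat).

    The reaction is uniform over unconstrained enzymatic reactions; the
    factor alpha is lognormal(log 3/2, 0.3); the direction is a decrease
    with probability ratio/(ratio+1), realized as division by alpha (the
    reciprocal of a lognormal has the mirrored log-mean, so magnitudes are
    symmetric in log space).
    """
    candidates = kcats.unconstrained_ids()
    if not candidates:
        raise ValueError("no unconstrained enzymatic reactions to mutate")
    rid = candidates[int(rng.integers(len(candidates)))]
    alpha = float(np.exp(rng.normal(config.mut_meanlog, config.mut_sdlog)))
    ratio = config.deleterious_ratio
    decrease = bool(rng.random() < ratio / (ratio + 1.0))
    kcat = kcats.values[rid]
    proposed = kcat / alpha if decrease else kcat * alpha
    return rid, alpha, "decrease" if decrease else "increase", proposed


def draw_candidate_environment(
    sources: dict[str, list[str]],
    oxygen_exchange: str | None,
    rng: np.random.Generator,
    uptake: float = 10.0,
    env_id: str | None = None,
) -> tuple[Environment, int]:
    """One random environment draw (no growth check).

    Oxygen uptake is allowed with probability 1/2; one uniformly chosen
    exchange per element (C, N, S, P) is always open; Binomial(2, 1/2)
    additional sources are drawn uniformly from all classified exchanges.
    Returns the environment and the number of extra-source draws.
    """
    all_sources = sorted(set().union(*sources.values()))
    open_ex: dict[str, float] = {}
    oxygen = bool(rng.random() < 0.5) if oxygen_exchange is not None else False
    if oxygen:
        open_ex[oxygen_exchange] = uptake
    for element in ("C", "N", "S", "P"):
        choices = sources[element]
        open_ex[choices[int(rng.integers(len(choices)))]] = uptake
    n_extra = int(rng.binomial(2, 0.5))
    for _ in range(n_extra):
        open_ex[all_sources[int(rng.integers(len(all_sources)))]] = uptake
    return Environment(open_exchanges=open_ex, oxygen_available=oxygen, id=env_id), n_extra


def sample_environment(
    model: MetabolicModel,
    rng: np.random.Generator,
    growth_check=None,
    uptake: float = 10.0,
    max_attempts: int = 10_000,
    env_id: str | None = None,
) -> Environment:
    """Sample a random growth-sustaining environment.

    Candidate environments from :func:`draw_candidate_environment` are
    resampled until ``growth_check(environment)`` passes (default: FBA
    growth > 1e-6 h^-1).
    """
    sources = classify_exchange_sources(model)
    missing = [e for e, lst in sources.items() if not lst]
    if missing:
        raise ValueError(f"model has no exchangeable source for elements: {missing}")
    o2 = model.oxygen_exchange_id()

    if growth_check is None:
        def growth_check(env: Environment) -> bool:
            sol = solve_fba(model, env)
            return sol.optimal and sol.growth_rate > 1e-6

    for _ in range(max_attempts):
        env, _ = draw_candidate_environment(sources, o2, rng, uptake=uptake,
                                            env_id=env_id)
        if growth_check(env):
            return env
    raise RuntimeError(
        f"no growth-sustaining environment found in {max_attempts} attempts"
    )


def run_evolution(
    model: MetabolicModel,
    config: EvolutionConfig,
    kcats: KcatVector | None = None,
    flags: dict[str, str] | None = None,
    environment: Environment | None = None,
    environment_mode: str = "constant",
) -> Trajectory:
    """Run the MCMC adaptive walk and return its trajectory.

    One iteration: propose a mutation, solve the mutant growth problem,
    compute s and the fixation probability, draw fixation, apply or
    discard.  The pre-mutation growth rate is cached between fixations and
    recomputed on environment switches.  The trajectory is reproducible
    bit-for-bit from (model, config, seed).
    """
    if environment_mode not in ("constant", "diverse"):
        raise ValueError(f"unknown environment_mode {environment_mode!r}")
    rng = np.random.default_rng(config.rng_seed)
    if kcats is None:
        if flags is None:
            flags = build_constrained_set(model)
        kcats = initial_kcats(model, flags, config)
    else:
        kcats = kcats.copy()
    initial = kcats.copy()

    def make_problem(env: Environment | None) -> MomentProblem:
        return MomentProblem(model, env, C=config.C, gpr_and_mode=config.gpr_and_mode)

    environments: list[tuple[int, Environment]] = []
    if environment_mode == "diverse":
        env = sample_environment(model, rng, uptake=config.environment_uptake,
                                 max_attempts=config.max_env_attempts, env_id="env0")
        environments.append((0, env))
    else:
        env = environment
        if env is not None:
            environments.append((0, env))
    problem = make_problem(env)
    base = problem.solve(kcats)
    if not base.optimal:
        raise RuntimeError(f"initial growth problem not optimal: {base.status}")
    mu = base.growth_rate

    cache: dict[tuple[str, float, str | None], float] = {}
    events: list[MutationEvent] = []
    snapshots: list[tuple[int, KcatVector]] = []
    env_label = env.id if env is not None else None

    for iteration in range(config.n_iterations):
        if environment_mode == "diverse" and iteration > 0 and iteration % config.env_switch_period == 0:
            env = sample_environment(model, rng, uptake=config.environment_uptake,
                                     max_attempts=config.max_env_attempts,
                                     env_id=f"env{iteration}")
            environments.append((iteration, env))
            env_label = env.id
            problem = make_problem(env)
            cache.clear()
            base = problem.solve(kcats)
            if not base.optimal:
                raise RuntimeError(f"growth problem not optimal after switch: {base.status}")
            mu = base.growth_rate

        rid, alpha, direction, proposed = propose_mutation(kcats, rng, config)
        key = (rid, proposed, env_label)
        if config.reuse_mutant_cache and key in cache:
            mu_mut = cache[key]
        else:
            trial = kcats.with_value(rid, proposed)
            sol = problem.solve(trial)
            mu_mut = sol.growth_rate if sol.optimal else 0.0
            if config.reuse_mutant_cache:
                cache[key] = mu_mut

        s = selection_coefficient(mu, mu_mut)
        pi = fixation_probability(s, config.N_e)
        u = float(rng.random())
        fixed = u < pi
        event = MutationEvent(
            iteration=iteration, reaction_id=rid, alpha=alpha, direction=direction,
            kcat_before=kcats.values[rid], kcat_after=proposed,
            mu_before=mu, mu_after=mu_mut, s=s, pi=pi, fixed=fixed,
            environment_id=env_label,
        )
        if fixed:
            kcats.values[rid] = proposed
            cache.clear()
            mu = mu_mut
        if config.record_all_proposals or fixed:
            events.append(event)
        if config.checkpoint_every and (iteration + 1) % config.checkpoint_every == 0:
            snapshots.append((iteration + 1, kcats.copy()))

    return Trajectory(events=events, endpoint=kcats, mu_end=mu, initial=initial,
                      snapshots=snapshots, environments=environments, config=config)


def replay_growth(model: MetabolicModel, trajectory: Trajectory) -> list[float]:
    """Recompute growth after each fixed event by replaying the trajectory.

    Rebuilds the kcat vector from the initial state, applies fixed
    mutations in order, and re-solves the growth problem in the recorded
    environment.  The result should reproduce the recorded mu_after values
    (determinism invariant).
    """
    config = trajectory.config or EvolutionConfig()
    envs = {env.id: env for _, env in trajectory.environments}
    kcats = trajectory.initial.copy()
    problems: dict[str | None, MomentProblem] = {}
    mus: list[float] = []
    for event in trajectory.fixed_events():
        kcats.values[event.reaction_id] = event.kcat_after
        key = event.environment_id
        if key not in problems:
            problems[key] = MomentProblem(model, envs.get(key), C=config.C,
                                          gpr_and_mode=config.gpr_and_mode)
        sol = problems[key].solve(kcats)
        mus.append(sol.growth_rate if sol.optimal else 0.0)
    return mus


def greedy_adaptation(
    model: MetabolicModel,
    kcats: KcatVector,
    environment: Environment | None = None,
    N_e: float = 2.5e7,
    C: float = DEFAULT_PROTEOME_BUDGET,
    gpr_and_mode: str = "max",
    factor: float = 2.0,
    mutable_ids: list[str] | None = None,
    max_steps: int = 100_000,
) -> Trajectory:
    """Greedy search: repeatedly fix the most beneficial kcat doubling.

    Each step doubles the kcat of the unconstrained reaction with maximal
    selection coefficient; the walk halts when even the best doubling is
    effectively neutral (max s < 1/N_e), the drift barrier.  Ties break by
    reaction id order, so the trajectory is deterministic.
    """
    kcats = kcats.copy()
    initial = kcats.copy()
    candidates = sorted(mutable_ids) if mutable_ids is not None else kcats.unconstrained_ids()
    if not candidates:
        raise ValueError("no unconstrained reactions to adapt")
    problem = MomentProblem(model, environment, C=C, gpr_and_mode=gpr_and_mode)
    base = problem.solve(kcats)
    if not base.optimal:
        raise RuntimeError(f"initial growth problem not optimal: {base.status}")
    mu = base.growth_rate
    threshold = 1.0 / N_e
    events: list[MutationEvent] = []

    for step in range(max_steps):
        best_rid, best_s, best_mu = None, -math.inf, mu
        for rid in candidates:
            trial = kcats.with_value(rid, kcats.values[rid] * factor)
            sol = problem.solve(trial)
            mu_mut = sol.growth_rate if sol.optimal else 0.0
            s = selection_coefficient(mu, mu_mut)
            if s > best_s:
                best_rid, best_s, best_mu = rid, s, mu_mut
        if best_rid is None or best_s < threshold:
            break
        events.append(MutationEvent(
            iteration=step, reaction_id=best_rid, alpha=factor, direction="increase",
            kcat_before=kcats.values[best_rid],
            kcat_after=kcats.values[best_rid] * factor,
            mu_before=mu, mu_after=best_mu, s=best_s,
            pi=fixation_probability(best_s, N_e), fixed=True,
        ))
        kcats.values[best_rid] *= factor
        mu = best_mu
    else:
        raise RuntimeError(f"greedy search did not halt within {max_steps} steps")

    return Trajectory(events=events, endpoint=kcats, mu_end=mu, initial=initial)
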