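"""Post-run statistics on adaptive-walk trajectories and endpoints.

Everything here is a pure function of trajectory/endpoint data: convergence
correlations between replicate endpoints, comparison with experimental kcat
tables, diminishing-returns diagnostics, detection of genes associated with
fitness jumps, adaptation-speed comparisons (Wilcoxon rank-sum), and the
flux/molecular-weight correlates of selection pressure.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gpr import GprExpression
from .model import Environment, MetabolicModel
from .moment import (
    UNCONSTRAINED,
    KcatVector,
    MomentProblem,
    flux_variability,
    parsimonious_fluxes,
)

__all__ = [
    "ExperimentalKcatSet",
    "CorrelationResult",
    "correlate_log",
    "endpoint_correlation_matrix",
    "epistasis_diagnostics",
    "detect_fitness_jumps",
    "adaptation_speed_test",
    "wilcoxon_rank_sum",
    "iterations_to_half_growth",
    "selection_pressure_correlates",
    "pairwise_endpoint_fitness",
    "reaction_molecular_weight",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentalKcatSet:
    """Per-reaction turnover numbers from (or emulating) experiments."""

    values: dict[str, float]
    provenance: str = "synthetic"  # in_vitro | in_vivo_kapp_max | synthetic

    def __post_init__(self) -> None:
        bad = [r for r, k in self.values.items() if not k > 0]
        if bad:
            raise ValueError(f"non-positive kcat for reactions: {bad}")


@dataclass
class CorrelationResult:
    n: int
    r: float
    t: float
    p: float


def _as_map(x) -> dict[str, float]:
    if isinstance(x, KcatVector):
        return x.values
    if isinstance(x, ExperimentalKcatSet):
        return x.values
    return dict(x)


def correlate_log(x, y, scope=None) -> CorrelationResult:
    """Pearson correlation of log10 values over shared reactions.

    The p-value is the two-sided t-test with n-2 degrees of freedom,
    t = R sqrt(n-2) / sqrt(1-R^2).  Requires >= 3 shared reactions with
    positive values; a zero-variance side is an error (R undefined).
    """
    xm, ym = _as_map(x), _as_map(y)
    keys = sorted(set(xm) & set(ym))
    if scope is not None:
        scope = set(scope)
        keys = [k for k in keys if k in scope]
    keys = [k for k in keys if xm[k] > 0 and ym[k] > 0]
    n = len(keys)
    if n < 3:
        raise ValueError(f"need >= 3 shared positive values, got {n}")
    a = np.log10([xm[k] for k in keys])
    b = np.log10([ym[k] for k in keys])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in log kcat values; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(n=n, r=r, t=t, p=p)


def endpoint_correlation_matrix(endpoints, scope=None) -> np.ndarray:
    """Symmetric matrix of pairwise endpoint log-kcat Pearson R."""
    k = len(endpoints)
    if k < 2:
        raise ValueError("need >= 2 endpoints")
    R = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        R[i, j] = R[j, i] = correlate_log(endpoints[i], endpoints[j], scope=scope).r
    return R


def epistasis_diagnostics(trajectory) -> pd.DataFrame:
    """Per-fixed-event records for s-vs-background-growth analysis.

    Columns: iteration, reaction_id, s, mu_before, mu_after, and the total
    number of fixed mutations of that reaction (n_fixed_reaction).
    """
    records = [
        {"iteration": e.iteration, "reaction_id": e.reaction_id, "s": e.s,
         "mu_before": e.mu_before, "mu_after": e.mu_after}
        for e in trajectory.fixed_events()
    ]
    df = pd.DataFrame(records, columns=["iteration", "reaction_id", "s",
                                        "mu_before", "mu_after"])
    if len(df):
        counts = df["reaction_id"].value_counts()
        df["n_fixed_reaction"] = df["reaction_id"].map(counts).astype(int)
    else:
        df["n_fixed_reaction"] = pd.Series(dtype=int)
    return df


def detect_fitness_jumps(trajectory, model: MetabolicModel,
                         threshold_factor: float = 10.0) -> pd.DataFrame:
    """Rank genes by association with unusually large fitness gains.

    A fixed event is a jump when its growth-rate gain exceeds
    ``threshold_factor`` times the median gain over fixed events; the genes
    of the mutated reaction's GPR accumulate jump counts.
    """
    fixed = trajectory.fixed_events()
    gains = np.array([e.mu_after - e.mu_before for e in fixed])
    out_cols = ["gene", "jump_count"]
    if len(gains) == 0:
        return pd.DataFrame(columns=out_cols)
    cutoff = threshold_factor * float(np.median(gains))
    counts: dict[str, int] = {}
    for e, gain in zip(fixed, gains):
        if gain > cutoff:
            for gene in sorted(model.reaction(e.reaction_id).genes):
                counts[gene] = counts.get(gene, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=out_cols)


def iterations_to_half_growth(trajectory) -> int | None:
    """First iteration at which growth reaches half the endpoint rate."""
    target = trajectory.mu_end / 2.0
    initial_mu = trajectory.fixed_events()[0].mu_before if trajectory.fixed_events() else trajectory.mu_end
    if initial_mu >= target:
        return 0
    for e in trajectory.fixed_events():
        if e.mu_after >= target:
            return e.iteration
    return None


def wilcoxon_rank_sum(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; exact by enumeration for small n.

    For groups of at most ``exact_max_n`` observations each, the p-value is
    computed by enumerating all rank assignments (midranks for ties);
    larger samples use the normal approximation.
    Returns (rank sum of the first group, p).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.array(x + y)
    ranks = stats.rankdata(combined)  # midranks for ties
    w_obs = float(np.sum(ranks[:n]))
    if max(n, m) <= exact_max_n:
        expected = n * (n + m + 1) / 2.0
        d_obs = abs(w_obs - expected)
        total = 0
        hits = 0
        for idx in itertools.combinations(range(n + m), n):
            total += 1
            w = float(np.sum(ranks[list(idx)]))
            if abs(w - expected) >= d_obs - 1e-12:
                hits += 1
        return w_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def adaptation_speed_test(runs_a, runs_b) -> tuple[float, float]:
    """Compare adaptation speed between two groups of runs.

    Speed is measured as the number of simulated mutations needed to reach
    half the endpoint growth rate; the two-sided Wilcoxon rank-sum p-value
    is returned together with the rank sum of the first group.  Runs with
    no crossing are excluded with a warning.
    """
    def crossings(runs):
        xs = []
        for t in runs:
            c = iterations_to_half_growth(t)
            if c is None:
                logger.warning("run has no half-endpoint crossing; excluded")
            else:
                xs.append(c)
        return xs

    xs, ys = crossings(runs_a), crossings(runs_b)
    if len(xs) < 3 or len(ys) < 3:
        raise ValueError("need >= 3 usable runs per group")
    return wilcoxon_rank_sum(xs, ys)


def reaction_molecular_weight(gpr: GprExpression, weights: dict[str, float],
                              gpr_and_mode: str = "max") -> float:
    """Effective enzyme MW of a reaction: cheapest satisfying assignment.

    OR picks the lightest branch (one isozyme suffices).  AND depends on
    the capacity semantics: under "max" a single (cheapest) subunit pool
    sets the capacity, under "min" every subunit is needed (sum), under
    "sum_mw" the complex weighs the sum of its subunits.
    """
    if gpr.kind == "GENE":
        return weights[gpr.gene]
    child = [reaction_molecular_weight(c, weights, gpr_and_mode) for c in gpr.children]
    if gpr.kind == "OR":
        return min(child)
    if gpr_and_mode == "max":
        return min(child)
    return sum(child)


def selection_pressure_correlates(
    endpoint: KcatVector,
    model: MetabolicModel,
    environments: list[Environment | None],
    scope=None,
    gpr_and_mode: str = "max",
) -> tuple[CorrelationResult, CorrelationResult]:
    """Correlates of evolved kcats: mean pFBA flux and enzyme MW.

    Returns Pearson correlations (log10 scale) between endpoint kcats and
    (i) the mean absolute parsimonious-FBA flux across the supplied
    environments, (ii) the effective enzyme molecular weight.  Scope
    defaults to unconstrained reactions contributing to growth in at least
    one environment.
    """
    if scope is None:
        scope = set()
        for env in environments:
            fva = flux_variability(model, env)
            scope |= {rid for rid, (_, _, rel) in fva.items() if rel}
    scope = set(scope) & set(endpoint.unconstrained_ids())
    if len(scope) < 3:
        raise ValueError("need >= 3 growth-relevant unconstrained reactions")

    flux_sum = {rid: 0.0 for rid in scope}
    for env in environments:
        fluxes = parsimonious_fluxes(model, env)
        for rid in scope:
            flux_sum[rid] += abs(fluxes[rid])
    mean_flux = {rid: v / len(environments) for rid, v in flux_sum.items() if v > 0}

    mws = {
        rid: reaction_molecular_weight(model.reaction(rid).gpr, model.gene_weights,
                                       gpr_and_mode)
        for rid in scope
        if model.reaction(rid).gpr is not None
    }
    r_flux = correlate_log(endpoint, mean_flux, scope=scope)
    r_mw = correlate_log(endpoint, mws, scope=scope)
    return r_flux, r_mw


def pairwise_endpoint_fitness(
    model: MetabolicModel,
    endpoints: list[KcatVector],
    environment: Environment | None = None,
    C: float = 0.32,
    gpr_and_mode: str = "max",
    mean: str = "geometric",
    rel_tol: float = 1e-6,
) -> pd.DataFrame:
    """Fitness of pairwise-averaged endpoints (fitness-valley check).

    For each endpoint pair the element-wise (default geometric) mean kcat
    vector is solved alongside both endpoints; ``intermediate`` flags
    whether the averaged vector's growth is at least the worse endpoint's
    (no fitness valley between the two).
    """
    if len(endpoints) < 2:
        raise ValueError("need >= 2 endpoints")
    if mean not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown mean {mean!r}")
    problem = MomentProblem(model, environment, C=C, gpr_and_mode=gpr_and_mode)

    def mu_of(kv: KcatVector) -> float:
        sol = problem.solve(kv)
        if not sol.optimal:
            raise RuntimeError(f"growth problem not optimal: {sol.status}")
        return sol.growth_rate

    mus = [mu_of(kv) for kv in endpoints]
    rows = []
    for i, j in itertools.combinations(range(len(endpoints)), 2):
        a, b = endpoints[i], endpoints[j]
        merged = a.copy()
        for rid in merged.values:
            x, y = a.values[rid], b.values[rid]
            merged.values[rid] = math.sqrt(x * y) if mean == "geometric" else (x + y) / 2
        mu_mean = mu_of(merged)
        lo = min(mus[i], mus[j])
        rows.append({
            "pair_i": i, "pair_j": j, "mu_end_i": mus[i], "mu_end_j": mus[j],
            "mu_mean_vector": mu_mean,
            "intermediate": bool(mu_mean >= lo * (1 - rel_tol) - 1e-12),
        })
    return pd.DataFrame(rows)
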