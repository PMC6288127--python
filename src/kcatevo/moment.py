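"""Proteome-cost-constrained growth prediction (MOMENT) and plain FBA.

The growth problem maximizes flux v_z into the biomass reaction subject to

    S v = 0,          v_min <= v <= v_max,
    v_i <= 3600 * kappa_i * f(GPR_i, g)   for enzymatic reactions,
    sum_j g_j MW_j <= C,

where g_j (mmol gDW^-1) are enzyme concentration variables shared across
all reactions a gene catalyzes, kappa_i (s^-1) is the reaction's turnover
number (the 3600 converts to h^-1 so fluxes stay in mmol gDW^-1 h^-1), and
C (g gDW^-1, default 0.32) is the metabolic proteome budget.  The GPR
capacity f is built recursively: a gene leaf contributes its concentration,
OR nodes (isozymes) sum their children, and AND nodes (complexes) are
handled per ``gpr_and_mode``:

``max``
    capacity limited by the largest subunit pool.  This disjunctive
    constraint is non-convex and is solved exactly as a MILP when AND
    nodes are present (pure LP otherwise).
``min``
    capacity limited by the scarcest subunit (convex, classic choice).
``sum_mw``
    one concentration variable per complex whose molecular weight is the
    sum of its subunits' weights (convex).

Reversible reactions are split into non-negative forward/backward halves
whose *sum* is capacity-bounded by the same kappa*g term, so a mutation in
kappa affects both directions equally (Haldane coupling, one kappa per
reaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .gpr import GprExpression
from .model import Environment, MetabolicModel, apply_environment

__all__ = [
    "KcatVector",
    "MomentSolution",
    "MomentProblem",
    "solve_fba",
    "solve_moment",
    "flux_variability",
    "parsimonious_fluxes",
    "theoretical_max_growth",
    "DEFAULT_PROTEOME_BUDGET",
    "GROWTH_RELEVANCE_THRESHOLD",
    "FAST_ENZYME_KCAT",
]

DEFAULT_PROTEOME_BUDGET = 0.32  # g protein per gDW, E. coli metabolic fraction
GROWTH_RELEVANCE_THRESHOLD = 1e-6  # mmol gDW^-1 h^-1
FAST_ENZYME_KCAT = 1e5  # s^-1, scale of the fastest known enzymes

CONSTRAINED = "constrained"
UNCONSTRAINED = "unconstrained"
NON_ENZYMATIC = "non_enzymatic"


@dataclass
class KcatVector:
    """Per-reaction turnover numbers (s^-1) with mutability flags.

    ``flags`` classifies each reaction as ``constrained`` (biophysically
    limited, immutable under mutation), ``unconstrained`` (evolving), or
    ``non_enzymatic`` (no GPR, no capacity constraint, no kcat).
    """

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, kcat in self.values.items():
            if not kcat > 0:
                raise ValueError(f"kcat for {rid} must be positive, got {kcat}")

    def unconstrained_ids(self) -> list[str]:
        return sorted(r for r, f in self.flags.items() if f == UNCONSTRAINED)

    def constrained_ids(self) -> list[str]:
        return sorted(r for r, f in self.flags.items() if f == CONSTRAINED)

    def copy(self) -> "KcatVector":
        return KcatVector(dict(self.values), dict(self.flags))

    def with_value(self, rid: str, kcat: float) -> "KcatVector":
        if self.flags.get(rid) == CONSTRAINED:
            raise ValueError(f"reaction {rid} is biophysically constrained")
        out = self.copy()
        out.values[rid] = kcat
        return out

    @classmethod
    def uniform(cls, model: MetabolicModel, kcat: float, flag: str = UNCONSTRAINED) -> "KcatVector":
        rids = model.enzymatic_reaction_ids()
        return cls({r: kcat for r in rids}, {r: flag for r in rids})


@dataclass
class MomentSolution:
    status: str
    growth_rate: float
    fluxes: dict[str, float]
    gene_concentrations: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def proteome_mass(self, model: MetabolicModel) -> float:
        return sum(
            g * model.gene_weights[gene]
            for gene, g in self.gene_concentrations.items()
            if gene in model.gene_weights
        )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class _Builder:
    """Incremental construction of variables and constraint rows."""

    def __init__(self) -> None:
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.rows_ub: list[dict[int, float]] = []
        self.rhs_ub: list[float] = []

    def add_var(self, lb: float, ub: float, integer: bool = False) -> int:
        self.lb.append(lb)
        self.ub.append(ub)
        self.integrality.append(1 if integer else 0)
        return len(self.lb) - 1

    def add_ub_row(self, coefs: dict[int, float], rhs: float) -> int:
        self.rows_ub.append(coefs)
        self.rhs_ub.append(rhs)
        return len(self.rows_ub) - 1


class MomentProblem:
    """Reusable MOMENT problem for one (model, environment, mode, budget).

    The constraint skeleton is built once; solving for a new kcat vector
    only rescales the per-reaction capacity rows.  This makes the adaptive
    walk (one LP per proposed mutation) cheap.
    """

    def __init__(
        self,
        model: MetabolicModel,
        environment: Environment | None = None,
        C: float = DEFAULT_PROTEOME_BUDGET,
        gpr_and_mode: str = "max",
        enzyme_constraints: bool = True,
    ) -> None:
        if not C > 0:
            raise ValueError(f"proteome budget C must be positive, got {C}")
        if gpr_and_mode not in ("max", "min", "sum_mw"):
            raise ValueError(f"unknown gpr_and_mode {gpr_and_mode!r}")
        if model.biomass_reaction_id is None:
            raise ValueError("model has no biomass reaction")
        self.model = model
        self.C = float(C)
        self.mode = gpr_and_mode
        self.enzyme_constraints = enzyme_constraints
        self.bounds_by_rxn = apply_environment(model, environment)

        b = _Builder()
        self._fwd: dict[str, int] = {}
        self._rev: dict[str, int] = {}
        for rxn in model.reactions:
            lb, ub = self.bounds_by_rxn[rxn.id]
            if ub > 0 or lb >= 0:
                self._fwd[rxn.id] = b.add_var(max(0.0, lb), max(0.0, ub))
            if lb < 0:
                self._rev[rxn.id] = b.add_var(max(0.0, -ub), -lb)

        self._gene_var: dict[str, int] = {}
        self._has_and = False
        self._budget_terms: dict[int, float] = {}
        self._capacity: list[tuple[str, int, dict[int, float]]] = []
        if enzyme_constraints:
            for gene in sorted(model.genes):
                try:
                    mw = model.gene_weights[gene]
                except KeyError:
                    raise ValueError(
                        f"gene {gene} has no molecular weight; supply a gene "
                        "weight table or protein FASTA"
                    ) from None
                self._gene_var[gene] = b.add_var(0.0, self.C / mw)
            self._budget_terms = {
                v: model.gene_weights[g] for g, v in self._gene_var.items()
            }
            # capacity rows: v_f + v_r - 3600*kappa*f_expr <= 0; the f_expr
            # coefficients are stored unscaled and multiplied by kappa at solve
            for rxn in model.reactions:
                if rxn.gpr is None:
                    continue
                f_expr = self._build_f(b, rxn.gpr)
                coefs: dict[int, float] = {}
                if rxn.id in self._fwd:
                    coefs[self._fwd[rxn.id]] = 1.0
                if rxn.id in self._rev:
                    coefs[self._rev[rxn.id]] = coefs.get(self._rev[rxn.id], 0.0) + 1.0
                row = b.add_ub_row(coefs, 0.0)
                self._capacity.append((rxn.id, row, f_expr))
            self._budget_row = b.add_ub_row(dict(self._budget_terms), self.C)
        self._b = b
        self._n_vars = len(b.lb)

        # steady-state rows S (v_f - v_r) = 0
        S = model.stoichiometric_matrix().tocoo()
        eq_rows: list[dict[int, float]] = [dict() for _ in model.metabolites]
        rids = model.reaction_ids()
        for i, j, coef in zip(S.row, S.col, S.data):
            rid = rids[j]
            if rid in self._fwd:
                eq_rows[i][self._fwd[rid]] = eq_rows[i].get(self._fwd[rid], 0.0) + coef
            if rid in self._rev:
                eq_rows[i][self._rev[rid]] = eq_rows[i].get(self._rev[rid], 0.0) - coef
        self._A_eq = self._dense(eq_rows, self._n_vars)
        self._b_eq = np.zeros(len(eq_rows))
        self._A_ub_template = self._dense(b.rows_ub, self._n_vars)
        self._rhs_ub = np.array(b.rhs_ub)
        self._extra_ub_rows: list[tuple[np.ndarray, float]] = []
        self._objective_override: np.ndarray | None = None
        self._minimize = False

    # -- GPR capacity recursion -------------------------------------------
    def _build_f(self, b: _Builder, node: GprExpression) -> dict[int, float]:
        if node.kind == "GENE":
            return {self._gene_var[node.gene]: 1.0}
        if node.kind == "OR":
            expr: dict[int, float] = {}
            for child in node.children:
                for var, coef in self._build_f(b, child).items():
                    expr[var] = expr.get(var, 0.0) + coef
            return expr
        # AND node
        if self.mode == "sum_mw":
            mw = sum(self.model.gene_weights[g] for g in node.genes())
            var = b.add_var(0.0, self.C / mw)
            self._budget_terms[var] = mw
            return {var: 1.0}
        child_exprs = [self._build_f(b, c) for c in node.children]
        bound = self._expr_bound_max(b, child_exprs)
        aux = b.add_var(0.0, bound)
        if self.mode == "min":
            for expr in child_exprs:
                row = {aux: 1.0}
                for var, coef in expr.items():
                    row[var] = row.get(var, 0.0) - coef
                b.add_ub_row(row, 0.0)
            return {aux: 1.0}
        # mode == "max": aux <= f_child_k + M (1 - y_k), sum_k y_k = 1
        self._has_and = True
        M = bound
        ys = []
        for expr in child_exprs:
            y = b.add_var(0.0, 1.0, integer=True)
            ys.append(y)
            row = {aux: 1.0, y: M}
            for var, coef in expr.items():
                row[var] = row.get(var, 0.0) - coef
            b.add_ub_row(row, M)
        b.add_ub_row({y: 1.0 for y in ys}, 1.0)
        b.add_ub_row({y: -1.0 for y in ys}, -1.0)
        return {aux: 1.0}

    def _expr_bound_max(self, b: _Builder, exprs: list[dict[int, float]]) -> float:
        best = 0.0
        for expr in exprs:
            best = max(best, sum(coef * b.ub[var] for var, coef in expr.items()))
        return best

    # -- assembly ----------------------------------------------------------
    @staticmethod
    def _dense(rows: list[dict[int, float]], n: int) -> np.ndarray:
        A = np.zeros((len(rows), n))
        for i, row in enumerate(rows):
            for j, coef in row.items():
                A[i, j] = coef
        return A

    def _objective(self) -> np.ndarray:
        if self._objective_override is not None:
            return self._objective_override
        c = np.zeros(self._n_vars)
        z = self.model.biomass_reaction_id
        if z in self._fwd:
            c[self._fwd[z]] = -1.0
        if z in self._rev:
            c[self._rev[z]] = 1.0
        return c

    def net_flux_coefs(self, rid: str) -> np.ndarray:
        c = np.zeros(self._n_vars)
        if rid in self._fwd:
            c[self._fwd[rid]] = 1.0
        if rid in self._rev:
            c[self._rev[rid]] = -1.0
        return c

    def _assemble_ub(self, kcats: KcatVector | None) -> tuple[np.ndarray, np.ndarray]:
        A = self._A_ub_template.copy()
        for rid, row, f_expr in self._capacity:
            if kcats is None:
                # no kcat vector: capacity constraints vacuous (plain FBA)
                A[row, :] = 0.0
                continue
            try:
                kappa = kcats.values[rid]
            except KeyError:
                raise ValueError(f"missing kcat for enzymatic reaction {rid}") from None
            scale = 3600.0 * kappa
            for var, coef in f_expr.items():
                A[row, var] = -scale * coef
        rhs = self._rhs_ub
        if self._extra_ub_rows:
            A = np.vstack([A] + [r for r, _ in self._extra_ub_rows])
            rhs = np.concatenate([rhs, [v for _, v in self._extra_ub_rows]])
        return A, rhs

    def solve(self, kcats: KcatVector | None) -> MomentSolution:
        c = self._objective()
        A_ub, b_ub = self._assemble_ub(kcats)
        bounds = np.column_stack([self._b.lb, self._b.ub])
        if self._has_and and kcats is not None:
            res = self._solve_milp(c, A_ub, b_ub, bounds)
        else:
            res = optimize.linprog(
                c,
                A_ub=A_ub,
                b_ub=b_ub,
                A_eq=self._A_eq,
                b_eq=self._b_eq,
                bounds=bounds,
                method="highs",
            )
        status = _STATUS.get(res.status, "failed")
        if status != "optimal":
            return MomentSolution(status, float("nan"), {}, {})
        x = res.x
        fluxes = {}
        for rxn in self.model.reactions:
            v = 0.0
            if rxn.id in self._fwd:
                v += x[self._fwd[rxn.id]]
            if rxn.id in self._rev:
                v -= x[self._rev[rxn.id]]
            fluxes[rxn.id] = float(v)
        genes = {g: float(x[var]) for g, var in self._gene_var.items()}
        mu = fluxes[self.model.biomass_reaction_id]
        if self._minimize:
            obj = float(res.fun)
        else:
            obj = mu
        sol = MomentSolution("optimal", max(0.0, mu), fluxes, genes)
        sol.objective_value = obj  # type: ignore[attr-defined]
        return sol

    def _solve_milp(self, c, A_ub, b_ub, bounds):
        constraints = [
            optimize.LinearConstraint(A_ub, -np.inf, b_ub),
            optimize.LinearConstraint(self._A_eq, self._b_eq, self._b_eq),
        ]
        res = optimize.milp(
            c,
            constraints=constraints,
            bounds=optimize.Bounds(bounds[:, 0], bounds[:, 1]),
            integrality=np.array(self._b.integrality),
        )
        # align status codes with linprog's
        res.status = {0: 0, 2: 2, 3: 3}.get(res.status, 4)
        return res


def solution_tables(model: MetabolicModel, solution: MomentSolution):
    """Flux and gene-concentration tables (pandas) for TSV export."""
    import pandas as pd

    fluxes = pd.DataFrame(
        [{"reaction_id": r, "flux": v} for r, v in sorted(solution.fluxes.items())]
    )
    genes = pd.DataFrame(
        [{"gene_id": g, "concentration_mmol_per_gDW": c,
          "mass_g_per_gDW": c * model.gene_weights.get(g, float("nan"))}
         for g, c in sorted(solution.gene_concentrations.items())]
    )
    return fluxes, genes


def fva_table(fva: dict[str, tuple[float, float, bool]]):
    """Flux-variability result as a pandas table for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [{"reaction_id": r, "min_flux": lo, "max_flux": hi, "growth_relevant": rel}
         for r, (lo, hi, rel) in sorted(fva.items())]
    )


def solve_fba(model: MetabolicModel, environment: Environment | None = None) -> MomentSolution:
    """Plain FBA: maximize biomass flux subject to S v = 0 and bounds."""
    problem = MomentProblem(model, environment, enzyme_constraints=False)
    return problem.solve(None)


def solve_moment(
    model: MetabolicModel,
    kcats: KcatVector,
    environment: Environment | None = None,
    C: float = DEFAULT_PROTEOME_BUDGET,
    gpr_and_mode: str = "max",
) -> MomentSolution:
    """Maximize growth under kcat capacity constraints and proteome budget."""
    problem = MomentProblem(model, environment, C=C, gpr_and_mode=gpr_and_mode)
    return problem.solve(kcats)


def _fix_growth(problem: MomentProblem, mu: float) -> None:
    z = problem.model.biomass_reaction_id
    row = -problem.net_flux_coefs(z)
    slack = max(1e-12, 1e-9 * abs(mu))
    problem._extra_ub_rows.append((row, -(mu - slack)))


def flux_variability(
    model: MetabolicModel,
    environment: Environment | None = None,
    kcats: KcatVector | None = None,
    C: float = DEFAULT_PROTEOME_BUDGET,
    gpr_and_mode: str = "max",
    threshold: float = GROWTH_RELEVANCE_THRESHOLD,
) -> dict[str, tuple[float, float, bool]]:
    """Per-reaction flux range at the growth optimum, plus growth relevance.

    A reaction "contributes to growth in silico" when its maximal flux or
    absolute minimal flux at the optimum exceeds 1e-6 mmol gDW^-1 h^-1.
    With ``kcats`` given the ranges are computed in the MOMENT polytope,
    otherwise in the FBA polytope.
    """
    problem = MomentProblem(model, environment, C=C, gpr_and_mode=gpr_and_mode,
                            enzyme_constraints=kcats is not None)
    base = problem.solve(kcats)
    if not base.optimal:
        raise RuntimeError(f"base problem not optimal: {base.status}")
    _fix_growth(problem, base.growth_rate)
    out: dict[str, tuple[float, float, bool]] = {}
    for rid in model.reaction_ids():
        coefs = problem.net_flux_coefs(rid)
        lo_hi = []
        for sign in (1.0, -1.0):
            problem._objective_override = sign * coefs
            problem._minimize = True
            sol = problem.solve(kcats)
            if not sol.optimal:
                raise RuntimeError(f"FVA subproblem for {rid} not optimal: {sol.status}")
            lo_hi.append(sol.fluxes[rid])
        problem._objective_override = None
        problem._minimize = False
        vmin, vmax = lo_hi
        relevant = (vmax > threshold) or (abs(vmin) > threshold)
        out[rid] = (float(vmin), float(vmax), bool(relevant))
    return out


def parsimonious_fluxes(
    model: MetabolicModel,
    environment: Environment | None = None,
    kcats: KcatVector | None = None,
    C: float = DEFAULT_PROTEOME_BUDGET,
    gpr_and_mode: str = "max",
) -> dict[str, float]:
    """pFBA: the flux vector of minimal total |v| among growth optima."""
    problem = MomentProblem(model, environment, C=C, gpr_and_mode=gpr_and_mode,
                            enzyme_constraints=kcats is not None)
    # forward/backward splitting makes sum of |v| a linear objective
    base = problem.solve(kcats)
    if not base.optimal:
        raise RuntimeError(f"base problem not optimal: {base.status}")
    _fix_growth(problem, base.growth_rate)
    c = np.zeros(problem._n_vars)
    for var in problem._fwd.values():
        c[var] = 1.0
    for var in problem._rev.values():
        c[var] = 1.0
    problem._objective_override = c
    problem._minimize = True
    sol = problem.solve(kcats)
    if not sol.optimal:
        raise RuntimeError(f"pFBA problem not optimal: {sol.status}")
    return sol.fluxes


def theoretical_max_growth(
    model: MetabolicModel,
    kcats: KcatVector,
    environment: Environment | None = None,
    C: float = DEFAULT_PROTEOME_BUDGET,
    gpr_and_mode: str = "max",
    fast_kcat: float = FAST_ENZYME_KCAT,
) -> float:
    """Growth with every unconstrained kcat set to the fast-enzyme scale.

    Constrained kcats are untouched; the result is the growth rate the
    network could reach if evolution were free to optimize every
    biophysically unconstrained enzyme to ~1e5 s^-1.
    """
    fast = kcats.copy()
    for rid in fast.unconstrained_ids():
        fast.values[rid] = fast_kcat
    sol = solve_moment(model, fast, environment, C=C, gpr_and_mode=gpr_and_mode)
    if not sol.optimal:
        raise RuntimeError(f"theoretical max problem not optimal: {sol.status}")
    return sol.growth_rate
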