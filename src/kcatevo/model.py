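"""In-memory representation of constraint-based metabolic models.

The central container is :class:`MetabolicModel`: a stoichiometric matrix
S (metabolites x reactions), per-reaction flux bounds and GPR rules, and
per-gene molecular weights (g mmol^-1) used by the proteome-cost growth
problem.  :class:`Environment` describes which exchange reactions allow
uptake (BiGG convention: uptake is a negative lower bound on the exchange
flux; the environment stores the non-negative uptake magnitude and the
sign is applied when bounds are materialised).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .gpr import GprExpression

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Environment",
    "ModelValidationError",
    "parse_formula",
]


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    formula: str | None = None
    compartment: str | None = None


@dataclass
class Reaction:
    """A reaction: stoichiometry, flux bounds (mmol gDW^-1 h^-1), GPR.

    ``metabolites`` maps metabolite id -> stoichiometric coefficient
    (negative = consumed).  ``gpr`` is ``None`` for non-enzymatic
    (spontaneous, exchange, biomass) reactions.
    """

    id: str
    metabolites: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GprExpression | None = None
    ec_number: str | None = None
    name: str | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()

    def validate(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.metabolites:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")


@dataclass
class MetabolicModel:
    """Stoichiometric network with GPRs and gene molecular weights."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    gene_weights: dict[str, float] = field(default_factory=dict)
    biomass_reaction_id: str | None = None
    declared_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ---------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return out

    @property
    def exchange_reaction_ids(self) -> list[str]:
        """Boundary reactions touching a single metabolite (biomass excluded)."""
        return [
            r.id for r in self.reactions
            if len(r.metabolites) == 1 and r.id != self.biomass_reaction_id
        ]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S as a sparse metabolite x reaction matrix."""
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.metabolites.items():
                try:
                    rows.append(self._met_index[mid])
                except KeyError:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references undeclared metabolite {mid}"
                    ) from None
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def enzymatic_reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.gpr is not None]

    def oxygen_exchange_id(self) -> str | None:
        """Exchange of a metabolite with formula O2, if any."""
        for rid in self.exchange_reaction_ids:
            (mid,) = self.reaction(rid).metabolites
            met = self.metabolite(mid)
            if met.formula and parse_formula(met.formula) == {"O": 2}:
                return rid
        return None

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ModelValidationError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelValidationError("duplicate reaction ids")
        for rxn in self.reactions:
            rxn.validate()
            for mid in rxn.metabolites:
                if mid not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {mid}"
                    )
            for gene in rxn.genes:
                if self.declared_genes and gene not in self.declared_genes:
                    raise ModelValidationError(
                        f"GPR of reaction {rxn.id} references undeclared gene {gene}"
                    )
                if gene in self.gene_weights:
                    mw = self.gene_weights[gene]
                    if not (mw > 0) or not math.isfinite(mw):
                        raise ModelValidationError(
                            f"gene {gene} has non-positive molecular weight {mw}"
                        )
        if self.biomass_reaction_id is not None:
            if self.biomass_reaction_id not in self._rxn_index:
                raise ModelValidationError(
                    f"biomass reaction {self.biomass_reaction_id} not in model"
                )
            if not self.reaction(self.biomass_reaction_id).upper_bound > 0:
                raise ModelValidationError(
                    "biomass reaction has non-positive upper bound"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[Metabolite(m.id, m.formula, m.compartment) for m in self.metabolites],
            reactions=[
                Reaction(
                    id=r.id,
                    metabolites=dict(r.metabolites),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    gpr=r.gpr,
                    ec_number=r.ec_number,
                    name=r.name,
                )
                for r in self.reactions
            ],
            gene_weights=dict(self.gene_weights),
            biomass_reaction_id=self.biomass_reaction_id,
            declared_genes=self.declared_genes,
        )


@dataclass
class Environment:
    """Growth environment: open exchange reactions with uptake magnitudes.

    ``open_exchanges`` maps exchange reaction id -> uptake bound magnitude
    (>= 0, applied as a negative lower bound).  Exchanges not listed allow
    secretion only.  ``oxygen_available`` records whether the oxygen
    exchange was opened (it then also appears in ``open_exchanges``).
    """

    open_exchanges: dict[str, float]
    oxygen_available: bool = False
    id: str | None = None

    def validate(self, model: MetabolicModel) -> None:
        exchanges = set(model.exchange_reaction_ids)
        for rid, uptake in self.open_exchanges.items():
            if rid not in exchanges:
                raise ModelValidationError(
                    f"environment opens {rid}, which is not an exchange reaction"
                )
            if uptake < 0:
                raise ModelValidationError(
                    f"environment uptake for {rid} is negative ({uptake})"
                )

    @classmethod
    def from_model(cls, model: MetabolicModel) -> "Environment":
        """Capture the model's native exchange lower bounds as an environment."""
        open_ex = {}
        for rid in model.exchange_reaction_ids:
            lb = model.reaction(rid).lower_bound
            if lb < 0:
                open_ex[rid] = -lb
        o2 = model.oxygen_exchange_id()
        return cls(open_exchanges=open_ex, oxygen_available=o2 in open_ex, id="native")


def apply_environment(
    model: MetabolicModel, environment: Environment | None
) -> dict[str, tuple[float, float]]:
    """Per-reaction (lb, ub) with the environment's uptake bounds applied.

    Exchange reactions get lb = -uptake if open else 0 (secretion keeps the
    model's upper bound); all other reactions keep their native bounds.
    """
    bounds = {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}
    if environment is None:
        return bounds
    environment.validate(model)
    for rid in model.exchange_reaction_ids:
        ub = model.reaction(rid).upper_bound
        uptake = environment.open_exchanges.get(rid, 0.0)
        bounds[rid] = (-float(uptake), ub)
    return bounds


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation chemical formula into element counts.

    Raises ``ValueError`` on charge annotations or polymeric R/X groups,
    which cannot be mapped to element counts.
    """
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, num = match.group(1), match.group(2)
        if element in ("R", "X"):
            raise ValueError(f"polymeric group {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts
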