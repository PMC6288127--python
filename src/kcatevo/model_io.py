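"""Reading, writing, and annotating metabolic models.

Two dialects are supported: BiGG-style JSON (canonical for the bundled toy
models because it is human-writable and can carry gene molecular weights in
gene annotations) and SBML Level 3 with the fbc package (parsed through
cobrapy and converted).  Gene molecular weights can come from an explicit
TSV table or be computed from protein FASTA sequences; an explicit table
takes precedence and a gene without either source is an error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.SeqUtils import molecular_weight as _bio_mw

from .gpr import parse_gpr
from .model import (
    Environment,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_formula,
)

__all__ = [
    "read_model",
    "write_model",
    "protein_molecular_weight",
    "load_gene_weights_tsv",
    "gene_weights_from_fasta",
    "classify_exchange_sources",
]

logger = logging.getLogger(__name__)

WATER_MW = 18.0153  # average mass of H2O, g mmol^-1

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def protein_molecular_weight(sequence: str) -> float:
    """Average molecular weight of a peptide in g mmol^-1 (== Da).

    Sum of average residue masses minus one water per peptide bond.
    Only the 20 standard amino-acid letters are accepted.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    for i, letter in enumerate(seq):
        if letter not in _AA_LETTERS:
            raise ValueError(
                f"unknown amino-acid letter {letter!r} at position {i} in sequence"
            )
    return float(_bio_mw(seq, seq_type="protein", monoisotopic=False))


def gene_weights_from_fasta(path: str | Path, strip_stop: bool = True) -> dict[str, float]:
    """Gene id -> molecular weight (g mmol^-1) from a protein FASTA file."""
    weights: dict[str, float] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if strip_stop:
            seq = seq.rstrip("*")
        weights[record.id] = protein_molecular_weight(seq)
    if not weights:
        raise ValueError(f"no sequences found in {path}")
    return weights


def load_gene_weights_tsv(path: str | Path) -> dict[str, float]:
    """Gene id -> MW from a TSV with columns gene_id, mw_g_per_mmol."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    if not {"gene_id", "mw_g_per_mmol"} <= set(table.columns):
        raise ValueError("gene weight table needs columns gene_id, mw_g_per_mmol")
    weights = dict(zip(table["gene_id"].astype(str), table["mw_g_per_mmol"].astype(float)))
    bad = [g for g, w in weights.items() if not w > 0]
    if bad:
        raise ValueError(f"non-positive molecular weight for genes: {bad}")
    return weights


def _find_biomass(reactions: list[Reaction], objective_ids: list[str]) -> str | None:
    if objective_ids:
        return objective_ids[0]
    for r in reactions:
        if "biomass" in r.id.lower():
            return r.id
    return None


def read_model(
    path: str | Path,
    dialect: str = "json",
    gene_weights: dict[str, float] | None = None,
) -> MetabolicModel:
    """Read and validate a metabolic model.

    ``dialect`` is ``"json"`` (BiGG-style JSON) or ``"sbml"`` (Level 3 +
    fbc, parsed via cobrapy).  ``gene_weights`` overrides/extends any
    weights carried in the file (explicit table > file annotation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "json":
        model = _read_json(path)
    elif dialect == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model dialect {dialect!r}")
    if gene_weights:
        model.gene_weights.update(gene_weights)
    model.validate()
    return model


def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"cannot parse JSON model {path}: {exc}") from exc
    try:
        metabolites = [
            Metabolite(
                id=str(m["id"]),
                formula=m.get("formula") or None,
                compartment=m.get("compartment") or None,
            )
            for m in doc["metabolites"]
        ]
        objective_ids = []
        reactions = []
        for r in doc["reactions"]:
            annotation = r.get("annotation") or {}
            ec = annotation.get("ec-code")
            if isinstance(ec, list):
                ec = ec[0] if ec else None
            reactions.append(
                Reaction(
                    id=str(r["id"]),
                    metabolites={str(k): float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", 1000.0)),
                    gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                    ec_number=ec,
                    name=r.get("name"),
                )
            )
            if float(r.get("objective_coefficient", 0.0)) != 0.0:
                objective_ids.append(str(r["id"]))
        gene_weights = {}
        declared = set()
        for g in doc.get("genes", []):
            declared.add(str(g["id"]))
            ann = g.get("annotation") or {}
            mw = ann.get("mw_g_per_mmol", g.get("mw_g_per_mmol"))
            if mw is not None:
                gene_weights[str(g["id"])] = float(mw)
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelValidationError(f"malformed JSON model {path}: {exc}") from exc
    return MetabolicModel(
        id=str(doc.get("id", path.stem)),
        metabolites=metabolites,
        reactions=reactions,
        gene_weights=gene_weights,
        biomass_reaction_id=_find_biomass(reactions, objective_ids),
        declared_genes=frozenset(declared),
    )


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [
        Metabolite(id=m.id, formula=m.formula or None, compartment=m.compartment or None)
        for m in cm.metabolites
    ]
    objective_ids = [r.id for r in cm.reactions if r.objective_coefficient]
    reactions = []
    for r in cm.reactions:
        ec = r.annotation.get("ec-code")
        if isinstance(ec, list):
            ec = ec[0] if ec else None
        reactions.append(
            Reaction(
                id=r.id,
                metabolites={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule),
                ec_number=ec,
                name=r.name or None,
            )
        )
    return MetabolicModel(
        id=cm.id or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        gene_weights={},
        biomass_reaction_id=_find_biomass(reactions, objective_ids),
        declared_genes=frozenset(g.id for g in cm.genes),
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model to BiGG-style JSON (round-trips with ``read_model``)."""
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "formula": m.formula, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.metabolites,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "annotation": {"ec-code": r.ec_number} if r.ec_number else {},
                "objective_coefficient": 1.0 if r.id == model.biomass_reaction_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [
            {"id": g, "annotation": {"mw_g_per_mmol": mw}}
            for g, mw in sorted(model.gene_weights.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False))


_SOURCE_ELEMENTS = ("C", "N", "S", "P")


def classify_exchange_sources(model: MetabolicModel) -> dict[str, list[str]]:
    """Map element in {C, N, S, P} -> exchanges whose metabolite contains it.

    One exchange may appear under several elements (e.g. cysteine under C,
    N, and S).  Exchanges whose metabolite lacks a parseable formula are
    excluded with a logged warning.
    """
    sources: dict[str, list[str]] = {e: [] for e in _SOURCE_ELEMENTS}
    for rid in model.exchange_reaction_ids:
        (mid,) = model.reaction(rid).metabolites
        met = model.metabolite(mid)
        if not met.formula:
            logger.warning("exchange %s: metabolite %s has no formula; excluded", rid, mid)
            continue
        try:
            counts = parse_formula(met.formula)
        except ValueError as exc:
            logger.warning("exchange %s: %s; excluded", rid, exc)
            continue
        for element in _SOURCE_ELEMENTS:
            if counts.get(element, 0) >= 1:
                sources[element].append(rid)
    return sources
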