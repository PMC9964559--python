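"""Metabolic network model: domain types, GPR rules, model I/O, medium bounds.

The native on-disk format is a small JSON dialect (see :func:`read_model`);
SBML Level 3 + FBC is supported through cobrapy for interoperability with
published genome-scale models.

Conventions
-----------
* Exchange reactions are reactions with exactly one metabolite; negative
  flux means uptake into the system (COBRA convention).
* GPR rules are boolean expressions over gene identifiers with ``and``,
  ``or`` and parentheses.  Evaluated numerically, ``and`` takes the minimum
  of its children (enzyme complex limited by its scarcest subunit) and
  ``or`` takes the sum (isozymes contribute additively).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import GprParseError, ValidationError

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "parse_gpr",
    "gpr_genes",
    "evaluate_gpr",
    "read_model",
    "write_model",
    "apply_medium",
]

_INF = math.inf


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and an optional GPR rule.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed).  Bounds are in µmol/min/L.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lb: float = 0.0
    ub: float = 1000.0
    reversible: bool | None = None
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if self.reversible is None:
            self.reversible = self.lb < 0
        if self.lb > self.ub:
            raise ValidationError(f"reaction {self.id!r}: lb ({self.lb}) > ub ({self.ub})")
        if not self.reversible and self.lb < 0:
            raise ValidationError(f"reaction {self.id!r}: irreversible but lb < 0")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def stoichiometric_matrix(self):
        """Dense S (metabolites x reactions) as a numpy array."""
        import numpy as np

        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], j] = coef
        return S

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            genes=list(self.genes),
            objective=dict(self.objective),
            id=self.id,
        )

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dups = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dups}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dups = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dups}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: {sorted(missing)}"
                )
        declared = set(self.genes)
        for r in self.reactions:
            used = r.genes()
            extra = used - declared
            if extra:
                # auto-declare rather than fail: GPR is the authority
                self.genes.extend(sorted(extra))
                declared |= extra
        for rid in self.objective:
            if rid not in set(rxn_ids):
                raise ValidationError(f"objective references unknown reaction {rid!r}")


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")
_KEYWORDS = {"and", "or"}


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str):
    """Parse a GPR string into a nested tuple AST.

    Nodes are ``("gene", id)``, ``("and", [children])`` or
    ``("or", [children])``.  Empty/whitespace rules parse to ``None``.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def pos():
        return tokens[idx][1] if idx < len(tokens) else len(rule)

    def parse_or():
        nonlocal idx
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_and():
        nonlocal idx
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_atom():
        nonlocal idx
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", len(rule))
        if tok == "(":
            idx += 1
            node = parse_or()
            if peek() != ")":
                raise GprParseError("expected ')'", pos())
            idx += 1
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GprParseError(f"unexpected token {tok!r}", pos())
        idx += 1
        return ("gene", tok)

    tree = parse_or()
    if idx != len(tokens):
        raise GprParseError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return tree


def gpr_genes(rule) -> frozenset[str]:
    """The set of gene ids referenced by a GPR string or AST."""
    tree = parse_gpr(rule) if isinstance(rule, str) or rule is None else rule
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        kind = node[0]
        if kind == "gene":
            out.add(node[1])
        else:
            for child in node[1]:
                walk(child)

    walk(tree)
    return frozenset(out)


def evaluate_gpr(rule, abundance: Mapping[str, float], missing: float | None = None):
    """Map gene abundances to an enzyme abundance through a GPR rule.

    AND returns the minimum of its children, OR the sum.  An empty rule
    returns ``None`` (the "unconstrained" sentinel).  Genes absent from
    ``abundance`` take the value ``missing``; if ``missing`` is None a
    ``KeyError`` is raised for absent genes.
    """
    tree = parse_gpr(rule) if isinstance(rule, str) or rule is None else rule
    if tree is None:
        return None

    def walk(node) -> float:
        kind = node[0]
        if kind == "gene":
            gene = node[1]
            if gene in abundance:
                return float(abundance[gene])
            if missing is None:
                raise KeyError(f"gene {gene!r} has no abundance entry")
            return float(missing)
        values = [walk(child) for child in node[1]]
        return min(values) if kind == "and" else sum(values)

    return walk(tree)


# ---------------------------------------------------------------------------
# Model I/O
# ---------------------------------------------------------------------------

def _network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "id": network.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lb": None if r.lb == -_INF else r.lb,
                "ub": None if r.ub == _INF else r.ub,
                "reversible": r.reversible,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in network.reactions
        ],
        "genes": list(network.genes),
        "objective": dict(network.objective),
    }


def _network_from_dict(doc: dict) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
            )
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            lb = r.get("lb", 0.0)
            ub = r.get("ub", 1000.0)
            rxns.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lb=-_INF if lb is None else float(lb),
                    ub=_INF if ub is None else float(ub),
                    reversible=r.get("reversible"),
                    gpr=r.get("gpr", "") or "",
                    subsystem=r.get("subsystem", "") or "",
                )
            )
    except KeyError as exc:
        raise ValidationError(f"model document missing required field {exc}") from exc
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        genes=list(doc.get("genes", [])),
        objective={k: float(v) for k, v in doc.get("objective", {}).items()},
        id=doc.get("id", "model"),
    )


def read_model(path, format: str = "json") -> MetabolicNetwork:
    """Read a metabolic model from disk.

    Parameters
    ----------
    path : str or Path
    format : {"json", "sbml"}
        ``json`` is the package's native dialect; ``sbml`` accepts
        SBML Level 3 + FBC via cobrapy.
    """
    if format == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"malformed model JSON in {path}: {exc}") from exc
        return _network_from_dict(doc)
    if format == "sbml":
        return _from_cobra(_read_sbml(path))
    raise ValidationError(f"unknown model format {format!r}")


def write_model(network: MetabolicNetwork, path, format: str = "json") -> None:
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_network_to_dict(network), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(network), str(path))
        return
    raise ValidationError(f"unknown model format {format!r}")


def _read_sbml(path):
    import cobra.io

    return cobra.io.read_sbml_model(str(path))


def _from_cobra(model) -> MetabolicNetwork:
    mets = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in model.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lb=float(r.lower_bound),
            ub=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
            subsystem=r.subsystem or "",
        )
        for r in model.reactions
    ]
    objective = {
        r.id: float(r.objective_coefficient)
        for r in model.reactions
        if r.objective_coefficient
    }
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        genes=[g.id for g in model.genes],
        objective=objective,
        id=model.id or "model",
    )


def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model(network.id)
    model.add_metabolites(
        [
            cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
            for m in network.metabolites
        ]
    )
    for r in network.reactions:
        rxn = cobra.Reaction(r.id, name=r.name, lower_bound=r.lb, upper_bound=r.ub)
        model.add_reactions([rxn])
        rxn.add_metabolites(
            {model.metabolites.get_by_id(mid): c for mid, c in r.stoichiometry.items()}
        )
        if r.gpr:
            rxn.gene_reaction_rule = r.gpr
        rxn.subsystem = r.subsystem
    if network.objective:
        model.objective = {
            model.reactions.get_by_id(rid): w for rid, w in network.objective.items()
        }
    return model


# ---------------------------------------------------------------------------
# Medium
# ---------------------------------------------------------------------------

def apply_medium(
    network: MetabolicNetwork,
    uptake: Mapping[str, tuple[float, float]],
    close_unlisted: bool = True,
) -> MetabolicNetwork:
    """Return a copy of the network with exchange bounds set from a medium.

    ``uptake`` maps exchange reaction ids to (lb, ub) pairs; negative lb
    allows uptake.  When ``close_unlisted`` is true, exchange reactions not
    listed have their uptake closed (lb = 0).  Non-exchange reactions are
    never touched.
    """
    exchange_ids = {r.id for r in network.exchanges()}
    unknown = sorted(set(uptake) - exchange_ids)
    if unknown:
        raise ValidationError(f"uptake table lists non-exchange or unknown reactions: {unknown}")
    out = network.copy()
    for r in out.reactions:
        if not r.is_exchange:
            continue
        if r.id in uptake:
            lb, ub = uptake[r.id]
            if lb > ub:
                raise ValidationError(f"uptake entry {r.id!r}: lb > ub")
            r.lb, r.ub = float(lb), float(ub)
            r.reversible = r.lb < 0
        elif close_unlisted:
            r.lb = max(r.lb, 0.0)
            r.reversible = False
    return out


def read_uptake_tsv(path) -> dict[str, tuple[float, float]]:
    """Read a 3-column uptake table (reaction_id, lb, ub), tab-separated."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    expected = {"reaction_id", "lb", "ub"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"uptake table must have columns {sorted(expected)}")
    return {row.reaction_id: (float(row.lb), float(row.ub)) for row in df.itertuples()}
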