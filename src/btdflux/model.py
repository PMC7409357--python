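"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric network: metabolites (rows of
the stoichiometric matrix S), reactions (columns, each with flux bounds in
mmol gDCW⁻¹ h⁻¹ and an optional gene-protein-reaction rule), and a biomass
objective reaction.  Exchange reactions are boundary pseudo-reactions that
touch exactly one metabolite; by convention a negative exchange flux is
uptake and a positive one is secretion.

A :class:`Condition` is a named growth medium: a map of exchange-reaction
bounds plus metadata identifying the single carbon source and its carbon
count, so that carbon-proportional uptake rates can be derived and competing
carbon uptakes closed.
"""

from __future__ import annotations

import ast
import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "GPRRule",
    "MetabolicModel",
    "Condition",
    "Violation",
    "InvalidModelError",
    "parse_gpr",
    "evaluate_gpr",
    "validate_model",
    "stoichiometric_matrix",
    "apply_condition",
]


class InvalidModelError(ValueError):
    """Raised when an operation requires a model that fails validation."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None


@dataclass(frozen=True)
class GPRRule:
    """Boolean expression tree over gene ids with AND/OR nodes.

    ``op`` is one of ``"gene"`` (leaf, ``gene`` set), ``"and"`` or ``"or"``
    (internal, ``children`` set).  Evaluation over continuous expression
    factors generalises boolean knockout logic: AND takes the minimum of its
    children (a complex is limited by its scarcest subunit), OR the maximum
    (an isozyme rescues).
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GPRRule", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene or self.children:
                raise ValueError("gene leaf must carry a gene id and no children")
        elif self.op in ("and", "or"):
            if self.gene is not None or len(self.children) < 2:
                raise ValueError(f"{self.op!r} node needs >= 2 children and no gene id")
        else:
            raise ValueError(f"unknown GPR node op {self.op!r}")

    @property
    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset((self.gene,))
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes
        return out

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def parse_gpr(rule: str) -> Optional[GPRRule]:
    """Parse a boolean gene-association string like ``"(gA and gB) or gC"``.

    Returns ``None`` for an empty rule.  The grammar is the COBRA community
    convention: gene identifiers combined with ``and`` / ``or`` and
    parentheses (case-insensitive keywords).
    """
    text = rule.strip()
    if not text:
        return None
    # Gene ids may contain '.' or start with digits; quote them so the
    # expression parses as Python.  Split on word boundaries conservatively.
    import re

    def _tok(m: "re.Match[str]") -> str:
        w = m.group(0)
        return w.lower() if w.lower() in ("and", "or") else f"G[{w!r}]"

    pattern = r"[A-Za-z0-9_][A-Za-z0-9_.\-,]*"
    pyexpr = re.sub(pattern, _tok, text)
    try:
        tree = ast.parse(pyexpr, mode="eval").body
    except SyntaxError as exc:
        raise ValueError(f"malformed GPR rule {rule!r}") from exc

    def _convert(node: ast.expr) -> GPRRule:
        if isinstance(node, ast.BoolOp):
            op = "and" if isinstance(node.op, ast.And) else "or"
            kids = tuple(_convert(v) for v in node.values)
            # flatten nested same-op nodes for a canonical tree
            flat: list[GPRRule] = []
            for k in kids:
                if k.op == op:
                    flat.extend(k.children)
                else:
                    flat.append(k)
            return GPRRule(op=op, children=tuple(flat))
        if isinstance(node, ast.Subscript):  # G['geneid']
            const = node.slice
            if isinstance(const, ast.Constant) and isinstance(const.value, str):
                return GPRRule(op="gene", gene=const.value)
        raise ValueError(f"malformed GPR rule {rule!r}")

    return _convert(tree)


def evaluate_gpr(rule: GPRRule, gene_factors: Mapping[str, float]) -> float:
    """Propagate per-gene expression factors to a reaction-level factor.

    Factors are nonnegative multipliers on wildtype activity: 0 is a
    knockout, values below 1 under-expression, above 1 over-expression.
    Genes absent from ``gene_factors`` default to 1 (unmodified).  AND nodes
    take the minimum of their children, OR nodes the maximum, so the binary
    knockout case reduces to ordinary boolean evaluation.
    """
    if rule.op == "gene":
        f = float(gene_factors.get(rule.gene, 1.0))
        if f < 0:
            raise ValueError(f"negative factor for gene {rule.gene!r}")
        return f
    vals = [evaluate_gpr(c, gene_factors) for c in rule.children]
    return min(vals) if rule.op == "and" else max(vals)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: Optional[GPRRule] = None
    is_exchange: bool = False
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_reaction: str = ""
    compartments: set[str] = field(default_factory=set)
    infeasible_marker: Optional[str] = None  # set by strain-design bound edits

    # -- lookups -------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction=self.objective_reaction,
            compartments=set(self.compartments),
            infeasible_marker=self.infeasible_marker,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        # equality covers the simulation-relevant content: metabolite
        # identities, stoichiometry, bounds, GPR, objective.  Names and
        # charges (which SBML-FBC defaults on write) are cosmetic.
        mine = [(m.id, m.compartment, m.formula) for m in self.metabolites]
        theirs = [(m.id, m.compartment, m.formula) for m in other.metabolites]
        return (
            self.id == other.id
            and mine == theirs
            and sorted(self.genes) == sorted(other.genes)
            and self.objective_reaction == other.objective_reaction
            and _reactions_equal(self.reactions, other.reactions)
        )


def _reactions_equal(a: list[Reaction], b: list[Reaction]) -> bool:
    if len(a) != len(b):
        return False
    for ra, rb in zip(a, b):
        ga = ra.gpr.to_string() if ra.gpr else ""
        gb = rb.gpr.to_string() if rb.gpr else ""
        if not (
            ra.id == rb.id
            and ra.stoichiometry == rb.stoichiometry
            and abs(ra.lower_bound - rb.lower_bound) <= 1e-9
            and abs(ra.upper_bound - rb.upper_bound) <= 1e-9
            and ga == gb
            and ra.is_exchange == rb.is_exchange
        ):
            return False
    return True


@dataclass(frozen=True)
class Condition:
    """A named medium: exchange bounds plus carbon-source metadata.

    ``carbon_exchanges`` lists every carbon-source exchange the condition
    family knows about; applying the condition closes the uptake side of all
    of them except ``carbon_source`` so growth is on a single carbon source.
    """

    name: str
    exchange_bounds: Mapping[str, tuple[float, float]]
    carbon_source: str
    carbon_atoms: int
    carbon_exchanges: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.carbon_atoms <= 0:
            raise ValueError("carbon_atoms must be positive")
        lb, _ = self.exchange_bounds.get(self.carbon_source, (0.0, 0.0))
        if lb > 0:
            raise ValueError("carbon-source lower bound must be <= 0 (uptake)")


@dataclass(frozen=True)
class Violation:
    entity: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule}" + (f" ({self.detail})" if self.detail else "")


def validate_model(model: MetabolicModel) -> list[Violation]:
    """Check every structural invariant; return one descriptor per breach.

    Reports rather than raises: an empty list means the model is valid.
    """
    out: list[Violation] = []
    met_ids = model.metabolite_ids()
    seen = set()
    for mid in met_ids:
        if mid in seen:
            out.append(Violation(mid, "duplicate metabolite id"))
        seen.add(mid)
    for m in model.metabolites:
        if not m.compartment:
            out.append(Violation(m.id, "empty compartment"))
    met_set = set(met_ids)
    gene_set = set(model.genes)
    if len(gene_set) != len(model.genes):
        out.append(Violation(model.id, "duplicate gene ids"))
    rxn_seen: set[str] = set()
    for r in model.reactions:
        if r.id in rxn_seen:
            out.append(Violation(r.id, "duplicate reaction id"))
        rxn_seen.add(r.id)
        if r.lower_bound > r.upper_bound:
            out.append(
                Violation(r.id, "lower_bound > upper_bound", f"{r.lower_bound} > {r.upper_bound}")
            )
        if not r.stoichiometry:
            out.append(Violation(r.id, "empty stoichiometry"))
        for mid, coef in r.stoichiometry.items():
            if coef == 0:
                out.append(Violation(r.id, "zero stoichiometric coefficient", mid))
            if mid not in met_set:
                out.append(Violation(r.id, "unresolved metabolite", mid))
        if r.is_exchange and len(r.stoichiometry) != 1:
            out.append(Violation(r.id, "exchange must touch exactly one metabolite"))
        if r.gpr is not None:
            for g in r.gpr.genes:
                if g not in gene_set:
                    out.append(Violation(r.id, "GPR references unknown gene", g))
    if model.objective_reaction and model.objective_reaction not in rxn_seen:
        out.append(Violation(model.objective_reaction, "objective reaction missing"))
    if not model.objective_reaction:
        out.append(Violation(model.id, "no objective reaction set"))
    return out


def stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """The sparse stoichiometric matrix S (metabolites × reactions).

    ``S[i, j]`` is the coefficient of metabolite *i* in reaction *j*
    (negative = consumed, positive = produced).  Row/column order follows
    the model's metabolite/reaction lists.
    """
    violations = validate_model(model)
    if violations:
        raise InvalidModelError(f"invalid model: {violations[0]}")
    met_index = {mid: i for i, mid in enumerate(model.metabolite_ids())}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coef))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def apply_condition(model: MetabolicModel, condition: Condition) -> MetabolicModel:
    """Return a copy of ``model`` with the condition's medium applied.

    Listed exchange bounds replace the model's; every known carbon-source
    exchange other than ``condition.carbon_source`` has its uptake closed
    (lower bound raised to 0) to enforce growth on a single carbon source.
    Oxygen and mineral-medium exchanges keep whatever the condition says
    (by convention ±1000, i.e. unlimited).
    """
    out = model.copy()
    by_id = {r.id: r for r in out.reactions}
    for rid, (lb, ub) in condition.exchange_bounds.items():
        if rid not in by_id:
            raise KeyError(f"condition {condition.name!r} references unknown exchange {rid!r}")
        by_id[rid].lower_bound = float(lb)
        by_id[rid].upper_bound = float(ub)
    for rid in condition.carbon_exchanges:
        if rid == condition.carbon_source or rid not in by_id:
            continue
        rxn = by_id[rid]
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out
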