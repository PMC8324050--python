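"""Domain types for stoichiometric metabolic models.

A :class:`MetabolicModel` is the object every analysis in this package
consumes: a set of metabolites (with elemental formulas over C/H/N/O/P/S),
reactions (exact-rational stoichiometry, flux bounds, boolean gene
associations) and genes.  Coefficients are stored as :class:`~fractions.Fraction`
because conversion-cone enumeration requires exact arithmetic; LP layers
convert to floats at the solver boundary.

Flux bounds are in the model's arbitrary "flux units".  Boundary reactions
(exchange/demand/sink) follow the community sign convention: they are written
as ``metabolite →`` so a positive flux exports the metabolite and uptake is a
negative flux.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

ELEMENTS = ("C", "H", "N", "O", "P", "S")

Number = Union[int, float, Fraction]


class ModelStructureError(ValueError):
    """A model violates a structural invariant (bad reference, duplicate id, ...)."""


# ---------------------------------------------------------------------------
# Gene-protein-reaction boolean logic
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


class Gpr:
    """Boolean AND/OR tree over gene identifiers.

    The empty expression (``Gpr.empty()``) means "no gene association": the
    reaction is always catalyzable.  Nodes are nested tuples::

        ("gene", "gA") | ("and", [node, ...]) | ("or", [node, ...]) | None
    """

    __slots__ = ("node",)

    def __init__(self, node=None):
        self.node = node

    # -- construction -------------------------------------------------------
    @classmethod
    def empty(cls) -> "Gpr":
        return cls(None)

    @classmethod
    def gene(cls, gene_id: str) -> "Gpr":
        return cls(("gene", gene_id))

    @classmethod
    def parse(cls, rule: str) -> "Gpr":
        """Parse a cobra-style rule string, e.g. ``"gA and (gB or gC)"``."""
        tokens = _GPR_TOKEN.findall(rule or "")
        if not tokens:
            return cls.empty()
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def parse_or():
            nonlocal pos
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                pos += 1
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else ("or", terms)

        def parse_and():
            nonlocal pos
            terms = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                pos += 1
                terms.append(parse_atom())
            return terms[0] if len(terms) == 1 else ("and", terms)

        def parse_atom():
            nonlocal pos
            tok = peek()
            if tok is None:
                raise ValueError(f"truncated gene rule: {rule!r}")
            if tok == "(":
                pos += 1
                inner = parse_or()
                if peek() != ")":
                    raise ValueError(f"unbalanced parentheses in gene rule: {rule!r}")
                pos += 1
                return inner
            if tok == ")":
                raise ValueError(f"unexpected ')' in gene rule: {rule!r}")
            pos += 1
            return ("gene", tok)

        tree = parse_or()
        if pos != len(tokens):
            raise ValueError(f"trailing tokens in gene rule: {rule!r}")
        return cls(tree)

    # -- queries ------------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.node is None

    def genes(self) -> set[str]:
        out: set[str] = set()

        def walk(n):
            if n is None:
                return
            if n[0] == "gene":
                out.add(n[1])
            else:
                for c in n[1]:
                    walk(c)

        walk(self.node)
        return out

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """True iff the reaction remains catalyzable after deleting ``deleted_genes``."""
        deleted = set(deleted_genes)

        def walk(n) -> bool:
            if n is None:
                return True
            kind = n[0]
            if kind == "gene":
                return n[1] not in deleted
            if kind == "and":
                return all(walk(c) for c in n[1])
            return any(walk(c) for c in n[1])

        return walk(self.node)

    def to_string(self) -> str:
        def walk(n, parent=None) -> str:
            if n is None:
                return ""
            if n[0] == "gene":
                return n[1]
            sep = f" {n[0]} "
            body = sep.join(walk(c, n[0]) for c in n[1])
            if parent is not None and parent != n[0]:
                return f"({body})"
            return body

        return walk(self.node)

    def __eq__(self, other):
        return isinstance(other, Gpr) and self.node == other.node

    def __hash__(self):
        return hash(repr(self.node))

    def __repr__(self):
        return f"Gpr({self.to_string()!r})"


def evaluate_gpr(expr: Gpr, deleted_genes: Iterable[str] = ()) -> bool:
    """AND = all children, OR = any child, leaf true iff its gene is not deleted."""
    return expr.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "internal"  # "internal" | "external"
    formula: Optional[dict[str, int]] = None  # element -> count over ELEMENTS
    charge: Optional[int] = None

    def __post_init__(self):
        if self.compartment not in ("internal", "external"):
            raise ModelStructureError(
                f"metabolite {self.id!r}: compartment must be internal/external, "
                f"got {self.compartment!r}"
            )
        if self.formula is not None:
            bad = {e: c for e, c in self.formula.items() if e not in ELEMENTS}
            if bad:
                raise ModelStructureError(f"metabolite {self.id!r}: unknown elements {bad}")
            if any(c < 0 or int(c) != c for c in self.formula.values()):
                raise ModelStructureError(
                    f"metabolite {self.id!r}: element counts must be nonnegative integers"
                )
            self.formula = {e: int(c) for e, c in self.formula.items() if c}

    def atoms(self, element: str) -> int:
        if self.formula is None:
            raise ModelStructureError(f"metabolite {self.id!r} has no formula")
        return self.formula.get(element, 0)

    def formula_string(self) -> str:
        if self.formula is None:
            return ""
        return "".join(
            f"{e}{self.formula[e]}" if self.formula[e] != 1 else e
            for e in ELEMENTS
            if e in self.formula
        )


REACTION_KINDS = ("metabolic", "transport", "exchange", "demand", "sink")
BOUNDARY_KINDS = ("exchange", "demand", "sink")

DEFAULT_BOUND = 1000.0


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Gpr = field(default_factory=Gpr.empty)
    kind: str = "metabolic"

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ModelStructureError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        self.stoichiometry = {m: Fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id!r}: all coefficients zero")
        if self.kind in BOUNDARY_KINDS and len(self.stoichiometry) != 1:
            raise ModelStructureError(
                f"reaction {self.id!r}: {self.kind} reactions must touch exactly one metabolite"
            )

    @property
    def is_boundary(self) -> bool:
        return self.kind in BOUNDARY_KINDS

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def boundary_metabolite(self) -> str:
        if not self.is_boundary:
            raise ModelStructureError(f"reaction {self.id!r} is not a boundary reaction")
        return next(iter(self.stoichiometry))


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    nitrogenase_id: Optional[str] = None
    # tracker pseudo-metabolite -> tracked reaction (see ecm.add_flux_tracker)
    trackers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._reindex()
        self.validate()

    def _reindex(self):
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups ------------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.compartment == "internal"]

    def external_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.compartment == "external"]

    def boundary_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_boundary]

    def exchange_for(self, met_id: str) -> Optional[Reaction]:
        """The boundary reaction touching ``met_id``, if any."""
        for r in self.reactions:
            if r.is_boundary and r.boundary_metabolite() == met_id:
                return r
        return None

    # -- validation ---------------------------------------------------------
    def validate(self):
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelStructureError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelStructureError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ModelStructureError("duplicate gene ids")
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelStructureError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            missing = r.gpr.genes() - gene_set
            if missing:
                raise ModelStructureError(
                    f"reaction {r.id!r}: GPR references unknown genes {sorted(missing)}"
                )
        if self.nitrogenase_id is not None and self.nitrogenase_id not in self._rxn_index:
            raise ModelStructureError(
                f"designated nitrogenase reaction {self.nitrogenase_id!r} not in model"
            )

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def stoichiometric_matrix(
    model: MetabolicModel, dtype: str = "fraction"
) -> tuple[list[str], list[str], object]:
    """The S matrix over *internal* metabolites (rows) and all reactions (columns).

    Entry (i, j) is the coefficient of internal metabolite i in reaction j;
    external metabolites are excluded from the rows.  Returns
    ``(metabolite_ids, reaction_ids, S)`` with ``S`` a list of Fraction rows
    (``dtype="fraction"``) or a float ndarray (``dtype="float"``).
    """
    mets = [m.id for m in model.internal_metabolites()]
    row_of = {m: i for i, m in enumerate(mets)}
    rxns = model.reaction_ids
    S = [[Fraction(0)] * len(rxns) for _ in mets]
    for j, r in enumerate(model.reactions):
        for met_id, coef in r.stoichiometry.items():
            i = row_of.get(met_id)
            if i is not None:
                S[i][j] = coef
    if dtype == "float":
        return mets, rxns, np.array([[float(c) for c in row] for row in S], dtype=float).reshape(
            len(mets), len(rxns)
        )
    if dtype != "fraction":
        raise ValueError(f"dtype must be 'fraction' or 'float', got {dtype!r}")
    return mets, rxns, S


def check_elemental_balance(
    model: MetabolicModel,
) -> tuple[dict[str, dict[str, Fraction]], list[str]]:
    """Net element imbalance per reaction.

    Exchange/demand/sink reactions are skipped (they are unbalanced by
    construction).  Reactions touching a formula-less metabolite are reported
    separately in the ``unknown`` list and no imbalance is claimed for them.
    Balanced reactions report an empty map.

    Returns ``(imbalances, unknown)``.
    """
    imbalances: dict[str, dict[str, Fraction]] = {}
    unknown: list[str] = []
    for r in model.reactions:
        if r.is_boundary:
            continue
        mets = [model.metabolite(m) for m in r.stoichiometry]
        if any(m.formula is None for m in mets):
            unknown.append(r.id)
            continue
        net: dict[str, Fraction] = {}
        for met_id, coef in r.stoichiometry.items():
            for element, count in (model.metabolite(met_id).formula or {}).items():
                net[element] = net.get(element, Fraction(0)) + coef * count
        net = {e: v for e, v in net.items() if v != 0}
        imbalances[r.id] = net
    return imbalances, unknown


@dataclass
class GapReport:
    """Structural and functional consistency findings for a model."""

    orphan_metabolites: dict[str, str]  # metabolite id -> "never_produced"/"never_consumed"
    dead_end_reactions: list[str]  # blocked at steady state with all exchanges open
    balanced_cycle_reactions: list[str]  # carry flux with every boundary reaction closed

    @property
    def clean(self) -> bool:
        return not (
            self.orphan_metabolites or self.dead_end_reactions or self.balanced_cycle_reactions
        )


def find_network_gaps(model: MetabolicModel, flux_threshold: float = 1e-6) -> GapReport:
    """Report orphan metabolites, dead-end (blocked) reactions and balanced cycles.

    Orphans are found structurally: a metabolite that no reaction can produce
    or none can consume (reversible reactions count for both sides).  Dead
    ends are found functionally: reactions with zero flux range by flux
    variability with every boundary reaction opened wide.  Stoichiometrically
    balanced cycles are reactions with a nonzero flux range (``> flux_threshold``)
    when every exchange/demand/sink is fixed to zero.
    """
    from . import fba  # local import: fba depends on this module

    producers: dict[str, int] = {m.id: 0 for m in model.metabolites}
    consumers: dict[str, int] = {m.id: 0 for m in model.metabolites}
    for r in model.reactions:
        for met_id, coef in r.stoichiometry.items():
            fwd = r.upper_bound > 0
            bwd = r.lower_bound < 0
            if (coef > 0 and fwd) or (coef < 0 and bwd):
                producers[met_id] += 1
            if (coef < 0 and fwd) or (coef > 0 and bwd):
                consumers[met_id] += 1

    orphans: dict[str, str] = {}
    for m in model.metabolites:
        # a metabolite whose only contact is its own boundary reaction is moot
        if producers[m.id] == 0:
            orphans[m.id] = "never_produced"
        elif consumers[m.id] == 0:
            orphans[m.id] = "never_consumed"

    # dead ends: FVA with all boundaries wide open, zero objective
    open_model = model.copy()
    for r in open_model.reactions:
        if r.is_boundary:
            r.lower_bound = -DEFAULT_BOUND
            r.upper_bound = DEFAULT_BOUND
    ranges = fba.flux_variability(open_model, objective=None)
    dead = [
        rid
        for rid, (lo, hi) in ranges.ranges.items()
        if abs(lo) <= flux_threshold and abs(hi) <= flux_threshold
    ]

    # balanced cycles: FVA with all boundaries closed
    closed_model = model.copy()
    for r in closed_model.reactions:
        if r.is_boundary:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    ranges = fba.flux_variability(closed_model, objective=None)
    cycles = [
        rid
        for rid, (lo, hi) in ranges.ranges.items()
        if max(abs(lo), abs(hi)) > flux_threshold and not closed_model.reaction(rid).is_boundary
    ]

    return GapReport(orphan_metabolites=orphans, dead_end_reactions=dead,
                     balanced_cycle_reactions=cycles)
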