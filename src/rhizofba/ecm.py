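"""Elementary conversion mode (ECM) enumeration.

A conversion is the net transformation of external metabolites a network can
sustain at steady state; the set of all conversions is a polyhedral cone and
its extreme rays are the ECMs.  They describe what the cell can do in
input/output terms without committing to internal pathways.

The enumeration here is a double-description computation with exact integer
arithmetic: reversible reactions are split, every metabolite balance row is
eliminated iteratively (greedy minimum |pos|·|neg| order), direction
constraints on external metabolites are realized as sign-restricted
uptake/export columns, and the surviving flux-cone rays are projected onto
the external-metabolite coordinates.  Extreme rays of the projected cone are
selected by LP-based redundancy elimination.  Floats appear only in the LP
presolve/extremality/reachability checks; the cone algebra itself is exact,
which is what keeps spurious rays out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, Metabolite, ModelStructureError, Reaction


class EcmError(RuntimeError):
    pass


@dataclass
class EcmConfig:
    """Partition of the external metabolites for conversion bookkeeping.

    inputs: usable only as net consumption (coefficient ≤ 0)
    outputs: usable only as net production (coefficient ≥ 0)
    free: usable in either direction
    hidden: removed from bookkeeping entirely (treated as freely balanced);
        the standard use is hiding cofactors to shrink the enumeration
    External metabolites listed nowhere must balance internally (closed).
    """

    inputs: set[str] = field(default_factory=set)
    outputs: set[str] = field(default_factory=set)
    free: set[str] = field(default_factory=set)
    hidden: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.inputs, self.outputs = set(self.inputs), set(self.outputs)
        self.free, self.hidden = set(self.free), set(self.hidden)
        sets = [self.inputs, self.outputs, self.free, self.hidden]
        union: set[str] = set()
        total = 0
        for s in sets:
            union |= s
            total += len(s)
        if len(union) != total:
            raise ModelStructureError("EcmConfig sets must be disjoint")

    @property
    def listed(self) -> set[str]:
        return self.inputs | self.outputs | self.free | self.hidden

    def validate(self, model: MetabolicModel):
        externals = {m.id for m in model.external_metabolites()}
        unknown = self.listed - externals
        if unknown:
            raise ModelStructureError(
                f"EcmConfig lists non-external metabolites: {sorted(unknown)}"
            )


@dataclass
class Conversion:
    """One ECM: net input→output stoichiometry over external metabolites.

    Consumption is negative.  ``tracked`` holds virtual-metabolite
    coordinates (flux of the tracked reaction per unit conversion).
    """

    coefficients: dict[str, Fraction]
    tracked: dict[str, Fraction] = field(default_factory=dict)
    normalization: str = "integer_gcd"

    def __post_init__(self):
        self.coefficients = {m: Fraction(c) for m, c in self.coefficients.items() if c != 0}
        self.tracked = {m: Fraction(c) for m, c in self.tracked.items() if c != 0}
        if not self.coefficients and not self.tracked:
            raise EcmError("conversion has no nonzero entry")

    def inputs(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.coefficients.items() if c < 0}

    def outputs(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.coefficients.items() if c > 0}

    def support(self) -> frozenset[str]:
        return frozenset(self.coefficients)

    def scaled(self, factor: Fraction, tag: str) -> "Conversion":
        if factor <= 0:
            raise EcmError("conversion scale factor must be positive")
        return Conversion(
            coefficients={m: c * factor for m, c in self.coefficients.items()},
            tracked={m: c * factor for m, c in self.tracked.items()},
            normalization=tag,
        )


def normalize_conversion(
    conv: Conversion, mode: str, model: Optional[MetabolicModel] = None
) -> Conversion:
    """Rescale a conversion by one positive factor (ratios preserved).

    ``unit_carbon_input`` scales to one mol of carbon atoms consumed (needs
    the model for formulas); ``unit_max_coeff`` scales the largest |coefficient|
    to one.
    """
    if mode == "unit_carbon_input":
        if model is None:
            raise ValueError("unit_carbon_input normalization needs the model for formulas")
        carbon = -sum(
            c * model.metabolite(m).atoms("C") for m, c in conv.coefficients.items() if c < 0
        )
        if carbon <= 0:
            raise EcmError("conversion has no carbon input; cannot normalize per carbon")
        return conv.scaled(Fraction(1, 1) / carbon, "unit_carbon_input")
    if mode == "unit_max_coeff":
        biggest = max((abs(c) for c in conv.coefficients.values()), default=Fraction(0))
        if biggest == 0:
            raise EcmError("all-zero conversion cannot be normalized")
        return conv.scaled(Fraction(1, 1) / biggest, "unit_max_coeff")
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# Virtual flux trackers
# ---------------------------------------------------------------------------


def add_flux_tracker(model: MetabolicModel, reaction_id: str, tracker_id: str) -> MetabolicModel:
    """Attach a virtual metabolite to a reaction so conversions expose its flux.

    The tracker is appended as a product with coefficient +1 and declared an
    output-only external species; its coefficient in any conversion equals
    the tracked reaction's flux per unit conversion.  FBA ignores tracker
    balance rows, so the tracked model behaves identically under LP analyses.
    """
    if tracker_id in {m.id for m in model.metabolites}:
        raise ModelStructureError(f"tracker id {tracker_id!r} collides with a metabolite")
    out = model.copy()
    rxn = out.reaction(reaction_id)
    out.metabolites.append(Metabolite(tracker_id, name=f"flux tracker for {reaction_id}",
                                      compartment="external"))
    rxn.stoichiometry[tracker_id] = Fraction(1)
    out.trackers[tracker_id] = reaction_id
    out._reindex()
    return out


# ---------------------------------------------------------------------------
# Cone construction and double description
# ---------------------------------------------------------------------------


@dataclass
class _Cone:
    """Integer equality system A x = 0, x >= 0 with column metadata."""

    rows: list[tuple[int, ...]]
    columns: list[tuple[str, str]]  # (kind, id): kind in {fwd, bwd, uptake, export}
    coord_ids: list[str]  # external metabolites kept as conversion coordinates


def _build_cone(model: MetabolicModel, config: EcmConfig) -> _Cone:
    config.validate(model)
    mets = [m.id for m in model.metabolites]
    row_of = {m: i for i, m in enumerate(mets)}
    columns: list[tuple[str, str]] = []
    col_entries: list[dict[int, Fraction]] = []

    for r in model.reactions:
        if r.is_boundary:
            continue  # boundary handling is replaced by the config's columns
        fwd = {row_of[m]: c for m, c in r.stoichiometry.items()}
        if r.upper_bound > 0:
            columns.append(("fwd", r.id))
            col_entries.append(fwd)
        if r.lower_bound < 0:
            columns.append(("bwd", r.id))
            col_entries.append({i: -c for i, c in fwd.items()})

    for met in sorted(config.listed):
        i = row_of[met]
        if met in config.inputs or met in config.free or met in config.hidden:
            columns.append(("uptake", met))
            col_entries.append({i: Fraction(1)})
        if met in config.outputs or met in config.free or met in config.hidden:
            columns.append(("export", met))
            col_entries.append({i: Fraction(-1)})

    rows: list[tuple[int, ...]] = []
    for i in range(len(mets)):
        row = [col_entries[j].get(i, Fraction(0)) for j in range(len(columns))]
        if all(v == 0 for v in row):
            continue
        denom_lcm = 1
        for v in row:
            denom_lcm = denom_lcm * v.denominator // gcd(denom_lcm, v.denominator)
        ints = [int(v * denom_lcm) for v in row]
        g = 0
        for v in ints:
            g = gcd(g, abs(v))
        if g > 1:
            ints = [v // g for v in ints]
        rows.append(tuple(ints))

    coord_ids = sorted((config.inputs | config.outputs | config.free))
    return _Cone(rows=rows, columns=columns, coord_ids=coord_ids)


def _presolve_blocked(cone: _Cone, tol: float = 1e-9) -> list[int]:
    """Columns that can never carry flux in the cone (checked on the unit box)."""
    ncols = len(cone.columns)
    A = np.zeros((len(cone.rows), ncols))
    for i, row in enumerate(cone.rows):
        A[i, :] = row
    blocked = []
    for j in range(ncols):
        c = np.zeros(ncols)
        c[j] = -1.0  # maximize x_j
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]),
                      bounds=[(0.0, 1.0)] * ncols, method="highs")
        if res.status == 0 and -res.fun <= tol:
            blocked.append(j)
    return blocked


def _reduce_ray(vec: list[int]) -> tuple[int, ...]:
    g = 0
    for v in vec:
        g = gcd(g, abs(v))
    if g > 1:
        vec = [v // g for v in vec]
    return tuple(vec)


def _double_description(
    rows: list[tuple[int, ...]], ncols: int, max_rays: int
) -> list[tuple[int, ...]]:
    """Extreme rays of {x >= 0 : A x = 0} by iterative row elimination.

    Rows are processed in greedy minimum |pos|·|neg| order; candidate
    positive/negative pairs are combined only if adjacent (combinatorial
    zero-set test on the nonnegativity constraints).
    """
    rays: list[tuple[int, ...]] = [
        tuple(1 if k == j else 0 for k in range(ncols)) for j in range(ncols)
    ]
    supports: list[int] = [1 << j for j in range(ncols)]
    remaining = list(rows)

    while remaining:
        best = None
        best_cost = None
        best_dots = None
        for ri, row in enumerate(remaining):
            dots = [sum(a * x for a, x in zip(row, ray) if a) for ray in rays]
            npos = sum(1 for d in dots if d > 0)
            nneg = sum(1 for d in dots if d < 0)
            cost = npos * nneg
            if best_cost is None or cost < best_cost:
                best, best_cost, best_dots = ri, cost, dots
                if cost == 0:
                    break
        row = remaining.pop(best)
        dots = best_dots

        zero_idx = [i for i, d in enumerate(dots) if d == 0]
        pos_idx = [i for i, d in enumerate(dots) if d > 0]
        neg_idx = [i for i, d in enumerate(dots) if d < 0]

        new_rays = [rays[i] for i in zero_idx]
        new_supports = [supports[i] for i in zero_idx]

        for ip in pos_idx:
            zp = supports[ip]
            for im in neg_idx:
                zm = supports[im]
                union = zp | zm
                # adjacency: no third ray's support fits inside supp(p) ∪ supp(m)
                adjacent = True
                for k, sk in enumerate(supports):
                    if k == ip or k == im:
                        continue
                    if sk & ~union == 0:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                a, b = dots[ip], -dots[im]
                combo = [a * rays[im][k] + b * rays[ip][k] for k in range(ncols)]
                ray = _reduce_ray(combo)
                new_rays.append(ray)
                new_supports.append(
                    sum(1 << k for k, v in enumerate(ray) if v)
                )
        rays = new_rays
        supports = new_supports
        if len(rays) > max_rays:
            raise EcmError(
                f"double description exceeded {max_rays} intermediate rays; "
                "hide more metabolites or rescale the model"
            )
    return rays


def _extreme_subset(vectors: list[tuple[Fraction, ...]], tol: float = 1e-8) -> list[int]:
    """Indices of vectors that are extreme rays of the cone they generate.

    A vector is redundant iff it is a nonnegative combination of the other
    (kept) vectors; redundancy is tested by LP feasibility in floats.
    """
    arr = np.array([[float(c) for c in v] for v in vectors], dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    arr = arr / norms[:, None]
    keep = list(range(len(vectors)))
    # test large-support candidates first: composites go before their parts
    order = sorted(keep, key=lambda i: -np.count_nonzero(arr[i]))
    for i in order:
        others = [k for k in keep if k != i]
        if not others:
            continue
        G = arr[others].T  # dims x m
        res = linprog(
            np.zeros(len(others)), A_eq=G, b_eq=arr[i],
            bounds=[(0.0, None)] * len(others), method="highs",
        )
        if res.status == 0:
            resid = abs(G @ res.x - arr[i]).max()
            if resid <= tol:
                keep.remove(i)
    return keep


def enumerate_ecms(
    model: MetabolicModel,
    config: EcmConfig,
    presolve: bool = True,
    max_rays: int = 200_000,
) -> list[Conversion]:
    """All elementary conversion modes of ``model`` under ``config``.

    Every returned conversion is reachable (an LP flux certificate exists)
    and elementary (an extreme ray of the conversion cone).  Rays are
    deduplicated up to positive scaling and returned gcd-normalized with
    integer coefficients; rays in which both directions of a split
    reversible reaction (or both uptake and export of one metabolite) are
    active are discarded as cycle artifacts.
    """
    cone = _build_cone(model, config)
    columns = cone.columns
    rows = list(cone.rows)

    if presolve:
        blocked = set(_presolve_blocked(cone))
        if blocked:
            keep = [j for j in range(len(columns)) if j not in blocked]
            columns = [columns[j] for j in keep]
            rows = [tuple(r[j] for j in keep) for r in rows]
            rows = [r for r in rows if any(r)]

    rays = _double_description(rows, len(columns), max_rays)

    # discard two-cycle artifacts (both members of a split pair active)
    paired: dict[str, dict[str, int]] = {}
    for j, (kind, rid) in enumerate(columns):
        paired.setdefault(rid, {})[kind] = j
    artifacts = []
    for by_kind in paired.values():
        if "fwd" in by_kind and "bwd" in by_kind:
            artifacts.append((by_kind["fwd"], by_kind["bwd"]))
        if "uptake" in by_kind and "export" in by_kind:
            artifacts.append((by_kind["uptake"], by_kind["export"]))
    clean_rays = [
        ray for ray in rays
        if not any(ray[a] and ray[b] for a, b in artifacts)
    ]

    # project onto conversion coordinates
    tracker_ids = set(model.trackers)
    coord_ids = cone.coord_ids
    uptake_col = {rid: j for j, (kind, rid) in enumerate(columns) if kind == "uptake"}
    export_col = {rid: j for j, (kind, rid) in enumerate(columns) if kind == "export"}
    seen: set[tuple[Fraction, ...]] = set()
    projections: list[tuple[Fraction, ...]] = []
    for ray in clean_rays:
        proj = []
        for met in coord_ids:
            c = Fraction(0)
            if met in export_col:
                c += ray[export_col[met]]
            if met in uptake_col:
                c -= ray[uptake_col[met]]
            proj.append(Fraction(c))
        if all(c == 0 for c in proj):
            continue
        ints = [int(c) for c in proj]
        g = 0
        for v in ints:
            g = gcd(g, abs(v))
        proj = tuple(Fraction(v, g) if g > 1 else Fraction(v) for v in ints)
        if proj not in seen:
            seen.add(proj)
            projections.append(proj)

    if not projections:
        return []
    keep = _extreme_subset(projections)

    conversions = []
    for i in keep:
        coeffs = {}
        tracked = {}
        for met, c in zip(coord_ids, projections[i]):
            if c == 0:
                continue
            if met in tracker_ids:
                tracked[met] = c
            else:
                coeffs[met] = c
        if not coeffs and not tracked:
            continue
        conversions.append(Conversion(coefficients=coeffs, tracked=tracked))
    return conversions


# ---------------------------------------------------------------------------
# Reachability certificate
# ---------------------------------------------------------------------------


def reachability_certificate(
    model: MetabolicModel, config: EcmConfig, conv: Conversion, tol: float = 1e-7
) -> Optional[dict[str, float]]:
    """An LP flux vector reproducing ``conv``, or None if none exists.

    Solves S_int·v = 0 with S_ext·v pinned to the conversion's coefficients
    (hidden metabolites left free, unlisted externals closed), reaction
    directionality from the model bounds but magnitudes unconstrained.
    """
    rxns = [r for r in model.reactions if not r.is_boundary]
    col_of = {r.id: j for j, r in enumerate(rxns)}
    target = dict(conv.coefficients)
    target.update(conv.tracked)

    rows = []
    rhs = []
    for m in model.metabolites:
        if m.id in config.hidden:
            continue
        row = np.zeros(len(rxns))
        for j, r in enumerate(rxns):
            c = r.stoichiometry.get(m.id)
            if c:
                row[j] = float(c)
        if m.compartment == "external" and m.id in (config.listed | set(model.trackers)):
            rhs.append(float(target.get(m.id, 0)))
        else:
            rhs.append(0.0)
        rows.append(row)
    A = np.array(rows)
    b = np.array(rhs)
    bounds = []
    for r in rxns:
        lo = -np.inf if r.lower_bound < 0 else 0.0
        hi = np.inf if r.upper_bound > 0 else 0.0
        bounds.append((lo, hi))
    res = linprog(np.zeros(len(rxns)), A_eq=A, b_eq=b, bounds=bounds, method="highs")
    if res.status != 0:
        return None
    if np.abs(A @ res.x - b).max() > tol:
        return None
    return {r.id: float(res.x[j]) for r, j in zip(rxns, range(len(rxns)))}
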