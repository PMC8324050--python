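"""LP-based analyses: FBA, taxicab-norm minimization, (loopless) FVA,
shadow prices, phenotype phase planes, single-gene deletion and
random-objective ensemble FBA.

All linear programs are solved with HiGHS through
:func:`scipy.optimize.linprog`.  Mass balance is imposed on every metabolite
row (internal and external); boundary reactions (exchange/demand/sink) are
the only unbalanced columns, so an external species is consumed from or
released to the environment exclusively through its boundary reaction.
Tracker pseudo-metabolites (see :func:`rhizofba.ecm.add_flux_tracker`) are
excluded from the balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelStructureError
from .scenario import ScenarioConstraints, apply_scenario

Objective = Union[str, Mapping[str, float], None]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}

#: objective tolerance when holding the optimum fixed in two-stage LPs
OPT_TOL = 1e-9
#: flux below which a gene deletion counts as "prevented flux"
ESSENTIALITY_THRESHOLD = 1e-6


class LPError(RuntimeError):
    """An LP terminated abnormally (not optimal/infeasible/unbounded)."""


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def l1_norm(self) -> float:
        return sum(abs(v) for v in self.fluxes.values())


@dataclass
class FVAResult:
    ranges: dict[str, tuple[float, float]]
    fraction_of_optimum: float
    objective_value: Optional[float] = None

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------


def _objective_weights(model: MetabolicModel, objective: Objective) -> dict[str, float]:
    if objective is None:
        if model.nitrogenase_id is None:
            raise ModelStructureError(
                "no objective given and model has no designated nitrogenase reaction"
            )
        objective = model.nitrogenase_id
    if isinstance(objective, str):
        objective = {objective: 1.0}
    weights = {}
    for rid, w in objective.items():
        model.reaction(rid)  # raises for unknown ids
        weights[rid] = float(w)
    if not weights:
        raise ValueError("empty objective")
    return weights


class _LP:
    """Equality system S·v = 0 with bounds, reusable across related solves."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        rows = [m.id for m in model.metabolites if m.id not in model.trackers]
        self.row_of = {m: i for i, m in enumerate(rows)}
        self.rxns = model.reaction_ids
        self.col_of = {r: j for j, r in enumerate(self.rxns)}
        self.n = len(self.rxns)
        S = np.zeros((len(rows), self.n))
        for j, r in enumerate(model.reactions):
            for met_id, coef in r.stoichiometry.items():
                i = self.row_of.get(met_id)
                if i is not None:
                    S[i, j] = float(coef)
        self.S = S
        self.bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]

    def solve(
        self,
        c: np.ndarray,
        sense: int = -1,
        extra_ub: Optional[tuple[np.ndarray, np.ndarray]] = None,
        bounds: Optional[list[tuple[float, float]]] = None,
    ):
        """Optimize ``sense * c·v`` (sense=-1 maximizes) over the flux polytope."""
        A_ub = b_ub = None
        if extra_ub is not None:
            A_ub, b_ub = extra_ub
        res = linprog(
            sense * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds if bounds is not None else self.bounds,
            method="highs",
        )
        return res


def _result(lp: _LP, res, weights: dict[str, float]) -> FluxDistribution:
    status = _STATUS.get(res.status, "numerical")
    if status in ("infeasible", "unbounded"):
        return FluxDistribution(fluxes={}, objective_value=math.nan, status=status)
    if status != "optimal":
        raise LPError(f"LP failed with status {status}: {res.message}")
    fluxes = {rid: float(res.x[j]) for rid, j in lp.col_of.items()}
    obj = sum(w * fluxes[rid] for rid, w in weights.items())
    return FluxDistribution(fluxes=fluxes, objective_value=obj, status="optimal")


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def solve_fba(
    model: MetabolicModel,
    scenario: Optional[ScenarioConstraints] = None,
    objective: Objective = None,
) -> FluxDistribution:
    """Maximize the objective over {v : S·v = 0, bounds}.

    The default objective is the scenario's, falling back to the model's
    designated nitrogenase reaction.  Infeasible or unbounded problems are
    reported honestly in ``status``; no fluxes are fabricated.
    """
    m = apply_scenario(model, scenario)
    if objective is None and scenario is not None and scenario.objective:
        objective = scenario.objective
    weights = _objective_weights(m, objective)
    lp = _LP(m)
    c = np.zeros(lp.n)
    for rid, w in weights.items():
        c[lp.col_of[rid]] = w
    return _result(lp, lp.solve(c), weights)


def solve_fba_l1(
    model: MetabolicModel,
    scenario: Optional[ScenarioConstraints] = None,
    objective: Objective = None,
) -> FluxDistribution:
    """FBA followed by taxicab-norm minimization among the optima.

    Stage two fixes the objective at its optimum (within ``OPT_TOL``
    relative) and minimizes Σ|v| by splitting each flux into nonnegative
    forward/backward parts.  This removes thermodynamically infeasible
    internal cycles from the reported distribution while preserving the
    objective value.
    """
    m = apply_scenario(model, scenario)
    if objective is None and scenario is not None and scenario.objective:
        objective = scenario.objective
    weights = _objective_weights(m, objective)
    first = solve_fba(m, None, weights)
    if not first.ok:
        return first
    opt = first.objective_value

    lp = _LP(m)
    n = lp.n
    # variables [v+, v-], v = v+ - v-
    S2 = np.hstack([lp.S, -lp.S])
    c2 = np.ones(2 * n)
    w = np.zeros(n)
    for rid, wt in weights.items():
        w[lp.col_of[rid]] = wt
    # pin the objective at its optimum (equality row; OPT_TOL guards the
    # documented relative agreement, the solver works to its own tolerance)
    A_eq = np.vstack([S2, np.hstack([w, -w])])
    b_eq = np.concatenate([np.zeros(S2.shape[0]), [opt]])
    bounds2 = []
    for lo, hi in lp.bounds:
        bounds2.append((max(lo, 0.0), max(hi, 0.0)))  # v+
    for lo, hi in lp.bounds:
        bounds2.append((max(-hi, 0.0), max(-lo, 0.0)))  # v-
    res = linprog(c2, A_eq=A_eq, b_eq=b_eq, bounds=bounds2, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        raise LPError(f"L1 stage failed with status {status}: {res.message}")
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v[j]) for rid, j in lp.col_of.items()}
    obj = sum(wt * fluxes[rid] for rid, wt in weights.items())
    return FluxDistribution(fluxes=fluxes, objective_value=obj, status="optimal")


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


def _cycle_free(lp: _LP, v_star: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """CycleFreeFlux post-processing: remove internal-cycle flux from ``v_star``.

    Boundary fluxes (and any column flagged in ``keep``) are fixed at their
    value in ``v_star``; every other flux is confined to the interval between
    0 and its value, and Σ|v| is minimized.  The result carries the same net
    conversion with all removable cycle flux stripped.
    """
    n = lp.n
    boundary = np.array([r.is_boundary for r in lp.model.reactions])
    fixed = boundary | keep
    bounds = []
    for j in range(n):
        if fixed[j]:
            bounds.append((v_star[j], v_star[j]))
        elif v_star[j] >= 0:
            bounds.append((0.0, v_star[j]))
        else:
            bounds.append((v_star[j], 0.0))
    # sign-restricted intervals make |v_j| linear: minimize sum sign(v*_j) v_j
    c = np.sign(v_star)
    c[fixed] = 0.0
    res = linprog(c, A_eq=lp.S, b_eq=np.zeros(lp.S.shape[0]), bounds=bounds, method="highs")
    if res.status != 0:
        # fall back to the raw solution if the restriction is numerically tight
        return v_star
    return res.x


def flux_variability(
    model: MetabolicModel,
    scenario: Optional[ScenarioConstraints] = None,
    objective: Objective = None,
    fraction_of_optimum: float = 1.0,
    loopless: bool = False,
    reactions: Optional[Sequence[str]] = None,
) -> FVAResult:
    """Per-reaction (min, max) flux subject to objective ≥ fraction·optimum.

    With ``objective=None`` the plain flux polytope is scanned (used by the
    consistency checks).  With ``loopless=True`` each extreme solution is
    post-processed CycleFreeFlux-style: the extreme solution's boundary
    fluxes are held fixed and Σ|v| is minimized, so flux carried only by
    stoichiometrically balanced cycles is excluded from the reported range.
    """
    m = apply_scenario(model, scenario)
    if objective is None and scenario is not None and scenario.objective:
        objective = scenario.objective
    lp = _LP(m)
    extra = None
    opt_value = None
    if objective is not None:
        weights = _objective_weights(m, objective)
        base = solve_fba(m, None, weights)
        if not base.ok:
            raise LPError(f"FVA baseline FBA is {base.status}")
        opt_value = base.objective_value
        if not (0.0 < fraction_of_optimum <= 1.0):
            raise ValueError("fraction_of_optimum must be in (0, 1]")
        threshold = opt_value - (1.0 - fraction_of_optimum) * abs(opt_value)
        threshold -= OPT_TOL * max(1.0, abs(opt_value))
        w = np.zeros(lp.n)
        for rid, wt in weights.items():
            w[lp.col_of[rid]] = wt
        extra = (-w.reshape(1, -1), np.array([-threshold]))

    scan = reactions if reactions is not None else lp.rxns
    ranges: dict[str, tuple[float, float]] = {}
    for rid in scan:
        j = lp.col_of[rid]
        c = np.zeros(lp.n)
        c[j] = 1.0
        out = []
        for sense in (1, -1):  # min then max
            res = lp.solve(c, sense=sense, extra_ub=extra)
            if res.status == 3:
                out.append(math.inf * -sense)
                continue
            if res.status != 0:
                raise LPError(f"FVA LP for reaction {rid!r} failed: {res.message}")
            v = res.x
            if loopless:
                keep = np.zeros(lp.n, dtype=bool)
                v = _cycle_free(lp, v, keep)
            out.append(float(v[j]))
        lo, hi = out
        if lo > hi:
            lo, hi = hi, lo
        ranges[rid] = (lo, hi)
    return FVAResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum,
                     objective_value=opt_value)


# ---------------------------------------------------------------------------
# Shadow prices
# ---------------------------------------------------------------------------


def shadow_prices(
    model: MetabolicModel,
    scenario: Optional[ScenarioConstraints] = None,
    objective: Objective = None,
    check: bool = False,
    eps: float = 1e-4,
) -> tuple[dict[str, float], set[str]]:
    """Dual value per boundary metabolite: marginal objective gain per unit
    relaxation of that metabolite's uptake bound.

    π ≥ 0 for limiting resources and 0 where the uptake bound is slack.  With
    ``check=True`` each π is compared against a central finite difference of
    the bound; metabolites where the two disagree (degenerate optima with
    non-unique duals) are returned in the second element.
    """
    m = apply_scenario(model, scenario)
    if objective is None and scenario is not None and scenario.objective:
        objective = scenario.objective
    weights = _objective_weights(m, objective)
    lp = _LP(m)
    c = np.zeros(lp.n)
    for rid, wt in weights.items():
        c[lp.col_of[rid]] = wt
    res = lp.solve(c)
    if res.status != 0:
        raise LPError(f"shadow-price LP not optimal: {_STATUS.get(res.status)}")

    prices: dict[str, float] = {}
    degenerate: set[str] = set()
    for rxn in m.boundary_reactions():
        met = rxn.boundary_metabolite()
        j = lp.col_of[rxn.id]
        # uptake capacity u enters as lower_bound = -u; relaxing u by du moves
        # the lower bound by -du, so π = -d(max obj)/d(lb).  linprog minimizes
        # sense*c with sense=-1, hence marginals refer to -obj and the two
        # sign flips cancel.
        pi = float(res.lower.marginals[j])
        prices[met] = pi
        if check:
            fd = _finite_difference_price(m, weights, rxn.id, eps)
            if fd is not None and abs(fd - pi) > 1e-4 * max(1.0, abs(pi)):
                degenerate.add(met)
    return prices, degenerate


def _finite_difference_price(model, weights, rxn_id, eps):
    """Central finite difference of the optimum w.r.t. the uptake capacity."""
    vals = []
    for delta in (-eps, eps):
        m2 = model.copy()
        r = m2.reaction(rxn_id)
        r.lower_bound -= delta  # relaxing uptake means a more negative lb
        sol = solve_fba(m2, None, weights)
        if not sol.ok:
            return None
        vals.append(sol.objective_value)
    return (vals[1] - vals[0]) / (2 * eps)


# ---------------------------------------------------------------------------
# Phenotype phase plane
# ---------------------------------------------------------------------------


@dataclass
class PhasePlane:
    axis_reactions: tuple[str, str]
    axis_metabolites: tuple[str, str]
    grid_a: np.ndarray  # uptake capacities along axis A
    grid_b: np.ndarray
    objective: np.ndarray  # shape (len(grid_a), len(grid_b)); NaN where infeasible
    price_a: np.ndarray
    price_b: np.ndarray
    labels: np.ndarray  # phase labels; -1 marks infeasible cells

    @property
    def n_phases(self) -> int:
        return len({int(v) for v in self.labels.ravel() if v >= 0})


SIGN_TOL = 1e-6


def _signature(pa: float, pb: float) -> tuple[int, int]:
    def q(x):
        if abs(x) <= SIGN_TOL:
            return 0
        return 1 if x > 0 else -1

    return (q(pa), q(pb))


def phase_plane(
    model: MetabolicModel,
    rxn_a: str,
    rxn_b: str,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    scenario: Optional[ScenarioConstraints] = None,
    objective: Objective = None,
) -> PhasePlane:
    """Objective value and shadow prices over a grid of two uptake bounds.

    ``grid_a``/``grid_b`` are uptake capacities (nonnegative); for each cell
    the corresponding exchange lower bound is set to minus the capacity, the
    FBA optimum and the two axis shadow prices are recorded, each shadow
    price is quantized to {-, 0, +} with tolerance ``SIGN_TOL``, and maximal
    4-connected regions of identical signature become the phases.  Infeasible
    cells are labeled -1.
    """
    m = apply_scenario(model, scenario)
    if objective is None and scenario is not None and scenario.objective:
        objective = scenario.objective
    weights = _objective_weights(m, objective)
    ra, rb = m.reaction(rxn_a), m.reaction(rxn_b)
    if not (ra.is_boundary and rb.is_boundary):
        raise ModelStructureError("phase-plane axes must be boundary reactions")
    met_a, met_b = ra.boundary_metabolite(), rb.boundary_metabolite()

    ga = np.asarray(list(grid_a), dtype=float)
    gb = np.asarray(list(grid_b), dtype=float)
    shape = (len(ga), len(gb))
    obj = np.full(shape, np.nan)
    pa = np.full(shape, np.nan)
    pb = np.full(shape, np.nan)

    for i, a in enumerate(ga):
        for j, b in enumerate(gb):
            m2 = m.copy()
            m2.reaction(rxn_a).lower_bound = -abs(a)
            m2.reaction(rxn_b).lower_bound = -abs(b)
            sol = solve_fba(m2, None, weights)
            if not sol.ok:
                continue
            obj[i, j] = sol.objective_value
            prices, _ = shadow_prices(m2, None, weights)
            pa[i, j] = prices[met_a]
            pb[i, j] = prices[met_b]

    labels = _segment(obj, pa, pb)
    return PhasePlane(
        axis_reactions=(rxn_a, rxn_b), axis_metabolites=(met_a, met_b),
        grid_a=ga, grid_b=gb, objective=obj, price_a=pa, price_b=pb, labels=labels,
    )


def _segment(obj: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Label maximal 4-connected regions of constant shadow-price signature."""
    ni, nj = obj.shape
    labels = np.full((ni, nj), -1, dtype=int)
    next_label = 0
    for i in range(ni):
        for j in range(nj):
            if labels[i, j] != -1 or math.isnan(obj[i, j]):
                continue
            sig = _signature(pa[i, j], pb[i, j])
            stack = [(i, j)]
            labels[i, j] = next_label
            while stack:
                ci, cj = stack.pop()
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    x, y = ci + di, cj + dj
                    if 0 <= x < ni and 0 <= y < nj and labels[x, y] == -1:
                        if math.isnan(obj[x, y]):
                            continue
                        if _signature(pa[x, y], pb[x, y]) == sig:
                            labels[x, y] = next_label
                            stack.append((x, y))
            next_label += 1
    return labels


# ---------------------------------------------------------------------------
# Gene deletion
# ---------------------------------------------------------------------------


def single_gene_deletion(
    model: MetabolicModel,
    scenario: Optional[ScenarioConstraints] = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> dict[str, tuple[str, float]]:
    """Exhaustive single-gene knockouts against the nitrogenase objective.

    For each gene, every reaction whose GPR evaluates false under the
    deletion is disabled and the nitrogenase flux is maximized; the gene is
    essential iff the optimum falls below ``threshold`` flux units (an
    infeasible knockout also counts as essential).  Returns
    ``gene -> (call, max_nitrogenase_flux)``.
    """
    m = apply_scenario(model, scenario)
    if m.nitrogenase_id is None:
        raise ModelStructureError("single_gene_deletion requires a designated nitrogenase")
    results: dict[str, tuple[str, float]] = {}
    for gene in m.genes:
        m2 = m.copy()
        for rxn in m2.reactions:
            if gene in rxn.gpr.genes() and not rxn.gpr.evaluate({gene}):
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
        sol = solve_fba(m2, None, m.nitrogenase_id)
        if not sol.ok:
            results[gene] = ("essential", math.nan)
        else:
            call = "essential" if sol.objective_value < threshold else "nonessential"
            results[gene] = (call, sol.objective_value)
    return results


# ---------------------------------------------------------------------------
# Ensemble-evolutionary FBA
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Random-objective ensemble: each objective draws a uniform number of
    reactions (without replacement) from the pool and assigns them
    uniform(0, 1] weights."""

    n_objectives: int = 50_000
    seed: int = 0
    pool: Optional[Sequence[str]] = None  # default: all reactions
    min_nitrogenase: float = 0.01

    def __post_init__(self):
        if self.n_objectives < 1:
            raise ValueError("n_objectives must be >= 1")


@dataclass
class EnsembleResult:
    sweep_reaction: str
    sweep_values: list[float]
    # sweep value index -> reaction -> (mean, sd) over feasible draws
    stats: list[dict[str, tuple[float, float]]]
    skipped: list[int]  # infeasible draws per sweep point


def random_objective_ensemble(
    model: MetabolicModel,
    spec: EnsembleSpec,
    sweep_reaction: str,
    sweep_bounds: Sequence[float],
    scenario: Optional[ScenarioConstraints] = None,
    track: Optional[Sequence[str]] = None,
) -> EnsembleResult:
    """Mean ± SD of fluxes across a random-objective ensemble, per sweep point.

    ``sweep_bounds`` are uptake capacities for ``sweep_reaction`` (its lower
    bound is set to minus each value in turn).  The same seeded draw stream
    is reused at every sweep point; infeasible draws are skipped and counted,
    not resampled, so the stream stays seed-stable.
    """
    m = apply_scenario(model, scenario)
    if m.nitrogenase_id is not None and spec.min_nitrogenase > 0:
        nif = m.reaction(m.nitrogenase_id)
        nif.lower_bound = max(nif.lower_bound, spec.min_nitrogenase)

    pool = list(spec.pool) if spec.pool is not None else m.reaction_ids
    for rid in pool:
        m.reaction(rid)
    rng = np.random.default_rng(spec.seed)
    draws = []
    for _ in range(spec.n_objectives):
        size = int(rng.integers(1, len(pool) + 1))
        idx = rng.choice(len(pool), size=size, replace=False)
        weights = 1.0 - rng.random(size)  # uniform (0, 1]
        draws.append((idx, weights))

    track = list(track) if track is not None else m.reaction_ids
    stats: list[dict[str, tuple[float, float]]] = []
    skipped: list[int] = []
    for bound in sweep_bounds:
        m2 = m.copy()
        m2.reaction(sweep_reaction).lower_bound = -abs(float(bound))
        lp = _LP(m2)
        track_cols = [lp.col_of[rid] for rid in track]
        acc = np.zeros((0, len(track)))
        rows = []
        n_skipped = 0
        for idx, weights in draws:
            c = np.zeros(lp.n)
            for k, w in zip(idx, weights):
                c[lp.col_of[pool[k]]] = w
            res = lp.solve(c)
            if res.status != 0:
                n_skipped += 1
                continue
            rows.append(res.x[track_cols])
        if rows:
            arr = np.array(rows)
            mean = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=0)
            stats.append({rid: (float(mu), float(s))
                          for rid, mu, s in zip(track, mean, sd)})
        else:
            stats.append({rid: (math.nan, math.nan) for rid in track})
        skipped.append(n_skipped)
    return EnsembleResult(
        sweep_reaction=sweep_reaction, sweep_values=[float(b) for b in sweep_bounds],
        stats=stats, skipped=skipped,
    )
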