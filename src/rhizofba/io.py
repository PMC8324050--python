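"""Model, scenario and result input/output.

Models are read and written in two formats: the community JSON model dialect
(native implementation, exact round trip) and SBML Level 3 with the
flux-bounds/GPR (fbc) extension, delegated to cobrapy.  Scenario constraint
tables are TSV (columns: reaction_id, lower, upper) or YAML; results go to
TSV with deterministic column order.

Sign convention: boundary reactions are written as ``metabolite →`` so
export is positive and uptake is a negative flux.  Reaction kind is
recovered on import from the id prefix (``EX_``/``DM_``/``SK_``) and, for
transports, from the compartments the reaction spans.
"""

from __future__ import annotations

import json
import re
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .ecm import Conversion
from .fba import FVAResult, FluxDistribution, PhasePlane
from .model import (
    DEFAULT_BOUND,
    Gpr,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
)
from .scenario import ScenarioConstraints

__all__ = [
    "read_model",
    "write_model",
    "read_scenario",
    "write_scenario",
    "write_results",
    "to_cobra",
    "from_cobra",
    "ScenarioConstraints",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

_COMPARTMENT_TO_SHORT = {"internal": "c", "external": "e"}
_SHORT_TO_COMPARTMENT = {"c": "internal", "e": "external",
                         "internal": "internal", "external": "external"}


def _parse_formula(s: str) -> Optional[dict[str, int]]:
    if not s:
        return None
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(s):
        if m.start() != pos:
            raise ModelStructureError(f"cannot parse formula {s!r}")
        pos = m.end()
        out[m.group(1)] = int(m.group(2) or 1)
    if pos != len(s):
        raise ModelStructureError(f"cannot parse formula {s!r}")
    return out


def _coef_to_number(c: Fraction) -> Union[int, float]:
    return int(c) if c.denominator == 1 else float(c)


def _number_to_coef(x) -> Fraction:
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(x).limit_denominator(10**9)


def _infer_kind(rxn_id: str, stoich: dict[str, Fraction], compartment_of) -> str:
    if rxn_id.startswith("EX_"):
        return "exchange"
    if rxn_id.startswith("DM_"):
        return "demand"
    if rxn_id.startswith("SK_"):
        return "sink"
    comps = {compartment_of(m) for m in stoich}
    if len(comps) > 1:
        return "transport"
    return "metabolic"


# ---------------------------------------------------------------------------
# JSON dialect (native)
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": _COMPARTMENT_TO_SHORT[m.compartment],
                "formula": m.formula_string(),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {m: _coef_to_number(c) for m, c in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "kind": r.kind,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
        "annotation": {
            "nitrogenase": model.nitrogenase_id,
            "trackers": dict(model.trackers),
        },
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    mets = []
    seen = set()
    for md in data.get("metabolites", []):
        if md["id"] in seen:
            raise ModelStructureError(f"duplicate metabolite id {md['id']!r}")
        seen.add(md["id"])
        mets.append(
            Metabolite(
                md["id"],
                name=md.get("name", ""),
                compartment=_SHORT_TO_COMPARTMENT.get(md.get("compartment", "c"), "internal"),
                formula=_parse_formula(md.get("formula", "") or ""),
                charge=md.get("charge"),
            )
        )
    met_comp = {m.id: m.compartment for m in mets}
    rxns = []
    seen = set()
    for rd in data.get("reactions", []):
        rid = rd["id"]
        if rid in seen:
            raise ModelStructureError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich = {m: _number_to_coef(c) for m, c in rd["metabolites"].items()}
        lb = rd.get("lower_bound")
        ub = rd.get("upper_bound")
        if lb is None or ub is None:
            # absent bounds: reversible default (-1000, 1000); irreversible (0, 1000)
            lb = -DEFAULT_BOUND if rd.get("reversible", True) else 0.0
            ub = DEFAULT_BOUND
        kind = rd.get("kind") or _infer_kind(rid, stoich, met_comp.get)
        rxns.append(
            Reaction(rid, stoich, name=rd.get("name", ""), lower_bound=float(lb),
                     upper_bound=float(ub), gpr=Gpr.parse(rd.get("gene_reaction_rule", "")),
                     kind=kind)
        )
    genes = [g["id"] if isinstance(g, dict) else str(g) for g in data.get("genes", [])]
    ann = data.get("annotation", {}) or {}
    return MetabolicModel(
        id=data.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        nitrogenase_id=ann.get("nitrogenase"),
        trackers=dict(ann.get("trackers", {})),
    )


# ---------------------------------------------------------------------------
# cobra bridge (SBML L3+fbc)
# ---------------------------------------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (compartments c=internal, e=external)."""
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=_COMPARTMENT_TO_SHORT[m.compartment],
            formula=m.formula_string() or None, charge=m.charge,
        )
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[m]: float(c) for m, c in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            cr.gene_reaction_rule = rule
    if model.nitrogenase_id is not None:
        cm.objective = model.nitrogenase_id
    return cm


def from_cobra(cm, nitrogenase_id: Optional[str] = None) -> MetabolicModel:
    """Convert a cobrapy model to the native representation."""
    mets = [
        Metabolite(
            m.id, name=m.name or "",
            compartment=_SHORT_TO_COMPARTMENT.get(m.compartment, "internal"),
            formula=_parse_formula(m.formula or ""),
            charge=m.charge if m.charge is not None else None,
        )
        for m in cm.metabolites
    ]
    met_comp = {m.id: m.compartment for m in mets}
    rxns = []
    for r in cm.reactions:
        stoich = {m.id: _number_to_coef(c) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(r.id, stoich, name=r.name or "", lower_bound=float(r.lower_bound),
                     upper_bound=float(r.upper_bound),
                     gpr=Gpr.parse(r.gene_reaction_rule or ""),
                     kind=_infer_kind(r.id, stoich, met_comp.get))
        )
    genes = [g.id for g in cm.genes]
    if nitrogenase_id is None and any(r.id == "NIF" for r in rxns):
        nitrogenase_id = "NIF"
    return MetabolicModel(id=cm.id or "model", metabolites=mets, reactions=rxns,
                          genes=genes, nitrogenase_id=nitrogenase_id)


# ---------------------------------------------------------------------------
# Public read/write
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".json",):
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path, format: Optional[str] = None,
               nitrogenase_id: Optional[str] = None) -> MetabolicModel:
    """Read a model from JSON (community dialect) or SBML Level 3 + fbc.

    The round trip write→read preserves ids, stoichiometry, bounds and gene
    rules.  ``nitrogenase_id`` overrides the designated nitrogenase (for SBML
    files the reaction id ``NIF`` is recognized automatically).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelStructureError(f"malformed JSON model {path.name}: {exc}") from exc
        model = _model_from_dict(data)
        if nitrogenase_id is not None:
            model.nitrogenase_id = nitrogenase_id
            model.validate()
        return model
    if fmt == "sbml":
        import cobra

        cm = cobra.io.read_sbml_model(str(path))
        return from_cobra(cm, nitrogenase_id)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1)
        return
    if fmt == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), str(path))
        return
    raise ValueError(f"unknown model format {fmt!r}")


def read_scenario(path, name: Optional[str] = None) -> ScenarioConstraints:
    """Read scenario constraints from TSV (reaction_id, lower, upper) or YAML.

    TSV rows apply verbatim as bound overrides; reactions not listed are
    untouched.  YAML files may additionally carry ``objective`` and ``notes``.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        bounds = {rid: (float(lo), float(hi))
                  for rid, (lo, hi) in (data.get("bounds") or {}).items()}
        return ScenarioConstraints(
            name=data.get("name", name or path.stem), bounds=bounds,
            objective={k: float(v) for k, v in (data.get("objective") or {}).items()},
            notes=data.get("notes", ""),
        )
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return ScenarioConstraints(name=name or path.stem)
    expected = {"reaction_id", "lower", "upper"}
    unknown = set(df.columns) - expected
    if unknown:
        raise ValueError(f"unknown scenario columns {sorted(unknown)} in {path.name}")
    if not expected <= set(df.columns):
        raise ValueError(f"scenario file {path.name} needs columns {sorted(expected)}")
    bounds = {}
    for _, row in df.iterrows():
        try:
            lo, hi = float(row["lower"]), float(row["upper"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric bound for {row['reaction_id']!r} in {path.name}"
            ) from exc
        bounds[str(row["reaction_id"])] = (lo, hi)
    return ScenarioConstraints(name=name or path.stem, bounds=bounds)


def write_scenario(scenario: ScenarioConstraints, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = {
            "name": scenario.name,
            "bounds": {rid: [lo, hi] for rid, (lo, hi) in sorted(scenario.bounds.items())},
            "objective": dict(sorted(scenario.objective.items())),
            "notes": scenario.notes,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return
    rows = [{"reaction_id": rid, "lower": lo, "upper": hi}
            for rid, (lo, hi) in sorted(scenario.bounds.items())]
    pd.DataFrame(rows, columns=["reaction_id", "lower", "upper"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def conversions_to_frames(
    convs: Sequence[Conversion], columns: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed-coefficient table and its indexed (−1/0/+1) companion.

    One row per conversion, one column per external metabolite (sorted for a
    deterministic layout); the indexed table represents inputs, outputs and
    nonparticipating compounds as −1, +1 and 0.
    """
    if columns is None:
        cols: set[str] = set()
        for c in convs:
            cols |= set(c.coefficients) | set(c.tracked)
        columns = sorted(cols)
    rows = []
    for c in convs:
        all_coef = dict(c.coefficients)
        all_coef.update(c.tracked)
        rows.append([float(all_coef.get(m, 0)) for m in columns])
    signed = pd.DataFrame(rows, columns=list(columns))
    indexed = signed.map(lambda v: 0 if v == 0 else (1 if v > 0 else -1))
    return signed, indexed


def write_results(obj, path) -> None:
    """Write an analysis result to TSV with deterministic column order.

    Flux distributions become (reaction, flux); FVA results (reaction, min,
    max); conversion lists a signed table plus an ``.indexed.tsv`` companion
    with −1/0/+1 entries; phase planes a long-format grid table.
    """
    path = Path(path)
    if isinstance(obj, FluxDistribution):
        rows = [{"reaction": r, "flux": v} for r, v in sorted(obj.fluxes.items())]
        df = pd.DataFrame(rows, columns=["reaction", "flux"])
        df.attrs["objective"] = obj.objective_value
        df.to_csv(path, sep="\t", index=False)
        return
    if isinstance(obj, FVAResult):
        rows = [{"reaction": r, "min": lo, "max": hi}
                for r, (lo, hi) in sorted(obj.ranges.items())]
        pd.DataFrame(rows, columns=["reaction", "min", "max"]).to_csv(
            path, sep="\t", index=False
        )
        return
    if isinstance(obj, PhasePlane):
        rows = []
        for i, a in enumerate(obj.grid_a):
            for j, b in enumerate(obj.grid_b):
                rows.append({
                    f"uptake_{obj.axis_reactions[0]}": a,
                    f"uptake_{obj.axis_reactions[1]}": b,
                    "objective": obj.objective[i, j],
                    f"price_{obj.axis_metabolites[0]}": obj.price_a[i, j],
                    f"price_{obj.axis_metabolites[1]}": obj.price_b[i, j],
                    "phase": obj.labels[i, j],
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return
    if isinstance(obj, (list, tuple)) and all(isinstance(c, Conversion) for c in obj):
        signed, indexed = conversions_to_frames(list(obj))
        signed.to_csv(path, sep="\t", index=False)
        indexed.to_csv(path.with_suffix(".indexed.tsv"), sep="\t", index=False)
        return
    raise TypeError(f"don't know how to write {type(obj).__name__} results")
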