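"""Scenario orchestration: the computational experiments end to end.

Each registered scenario resolves its constraints, runs the corresponding
analysis on the model and writes a result bundle (resolved constraints,
output tables, seed, log) to an output directory.  Every scenario is
deterministic given (model, config, seed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from . import fba, io, metrics
from .ecm import EcmConfig, add_flux_tracker, enumerate_ecms
from .model import MetabolicModel
from .scenario import ScenarioConstraints
from .synth import (
    SOURCE_EXCHANGE,
    bacteroid_scenario,
    ground_truth_essentiality,
    make_mock_experimental_calls,
)

log = logging.getLogger("rhizofba")


# ---------------------------------------------------------------------------
# Essentiality comparison
# ---------------------------------------------------------------------------


@dataclass
class EssentialityComparison:
    """In-silico vs experimental essentiality, 'essential' counted positive.

    False negatives are in-silico nonessential genes that are essential
    experimentally.
    """

    calls: dict[str, tuple[str, str]]  # gene -> (in_silico, experimental)
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return len(self.calls)

    @property
    def agreement(self) -> int:
        return self.tp + self.tn

    @property
    def agreement_fraction(self) -> float:
        return self.agreement / self.n if self.n else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "in_silico": a, "experimental": b}
                for g, (a, b) in sorted(self.calls.items())]
        return pd.DataFrame(rows, columns=["gene", "in_silico", "experimental"])


def compare_essentiality(
    in_silico: Mapping[str, str], experimental: Mapping[str, str]
) -> EssentialityComparison:
    """Confusion counts and agreement over the shared gene set.

    Comparison is restricted to the intersection of the two gene sets (the
    non-overlap is logged); an empty intersection is an error.
    """
    shared = sorted(set(in_silico) & set(experimental))
    if not shared:
        raise ValueError("no genes shared between in-silico and experimental calls")
    dropped = (set(in_silico) | set(experimental)) - set(shared)
    if dropped:
        log.info("essentiality comparison: %d genes outside the intersection", len(dropped))
    calls = {}
    tp = tn = fp = fn = 0
    for g in shared:
        a, b = in_silico[g], experimental[g]
        calls[g] = (a, b)
        if a == "essential" and b == "essential":
            tp += 1
        elif a == "nonessential" and b == "nonessential":
            tn += 1
        elif a == "essential" and b == "nonessential":
            fp += 1
        else:
            fn += 1
    return EssentialityComparison(calls=calls, tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Defaults mirror the study conditions where they are printed: carbon
    uptake 4 flux units, ensemble minimum nitrogenase flux 0.01, amino-acid
    demands 0.01-0.05, ensemble size 50,000 (scale down via n_objectives for
    quick runs).  The oxygen ceiling has no printed literature value and must
    be chosen explicitly."""

    o2_max: float = 4.0
    carbon_source: str = "malate"
    carbon_uptake: float = 4.0
    seed: int = 0
    n_objectives: int = 50_000
    o2_grid: tuple[float, ...] = (6.0, 4.0, 2.0)
    fva_fraction: float = 0.99
    phase_grid_points: int = 20
    nitrogenase_level: float = 0.3  # matched activity for O2-minimization scenarios
    glutamate_demand: float = 0.5
    mock_agreement: float = 0.87
    ecm_inputs: tuple[str, ...] = ("mal_e", "succ_e", "gaba_e", "n2_e", "o2_e", "pi_e")
    ecm_outputs: tuple[str, ...] = (
        "nh3_e", "ala_e", "asp_e", "glu_e", "gln_e", "co2_e", "h2_e",
        "phb_e", "glyg_e", "pmt_e", "glyclip_e",
    )
    ecm_hidden: tuple[str, ...] = ("h2o_e",)


def default_ecm_config(cfg: PipelineConfig, extra_outputs: tuple[str, ...] = ()) -> EcmConfig:
    return EcmConfig(
        inputs=set(cfg.ecm_inputs),
        outputs=set(cfg.ecm_outputs) | set(extra_outputs),
        hidden=set(cfg.ecm_hidden),
    )


class ResultBundle(dict):
    """Scenario outputs; ``write(out_dir)`` persists every entry."""

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, value in self.items():
            if isinstance(value, ScenarioConstraints):
                io.write_scenario(value, out_dir / f"{key}.tsv")
            elif isinstance(value, pd.DataFrame):
                value.to_csv(out_dir / f"{key}.tsv", sep="\t", index=False)
            elif isinstance(value, (fba.FluxDistribution, fba.FVAResult, fba.PhasePlane, list)):
                io.write_results(value, out_dir / f"{key}.tsv")
            else:
                with open(out_dir / f"{key}.json", "w") as fh:
                    json.dump(value, fh, indent=1, default=str)
        return out_dir


def _scenario_fba_max_nitrogenase(model, cfg: PipelineConfig) -> ResultBundle:
    sc = bacteroid_scenario(model, o2_max=cfg.o2_max, carbon_source=cfg.carbon_source,
                            carbon_uptake=cfg.carbon_uptake)
    sol = fba.solve_fba_l1(model, sc)
    return ResultBundle(constraints=sc, fluxes=sol,
                        summary={"objective": sol.objective_value, "status": sol.status})


def _scenario_fva_phases(model, cfg: PipelineConfig) -> ResultBundle:
    """Loopless FVA at near-optimal nitrogenase across an oxygen ladder."""
    rows = []
    watch = [r for r in ("CS", "PHBS", "FAS", "ALADH", "ICDH") if r in model._rxn_index]
    bundle = ResultBundle()
    for o2 in cfg.o2_grid:
        sc = bacteroid_scenario(model, o2_max=o2, carbon_source=cfg.carbon_source,
                                carbon_uptake=cfg.carbon_uptake, fix_carbon=True)
        fva = fba.flux_variability(model, sc, fraction_of_optimum=cfg.fva_fraction,
                                   loopless=True, reactions=watch)
        for rid in watch:
            lo, hi = fva[rid]
            rows.append({"o2_max": o2, "reaction": rid, "min": lo, "max": hi,
                         "nitrogenase_opt": fva.objective_value})
    bundle["fva"] = pd.DataFrame(rows)
    return bundle


def _scenario_phase_plane(model, cfg: PipelineConfig) -> ResultBundle:
    carbon_ex, _ = SOURCE_EXCHANGE[cfg.carbon_source]
    sc = bacteroid_scenario(model, o2_max=cfg.o2_max, carbon_source=cfg.carbon_source,
                            carbon_uptake=cfg.carbon_uptake)
    n = cfg.phase_grid_points
    grid_c = np.linspace(0.25, 8.0, n)
    grid_o = np.linspace(0.25, 8.0, n)
    pp = fba.phase_plane(model, carbon_ex, "EX_o2", grid_c, grid_o, scenario=sc)
    return ResultBundle(phase_plane=pp, summary={"n_phases": pp.n_phases})


def _scenario_ecm_survey(model, cfg: PipelineConfig) -> ResultBundle:
    tracked = add_flux_tracker(model, "GS", "trk_gs")
    ecm_cfg = default_ecm_config(cfg, extra_outputs=("trk_gs",))
    ecms = enumerate_ecms(tracked, ecm_cfg)
    kept, rejected = metrics.filter_conversions(ecms, tracked)
    rows = []
    for i, conv in enumerate(ecms):
        mm = metrics.conversion_metrics(conv, tracked, gs_tracker="trk_gs")
        rows.append({
            "index": i,
            "o2_per_carbon": mm.o2_per_carbon,
            "o2_per_n2": mm.o2_per_n2,
            "carbon_cost_g_per_g_n": mm.carbon_cost_g_per_g_n,
            "net_n_out": mm.net_n_out,
            "gs_flux": mm.gs_flux,
            "polymer_producing": mm.classes.polymer_producing,
            "ammonia_only": mm.classes.ammonia_only,
            "amino_acid_secreting": mm.classes.amino_acid_secreting,
            "amino_acid_consuming": mm.classes.amino_acid_consuming,
            "kept": i not in rejected,
            "rejection_reasons": ";".join(rejected.get(i, [])),
        })
    return ResultBundle(
        conversions=ecms, metrics=pd.DataFrame(rows),
        summary={"n_ecms": len(ecms), "n_kept": len(kept)},
    )


def _scenario_ensemble(model, cfg: PipelineConfig) -> ResultBundle:
    sc = bacteroid_scenario(model, o2_max=max(cfg.o2_grid), carbon_source=cfg.carbon_source,
                            carbon_uptake=cfg.carbon_uptake, fix_carbon=True)
    spec = fba.EnsembleSpec(n_objectives=cfg.n_objectives, seed=cfg.seed)
    track = [r for r in ("CS", "PHBS", "FAS", "ALADH", "NIF") if r in model._rxn_index]
    res = fba.random_objective_ensemble(model, spec, "EX_o2", list(cfg.o2_grid),
                                        scenario=sc, track=track)
    rows = []
    for i, o2 in enumerate(res.sweep_values):
        for rid, (mu, sd) in res.stats[i].items():
            rows.append({"o2_max": o2, "reaction": rid, "mean": mu, "sd": sd,
                         "skipped": res.skipped[i]})
    return ResultBundle(ensemble=pd.DataFrame(rows),
                        summary={"n_objectives": cfg.n_objectives, "seed": cfg.seed})


def _scenario_essentiality(model, cfg: PipelineConfig) -> ResultBundle:
    sc = bacteroid_scenario(model, o2_max=cfg.o2_max, carbon_source=cfg.carbon_source,
                            carbon_uptake=cfg.carbon_uptake)
    deletions = fba.single_gene_deletion(model, sc)
    in_silico = {g: call for g, (call, _) in deletions.items()}
    mock = make_mock_experimental_calls(in_silico, cfg.mock_agreement, cfg.seed)
    comparison = compare_essentiality(in_silico, mock)
    table = comparison.to_frame()
    table["max_nitrogenase"] = [deletions[g][1] for g in table["gene"]]
    return ResultBundle(
        essentiality=table,
        summary={
            "n_genes": comparison.n, "agreement": comparison.agreement,
            "agreement_fraction": comparison.agreement_fraction,
            "tp": comparison.tp, "tn": comparison.tn,
            "fp": comparison.fp, "fn": comparison.fn,
        },
    )


def _scenario_glutamate_forcing(model, cfg: PipelineConfig) -> ResultBundle:
    """Minimum oxygen demand at matched nitrogenase activity, with and
    without a forced glutamate demand (the ammonia-assimilation scenario)."""
    rows = []
    for forced, glu in (("without", None), ("with", cfg.glutamate_demand)):
        sc = bacteroid_scenario(model, o2_max=1e6, carbon_source=cfg.carbon_source,
                                carbon_uptake=cfg.carbon_uptake, glutamate_demand=glu)
        sc.bounds["NIF"] = (cfg.nitrogenase_level, cfg.nitrogenase_level)
        sol = fba.solve_fba(model, sc, objective={"EX_o2": 1.0})
        rows.append({
            "glutamate_forcing": forced,
            "nitrogenase": cfg.nitrogenase_level,
            "min_o2_demand": -sol.objective_value if sol.ok else math.nan,
            "status": sol.status,
        })
    return ResultBundle(glutamate_forcing=pd.DataFrame(rows))


def _scenario_carbon_source_compare(
    model, cfg: PipelineConfig, sources: tuple[str, ...] = ("malate", "sucrose"),
    carbon_atoms: float = 12.0,
) -> ResultBundle:
    """Per-carbon-atom maximum nitrogenase activity and minimum oxygen demand
    for each carbon source at matched constraints."""
    rows = []
    nif_per_c = cfg.nitrogenase_level / 6.0  # matched activity per carbon atom
    for source in sources:
        ex, n_c = SOURCE_EXCHANGE[source]
        uptake = carbon_atoms / n_c
        sc = bacteroid_scenario(model, o2_max=cfg.o2_max, carbon_source=source,
                                carbon_uptake=uptake)
        sol = fba.solve_fba(model, sc)
        sc2 = bacteroid_scenario(model, o2_max=1e6, carbon_source=source,
                                 carbon_uptake=uptake)
        nif = nif_per_c * carbon_atoms
        sc2.bounds["NIF"] = (nif, nif)
        sol_o2 = fba.solve_fba(model, sc2, objective={"EX_o2": 1.0})
        rows.append({
            "carbon_source": source,
            "carbon_atoms": carbon_atoms,
            "max_nitrogenase_per_c": sol.objective_value / carbon_atoms if sol.ok else math.nan,
            "min_o2_per_c": (-sol_o2.objective_value / carbon_atoms) if sol_o2.ok else math.nan,
            "status": sol.status,
        })
    return ResultBundle(carbon_sources=pd.DataFrame(rows))


SCENARIOS: dict[str, Callable[[MetabolicModel, PipelineConfig], ResultBundle]] = {
    "fba_max_nitrogenase": _scenario_fba_max_nitrogenase,
    "fva_phases": _scenario_fva_phases,
    "phase_plane": _scenario_phase_plane,
    "ecm_survey": _scenario_ecm_survey,
    "ensemble": _scenario_ensemble,
    "essentiality": _scenario_essentiality,
    "glutamate_forcing": _scenario_glutamate_forcing,
    "carbon_source_compare": _scenario_carbon_source_compare,
}


def run_scenario(
    name: str,
    model: MetabolicModel,
    config: Optional[PipelineConfig] = None,
    out_dir=None,
) -> ResultBundle:
    """Run a registered scenario; optionally persist the bundle to disk.

    The bundle always echoes the resolved configuration and the seed, so a
    run is reproducible from its output directory alone.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; registry: {sorted(SCENARIOS)}")
    cfg = config or PipelineConfig()
    log.info("running scenario %s (seed=%d)", name, cfg.seed)
    bundle = SCENARIOS[name](model, cfg)
    bundle["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(cfg).items()}
    if out_dir is not None:
        bundle.write(Path(out_dir) / name)
    return bundle
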