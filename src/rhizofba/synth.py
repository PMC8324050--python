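"""Programmatic generator of a core-bacteroid metabolic model.

The generated network is a fully specified, element-balanced stand-in for a
core model of nitrogen-fixing rhizobial bacteroids: dicarboxylate uptake
feeding a full TCA cycle, malic enzyme and pyruvate dehydrogenase,
gluconeogenesis with a lumped pentose-phosphate branch, an electron-transport
chain with configurable P/O ratios, ferredoxin-coupled nitrogenase, GS-GOGAT
ammonia assimilation, alanine dehydrogenase and aspartate transaminase,
storage-polymer synthesis (PHB, glycogen, palmitate, glycerolipid), sugar
(sucrose/glucose/arabinose) and GABA catabolism, and amino-acid demand
reactions.  Every metabolite carries a full C/H/N/O/P/S formula and every
internal reaction is exactly element-balanced (water and protons are filled
in automatically), so the consistency checks, FBA analyses and exact ECM
enumeration all run on it without downloads.

Lumped steps (glycolysis, gluconeogenesis from PEP, the pentose-phosphate
branch, polymer synthesis, arabinose catabolism) use textbook net
stoichiometries; they are this package's own lumps, documented in the
methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional

import numpy as np

from . import fba
from .model import Gpr, MetabolicModel, Metabolite, Reaction
from .scenario import ScenarioConstraints

F = Fraction

# -- formulas (neutral species) ---------------------------------------------

FORMULAS: dict[str, dict[str, int]] = {
    "h2o": {"H": 2, "O": 1},
    "h": {"H": 1},
    "o2": {"O": 2},
    "co2": {"C": 1, "O": 2},
    "n2": {"N": 2},
    "nh3": {"N": 1, "H": 3},
    "h2": {"H": 2},
    "pi": {"H": 3, "P": 1, "O": 4},
    # carbon skeletons
    "mal": {"C": 4, "H": 6, "O": 5},
    "succ": {"C": 4, "H": 6, "O": 4},
    "fum": {"C": 4, "H": 4, "O": 4},
    "oaa": {"C": 4, "H": 4, "O": 5},
    "pyr": {"C": 3, "H": 4, "O": 3},
    "cit": {"C": 6, "H": 8, "O": 7},
    "icit": {"C": 6, "H": 8, "O": 7},
    "akg": {"C": 5, "H": 6, "O": 5},
    "ssa": {"C": 4, "H": 6, "O": 3},
    "pep": {"C": 3, "H": 5, "O": 6, "P": 1},
    "g6p": {"C": 6, "H": 13, "O": 9, "P": 1},
    "f6p": {"C": 6, "H": 13, "O": 9, "P": 1},
    "ru5p": {"C": 5, "H": 11, "O": 8, "P": 1},
    "glc": {"C": 6, "H": 12, "O": 6},
    "fru": {"C": 6, "H": 12, "O": 6},
    "sucr": {"C": 12, "H": 22, "O": 11},
    "arab": {"C": 5, "H": 10, "O": 5},
    # cofactors
    "coa": {"C": 21, "H": 36, "N": 7, "O": 16, "P": 3, "S": 1},
    "accoa": {"C": 23, "H": 38, "N": 7, "O": 17, "P": 3, "S": 1},
    "succoa": {"C": 25, "H": 40, "N": 7, "O": 19, "P": 3, "S": 1},
    "nad": {"C": 21, "H": 26, "N": 7, "O": 14, "P": 2},
    "nadh": {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2},
    "fad": {"C": 27, "H": 33, "N": 9, "O": 15, "P": 2},
    "fadh2": {"C": 27, "H": 35, "N": 9, "O": 15, "P": 2},
    "atp": {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3},
    "adp": {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2},
    # one-electron carrier (iron-sulfur cluster stand-in; reduced form +1 H)
    "fdxo": {"S": 4},
    "fdxr": {"H": 1, "S": 4},
    # nitrogen compounds
    "glu": {"C": 5, "H": 9, "N": 1, "O": 4},
    "gln": {"C": 5, "H": 10, "N": 2, "O": 3},
    "ala": {"C": 3, "H": 7, "N": 1, "O": 2},
    "asp": {"C": 4, "H": 7, "N": 1, "O": 4},
    "gaba": {"C": 4, "H": 9, "N": 1, "O": 2},
    # storage polymers (per monomer unit; glyclip is a lumped phosphatidate)
    "phb": {"C": 4, "H": 6, "O": 2},
    "glyg": {"C": 6, "H": 10, "O": 5},
    "pmt": {"C": 16, "H": 32, "O": 2},
    "glyclip": {"C": 35, "H": 69, "O": 8, "P": 1},
}

CARBON_SOURCES = ("malate", "succinate", "sucrose", "glucose", "arabinose", "gaba")
POLYMERS = ("phb", "glycogen", "palmitate", "glycerolipid")

#: uptake exchange per carbon source and carbon atoms per uptake unit
SOURCE_EXCHANGE = {
    "malate": ("EX_mal", 4),
    "succinate": ("EX_succ", 4),
    "sucrose": ("EX_sucr", 12),
    "glucose": ("EX_glc", 6),
    "arabinose": ("EX_arab", 5),
    "gaba": ("EX_gaba", 4),
}

POLYMER_SINK = {
    "phb": ("SK_phb", "phb"),
    "glycogen": ("SK_glyg", "glyg"),
    "palmitate": ("SK_pmt", "pmt"),
    "glycerolipid": ("SK_glyclip", "glyclip"),
}

AMINO_ACID_DEMANDS = {"glu": "DM_glu", "gln": "DM_gln", "ala": "DM_ala", "asp": "DM_asp"}


@dataclass
class CoreModelConfig:
    """Knobs of the synthetic bacteroid network.

    p_o_nadh / p_o_fadh2: ATP formed per 2-electron transfer to oxygen for
    each donor (mol ATP per 1/2 mol O2).  nitrogenase_atp_per_n2: ATP
    hydrolyzed per N2 fixed (8 electrons via reduced ferredoxin are fixed
    alongside).  ``seed`` drives the randomized gene-association scheme.
    """

    carbon_sources: frozenset = frozenset(CARBON_SOURCES)
    include_polymers: frozenset = frozenset(POLYMERS)
    p_o_nadh: Fraction = F(3, 2)
    p_o_fadh2: Fraction = F(1)
    nitrogenase_atp_per_n2: int = 16
    seed: int = 0

    def __post_init__(self):
        self.carbon_sources = frozenset(self.carbon_sources)
        self.include_polymers = frozenset(self.include_polymers)
        unknown = self.carbon_sources - set(CARBON_SOURCES)
        if unknown:
            raise ValueError(f"unknown carbon sources: {sorted(unknown)}")
        unknown = self.include_polymers - set(POLYMERS)
        if unknown:
            raise ValueError(f"unknown polymers: {sorted(unknown)}")
        if not self.carbon_sources:
            raise ValueError("at least one carbon source is required")
        if self.p_o_nadh <= 0 or self.p_o_fadh2 <= 0:
            raise ValueError("P/O ratios must be positive")
        if "glycerolipid" in self.include_polymers and "palmitate" not in self.include_polymers:
            raise ValueError("glycerolipid synthesis requires palmitate")


def _balance_h_o(stoich: dict[str, Fraction]) -> dict[str, Fraction]:
    """Fill in water and protons so the reaction balances H and O exactly.

    C, N, P and S must already balance; anything else is a construction bug
    and raises.
    """
    net = {e: F(0) for e in ("C", "H", "N", "O", "P", "S")}
    for met, coef in stoich.items():
        for e, n in FORMULAS[met].items():
            net[e] += coef * n
    for e in ("C", "N", "P", "S"):
        if net[e] != 0:
            raise ValueError(f"unbalanced {e} ({net[e]}) in stoichiometry {stoich}")
    out = dict(stoich)
    if net["O"] != 0:
        out["h2o"] = out.get("h2o", F(0)) - net["O"]
        net["H"] -= 2 * net["O"]
        net["O"] = F(0)
    if net["H"] != 0:
        out["h"] = out.get("h", F(0)) - net["H"]
    return {m: c for m, c in out.items() if c != 0}


def build_core_bacteroid_model(config: Optional[CoreModelConfig] = None) -> MetabolicModel:
    """Generate the synthetic core-bacteroid model.

    All uptake exchanges are open by default (scenario constraints select
    the biological condition); see :func:`bacteroid_scenario`.
    """
    cfg = config or CoreModelConfig()

    internal: dict[str, Fraction] = {}
    reactions: list[Reaction] = []

    sugar_on = bool(cfg.carbon_sources & {"sucrose", "glucose", "arabinose"})
    sucrose_on = "sucrose" in cfg.carbon_sources
    arab_on = "arabinose" in cfg.carbon_sources
    gaba_on = "gaba" in cfg.carbon_sources
    p = cfg.p_o_nadh
    q = cfg.p_o_fadh2
    natp = F(cfg.nitrogenase_atp_per_n2)

    def rxn(rid, name, stoich, rev=False, kind="metabolic", balance=True):
        st = {m: F(c) for m, c in stoich.items()}
        if balance and kind == "metabolic":
            st = _balance_h_o(st)
        reactions.append(
            Reaction(rid, st, name=name,
                     lower_bound=-1000.0 if rev else 0.0, upper_bound=1000.0, kind=kind)
        )

    # --- TCA cycle and anaplerosis -------------------------------------
    rxn("CS", "citrate synthase", {"accoa": -1, "oaa": -1, "cit": 1, "coa": 1})
    rxn("ACONT", "aconitase", {"cit": -1, "icit": 1}, rev=True)
    rxn("ICDH", "isocitrate dehydrogenase",
        {"icit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1})
    rxn("AKGDH", "2-oxoglutarate dehydrogenase",
        {"akg": -1, "coa": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1})
    rxn("SUCOAS", "succinyl-CoA synthetase",
        {"succoa": -1, "adp": -1, "pi": -1, "succ": 1, "coa": 1, "atp": 1})
    rxn("SDH", "succinate dehydrogenase", {"succ": -1, "fad": -1, "fum": 1, "fadh2": 1})
    rxn("FUM", "fumarase", {"fum": -1, "mal": 1}, rev=True)
    rxn("MDH", "malate dehydrogenase", {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, rev=True)
    rxn("ME", "malic enzyme", {"mal": -1, "nad": -1, "pyr": 1, "co2": 1, "nadh": 1})
    rxn("PDH", "pyruvate dehydrogenase",
        {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1})

    # --- anaplerosis, gluconeogenesis and pentose phosphate branch ------
    rxn("PC", "pyruvate carboxylase",
        {"pyr": -1, "co2": -1, "atp": -1, "oaa": 1, "adp": 1, "pi": 1})
    rxn("PEPCK", "PEP carboxykinase", {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1})
    rxn("GNG", "gluconeogenesis (PEP to G6P, lumped)",
        {"pep": -2, "atp": -2, "nadh": -2, "g6p": 1, "adp": 2, "nad": 2, "pi": 3})
    rxn("PPPOX", "oxidative pentose phosphate branch (lumped)",
        {"g6p": -1, "nad": -2, "ru5p": 1, "co2": 1, "nadh": 2})
    rxn("PPPNOX", "non-oxidative pentose phosphate branch (lumped)",
        {"ru5p": -6, "g6p": 5, "pi": 1})

    # --- sugar catabolism (alternative carbon routes) -------------------
    if sugar_on:
        rxn("EMP", "glycolysis (G6P to pyruvate, lumped)",
            {"g6p": -1, "adp": -3, "pi": -2, "nad": -2, "pyr": 2, "atp": 3, "nadh": 2})
    if sucrose_on:
        rxn("INV", "invertase", {"sucr": -1, "glc": 1, "fru": 1})
        rxn("FRK", "fructokinase", {"fru": -1, "atp": -1, "f6p": 1, "adp": 1})
        rxn("PGI", "phosphoglucose isomerase", {"f6p": -1, "g6p": 1}, rev=True)
    if sucrose_on or "glucose" in cfg.carbon_sources:
        rxn("HEX", "glucokinase", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1})
    if arab_on:
        rxn("ARAD", "arabinose catabolism to 2-oxoglutarate (lumped)",
            {"arab": -1, "nad": -2, "akg": 1, "nadh": 2})

    # --- GABA shunt -----------------------------------------------------
    if gaba_on:
        rxn("GABAT", "GABA transaminase", {"gaba": -1, "akg": -1, "ssa": 1, "glu": 1})
        rxn("SSADH", "succinate-semialdehyde dehydrogenase",
            {"ssa": -1, "nad": -1, "succ": 1, "nadh": 1})

    # --- respiration and nitrogen fixation ------------------------------
    rxn("NADHDH", "NADH dehydrogenase + oxidase (ETC, lumped)",
        {"nadh": -1, "o2": F(-1, 2), "adp": -p, "pi": -p, "nad": 1, "atp": p})
    rxn("FADH2DH", "FADH2 oxidase (ETC, lumped)",
        {"fadh2": -1, "o2": F(-1, 2), "adp": -q, "pi": -q, "fad": 1, "atp": q})
    rxn("FNR", "ferredoxin-NAD reductase", {"nadh": -1, "fdxo": -2, "nad": 1, "fdxr": 2})
    rxn("NIF", "nitrogenase",
        {"n2": -1, "fdxr": -8, "atp": -natp,
         "nh3": 2, "h2": 1, "fdxo": 8, "adp": natp, "pi": natp})
    rxn("ATPM", "ATP maintenance", {"atp": -1, "adp": 1, "pi": 1})

    # --- ammonia assimilation and amino acids ---------------------------
    rxn("GS", "glutamine synthetase",
        {"glu": -1, "nh3": -1, "atp": -1, "gln": 1, "adp": 1, "pi": 1})
    rxn("GOGAT", "glutamate synthase (NADH)",
        {"gln": -1, "akg": -1, "nadh": -1, "glu": 2, "nad": 1})
    rxn("ALADH", "alanine dehydrogenase",
        {"pyr": -1, "nh3": -1, "nadh": -1, "ala": 1, "nad": 1})
    rxn("ASPT", "aspartate transaminase", {"oaa": -1, "glu": -1, "asp": 1, "akg": 1}, rev=True)

    # --- storage polymers -----------------------------------------------
    if "phb" in cfg.include_polymers:
        rxn("PHBS", "PHB synthesis (lumped)",
            {"accoa": -2, "nadh": -1, "phb": 1, "coa": 2, "nad": 1})
    if "glycogen" in cfg.include_polymers:
        rxn("GLYGS", "glycogen synthesis (lumped)",
            {"g6p": -1, "atp": -1, "glyg": 1, "adp": 1, "pi": 2})
    if "palmitate" in cfg.include_polymers:
        rxn("FAS", "palmitate synthesis (lumped)",
            {"accoa": -8, "nadh": -14, "atp": -7,
             "pmt": 1, "coa": 8, "nad": 14, "adp": 7, "pi": 7})
    if "glycerolipid" in cfg.include_polymers:
        rxn("GLIPS", "glycerolipid (phosphatidate) synthesis (lumped)",
            {"pmt": -2, "g6p": F(-1, 2), "nadh": -1, "atp": -2,
             "glyclip": 1, "nad": 1, "adp": 2, "pi": F(3, 2)})

    # --- boundary species: transports + exchanges/demands/sinks ---------
    uptakes = ["n2", "o2", "pi"]
    if "malate" in cfg.carbon_sources:
        uptakes.append("mal")
    if "succinate" in cfg.carbon_sources:
        uptakes.append("succ")
    if sucrose_on:
        uptakes.append("sucr")
    if "glucose" in cfg.carbon_sources:
        uptakes.append("glc")
    if arab_on:
        uptakes.append("arab")
    if gaba_on:
        uptakes.append("gaba")
    # protons stay internal: with neutral-species formulas the redox balance
    # pins net proton exchange to zero, so a proton boundary would be dead
    exports = ["nh3", "co2", "h2"]
    frees = ["h2o"]

    boundary_species: list[str] = []

    def boundary(species, direction, prefix="EX"):
        """transport internal<->external plus a boundary reaction on the _e species."""
        ext = f"{species}_e"
        boundary_species.append((species, ext))
        if direction == "in":
            rxn(f"T_{species}", f"{species} transport",
                {ext: -1, species: 1}, kind="transport", balance=False)
            lb, ub = -1000.0, 0.0
        elif direction == "out":
            rxn(f"T_{species}", f"{species} transport",
                {species: -1, ext: 1}, kind="transport", balance=False)
            lb, ub = 0.0, 1000.0
        else:  # free
            rxn(f"T_{species}", f"{species} transport",
                {ext: -1, species: 1}, rev=True, kind="transport", balance=False)
            lb, ub = -1000.0, 1000.0
        kind = {"EX": "exchange", "DM": "demand", "SK": "sink"}[prefix]
        reactions.append(Reaction(f"{prefix}_{species}", {ext: F(-1)},
                                  name=f"{species} {kind}", lower_bound=lb, upper_bound=ub,
                                  kind=kind))

    for sp in uptakes:
        boundary(sp, "in")
    for sp in exports:
        boundary(sp, "out")
    for sp in frees:
        boundary(sp, "free")
    for aa, dm in AMINO_ACID_DEMANDS.items():
        ext = f"{aa}_e"
        boundary_species.append((aa, ext))
        rxn(f"T_{aa}", f"{aa} transport", {aa: -1, ext: 1}, kind="transport", balance=False)
        reactions.append(Reaction(dm, {ext: F(-1)}, name=f"{aa} demand",
                                  lower_bound=0.0, upper_bound=1000.0, kind="demand"))
    for polymer in cfg.include_polymers:
        sink_id, sp = POLYMER_SINK[polymer]
        ext = f"{sp}_e"
        boundary_species.append((sp, ext))
        rxn(f"T_{sp}", f"{sp} storage deposition", {sp: -1, ext: 1},
            kind="transport", balance=False)
        reactions.append(Reaction(sink_id, {ext: F(-1)}, name=f"{polymer} sink",
                                  lower_bound=0.0, upper_bound=1000.0, kind="sink"))

    # --- metabolite objects --------------------------------------------
    used: set[str] = set()
    for r in reactions:
        used |= set(r.stoichiometry)
    externals = {ext for _, ext in boundary_species}
    mets = []
    for mid in sorted(used):
        if mid in externals:
            base = mid[:-2]
            mets.append(Metabolite(mid, name=base, compartment="external",
                                   formula=dict(FORMULAS[base])))
        else:
            mets.append(Metabolite(mid, name=mid, compartment="internal",
                                   formula=dict(FORMULAS[mid])))

    # --- gene associations ----------------------------------------------
    rng = np.random.default_rng(cfg.seed)
    genes: list[str] = []

    def new_genes(rid, n):
        out = [f"{rid.lower()}_g{i + 1}" for i in range(n)]
        genes.extend(out)
        return out

    for r in reactions:
        if r.is_boundary:
            continue
        if r.id == "NIF":
            g = ["nifH", "nifD", "nifK"]
            genes.extend(g)
            r.gpr = Gpr.parse(" and ".join(g))
        elif r.id == "ATPM":
            continue  # non-enzymatic maintenance pseudo-reaction
        elif r.kind == "transport":
            r.gpr = Gpr.gene(new_genes(r.id, 1)[0])
        else:
            u = rng.random()
            if u < 0.4:
                r.gpr = Gpr.gene(new_genes(r.id, 1)[0])
            elif u < 0.7:
                g = new_genes(r.id, 2)
                r.gpr = Gpr.parse(f"{g[0]} and {g[1]}")
            else:
                g = new_genes(r.id, 2)
                r.gpr = Gpr.parse(f"{g[0]} or {g[1]}")

    return MetabolicModel(
        id="core_bacteroid", metabolites=mets, reactions=reactions, genes=genes,
        nitrogenase_id="NIF",
    )


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def bacteroid_scenario(
    model: MetabolicModel,
    o2_max: float,
    carbon_source: str = "malate",
    carbon_uptake: float = 4.0,
    fix_carbon: bool = False,
    glutamate_demand: Optional[float] = None,
    aa_demand: tuple[float, float] = (0.01, 0.05),
    name: Optional[str] = None,
) -> ScenarioConstraints:
    """Bound set for a nitrogen-fixing bacteroid on a single carbon source.

    The oxygen ceiling ``o2_max`` is a required parameter (no literature
    default is hard-coded).  Amino-acid demand fluxes are constrained to
    ``aa_demand`` (default 0.01–0.05 flux units) to mimic low-level protein
    synthesis, except that the alanine and aspartate demands keep an open
    upper bound because those amino acids are secreted.  All carbon uptakes
    other than ``carbon_source`` are closed; ``fix_carbon=True`` pins the
    carbon uptake at exactly ``carbon_uptake`` flux units.
    ``glutamate_demand`` forces a minimum flux through the glutamate demand
    (the ammonia-assimilation scenario).
    """
    if carbon_source not in SOURCE_EXCHANGE:
        raise ValueError(f"unknown carbon source {carbon_source!r}")
    bounds: dict[str, tuple[float, float]] = {}
    for source, (ex, _) in SOURCE_EXCHANGE.items():
        if model.exchange_for(f"{ex.split('_')[1]}_e") is None:
            continue
        if source == carbon_source:
            lo = -abs(carbon_uptake)
            bounds[ex] = (lo, lo if fix_carbon else 0.0)
        else:
            bounds[ex] = (0.0, 0.0)
    bounds["EX_o2"] = (-abs(o2_max), 0.0)
    bounds["EX_n2"] = (-1000.0, 0.0)
    bounds["EX_pi"] = (-1000.0, 0.0)
    lo, hi = aa_demand
    bounds["DM_glu"] = (lo, hi)
    bounds["DM_gln"] = (lo, hi)
    bounds["DM_ala"] = (lo, 1000.0)
    bounds["DM_asp"] = (lo, 1000.0)
    if glutamate_demand is not None:
        bounds["DM_glu"] = (glutamate_demand, 1000.0)
    return ScenarioConstraints(
        name=name or f"bacteroid_{carbon_source}",
        bounds=bounds,
        objective={model.nitrogenase_id: 1.0} if model.nitrogenase_id else {},
        notes=f"{carbon_source} uptake <= {carbon_uptake}, O2 uptake <= {o2_max}",
    )


# ---------------------------------------------------------------------------
# Ground-truth essentiality and mock experimental calls
# ---------------------------------------------------------------------------


def ground_truth_essentiality(
    model: MetabolicModel,
    scenario: Optional[ScenarioConstraints] = None,
    threshold: float = fba.ESSENTIALITY_THRESHOLD,
) -> dict[str, str]:
    """Exhaustive single-gene deletion phenotype of the model.

    A direct loop over genes maximizing nitrogenase flux after disabling
    every reaction whose gene association fails; used as the in-silico
    ground truth that mock experimental calls are derived from.
    """
    from .scenario import apply_scenario

    base = apply_scenario(model, scenario)
    truth: dict[str, str] = {}
    for gene in base.genes:
        m2 = base.copy()
        for r in m2.reactions:
            if gene in r.gpr.genes() and not r.gpr.evaluate({gene}):
                r.lower_bound = 0.0
                r.upper_bound = 0.0
        sol = fba.solve_fba(m2, objective=base.nitrogenase_id)
        essential = (not sol.ok) or sol.objective_value < threshold
        truth[gene] = "essential" if essential else "nonessential"
    return truth


def make_mock_experimental_calls(
    truth: Mapping[str, str], agreement_fraction: float, seed: int
) -> dict[str, str]:
    """Mock experimental essentiality calls at a chosen agreement level.

    Flips exactly ``round((1 - agreement_fraction) * n_genes)`` randomly
    chosen calls; seeded and reproducible.
    """
    if not 0.0 <= agreement_fraction <= 1.0:
        raise ValueError("agreement_fraction must be in [0, 1]")
    genes = sorted(truth)
    n_flip = round((1.0 - agreement_fraction) * len(genes))
    rng = np.random.default_rng(seed)
    flip = set(rng.choice(len(genes), size=n_flip, replace=False)) if n_flip else set()
    out = {}
    for i, g in enumerate(genes):
        call = truth[g]
        if i in flip:
            call = "nonessential" if call == "essential" else "essential"
        out[g] = call
    return out
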