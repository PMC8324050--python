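"""Elementary conversion modes: enumeration against a brute-force oracle,
trackers, normalization, conservation and reachability.

The oracle enumerates candidate rays combinatorially: for every support
subset of the split-reaction columns it computes the exact nullspace and
keeps one-dimensional, sign-consistent kernels — the textbook definition of
an elementary flux mode — then projects and prunes to extreme rays of the
conversion cone by LP membership.  It shares no code with the
double-description implementation.
"""

import itertools
from fractions import Fraction as F

import numpy as np
import pytest
import sympy
from scipy.optimize import linprog

from rhizofba.ecm import (
    Conversion,
    EcmConfig,
    EcmError,
    add_flux_tracker,
    enumerate_ecms,
    normalize_conversion,
    reachability_certificate,
)
from rhizofba.metrics import element_flux
from rhizofba.model import MetabolicModel, Metabolite, ModelStructureError, Reaction


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _split_system(model, config):
    """Columns of the split flux cone: irreversible reactions plus direction-
    restricted uptake/export columns per listed external metabolite."""
    mets = [m.id for m in model.metabolites]
    row_of = {m: i for i, m in enumerate(mets)}
    cols = []
    labels = []  # ("rxn", id) | ("uptake", met) | ("export", met)
    for r in model.reactions:
        if r.is_boundary:
            continue
        base = np.zeros(len(mets), dtype=object)
        for mid, c in r.stoichiometry.items():
            base[row_of[mid]] = c
        if r.upper_bound > 0:
            cols.append(base.copy())
            labels.append(("rxn", r.id))
        if r.lower_bound < 0:
            cols.append(-base)
            labels.append(("rxn", r.id + "__rev"))
    for met in sorted(config.listed):
        vec = np.zeros(len(mets), dtype=object)
        vec[row_of[met]] = F(1)
        if met in config.inputs or met in config.free or met in config.hidden:
            cols.append(vec.copy())
            labels.append(("uptake", met))
        if met in config.outputs or met in config.free or met in config.hidden:
            cols.append(-vec)
            labels.append(("export", met))
    A = sympy.Matrix([[sympy.Rational(str(c[i])) for c in cols] for i in range(len(mets))])
    return labels, A


def brute_force_conversions(model, config):
    labels, A = _split_system(model, config)
    ncols = A.shape[1]
    rays = []
    for size in range(1, ncols + 1):
        for support in itertools.combinations(range(ncols), size):
            sub = A[:, list(support)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            vec = null[0]
            signs = {sympy.sign(x) for x in vec}
            if 0 in signs:
                continue  # support not minimal: some chosen column unused
            if signs == {1}:
                ray = vec
            elif signs == {-1}:
                ray = -vec
            else:
                continue
            full = [sympy.Integer(0)] * ncols
            for k, j in enumerate(support):
                full[j] = ray[k]
            rays.append(full)
    # read the conversion off the uptake/export columns
    from math import gcd

    coord_ids = sorted(config.inputs | config.outputs | config.free)
    uptake_col = {met: j for j, (kind, met) in enumerate(labels) if kind == "uptake"}
    export_col = {met: j for j, (kind, met) in enumerate(labels) if kind == "export"}
    projections = set()
    for ray in rays:
        conv = []
        for met in coord_ids:
            total = sympy.Integer(0)
            if met in export_col:
                total += ray[export_col[met]]
            if met in uptake_col:
                total -= ray[uptake_col[met]]
            conv.append(F(int(sympy.numer(total)), int(sympy.denom(total))))
        if all(c == 0 for c in conv):
            continue
        lcm = 1
        for c in conv:
            lcm = lcm * c.denominator // gcd(lcm, c.denominator)
        ints = [int(c * lcm) for c in conv]
        g = 0
        for v in ints:
            g = gcd(g, abs(v))
        projections.add(tuple(F(v, g) for v in ints))
    projections = sorted(projections)
    # extreme-ray pruning by LP conic membership
    arr = np.array([[float(c) for c in p] for p in projections])
    keep = []
    for i in range(len(projections)):
        others = [k for k in range(len(projections)) if k != i]
        if not others:
            keep.append(i)
            continue
        G = arr[others].T
        res = linprog(np.zeros(len(others)), A_eq=G, b_eq=arr[i],
                      bounds=[(0, None)] * len(others), method="highs")
        member = res.status == 0 and np.abs(G @ res.x - arr[i]).max() < 1e-8
        if not member:
            keep.append(i)
    return {
        frozenset((coord_ids[k], c) for k, c in enumerate(projections[i]) if c != 0)
        for i in keep
    }


def as_key_set(conversions):
    out = set()
    for conv in conversions:
        coeffs = dict(conv.coefficients)
        coeffs.update(conv.tracked)
        out.add(frozenset(coeffs.items()))
    return out


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


class TestEnumeration:
    def test_unique_path_single_ecm(self, chain_model):
        cfg = EcmConfig(inputs={"A_e"}, outputs={"B_e"})
        ecms = enumerate_ecms(chain_model, cfg)
        assert len(ecms) == 1
        assert ecms[0].coefficients == {"A_e": F(-1), "B_e": F(1)}

    @pytest.mark.parametrize("fixture", ["chain_model", "two_path_model", "cycle_model"])
    def test_matches_brute_force_oracle(self, fixture, request):
        model = request.getfixturevalue(fixture)
        external = {m.id for m in model.external_metabolites()}
        inputs = {m for m in external if m in ("A_e", "O_e")}
        outputs = external - inputs
        cfg = EcmConfig(inputs=inputs, outputs=outputs)
        ours = as_key_set(enumerate_ecms(model, cfg))
        oracle = brute_force_conversions(model, cfg)
        assert ours == oracle

    def test_two_path_conversions(self, two_path_model):
        cfg = EcmConfig(inputs={"A_e", "O_e"}, outputs={"C_e"})
        ecms = as_key_set(enumerate_ecms(two_path_model, cfg))
        assert frozenset({("A_e", F(-1)), ("C_e", F(1))}) in ecms
        assert frozenset({("A_e", F(-1)), ("O_e", F(-1)), ("C_e", F(2))}) in ecms
        assert len(ecms) == 2

    def test_hidden_equals_free_boundary_with_column_dropped(self, two_path_model):
        hidden_cfg = EcmConfig(inputs={"A_e"}, outputs={"C_e"}, hidden={"O_e"})
        free_cfg = EcmConfig(inputs={"A_e"}, outputs={"C_e"}, free={"O_e"})
        hidden = as_key_set(enumerate_ecms(two_path_model, hidden_cfg))
        freed = set()
        for conv in enumerate_ecms(two_path_model, free_cfg):
            coeffs = {m: c for m, c in conv.coefficients.items() if m != "O_e"}
            if coeffs:
                freed.add(frozenset(Conversion(coeffs).coefficients.items()))
        assert hidden == freed
        assert all("O_e" not in dict(k) for k in hidden)

    def test_empty_cone_returns_empty_list(self, chain_model):
        cfg = EcmConfig(inputs=set(), outputs={"B_e"})  # nothing may enter
        assert enumerate_ecms(chain_model, cfg) == []

    def test_no_returned_ray_is_a_conic_combination_of_others(self, bacteroid_ecms):
        """Elementarity: every returned conversion is an extreme ray — it
        cannot be written as a nonnegative combination of the others."""
        cols = sorted({m for c in bacteroid_ecms for m in c.coefficients})
        arr = np.array([[float(c.coefficients.get(m, 0)) for m in cols]
                        for c in bacteroid_ecms])
        arr = arr / np.linalg.norm(arr, axis=1, keepdims=True)
        for i in range(len(arr)):
            others = [k for k in range(len(arr)) if k != i]
            G = arr[others].T
            res = linprog(np.zeros(len(others)), A_eq=G, b_eq=arr[i],
                          bounds=[(0, None)] * len(others), method="highs")
            member = res.status == 0 and np.abs(G @ res.x - arr[i]).max() < 1e-8
            assert not member, f"conversion {i} is decomposable"


class TestTrackers:
    def test_tracker_reports_reaction_flux(self, chain_model):
        tracked = add_flux_tracker(chain_model, "R1", "trk")
        cfg = EcmConfig(inputs={"A_e"}, outputs={"B_e", "trk"})
        (conv,) = enumerate_ecms(tracked, cfg)
        assert conv.tracked == {"trk": F(1)}  # R1 carries the whole unit flux

    def test_tracked_set_projects_to_untracked_set(self, bacteroid_model, bacteroid_ecms,
                                                   tracked_ecms):
        untracked = as_key_set(bacteroid_ecms)
        projected = set()
        for conv in tracked_ecms:
            projected.add(frozenset(conv.coefficients.items()))
        assert projected == untracked

    def test_id_collision_rejected(self, chain_model):
        with pytest.raises(ModelStructureError):
            add_flux_tracker(chain_model, "R1", "A_e")


class TestNormalization:
    def test_unit_carbon_input_arithmetic(self):
        mets = [Metabolite("malx_e", compartment="external", formula={"C": 4, "H": 6, "O": 5}),
                Metabolite("co2_e", compartment="external", formula={"C": 1, "O": 2})]
        model = MetabolicModel("t", mets, [Reaction("EX", {"malx_e": F(-1)}, kind="exchange")],
                               genes=[])
        conv = Conversion({"malx_e": F(-2), "co2_e": F(8)})
        out = normalize_conversion(conv, "unit_carbon_input", model)
        assert out.coefficients == {"malx_e": F(-1, 4), "co2_e": F(1)}

    def test_metrics_scale_invariant(self, bacteroid_model, bacteroid_ecms):
        conv = next(c for c in bacteroid_ecms if element_flux(conv=c, model=bacteroid_model,
                                                              element="C", side="input") > 0)
        scaled = conv.scaled(F(7, 3), "test")
        raw_ratio = element_flux(conv, bacteroid_model, "C", "output") / element_flux(
            conv, bacteroid_model, "C", "input")
        scaled_ratio = element_flux(scaled, bacteroid_model, "C", "output") / element_flux(
            scaled, bacteroid_model, "C", "input")
        assert raw_ratio == scaled_ratio

    def test_all_zero_conversion_rejected(self):
        with pytest.raises(EcmError):
            Conversion({})


class TestConservationAndReachability:
    def test_every_bacteroid_ecm_is_element_balanced(self, bacteroid_model, bacteroid_ecms,
                                                     survey_config):
        """With no carbon/nitrogen species hidden, net C and N of every
        conversion must vanish once CO2, O2, NH3 etc. are counted."""
        for conv in bacteroid_ecms:
            for element in ("C", "N", "P"):
                net = sum(
                    c * bacteroid_model.metabolite(m).atoms(element)
                    for m, c in conv.coefficients.items()
                )
                assert net == 0, (element, conv.coefficients)

    def test_every_bacteroid_ecm_is_reachable(self, bacteroid_model, bacteroid_ecms,
                                              survey_config):
        for conv in bacteroid_ecms:
            assert reachability_certificate(bacteroid_model, survey_config, conv) is not None

    def test_expected_products_all_covered(self, bacteroid_ecms):
        produced = set()
        for conv in bacteroid_ecms:
            produced |= set(conv.outputs())
        expected = {"nh3_e", "ala_e", "asp_e", "phb_e", "glyg_e", "pmt_e", "glyclip_e"}
        assert expected <= produced
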