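"""LP analyses: FBA, taxicab minimization, FVA, duals, phase planes,
gene deletion and the random-objective ensemble.

The brute-force oracle enumerates all vertices of the flux polytope
{S v = 0, lb <= v <= ub} by pinning subsets of variables at their bounds and
solving the remaining equality system; the LP optimum must equal the best
vertex value.
"""

import itertools
import math
from fractions import Fraction as F

import numpy as np
import pytest

from rhizofba import fba
from rhizofba.model import MetabolicModel, Metabolite, Reaction, stoichiometric_matrix
from rhizofba.scenario import ScenarioConstraints


def enumerate_vertices(model):
    """All vertices of {S v = 0, bounds} by exhaustive bound-pinning."""
    mets, rxns, S = stoichiometric_matrix(model, dtype="float")
    # balance every metabolite (including external): matches the LP layer
    rows = []
    for m in model.metabolites:
        row = np.zeros(len(rxns))
        for j, r in enumerate(model.reactions):
            c = r.stoichiometry.get(m.id)
            if c:
                row[j] = float(c)
        rows.append(row)
    A = np.array(rows)
    n = len(rxns)
    rank = np.linalg.matrix_rank(A)
    n_pin = n - rank
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    vertices = []
    for pin in itertools.combinations(range(n), n_pin):
        free = [j for j in range(n) if j not in pin]
        for sides in itertools.product([0, 1], repeat=n_pin):
            fixed = np.array([lb[j] if s == 0 else ub[j] for j, s in zip(pin, sides)])
            rhs = -A[:, list(pin)] @ fixed
            sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            v = np.zeros(n)
            v[list(pin)] = fixed
            v[free] = sol
            if np.abs(A @ v).max() > 1e-8:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            vertices.append(v)
    return rxns, vertices


class TestSolveFba:
    def test_single_path_optimum_equals_uptake_capacity(self, chain_model):
        sol = fba.solve_fba(chain_model, objective="EX_B")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0)

    def test_forced_infeasibility_reported_without_fluxes(self, chain_model):
        sc = ScenarioConstraints("bad", bounds={"EX_B": (20.0, 20.0)})
        sol = fba.solve_fba(chain_model, sc, objective="EX_B")
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_two_path_optimum_matches_vertex_oracle(self, two_path_model):
        """Under the O-uptake cap the LP picks the best mix of the two routes."""
        rxns, vertices = enumerate_vertices(two_path_model)
        j = rxns.index("EX_C")
        best = max(v[j] for v in vertices)
        sol = fba.solve_fba(two_path_model, objective="EX_C")
        assert sol.objective_value == pytest.approx(best, rel=1e-9)
        assert sol.objective_value == pytest.approx(15.0)  # 5 via O route (x2), 5 direct


class TestTaxicabMinimization:
    def test_cycle_flux_removed_objective_preserved(self, cycle_model):
        plain = fba.solve_fba(cycle_model, objective="EX_B")
        l1 = fba.solve_fba_l1(cycle_model, objective="EX_B")
        assert l1.objective_value == pytest.approx(plain.objective_value, rel=1e-9)
        assert abs(l1["CYC1"]) < 1e-9 and abs(l1["CYC2"]) < 1e-9

    def test_unique_optimum_identical_to_plain_fba(self, chain_model):
        plain = fba.solve_fba(chain_model, objective="EX_B")
        l1 = fba.solve_fba_l1(chain_model, objective="EX_B")
        for rid, v in plain.fluxes.items():
            assert l1[rid] == pytest.approx(v, abs=1e-8)

    def test_l1_norm_is_minimal_over_vertices(self, two_path_model):
        rxns, vertices = enumerate_vertices(two_path_model)
        j = rxns.index("EX_C")
        best = max(v[j] for v in vertices)
        optimal_norms = [np.abs(v).sum() for v in vertices if v[j] >= best - 1e-9]
        l1 = fba.solve_fba_l1(two_path_model, objective="EX_C")
        assert l1.l1_norm() <= min(optimal_norms) + 1e-6


class TestFluxVariability:
    def test_blocked_reaction_has_zero_range(self, chain_model):
        m = chain_model.copy()
        m.metabolites.append(Metabolite("Z"))
        m.reactions.append(Reaction("DEAD", {"B": F(-1), "Z": F(1)}))
        m._reindex()
        res = fba.flux_variability(m, objective="EX_B", fraction_of_optimum=1.0)
        assert res["DEAD"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))

    def test_unique_path_pinned_at_full_fraction(self, chain_model):
        res = fba.flux_variability(chain_model, objective="EX_B", fraction_of_optimum=1.0)
        lo, hi = res["R1"]
        assert lo == pytest.approx(10.0, abs=1e-7) and hi == pytest.approx(10.0, abs=1e-7)

    def test_parallel_paths_each_span_full_range(self):
        mets = [Metabolite("A_e", compartment="external"), Metabolite("A"), Metabolite("B"),
                Metabolite("B_e", compartment="external")]
        rxns = [
            Reaction("EX_A", {"A_e": F(-1)}, kind="exchange", lower_bound=-10, upper_bound=0),
            Reaction("T_A", {"A_e": F(-1), "A": F(1)}, kind="transport"),
            Reaction("P1", {"A": F(-1), "B": F(1)}),
            Reaction("P2", {"A": F(-1), "B": F(1)}),
            Reaction("T_B", {"B": F(-1), "B_e": F(1)}, kind="transport"),
            Reaction("EX_B", {"B_e": F(-1)}, kind="exchange"),
        ]
        m = MetabolicModel("parallel", mets, rxns, genes=[])
        res = fba.flux_variability(m, objective="EX_B", fraction_of_optimum=1.0)
        for rid in ("P1", "P2"):
            lo, hi = res[rid]
            assert lo == pytest.approx(0.0, abs=1e-7)
            assert hi == pytest.approx(10.0, abs=1e-7)

    def test_loopless_excludes_cycle_only_flux(self, cycle_model):
        raw = fba.flux_variability(cycle_model, objective="EX_B", fraction_of_optimum=1.0)
        loopless = fba.flux_variability(cycle_model, objective="EX_B",
                                        fraction_of_optimum=1.0, loopless=True)
        # the raw maximum of a cycle member is bound-limited, not physiological
        assert raw["CYC1"][1] > 100
        assert loopless["CYC1"][1] == pytest.approx(0.0, abs=1e-7)

    def test_intervals_contain_l1_solution(self, two_path_model):
        l1 = fba.solve_fba_l1(two_path_model, objective="EX_C")
        res = fba.flux_variability(two_path_model, objective="EX_C", fraction_of_optimum=1.0)
        for rid, (lo, hi) in res.ranges.items():
            assert lo - 1e-6 <= l1[rid] <= hi + 1e-6


class TestShadowPrices:
    def test_binding_substrate_price_matches_finite_difference(self, chain_model):
        prices, degenerate = fba.shadow_prices(chain_model, objective="EX_B", check=True)
        assert "A_e" not in degenerate
        fd = fba._finite_difference_price(chain_model, {"EX_B": 1.0}, "EX_A", 1e-4)
        assert prices["A_e"] == pytest.approx(fd, abs=1e-6)
        assert prices["A_e"] == pytest.approx(1.0)

    def test_non_binding_bound_has_zero_price(self, two_path_model):
        m = two_path_model.copy()
        m.reaction("EX_O").lower_bound = -1000.0  # oxygen no longer limiting
        prices, _ = fba.shadow_prices(m, objective="EX_C")
        assert prices["O_e"] == pytest.approx(0.0, abs=1e-9)

    def test_duality_homogeneity(self, chain_model):
        p1, _ = fba.shadow_prices(chain_model, objective={"EX_B": 1.0})
        p2, _ = fba.shadow_prices(chain_model, objective={"EX_B": 2.0})
        for met in p1:
            assert p2[met] == pytest.approx(2 * p1[met], abs=1e-9)


def make_two_substrate_model():
    """Product requires one unit of each substrate: the objective switches its
    limiting resource where the two uptake capacities cross."""
    mets = [Metabolite("S1_e", compartment="external"), Metabolite("S2_e", compartment="external"),
            Metabolite("S1"), Metabolite("S2"), Metabolite("P"),
            Metabolite("P_e", compartment="external")]
    rxns = [
        Reaction("EX_S1", {"S1_e": F(-1)}, kind="exchange", lower_bound=-1, upper_bound=0),
        Reaction("EX_S2", {"S2_e": F(-1)}, kind="exchange", lower_bound=-1, upper_bound=0),
        Reaction("T_S1", {"S1_e": F(-1), "S1": F(1)}, kind="transport"),
        Reaction("T_S2", {"S2_e": F(-1), "S2": F(1)}, kind="transport"),
        Reaction("R", {"S1": F(-1), "S2": F(-1), "P": F(1)}),
        Reaction("T_P", {"P": F(-1), "P_e": F(1)}, kind="transport"),
        Reaction("EX_P", {"P_e": F(-1)}, kind="exchange"),
    ]
    return MetabolicModel("two_substrate", mets, rxns, genes=[])


class TestPhasePlane:
    def test_single_limiting_substrate_gives_one_phase(self, two_path_model):
        # the second axis is opened so wide it never limits: one signature
        pp = fba.phase_plane(two_path_model, "EX_A", "EX_O",
                             [1, 2, 3], [500, 600, 700], objective="EX_C")
        assert pp.n_phases == 1

    def test_two_substrate_switchover_gives_two_phases(self):
        m = make_two_substrate_model()
        # offset grids so no cell sits exactly on the degenerate diagonal
        pp = fba.phase_plane(m, "EX_S1", "EX_S2",
                             [0.5, 1.0, 1.5, 2.0], [0.75, 1.25, 1.75, 2.25],
                             objective="EX_P")
        assert pp.n_phases == 2
        # below the diagonal S1 limits (price 1 on S1, 0 on S2); above it flips
        i, j = 0, 3  # S1 = 0.5, S2 = 2.25
        assert pp.price_a[i, j] == pytest.approx(1.0)
        assert pp.price_b[i, j] == pytest.approx(0.0, abs=1e-9)
        i, j = 3, 0  # S1 = 2.0, S2 = 0.75
        assert pp.price_a[i, j] == pytest.approx(0.0, abs=1e-9)
        assert pp.price_b[i, j] == pytest.approx(1.0)
        assert pp.objective[1, 1] == pytest.approx(1.0)  # min(1.0, 1.25)

    def test_infeasible_cells_labeled_distinctly(self):
        m = make_two_substrate_model()
        m.reaction("EX_P").lower_bound = 3.0  # demand no grid cell can satisfy
        pp = fba.phase_plane(m, "EX_S1", "EX_S2", [0.5, 1.0], [0.5, 1.0],
                             objective="EX_P")
        assert np.all(pp.labels == -1)
        assert pp.n_phases == 0


class TestGeneDeletion:
    def test_sole_catalyst_essential_isozymes_not(self):
        from rhizofba.model import Gpr

        mets = [Metabolite("A_e", compartment="external"), Metabolite("A"),
                Metabolite("B"), Metabolite("B_e", compartment="external")]
        rxns = [
            Reaction("EX_A", {"A_e": F(-1)}, kind="exchange", lower_bound=-10, upper_bound=0),
            Reaction("T_A", {"A_e": F(-1), "A": F(1)}, kind="transport",
                     gpr=Gpr.parse("tA")),
            Reaction("NIF", {"A": F(-1), "B": F(1)}, gpr=Gpr.parse("n1 and n2")),
            Reaction("T_B", {"B": F(-1), "B_e": F(1)}, kind="transport",
                     gpr=Gpr.parse("tB1 or tB2")),
            Reaction("EX_B", {"B_e": F(-1)}, kind="exchange"),
        ]
        m = MetabolicModel("t", mets, rxns, genes=["tA", "n1", "n2", "tB1", "tB2"],
                           nitrogenase_id="NIF")
        calls = fba.single_gene_deletion(m)
        assert calls["n1"][0] == "essential" and calls["n2"][0] == "essential"
        assert calls["tA"][0] == "essential"
        assert calls["tB1"][0] == "nonessential" and calls["tB2"][0] == "nonessential"


class TestEnsemble:
    def test_same_seed_is_bitwise_reproducible(self, two_path_model):
        spec = fba.EnsembleSpec(n_objectives=25, seed=11, min_nitrogenase=0.0)
        out = []
        for _ in range(2):
            res = fba.random_objective_ensemble(two_path_model, spec, "EX_O", [5.0, 1.0])
            out.append([(rid, mu, sd) for stats in res.stats
                        for rid, (mu, sd) in sorted(stats.items())])
        assert out[0] == out[1]

    def test_blocked_reaction_mean_and_sd_zero(self, chain_model):
        m = chain_model.copy()
        m.metabolites.append(Metabolite("Z"))
        m.reactions.append(Reaction("DEAD", {"B": F(-1), "Z": F(1)}))
        m._reindex()
        spec = fba.EnsembleSpec(n_objectives=30, seed=3, min_nitrogenase=0.0)
        res = fba.random_objective_ensemble(m, spec, "EX_A", [10.0, 2.0], track=["DEAD"])
        for stats in res.stats:
            mu, sd = stats["DEAD"]
            assert mu == pytest.approx(0.0, abs=1e-9)
            assert sd == pytest.approx(0.0, abs=1e-9)

    def test_doubling_draws_moves_means_within_three_se(self, two_path_model):
        def run(n):
            spec = fba.EnsembleSpec(n_objectives=n, seed=5, min_nitrogenase=0.0)
            return fba.random_objective_ensemble(two_path_model, spec, "EX_O", [5.0],
                                                 track=["EX_C"])
        small = run(120)
        big = run(240)
        mu1, sd1 = small.stats[0]["EX_C"]
        mu2, _ = big.stats[0]["EX_C"]
        se = sd1 / math.sqrt(120)
        assert abs(mu2 - mu1) < 3 * se + 1e-9
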