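"""Shared fixtures: toy networks, the synthetic bacteroid model and its
enumerated conversion sets (session-scoped; everything is generated
programmatically)."""

from fractions import Fraction as F

import pytest

from rhizofba.ecm import EcmConfig, add_flux_tracker, enumerate_ecms
from rhizofba.model import MetabolicModel, Metabolite, Reaction
from rhizofba.pipeline import PipelineConfig, default_ecm_config
from rhizofba.synth import build_core_bacteroid_model


def make_chain_model():
    """A_e -> A -> B -> B_e with uptake capacity 10."""
    mets = [
        Metabolite("A_e", compartment="external"),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("B_e", compartment="external"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": F(-1)}, kind="exchange", lower_bound=-10, upper_bound=0),
        Reaction("T_A", {"A_e": F(-1), "A": F(1)}, kind="transport"),
        Reaction("R1", {"A": F(-1), "B": F(1)}),
        Reaction("T_B", {"B": F(-1), "B_e": F(1)}, kind="transport"),
        Reaction("EX_B", {"B_e": F(-1)}, kind="exchange"),
    ]
    return MetabolicModel("chain", mets, rxns, genes=[])


def make_cycle_model():
    """The chain model plus a 2-reaction stoichiometrically balanced cycle."""
    m = make_chain_model()
    m.metabolites.append(Metabolite("C"))
    m.reactions.append(Reaction("CYC1", {"B": F(-1), "C": F(1)}))
    m.reactions.append(Reaction("CYC2", {"C": F(-1), "B": F(1)}))
    m._reindex()
    m.validate()
    return m


def make_two_path_model():
    """Two routes from A to C: direct, and an O-consuming route with double yield."""
    mets = [Metabolite(x, compartment="external") for x in ("A_e", "C_e", "O_e")] + [
        Metabolite(x) for x in ("A", "B", "D")
    ]
    rxns = [
        Reaction("EX_A", {"A_e": F(-1)}, kind="exchange", lower_bound=-10, upper_bound=0),
        Reaction("EX_O", {"O_e": F(-1)}, kind="exchange", lower_bound=-5, upper_bound=0),
        Reaction("EX_C", {"C_e": F(-1)}, kind="exchange"),
        Reaction("T_A", {"A_e": F(-1), "A": F(1)}, kind="transport"),
        Reaction("R1", {"A": F(-1), "B": F(1)}),
        Reaction("R2", {"B": F(-1), "C_e": F(1)}, kind="transport"),
        Reaction("R3", {"A": F(-1), "O_e": F(-1), "D": F(1)}),
        Reaction("R4", {"D": F(-1), "C_e": F(2)}, kind="transport"),
    ]
    return MetabolicModel("two_path", mets, rxns, genes=[])


@pytest.fixture(scope="session")
def chain_model():
    return make_chain_model()


@pytest.fixture(scope="session")
def cycle_model():
    return make_cycle_model()


@pytest.fixture(scope="session")
def two_path_model():
    return make_two_path_model()


@pytest.fixture(scope="session")
def bacteroid_model():
    return build_core_bacteroid_model()


@pytest.fixture(scope="session")
def survey_config():
    return default_ecm_config(PipelineConfig())


@pytest.fixture(scope="session")
def bacteroid_ecms(bacteroid_model, survey_config):
    return enumerate_ecms(bacteroid_model, survey_config)


@pytest.fixture(scope="session")
def tracked_bacteroid(bacteroid_model):
    """The bacteroid model with a glutamine-synthetase flux tracker."""
    return add_flux_tracker(bacteroid_model, "GS", "trk_gs")


@pytest.fixture(scope="session")
def tracked_ecms(tracked_bacteroid):
    cfg = default_ecm_config(PipelineConfig(), extra_outputs=("trk_gs",))
    return enumerate_ecms(tracked_bacteroid, cfg)
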