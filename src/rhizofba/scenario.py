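"""Scenario constraints: named bound overrides encoding a biological condition.

A scenario is how a condition like "bacteroid on malate under an oxygen
ceiling" or "forced glutamate demand" is expressed: a set of per-reaction
(lower, upper) overrides in flux units, optionally with an objective.
Application is idempotent and never mutates the input model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import MetabolicModel, ModelStructureError


@dataclass
class ScenarioConstraints:
    name: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ModelStructureError(
                    f"scenario {self.name!r}: reaction {rid!r} has lower bound {lo} > upper {hi}"
                )

    def merged(self, other: "ScenarioConstraints") -> "ScenarioConstraints":
        """Overlay ``other`` on top of this scenario (other wins on conflicts)."""
        bounds = dict(self.bounds)
        bounds.update(other.bounds)
        objective = dict(other.objective) if other.objective else dict(self.objective)
        return ScenarioConstraints(
            name=f"{self.name}+{other.name}", bounds=bounds, objective=objective,
            notes="; ".join(s for s in (self.notes, other.notes) if s),
        )


def apply_scenario(
    model: MetabolicModel, scenario: Optional[ScenarioConstraints]
) -> MetabolicModel:
    """Return a copy of ``model`` with the scenario's bound overrides applied.

    Reactions not mentioned by the scenario are untouched.  Unknown reaction
    ids are an error (scenarios must resolve at application time).
    """
    out = model.copy()
    if scenario is None:
        return out
    for rid, (lo, hi) in scenario.bounds.items():
        rxn = out.reaction(rid)  # raises KeyError for unknown ids
        rxn.lower_bound = float(lo)
        rxn.upper_bound = float(hi)
    return out
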