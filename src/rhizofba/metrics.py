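"""Derived quantities over conversions: oxygen economy, carbon cost of
nitrogen fixation, biological classification and filtering, and the rank
correlation used for the oxygen-vs-GS analysis.

All metrics are invariant under positive rescaling of a conversion.  The
carbon-cost crediting rule deserves a word: the cost of nitrogen export is
(carbon in − carbon credited out) per nitrogen secreted, in grams.  Secreted
organic metabolites (alanine, aspartate, glutamate, ...) are credited as
carbon outputs; CO2 (waste) and storage polymers (retained by the bacteroid,
not delivered to the plant) are NOT credited, so polymer carbon counts
toward the cost.  Under this reading polymer-free conversions sit near the
theoretical cost of fixation while polymer-producing ones are substantially
more expensive.  The rule is configurable via ``credited_outputs``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .ecm import Conversion
from .model import MetabolicModel, ModelStructureError

MASS_C = 12.011
MASS_N = 14.007

#: default identities in the synthetic bacteroid model
DEFAULT_POLYMER_IDS = frozenset({"phb_e", "glyg_e", "pmt_e", "glyclip_e"})
DEFAULT_AMINO_ACID_IDS = frozenset({"ala_e", "asp_e", "glu_e", "gln_e", "gaba_e"})
DEFAULT_AMMONIA_ID = "nh3_e"
DEFAULT_N2_ID = "n2_e"
DEFAULT_O2_ID = "o2_e"
DEFAULT_CO2_ID = "co2_e"


def element_flux(conv: Conversion, model: MetabolicModel, element: str, side: str) -> Fraction:
    """Mol atoms of ``element`` entering (side="input") or leaving (side="output")
    per unit conversion; |coefficient| × atom count summed over that side."""
    if side not in ("input", "output"):
        raise ValueError("side must be 'input' or 'output'")
    total = Fraction(0)
    for met_id, coef in conv.coefficients.items():
        if (side == "input") != (coef < 0):
            continue
        met = model.metabolite(met_id)
        if met.formula is None:
            raise ModelStructureError(f"metabolite {met_id!r} has no formula")
        total += abs(coef) * met.atoms(element)
    return total


def carbon_cost_per_nitrogen(
    conv: Conversion,
    model: MetabolicModel,
    credited_outputs: Optional[Iterable[str]] = None,
    polymer_ids: Iterable[str] = DEFAULT_POLYMER_IDS,
    n2_id: str = DEFAULT_N2_ID,
    co2_id: str = DEFAULT_CO2_ID,
    mass_c: float = MASS_C,
    mass_n: float = MASS_N,
) -> Optional[float]:
    """Grams of carbon spent per gram of nitrogen secreted.

    cost = mass_c·(C_in − C_out,credited) / (mass_n·(N_out − N_in,organic)),
    where credited carbon outputs default to secreted organic metabolites
    (CO2 and storage polymers excluded) and N_in,organic excludes N2 itself.
    Returns None when net nitrogen secreted is ≤ 0 (metric undefined; the
    conversion is still reportable).
    """
    polymer_ids = set(polymer_ids)
    c_in = float(element_flux(conv, model, "C", "input"))
    if credited_outputs is None:
        credited = {
            m for m, c in conv.coefficients.items()
            if c > 0 and m != co2_id and m not in polymer_ids
        }
    else:
        credited = set(credited_outputs)
    c_out = sum(
        float(c) * model.metabolite(m).atoms("C")
        for m, c in conv.coefficients.items()
        if c > 0 and m in credited
    )
    n_out = float(element_flux(conv, model, "N", "output"))
    n_in_organic = sum(
        float(-c) * model.metabolite(m).atoms("N")
        for m, c in conv.coefficients.items()
        if c < 0 and m != n2_id
    )
    net_n = n_out - n_in_organic
    if net_n <= 0:
        return None
    return mass_c * (c_in - c_out) / (mass_n * net_n)


@dataclass
class ConversionClass:
    polymer_producing: bool
    ammonia_only: bool
    amino_acid_secreting: bool
    amino_acid_consuming: bool


def classify_conversion(
    conv: Conversion,
    polymer_ids: Iterable[str] = DEFAULT_POLYMER_IDS,
    amino_acid_ids: Iterable[str] = DEFAULT_AMINO_ACID_IDS,
    ammonia_id: str = DEFAULT_AMMONIA_ID,
    model: Optional[MetabolicModel] = None,
) -> ConversionClass:
    """Class flags: polymer producer, ammonia-only secretor, amino-acid
    secretor/consumer.  ``ammonia_only`` requires ammonia to be the sole
    nitrogen-containing product (checked by formula when the model is given,
    else against the amino-acid list)."""
    polymer_ids, amino_acid_ids = set(polymer_ids), set(amino_acid_ids)
    outs = conv.outputs()
    ins = conv.inputs()
    polymer = any(m in polymer_ids for m in outs)
    if model is not None:
        n_products = {m for m in outs if model.metabolite(m).atoms("N") > 0}
    else:
        n_products = {m for m in outs if m in amino_acid_ids or m == ammonia_id}
    ammonia_only = n_products == {ammonia_id}
    return ConversionClass(
        polymer_producing=polymer,
        ammonia_only=ammonia_only,
        amino_acid_secreting=any(m in amino_acid_ids for m in outs),
        amino_acid_consuming=any(m in amino_acid_ids for m in ins),
    )


@dataclass
class ConversionMetrics:
    """Per-conversion summary used by the survey tables."""

    o2_per_carbon: Optional[float]
    o2_per_n2: Optional[float]
    carbon_cost_g_per_g_n: Optional[float]
    net_n_out: float
    classes: ConversionClass
    gs_flux: float  # tracked flux per unit conversion (0 without a tracker)


def conversion_metrics(
    conv: Conversion,
    model: MetabolicModel,
    polymer_ids: Iterable[str] = DEFAULT_POLYMER_IDS,
    amino_acid_ids: Iterable[str] = DEFAULT_AMINO_ACID_IDS,
    o2_id: str = DEFAULT_O2_ID,
    n2_id: str = DEFAULT_N2_ID,
    ammonia_id: str = DEFAULT_AMMONIA_ID,
    gs_tracker: Optional[str] = None,
) -> ConversionMetrics:
    """O2 per C input, O2 per N2 fixed, carbon cost per N and class flags."""
    o2_in = float(-conv.coefficients.get(o2_id, Fraction(0)))
    n2_in = float(-conv.coefficients.get(n2_id, Fraction(0)))
    c_in = float(element_flux(conv, model, "C", "input"))
    n_out = float(element_flux(conv, model, "N", "output"))
    n_in_organic = sum(
        float(-c) * model.metabolite(m).atoms("N")
        for m, c in conv.coefficients.items()
        if c < 0 and m != n2_id
    )
    gs = 0.0
    if gs_tracker is not None:
        gs = float(conv.tracked.get(gs_tracker, Fraction(0)))
    return ConversionMetrics(
        o2_per_carbon=o2_in / c_in if c_in > 0 else None,
        o2_per_n2=o2_in / n2_in if n2_in > 0 else None,
        carbon_cost_g_per_g_n=carbon_cost_per_nitrogen(
            conv, model, polymer_ids=polymer_ids, n2_id=n2_id
        ),
        net_n_out=n_out - n_in_organic,
        classes=classify_conversion(conv, polymer_ids, amino_acid_ids, ammonia_id, model),
        gs_flux=gs,
    )


def filter_conversions(
    convs: Sequence[Conversion],
    model: MetabolicModel,
    max_cost: float = 40.0,
    max_amino_inputs: int = 1,
    require_positive_net_n: bool = True,
    polymer_ids: Iterable[str] = DEFAULT_POLYMER_IDS,
    amino_acid_ids: Iterable[str] = DEFAULT_AMINO_ACID_IDS,
) -> tuple[list[Conversion], dict[int, list[str]]]:
    """Biological plausibility filter over an enumerated conversion set.

    Keeps conversions with (i) a positive carbon cost below ``max_cost``
    grams of carbon per gram of nitrogen, (ii) at most ``max_amino_inputs``
    amino-acid inputs (GABA counts as one), and (iii) positive net nitrogen
    output.  Returns the kept list plus machine-readable rejection reasons
    keyed by the conversion's index in ``convs``.
    """
    amino_acid_ids = set(amino_acid_ids)
    kept: list[Conversion] = []
    rejected: dict[int, list[str]] = {}
    for i, conv in enumerate(convs):
        reasons: list[str] = []
        cost = carbon_cost_per_nitrogen(conv, model, polymer_ids=polymer_ids)
        n_amino_in = sum(1 for m in conv.inputs() if m in amino_acid_ids)
        if n_amino_in > max_amino_inputs:
            reasons.append("amino_acid_inputs")
        if cost is None:
            if require_positive_net_n:
                reasons.append("net_nitrogen")
        elif not (0.0 < cost < max_cost):
            reasons.append("carbon_cost")
        if reasons:
            rejected[i] = reasons
        else:
            kept.append(conv)
    return kept, rejected


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rho with midrank ties.

    The p-value is exact (full permutation distribution of one rank vector)
    for n ≤ ``exact_max_n`` and the usual t-approximation above.  A constant
    vector leaves rho undefined: (nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = rho_of(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = rho_of(rx[list(perm)], ry)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-15, 1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, p
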