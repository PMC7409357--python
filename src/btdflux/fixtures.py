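"""Synthetic metabolic models for development and testing.

Genome-scale models are large downloads; everything in this package is
exercisable on two families of small, fully deterministic stand-ins:

* :func:`btd_core_model` — a hand-built ~20-reaction network with the
  biology the analysis cares about: glucose and glycerol uptake, lumped
  glycolysis/TCA/respiration, an oxygen transport step, the three-step
  2,3-butanediol branch from pyruvate (acetolactate synthase →
  acetolactate decarboxylase → butanediol dehydrogenase) with its
  transport and exchange, and a biomass pseudo-reaction.  All coefficients
  are small integers so optima are hand-checkable.
* :func:`random_consistent_model` — seeded random networks whose internal
  reactions conserve a strictly positive mass vector, so mass cannot be
  created except through exchanges.  These drive property tests.

Both carry the field's bound conventions: irreversible reactions 0…1000,
reversible −1000…1000 mmol gDCW⁻¹ h⁻¹, mineral-medium exchanges open at
±1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from .model import Condition, MetabolicModel, Metabolite, Reaction, parse_gpr

__all__ = [
    "FixtureSpec",
    "btd_core_model",
    "random_consistent_model",
    "condition_presets",
    "GLUCOSE_CARBONS",
]

#: carbon counts of the four substrates the condition presets cover
CARBON_COUNTS = {"glucose": 6, "xylose": 5, "arabinose": 5, "glycerol": 3}
GLUCOSE_CARBONS = 6

# candidate exchange ids per substrate: toy ids first, then BIGG-style ids
# used by genome-scale models (the reader must not assume one namespace)
_EXCHANGE_ALIASES = {
    "glucose": ("EX_glc", "EX_glc__D_e", "EX_glc_e", "EX_glc_D_e"),
    "xylose": ("EX_xyl", "EX_xyl__D_e", "EX_xyl_e"),
    "arabinose": ("EX_arab", "EX_arab__L_e", "EX_arab_L_e", "EX_arab_e"),
    "glycerol": ("EX_glyc", "EX_glyc_e"),
}
_OXYGEN_ALIASES = ("EX_o2", "EX_o2_e")
# mineral (Pfennig-style) medium components kept open at ±1000 when present
_MINERAL_ALIASES = (
    "EX_nh4_e", "EX_nh3_e", "EX_pi_e", "EX_mg2_e", "EX_ca2_e", "EX_k_e",
    "EX_na1_e", "EX_h2o_e", "EX_h_e", "EX_so4_e", "EX_fe2_e", "EX_fe3_e",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a seeded random fixture model (bit-stable per seed)."""

    name: str = "random"
    seed: int = 0
    n_metabolites: int = 8
    n_extra_reactions: int = 4
    reversible_fraction: float = 0.3


def _met(mid: str, formula: Optional[str] = None, comp: str = "c") -> Metabolite:
    return Metabolite(id=mid, name=mid, compartment=comp, formula=formula)


def btd_core_model(with_futile_drain: bool = False) -> MetabolicModel:
    """The hand-built core network with a 2,3-butanediol branch.

    Stoichiometry (all lumped, integer coefficients):

    * glycolysis: glc + 2 ADP + 2 NAD → 2 pyr + 2 ATP + 2 NADH
    * glycerol entry: glyc + ADP + 2 NAD → pyr + ATP + 2 NADH
    * TCA: pyr + 4 NAD + ADP → 3 CO2 + 4 NADH + ATP
    * respiration (P/O = 2): NADH + ½ O2 + 2 ADP → NAD + 2 ATP
    * BTD branch: 2 pyr → acetolactate + CO2 → acetoin + CO2;
      acetoin + NADH → 2,3-BTD (then transport and exchange)
    * biomass: 2 pyr + 12 ATP → biomass + 12 ADP

    The acetolactate steps carry GPRs with an isozyme pair (``alsA or
    alsB``) so gene-level modifications are testable.  With
    ``with_futile_drain=True`` a forced ATP-wasting reaction
    ``DRAIN_ATP`` (lower bound 6) is planted; its knockout frees ATP and
    is the known-good strain design used by optimizer tests.
    """
    mets = [
        _met("glc_e", "C6H12O6", "e"), _met("glc_c", "C6H12O6"),
        _met("glyc_e", "C3H8O3", "e"), _met("glyc_c", "C3H8O3"),
        _met("o2_e", "O2", "e"), _met("o2_c", "O2"),
        _met("co2_e", "CO2", "e"), _met("co2_c", "CO2"),
        _met("btd_e", "C4H10O2", "e"), _met("btd_c", "C4H10O2"),
        _met("pyr_c", "C3H4O3"), _met("alac_c", "C5H8O4"),
        _met("actn_c", "C4H8O2"),
        _met("atp_c"), _met("adp_c"), _met("nad_c"), _met("nadh_c"),
        _met("biomass_c"), _met("ddm_c"),
    ]
    R = Reaction
    rxns = [
        R("EX_glc", {"glc_e": -1}, 0, 1000, name="D-glucose exchange", is_exchange=True),
        R("EX_glyc", {"glyc_e": -1}, 0, 1000, name="glycerol exchange", is_exchange=True),
        R("EX_o2", {"o2_e": -1}, -1000, 1000, name="O2 exchange", is_exchange=True),
        R("EX_co2", {"co2_e": -1}, 0, 1000, name="CO2 exchange", is_exchange=True),
        R("EX_btd", {"btd_e": -1}, 0, 1000, name="(R,R)-2,3-butanediol exchange",
          is_exchange=True),
        R("SK_biomass", {"biomass_c": -1}, 0, 1000, name="biomass drain", is_exchange=True),
        R("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, name="glucose transport"),
        R("GLYCt", {"glyc_e": -1, "glyc_c": 1}, 0, 1000, name="glycerol transport"),
        R("O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000, name="oxygen transport"),
        R("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000, name="CO2 transport"),
        R("BTDt", {"btd_c": -1, "btd_e": 1}, 0, 1000, name="2,3-butanediol transport",
          gpr=parse_gpr("btdT")),
        R("GLYCOLYSIS", {"glc_c": -1, "adp_c": -2, "nad_c": -2,
                         "pyr_c": 2, "atp_c": 2, "nadh_c": 2},
          0, 1000, name="lumped glycolysis", subsystem="glycolysis"),
        R("GLYCENT", {"glyc_c": -1, "adp_c": -1, "nad_c": -2,
                      "pyr_c": 1, "atp_c": 1, "nadh_c": 2},
          0, 1000, name="lumped glycerol entry", subsystem="glycolysis"),
        R("TCA", {"pyr_c": -1, "nad_c": -4, "adp_c": -1,
                  "co2_c": 3, "nadh_c": 4, "atp_c": 1},
          0, 1000, name="lumped TCA cycle", subsystem="tca"),
        R("RESP", {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2,
                   "nad_c": 1, "atp_c": 2},
          0, 1000, name="lumped respiration", subsystem="oxphos"),
        R("ALS", {"pyr_c": -2, "alac_c": 1, "co2_c": 1}, 0, 1000,
          name="acetolactate synthase", gpr=parse_gpr("alsA or alsB"), subsystem="btd"),
        R("ALDC", {"alac_c": -1, "actn_c": 1, "co2_c": 1}, 0, 1000,
          name="acetolactate decarboxylase", gpr=parse_gpr("alsA"), subsystem="btd"),
        R("BDH", {"actn_c": -1, "nadh_c": -1, "btd_c": 1, "nad_c": 1}, 0, 1000,
          name="(R,R)-butanediol dehydrogenase", gpr=parse_gpr("bdhA"), subsystem="btd"),
        R("BIOMASS", {"pyr_c": -2, "atp_c": -12, "adp_c": 12, "biomass_c": 1},
          0, 1000, name="biomass pseudo-reaction", subsystem="biomass"),
        R("ALD_X", {"pyr_c": -1, "nadh_c": -1, "ddm_c": 1, "nad_c": 1}, 0, 1000,
          name="dead-end side reaction"),
    ]
    if with_futile_drain:
        rxns.append(
            R("DRAIN_ATP", {"atp_c": -1, "adp_c": 1}, 6, 1000, name="futile ATP drain")
        )
    genes = ["alsA", "alsB", "bdhA", "btdT"]
    return MetabolicModel(
        id="btd_core" + ("_drain" if with_futile_drain else ""),
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction="BIOMASS",
        compartments={"c", "e"},
    )


def condition_presets(
    model: MetabolicModel,
    glucose_uptake: float = -16.0,
    oxygen_lower: float = -1000.0,
) -> list[Condition]:
    """Single-carbon-source medium presets for whatever substrates ``model`` has.

    Glucose uptake defaults to −16 mmol gDCW⁻¹ h⁻¹; the other substrates
    get carbon-proportional rates (uptake × 6 / carbon count): xylose and
    arabinose −19.2, glycerol −32.  Oxygen and any recognised mineral
    exchanges stay open at ±1000.  For toy models pass a smaller
    ``glucose_uptake`` (btd_core uses −10, hence glycerol −20) to keep
    round numbers.
    """
    present: dict[str, str] = {}
    for substrate, aliases in _EXCHANGE_ALIASES.items():
        for rid in aliases:
            if model.has_reaction(rid):
                present[substrate] = rid
                break
    if not present:
        raise KeyError(f"model {model.id!r} exposes none of the known carbon exchanges")
    oxy = next((rid for rid in _OXYGEN_ALIASES if model.has_reaction(rid)), None)
    carbon_family = tuple(sorted(present.values()))
    conditions = []
    for substrate, rid in present.items():
        atoms = CARBON_COUNTS[substrate]
        uptake = glucose_uptake * GLUCOSE_CARBONS / atoms
        bounds: dict[str, tuple[float, float]] = {rid: (uptake, 1000.0)}
        if oxy:
            bounds[oxy] = (oxygen_lower, 1000.0)
        for mineral in _MINERAL_ALIASES:
            if model.has_reaction(mineral):
                bounds[mineral] = (-1000.0, 1000.0)
        conditions.append(
            Condition(
                name=substrate,
                exchange_bounds=bounds,
                carbon_source=rid,
                carbon_atoms=atoms,
                carbon_exchanges=carbon_family,
            )
        )
    conditions.sort(key=lambda c: c.name)
    return conditions


def _masses(rng: np.random.Generator, n: int) -> list[Fraction]:
    return [Fraction(int(rng.integers(2, 12))) for _ in range(n)]


def random_consistent_model(spec: FixtureSpec) -> MetabolicModel:
    """A seeded random network that cannot create mass internally.

    Every internal (non-exchange) reaction is balanced against a strictly
    positive "mass" assigned to each metabolite, so the internal
    stoichiometric matrix has a strictly positive left null vector and the
    only way to grow is to import carbon.  The topology is a backbone chain
    from a carbon exchange through intermediates to a biomass drain, plus
    random mass-balanced side reactions (some reversible).
    """
    if spec.n_metabolites < 5:
        raise ValueError("need at least 5 metabolites for a viable fixture")
    rng = np.random.default_rng(spec.seed)
    k = spec.n_metabolites
    # internal intermediates M0..M{k-1}; M0 is the carbon entry, M{k-1} biomass
    mids = [f"M{i}_c" for i in range(k)]
    mass = dict(zip(mids, _masses(rng, k)))
    ext = "M0_e"
    mass[ext] = mass["M0_c"]
    mets = [_met(ext, comp="e")] + [_met(m) for m in mids]
    rxns: list[Reaction] = [
        Reaction("EX_carbon", {ext: -1}, 0, 1000, is_exchange=True),
        Reaction("T_carbon", {ext: -1, "M0_c": 1}, 0, 1000),
        Reaction("EX_biomass", {mids[-1]: -1}, 0, 1000, is_exchange=True),
    ]
    # backbone chain: Mi -> Mi+1, coefficients from the mass ratio
    for i in range(k - 1):
        a, b = mass[mids[i]], mass[mids[i + 1]]
        # a_coef * a == b_coef * b, smallest integers
        ratio = b / a
        rxns.append(
            Reaction(
                f"B{i}",
                {mids[i]: -float(ratio.numerator), mids[i + 1]: float(ratio.denominator)},
                0,
                1000,
            )
        )
    # random mass-balanced side reactions
    for t in range(spec.n_extra_reactions):
        subs = rng.choice(k, size=int(rng.integers(1, 3)), replace=False)
        prods = [p for p in rng.choice(k, size=int(rng.integers(1, 3)), replace=False)
                 if p not in subs]
        if not prods:
            continue
        stoich: dict[str, float] = {}
        consumed = Fraction(0)
        for s in subs:
            coef = int(rng.integers(1, 4))
            stoich[mids[s]] = -float(coef)
            consumed += coef * mass[mids[s]]
        remaining = consumed
        for j, p in enumerate(prods):
            if j < len(prods) - 1:
                share = Fraction(int(rng.integers(25, 75)), 100)
                amount = remaining * share
            else:
                amount = remaining
            coef = amount / mass[mids[p]]
            stoich[mids[p]] = stoich.get(mids[p], 0.0) + float(coef)
            remaining -= amount
        reversible = rng.random() < spec.reversible_fraction
        rxns.append(Reaction(f"X{t}", stoich, -1000 if reversible else 0, 1000))
    model = MetabolicModel(
        id=f"{spec.name}_{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        genes=[],
        objective_reaction="EX_biomass",
        compartments={"c", "e"},
    )
    return model


def random_fixture_condition(model: MetabolicModel, uptake: float = -10.0) -> Condition:
    """The default single-carbon condition for :func:`random_consistent_model`."""
    return Condition(
        name="carbon",
        exchange_bounds={"EX_carbon": (uptake, 1000.0)},
        carbon_source="EX_carbon",
        carbon_atoms=6,
        carbon_exchanges=("EX_carbon",),
    )
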