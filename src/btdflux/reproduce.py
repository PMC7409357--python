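"""Reproduction of published iMK1321 simulation benchmarks (download path).

The deposited iMK1321 genome-scale model (and optionally the published
*B. subtilis* iYO844 model) is not shipped with this package; when the
files are supplied locally this module re-runs the published growth and
strain-design simulations and reports per-value deltas.  Tolerances are
±0.001 h⁻¹ on growth rates and ±0.01 mmol gDCW⁻¹ h⁻¹ on production rates
(published optima may sit on degenerate alternate-optima faces).

Without the model files every check is skipped with a notice — nothing in
the desk-scale test suite depends on this module succeeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .design import DesignCandidate, Modification, evaluate_candidate
from .fixtures import condition_presets
from .io import read_json, read_sbml
from .model import MetabolicModel
from .simulate import pfba, reference_state

__all__ = ["MissingDataError", "find_model_file", "reproduce_report",
           "GROWTH_TOL", "PRODUCTION_TOL"]

GROWTH_TOL = 0.001
PRODUCTION_TOL = 0.01

#: published pFBA growth rates (h⁻¹) for iMK1321 by substrate
IMK1321_GROWTH = {"glucose": 0.502, "xylose": 0.497, "arabinose": 0.497,
                  "glycerol": 0.502}
#: published iYO844 growth at a glucose uptake of −16 mmol gDCW⁻¹ h⁻¹
IYO844_GROWTH_AT_16 = 0.624

#: published best strain designs: (method, substrate, modifications,
#: expected production, expected growth); factors are wildtype-flux multiples
IMK1321_DESIGNS = [
    ("lmoma", "glucose", [("reaction", "O2t", 0.03125)], 4.14, 0.4136),
    ("lmoma", "arabinose", [("reaction", "CS", 0.03125)], 6.00, 0.371),
    ("mimbl", "glycerol", [("gene", "EP10_13815", 0.03125),
                           ("gene", "EP10_15190", 0.03125)], 6.55, 0.357),
    ("pfba", "glucose", [("reaction", "EX_o2_e", 0.03125)], 4.16, 0.42),
    ("pfba", "glycerol", [("reaction", "O2t", 0.0625)], 12.23, 0.25),
]

#: published network statistics for iMK1321
IMK1321_COUNTS = {"reactions": 1676, "metabolites": 1589, "genes": 1321}

_PRODUCT_ALIASES = ("EX_btd_RR_e", "EX_btd__RR_e", "EX_btd_e", "EX_btd")


class MissingDataError(FileNotFoundError):
    """The deposited model files required for reproduction are absent."""


def find_model_file(model_dir: Path) -> Optional[Path]:
    """Locate an iMK1321 model file (SBML preferred, else JSON) in a directory."""
    model_dir = Path(model_dir)
    if not model_dir.is_dir():
        return None
    for pattern in ("*iMK1321*.xml", "*.xml", "*iMK1321*.json", "*.json"):
        hits = sorted(model_dir.glob(pattern))
        if hits:
            return hits[0]
    return None


def _load(path: Path) -> MetabolicModel:
    if path.suffix == ".json":
        return read_json(path)
    return read_sbml(path)


def _product_exchange(model: MetabolicModel) -> str:
    for rid in _PRODUCT_ALIASES:
        if model.has_reaction(rid):
            return rid
    raise MissingDataError(
        f"model {model.id!r} has no recognised 2,3-butanediol exchange "
        f"(looked for {', '.join(_PRODUCT_ALIASES)})"
    )


def reproduce_report(model_path: Path,
                     iyo844_path: Optional[Path] = None) -> pd.DataFrame:
    """Recompute the published iMK1321 benchmarks and report deltas.

    Returns a table with columns (check, substrate, quantity, expected,
    computed, delta, within_tolerance).
    """
    model = _load(Path(model_path))
    rows: list[dict] = []
    for key, expected in IMK1321_COUNTS.items():
        computed = {"reactions": len(model.reactions),
                    "metabolites": len(model.metabolites),
                    "genes": len(model.genes)}[key]
        rows.append(dict(check="model-statistics", substrate="", quantity=key,
                         expected=expected, computed=computed,
                         delta=computed - expected,
                         within_tolerance=computed == expected))
    conditions = {c.name: c for c in condition_presets(model)}
    for substrate, expected in IMK1321_GROWTH.items():
        if substrate not in conditions:
            continue
        sol = pfba(model, condition=conditions[substrate])
        g = sol.objective_value if sol.optimal else float("nan")
        rows.append(dict(check="pfba-growth", substrate=substrate,
                         quantity="growth", expected=expected, computed=g,
                         delta=g - expected,
                         within_tolerance=abs(g - expected) <= GROWTH_TOL))
    try:
        product = _product_exchange(model)
    except MissingDataError:
        product = None
    if product is not None:
        for method, substrate, mods, exp_prod, exp_growth in IMK1321_DESIGNS:
            if substrate not in conditions:
                continue
            cond = conditions[substrate]
            from .model import apply_condition

            conditioned = apply_condition(model, cond)
            ref = reference_state(conditioned)
            cand = DesignCandidate(tuple(Modification(k, t, f) for k, t, f in mods))
            try:
                res = evaluate_candidate(conditioned, ref, cand, method,
                                         product, cond.carbon_source)
            except KeyError as exc:
                rows.append(dict(check=f"{method}-design", substrate=substrate,
                                 quantity=str(cand), expected=exp_prod,
                                 computed=float("nan"), delta=float("nan"),
                                 within_tolerance=False))
                continue
            rows.append(dict(check=f"{method}-design", substrate=substrate,
                             quantity=f"production [{cand}]", expected=exp_prod,
                             computed=res.production,
                             delta=res.production - exp_prod,
                             within_tolerance=abs(res.production - exp_prod)
                             <= PRODUCTION_TOL))
            rows.append(dict(check=f"{method}-design", substrate=substrate,
                             quantity=f"growth [{cand}]", expected=exp_growth,
                             computed=res.growth, delta=res.growth - exp_growth,
                             within_tolerance=abs(res.growth - exp_growth)
                             <= GROWTH_TOL))
    if iyo844_path is not None:
        other = _load(Path(iyo844_path))
        conds = {c.name: c for c in condition_presets(other)}
        if "glucose" in conds:
            sol = pfba(other, condition=conds["glucose"])
            g = sol.objective_value if sol.optimal else float("nan")
            rows.append(dict(check="pfba-growth-iYO844", substrate="glucose",
                             quantity="growth", expected=IYO844_GROWTH_AT_16,
                             computed=g, delta=g - IYO844_GROWTH_AT_16,
                             within_tolerance=abs(g - IYO844_GROWTH_AT_16)
                             <= GROWTH_TOL))
    return pd.DataFrame(rows)
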