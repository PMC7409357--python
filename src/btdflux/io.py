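"""Model I/O: SBML L3+FBC v2, the COBRA-community JSON dialect, flux tables.

SBML reading/writing is delegated to cobrapy (which itself uses
python-libsbml) through lossless conversion between this package's
:class:`~btdflux.model.MetabolicModel` and :class:`cobra.Model`.  The JSON
dialect — the plain-text schema genome-scale models are commonly deposited
in — is read and written directly so schema errors can point at the
offending field.

Flux tables replace map rendering: :func:`export_flux_table` turns a
solution into a tidy table (reaction id, flux, subsystem) sorted by |flux|,
serialisable to CSV at 9 significant digits or to a ``{reaction: flux}``
JSON suitable for external map-colouring tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    Condition,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
    validate_model,
)
from .simulate import FluxSolution

__all__ = [
    "ModelIOError",
    "read_sbml",
    "write_sbml",
    "read_json",
    "write_json",
    "read_condition",
    "export_flux_table",
    "write_flux_csv",
    "write_flux_json",
    "to_cobra",
    "from_cobra",
]

PathLike = Union[str, Path]
FLUX_PRECISION = 9  # significant digits in serialised fluxes


class ModelIOError(ValueError):
    """A model file failed to parse or violated its schema."""


# --------------------------------------------------------------------------
# cobra conversion + SBML
# --------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a :class:`cobra.Model` (for SBML export and cross-checks)."""
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cm_met = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment,
            formula=m.formula, charge=m.charge,
        )
        cmets[m.id] = cm_met
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    if model.objective_reaction:
        cm.objective = model.objective_reaction
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a :class:`cobra.Model` into this package's model type."""
    mets = [
        Metabolite(
            id=m.id, name=m.name or "", compartment=m.compartment or "c",
            formula=m.formula or None,
            charge=int(m.charge) if m.charge is not None else None,
        )
        for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                name=r.name or "",
                gpr=parse_gpr(r.gene_reaction_rule or ""),
                is_exchange=len(r.metabolites) == 1 and r in cm.boundary,
                subsystem=r.subsystem or "",
            )
        )
    objective = ""
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
        if coeffs:
            objective = max(coeffs, key=lambda rx: coeffs[rx]).id
    except Exception:  # pragma: no cover - solver-interface quirks
        pass
    if not objective:
        raise ModelIOError(f"model {cm.id!r} carries no FBC objective")
    return MetabolicModel(
        id=cm.id or "model",
        metabolites=mets,
        reactions=rxns,
        genes=[g.id for g in cm.genes],
        objective_reaction=objective,
        compartments={m.compartment for m in cm.metabolites if m.compartment},
    )


def read_sbml(path: PathLike) -> MetabolicModel:
    """Read an SBML Level 3 + FBC model file.

    Bounds come from FBC flux-bound parameters, the objective from the FBC
    objective, GPRs from gene-product associations.  Raises
    :class:`ModelIOError` on parse failure or a missing objective; never
    returns a partial model.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelIOError(f"cannot parse SBML file {path}: {exc}") from exc
    model = from_cobra(cm)
    violations = validate_model(model)
    if violations:
        raise ModelIOError(f"SBML model {path} invalid: {violations[0]}")
    return model


def write_sbml(model: MetabolicModel, path: PathLike) -> None:
    """Write the model as SBML Level 3 Version 1 with FBC v2."""
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


# --------------------------------------------------------------------------
# JSON dialect
# --------------------------------------------------------------------------

def _require(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise ModelIOError(f"missing required field at {pointer}/{key}")
    return obj[key]


def read_json(path: PathLike) -> MetabolicModel:
    """Read a model in the COBRA-community JSON dialect.

    Schema errors raise :class:`ModelIOError` with a JSON-pointer-style
    location (e.g. ``/reactions/5/lower_bound``).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"cannot parse JSON file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelIOError("top-level JSON value must be an object at /")
    mets = []
    for i, m in enumerate(_require(doc, "metabolites", "")):
        ptr = f"/metabolites/{i}"
        mets.append(
            Metabolite(
                id=_require(m, "id", ptr),
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula") or None,
                charge=m.get("charge"),
            )
        )
    genes = [
        _require(g, "id", f"/genes/{i}") if isinstance(g, dict) else str(g)
        for i, g in enumerate(doc.get("genes", []))
    ]
    rxns = []
    objective = ""
    for i, r in enumerate(_require(doc, "reactions", "")):
        ptr = f"/reactions/{i}"
        rid = _require(r, "id", ptr)
        ptr = f"/reactions/{i}({rid})"
        stoich = {str(k): float(v) for k, v in _require(r, "metabolites", ptr).items()}
        try:
            rule = parse_gpr(r.get("gene_reaction_rule", ""))
        except ValueError as exc:
            raise ModelIOError(f"bad GPR at {ptr}/gene_reaction_rule: {exc}") from exc
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(_require(r, "lower_bound", ptr)),
                upper_bound=float(_require(r, "upper_bound", ptr)),
                name=r.get("name", ""),
                gpr=rule,
                is_exchange=bool(r.get("is_exchange", len(stoich) == 1
                                       and (rid.startswith(("EX_", "DM_", "SK_"))))),
                subsystem=r.get("subsystem", ""),
            )
        )
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            objective = rid
    model = MetabolicModel(
        id=doc.get("id", path.stem),
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction=objective,
        compartments={m.compartment for m in mets},
    )
    if not objective:
        raise ModelIOError("no reaction carries a nonzero objective_coefficient at /reactions")
    violations = validate_model(model)
    if violations:
        raise ModelIOError(f"JSON model {path} invalid: {violations[0]}")
    return model


def write_json(model: MetabolicModel, path: PathLike) -> None:
    """Write the model in the COBRA-community JSON dialect (round-trip stable)."""
    doc = {
        "id": model.id,
        "version": "1",
        "compartments": {c: c for c in sorted(model.compartments)},
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
                "is_exchange": r.is_exchange,
                **(
                    {"objective_coefficient": 1.0}
                    if r.id == model.objective_reaction
                    else {}
                ),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def read_condition(path: PathLike) -> Condition:
    """Read a medium/condition file (YAML or JSON)."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ModelIOError("condition file must contain a mapping")
    try:
        return Condition(
            name=doc["name"],
            exchange_bounds={
                str(k): (float(v[0]), float(v[1])) for k, v in doc["exchange_bounds"].items()
            },
            carbon_source=doc["carbon_source"],
            carbon_atoms=int(doc["carbon_atoms"]),
            carbon_exchanges=tuple(doc.get("carbon_exchanges", ())),
        )
    except KeyError as exc:
        raise ModelIOError(f"condition file missing key {exc.args[0]!r}") from exc


# --------------------------------------------------------------------------
# flux tables
# --------------------------------------------------------------------------

def export_flux_table(model: MetabolicModel, solution: FluxSolution) -> pd.DataFrame:
    """A tidy flux table: one row per reaction, sorted by |flux| descending.

    Zero-flux rows are retained so the table always covers the whole model.
    Raises ``KeyError`` if the solution lacks any model reaction.
    """
    missing = [r.id for r in model.reactions if r.id not in solution.fluxes]
    if missing:
        raise KeyError(f"solution missing fluxes for reactions {missing[:3]}")
    df = pd.DataFrame(
        {
            "reaction": [r.id for r in model.reactions],
            "flux": [solution.fluxes[r.id] for r in model.reactions],
            "subsystem": [r.subsystem for r in model.reactions],
        }
    )
    df = df.reindex(df["flux"].abs().sort_values(ascending=False, kind="stable").index)
    return df.reset_index(drop=True)


def write_flux_csv(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False, float_format=f"%.{FLUX_PRECISION}g")


def write_flux_json(table: pd.DataFrame, path: PathLike) -> None:
    """``{reaction id: flux}`` JSON for external map-colouring tools."""
    data = {
        row.reaction: float(f"%.{FLUX_PRECISION}g" % row.flux)
        for row in table.itertuples()
    }
    Path(path).write_text(json.dumps(data, indent=0) + "\n")
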