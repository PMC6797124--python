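"""Model serialization.

Two formats are supported:

* a documented JSON dialect (the native round-trip format, schema below);
* SBML Level 3 with the FBC package (bounds, objective,
  geneProductAssociation), read through libsbml as a thin adapter.

JSON schema::

    {
      "name": str, "version": str, "objective": reaction-id,
      "metabolites": [{"id": str, "name": str, "compartment": str}, ...],
      "reactions": [{"id": str, "name": str,
                     "stoichiometry": {metabolite-id: coefficient, ...},
                     "lower_bound": float, "upper_bound": float,
                     "gpr": rule-string-or-null}, ...]
    }
"""

from __future__ import annotations

import json
from pathlib import Path

from .gpr import parse_gpr, render_gpr
from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction, validate_model

__all__ = ["read_model", "write_model", "model_to_dict", "model_from_dict"]


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "version": model.version,
        "objective": model.objective_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": render_gpr(r.gpr) if r.gpr is not None else None,
            }
            for r in model.reactions.values()
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(
        name=data.get("name", ""),
        version=data.get("version", ""),
        objective_reaction_id=data.get("objective", ""),
    )
    for m in data.get("metabolites", []):
        model.add_metabolite(
            Metabolite(id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "c"))
        )
    for r in data.get("reactions", []):
        gpr_text = r.get("gpr")
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(gpr_text) if gpr_text else None,
            )
        )
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model in the JSON dialect."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from JSON (native dialect) or SBML L3/FBC.

    ``format`` is ``"json"`` or ``"sbml"``; inferred from the file suffix
    (.json vs .xml/.sbml) when omitted.  The returned model has passed
    :func:`validate_model`; violations raise :class:`ModelValidationError`
    listing every finding.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        model = model_from_dict(json.loads(path.read_text()))
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    findings = validate_model(model)
    if findings:
        raise ModelValidationError(findings)
    return model


# --- SBML/FBC adapter -------------------------------------------------------


def _association_to_rule(assoc) -> str | None:
    """Render an FBC gene-product association subtree as a rule string."""
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getSBMLDocument().getModel().getPlugin("fbc").getGeneProduct(
            assoc.getGeneProduct()
        )
        # prefer the biological label (systematic gene name) over the SBML id
        if gp is not None and gp.isSetLabel() and gp.getLabel():
            return gp.getLabel()
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_association_to_rule(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(p for p in parts if p) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_association_to_rule(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(p for p in parts if p) + ")"
    raise ValueError(f"unsupported FBC association node {type(assoc)!r}")


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelValidationError([f"SBML read error: {m}" for m in msgs])
    sb = doc.getModel()
    if sb is None:
        raise ModelValidationError(["SBML file contains no model"])
    fbc = sb.getPlugin("fbc")

    model = MetabolicModel(name=sb.getName() or sb.getId(), version=str(sb.getVersion()))
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are not balanced
        model.add_metabolite(
            Metabolite(id=sp.getId(), name=sp.getName(), compartment=sp.getCompartment())
        )

    def _param_value(pid: str) -> float:
        p = sb.getParameter(pid)
        if p is None:
            raise ModelValidationError([f"missing flux-bound parameter {pid!r}"])
        return p.getValue()

    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        rfbc = rx.getPlugin("fbc")
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in model.metabolites:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in model.metabolites:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        rule = None
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            rule = _association_to_rule(rfbc.getGeneProductAssociation().getAssociation())
        model.add_reaction(
            Reaction(
                id=rx.getId(),
                name=rx.getName(),
                stoichiometry=stoich,
                lower_bound=_param_value(rfbc.getLowerFluxBound()) if rfbc else 0.0,
                upper_bound=_param_value(rfbc.getUpperFluxBound()) if rfbc else 1000.0,
                gpr=parse_gpr(rule) if rule else None,
            )
        )

    mfbc = sb.getPlugin("fbc")
    if mfbc is not None and mfbc.getNumObjectives() > 0:
        obj = mfbc.getActiveObjective() or mfbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            model.objective_reaction_id = obj.getFluxObjective(0).getReaction()
    return model
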