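"""Loading, validation and interrogation of constraint-based metabolic models.

The in-memory representation is a :class:`cobra.Model`.  Two on-disk dialects
are supported:

* SBML Level 3 with the ``fbc`` package (bounds + gene-protein-reaction rules),
  the community-standard interchange format, read and written through cobrapy.
  Pathway ("subsystem") labels travel as SBML groups.
* A flat JSON dialect meant for small, human-readable, diff-able fixtures::

      {"metabolites": [{"id": "glu_c", "compartment": "c"}, ...],
       "reactions":   [{"id": "R1", "stoich": {"glu_c": -1, "akg_c": 1},
                        "lb": 0.0, "ub": 1000.0, "gpr": "gA and gB",
                        "subsystem": "TCA cycle", "external_id": null}, ...],
       "biomass": "BIOMASS"}

Reversibility is encoded solely by bounds (reversible iff lb < 0 < ub).
Uptake on an exchange reaction (a reaction touching exactly one metabolite,
written ``met_e <-> nothing``) is a negative flux; an uptake rate ``r`` is
imposed as ``lower_bound = -r``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

import cobra
from cobra import Model, Reaction, Metabolite
from cobra.core.gene import GPR

__all__ = [
    "ModelError",
    "ModelValidationError",
    "GPRError",
    "read_model",
    "write_model",
    "validate_model",
    "exchange_reaction_ids",
    "biomass_reaction_id",
    "parse_gpr",
    "genes_for_reactions",
    "flip_reaction",
]


class ModelError(Exception):
    """Base class for model I/O and validation failures."""


class ModelValidationError(ModelError):
    """An invariant of the metabolic model is violated."""


class GPRError(ModelError):
    """A gene-protein-reaction rule failed to parse."""


# ---------------------------------------------------------------------------
# GPR handling
# ---------------------------------------------------------------------------

def parse_gpr(rule: str) -> frozenset[str]:
    """Parse a boolean GPR string (``and``/``or``, parentheses) into its gene set.

    An empty rule yields the empty set.  Raises :class:`GPRError` on a
    malformed expression instead of silently returning an empty rule.
    """
    if not rule or not rule.strip():
        return frozenset()
    with warnings.catch_warnings():
        warnings.simplefilter("error", SyntaxWarning)
        try:
            return frozenset(GPR.from_string(rule).genes)
        except (SyntaxWarning, SyntaxError, TypeError) as exc:
            raise GPRError(f"malformed GPR rule {rule!r}: {exc}") from exc


def genes_for_reactions(model: Model, reaction_ids: Iterable[str]) -> set[str]:
    """Union of gene ids appearing in the GPR rules of the named reactions.

    Reactions with an empty GPR contribute nothing.  Unknown reaction ids raise
    ``KeyError``.
    """
    genes: set[str] = set()
    for rid in reaction_ids:
        rxn = model.reactions.get_by_id(rid)  # KeyError if absent
        genes |= parse_gpr(rxn.gene_reaction_rule)
    return genes


# ---------------------------------------------------------------------------
# Structure queries
# ---------------------------------------------------------------------------

def exchange_reaction_ids(model: Model) -> set[str]:
    """Reactions touching exactly one metabolite (boundary uptake/secretion).

    The biomass (objective) reaction is excluded even when written as a pure
    drain: it models macromolecule assembly, not nutrient exchange.
    """
    return {
        r.id
        for r in model.reactions
        if len(r.metabolites) == 1 and not r.objective_coefficient
    }


def biomass_reaction_id(model: Model) -> str:
    """Id of the (single) reaction carrying the objective coefficient."""
    objs = [r.id for r in model.reactions if r.objective_coefficient]
    if len(objs) != 1:
        raise ModelValidationError(
            f"expected exactly one objective (biomass) reaction, found {objs!r}"
        )
    return objs[0]


def validate_model(model: Model) -> Model:
    """Check the structural invariants; return the model on success.

    * every reaction has ``lower_bound <= upper_bound``;
    * every GPR parses;
    * a single biomass (objective) reaction exists and consumes at least one
      metabolite.
    """
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
        parse_gpr(rxn.gene_reaction_rule)
    bid = biomass_reaction_id(model)
    biomass = model.reactions.get_by_id(bid)
    if not any(coef < 0 for coef in biomass.metabolites.values()):
        raise ModelValidationError(
            f"biomass reaction {bid!r} has no substrate"
        )
    return model


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in {".xml", ".sbml"}:
        return "sbml"
    if path.suffix.lower() == ".json":
        return "tabular_json"
    raise ModelError(f"cannot infer model dialect from {path.name!r}")


def read_model(path: str | Path, dialect: str | None = None) -> Model:
    """Read and validate a model in SBML or the tabular JSON dialect."""
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        model = cobra.io.read_sbml_model(str(path))
        _subsystems_from_groups(model)
    elif dialect == "tabular_json":
        model = _read_tabular_json(path)
    else:
        raise ModelError(f"unknown model dialect {dialect!r}")
    return validate_model(model)


def write_model(model: Model, path: str | Path, dialect: str | None = None) -> Path:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        _groups_from_subsystems(model)
        cobra.io.write_sbml_model(model, str(path))
    elif dialect == "tabular_json":
        _write_tabular_json(model, path)
    else:
        raise ModelError(f"unknown model dialect {dialect!r}")
    return path


def _read_tabular_json(path: Path) -> Model:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"malformed JSON model {path.name}: {exc}") from exc
    for key in ("metabolites", "reactions", "biomass"):
        if key not in doc:
            raise ModelError(f"model {path.name} lacks required key {key!r}")
    model = Model(path.stem)
    mets = {}
    for m in doc["metabolites"]:
        mets[m["id"]] = Metabolite(m["id"], compartment=m.get("compartment"))
    model.add_metabolites(list(mets.values()))
    reactions = []
    for r in doc["reactions"]:
        rxn = Reaction(r["id"])
        lb, ub = float(r["lb"]), float(r["ub"])
        if lb > ub:
            raise ModelValidationError(
                f"reaction {r['id']!r}: lower_bound {lb} > upper_bound {ub}"
            )
        rxn.lower_bound = lb
        rxn.upper_bound = ub
        rxn.subsystem = r.get("subsystem", "") or ""
        reactions.append((rxn, r))
    model.add_reactions([rx for rx, _ in reactions])
    for rxn, r in reactions:
        try:
            rxn.add_metabolites({mets[mid]: float(c) for mid, c in r["stoich"].items()})
        except KeyError as exc:
            raise ModelError(
                f"reaction {r['id']!r} references undeclared metabolite {exc.args[0]!r}"
            ) from exc
        gpr = r.get("gpr", "") or ""
        parse_gpr(gpr)  # raise before mutating the model with a bad rule
        rxn.gene_reaction_rule = gpr
        if r.get("external_id"):
            rxn.annotation["external_id"] = r["external_id"]
    bid = doc["biomass"]
    if bid not in model.reactions:
        raise ModelValidationError(f"biomass reaction {bid!r} not in model")
    model.objective = bid
    return model


def _write_tabular_json(model: Model, path: Path) -> None:
    doc = {
        "metabolites": [
            {"id": m.id, "compartment": m.compartment} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": {m.id: float(c) for m, c in sorted(r.metabolites.items(),
                                                             key=lambda kv: kv[0].id)},
                "lb": float(r.lower_bound),
                "ub": float(r.upper_bound),
                "gpr": r.gene_reaction_rule,
                "subsystem": r.subsystem or "",
                "external_id": r.annotation.get("external_id"),
            }
            for r in model.reactions
        ],
        "biomass": biomass_reaction_id(model),
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _subsystems_from_groups(model: Model) -> None:
    # SBML carries pathway labels as groups; mirror them onto reaction.subsystem
    for group in getattr(model, "groups", []):
        for member in group.members:
            if isinstance(member, Reaction) and not member.subsystem:
                member.subsystem = group.name or group.id


def _groups_from_subsystems(model: Model) -> None:
    from cobra.core.group import Group

    existing = {g.id for g in model.groups}
    by_sub: dict[str, list[Reaction]] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            by_sub.setdefault(rxn.subsystem, []).append(rxn)
    new = []
    for i, (sub, members) in enumerate(sorted(by_sub.items())):
        gid = f"g{i + 1}"
        if gid in existing:
            continue
        grp = Group(gid, name=sub, members=members, kind="partonomy")
        new.append(grp)
    if new:
        model.add_groups(new)


def flip_reaction(model: Model, reaction_id: str) -> None:
    """Rewrite a reaction in the opposite direction (equivalent network).

    Negates all stoichiometric coefficients and maps bounds
    ``(lb, ub) -> (-ub, -lb)``.  Any feasible flux ``v`` of the original maps
    to ``-v``; optima of downstream analyses are unchanged.
    """
    rxn = model.reactions.get_by_id(reaction_id)
    lb, ub = rxn.lower_bound, rxn.upper_bound
    rxn.bounds = (-1000000.0, 1000000.0)  # avoid transient bound violation
    rxn.add_metabolites({m: -2 * c for m, c in rxn.metabolites.items()})
    rxn.bounds = (-ub, -lb)
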