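"""Readers and writers: SBML models, tabular stoichiometry, ECM tables.

External-metabolite inference from SBML follows constraint-based modelling
conventions: a species is external iff it carries boundaryCondition=true or
it participates in an exchange reaction (a reaction whose stoichiometry is
nonzero for exactly one species).  The direction of an external metabolite is
read off the exchange reaction's orientation, its reversibility flag and,
when present, its fbc flux bounds.  Exchange pseudo-reactions are removed
from the returned network — external metabolites are not balanced, so a
boundary transporter carries no information for conversion analysis.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path
from typing import Mapping

from ._rational import frac
from .network import (
    Direction,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
)


class FormatError(ValueError):
    """Unparseable input file."""


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _species_stoich(reaction) -> dict[str, Fraction]:
    stoich: dict[str, Fraction] = {}
    for ref in reaction.getListOfReactants():
        stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) - frac(
            ref.getStoichiometry()
        )
    for ref in reaction.getListOfProducts():
        stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + frac(
            ref.getStoichiometry()
        )
    return {k: v for k, v in stoich.items() if v != 0}


def _bound_value(model, reaction, which: str):
    fbc = reaction.getPlugin("fbc")
    if fbc is None:
        return None
    pid = fbc.getLowerFluxBound() if which == "lower" else fbc.getUpperFluxBound()
    if not pid:
        return None
    param = model.getParameter(pid)
    return param.getValue() if param is not None else None


def read_sbml(
    path: str | Path,
    external_policy: Mapping[str, str] | None = None,
) -> MetabolicNetwork:
    """Read an SBML L2/L3 model into an exact-rational network.

    ``external_policy`` optionally overrides the inferred annotation per
    metabolite id: values are "input", "output", "both" or "internal".
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise FormatError(f"unreadable SBML file: {path}")
    model = doc.getModel()

    boundary = {
        sp.getId() for sp in model.getListOfSpecies() if sp.getBoundaryCondition()
    }
    names = {sp.getId(): sp.getName() or "" for sp in model.getListOfSpecies()}
    declared = set(names)

    reactions: list[tuple[str, dict[str, Fraction], bool]] = []
    # external id -> (can_be_consumed_by_network, can_be_produced_by_network)
    ext_dir: dict[str, list[bool]] = {}
    for rxn in model.getListOfReactions():
        stoich = _species_stoich(rxn)
        if not stoich:
            continue
        undeclared = set(stoich) - declared
        if undeclared:
            raise NetworkError(
                f"reaction {rxn.getId()!r} references undeclared species {sorted(undeclared)}"
            )
        if len(stoich) == 1:
            # exchange reaction: infer external status + direction, then drop
            (mid, coeff), = stoich.items()
            lb = _bound_value(model, rxn, "lower")
            ub = _bound_value(model, rxn, "upper")
            forward = ub is None or ub > 0
            backward = rxn.getReversible() if lb is None else lb < 0
            # coeff < 0: written as "X ->" (forward flux exports X)
            exports = (coeff < 0 and forward) or (coeff > 0 and backward)
            imports = (coeff > 0 and forward) or (coeff < 0 and backward)
            d = ext_dir.setdefault(mid, [False, False])
            d[0] = d[0] or imports
            d[1] = d[1] or exports
            continue
        reactions.append((rxn.getId(), stoich, rxn.getReversible()))

    for mid in boundary:
        ext_dir.setdefault(mid, [True, True])

    policy = dict(external_policy or {})
    metabolites: list[Metabolite] = []
    for sp in model.getListOfSpecies():
        mid = sp.getId()
        override = policy.pop(mid, None)
        if override == "internal":
            external, direction = False, None
        elif override is not None:
            external, direction = True, Direction(override)
        elif mid in ext_dir:
            imports, exports = ext_dir[mid]
            external = True
            if imports and exports:
                direction = Direction.BOTH
            elif exports:
                direction = Direction.OUTPUT
            else:
                direction = Direction.INPUT
        else:
            external, direction = False, None
        metabolites.append(
            Metabolite(
                id=mid,
                name=names[mid],
                is_internal=not external,
                direction=direction,
            )
        )
    if policy:
        raise NetworkError(f"external_policy names unknown metabolites: {sorted(policy)}")

    used = set()
    for _, stoich, _ in reactions:
        used |= set(stoich)
    metabolites = [m for m in metabolites if m.id in used or not m.is_internal]

    metadata: dict = {"source": str(path)}
    biomass = _objective_product(model, dict((r[0], r[1]) for r in reactions))
    if biomass is not None:
        metadata["biomass"] = biomass

    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=[
            Reaction(id=rid, stoichiometry=st, reversible=rev)
            for rid, st, rev in reactions
        ],
        metadata=metadata,
    )


def _objective_product(model, stoich_by_rid) -> str | None:
    """Product of the fbc active-objective reaction, if the model has one."""
    fbc = model.getPlugin("fbc")
    if fbc is None or fbc.getNumObjectives() == 0:
        return None
    obj = fbc.getActiveObjective() or fbc.getObjective(0)
    if obj is None or obj.getNumFluxObjectives() == 0:
        return None
    rid = obj.getFluxObjective(0).getReaction()
    stoich = stoich_by_rid.get(rid)
    if not stoich:
        return None
    products = [(c, m) for m, c in stoich.items() if c > 0]
    return max(products)[1] if products else None


# ---------------------------------------------------------------------------
# Tabular format
# ---------------------------------------------------------------------------

def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_table_network(
    matrix_file: str | Path, annotations_file: str | Path
) -> MetabolicNetwork:
    """Read a network from a stoichiometry table plus an annotations table.

    Matrix: first column "metabolite_id", remaining columns one per reaction,
    entries exact rationals ("-1", "1/2", "0.25").  Annotations: columns
    kind (metabolite|reaction), id, is_internal, direction, reversible.
    """
    matrix_file, annotations_file = Path(matrix_file), Path(annotations_file)
    with open(matrix_file, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=_delimiter(matrix_file)) if r]
    if not rows or rows[0][:1] != ["metabolite_id"]:
        raise FormatError("matrix file must start with a 'metabolite_id' header column")
    reaction_ids = rows[0][1:]
    met_ids: list[str] = []
    coeffs: dict[str, dict[str, Fraction]] = {rid: {} for rid in reaction_ids}
    for row in rows[1:]:
        if len(row) != len(reaction_ids) + 1:
            raise FormatError(f"matrix row for {row[0]!r} has wrong width")
        mid = row[0]
        met_ids.append(mid)
        for rid, cell in zip(reaction_ids, row[1:]):
            try:
                val = frac(cell)
            except (ValueError, ZeroDivisionError) as e:
                raise FormatError(f"bad coefficient {cell!r} for {mid}/{rid}") from e
            if val != 0:
                coeffs[rid][mid] = val

    met_ann: dict[str, dict] = {}
    rxn_ann: dict[str, dict] = {}
    with open(annotations_file, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(annotations_file))
        for rec in reader:
            kind = (rec.get("kind") or "").strip()
            if kind == "metabolite":
                met_ann[rec["id"]] = rec
            elif kind == "reaction":
                rxn_ann[rec["id"]] = rec
            elif kind:
                raise FormatError(f"unknown annotation kind {kind!r}")

    missing = set(met_ids) ^ set(met_ann)
    if missing:
        raise FormatError(f"annotation/matrix metabolite mismatch: {sorted(missing)}")
    if set(reaction_ids) - set(rxn_ann):
        raise FormatError("annotations missing for some reactions")

    def truthy(s: str | None) -> bool:
        return (s or "").strip().lower() in {"1", "true", "yes"}

    metabolites = []
    for mid in met_ids:
        rec = met_ann[mid]
        internal = truthy(rec.get("is_internal"))
        direction = None if internal else Direction((rec.get("direction") or "").strip())
        metabolites.append(
            Metabolite(id=mid, name=rec.get("name") or "", is_internal=internal,
                       direction=direction)
        )
    reactions = [
        Reaction(
            id=rid,
            stoichiometry=coeffs[rid],
            reversible=truthy(rxn_ann[rid].get("reversible")),
        )
        for rid in reaction_ids
    ]
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions,
                            metadata={"source": str(matrix_file)})


def write_table_network(
    net: MetabolicNetwork, matrix_file: str | Path, annotations_file: str | Path
) -> None:
    """Inverse of read_table_network (exact round trip)."""
    matrix_file, annotations_file = Path(matrix_file), Path(annotations_file)
    delim = _delimiter(matrix_file)
    with open(matrix_file, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["metabolite_id"] + net.reaction_ids)
        for m in net.metabolites:
            w.writerow([m.id] + [str(r.stoichiometry.get(m.id, 0)) for r in net.reactions])
    with open(annotations_file, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=_delimiter(annotations_file))
        w.writerow(["kind", "id", "name", "is_internal", "direction", "reversible"])
        for m in net.metabolites:
            w.writerow(
                ["metabolite", m.id, m.name, str(m.is_internal).lower(),
                 m.direction.value if m.direction else "", ""]
            )
        for r in net.reactions:
            w.writerow(["reaction", r.id, "", "", "", str(r.reversible).lower()])


# ---------------------------------------------------------------------------
# ECM tables
# ---------------------------------------------------------------------------

def write_ecms(ecms, path: str | Path, format: str = "csv", rendering: str = "rational") -> None:
    """Write an ECMSet as a delimited table, one row per reported metabolite.

    Header comment lines record the normalization rule and hidden/tagged
    entities; coefficients render as exact "p/q" strings by default or as
    floats with ``rendering="float"``.
    """
    if format not in {"csv", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    delim = "\t" if format == "tsv" else ","
    path = Path(path)

    def render(x: Fraction) -> str:
        return str(float(x)) if rendering == "float" else str(x)

    with open(path, "w", newline="") as fh:
        fh.write(f"# normalization: {ecms.normalization}\n")
        if ecms.hidden:
            fh.write(f"# hidden: {','.join(ecms.hidden)}\n")
        if ecms.tags:
            fh.write(
                "# tags: "
                + ",".join(f"{t}={r}" for t, r in sorted(ecms.tags.items()))
                + "\n"
            )
        w = csv.writer(fh, delimiter=delim)
        labels = [f"ecm_{k + 1:04d}" for k in range(len(ecms.conversions))]
        w.writerow(["metabolite_id"] + labels)
        for mid in ecms.metabolite_ids:
            w.writerow([mid] + [render(c[mid]) for c in ecms.conversions])
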