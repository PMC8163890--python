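"""Constraint-based strain models: metabolites, reactions, media, JSON I/O.

Conventions (COBRA-style):

* every exchange reaction touches exactly one extracellular metabolite with
  coefficient -1, so *negative* flux is uptake and *positive* flux is secretion;
* uptake limits live in a :class:`Medium`; applying a medium sets each exchange
  lower bound to ``-limit`` (0 when the metabolite is absent from the medium)
  and never touches secretion (upper) bounds;
* exchange reaction ids conventionally start with ``EX_``;
* metabolite ids conventionally end in ``_c`` (cytosol) or ``_e`` (extracellular).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

CYTOSOL = "cytosol"
EXTRACELLULAR = "extracellular"
COMPARTMENTS = (CYTOSOL, EXTRACELLULAR)

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates the schema or a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = CYTOSOL

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    is_biomass: bool = False

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ModelValidationError(
                f"reaction {self.id!r}: zero stoichiometric coefficients listed"
            )


@dataclass
class StrainModel:
    strain_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str

    def __post_init__(self):
        validate_model(self)

    @property
    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "StrainModel":
        return StrainModel(
            strain_id=self.strain_id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            biomass_reaction_id=self.biomass_reaction_id,
        )


def validate_model(model: StrainModel) -> None:
    met_ids = [m.id for m in model.metabolites]
    if len(met_ids) != len(set(met_ids)):
        dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
        raise ModelValidationError(f"duplicate metabolite ids: {dup}")
    rxn_ids = [r.id for r in model.reactions]
    if len(rxn_ids) != len(set(rxn_ids)):
        dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        raise ModelValidationError(f"duplicate reaction ids: {dup}")
    known = set(met_ids)
    comp = {m.id: m.compartment for m in model.metabolites}
    for r in model.reactions:
        unknown = sorted(set(r.stoichiometry) - known)
        if unknown:
            raise ModelValidationError(
                f"reaction {r.id!r} references unknown metabolites: {unknown}"
            )
        if r.is_exchange:
            ext = [m for m in r.stoichiometry if comp[m] == EXTRACELLULAR]
            if len(r.stoichiometry) != 1 or len(ext) != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id!r} must touch exactly one "
                    f"extracellular metabolite"
                )
    biomass = [r for r in model.reactions if r.is_biomass]
    if not model.biomass_reaction_id:
        raise ModelValidationError("missing biomass_reaction_id")
    if [r.id for r in biomass] != [model.biomass_reaction_id]:
        raise ModelValidationError(
            f"biomass reaction {model.biomass_reaction_id!r} must exist and be "
            f"the unique is_biomass reaction (found {[r.id for r in biomass]})"
        )


@dataclass
class Medium:
    """Maximum uptake flux per extracellular metabolite (all limits >= 0)."""

    uptake: dict[str, float]
    name: str = "medium"

    def __post_init__(self):
        bad = {m: v for m, v in self.uptake.items() if v < 0}
        if bad:
            raise ModelValidationError(f"negative uptake limits: {bad}")

    def without(self, *metabolite_ids: str) -> "Medium":
        """A copy of the medium with the given compounds removed."""
        keep = {m: v for m, v in self.uptake.items() if m not in metabolite_ids}
        return Medium(keep, name=f"{self.name} -{','.join(metabolite_ids)}")

    def with_compound(self, metabolite_id: str, limit: float) -> "Medium":
        new = dict(self.uptake)
        new[metabolite_id] = limit
        return Medium(new, name=self.name)


def apply_medium(model: StrainModel, medium: Medium) -> StrainModel:
    """Return a copy with exchange lower bounds set from the medium.

    Exchange lower bound becomes ``-limit`` for metabolites in the medium and 0
    otherwise; secretion (upper bounds) is unchanged.  Medium compounds with no
    exchange reaction in the model trigger a warning and are ignored.
    """
    exchanged = set()
    new_reactions = []
    for r in model.reactions:
        if not r.is_exchange:
            new_reactions.append(r)
            continue
        met = next(iter(r.stoichiometry))
        exchanged.add(met)
        limit = medium.uptake.get(met, 0.0)
        new_reactions.append(replace(r, lower_bound=-limit))
    missing = sorted(set(medium.uptake) - exchanged)
    if missing:
        warnings.warn(
            f"medium {medium.name!r} names metabolites with no exchange "
            f"reaction in {model.strain_id!r}: {missing}",
            stacklevel=2,
        )
    return StrainModel(
        strain_id=model.strain_id,
        metabolites=list(model.metabolites),
        reactions=new_reactions,
        biomass_reaction_id=model.biomass_reaction_id,
    )


@dataclass
class UniversalReactionDB:
    """Reaction database for gapfilling, with per-reaction penalties (> 0)."""

    reactions: list[Reaction]
    metabolites: list[Metabolite] = field(default_factory=list)
    penalties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for r in self.reactions:
            self.penalties.setdefault(r.id, 1.0)
        bad = {r: p for r, p in self.penalties.items() if p <= 0}
        if bad:
            raise ModelValidationError(f"non-positive gapfill penalties: {bad}")


# ---------------------------------------------------------------------------
# JSON I/O (canonical key order so write ∘ read is byte-stable)

_SCHEMA_KEYS = {"strain_id", "metabolites", "reactions", "biomass_reaction_id"}


def model_to_dict(model: StrainModel) -> dict:
    return {
        "strain_id": model.strain_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "is_exchange": r.is_exchange,
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
        "biomass_reaction_id": model.biomass_reaction_id,
    }


def model_from_dict(data: dict) -> StrainModel:
    if not isinstance(data, dict):
        raise ModelValidationError("model document must be a JSON object")
    missing = sorted(_SCHEMA_KEYS - set(data))
    extra = sorted(set(data) - _SCHEMA_KEYS)
    if missing or extra:
        raise ModelValidationError(
            f"model schema violation: missing keys {missing}, unknown keys {extra}"
        )
    mets = [
        Metabolite(id=m["id"], name=m.get("name", ""), compartment=m["compartment"])
        for m in data["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lb"]),
            upper_bound=float(r["ub"]),
            is_exchange=bool(r.get("is_exchange", r["id"].startswith("EX_"))),
            is_biomass=bool(r.get("is_biomass", False)),
        )
        for r in data["reactions"]
    ]
    return StrainModel(
        strain_id=data["strain_id"],
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=data["biomass_reaction_id"],
    )


def write_model(model: StrainModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


def read_model(path) -> StrainModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def load_medium(path) -> Medium:
    """Read a medium from YAML (mapping) or TSV (metabolite_id <tab> limit)."""
    import yaml

    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        name = doc.get("name", "medium") if isinstance(doc, dict) else "medium"
        uptake = doc.get("uptake", doc) if isinstance(doc, dict) else doc
        return Medium({str(k): float(v) for k, v in uptake.items()}, name=name)
    uptake = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ModelValidationError(f"{path}:{i}: expected 2 columns")
            uptake[parts[0]] = float(parts[1])
    return Medium(uptake)
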