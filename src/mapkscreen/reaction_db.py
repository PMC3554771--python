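"""Reaction-based model store.

Unlike model-based repositories, where one complete model is one opaque
record, the unit record here is a single reaction.  Species names from
different models are unified through an alias table mapping per-model
synonyms to canonical ids; reactions whose canonicalized participants and
rate law coincide are stored once and shared between models.  This makes
cross-model queries (which models contain this reaction? which models
overlap with this one?) and model comparison direct set operations.

Storage is a flat JSON document — the contribution is the data structure,
not a DBMS.  Rate laws that are not a plain mass-action constant are kept
as opaque text and compared after whitespace normalization.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ReactionRecord", "ModelRecord", "ReactionDB",
    "AliasConflictError", "NotFoundError",
]


class AliasConflictError(ValueError):
    """One synonym maps to two different canonical species ids."""


class NotFoundError(KeyError):
    """Unknown reaction or model id."""


def _norm_law(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: participants by species id, with a rate-law descriptor.

    ``rate_law`` is either a mass-action constant name or opaque expression
    text.  ``reactants`` / ``products`` map species ids to stoichiometries;
    ``modifiers`` are catalytic participants that are not consumed.
    """

    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    modifiers: tuple[str, ...]
    rate_law: str
    annotation: str = ""

    @classmethod
    def create(cls, reactants: dict, products: dict, rate_law: str,
               modifiers=(), annotation: str = "") -> "ReactionRecord":
        return cls(tuple(sorted((str(k), float(v)) for k, v in reactants.items())),
                   tuple(sorted((str(k), float(v)) for k, v in products.items())),
                   tuple(sorted(str(m) for m in modifiers)),
                   _norm_law(rate_law), annotation)

    def canonical_key(self, resolve) -> str:
        """Dedup key: sorted canonical participant multiset + rate-law hash."""
        parts = (
            tuple(sorted((resolve(s), c) for s, c in self.reactants)),
            tuple(sorted((resolve(s), c) for s, c in self.products)),
            tuple(sorted(resolve(s) for s in self.modifiers)),
            _norm_law(self.rate_law),
        )
        return hashlib.sha1(repr(parts).encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"reactants": dict(self.reactants),
                "products": dict(self.products),
                "modifiers": list(self.modifiers),
                "rate_law": self.rate_law, "annotation": self.annotation}

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionRecord":
        return cls.create(d["reactants"], d["products"], d["rate_law"],
                          d.get("modifiers", ()), d.get("annotation", ""))


@dataclass
class ModelRecord:
    """A model is an ordered list of reaction ids plus metadata."""

    model_id: str
    reaction_ids: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


class ReactionDB:
    """In-memory reaction store with JSON persistence.

    ``aliases`` maps synonym -> canonical species id.  Canonical ids map to
    themselves implicitly.  Synonym sets of different canonical ids must be
    disjoint (enforced at registration).
    """

    def __init__(self):
        self.reactions: dict[str, ReactionRecord] = {}
        self.models: dict[str, ModelRecord] = {}
        self.aliases: dict[str, str] = {}

    # -- alias handling ----------------------------------------------------
    def resolve(self, species: str) -> str:
        return self.aliases.get(species, species)

    def add_aliases(self, aliases: dict[str, str]) -> None:
        """Merge synonym -> canonical mappings, rejecting conflicts."""
        for syn, canon in aliases.items():
            existing = self.aliases.get(syn)
            if existing is not None and existing != canon:
                raise AliasConflictError(
                    f"synonym {syn!r} maps to both {existing!r} and {canon!r}")
        self.aliases.update(aliases)

    # -- registration ------------------------------------------------------
    def register_model(self, model: ModelRecord,
                       reactions: list[ReactionRecord],
                       aliases: dict[str, str] | None = None) -> list[str]:
        """Store a model, deduplicating its reactions against the store.

        Returns the model's reaction ids (shared ids where a reaction with
        the same canonicalized participants and rate law already exists).
        Registering the same model id twice replaces its reaction list but
        creates no duplicate reaction records.
        """
        if aliases:
            self.add_aliases(aliases)
        ids: list[str] = []
        seen_in_model: set[str] = set()
        for rec in reactions:
            key = rec.canonical_key(self.resolve)
            if key in seen_in_model:
                continue  # within-model duplicate collapses
            seen_in_model.add(key)
            if key not in self.reactions:
                self.reactions[key] = rec
            ids.append(key)
        self.models[model.model_id] = ModelRecord(
            model.model_id, ids, dict(model.metadata))
        return ids

    # -- queries -----------------------------------------------------------
    def query_related(self, target: str) -> dict:
        """Related records for a reaction id or a model id.

        For a reaction id: all models containing it.  For a model id: all
        other models sharing at least one reaction, with the shared ids.
        """
        if target in self.reactions:
            return {"kind": "reaction",
                    "models": [m.model_id for m in self.models.values()
                               if target in m.reaction_ids]}
        if target in self.models:
            mine = set(self.models[target].reaction_ids)
            related = {}
            for other in self.models.values():
                if other.model_id == target:
                    continue
                shared = sorted(mine & set(other.reaction_ids))
                if shared:
                    related[other.model_id] = shared
            return {"kind": "model", "related": related}
        raise NotFoundError(f"no reaction or model with id {target!r}")

    def compare_models(self, a: str, b: str) -> dict[str, list[str]]:
        """Partition the union of two models' reactions: shared/only_a/only_b."""
        for mid in (a, b):
            if mid not in self.models:
                raise NotFoundError(f"unknown model {mid!r}")
        ra, rb = (set(self.models[a].reaction_ids),
                  set(self.models[b].reaction_ids))
        return {"shared": sorted(ra & rb),
                "only_a": sorted(ra - rb),
                "only_b": sorted(rb - ra)}

    # -- persistence and interchange ----------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "aliases": self.aliases,
            "reactions": {k: r.to_dict() for k, r in self.reactions.items()},
            "models": {m.model_id: {"reactions": m.reaction_ids,
                                    "metadata": m.metadata}
                       for m in self.models.values()},
        }, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ReactionDB":
        data = json.loads(Path(path).read_text())
        db = cls()
        db.aliases = dict(data.get("aliases", {}))
        for key, rd in data.get("reactions", {}).items():
            db.reactions[key] = ReactionRecord.from_dict(rd)
        for mid, md in data.get("models", {}).items():
            db.models[mid] = ModelRecord(mid, list(md["reactions"]),
                                         dict(md.get("metadata", {})))
        return db

    def export_model(self, model_id: str) -> dict:
        """Native interchange format: one reaction per record."""
        if model_id not in self.models:
            raise NotFoundError(f"unknown model {model_id!r}")
        m = self.models[model_id]
        return {"model_id": m.model_id, "metadata": m.metadata,
                "reactions": [self.reactions[rid].to_dict()
                              for rid in m.reaction_ids]}

    def import_model(self, record: dict,
                     aliases: dict[str, str] | None = None) -> list[str]:
        recs = [ReactionRecord.from_dict(r) for r in record["reactions"]]
        model = ModelRecord(record["model_id"], [],
                            dict(record.get("metadata", {})))
        return self.register_model(model, recs, aliases)


def model_from_sbml(db: ReactionDB, source, model_id: str | None = None,
                    aliases: dict[str, str] | None = None) -> list[str]:
    """Register an SBML document's reactions (species referenced by name)."""
    from .sbml import read_sbml
    doc = read_sbml(source)
    name_of = lambda sid: doc.species.get(sid, sid)  # noqa: E731
    recs = [ReactionRecord.create(
        {name_of(s): c for s, c in rx.reactants.items()},
        {name_of(s): c for s, c in rx.products.items()},
        rx.rate_law or rx.id,
        modifiers=[name_of(s) for s in rx.modifiers],
        annotation=rx.name) for rx in doc.reactions]
    model = ModelRecord(model_id or doc.id, [], {"source": "sbml"})
    return db.register_model(model, recs, aliases)
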