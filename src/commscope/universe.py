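"""Reaction universe: the global bank of reactions and compounds.

The universe is the catalogue of enzymatic reactions (KEGG-style
accessions, EC labels, qualitative substrate/product sets, reversibility
flags) against which all graph construction and expansion feasibility is
checked, together with pathway->compound and module->KO membership maps
used for enrichment.  Stoichiometry and mass balance are deliberately
absent: the downstream methods are purely set/graph based.

File dialects
-------------
TSV: a reaction table with columns ``reaction_id``, ``ec_list``
(semicolon-separated), ``substrates``, ``products`` (semicolon-separated
compound ids) and ``reversible`` ({0,1}); optional side tables
``pathways.tsv`` / ``modules.tsv`` with columns (``pathway_id``,
``member_id``) and (``module_id``, ``ko_id``); optional ``compounds.tsv``
with (``compound_id``, ``name``).  JSON: one document carrying the same
fields.  The flat dialect keeps the tool independent of any particular
database snapshot.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

REACTION_COLUMNS = ["reaction_id", "ec_list", "substrates", "products", "reversible"]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ReferentialIntegrityError(ValueError):
    """A reaction references a compound id absent from the universe."""


@dataclass(frozen=True)
class Compound:
    """A metabolite node, identified by its accession (e.g. ``C17954``)."""

    id: str
    name: str = ""
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("compound id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """An enzymatic reaction: EC labels plus qualitative substrate/product sets.

    ``substrates`` and ``products`` may overlap (catalytic participants)
    but neither may be empty.  A reaction is considered available to an
    enzyme set if ANY of its ECs is present: one annotated catalyst
    suffices for feasibility.
    """

    id: str
    ecs: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("reaction id must be non-empty")
        if not self.ecs:
            raise SchemaError(f"reaction {self.id}: at least one EC required")
        if not self.substrates or not self.products:
            raise SchemaError(
                f"reaction {self.id}: substrate and product sets must be non-empty"
            )


@dataclass
class ReactionUniverse:
    """The reaction bank: compounds, reactions and membership maps."""

    compounds: dict[str, Compound]
    reactions: dict[str, Reaction]
    pathway_map: dict[str, frozenset[str]] = field(default_factory=dict)
    module_map: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        missing: dict[str, set[str]] = {}
        for rxn in self.reactions.values():
            unknown = (rxn.substrates | rxn.products) - self.compounds.keys()
            if unknown:
                missing[rxn.id] = unknown
        if missing:
            detail = "; ".join(
                f"{rid}: {sorted(ids)}" for rid, ids in sorted(missing.items())
            )
            raise ReferentialIntegrityError(
                f"reactions reference unknown compounds ({detail})"
            )
        for pid, members in self.pathway_map.items():
            stray = members - self.compounds.keys()
            if stray:
                logger.warning(
                    "pathway %s: dropping %d members absent from universe",
                    pid,
                    len(stray),
                )
                self.pathway_map[pid] = frozenset(members - stray)
        # compound->pathway annotations are derived from pathway_map, the
        # single source of truth, so they survive any construction route
        inv: dict[str, set[str]] = {}
        for pid, members in self.pathway_map.items():
            for cid in members:
                inv.setdefault(cid, set()).add(pid)
        for cid, compound in self.compounds.items():
            want = frozenset(inv.get(cid, ()))
            if compound.pathways != want:
                self.compounds[cid] = replace(compound, pathways=want)

    @property
    def ec_index(self) -> dict[str, frozenset[str]]:
        """EC accession -> ids of reactions it catalyses (exact inverse of Reaction.ecs)."""
        idx: dict[str, set[str]] = {}
        for rxn in self.reactions.values():
            for ec in rxn.ecs:
                idx.setdefault(ec, set()).add(rxn.id)
        return {ec: frozenset(rids) for ec, rids in idx.items()}

    @property
    def all_ecs(self) -> frozenset[str]:
        return frozenset(ec for rxn in self.reactions.values() for ec in rxn.ecs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionUniverse):
            return NotImplemented
        return (
            self.compounds == other.compounds
            and self.reactions == other.reactions
            and self.pathway_map == other.pathway_map
            and self.module_map == other.module_map
        )


def _split(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    return frozenset(tok for tok in str(cell).split(";") if tok)


def _read_membership(path: Path, key_col: str, val_col: str) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key_col, val_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    out: dict[str, set[str]] = {}
    for key, val in zip(df[key_col], df[val_col]):
        out.setdefault(key, set()).add(val)
    return {k: frozenset(v) for k, v in out.items()}


def load_universe(
    path: str | os.PathLike,
    format: str | None = None,
    *,
    pathways: str | os.PathLike | None = None,
    modules: str | os.PathLike | None = None,
    compounds: str | os.PathLike | None = None,
    exclude_compounds: Iterable[str] | None = None,
) -> ReactionUniverse:
    """Load and validate a reaction universe from TSV or JSON.

    ``path`` is either a directory containing ``reactions.tsv`` (plus
    optional ``pathways.tsv``, ``modules.tsv``, ``compounds.tsv``), the
    reaction TSV itself, or a JSON document.  ``exclude_compounds``
    names currency metabolites (cofactors such as water or ATP) to drop
    from substrate/product sets at load time; exclusion is logged and a
    reaction left without substrates or products is removed entirely.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "tsv"
    if format == "json":
        universe = _load_json(path)
    elif format == "tsv":
        if path.is_dir():
            rxn_path = path / "reactions.tsv"
            pathways = pathways or (
                path / "pathways.tsv" if (path / "pathways.tsv").exists() else None
            )
            modules = modules or (
                path / "modules.tsv" if (path / "modules.tsv").exists() else None
            )
            compounds = compounds or (
                path / "compounds.tsv" if (path / "compounds.tsv").exists() else None
            )
        else:
            rxn_path = path
        universe = _load_tsv(rxn_path, pathways, modules, compounds)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")
    if exclude_compounds:
        universe = _exclude(universe, frozenset(exclude_compounds))
    return universe


def _load_tsv(rxn_path, pathways, modules, compounds) -> ReactionUniverse:
    df = pd.read_csv(rxn_path, sep="\t", dtype=str)
    for col in REACTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{rxn_path}: missing required column '{col}'")
    reactions: dict[str, Reaction] = {}
    for row in df.itertuples(index=False):
        reactions[row.reaction_id] = Reaction(
            id=row.reaction_id,
            ecs=_split(row.ec_list),
            substrates=_split(row.substrates),
            products=_split(row.products),
            reversible=str(row.reversible) in {"1", "True", "true"},
        )
    names: dict[str, str] = {}
    if compounds is not None:
        cdf = pd.read_csv(compounds, sep="\t", dtype=str)
        if "compound_id" not in cdf.columns:
            raise SchemaError(f"{compounds}: missing required column 'compound_id'")
        name_col = cdf["name"].fillna("") if "name" in cdf.columns else cdf["compound_id"]
        names = dict(zip(cdf["compound_id"], name_col))
    pathway_map = _read_membership(Path(pathways), "pathway_id", "member_id") if pathways else {}
    module_map = _read_membership(Path(modules), "module_id", "ko_id") if modules else {}
    return _assemble(reactions, names, pathway_map, module_map)


def _load_json(path: Path) -> ReactionUniverse:
    with open(path) as fh:
        doc = json.load(fh)
    if "reactions" not in doc:
        raise SchemaError(f"{path}: missing required field 'reactions'")
    reactions = {
        r["id"]: Reaction(
            id=r["id"],
            ecs=frozenset(r["ecs"]),
            substrates=frozenset(r["substrates"]),
            products=frozenset(r["products"]),
            reversible=bool(r.get("reversible", False)),
        )
        for r in doc["reactions"]
    }
    names = {c["id"]: c.get("name", "") for c in doc.get("compounds", [])}
    pathway_map = {k: frozenset(v) for k, v in doc.get("pathways", {}).items()}
    module_map = {k: frozenset(v) for k, v in doc.get("modules", {}).items()}
    return _assemble(reactions, names, pathway_map, module_map)


def _assemble(reactions, names, pathway_map, module_map) -> ReactionUniverse:
    cids: set[str] = set(names)
    for rxn in reactions.values():
        cids |= rxn.substrates | rxn.products
    inv_path: dict[str, set[str]] = {}
    for pid, members in pathway_map.items():
        for cid in members:
            inv_path.setdefault(cid, set()).add(pid)
    compounds = {
        cid: Compound(
            id=cid, name=names.get(cid, ""), pathways=frozenset(inv_path.get(cid, ()))
        )
        for cid in sorted(cids)
    }
    return ReactionUniverse(
        compounds=compounds,
        reactions=reactions,
        pathway_map=dict(pathway_map),
        module_map=dict(module_map),
    )


def _exclude(universe: ReactionUniverse, excluded: frozenset[str]) -> ReactionUniverse:
    logger.info("excluding %d currency compounds from substrate/product sets", len(excluded))
    reactions: dict[str, Reaction] = {}
    for rxn in universe.reactions.values():
        subs = rxn.substrates - excluded
        prods = rxn.products - excluded
        if not subs or not prods:
            logger.warning("reaction %s dropped: only currency compounds on one side", rxn.id)
            continue
        reactions[rxn.id] = Reaction(rxn.id, rxn.ecs, subs, prods, rxn.reversible)
    return _prune(universe, reactions)


def _prune(universe: ReactionUniverse, reactions: dict[str, Reaction]) -> ReactionUniverse:
    keep: set[str] = set()
    for rxn in reactions.values():
        keep |= rxn.substrates | rxn.products
    compounds = {cid: universe.compounds[cid] for cid in sorted(keep)}
    pathway_map = {
        pid: frozenset(m & keep)
        for pid, m in universe.pathway_map.items()
        if m & keep
    }
    return ReactionUniverse(
        compounds=compounds,
        reactions=reactions,
        pathway_map=pathway_map,
        module_map=dict(universe.module_map),
    )


def restrict_to_ecs(universe: ReactionUniverse, ecs: Iterable[str]) -> ReactionUniverse:
    """Sub-universe of reactions catalysed by any EC in ``ecs``.

    Used to build treatment-specific sub-networks from differentially
    abundant enzymes.  Compounds not referenced by any surviving reaction
    are pruned; ECs in the query absent from the universe are logged.
    """
    query = frozenset(ecs)
    unknown = query - universe.all_ecs
    if unknown:
        logger.info("restrict_to_ecs: %d query ECs not in universe", len(unknown))
    reactions = {
        rid: rxn for rid, rxn in universe.reactions.items() if rxn.ecs & query
    }
    return _prune(universe, reactions)


def save_universe(universe: ReactionUniverse, path: str | os.PathLike, format: str = "tsv") -> None:
    """Serialize a universe to the TSV directory dialect or a JSON document."""
    path = Path(path)
    if format == "json":
        doc = {
            "compounds": [
                {"id": c.id, "name": c.name} for c in universe.compounds.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "ecs": sorted(r.ecs),
                    "substrates": sorted(r.substrates),
                    "products": sorted(r.products),
                    "reversible": r.reversible,
                }
                for r in sorted(universe.reactions.values(), key=lambda r: r.id)
            ],
            "pathways": {k: sorted(v) for k, v in sorted(universe.pathway_map.items())},
            "modules": {k: sorted(v) for k, v in sorted(universe.module_map.items())},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
        return
    path.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "reaction_id": r.id,
            "ec_list": ";".join(sorted(r.ecs)),
            "substrates": ";".join(sorted(r.substrates)),
            "products": ";".join(sorted(r.products)),
            "reversible": int(r.reversible),
        }
        for r in sorted(universe.reactions.values(), key=lambda r: r.id)
    ]
    pd.DataFrame(rows, columns=REACTION_COLUMNS).to_csv(
        path / "reactions.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"compound_id": c.id, "name": c.name} for c in universe.compounds.values()]
    ).to_csv(path / "compounds.tsv", sep="\t", index=False)
    prows = [
        {"pathway_id": pid, "member_id": cid}
        for pid, members in sorted(universe.pathway_map.items())
        for cid in sorted(members)
    ]
    pd.DataFrame(prows, columns=["pathway_id", "member_id"]).to_csv(
        path / "pathways.tsv", sep="\t", index=False
    )
    mrows = [
        {"module_id": mid, "ko_id": ko}
        for mid, members in sorted(universe.module_map.items())
        for ko in sorted(members)
    ]
    pd.DataFrame(mrows, columns=["module_id", "ko_id"]).to_csv(
        path / "modules.tsv", sep="\t", index=False
    )
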