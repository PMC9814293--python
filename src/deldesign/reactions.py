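"""Reaction objects: FG-tuple rewrites with heavy-atom bookkeeping.

Reactions operate on FG ids, not molecules.  A *connecting* reaction consumes
one FG on the growing design and one exposed FG on the incoming building
block, optionally emitting new FGs (entry-1/entry-2 semantics).  A
*deprotection* rewrites a single design FG, either with no mass change (Boc
removal) or while installing a scaffold (cyanuric chloride turning a primary
amine into a dichlorotriazine).  Heavy-atom deltas are declared per reaction,
split into a design-side and a BB-side contribution so that the effective
atom count of every building block is well defined; ``scaffold_atoms`` counts
atoms a deprotection adds.  The ``transform`` field carries the reaction
SMARTS used for structure enumeration, and ``enum_index`` groups reactions
that one experimental procedure can realise together (e.g. amidation of
primary and secondary amines).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

CONNECTING = "connecting"
DEPROTECTION = "deprotection"


class ReactionError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    rxn_id: str
    kind: str  # connecting | deprotection
    inputs: tuple[int, ...]  # connecting: (design_fg, bb_fg); deprotection: (design_fg,)
    outputs: tuple[int, ...] = ()
    enum_index: int = 0
    design_side_atom_delta: int = 0
    bb_side_atom_delta: int = 0
    scaffold_atoms: int = 0
    transform: str = ""
    production_status: str = "production"

    def __post_init__(self):
        if self.kind == CONNECTING and len(self.inputs) != 2:
            raise ReactionError(f"{self.rxn_id}: connecting reactions take 2 input FGs")
        if self.kind == DEPROTECTION and len(self.inputs) != 1:
            raise ReactionError(f"{self.rxn_id}: deprotections take 1 input FG")
        if self.kind not in (CONNECTING, DEPROTECTION):
            raise ReactionError(f"{self.rxn_id}: unknown kind {self.kind!r}")
        if self.scaffold_atoms and self.kind != DEPROTECTION:
            raise ReactionError(f"{self.rxn_id}: scaffold_atoms only for deprotections")
        if self.scaffold_atoms < 0:
            raise ReactionError(f"{self.rxn_id}: scaffold_atoms must be >= 0")

    @property
    def design_fg(self) -> int:
        return self.inputs[0]

    @property
    def bb_fg(self) -> int:
        if self.kind != CONNECTING:
            raise ReactionError(f"{self.rxn_id}: deprotections have no BB-side FG")
        return self.inputs[1]

    @property
    def net_design_delta(self) -> int:
        """Heavy atoms this step adds to the growing design, BB excluded."""
        return self.design_side_atom_delta + self.scaffold_atoms


@dataclass
class ReactionSet:
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.rxn_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ReactionError("duplicate rxn_id in reaction set")
        self.reactions = sorted(self.reactions, key=lambda r: r.rxn_id)

    def __iter__(self):
        return iter(self.reactions)

    def __len__(self):
        return len(self.reactions)

    def __getitem__(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.rxn_id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def connecting(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == CONNECTING]

    def deprotections(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == DEPROTECTION]

    def scoped(self, scope: str) -> "ReactionSet":
        """Restrict to production reactions (scope="production") or keep all
        production + validated reactions (scope="both")."""
        if scope == "both":
            return ReactionSet(list(self.reactions))
        if scope == "production":
            return ReactionSet(
                [r for r in self.reactions if r.production_status == "production"]
            )
        raise ReactionError(f"unknown reaction scope {scope!r}")


def _reaction_from_record(rec) -> Reaction:
    def ints(v) -> tuple[int, ...]:
        if v in (None, ""):
            return ()
        if isinstance(v, str):
            return tuple(int(x) for x in v.split(";") if x.strip())
        if isinstance(v, int):
            return (v,)
        return tuple(int(x) for x in v)

    return Reaction(
        rxn_id=str(rec["rxn_id"]),
        kind=str(rec["kind"]),
        inputs=ints(rec["input_fgs"]),
        outputs=ints(rec.get("output_fgs")),
        enum_index=int(rec.get("enum_index") or 0),
        design_side_atom_delta=int(rec.get("design_side_atom_delta") or 0),
        bb_side_atom_delta=int(rec.get("bb_side_atom_delta") or 0),
        scaffold_atoms=int(rec.get("scaffold_atoms") or 0),
        transform=str(rec.get("transform") or ""),
        production_status=str(rec.get("production_status") or "production"),
    )


def load_reactions(path: str | Path) -> ReactionSet:
    """Load a reaction set from YAML (``reactions:`` list) or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        records = doc["reactions"] if isinstance(doc, dict) else doc
    else:
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
    return ReactionSet([_reaction_from_record(r) for r in records])


def save_reactions(rxns: Iterable[Reaction], path: str | Path) -> None:
    records = []
    for r in rxns:
        records.append(
            {
                "rxn_id": r.rxn_id,
                "kind": r.kind,
                "input_fgs": list(r.inputs),
                "output_fgs": list(r.outputs),
                "enum_index": r.enum_index,
                "design_side_atom_delta": r.design_side_atom_delta,
                "bb_side_atom_delta": r.bb_side_atom_delta,
                "scaffold_atoms": r.scaffold_atoms,
                "transform": r.transform,
                "production_status": r.production_status,
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump({"reactions": records}, fh, sort_keys=False)


@dataclass
class ReactionFGMatrices:
    """On-DNA / off-DNA reaction×FG incompatibilities.

    ``on_dna`` blocks a reaction when the FG sits on the growing (DNA-bound)
    design; ``off_dna`` blocks it when the FG arrives on the incoming BB.
    Entries are (rxn_id, fg_id) pairs.
    """

    on_dna: set[tuple[str, int]] = field(default_factory=set)
    off_dna: set[tuple[str, int]] = field(default_factory=set)

    def blocks_on_dna(self, rxn_id: str, fg_id: int) -> bool:
        return (rxn_id, fg_id) in self.on_dna

    def blocks_off_dna(self, rxn_id: str, fg_id: int) -> bool:
        return (rxn_id, fg_id) in self.off_dna


def load_reaction_fg_matrices(path: str | Path) -> ReactionFGMatrices:
    """YAML with ``on_dna:``/``off_dna:`` lists of [rxn_id, fg_id] pairs."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return ReactionFGMatrices(
        on_dna={(str(r), int(f)) for r, f in doc.get("on_dna", [])},
        off_dna={(str(r), int(f)) for r, f in doc.get("off_dna", [])},
    )


def save_reaction_fg_matrices(m: ReactionFGMatrices, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "on_dna": sorted([r, f] for r, f in m.on_dna),
                "off_dna": sorted([r, f] for r, f in m.off_dna),
            },
            fh,
        )
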