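"""Building-block standardization, filtering, FG annotation and BBT assignment.

The pipeline is: parse → strip salts/solvents to the parent organic fragment
→ neutralize → canonicalize (so free bases and their salts consolidate to one
record) → annotate FG match sites with the ontology SMARTS → resolve the FG
hierarchy per site → reject on unwanted FGs / size / flexibility → assign the
surviving leaf-FG combination to exactly one BBT.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .ontology import (
    BBT,
    NULL_FG,
    FGOntology,
    IncompatibilityMatrix,
    TooManyFGsError,
    canonical_bbt,
    resolve_fg_hierarchy,
)
from .reactions import Reaction, ReactionError


class StandardizationError(ValueError):
    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class Rejection:
    """Why a BB failed; ``reasons[0]`` is the primary reason."""

    reasons: list[str]

    @property
    def reason(self) -> str:
        return self.reasons[0]

    def __bool__(self) -> bool:  # falsy so `if result:` means "passed"
        return False


@dataclass
class BuildingBlock:
    bb_id: str
    smiles: str
    source: str = "internal"
    heavy_atoms: int = 0
    rotatable_bonds: int = 0
    bbt: BBT | None = None
    fg_sites: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    status: str = "raw"
    reject_reasons: list[str] = field(default_factory=list)

    @property
    def fg_ids(self) -> tuple[int, ...]:
        return tuple(sorted({fg for fg, _ in self.fg_sites}))


@dataclass
class FilterPolicy:
    """Curation thresholds applied after standardization.

    Defaults keep BBs small enough to assemble drug-sized products: at most
    30 heavy atoms and 10 rotatable bonds, no unwanted FGs.
    """

    unwanted_fg_ids: frozenset[int] = frozenset()
    max_heavy_atoms: int = 30
    max_rotatable_bonds: int = 10

    def __post_init__(self):
        if self.max_heavy_atoms <= 0 or self.max_rotatable_bonds <= 0:
            raise ValueError("filter thresholds must be positive")


_uncharger = rdMolStandardize.Uncharger()


def standardize(raw_smiles: str) -> str:
    """Canonical neutral parent-fragment SMILES of *raw_smiles*.

    Salt and solvent fragments are stripped (largest organic fragment wins),
    charges are neutralized where possible, and the result is the RDKit
    canonical SMILES — idempotent, so an acetate salt and the free base of
    the same amine consolidate to one canonical form.
    Raises :class:`StandardizationError` with reason ``"parse"`` or
    ``"no_organic_fragment"``.
    """
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise StandardizationError("parse", raw_smiles)
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)
    if mol is None or mol.GetNumAtoms() == 0 or not any(
        a.GetAtomicNum() == 6 for a in mol.GetAtoms()
    ):
        raise StandardizationError("no_organic_fragment", raw_smiles)
    mol = _uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


def annotate_fgs(
    bb: BuildingBlock, ontology: FGOntology
) -> list[tuple[int, tuple[int, ...]]]:
    """Match every ontology SMARTS against the BB and resolve the hierarchy.

    Returns (fg_id, atom-index tuple) pairs, one per surviving match site;
    when an ancestor and a descendant hit overlapping atoms only the most
    specific FG keeps the site.  The result is stored on ``bb.fg_sites``.
    """
    mol = Chem.MolFromSmiles(bb.smiles)
    if mol is None:
        raise StandardizationError("parse", bb.smiles)
    raw: dict[int, list[frozenset[int]]] = {}
    for fg in ontology:
        if fg.id == NULL_FG:
            continue
        hits = mol.GetSubstructMatches(ontology.pattern(fg.id))
        if hits:
            raw[fg.id] = [frozenset(h) for h in hits]
    resolved = resolve_fg_hierarchy(raw, ontology)
    sites = []
    for fg_id in sorted(resolved):
        for site in resolved[fg_id]:
            sites.append((fg_id, tuple(sorted(site))))
    bb.fg_sites = sites
    return sites


def filter_bb(bb: BuildingBlock, policy: FilterPolicy) -> bool | Rejection:
    """True when the BB passes curation; otherwise a :class:`Rejection`
    listing every failing rule in evaluation order (unwanted FG, then heavy
    atoms, then rotatable bonds)."""
    reasons = []
    bad = sorted(set(bb.fg_ids) & policy.unwanted_fg_ids)
    if bad:
        reasons.append("unwanted_fg")
    if bb.heavy_atoms > policy.max_heavy_atoms:
        reasons.append("heavy_atoms")
    if bb.rotatable_bonds > policy.max_rotatable_bonds:
        reasons.append("rotatable_bonds")
    return Rejection(reasons) if reasons else True


def assign_bbt(
    bb: BuildingBlock, ontology: FGOntology, incompat: IncompatibilityMatrix
) -> BBT | Rejection:
    """Map the BB's resolved leaf FGs to its unique BBT.

    Rejects with ``no_fg`` (nothing reactive), ``too_many_fgs`` (>3 distinct
    leaf FGs) or ``incompatible`` (the combination is pruned from BBT space).
    """
    ids = bb.fg_ids
    if not ids:
        return Rejection(["no_fg"])
    try:
        bbt = canonical_bbt(ids, ontology)
    except TooManyFGsError:
        return Rejection(["too_many_fgs"])
    if incompat.violates(bbt.fgs):
        return Rejection(["incompatible"])
    bb.bbt = bbt
    return bbt


def effective_heavy_atoms(
    bb: BuildingBlock,
    incoming_reaction: Reaction,
    extra_deltas: Sequence[int] = (),
) -> int:
    """Heavy atoms the BB contributes to a product through *incoming_reaction*.

    The BB-side leaving-group delta of the reaction is applied (e.g. −1 for
    the hydroxyl an acid loses in amidation); *extra_deltas* compose further
    losses such as a later deprotection of a protected FG the BB carried.
    The reaction must consume one of the BB's FGs.
    """
    if incoming_reaction.kind != "connecting":
        raise ReactionError(
            f"{incoming_reaction.rxn_id}: only connecting reactions consume a BB"
        )
    if incoming_reaction.bb_fg not in bb.fg_ids:
        raise ReactionError(
            f"{incoming_reaction.rxn_id} consumes FG {incoming_reaction.bb_fg}, "
            f"absent from BB {bb.bb_id}"
        )
    return bb.heavy_atoms + incoming_reaction.bb_side_atom_delta + sum(extra_deltas)


def process_bb(
    bb_id: str,
    raw_smiles: str,
    source: str,
    ontology: FGOntology,
    incompat: IncompatibilityMatrix,
    policy: FilterPolicy,
) -> BuildingBlock:
    """Run one raw record through the full curation pipeline."""
    bb = BuildingBlock(bb_id=bb_id, smiles=raw_smiles, source=source)
    try:
        bb.smiles = standardize(raw_smiles)
    except StandardizationError as err:
        bb.status = "rejected"
        bb.reject_reasons = [err.reason]
        return bb
    mol = Chem.MolFromSmiles(bb.smiles)
    bb.heavy_atoms = mol.GetNumHeavyAtoms()
    bb.rotatable_bonds = Descriptors.NumRotatableBonds(mol)
    annotate_fgs(bb, ontology)
    verdict = filter_bb(bb, policy)
    if isinstance(verdict, Rejection):
        bb.status = "rejected"
        bb.reject_reasons = verdict.reasons
        return bb
    assigned = assign_bbt(bb, ontology, incompat)
    if isinstance(assigned, Rejection):
        bb.status = "rejected"
        bb.reject_reasons = assigned.reasons
        return bb
    bb.status = "accepted"
    return bb


def process_collection(
    records: Iterable[tuple[str, str, str]],
    ontology: FGOntology,
    incompat: IncompatibilityMatrix,
    policy: FilterPolicy | None = None,
) -> tuple[list[BuildingBlock], list[tuple[str, str]]]:
    """Process (bb_id, smiles, source) records; returns (BBs, merge log).

    Duplicates after standardization (same canonical form and source) are
    merged keeping the lexicographically first id; the merge log records
    (kept_id, dropped_id) pairs.
    """
    policy = policy or FilterPolicy()
    processed = [
        process_bb(bb_id, smi, src, ontology, incompat, policy)
        for bb_id, smi, src in records
    ]
    by_key: dict[tuple[str, str], BuildingBlock] = {}
    merges: list[tuple[str, str]] = []
    for bb in sorted(processed, key=lambda b: b.bb_id):
        if bb.status != "accepted":
            by_key[(bb.bb_id, "")] = bb  # rejected records kept individually
            continue
        key = (bb.smiles, bb.source)
        if key in by_key:
            merges.append((by_key[key].bb_id, bb.bb_id))
        else:
            by_key[key] = bb
    out = sorted(by_key.values(), key=lambda b: b.bb_id)
    return out, merges


def accepted(bbs: Iterable[BuildingBlock]) -> list[BuildingBlock]:
    return [b for b in bbs if b.status == "accepted"]


def bbs_by_bbt(
    bbs: Iterable[BuildingBlock], source: str | None = None
) -> dict[BBT, list[BuildingBlock]]:
    """Group accepted BBs by their BBT, optionally restricted to one source."""
    out: dict[BBT, list[BuildingBlock]] = {}
    for bb in bbs:
        if bb.status != "accepted" or bb.bbt is None:
            continue
        if source is not None and bb.source != source:
            continue
        out.setdefault(bb.bbt, []).append(bb)
    return out


def bb_collection_report(bbs: Iterable[BuildingBlock]) -> pd.DataFrame:
    """Per (source, multiplicity) census: BBT count with ≥1 BB, BB count and
    the heavy-atom histogram of members — the library-planning view of a
    collection."""
    rows = []
    groups: dict[tuple[str, int], list[BuildingBlock]] = {}
    for bb in accepted(bbs):
        groups.setdefault((bb.source, bb.bbt.multiplicity), []).append(bb)
    for (source, mult), members in sorted(groups.items()):
        hist = Counter(b.heavy_atoms for b in members)
        rows.append(
            {
                "source": source,
                "multiplicity": mult,
                "n_bbts": len({b.bbt for b in members}),
                "n_bbs": len(members),
                "heavy_atom_histogram": dict(sorted(hist.items())),
            }
        )
    return pd.DataFrame(
        rows, columns=["source", "multiplicity", "n_bbts", "n_bbs", "heavy_atom_histogram"]
    )


# ---------------------------------------------------------------------------
# File formats


def load_bb_records(path: str | Path) -> list[tuple[str, str, str]]:
    """Read (bb_id, smiles, source) from CSV (bb_id,smiles,source columns) or
    a SMILES file (smiles first, id second, whitespace separated)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            return [
                (r["bb_id"], r["smiles"], r.get("source", "internal"))
                for r in csv.DictReader(fh)
            ]
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            bb_id = parts[1] if len(parts) > 1 else f"bb{i}"
            records.append((bb_id, parts[0], "internal"))
    return records


def save_processed_bbs(bbs: Iterable[BuildingBlock], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "bb_id",
                "source",
                "canonical_smiles",
                "heavy_atoms",
                "rotatable_bonds",
                "bbt",
                "status",
                "reject_reason",
            ]
        )
        for bb in bbs:
            writer.writerow(
                [
                    bb.bb_id,
                    bb.source,
                    bb.smiles,
                    bb.heavy_atoms,
                    bb.rotatable_bonds,
                    str(bb.bbt) if bb.bbt else "",
                    bb.status,
                    ";".join(bb.reject_reasons),
                ]
            )
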