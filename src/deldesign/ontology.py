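"""Functional-group ontology, building-block types and incompatibility rules.

A *functional group* (FG) here is not the organic-chemistry textbook notion:
it is any atom group that either participates in a DNA-compatible reaction or
masks such a group until a deprotection exposes it (so Boc-carbamates and
ortho-fluoronitroarenes are FGs, while an amide is not).  FGs live in a
hierarchy (amine ⊃ aliphatic amine ⊃ primary aliphatic amine) so that a
substructure match can always be reduced to its most specific leaf.

A *building-block type* (BBT) is a canonical triple of FG ids padded with the
null FG (id 0); it is the reactivity equivalence class under which individual
building blocks are interchangeable during design generation.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from rdkit import Chem

NULL_FG = 0


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown FG references."""


@dataclass(frozen=True)
class FG:
    """One node of the functional-group ontology.

    Parameters
    ----------
    id:
        Small non-negative integer; 0 is reserved for the null FG used to pad
        BBT triples.
    name:
        Short label, unique within an ontology.
    smarts:
        Substructure pattern; empty only for the null FG.
    parent_id:
        Id of the immediately more generic FG, or ``None`` for roots.
    protected:
        True when the group masks another FG and needs a deprotection step
        before it can react.
    class_tags:
        Reactivity-class labels (e.g. ``strong_electrophile``) expanded into
        pairwise incompatibilities at load time.
    """

    id: int
    name: str
    smarts: str
    parent_id: int | None = None
    protected: bool = False
    class_tags: tuple[str, ...] = ()


NULL = FG(id=NULL_FG, name="null", smarts="")


@dataclass(frozen=True, order=True)
class BBT:
    """Canonical unordered triple of FG ids defining a reactivity class.

    Non-null ids are sorted ascending and null ids (0) are pushed to the end,
    so two BBTs built from the same FG multiset compare equal.
    """

    fgs: tuple[int, int, int]

    @property
    def multiplicity(self) -> int:
        return sum(1 for f in self.fgs if f != NULL_FG)

    @property
    def non_null(self) -> tuple[int, ...]:
        return tuple(f for f in self.fgs if f != NULL_FG)

    def __str__(self) -> str:  # compact id form used in traces and reports
        return "(" + ",".join(str(f) for f in self.fgs) + ")"


class TooManyFGsError(ValueError):
    """A building block carries more than three reactive FGs."""


def canonical_bbt(fg_ids: Iterable[int], ontology: "FGOntology | None" = None) -> BBT:
    """Canonicalize a collection of at most three FG ids into a BBT.

    Null entries are dropped and re-padded to the end; duplicate non-null ids
    collapse to one (a BB carrying two copies of the same FG is typed by the
    FG once).  Raises :class:`TooManyFGsError` for more than three distinct
    non-null FGs and :class:`OntologyError` for ids missing from *ontology*.
    """
    non_null = sorted({f for f in fg_ids if f != NULL_FG})
    if not non_null:
        raise OntologyError("a BBT needs at least one non-null FG")
    if len(non_null) > 3:
        raise TooManyFGsError(f"more than 3 non-null FGs: {non_null}")
    if ontology is not None:
        for f in non_null:
            if f not in ontology:
                raise OntologyError(f"unknown FG id {f}")
    padded = tuple(non_null) + (NULL_FG,) * (3 - len(non_null))
    return BBT(fgs=padded)  # type: ignore[arg-type]


@dataclass
class IncompatibilityMatrix:
    """Symmetric set of FG-id pairs that may not coexist on one BB."""

    pairs: set[frozenset[int]] = field(default_factory=set)

    def add(self, a: int, b: int) -> None:
        if NULL_FG in (a, b):
            raise OntologyError("the null FG cannot appear in incompatibilities")
        self.pairs.add(frozenset((a, b)))

    def incompatible(self, a: int, b: int) -> bool:
        return frozenset((a, b)) in self.pairs

    def violates(self, fg_ids: Sequence[int]) -> bool:
        """True if any pair among *fg_ids* (ignoring null) is incompatible."""
        live = [f for f in fg_ids if f != NULL_FG]
        return any(
            self.incompatible(a, b) for a, b in itertools.combinations(live, 2)
        )

    @classmethod
    def from_rules(
        cls,
        ontology: "FGOntology",
        pairs: Iterable[tuple[int, int]] = (),
        class_rules: Iterable[tuple[str, str]] = (),
    ) -> "IncompatibilityMatrix":
        """Build a matrix from explicit pairs plus class-level rules.

        A class rule ``(tag_a, tag_b)`` expands to every pair of distinct FGs
        where one carries *tag_a* and the other *tag_b* (the same FG may carry
        both tags; self-pairs are not generated).
        """
        m = cls()
        for a, b in pairs:
            m.add(a, b)
        by_tag: dict[str, list[int]] = {}
        for fg in ontology:
            for tag in fg.class_tags:
                by_tag.setdefault(tag, []).append(fg.id)
        for tag_a, tag_b in class_rules:
            for a in by_tag.get(tag_a, ()):
                for b in by_tag.get(tag_b, ()):
                    if a != b:
                        m.add(a, b)
        return m


class FGOntology:
    """Container for an FG hierarchy with SMARTS access and ancestry queries."""

    def __init__(self, fgs: Iterable[FG]):
        self._by_id: dict[int, FG] = {}
        for fg in fgs:
            if fg.id in self._by_id:
                raise OntologyError(f"duplicate FG id {fg.id}")
            self._by_id[fg.id] = fg
        if NULL_FG not in self._by_id:
            self._by_id[NULL_FG] = NULL
        null = self._by_id[NULL_FG]
        if null.smarts or null.parent_id is not None:
            raise OntologyError("FG 0 must be the null FG (no SMARTS, no parent)")
        self._by_name = {fg.name: fg for fg in self._by_id.values()}
        if len(self._by_name) != len(self._by_id):
            raise OntologyError("FG names must be unique")
        self._patterns: dict[int, Chem.Mol] = {}
        for fg in self._by_id.values():
            if fg.id == NULL_FG:
                continue
            patt = Chem.MolFromSmarts(fg.smarts)
            if patt is None:
                raise OntologyError(f"FG {fg.id} ({fg.name}): bad SMARTS {fg.smarts!r}")
            self._patterns[fg.id] = patt
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for fg in self._by_id.values():
            seen = set()
            cur: int | None = fg.id
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"parent cycle at FG {fg.id}")
                seen.add(cur)
                parent = self._by_id.get(cur)
                if parent is None:
                    raise OntologyError(f"FG {fg.id}: unknown parent chain id {cur}")
                cur = parent.parent_id

    # -- mapping-ish access -------------------------------------------------
    def __contains__(self, fg_id: int) -> bool:
        return fg_id in self._by_id

    def __iter__(self):
        return iter(sorted(self._by_id.values(), key=lambda f: f.id))

    def __len__(self) -> int:
        return len(self._by_id)

    def __getitem__(self, fg_id: int) -> FG:
        try:
            return self._by_id[fg_id]
        except KeyError:
            raise OntologyError(f"unknown FG id {fg_id}") from None

    def by_name(self, name: str) -> FG:
        try:
            return self._by_name[name]
        except KeyError:
            raise OntologyError(f"unknown FG name {name!r}") from None

    def id_of(self, name: str) -> int:
        return self.by_name(name).id

    def pattern(self, fg_id: int) -> Chem.Mol:
        return self._patterns[fg_id]

    @property
    def non_null_ids(self) -> list[int]:
        return [f.id for f in self if f.id != NULL_FG]

    def exposed_ids(self) -> list[int]:
        return [f.id for f in self if f.id != NULL_FG and not f.protected]

    # -- hierarchy ----------------------------------------------------------
    def ancestors(self, fg_id: int) -> list[int]:
        """Ids of all strict ancestors, nearest first."""
        out = []
        cur = self[fg_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self[cur].parent_id
        return out

    def is_ancestor(self, ancestor_id: int, fg_id: int) -> bool:
        return ancestor_id in self.ancestors(fg_id)


def resolve_fg_hierarchy(
    matches: Mapping[int, Sequence[frozenset[int]]] | Iterable[int],
    ontology: FGOntology,
):
    """Keep only the most specific FG per matched site.

    Two call forms are supported.  Given a mapping ``{fg_id: [atom-index
    sets]}`` (one entry per match site), an ancestor's match site is dropped
    whenever a strict descendant matched an overlapping atom set; the pruned
    mapping is returned.  Given a plain collection of FG ids, all ids are
    treated as matches of the same site and the set of ids with no descendant
    present is returned.

    Matches of related FGs on *distinct* sites are all retained: a molecule
    with one primary aliphatic amine and one aromatic amine keeps both leaves.
    """
    if not isinstance(matches, Mapping):
        ids = set(matches)
        return {
            f
            for f in ids
            if not any(f in ontology.ancestors(other) for other in ids if other != f)
        }

    resolved: dict[int, list[frozenset[int]]] = {}
    for fg_id, sites in matches.items():
        kept = []
        for site in sites:
            shadowed = False
            for other_id, other_sites in matches.items():
                if other_id == fg_id or not ontology.is_ancestor(fg_id, other_id):
                    continue
                if any(site & s for s in other_sites):
                    shadowed = True
                    break
            if not shadowed:
                kept.append(site)
        if kept:
            resolved[fg_id] = kept
    return resolved


def enumerate_bbt_space(
    ontology: FGOntology, incompat: IncompatibilityMatrix | None = None
) -> list[BBT]:
    """All canonical triples of distinct FGs, pruned by incompatibility.

    The triples are combinations without repetition drawn from the full
    ontology including the null FG, so an ontology of *n* FGs yields C(n, 3)
    triples before pruning (a 43-FG ontology gives 12,341).  Triples
    containing the null FG are bifunctional; the rest are trifunctional.
    Monofunctional BBTs ``(x, 0, 0)`` repeat the null slot and therefore are
    not part of this combination count; they arise from building-block
    assignment via :func:`canonical_bbt`.
    """
    all_ids = sorted(f.id for f in ontology)
    out = []
    for combo in itertools.combinations(all_ids, 3):
        if incompat is not None and incompat.violates(combo):
            continue
        out.append(canonical_bbt(combo))
    return sorted(out)


# ---------------------------------------------------------------------------
# File formats


def _fg_from_record(rec: Mapping) -> FG:
    parent = rec.get("parent_id")
    if parent in ("", None, "none", "None"):
        parent = None
    else:
        parent = int(parent)
    tags = rec.get("class_tags") or ()
    if isinstance(tags, str):
        tags = tuple(t.strip() for t in tags.split(";") if t.strip())
    else:
        tags = tuple(tags)
    protected = rec.get("protected", False)
    if isinstance(protected, str):
        protected = protected.strip().lower() in ("1", "true", "yes")
    return FG(
        id=int(rec["id"]),
        name=str(rec["name"]),
        smarts=str(rec.get("smarts") or ""),
        parent_id=parent,
        protected=bool(protected),
        class_tags=tags,
    )


def load_ontology(path: str | Path) -> FGOntology:
    """Load an FG ontology from YAML (``fgs:`` list) or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        records = doc["fgs"] if isinstance(doc, dict) else doc
    else:
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
    return FGOntology(_fg_from_record(r) for r in records)


def save_ontology(ontology: FGOntology, path: str | Path) -> None:
    records = []
    for fg in ontology:
        if fg.id == NULL_FG:
            continue
        records.append(
            {
                "id": fg.id,
                "name": fg.name,
                "smarts": fg.smarts,
                "parent_id": fg.parent_id,
                "protected": fg.protected,
                "class_tags": list(fg.class_tags),
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump({"fgs": records}, fh, sort_keys=False)


def load_incompatibility(
    path: str | Path, ontology: FGOntology
) -> IncompatibilityMatrix:
    """Load incompatibilities from YAML (``pairs`` + ``class_rules``) or a
    two-column CSV of FG-id pairs."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        pairs = [tuple(int(x) for x in p) for p in doc.get("pairs", [])]
        rules = [tuple(r) for r in doc.get("class_rules", [])]
        return IncompatibilityMatrix.from_rules(ontology, pairs, rules)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        pairs = []
        for row in reader:
            if not row or row[0].startswith("#") or not row[0].strip().isdigit():
                continue
            pairs.append((int(row[0]), int(row[1])))
    return IncompatibilityMatrix.from_rules(ontology, pairs)
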