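"""Exhaustive generation of multi-cycle library designs (eDESIGN graphs).

A design starts from a DNA headpiece carrying one FG.  Each cycle optionally
applies one deprotection (which may install a scaffold) and then connects
exactly one BBT through a connecting reaction; the design's state is the
multiset of FGs currently live on it.  Every live FG remembers the node
(cycle; 0 = headpiece) it sits on, and reactions record the node they attach
to, so two routes that consume chemically identical FGs from different nodes
are distinct designs — they have different connectivity and cannot be
produced in the same library.  Generation is breadth-first over all
(headpiece × per-cycle deprotection × reaction × attachment × BBT) branches,
pruned by reaction×FG incompatibilities that differ for FGs sitting on the
DNA-bound design (on-DNA) versus on the incoming building block (off-DNA).
Designs ending with disallowed FGs are removed at the end.

Designs are identified by their replay trace — headpiece FG plus the
ordered (deprotection@node, reaction@node, BBT) token per cycle — which
makes deduplication, serialization and replay byte-stable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .ontology import BBT, FGOntology, OntologyError
from .reactions import CONNECTING, DEPROTECTION, Reaction, ReactionFGMatrices


class DesignError(ValueError):
    pass


class DesignSpaceOverflow(RuntimeError):
    """The combinatorial expansion exceeded the configured hard cap."""


@dataclass(frozen=True)
class CycleTrace:
    """Replay token for one cycle."""

    deprotection_id: str  # "" when the cycle has none
    deprotection_node: int  # node whose FG was deprotected (-1 when none)
    rxn_id: str
    attach_node: int  # node whose FG the connection consumed
    bbt: BBT


@dataclass(frozen=True)
class EDesign:
    """One fully specified synthesis route; immutable, grown by copying.

    ``live`` holds (fg_id, origin node) pairs; deprotection outputs stay on
    the node of the FG they unmasked, connection outputs and unconsumed BBT
    FGs sit on the node added that cycle.
    """

    headpiece_fg: int
    nodes: tuple[tuple[int, BBT], ...] = ()  # (cycle index, BBT)
    live: tuple[tuple[int, int], ...] = ()  # sorted (fg, origin) multiset
    n_cycles_done: int = 0
    trace: tuple[CycleTrace, ...] = ()

    @property
    def live_fgs(self) -> tuple[int, ...]:
        return tuple(fg for fg, _ in self.live)

    @property
    def edges(self) -> tuple[tuple[str, int], ...]:
        """(rxn_id, attach node) per step, deprotections included."""
        out = []
        for t in self.trace:
            if t.deprotection_id:
                out.append((t.deprotection_id, t.deprotection_node))
            out.append((t.rxn_id, t.attach_node))
        return tuple(out)

    def trace_line(self) -> str:
        """Tab-separated replay trace, one line per design."""
        tokens = [f"HP:{self.headpiece_fg}"]
        for t in self.trace:
            dep = f"D:{t.deprotection_id}@{t.deprotection_node}" if t.deprotection_id else "D:-"
            tokens.append(dep)
            tokens.append(f"R:{t.rxn_id}@{t.attach_node}")
            tokens.append(f"B:{','.join(map(str, t.bbt.fgs))}")
        return "\t".join(tokens)


def parse_trace_line(line: str) -> tuple[int, list[CycleTrace]]:
    """Inverse of :meth:`EDesign.trace_line`."""
    tokens = line.rstrip("\n").split("\t")
    if not tokens or not tokens[0].startswith("HP:"):
        raise DesignError(f"bad trace line: {line!r}")
    headpiece = int(tokens[0][3:])
    steps = []
    for i in range(1, len(tokens), 3):
        dep_tok = tokens[i][2:]
        if dep_tok == "-":
            dep_id, dep_node = "", -1
        else:
            dep_id, node_s = dep_tok.rsplit("@", 1)
            dep_node = int(node_s)
        rxn_id, attach_s = tokens[i + 1][2:].rsplit("@", 1)
        fgs = tuple(int(x) for x in tokens[i + 2][2:].split(","))
        steps.append(CycleTrace(dep_id, dep_node, rxn_id, int(attach_s), BBT(fgs)))
    return headpiece, steps


def init_edesigns(headpieces: Sequence[int], ontology: FGOntology) -> list[EDesign]:
    """One zero-cycle design per distinct headpiece FG (duplicates collapse)."""
    seen: list[int] = []
    for fg in headpieces:
        if fg not in ontology:
            raise OntologyError(f"unknown headpiece FG {fg}")
        if fg not in seen:
            seen.append(fg)
    return [EDesign(headpiece_fg=fg, live=((fg, 0),)) for fg in seen]


def check_compatibility(
    d: EDesign,
    r: Reaction,
    bbt: BBT | None,
    matrices: ReactionFGMatrices,
) -> str | None:
    """None when the step is allowed, else a string naming the violation.

    Spectator FGs on the design are checked against the reaction's on-DNA
    blocks; spectator FGs arriving on the BBT against its off-DNA blocks.
    One instance of each consumed FG is exempt.
    """
    live = Counter(d.live_fgs)
    live[r.design_fg] -= 1  # the consumed design FG is a participant
    for fg, count in live.items():
        if count > 0 and matrices.blocks_on_dna(r.rxn_id, fg):
            return f"on_dna:{r.rxn_id}x{fg}"
    if bbt is not None and r.kind == CONNECTING:
        incoming = Counter(bbt.non_null)
        incoming[r.bb_fg] -= 1
        for fg, count in incoming.items():
            if count > 0 and matrices.blocks_off_dna(r.rxn_id, fg):
                return f"off_dna:{r.rxn_id}x{fg}"
    return None


def _fg_origins(d: EDesign, fg: int) -> list[int]:
    return sorted({origin for f, origin in d.live if f == fg})


def _consume(live: Sequence[tuple[int, int]], fg: int, origin: int) -> list:
    out = list(live)
    try:
        out.remove((fg, origin))
    except ValueError:
        raise DesignError(f"fg_not_available: {fg} at node {origin}") from None
    return out


def apply_deprotection(d: EDesign, r: Reaction, node: int | None = None) -> EDesign:
    """Rewrite one live FG via a deprotection/scaffold reaction (pure).

    *node* selects which instance to deprotect when the FG is live on
    several nodes; default is the lowest node.  Outputs stay on that node.
    """
    if r.kind != DEPROTECTION:
        raise DesignError(f"{r.rxn_id} is not a deprotection")
    origins = _fg_origins(d, r.design_fg)
    if not origins:
        raise DesignError(f"fg_not_available: {r.design_fg} for {r.rxn_id}")
    node = origins[0] if node is None else node
    live = _consume(d.live, r.design_fg, node)
    live.extend((fg, node) for fg in r.outputs)
    return replace(d, live=tuple(sorted(live)))


def apply_connection(
    d: EDesign,
    r: Reaction,
    bbt: BBT,
    matrices: ReactionFGMatrices | None = None,
    attach_node: int | None = None,
    deprotection: tuple[str, int] = ("", -1),
) -> EDesign:
    """Attach one BBT through a connecting reaction (pure).

    The design FG (on *attach_node*; default the lowest live node carrying
    it) and the BB FG are consumed; the reaction outputs and the BBT's
    unconsumed non-null FGs join the live multiset on the new node, and the
    cycle's replay token is appended.
    """
    if r.kind != CONNECTING:
        raise DesignError(f"{r.rxn_id} is not a connecting reaction")
    origins = _fg_origins(d, r.design_fg)
    if not origins:
        raise DesignError(f"fg_not_available: {r.design_fg} on design for {r.rxn_id}")
    if r.bb_fg not in bbt.non_null:
        raise DesignError(f"fg_not_available: {r.bb_fg} on BBT {bbt} for {r.rxn_id}")
    if matrices is not None:
        violation = check_compatibility(d, r, bbt, matrices)
        if violation:
            raise DesignError(f"incompatible: {violation}")
    attach_node = origins[0] if attach_node is None else attach_node
    cycle = d.n_cycles_done + 1
    live = _consume(d.live, r.design_fg, attach_node)
    incoming = list(bbt.non_null)
    incoming.remove(r.bb_fg)
    live.extend((fg, cycle) for fg in incoming)
    live.extend((fg, cycle) for fg in r.outputs)
    return replace(
        d,
        nodes=d.nodes + ((cycle, bbt),),
        live=tuple(sorted(live)),
        n_cycles_done=cycle,
        trace=d.trace + (CycleTrace(*deprotection, r.rxn_id, attach_node, bbt),),
    )


def grow_all(
    designs: Sequence[EDesign],
    reactions: Sequence[Reaction],
    bbts: Sequence[BBT],
    matrices: ReactionFGMatrices,
    n_cycles: int,
    max_designs: int = 10**8,
) -> list[EDesign]:
    """Exhaustive breadth-first expansion over *n_cycles* cycles.

    Per cycle and per design the branches are {no deprotection} ∪ {each
    applicable (deprotection × node)}, then each applicable (connecting
    reaction × attachment node × BBT) — exactly one BBT is added per cycle
    and at most one deprotection is attempted before it.  Iteration order
    (deprotections, reactions by rxn_id; nodes ascending; BBTs in canonical
    order) is fixed so the output is reproducible byte-for-byte.  Raises
    :class:`DesignSpaceOverflow` past *max_designs*.
    """
    deprotections = sorted(
        (r for r in reactions if r.kind == DEPROTECTION), key=lambda r: r.rxn_id
    )
    connections = sorted(
        (r for r in reactions if r.kind == CONNECTING), key=lambda r: r.rxn_id
    )
    bbts = sorted(bbts)
    current = list(designs)
    for _ in range(n_cycles):
        nxt: list[EDesign] = []
        seen: set[tuple] = set()
        for d in current:
            branches: list[tuple[tuple[str, int], EDesign]] = [(("", -1), d)]
            for dep in deprotections:
                if check_compatibility(d, dep, None, matrices):
                    continue
                for node in _fg_origins(d, dep.design_fg):
                    branches.append(
                        ((dep.rxn_id, node), apply_deprotection(d, dep, node))
                    )
            for dep_key, base in branches:
                for r in connections:
                    nodes = _fg_origins(base, r.design_fg)
                    if not nodes:
                        continue
                    for node in nodes:
                        for bbt in bbts:
                            if r.bb_fg not in bbt.non_null:
                                continue
                            if check_compatibility(base, r, bbt, matrices):
                                continue
                            child = apply_connection(
                                base, r, bbt, attach_node=node,
                                deprotection=dep_key,
                            )
                            key = (child.headpiece_fg, child.trace)
                            if key in seen:
                                continue
                            seen.add(key)
                            nxt.append(child)
                            if len(nxt) > max_designs:
                                raise DesignSpaceOverflow(
                                    f"more than {max_designs} designs at "
                                    f"cycle {d.n_cycles_done + 1}"
                                )
        current = nxt
    return current


def finalize(
    designs: Iterable[EDesign], disallowed_final_fgs: Iterable[int]
) -> list[EDesign]:
    """Drop designs whose final live FGs intersect the disallowed set."""
    banned = set(disallowed_final_fgs)
    return [d for d in designs if not (banned & set(d.live_fgs))]


def replay(
    headpiece_fg: int,
    steps: Sequence[CycleTrace],
    reactions: Sequence[Reaction],
    ontology: FGOntology,
) -> EDesign:
    """Rebuild an EDesign from its trace; the determinism anchor for I/O."""
    by_id = {r.rxn_id: r for r in reactions}
    d = init_edesigns([headpiece_fg], ontology)[0]
    for t in steps:
        if t.deprotection_id:
            d = apply_deprotection(d, by_id[t.deprotection_id], t.deprotection_node)
        d = apply_connection(
            d, by_id[t.rxn_id], t.bbt, attach_node=t.attach_node,
            deprotection=(t.deprotection_id, t.deprotection_node),
        )
    return d


def save_designs(designs: Iterable[EDesign], path) -> None:
    with open(path, "w") as fh:
        for d in designs:
            fh.write(d.trace_line() + "\n")


def load_designs(path, reactions: Sequence[Reaction], ontology: FGOntology) -> list[EDesign]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                hp, steps = parse_trace_line(line)
                out.append(replay(hp, steps, reactions, ontology))
    return out
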