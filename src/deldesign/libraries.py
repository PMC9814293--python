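"""libDESIGNs: merged designs, heavy-atom convolution and size maximization.

Designs that share topology (headpiece FG and cycle count) and the same
per-cycle enum-index of their reactions can be produced in one experimental
library, so they merge into a single libDESIGN holding a *set* of BBTs per
node and a set of reactions per edge.  The heavy-atom distribution of the
full combinatorial product space is then the discrete convolution of the
per-node effective heavy-atom histograms, shifted by the headpiece atom
count and the per-edge design-side deltas — no product is ever enumerated.
Given a target median product size, a per-node monotone cap search (drop the
heaviest BBs first) finds the largest library whose size median meets the
target.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .building_blocks import BuildingBlock, bbs_by_bbt, effective_heavy_atoms
from .designs import EDesign
from .ontology import BBT
from .reactions import Reaction, ReactionError

# A heavy-atom histogram is a plain {heavy_atom_count: compound_count} dict.
HAHistogram = dict


def hist_total(h: Mapping[int, int]) -> int:
    return sum(h.values())


def hist_shift(h: Mapping[int, int], delta: int) -> HAHistogram:
    return {k + delta: v for k, v in h.items()}


def hist_convolve(a: Mapping[int, int], b: Mapping[int, int]) -> HAHistogram:
    """Discrete convolution: sizes add, counts multiply (product rule)."""
    if not a or not b:
        return {}
    amin, amax = min(a), max(a)
    bmin, bmax = min(b), max(b)
    va = np.zeros(amax - amin + 1, dtype=np.int64)
    vb = np.zeros(bmax - bmin + 1, dtype=np.int64)
    for k, v in a.items():
        va[k - amin] = v
    for k, v in b.items():
        vb[k - bmin] = v
    conv = np.convolve(va, vb)
    return {
        amin + bmin + i: int(c) for i, c in enumerate(conv) if c
    }


def hist_median(h: Mapping[int, int]) -> float:
    """Lower median: smallest value whose cumulative count reaches half the
    total (deterministic on integer histograms)."""
    total = hist_total(h)
    if total == 0:
        raise ValueError("median of an empty histogram")
    cum = 0
    for k in sorted(h):
        cum += h[k]
        if 2 * cum >= total:
            return float(k)
    raise AssertionError("unreachable")


def hist_truncate(h: Mapping[int, int], cap: int) -> HAHistogram:
    return {k: v for k, v in h.items() if k <= cap}


@dataclass
class LibDesign:
    """A mergeable family of designs that one experimental library realises."""

    lib_id: str
    headpiece_fg: int
    n_cycles: int
    # per cycle: (deprotection enum_index or None, deprotected node,
    #             connection enum_index, attachment node)
    enum_key: tuple[tuple[int | None, int, int, int], ...]
    node_bbts: tuple[frozenset[BBT], ...] = ()
    # per cycle: (deprotection rxn ids, connection rxn ids)
    edge_reactions: tuple[tuple[frozenset[str], frozenset[str]], ...] = ()
    members: list[EDesign] = field(default_factory=list)
    # reaction feeding each BBT at each node, {cycle: {bbt: rxn_id}}
    node_bbt_reaction: dict = field(default_factory=dict)
    # filled by sizing
    ha_histogram: HAHistogram = field(default_factory=dict)
    max_size: int = 0
    selection: tuple[int, ...] | None = None  # per-node heavy-atom caps
    median_ha: float | None = None
    feasible: bool = True

    @property
    def topology(self) -> tuple[int, int]:
        return (self.headpiece_fg, self.n_cycles)


def _complete_subgroups(members: list[EDesign]) -> list[list[EDesign]]:
    """Split a candidate group until its members form a full Cartesian
    product of per-node BBT choices.

    A libDESIGN's combinatorial space is the product of its per-node BB
    lists, so a group is only valid when every BBT combination across nodes
    corresponds to an actual generated design (a combination missing from
    the members — e.g. because no node would carry the FG a later
    deprotection needs, or an incompatibility blocked it — must not be
    counted or enumerated).  Splitting is by the first over-full node,
    recursively; deterministic."""
    n_cycles = members[0].n_cycles_done
    combos = {tuple(t.bbt for t in d.trace) for d in members}
    node_sets = [sorted({c[i] for c in combos}) for i in range(n_cycles)]
    if math.prod(len(s) for s in node_sets) == len(combos):
        return [members]
    split_at = next(i for i in range(n_cycles) if len(node_sets[i]) > 1)
    parts: dict[BBT, list[EDesign]] = {}
    for d in members:
        parts.setdefault(d.trace[split_at].bbt, []).append(d)
    out = []
    for bbt in sorted(parts):
        out.extend(_complete_subgroups(parts[bbt]))
    return out


def group_libdesigns(
    edesigns: Sequence[EDesign], reactions: Sequence[Reaction]
) -> list[LibDesign]:
    """Partition designs into libDESIGNs producible as one experimental
    library.

    The grouping key is (headpiece FG, cycle count, per-cycle (deprotection
    enum-index or None, deprotected node, connection enum-index, attachment
    node)); "no deprotection" is its own key value.  Node BBT sets are
    unions over members, so two designs that differ only in primary- versus
    secondary-amine amidation (same enum-index) become one libDESIGN with
    two BBTs at that node.  Groups are additionally split until their
    members form a full per-node Cartesian product, which makes the
    convolution sizing and the sampler exact.
    """
    by_id = {r.rxn_id: r for r in reactions}
    groups: dict[tuple, list[EDesign]] = {}
    for d in edesigns:
        key_cycles = []
        for t in d.trace:
            dep_enum = by_id[t.deprotection_id].enum_index if t.deprotection_id else None
            key_cycles.append(
                (dep_enum, t.deprotection_node, by_id[t.rxn_id].enum_index, t.attach_node)
            )
        key = (d.headpiece_fg, d.n_cycles_done, tuple(key_cycles))
        groups.setdefault(key, []).append(d)
    libs = []
    i = 0
    for key in sorted(groups, key=repr):
        for members in _complete_subgroups(groups[key]):
            d0 = members[0]
            key_cycles = key[2]
            lib = LibDesign(
                lib_id=f"L{i:06d}",
                headpiece_fg=d0.headpiece_fg,
                n_cycles=d0.n_cycles_done,
                enum_key=key_cycles,
                members=members,
            )
            i += 1
            node_bbts: list[set[BBT]] = [set() for _ in range(lib.n_cycles)]
            deps: list[set[str]] = [set() for _ in range(lib.n_cycles)]
            conns: list[set[str]] = [set() for _ in range(lib.n_cycles)]
            bbt_rxn: dict[int, dict[BBT, str]] = {c: {} for c in range(lib.n_cycles)}
            for d in lib.members:
                for c, t in enumerate(d.trace):
                    node_bbts[c].add(t.bbt)
                    if t.deprotection_id:
                        deps[c].add(t.deprotection_id)
                    conns[c].add(t.rxn_id)
                    prev = bbt_rxn[c].get(t.bbt)
                    if prev is None or t.rxn_id < prev:
                        bbt_rxn[c][t.bbt] = t.rxn_id
            lib.node_bbts = tuple(frozenset(s) for s in node_bbts)
            lib.edge_reactions = tuple(
                (frozenset(d_), frozenset(c_)) for d_, c_ in zip(deps, conns)
            )
            lib.node_bbt_reaction = bbt_rxn
            libs.append(lib)
    return libs


def ungroup(libs: Iterable[LibDesign]) -> list[EDesign]:
    return [d for lib in libs for d in lib.members]


def bbt_ha_histogram(
    bbt: BBT,
    bbs: Sequence[BuildingBlock],
    reaction: Reaction,
    extra_deltas: Sequence[int] = (),
) -> HAHistogram:
    """Histogram of effective heavy atoms over the BBs of one BBT entering
    through *reaction* (empty histogram for an empty BB set)."""
    hist: HAHistogram = {}
    for bb in bbs:
        if bb.bbt != bbt:
            continue
        size = effective_heavy_atoms(bb, reaction, extra_deltas)
        hist[size] = hist.get(size, 0) + 1
    return hist


def node_histograms(
    lib: LibDesign,
    bbs: Sequence[BuildingBlock],
    reactions: Sequence[Reaction],
    source: str | None = "internal",
) -> list[HAHistogram]:
    """Per-node heavy-atom histograms: union over the node's BBTs of their
    member-BB histograms, each BB counted once with the delta of the
    reaction that consumes it.  Sizing conventionally restricts to the
    internal source (pass ``source=None`` to use all BBs)."""
    by_id = {r.rxn_id: r for r in reactions}
    pools = bbs_by_bbt(bbs, source=source)
    out = []
    for cycle in range(lib.n_cycles):
        hist: HAHistogram = {}
        for bbt, rxn_id in sorted(lib.node_bbt_reaction[cycle].items()):
            sub = bbt_ha_histogram(bbt, pools.get(bbt, []), by_id[rxn_id])
            for k, v in sub.items():
                hist[k] = hist.get(k, 0) + v
        out.append(hist)
    return out


def design_shift(lib: LibDesign, reactions: Sequence[Reaction]) -> int:
    """Total design-side heavy-atom delta: deprotection scaffolds plus the
    connection design-side deltas, summed over cycles.

    Deltas must agree across the reactions merged on one edge (they share an
    enum-index); a disagreement is a modelling error and raises.
    """
    by_id = {r.rxn_id: r for r in reactions}
    shift = 0
    for dep_ids, conn_ids in lib.edge_reactions:
        dep_deltas = {by_id[i].net_design_delta for i in dep_ids}
        if len(dep_deltas) > 1:
            raise ReactionError(
                f"{lib.lib_id}: merged deprotections disagree on atom delta"
            )
        if dep_deltas:
            shift += dep_deltas.pop()
        conn_deltas = {by_id[i].design_side_atom_delta for i in conn_ids}
        if len(conn_deltas) > 1:
            raise ReactionError(
                f"{lib.lib_id}: merged connections disagree on design-side delta"
            )
        if len({by_id[i].bb_side_atom_delta for i in conn_ids}) > 1:
            raise ReactionError(
                f"{lib.lib_id}: merged connections disagree on BB-side delta"
            )
        shift += conn_deltas.pop()
    return shift


def convolve_design_ha(
    lib: LibDesign,
    headpiece_atoms: int,
    node_hists: Sequence[HAHistogram],
    shift: int,
) -> HAHistogram:
    """Product heavy-atom histogram of the full library, by convolution.

    Total equals the product of per-node BB counts; any empty node histogram
    yields an empty result (the library cannot be made from the given BBs).
    """
    if any(not h for h in node_hists):
        return {}
    acc: HAHistogram = {0: 1}
    for h in node_hists:
        acc = hist_convolve(acc, h)
    return hist_shift(acc, headpiece_atoms + shift)


def maximize_size(
    node_hists: Sequence[HAHistogram],
    target_median: int,
    base_shift: int,
    exact_threshold: int = 10**5,
) -> tuple[tuple[int, ...] | None, int, float | None]:
    """Largest library size achievable with per-node heavy-atom caps such
    that the product-size median stays ≤ *target_median*.

    Returns (caps, max_size, median); (None, 0, None) when even the lightest
    selection misses the target.  The search is exact over the cap lattice
    when the lattice has at most *exact_threshold* points, else a greedy
    coordinate descent from unrestricted caps (documented as approximate).
    *base_shift* is the headpiece plus design-side delta added to every
    product.
    """
    if any(not h for h in node_hists):
        return None, 0, None
    sizes = [sorted(h) for h in node_hists]

    def evaluate(caps: Sequence[int]):
        hists = [hist_truncate(h, c) for h, c in zip(node_hists, caps)]
        acc: HAHistogram = {0: 1}
        for h in hists:
            acc = hist_convolve(acc, h)
        acc = hist_shift(acc, base_shift)
        return acc

    lattice = math.prod(len(s) for s in sizes)
    full_caps = tuple(s[-1] for s in sizes)
    full = evaluate(full_caps)
    if hist_median(full) <= target_median:
        return full_caps, hist_total(full), hist_median(full)

    if lattice <= exact_threshold:
        best = (None, 0, None)
        for combo in itertools.product(*sizes):
            hist = evaluate(combo)
            med = hist_median(hist)
            if med > target_median:
                continue
            total = hist_total(hist)
            if total > best[1]:
                best = (tuple(combo), total, med)
        return best

    # greedy coordinate descent: repeatedly lower the one cap whose
    # reduction keeps the largest library, until the median constraint holds
    idx = [len(s) - 1 for s in sizes]
    while True:
        caps = tuple(s[i] for s, i in zip(sizes, idx))
        hist = evaluate(caps)
        if hist_median(hist) <= target_median:
            return caps, hist_total(hist), hist_median(hist)
        best_move, best_total = None, -1
        for n in range(len(sizes)):
            if idx[n] == 0:
                continue
            trial = list(idx)
            trial[n] -= 1
            t_caps = tuple(s[i] for s, i in zip(sizes, trial))
            t_hist = evaluate(t_caps)
            t_total = hist_total(t_hist)
            if t_total > best_total:
                best_move, best_total = n, t_total
        if best_move is None:
            return None, 0, None
        idx[best_move] -= 1


def size_libdesign(
    lib: LibDesign,
    bbs: Sequence[BuildingBlock],
    reactions: Sequence[Reaction],
    target_median: int,
    headpiece_atoms: int,
    source: str | None = "internal",
) -> LibDesign:
    """Attach histogram, caps, max_size and median to *lib* (in place)."""
    hists = node_histograms(lib, bbs, reactions, source=source)
    shift = design_shift(lib, reactions) + headpiece_atoms
    caps, size, median = maximize_size(hists, target_median, shift)
    lib.selection = caps
    lib.max_size = size
    lib.median_ha = median
    lib.feasible = caps is not None
    if caps is not None:
        lib.ha_histogram = convolve_design_ha(
            lib, 0, [hist_truncate(h, c) for h, c in zip(hists, caps)], shift
        )
    else:
        lib.ha_histogram = {}
    return lib


def select_libdesigns(
    libs: Iterable[LibDesign], min_size: int
) -> list[LibDesign]:
    """Keep sized libDESIGNs reaching *min_size* under the median constraint,
    sorted by achievable size descending (ties by id)."""
    kept = [l for l in libs if l.feasible and l.max_size >= min_size]
    return sorted(kept, key=lambda l: (-l.max_size, l.lib_id))


# ---------------------------------------------------------------------------
# Serialization


def libdesign_record(lib: LibDesign) -> dict:
    return {
        "lib_id": lib.lib_id,
        "headpiece_fg": lib.headpiece_fg,
        "n_cycles": lib.n_cycles,
        "enum_key": [list(k) for k in lib.enum_key],
        "nodes": [
            {
                "cycle": c,
                "bbts": sorted(str(b) for b in lib.node_bbts[c]),
                "cap": None if lib.selection is None else lib.selection[c],
            }
            for c in range(lib.n_cycles)
        ],
        "edges": [
            {"cycle": c, "deprotections": sorted(d), "connections": sorted(r)}
            for c, (d, r) in enumerate(lib.edge_reactions)
        ],
        "n_members": len(lib.members),
        "max_size": lib.max_size,
        "median_ha": lib.median_ha,
        "feasible": lib.feasible,
        "ha_histogram": {str(k): v for k, v in sorted(lib.ha_histogram.items())},
    }


def save_libdesigns(libs: Iterable[LibDesign], path) -> None:
    with open(path, "w") as fh:
        for lib in libs:
            fh.write(json.dumps(libdesign_record(lib)) + "\n")
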