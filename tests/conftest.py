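"""Shared fixtures: toy study systems, processed BB collections, and an
independently coded brute-force design-generation oracle."""

from __future__ import annotations

from collections import Counter

import pytest

import deldesign as dd
from deldesign import building_blocks as bbm


@pytest.fixture(scope="session")
def small_system():
    return dd.make_toy_system("small", seed=7)


@pytest.fixture(scope="session")
def small_processed(small_system):
    bbs, _ = dd.process_collection(
        small_system.bb_records,
        small_system.ontology,
        small_system.incompat,
        small_system.filter_policy,
    )
    return bbm.accepted(bbs)


@pytest.fixture(scope="session")
def medium_system():
    return dd.make_toy_system("medium", seed=11)


@pytest.fixture(scope="session")
def medium_processed(medium_system):
    bbs, _ = dd.process_collection(
        medium_system.bb_records,
        medium_system.ontology,
        medium_system.incompat,
        medium_system.filter_policy,
    )
    return bbm.accepted(bbs)


# ---------------------------------------------------------------------------
# Brute-force oracle for design generation.  Deliberately written as a plain
# recursion over FG multisets with origins — structured nothing like the
# breadth-first engine — so agreement is meaningful.


def oracle_designs(headpiece_fg, reactions, bbts, matrices, n_cycles):
    """All replay traces reachable in *n_cycles* cycles, as a set of tuples
    ((dep_id, dep_node, rxn_id, attach_node, bbt_fgs), ...) per design."""

    def blocked_on(r, live_fgs, consumed):
        c = Counter(live_fgs)
        c[consumed] -= 1
        return any(
            n > 0 and matrices.blocks_on_dna(r.rxn_id, fg) for fg, n in c.items()
        )

    def blocked_off(r, bbt):
        c = Counter(bbt.non_null)
        c[r.bb_fg] -= 1
        return any(
            n > 0 and matrices.blocks_off_dna(r.rxn_id, fg) for fg, n in c.items()
        )

    results = set()

    def recurse(live, cycle, trace):
        if cycle > n_cycles:
            results.add(trace)
            return
        # branch: optional single deprotection first
        dep_options = [("", -1, live)]
        for r in reactions:
            if r.kind != "deprotection":
                continue
            if blocked_on(r, [f for f, _ in live], r.design_fg):
                continue
            for node in sorted({o for f, o in live if f == r.design_fg}):
                nxt = list(live)
                nxt.remove((r.design_fg, node))
                nxt.extend((f, node) for f in r.outputs)
                dep_options.append((r.rxn_id, node, tuple(sorted(nxt))))
        for dep_id, dep_node, base in dep_options:
            for r in reactions:
                if r.kind != "connecting":
                    continue
                for node in sorted({o for f, o in base if f == r.design_fg}):
                    for bbt in bbts:
                        if r.bb_fg not in bbt.non_null:
                            continue
                        if blocked_on(r, [f for f, _ in base], r.design_fg):
                            continue
                        if blocked_off(r, bbt):
                            continue
                        nxt = list(base)
                        nxt.remove((r.design_fg, node))
                        rest = list(bbt.non_null)
                        rest.remove(r.bb_fg)
                        nxt.extend((f, cycle) for f in rest)
                        nxt.extend((f, cycle) for f in r.outputs)
                        recurse(
                            tuple(sorted(nxt)),
                            cycle + 1,
                            trace + ((dep_id, dep_node, r.rxn_id, node, bbt.fgs),),
                        )

    recurse(((headpiece_fg, 0),), 1, ())
    return results


def trace_key(design):
    """Engine EDesign -> the oracle's trace tuple form."""
    return tuple(
        (t.deprotection_id, t.deprotection_node, t.rxn_id, t.attach_node, t.bbt.fgs)
        for t in design.trace
    )


@pytest.fixture(scope="session")
def design_oracle():
    return oracle_designs
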