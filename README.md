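# deldesign

Combinatorial design, sizing, sampling and diversity profiling of
DNA-encoded libraries (DELs).

DEL synthesis couples small building blocks (BBs) in two or three cycles on
a DNA headpiece, so a handful of reliable on-DNA reactions and a BB
catalogue implicitly define an enormous space of *library designs*. Which
of those designs are worth making? A good design must (a) be chemically
feasible end to end, (b) deliver enough compounds — typically over a
million — from the BBs you actually own, (c) keep the product size
distribution drug-like rather than letting three 25-atom BBs stack into
75-atom grease, and (d) add structural diversity that existing screening
collections do not already cover. `deldesign` answers all four questions
without ever enumerating a full library. It is written for computational
and medicinal chemists planning DEL campaigns, and for method developers
who want a transparent, fully seeded reference implementation to extend.

## The method

**Objects.** A *functional group* (FG) is any atom group that either reacts
under DNA-compatible conditions or masks such a group (Boc-carbamate,
ortho-fluoronitroarene, …); FGs live in a hierarchy (amine ⊃ aliphatic ⊃
primary) and substructure hits are resolved to the most specific leaf per
site. A *building-block type* (BBT) is a canonical triple of FG ids padded
with the null FG `0` — the reactivity class under which individual BBs are
interchangeable. An ontology of *n* FGs (null included) spans C(*n*, 3)
distinct-FG triples — 12,341 for *n* = 43 — cut down by pairwise
incompatibility rules (strong nucleophiles/electrophiles cannot coexist on
one BB). *Reactions* rewrite FG tuples: connecting reactions consume one
design FG and one BB FG, deprotections rewrite a single design FG,
optionally installing a scaffold (cyanuric chloride: amine →
dichlorotriazine, +8 heavy atoms).

**Design generation.** Designs grow breadth-first from every candidate
headpiece FG: per cycle, at most one deprotection followed by exactly one
(reaction × attachment node × BBT) coupling, screened by reaction×FG
incompatibility matrices that distinguish FGs on the DNA-bound design
(*on-DNA*) from FGs arriving on the BB (*off-DNA*). Designs ending with
disallowed FGs are discarded. Designs that differ only in reactions one
experimental procedure can realise together (shared *enum-index*, e.g.
amidation of primary and secondary amines) merge into *libDESIGNs* — one
experimental library each — holding a set of BBTs per node; groups are
split until their members form a full per-node Cartesian product, so a
libDESIGN's space is exactly the product of its BB lists.

**Sizing without enumeration.** Heavy atoms are additive: the product-size
histogram of a full library is the discrete convolution of per-node
effective-BB-size histograms (BB atoms plus the reaction's leaving-group
delta), shifted by the headpiece (4 atoms) and per-edge deltas. Per-node
size caps (drop the heaviest BBs first) are then searched — exhaustively on
small cap lattices, greedily beyond — for the largest library whose median
product size stays at the target (29 heavy atoms by default, matching a
drug-like screening collection plus the headpiece). Libraries below the
minimum achievable size are dropped.

**Sampling and diversity.** Surviving libDESIGNs become enumeration
configs: reaction SMARTS per step plus cap-compliant BB lists. Products are
drawn uniformly without replacement from the combinatorial space and built
by applying the transforms from a headpiece surrogate; every product's
heavy-atom count is asserted against the convolution model, tying the
estimate to real structures. Samples (default 10,000 compounds) are
profiled (heavy atoms, cLogP, fraction Csp³, TPSA, rotatable bonds) and
compared with reference collections through linear-path fingerprints
(7-bond paths, 2048 bits): average pairwise Tanimoto distance per
reference, and a greedy max-min *spread design* ranking — repeatedly select
the library with the largest mean near-neighbour distance to the references
plus everything already selected.

Because real DEL BB catalogues and corporate screening decks are
proprietary, the package ships a seeded synthetic-data module
(`deldesign.fixtures`) that generates chemically valid BB collections with
known ground-truth BBT assignments, reaction sets (amidation, reductive
amination, triazine SNAr, benzimidazole formation, Boc/Fmoc chemistry) and
drug-like reference sets, at an exhaustively checkable small scale and an
integration-scale medium one.

## Worked example

```python
import deldesign as dd
from deldesign.building_blocks import bbs_by_bbt
from deldesign.designs import finalize, grow_all, init_edesigns
from deldesign.libraries import group_libdesigns, select_libdesigns, size_libdesign

system = dd.make_toy_system("medium", seed=7)          # ~1,900 synthetic BBs
bbs, _ = dd.process_collection(system.bb_records, system.ontology,
                               system.incompat, system.filter_policy)
accepted = [b for b in bbs if b.status == "accepted"]

designs = finalize(
    grow_all(init_edesigns([3], system.ontology),      # amine headpiece
             list(system.reactions.scoped("production")),
             sorted(bbs_by_bbt(accepted)), system.matrices, n_cycles=2),
    system.disallowed_final_fgs)
libs = group_libdesigns(designs, list(system.reactions))
for lib in libs:
    size_libdesign(lib, accepted, list(system.reactions),
                   target_median=29, headpiece_atoms=4)
for lib in select_libdesigns(libs, min_size=20_000):
    print(lib.lib_id, f"{lib.max_size:,d}", lib.median_ha)
```

prints

```
L000002 26,400 29.0
L000006 22,880 29.0
```

— 42 two-cycle designs collapse to 8 experimental libraries, of which two
can deliver over 20,000 compounds from internal BBs while holding the
median product size at 29 heavy atoms; `lib.selection` holds the per-cycle
BB size caps that achieve it. The scripts in `examples/` continue from
here: sampling products (`04`, mean heavy atoms 28.9 for the top library)
and ranking libraries by spread (`05`, top spread value 0.34 against the
synthetic references).

The same pipeline runs from the shell:

```bash
deldesign fixtures --out rundir --scale medium --seed 7
deldesign run --params rundir/params.yaml --out results/
```

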