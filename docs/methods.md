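# Methods

This note documents the model behind `deldesign`, the choices made where
the design was genuinely open, and what the shipped synthetic study systems
do and do not establish about real data.

## Objects and assumptions

**Functional groups.** An FG is a SMARTS-defined atom group that either
participates in a DNA-compatible reaction or masks one (protected FGs need
a deprotection before reacting). The definition is operational, not the
organic-chemistry one: an amide is not an FG because no shipped reaction
consumes it, while an ortho-fluoronitroarene is one because SNAr plus
reductive cyclization uses the fluoride and the nitro group as a unit. FGs
form a forest (amine ⊃ aliphatic amine ⊃ primary/secondary; nitro ⊃
ortho-fluoronitroarene); annotation keeps, per matched atom set, only the
most specific FG whose match overlaps it. Resolution is per site, not per
molecule: a BB carrying a primary aliphatic amine *and* an aromatic amine
keeps both leaves. Placing ortho-fluoronitroarene under nitro is an
operational use of the same mechanism — it suppresses the spurious nitro
annotation on SNAr-ready arenes.

**BBTs.** A building-block type is a sorted triple of FG ids padded with
the null FG 0; a BB with two copies of one FG is typed by that FG once.
`enumerate_bbt_space` returns all triples of *distinct* FGs drawn from the
ontology (null included), C(n, 3) of them, matching the standard printed
count for n = 43; monofunctional BBTs (x, 0, 0) repeat the null slot and
enter the system through BB assignment rather than through this
combination count. Incompatibility is pairwise only: explicit FG pairs plus
class rules (electrophile×electrophile, nucleophile×electrophile,
nucleophile×nucleophile) expanded over class tags at load time. Whether
production systems also use triple-wise rules is not documentable from
public sources; pairwise is what is implemented and tested.

**Reactions.** Connecting reactions are FG-tuple rewrites
`(design_fg, bb_fg) → outputs`; deprotections are `(design_fg,) → outputs`
with `scaffold_atoms ≥ 0`. Heavy-atom deltas are declared per reaction and
split into a design-side and a BB-side contribution so that each BB's
*effective* atom count (what it adds to a product) is well defined; the
reaction-SMARTS `transform` used for structure generation must realise
exactly the declared deltas, and the sampler asserts this on every product
it builds. Two consequences worth noting: Boc removal is −7 heavy atoms
(the full tert-butoxycarbonyl group, counted on an explicit transform), and
the cyanuric-chloride scaffold step is +8 at the deprotection (triazine
ring plus two chlorines) with −1 on each subsequent SNAr — netting the
six-atom triazine in the final molecule. Per-step deltas must match the
per-step transforms or the cross-check fails, which is why the net figure
is not used directly.

## Design generation

One eDESIGN is a replay trace: headpiece FG, then per cycle an optional
deprotection, a connecting reaction, an attachment node and a BBT. Live FGs
carry the node they sit on (0 = headpiece); deprotection outputs stay on
the node whose FG they unmask, while connection outputs and unconsumed BBT
FGs sit on the node added that cycle. Attachment matters: consuming
chemically identical FGs from different nodes gives different molecules and
different libraries, so the engine branches over attachment nodes and the
trace records them. Exactly one BBT is added per cycle and at most one
deprotection precedes it; chained deprotections within a cycle are
excluded (that also resolves whether a scaffold-adding and a plain
deprotection may share a cycle: no). Compatibility screens are look-ups in
two reaction×FG matrices — on-DNA for spectator FGs already on the design,
off-DNA for spectator FGs arriving on the BBT — with one instance of each
consumed FG exempt. Iteration order is fixed (headpieces, then
deprotections, reactions and attachment nodes by id, BBTs canonically), so
output lists are byte-reproducible; a configurable hard cap (default 10⁸
designs) aborts runaway expansions cleanly. The engine is validated by
exact trace-set equality against an independently written recursive
expansion on the small system, with and without incompatibility matrices,
for 1–3 cycles.

## libDESIGN grouping

Designs merge when one experimental library can realise them: same
headpiece FG, cycle count, and per cycle the same (deprotection enum-index
or none, deprotected node, connection enum-index, attachment node).
Enum-indexes group reactions one procedure covers (amidation of primary and
secondary amines); "no deprotection" is its own key value, and the
deprotection's own enum-index is used for deprotection compatibility.
Including the attachment nodes in the key is this package's resolution of
the under-specified "same topology" condition for linear designs — without
it, groups can mix members whose later chemistry consumes FGs from
different nodes.

Even with that key, a candidate group's members need not fill the full
Cartesian product of its per-node BBT sets (a combination may be missing
because no node supplies the FG a later deprotection needs, or an
incompatibility blocked it). Since a libDESIGN's space *is* the product of
its BB lists, groups are recursively split at the first over-full node
until members form an exact product. Merged reactions on one edge must
agree on their atom deltas (enforced), and a libDESIGN may legitimately
apply the same enum-index in different per-cycle roles across members
(acylate the primary amine in cycle 2 and the secondary in cycle 3, or
vice versa); the enumeration config therefore carries a route table mapping
each BBT combination to the per-cycle reactions of the member design that
realises it.

## Heavy-atom convolution and size maximization

Per node, the effective-size histogram pools the BBs of the node's BBTs
(each BB once, with the delta of the reaction consuming it). The library's
product-size histogram is the convolution of the node histograms shifted by
headpiece atoms plus all design-side deltas; totals obey the product rule
exactly, and the result equals exhaustive enumeration on toy libraries by
construction and by test. Sizing restricts to the `internal` BB source by
default — the size and median guarantees should hold with the BBs one
already owns — while sampling may draw from all sources.

The maximizer searches per-node monotone heavy-atom caps (excluding the
heaviest BBs first): any median-constrained selection closed under
replacing a BB by a lighter one is cap-representable, so caps lose no
generality in this family. The median is the lower median (smallest value
whose cumulative count reaches half the total), deterministic on integer
histograms, and the constraint is `median ≤ target` — the binding direction
when BB catalogues skew heavy. The search is exact over the cap lattice
when it has ≤ 10⁵ points (toy and medium scales always fall in this
regime), otherwise a documented greedy coordinate descent from unrestricted
caps that always returns a feasible selection but may be sub-optimal.
Whether the original production implementation is exact is not
documentable; exactness here is verified against exhaustive lattice search
on ≤ 30×30 instances.

## Enumeration and sampling

A config stores, per cycle, the deprotection transform(s), the connection
transforms keyed by reaction id, the declared deltas and the cap-compliant
BB list, plus the route table and a headpiece surrogate SMILES. The DNA and
its PEG linker are represented only by that surrogate (default `NCCO`, a
4-heavy-atom aminoethoxy stub carrying the primary-amine FG; configurable,
and the stub's actual atom count is what enters the arithmetic). Products
are drawn uniformly without replacement from `range(∏ node sizes)` —
full-permutation shuffle when the request exceeds 10% of the space,
hash-rejection otherwise — and unranked into per-node BB indices.
Transforms apply in order; when a SMARTS matches several sites, the
chemically distinct products are tie-broken by lowest canonical SMILES
(deterministic; real regiochemistry is out of scope) and the multiplicity
is available to callers. Failed transforms are logged and replaced by fresh
draws; a failure rate above 5% aborts. Every built product's heavy-atom
count is asserted against the model's prediction for its provenance tuple;
`sample_provenance` provides the structure-free fast path for additive
properties.

## Profiling and spread design

Descriptors: RDKit heavy-atom count, Crippen cLogP, fraction Csp³, TPSA,
rotatable bonds. Fingerprints: RDKit linear-path fingerprints, maximum path
7 bonds, 2048 bits, branched paths off — a documented stand-in for
proprietary path-based fingerprints, carried in `FingerprintParams` so
every report is labelled with the parameters that produced it. Two
library-level measures are exposed and named in report metadata, because
both are standard: `avg_pairwise_distance` (mean of all |A|×|B| Tanimoto
distances) for library-versus-reference reports, and `mean_nn_distance`
(mean over a library's compounds of the minimum distance to the reference
pool) inside `spread_rank`. Spread design greedily selects the library
maximising the mean near-neighbour distance to the current pool (original
references plus all libraries already selected), emits that value, and adds
the library's compounds to the pool; ties break toward the larger library,
then lexicographic id. The 0.25 "adequate" and 0.20 "sufficiently
different" thresholds only flag report rows, never filter. When several
reference collections are given, spread uses their union (configurable by
passing whichever pool is wanted).

## Synthetic study systems

The generator assembles BBs from a vetted template table — one
attachment-ready SMILES fragment per FG — joined by seeded random saturated
linkers (branched chains with 1,4-cyclohexylene insertions to keep
rotatable-bond counts catalogue-like). That guarantees chemical validity
and makes every BB's intended BBT, source and atom count part of a
manifest; processing a generated collection recovers 100% of manifest
assignments, which is a test invariant. Heavy-atom targets are drawn from
truncated normals; the internal source is parameterised heavier (medium
system: mean ≈ 14–22 by class) than the external one (≈ 10–20), emulating
the usual corporate-versus-vendor shape. Reference sets are assembled from
drug-like scaffold templates, targeting a configurable mean size (default
25 heavy atoms, a typical screening-deck value). Two scales ship: *small*
(5 FGs, 3 reactions — acylation, reductive amination, Boc removal — and 30
BBs; every oracle runs exhaustively) and *medium* (the full 24-FG default
ontology, 13 reactions including triazine SNAr and benzimidazole formation,
~1,900 BBs across two sources, two reference sets). Default run parameters
follow the study conditions of this class of method: target median 29 heavy
atoms, headpiece 4 atoms, 10,000-compound profiling samples, and a
minimum-size threshold scaled to the fixture (20,000 on the medium system,
whose BB pools are ~150× smaller than production catalogues, standing in
for the production "more than one million").

What passing tests show — and do not. The fixtures establish exactness of
the combinatorics (design recursion, convolution, cap search, spread
greedy) and end-to-end chemical consistency of the shipped reaction set.
They do not establish that the default SMARTS patterns cover the long tail
of real catalogue chemistry (salt diversity, tautomers, exotic protecting
groups), nor the absolute design counts of any production system, which
depend on proprietary FG lists, reaction sets and BB collections.

## Numerical and degenerate-input conventions

Convolution uses exact 64-bit integer counts (library sizes up to ~10¹⁸).
Empty node histograms make a library infeasible (`max_size` 0, flagged),
never an exception mid-pipeline. Duplicate BB records after
standardization merge keeping the lexicographically first id, with a merge
log. Rejection reasons accumulate in rule order (unwanted FG, heavy atoms,
rotatable bonds); the first is primary. All stages are pure functions of
(inputs, seed); the pipeline writes per-stage outputs as checkpoints and a
manifest with input hashes, and reruns reproduce outputs byte-for-byte.

## Known limitations

- Regiochemistry is collapsed by a deterministic tie-break, so samples can
  under-represent positional isomers.
- The greedy cap search beyond the exact-lattice regime has no optimality
  guarantee (feasibility only).
- Stereochemistry, tautomer canonicalization beyond the standardizer's
  defaults, protonation modelling, yield/feasibility scoring and DNA-tag
  assignment are out of scope.
- Monofunctional BBTs are excluded from the C(n,3) combination count by
  the distinct-FG convention; they are fully supported everywhere else.
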