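"""Enumerate the building-block-type (BBT) space of an FG ontology.

A BBT is a canonical triple of functional-group ids (padded with the null
FG, id 0) that defines a reactivity class of building blocks.  The space of
distinct-FG triples over an ontology of n FGs has C(n, 3) members before
incompatibility pruning; class rules (strong nucleophiles and electrophiles
cannot share a molecule) then remove chemically untenable combinations.
"""

import deldesign as dd

onto = dd.default_ontology()
space = dd.enumerate_bbt_space(onto)
pruned = dd.enumerate_bbt_space(onto, dd.default_incompatibility(onto))

print(f"ontology: {len(onto)} FGs (null included)")
print(f"unpruned BBT space: {len(space)}  (= C({len(onto)},3))")
print(f"after incompatibility pruning: {len(pruned)}")
print("example pruned-out pair: primary amine x isocyanate on one BB")

# A 43-FG ontology, the size used for production-scale design work, gives
# the classic count:
from deldesign.ontology import FG, FGOntology

big = FGOntology(FG(id=i, name=f"fg{i}", smarts="[C]") for i in range(1, 43))
print(f"43-FG ontology: {len(dd.enumerate_bbt_space(big))} BBT combinations")
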