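"""Curate a building-block collection and assign each BB to its BBT.

Raw structures are salt-stripped and canonicalized, annotated with ontology
SMARTS (hierarchy-resolved so only the most specific FG per site counts),
filtered on unwanted FGs / size / flexibility, and classified into BBTs.
The census report is the view a library designer uses to judge a
collection: how many reactivity classes are populated, by how many BBs, at
what sizes.
"""

import deldesign as dd
from deldesign.building_blocks import bb_collection_report, bbs_by_bbt

system = dd.make_toy_system("small", seed=7)
bbs, merges = dd.process_collection(
    system.bb_records, system.ontology, system.incompat, system.filter_policy
)
accepted = [b for b in bbs if b.status == "accepted"]

print(f"input records: {len(system.bb_records)}, accepted: {len(accepted)}, "
      f"duplicate merges: {len(merges)}")

report = bb_collection_report(accepted)
print("\ncensus by source and multiplicity (mono/bi-functional):")
print(report[["source", "multiplicity", "n_bbts", "n_bbs"]].to_string(index=False))

print("\nBBT membership:")
for bbt, members in sorted(bbs_by_bbt(accepted).items()):
    names = [system.ontology[f].name for f in bbt.non_null]
    print(f"  {bbt}  {'+'.join(names):40s} {len(members):3d} BBs")
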