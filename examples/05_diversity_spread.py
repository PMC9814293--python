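"""Rank candidate libraries by structural diversity (spread design).

Library samples are compared through linear-path fingerprints: average
pairwise Tanimoto distance to each reference collection, then a greedy
max-min *spread* ordering — repeatedly pick the library whose compounds are
farthest (mean near-neighbour distance) from the references plus everything
already picked.  High spread values mean a library adds chemistry the
existing collections do not cover.
"""

import deldesign as dd
from deldesign.pipeline import RunParams, run_pipeline
from deldesign.profiling import library_distance_report

system = dd.make_toy_system("medium", seed=7)
params = RunParams(
    n_cycles=2, reaction_scope="production", min_library_size=20_000,
    target_median_atoms=29, sample_size=400, seed=7, max_profiled_libraries=4,
)
run_pipeline(params, system, "scratch/example_spread")

from deldesign.enumeration import load_xset
from pathlib import Path

xsets = {
    p.stem: load_xset(p).smiles
    for p in sorted(Path("scratch/example_spread/xsets").glob("*.smi"))
}
report = library_distance_report(xsets, system.references)
cols = ["library", "size", "spread_rank", "spread_value", "adequate"]
print(report[cols].to_string(index=False))
print("\nspread_value = mean near-neighbour distance to references plus all")
print("libraries already selected; values above 0.25 are flagged adequate.")
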