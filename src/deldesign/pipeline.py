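"""End-to-end orchestration: BB curation → design generation → libDESIGN
sizing/selection → sampling → profiling → spread ranking.

Each stage writes its outputs into the run directory as it completes, so an
aborted run can resume from the last finished stage; a manifest records the
seed and SHA-256 hashes of all inputs for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import building_blocks as bb
from . import designs as dz
from . import enumeration as en
from . import fixtures as fx
from . import libraries as lb
from . import profiling as pf
from .ontology import load_incompatibility, load_ontology
from .reactions import load_reaction_fg_matrices, load_reactions

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunParams:
    """Run-level knobs.

    ``headpiece_atoms`` is the fixed heavy-atom contribution of the DNA
    headpiece (default 4); ``target_median_atoms`` constrains the product
    size median; ``min_library_size`` is the smallest acceptable library
    achievable with internal BBs alone.
    """

    n_cycles: int = 2
    reaction_scope: str = "production"  # production | both
    min_library_size: int = 50_000
    target_median_atoms: int = 29
    headpiece_atoms: int = 4
    sample_size: int = 10_000
    seed: int = 0
    headpiece_fgs: list[int] = field(default_factory=lambda: [3])
    disallowed_final_fgs: list[int] = field(
        default_factory=lambda: list(fx.DISALLOWED_FINAL_FGS)
    )
    max_profiled_libraries: int = 10  # top-N by size carried into sampling
    sizing_source: str | None = "internal"
    sampling_source: str | None = None  # None = all sources

    def __post_init__(self):
        for name in ("n_cycles", "min_library_size", "target_median_atoms",
                     "headpiece_atoms", "sample_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reaction_scope not in ("production", "both"):
            raise ValueError("reaction_scope must be 'production' or 'both'")


def load_inputs(params_file: str | Path) -> tuple[RunParams, fx.ToySystem]:
    """Read a params YAML plus the input files it references."""
    params_file = Path(params_file)
    base = params_file.parent
    with open(params_file) as fh:
        doc = yaml.safe_load(fh)
    paths = {
        k: base / doc.pop(k)
        for k in ("ontology", "reactions", "reaction_fg_matrices",
                  "incompatibility", "bbs", "references")
        if k in doc
    }
    params = RunParams(**doc)
    ontology = load_ontology(paths["ontology"])
    references = {}
    if "references" in paths:
        for f in sorted(Path(paths["references"]).glob("*.smi")):
            references[f.stem] = [line.split()[0] for line in open(f) if line.strip()]
    system = fx.ToySystem(
        ontology=ontology,
        incompat=load_incompatibility(paths["incompatibility"], ontology),
        reactions=load_reactions(paths["reactions"]),
        matrices=load_reaction_fg_matrices(paths["reaction_fg_matrices"]),
        bb_records=bb.load_bb_records(paths["bbs"]),
        manifest=fx.FixtureManifest(seed=params.seed),
        references=references,
        headpiece_fgs=params.headpiece_fgs,
        disallowed_final_fgs=tuple(params.disallowed_final_fgs),
        filter_policy=bb.FilterPolicy(),
    )
    return params, system


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    params: RunParams,
    system: fx.ToySystem,
    outdir: str | Path,
) -> dict:
    """Execute all stages; returns the counts summary dict.

    Outputs land under *outdir*: processed BBs, design traces, libDESIGN
    records, per-library enumeration configs and samples, property and
    distance reports, a counts summary and a manifest with input hashes.
    Every stage's outputs are written as the stage completes and the whole
    run is deterministic under a fixed seed, so the per-stage files act as
    checkpoints: after an aborted run, rerunning reproduces them exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {
        "n_cycles": params.n_cycles,
        "reaction_scope": params.reaction_scope,
        "min_library_size": params.min_library_size,
        "target_median_atoms": params.target_median_atoms,
        "seed": params.seed,
    }
    t0 = time.time()

    def log_stage(name, **info):
        logger.info("stage=%s t=%.1fs %s", name, time.time() - t0, info)

    scoped = system.reactions.scoped(params.reaction_scope)

    # --- stage: bbts -------------------------------------------------------
    try:
        processed, merges = bb.process_collection(
            system.bb_records, system.ontology, system.incompat,
            system.filter_policy,
        )
        accepted = bb.accepted(processed)
        bb.save_processed_bbs(processed, outdir / "processed_bbs.csv")
        counts["n_bbs_input"] = len(system.bb_records)
        counts["n_bbs_accepted"] = len(accepted)
        counts["n_bbs_merged"] = len(merges)
        counts["n_bbts_with_bbs"] = len(bb.bbs_by_bbt(accepted))
        log_stage("bbts", accepted=len(accepted))
    except Exception as err:
        raise StageFailure("bbts", err) from err

    # --- stage: designs ----------------------------------------------------
    try:
        bbts = sorted(bb.bbs_by_bbt(accepted))
        initial = dz.init_edesigns(params.headpiece_fgs, system.ontology)
        grown = dz.grow_all(
            initial, list(scoped), bbts, system.matrices, params.n_cycles
        )
        designs = dz.finalize(grown, params.disallowed_final_fgs)
        dz.save_designs(designs, outdir / "designs.txt")
        counts["n_edesigns"] = len(designs)
        log_stage("designs", n=len(designs))
    except Exception as err:
        raise StageFailure("designs", err) from err

    # --- stage: libdesigns -------------------------------------------------
    try:
        libs = lb.group_libdesigns(designs, list(scoped))
        for lib in libs:
            lb.size_libdesign(
                lib, accepted, list(scoped), params.target_median_atoms,
                params.headpiece_atoms, source=params.sizing_source,
            )
        selected = lb.select_libdesigns(libs, params.min_library_size)
        lb.save_libdesigns(libs, outdir / "libdesigns.jsonl")
        lb.save_libdesigns(selected, outdir / "libdesigns_selected.jsonl")
        counts["n_libdesigns"] = len(libs)
        counts["n_selected"] = len(selected)
        log_stage("libdesigns", n=len(libs), selected=len(selected))
    except Exception as err:
        raise StageFailure("libdesigns", err) from err

    # --- stage: enumerate --------------------------------------------------
    try:
        cfg_dir = outdir / "configs"
        xset_dir = outdir / "xsets"
        cfg_dir.mkdir(exist_ok=True)
        xset_dir.mkdir(exist_ok=True)
        profiled = selected[: params.max_profiled_libraries]
        xsets: dict[str, en.XSet] = {}
        configs: dict[str, en.EnumConfig] = {}
        for lib in profiled:
            hp = fx.headpiece_fragment(lib.headpiece_fg, params.headpiece_atoms)
            cfg = en.write_config(
                lib, accepted, list(scoped), headpiece_smiles=hp,
                source=params.sampling_source, sample_size=params.sample_size,
                seed=params.seed,
            )
            en.save_config(cfg, cfg_dir / f"{lib.lib_id}.json")
            xset = en.sample_products(cfg, params.sample_size, params.seed)
            en.save_xset(xset, xset_dir / f"{lib.lib_id}.smi")
            configs[lib.lib_id] = cfg
            xsets[lib.lib_id] = xset
        counts["n_profiled"] = len(xsets)
        log_stage("enumerate", n=len(xsets))
    except Exception as err:
        raise StageFailure("enumerate", err) from err

    # --- stage: profile + spread -------------------------------------------
    try:
        prof_rows = []
        for lib_id, xset in xsets.items():
            _, means, skipped = pf.profile_set(xset.smiles)
            prof_rows.append({"library": lib_id, "n_skipped": skipped, **means})
        if prof_rows:
            import pandas as pd

            pd.DataFrame(prof_rows).to_csv(outdir / "profile.csv", index=False)
        if xsets and system.references:
            report = pf.library_distance_report(
                {k: v.smiles for k, v in xsets.items()}, system.references
            )
            report.to_csv(outdir / "distance_report.csv", index=False)
            counts["top_spread_value"] = float(report.iloc[0]["spread_value"])
            usage = pf.bb_usage_report(configs.values(), accepted)
            usage.to_csv(outdir / "bb_usage.csv", index=False)
        log_stage("profile", n=len(prof_rows))
    except Exception as err:
        raise StageFailure("profile", err) from err

    manifest = {
        "seed": params.seed,
        "params": asdict(params),
        "input_hashes": {
            "bb_records": _hash_obj(system.bb_records),
            "reactions": _hash_obj([r.rxn_id for r in system.reactions]),
            "ontology": _hash_obj([f.id for f in system.ontology]),
        },
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "counts.json").write_text(json.dumps(counts, indent=1))
    # Table-style one-row CSV summary of the run
    with open(outdir / "counts.csv", "w") as fh:
        keys = list(counts)
        fh.write(",".join(keys) + "\n")
        fh.write(",".join(str(counts[k]) for k in keys) + "\n")
    return counts
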