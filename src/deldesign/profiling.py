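"""Property profiles, fingerprint distances and spread-design ranking.

Libraries are compared through their enumerated samples: per-compound
physchem descriptors (heavy atoms, cLogP, fraction Csp3, TPSA, rotatable
bonds), average pairwise Tanimoto distance between two sets, per-compound
near-neighbour distances to a reference, and a greedy max-min *spread
design* that repeatedly selects the library farthest (by mean
near-neighbour distance) from the growing reference pool.  Fingerprints are
linear-path fingerprints (up to 7 bonds, hashed to 2048 bits); parameters
travel in :class:`FingerprintParams` so every report is labelled with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FingerprintParams:
    max_path: int = 7  # bonds
    n_bits: int = 2048


@dataclass(frozen=True)
class PropertyRecord:
    heavy_atoms: int
    clogp: float
    fraction_csp3: float
    tpsa: float
    rotatable_bonds: int


def profile_set(
    smiles: Iterable[str],
) -> tuple[list[PropertyRecord], dict[str, float], int]:
    """Per-compound descriptor records plus per-set means.

    Returns (records, means, n_skipped); unparseable structures are logged
    and skipped.
    """
    records = []
    skipped = 0
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            skipped += 1
            logger.warning("unparseable structure skipped: %s", s)
            continue
        records.append(
            PropertyRecord(
                heavy_atoms=mol.GetNumHeavyAtoms(),
                clogp=Crippen.MolLogP(mol),
                fraction_csp3=rdMolDescriptors.CalcFractionCSP3(mol),
                tpsa=rdMolDescriptors.CalcTPSA(mol),
                rotatable_bonds=Descriptors.NumRotatableBonds(mol),
            )
        )
    if records:
        means = {
            k: float(np.mean([getattr(r, k) for r in records]))
            for k in ("heavy_atoms", "clogp", "fraction_csp3", "tpsa", "rotatable_bonds")
        }
    else:
        means = {}
    return records, means, skipped


def fingerprints(
    smiles: Sequence[str], params: FingerprintParams = FingerprintParams()
):
    """Linear-path fingerprints for a set of structures (None for bad input)."""
    out = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            logger.warning("unparseable structure skipped: %s", s)
            continue
        out.append(
            Chem.RDKFingerprint(
                mol, maxPath=params.max_path, fpSize=params.n_bits, branchedPaths=False
            )
        )
    return out


def avg_pairwise_distance(fps_a: Sequence, fps_b: Sequence) -> float:
    """Mean over all |A|×|B| pairs of 1 − Tanimoto similarity; symmetric."""
    if not fps_a or not fps_b:
        raise ValueError("average pairwise distance needs two non-empty sets")
    total = 0.0
    for fa in fps_a:
        sims = DataStructs.BulkTanimotoSimilarity(fa, list(fps_b))
        total += sum(1.0 - s for s in sims)
    return total / (len(fps_a) * len(fps_b))


def nn_distances(fps: Sequence, reference_fps: Sequence) -> list[float]:
    """Per-compound minimum Tanimoto distance to the reference set."""
    if not reference_fps:
        raise ValueError("near-neighbour distances need a non-empty reference")
    out = []
    for f in fps:
        sims = DataStructs.BulkTanimotoSimilarity(f, list(reference_fps))
        out.append(1.0 - max(sims))
    return out


def mean_nn_distance(fps: Sequence, reference_fps: Sequence) -> float:
    return float(np.mean(nn_distances(fps, reference_fps)))


def spread_rank(
    library_fps: Mapping[str, Sequence],
    reference_fps: Sequence = (),
    library_sizes: Mapping[str, int] | None = None,
    max_selected: int | None = None,
    min_spread: float | None = None,
) -> list[tuple[str, float]]:
    """Greedy max-min ordering of libraries by diversity to a growing pool.

    At each step the library with the largest mean near-neighbour distance
    to the current reference pool (original references plus all libraries
    selected so far) is emitted together with that distance (its *spread
    value*), and its compounds join the pool.  With no reference compounds
    the first pick maximises the mean nn distance to all *other* libraries
    pooled.  Ties break toward the larger library, then lexicographic id.
    Stops after *max_selected* picks or when the spread drops below
    *min_spread*.
    """
    if not library_fps:
        raise ValueError("spread_rank needs at least one library")
    sizes = library_sizes or {}
    remaining = dict(library_fps)
    pool = list(reference_fps)
    order: list[tuple[str, float]] = []
    while remaining:
        scores = {}
        for lib_id, fps in remaining.items():
            if pool:
                ref = pool
            else:  # no references yet: distance to all other libraries
                ref = [f for other, fp in remaining.items() if other != lib_id for f in fp]
                if not ref:
                    scores[lib_id] = 0.0
                    continue
            scores[lib_id] = mean_nn_distance(fps, ref)
        pick = min(
            scores,
            key=lambda k: (-scores[k], -sizes.get(k, len(remaining[k])), k),
        )
        value = scores[pick]
        if min_spread is not None and value < min_spread:
            break
        order.append((pick, value))
        pool.extend(remaining.pop(pick))
        if max_selected is not None and len(order) >= max_selected:
            break
    return order


def library_distance_report(
    libraries: Mapping[str, Sequence[str]],
    references: Mapping[str, Sequence[str]],
    params: FingerprintParams = FingerprintParams(),
    adequate_spread: float = 0.25,
    distinct_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-library average pairwise distance to each reference collection
    plus spread value and rank; thresholds only flag rows, never filter.

    Spread uses the union of the references as its starting pool.
    """
    lib_fps = {k: fingerprints(v, params) for k, v in libraries.items()}
    ref_fps = {k: fingerprints(v, params) for k, v in references.items()}
    rows = {
        lib_id: {
            "library": lib_id,
            "size": len(smiles),
            **{
                f"avg_dist_{ref}": avg_pairwise_distance(lib_fps[lib_id], rf)
                for ref, rf in ref_fps.items()
            },
        }
        for lib_id, smiles in libraries.items()
    }
    union = [f for rf in ref_fps.values() for f in rf]
    ranking = spread_rank(
        lib_fps, union, {k: len(v) for k, v in libraries.items()}
    )
    for rank, (lib_id, value) in enumerate(ranking, start=1):
        rows[lib_id]["spread_value"] = value
        rows[lib_id]["spread_rank"] = rank
        rows[lib_id]["adequate"] = value >= adequate_spread
        rows[lib_id]["distinct"] = value >= distinct_threshold
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["spread_rank"]))
    df.attrs["fingerprint_params"] = params
    df.attrs["spread_measure"] = "mean_nn_distance"
    df.attrs["pairwise_measure"] = "avg_pairwise_distance"
    return df


def bb_usage_report(selected_libs, bbs) -> pd.DataFrame:
    """How often each BB appears in the (capped) BB lists of the selected
    libDESIGN configs.

    *selected_libs* is an iterable of :class:`~deldesign.enumeration.EnumConfig`;
    usage of a BB = number of configs whose BB lists include it.  The frame
    carries per-BB usage with atom count and BBT multiplicity for the usual
    usage-versus-size aggregations.
    """
    usage: dict[str, int] = {}
    for cfg in selected_libs:
        ids = {b.bb_id for step in cfg.steps for b in step.bbs}
        for bb_id in ids:
            usage[bb_id] = usage.get(bb_id, 0) + 1
    rows = []
    for bb in bbs:
        rows.append(
            {
                "bb_id": bb.bb_id,
                "source": bb.source,
                "heavy_atoms": bb.heavy_atoms,
                "multiplicity": bb.bbt.multiplicity if bb.bbt else 0,
                "usage": usage.get(bb.bb_id, 0),
            }
        )
    return pd.DataFrame(rows, columns=["bb_id", "source", "heavy_atoms", "multiplicity", "usage"])


def plot_distance_vs_size(report: pd.DataFrame, distance_column: str, path) -> None:
    """Scatter of a distance column against library size (one dot per
    library), the panel type used to compare candidate libraries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report["size"], report[distance_column], s=12)
    ax.set_xscale("log")
    ax.set_xlabel("library size")
    ax.set_ylabel(distance_column)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
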