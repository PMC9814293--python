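"""Translate libDESIGNs into executable enumeration configs and sample
product structures without full enumeration.

A config is an ordered list of steps replaying the libDESIGN's edges: an
optional deprotection/scaffold rewrite per cycle followed by a connection
step carrying the cap-compliant BB list, each BB tagged with its BBT.  A
libDESIGN merges designs that may apply the same set of reactions in
different per-cycle roles (e.g. acylating the primary amine in cycle 2 and
the secondary in cycle 3, or vice versa), so the config also carries a
*route table*: for every per-node BBT combination, the (deprotection,
reaction) pair to apply at each cycle, taken from the member design with
that combination.  Sampling draws provenance tuples uniformly without
replacement from the Cartesian product of the BB lists and applies the
routed reaction SMARTS in sequence starting from a headpiece surrogate
fragment (the DNA itself is not modelled; the default surrogate is a
4-heavy-atom aminoethoxy stub).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .building_blocks import BuildingBlock, bbs_by_bbt, effective_heavy_atoms
from .libraries import LibDesign
from .reactions import Reaction

logger = logging.getLogger(__name__)

DEFAULT_HEADPIECE_SMILES = "NCCO"  # 4-heavy-atom amine-bearing linker stub


class EnumerationError(RuntimeError):
    pass


class TransformFailure(EnumerationError):
    """The reaction SMARTS produced no valid product for these reactants."""


@dataclass(frozen=True)
class BBEntry:
    bb_id: str
    smiles: str
    bbt: str  # compact BBT id string, the route-table key component
    effective_ha: int


@dataclass(frozen=True)
class CycleStep:
    """One cycle of the replay."""

    deprotection_transforms: tuple[tuple[str, str], ...]  # (dep_id, SMARTS)
    deprotection_delta: int  # net design-side atoms any deprotection adds
    transforms: tuple[tuple[str, str], ...]  # (rxn_id, reaction SMARTS)
    connection_delta: int  # design-side delta of the connection
    bbs: tuple[BBEntry, ...]


@dataclass(frozen=True)
class EnumConfig:
    lib_id: str
    headpiece_smiles: str
    headpiece_atoms: int
    steps: tuple[CycleStep, ...]
    # per-node BBT combination -> per-cycle (deprotection id or "", rxn id)
    routes: tuple[tuple[tuple[str, ...], tuple[tuple[str, str], ...]], ...]
    sample_size: int = 10_000
    seed: int = 0
    schema_version: int = 2

    @property
    def library_size(self) -> int:
        out = 1
        for s in self.steps:
            out *= len(s.bbs)
        return out

    def route_for(self, bbt_combo: tuple[str, ...]) -> tuple[tuple[str, str], ...]:
        for combo, route in self.routes:
            if combo == bbt_combo:
                return route
        raise EnumerationError(f"{self.lib_id}: no route for BBT combo {bbt_combo}")

    def predicted_heavy_atoms(self, provenance_idx: Sequence[int]) -> int:
        """Convolution-model size prediction for one provenance tuple."""
        total = self.headpiece_atoms
        combo = tuple(s.bbs[i].bbt for s, i in zip(self.steps, provenance_idx))
        route = self.route_for(combo)
        for step, i, (dep_id, _rxn) in zip(self.steps, provenance_idx, route):
            if dep_id:
                total += step.deprotection_delta
            total += step.connection_delta
            total += step.bbs[i].effective_ha
        return total


@dataclass
class XSet:
    """A random product sample from one libDESIGN."""

    lib_id: str
    seed: int
    # (product smiles, provenance tuple of bb_ids per cycle)
    products: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    n_transform_failures: int = 0

    @property
    def smiles(self) -> list[str]:
        return [s for s, _ in self.products]


def write_config(
    lib: LibDesign,
    bbs: Sequence[BuildingBlock],
    reactions: Sequence[Reaction],
    headpiece_smiles: str = DEFAULT_HEADPIECE_SMILES,
    source: str | None = None,
    sample_size: int = 10_000,
    seed: int = 0,
) -> EnumConfig:
    """Materialize a sized libDESIGN into an enumeration config.

    BB lists honour the per-node heavy-atom caps found by the maximizer
    (effective heavy atoms above a node's cap are excluded); the route table
    is built from the member designs (one representative per BBT
    combination, lowest trace first).  Raises :class:`EnumerationError`
    when a node has no BBs.
    """
    by_id = {r.rxn_id: r for r in reactions}
    pools = bbs_by_bbt(bbs, source=source)
    hp_mol = Chem.MolFromSmiles(headpiece_smiles)
    if hp_mol is None:
        raise EnumerationError(f"bad headpiece SMILES {headpiece_smiles!r}")

    routes: dict[tuple[str, ...], tuple[tuple[str, str], ...]] = {}
    for d in sorted(lib.members, key=lambda m: m.trace_line()):
        combo = tuple(str(t.bbt) for t in d.trace)
        routes.setdefault(
            combo, tuple((t.deprotection_id, t.rxn_id) for t in d.trace)
        )

    steps = []
    for cycle in range(lib.n_cycles):
        dep_ids, conn_ids = lib.edge_reactions[cycle]
        dep_deltas = {by_id[i].net_design_delta for i in dep_ids}
        if len(dep_deltas) > 1:
            raise EnumerationError(f"{lib.lib_id}: inconsistent deprotection deltas")
        conn_deltas = {by_id[i].design_side_atom_delta for i in conn_ids}
        if len(conn_deltas) != 1:
            raise EnumerationError(f"{lib.lib_id}: inconsistent connection deltas")
        cap = None if lib.selection is None else lib.selection[cycle]
        entries = []
        for bbt, rxn_id in sorted(lib.node_bbt_reaction[cycle].items()):
            rxn = by_id[rxn_id]
            for bb in sorted(pools.get(bbt, []), key=lambda b: b.bb_id):
                eff = effective_heavy_atoms(bb, rxn)
                if cap is not None and eff > cap:
                    continue
                entries.append(BBEntry(bb.bb_id, bb.smiles, str(bbt), eff))
        if not entries:
            raise EnumerationError(f"{lib.lib_id}: empty BB list at cycle {cycle}")
        steps.append(
            CycleStep(
                deprotection_transforms=tuple(
                    sorted((i, by_id[i].transform) for i in dep_ids)
                ),
                deprotection_delta=dep_deltas.pop() if dep_deltas else 0,
                transforms=tuple(sorted((i, by_id[i].transform) for i in conn_ids)),
                connection_delta=conn_deltas.pop(),
                bbs=tuple(entries),
            )
        )
    return EnumConfig(
        lib_id=lib.lib_id,
        headpiece_smiles=headpiece_smiles,
        headpiece_atoms=hp_mol.GetNumHeavyAtoms(),
        steps=tuple(steps),
        routes=tuple(sorted(routes.items())),
        sample_size=sample_size,
        seed=seed,
    )


def apply_transform(
    current: Chem.Mol, transform: str, bb: Chem.Mol | None = None
) -> tuple[Chem.Mol, int]:
    """Apply one reaction SMARTS; returns (product, number of distinct
    products seen).

    When the rewrite matches several sites the chemically distinct products
    are tie-broken deterministically by lowest canonical SMILES; the
    multiplicity is returned so callers can log regiochemical ambiguity.
    Raises :class:`TransformFailure` when no valid product results.
    """
    rxn = AllChem.ReactionFromSmarts(transform)
    reactants = (current,) if bb is None else (current, bb)
    if rxn.GetNumReactantTemplates() != len(reactants):
        raise TransformFailure(
            f"transform arity {rxn.GetNumReactantTemplates()} != {len(reactants)}"
        )
    candidates = set()
    for prods in rxn.RunReactants(reactants):
        mol = prods[0]
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        candidates.add(Chem.MolToSmiles(mol))
    if not candidates:
        raise TransformFailure("no product")
    best = min(candidates)
    return Chem.MolFromSmiles(best), len(candidates)


def _build_product(cfg: EnumConfig, idx: Sequence[int]) -> str:
    combo = tuple(s.bbs[i].bbt for s, i in zip(cfg.steps, idx))
    route = cfg.route_for(combo)
    mol = Chem.MolFromSmiles(cfg.headpiece_smiles)
    for step, i, (dep_id, rxn_id) in zip(cfg.steps, idx, route):
        if dep_id:
            mol, _ = apply_transform(mol, dict(step.deprotection_transforms)[dep_id])
        entry = step.bbs[i]
        mol, _ = apply_transform(
            mol, dict(step.transforms)[rxn_id], Chem.MolFromSmiles(entry.smiles)
        )
    return Chem.MolToSmiles(mol)


def _index_stream(rng: np.random.Generator, total: int, n: int):
    """Unique uniform indices from range(total); full shuffle when the
    request is a sizable fraction, hash-rejection otherwise."""
    if n >= total or n > total // 10:
        yield from rng.permutation(total)
    else:
        seen: set[int] = set()
        while len(seen) < total:
            i = int(rng.integers(total))
            if i in seen:
                continue
            seen.add(i)
            yield i


def _unrank(idx: int, sizes: Sequence[int]) -> tuple[int, ...]:
    out = []
    for s in reversed(sizes):
        out.append(idx % s)
        idx //= s
    return tuple(reversed(out))


def sample_provenance(
    cfg: EnumConfig, n: int, seed: int
) -> list[tuple[int, ...]]:
    """Uniform provenance index tuples without replacement, no structures.

    Useful for estimating additive properties (heavy atoms) of huge
    libraries through :meth:`EnumConfig.predicted_heavy_atoms` without
    paying for structure generation.
    """
    total = cfg.library_size
    n = min(n, total)
    sizes = [len(s.bbs) for s in cfg.steps]
    rng = np.random.default_rng(seed)
    out = []
    for flat in _index_stream(rng, total, n):
        out.append(_unrank(int(flat), sizes))
        if len(out) == n:
            break
    return out


def sample_products(
    cfg: EnumConfig,
    n: int | None = None,
    seed: int | None = None,
    max_failure_rate: float = 0.05,
    check_atoms: bool = True,
) -> XSet:
    """Enumerate a uniform random sample of *n* products without replacement.

    Provenance tuples are drawn uniformly from the Cartesian product of the
    per-cycle BB lists; each draw replays the config's transforms from the
    headpiece.  Failed transforms are logged and replaced by fresh draws; a
    failure rate above *max_failure_rate* aborts.  With *check_atoms* every
    product's heavy-atom count is asserted against the convolution model's
    prediction for its provenance tuple.  Fully deterministic under a fixed
    seed; requesting more than the library holds returns the full
    enumeration with a warning.
    """
    n = cfg.sample_size if n is None else n
    seed = cfg.seed if seed is None else seed
    if n < 1:
        raise ValueError("sample size must be >= 1")
    total = cfg.library_size
    if n > total:
        warnings.warn(
            f"{cfg.lib_id}: requested {n} > library size {total}; "
            "returning the full enumeration"
        )
        n = total
    sizes = [len(s.bbs) for s in cfg.steps]
    rng = np.random.default_rng(seed)
    xset = XSet(lib_id=cfg.lib_id, seed=seed)
    failures = 0
    for flat in _index_stream(rng, total, n):
        idx = _unrank(int(flat), sizes)
        try:
            smiles = _build_product(cfg, idx)
        except TransformFailure as err:
            failures += 1
            logger.warning("%s: transform failure at %s: %s", cfg.lib_id, idx, err)
            attempts = len(xset.products) + failures
            if attempts >= 20 and failures / attempts > max_failure_rate:
                raise EnumerationError(
                    f"{cfg.lib_id}: transform failure rate "
                    f"{failures}/{attempts} exceeds {max_failure_rate:.0%}"
                )
            continue
        if check_atoms:
            actual = Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()
            predicted = cfg.predicted_heavy_atoms(idx)
            if actual != predicted:
                raise EnumerationError(
                    f"{cfg.lib_id}: heavy-atom mismatch at {idx}: "
                    f"model {predicted}, product {actual}"
                )
        provenance = tuple(
            step.bbs[i].bb_id for step, i in zip(cfg.steps, idx)
        )
        xset.products.append((smiles, provenance))
        if len(xset.products) == n:
            break
    xset.n_transform_failures = failures
    return xset


# ---------------------------------------------------------------------------
# Serialization


def config_to_dict(cfg: EnumConfig) -> dict:
    return {
        "schema_version": cfg.schema_version,
        "lib_id": cfg.lib_id,
        "headpiece_smiles": cfg.headpiece_smiles,
        "headpiece_atoms": cfg.headpiece_atoms,
        "sample_size": cfg.sample_size,
        "seed": cfg.seed,
        "routes": [
            {"combo": list(combo), "route": [list(step) for step in route]}
            for combo, route in cfg.routes
        ],
        "steps": [
            {
                "deprotection_transforms": [list(t) for t in s.deprotection_transforms],
                "deprotection_delta": s.deprotection_delta,
                "transforms": [list(t) for t in s.transforms],
                "connection_delta": s.connection_delta,
                "bbs": [
                    [b.bb_id, b.smiles, b.bbt, b.effective_ha] for b in s.bbs
                ],
            }
            for s in cfg.steps
        ],
    }


def config_from_dict(doc: dict) -> EnumConfig:
    steps = tuple(
        CycleStep(
            deprotection_transforms=tuple(
                tuple(t) for t in s["deprotection_transforms"]
            ),
            deprotection_delta=s["deprotection_delta"],
            transforms=tuple(tuple(t) for t in s["transforms"]),
            connection_delta=s["connection_delta"],
            bbs=tuple(BBEntry(*b) for b in s["bbs"]),
        )
        for s in doc["steps"]
    )
    routes = tuple(
        (tuple(r["combo"]), tuple(tuple(step) for step in r["route"]))
        for r in doc["routes"]
    )
    return EnumConfig(
        lib_id=doc["lib_id"],
        headpiece_smiles=doc["headpiece_smiles"],
        headpiece_atoms=doc["headpiece_atoms"],
        steps=steps,
        routes=routes,
        sample_size=doc["sample_size"],
        seed=doc["seed"],
        schema_version=doc.get("schema_version", 2),
    )


def save_config(cfg: EnumConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(cfg), fh, indent=1)


def load_config(path: str | Path) -> EnumConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def save_xset(xset: XSet, path: str | Path) -> None:
    """SMILES file with columns smiles, product_id, bb_ids, libdesign_id."""
    with open(path, "w") as fh:
        fh.write("smiles\tproduct_id\tbb_ids\tlibdesign_id\n")
        for i, (smiles, prov) in enumerate(xset.products):
            fh.write(f"{smiles}\t{xset.lib_id}_{i:06d}\t{';'.join(prov)}\t{xset.lib_id}\n")


def load_xset(path: str | Path) -> XSet:
    products = []
    lib_id = ""
    with open(path) as fh:
        fh.readline()
        for line in fh:
            smiles, _pid, bb_ids, lib_id = line.rstrip("\n").split("\t")
            products.append((smiles, tuple(bb_ids.split(";"))))
    return XSet(lib_id=lib_id, seed=-1, products=products)
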