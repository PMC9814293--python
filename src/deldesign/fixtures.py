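"""Synthetic inputs with known ground truth: FG ontologies, reaction sets,
building-block collections and reference compound sets.

Real DEL building-block catalogues and screening collections are proprietary,
so every pipeline stage here is exercised on generated data.  BBs are
assembled from a vetted template table (one attachment-ready fragment per
FG) joined by randomly branched alkyl linkers, which guarantees chemical
validity and makes the intended BBT of every BB part of the generator's
manifest.  Heavy-atom counts are drawn from truncated normal distributions;
the internal source is parameterised heavier than the external one, matching
the qualitative shape of corporate versus vendor catalogues.  Everything is
seeded and byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .building_blocks import FilterPolicy
from .ontology import FG, FGOntology, IncompatibilityMatrix
from .reactions import Reaction, ReactionFGMatrices, ReactionSet

# ---------------------------------------------------------------------------
# Default ontology (a representative subset; the full production FG list is
# supplied by the user as a config file)

_FGS = [
    # id, name, smarts, parent, protected, tags
    (1, "amine", "[$([NX3;H2;!$(NC=O);!$(NS=O);!$(N=*);!$(N-[N+])]),$([NX3;H1;!$(NC=O);!$(NS=O);!$(N=*);!$(N-c);!$(N-[N+])])]", None, False, ("strong_nucleophile",)),
    (2, "amine_aliphatic", "[NX3;H1,H2;!$(NC=O);!$(NS=O);!$(N=*);!$(N-c);!$(N-[N+])]", 1, False, ("strong_nucleophile",)),
    (3, "amine_aliphatic_primary", "[NX3;H2;!$(NC=O);!$(NS=O);!$(N=*);!$(N-c);!$(N-[N+])]", 2, False, ("strong_nucleophile",)),
    (4, "amine_aliphatic_secondary", "[NX3;H1;!$(NC=O);!$(NS=O);!$(N=*);!$(N-c);!$(N-[N+])]", 2, False, ("strong_nucleophile",)),
    (5, "amine_aromatic", "[NX3;H2;$(N-c);!$(NC=O)]", 1, False, ("strong_nucleophile",)),
    (6, "acid", "[CX3](=O)[OX2H1]", None, False, ()),
    (7, "aldehyde", "[CX3H1](=O)[#6]", None, False, ()),
    (8, "ketone", "[#6][CX3](=O)[#6;!$([CX3]=O)]", None, False, ()),
    (9, "phenol", "[OX2H][c]", None, False, ()),
    (10, "thiol", "[SX2H]", None, False, ("strong_nucleophile",)),
    (11, "azide", "[NX2]=[NX2+]=[NX1-]", None, False, ()),
    (12, "alkyne_terminal", "[CX2]#[CX2H1]", None, False, ()),
    (13, "aryl_halide", "c-[Br,I]", None, False, ()),
    (14, "boronate", "c-[BX3]([OX2])[OX2]", None, False, ()),
    (15, "sulfonyl_chloride", "[SX4](=O)(=O)Cl", None, False, ("strong_electrophile",)),
    (16, "isocyanate", "[NX2]=[CX2]=[OX1]", None, False, ("strong_electrophile",)),
    (17, "boc_amine", "[NX3;H1]C(=O)O[CX4]([CH3])([CH3])[CH3]", None, True, ()),
    (18, "fmoc_amine", "[NX3;H1]C(=O)OCC1c2ccccc2-c2ccccc21", None, True, ()),
    (20, "nitro", "[#6][N+](=O)[O-]", None, False, ()),
    (19, "ortho_fluoronitroarene", "F-c:c-[N+](=O)[O-]", 20, False, ()),
    (21, "dichlorotriazine", "Clc1nc(Cl)nc(*)n1", None, False, ()),
    (22, "monochlorotriazine", "Clc1nc([#6,#7,#8,#16])nc([#6,#7,#8,#16])n1", None, False, ()),
    (23, "ester", "[#6][CX3](=O)[OX2][#6]", None, False, ()),
    (24, "nitroarylamine", "[NX3;H1]([#6])-c:c-[N+](=O)[O-]", None, False, ()),
]

DEFAULT_CLASS_RULES = [
    ("strong_electrophile", "strong_electrophile"),
    ("strong_nucleophile", "strong_electrophile"),
    ("strong_nucleophile", "strong_nucleophile"),
]

DISALLOWED_FINAL_FGS = (15, 16, 21, 22, 24)


def default_ontology() -> FGOntology:
    return FGOntology(
        FG(id=i, name=n, smarts=s, parent_id=p, protected=prot, class_tags=t)
        for i, n, s, p, prot, t in _FGS
    )


def default_incompatibility(ontology: FGOntology | None = None) -> IncompatibilityMatrix:
    ontology = ontology or default_ontology()
    return IncompatibilityMatrix.from_rules(ontology, class_rules=DEFAULT_CLASS_RULES)


# ---------------------------------------------------------------------------
# Reactions (transforms verified to add exactly the declared atom deltas)

_PRI = "[NX3;H2;!$(NC=O);!$(NS=O);!$(N=*);!$(N-c)"
_SEC = "[NX3;H1;!$(NC=O);!$(NS=O);!$(N=*);!$(N-c)"

_REACTIONS = [
    # connecting: rxn_id, (design_fg, bb_fg), outputs, enum, ds, bb, transform, status
    ("c_amide_pri", (6, 3), (), 1, -1, 0,
     f"[CX3:1](=[O:2])[OX2H1].{_PRI}:3]>>[C:1](=[O:2])[N:3]", "production"),
    ("c_amide_sec", (6, 4), (), 1, -1, 0,
     f"[CX3:1](=[O:2])[OX2H1].{_SEC}:3]>>[C:1](=[O:2])[N:3]", "production"),
    ("c_acyl_pri", (3, 6), (), 2, 0, -1,
     f"{_PRI}:1].[CX3:2](=[O:3])[OX2H1]>>[N:1][C:2]=[O:3]", "production"),
    ("c_acyl_sec", (4, 6), (), 2, 0, -1,
     f"{_SEC}:1].[CX3:2](=[O:3])[OX2H1]>>[N:1][C:2]=[O:3]", "production"),
    ("c_red_am", (3, 7), (4,), 3, 0, -1,
     f"{_PRI}:1].[CX3H1:2](=[OX1])[#6:3]>>[N:1][CH2:2][#6:3]", "production"),
    ("c_snar_phenol", (21, 9), (22,), 4, -1, 0,
     "[Cl][c:1]1[n:2][c:3]([Cl])[n:4][c:5][n:6]1.[OX2H1:7][c:8]>>"
     "[c:1]1([O:7][c:8])[n:2][c:3]([Cl])[n:4][c:5][n:6]1", "production"),
    ("c_snar_am_pri", (22, 3), (), 5, -1, 0,
     "[Cl][c:1]1[n:2][c:3]([#7,#8:9])[n:4][c:5]([#7,#8:10])[n:6]1."
     f"{_PRI}:7]>>[N:7][c:1]1[n:2][c:3]([*:9])[n:4][c:5]([*:10])[n:6]1", "production"),
    ("c_snar_am_sec", (22, 4), (), 5, -1, 0,
     "[Cl][c:1]1[n:2][c:3]([#7,#8:9])[n:4][c:5]([#7,#8:10])[n:6]1."
     f"{_SEC}:7]>>[N:7][c:1]1[n:2][c:3]([*:9])[n:4][c:5]([*:10])[n:6]1", "production"),
    ("c_snar_ofna", (3, 19), (24,), 6, 0, -1,
     f"{_PRI}:1].[F][c:2]([c:3]-[NX3+:4](=[OX1:5])[O-:6])>>"
     "[N:1][c:2][c:3][N+:4](=[O:5])[O-:6]", "production"),
    ("c_benzimidazole", (24, 7), (), 7, -2, -1,
     "[O-][N+](=O)[c:1][c:2][NX3H1:3][#6:4].[CX3H1:5](=[OX1])[#6:6]>>"
     "[#6:4][n:3]1[c:5]([#6:6])n[c:1][c:2]1", "production"),
    ("c_sulfonamide", (3, 15), (), 8, 0, -1,
     f"{_PRI}:1].[SX4:2](=[O:3])(=[O:4])(Cl)[#6:5]>>"
     "[N:1][S:2](=[O:3])(=[O:4])[#6:5]", "validated"),
]

_DEPROTECTIONS = [
    # rxn_id, design_fg, outputs, enum, ds_delta, scaffold, transform, status
    ("d_boc", 17, (3,), 101, -7, 0,
     "[NX3;H1:1]C(=O)OC(C)(C)C>>[N:1]", "production"),
    ("d_fmoc", 18, (3,), 102, -17, 0,
     "[NX3;H1:1]C(=O)OCC1c2ccccc2-c2ccccc21>>[N:1]", "validated"),
    ("d_cyanuric", 3, (21,), 103, 0, 8,
     f"{_PRI}:1]>>[N:1]c1nc(Cl)nc(Cl)n1", "production"),
]


def default_reactions() -> ReactionSet:
    rxns = [
        Reaction(
            rxn_id=rid, kind="connecting", inputs=inp, outputs=out,
            enum_index=enum, design_side_atom_delta=ds, bb_side_atom_delta=bb,
            transform=tf, production_status=status,
        )
        for rid, inp, out, enum, ds, bb, tf, status in _REACTIONS
    ] + [
        Reaction(
            rxn_id=rid, kind="deprotection", inputs=(fg,), outputs=out,
            enum_index=enum, design_side_atom_delta=ds, scaffold_atoms=sc,
            transform=tf, production_status=status,
        )
        for rid, fg, out, enum, ds, sc, tf, status in _DEPROTECTIONS
    ]
    return ReactionSet(rxns)


def default_reaction_fg_matrices() -> ReactionFGMatrices:
    """Deliberately small on-/off-DNA block lists for the default system:
    competing live FGs block a reaction on-DNA; cross-reactive spectator FGs
    on the incoming BB block it off-DNA (phenol is allowed on-DNA during
    triazine amination but blocked off-DNA, an asymmetric case)."""
    on_dna = {
        ("c_amide_pri", 3), ("c_amide_pri", 4),
        ("c_amide_sec", 3), ("c_amide_sec", 4),
        ("c_red_am", 7),
        ("c_snar_phenol", 9),
    }
    off_dna = {
        ("c_acyl_pri", 7), ("c_acyl_sec", 7),
        ("c_snar_am_pri", 9), ("c_snar_am_sec", 9),
    }
    return ReactionFGMatrices(on_dna=on_dna, off_dna=off_dna)


# ---------------------------------------------------------------------------
# BB assembly templates.  ``prefix`` is a format string taking the alkyl
# chain (plus optional suffix fragments); ``suffix`` is appended after a
# chain.  Chains keep FG environments apart so annotation stays exact.

_TEMPLATES: dict[int, dict] = {
    3: {"prefix": "N{chain}", "suffix": "N"},
    4: {"prefix": "CN{chain}", "suffix": "NC"},
    5: {"prefix": "Nc1ccc({chain})cc1", "suffix": "c1ccc(N)cc1"},
    6: {"prefix": "OC(=O){chain}", "suffix": "C(=O)O"},
    7: {"prefix": "O=C{chain}", "suffix": "C=O"},
    8: {"prefix": "CC(=O){chain}", "suffix": "C(=O)C"},
    9: {"prefix": "Oc1ccc({chain})cc1", "suffix": "c1ccc(O)cc1"},
    10: {"prefix": "S{chain}", "suffix": "S"},
    11: {"prefix": "[N-]=[N+]=N{chain}", "suffix": "N=[N+]=[N-]"},
    12: {"prefix": "C#C{chain}", "suffix": "C#C"},
    13: {"prefix": "Brc1ccc({chain})cc1", "suffix": "c1ccc(Br)cc1"},
    14: {"prefix": "OB(O)c1ccc({chain})cc1", "suffix": "c1ccc(B(O)O)cc1"},
    15: {"prefix": "ClS(=O)(=O){chain}", "suffix": "S(=O)(=O)Cl"},
    16: {"prefix": "O=C=N{chain}", "suffix": "N=C=O"},
    17: {"prefix": "CC(C)(C)OC(=O)N{chain}", "suffix": "NC(=O)OC(C)(C)C"},
    18: {"prefix": "O=C(N{chain})OCC1c2ccccc2-c2ccccc21",
         "suffix": "NC(=O)OCC1c2ccccc2-c2ccccc21"},
    19: {"prefix": "Fc1ccc({chain})cc1[N+](=O)[O-]",
         "suffix": "c1ccc(F)c([N+](=O)[O-])c1"},
    20: {"prefix": "[O-][N+](=O){chain}", "suffix": "[N+](=O)[O-]"},
    23: {"prefix": "COC(=O){chain}", "suffix": "C(=O)OC"},
    24: {"prefix": "[O-][N+](=O)c1ccccc1N{chain}",
         "suffix": "Nc1ccccc1[N+](=O)[O-]"},
}


class FixtureError(ValueError):
    pass


def _alkyl(n: int, rng: np.random.Generator, ring_bias: float = 0.45) -> str:
    """Random saturated linker of *n* carbons as a SMILES fragment open at
    both ends (prefix bonds to the first atom, any suffix to the last).

    Larger linkers embed 1,4-linked cyclohexane rings with probability
    *ring_bias* per opportunity, keeping rotatable-bond counts realistic for
    catalogue building blocks."""
    if n <= 0:
        raise FixtureError("chain length must be positive")
    if n >= 6 and rng.random() < ring_bias:
        pre = int(rng.integers(0, n - 5))
        post = n - 6 - pre
        out = ("" if pre == 0 else _alkyl(pre, rng, ring_bias)) + "C9CCC(CC9)"
        if post > 0:
            out += _alkyl(post, rng, ring_bias)
        return out
    if n <= 2:
        return "C" * n
    backbone = int(rng.integers(max(2, (n + 1) // 2), n + 1))
    remaining = n - backbone
    # interior positions hold up to two methyl/ethyl branches each
    load = {i: 0 for i in range(1, backbone - 1)}
    branches: dict[int, list[str]] = {}
    while remaining > 0:
        free = [i for i, l in load.items() if l < 2]
        if not free:
            backbone += remaining
            remaining = 0
            break
        i = int(rng.choice(free))
        length = int(min(remaining, rng.integers(1, 3)))
        branches.setdefault(i, []).append("C" * length)
        load[i] += 1
        remaining -= length
    return "".join(
        "C" + "".join(f"({b})" for b in branches.get(i, ()))
        for i in range(backbone)
    )


def assemble_bb_smiles(
    fg_ids: tuple[int, ...], total_chain: int, rng: np.random.Generator
) -> str:
    """Join one prefix template and up to two suffix templates with alkyl
    chains totalling *total_chain* carbons."""
    fg_ids = tuple(fg_ids)
    for f in fg_ids:
        if f not in _TEMPLATES:
            raise FixtureError(f"no assembly template for FG {f}")
    prefix = _TEMPLATES[fg_ids[0]]["prefix"]
    if len(fg_ids) == 1:
        return prefix.format(chain=_alkyl(total_chain, rng))
    if len(fg_ids) == 2:
        inner = _alkyl(total_chain, rng)
        return prefix.format(chain=inner + _TEMPLATES[fg_ids[1]]["suffix"])
    if len(fg_ids) == 3:
        if total_chain < 3:
            total_chain = 3
        a = int(rng.integers(1, total_chain - 1))
        b = total_chain - a - 1
        chain = (
            _alkyl(a, rng)
            + f"C({_alkyl(b, rng)}{_TEMPLATES[fg_ids[1]]['suffix']})"
            + _TEMPLATES[fg_ids[2]]["suffix"]
        )
        return prefix.format(chain=chain)
    raise FixtureError("at most 3 FGs per BB")


@dataclass
class CollectionRequest:
    """One homogeneous slice of a synthetic BB collection."""

    fg_ids: tuple[int, ...]
    n: int
    source: str = "internal"
    ha_mean: float = 14.0
    ha_sd: float = 3.0
    ha_min: int = 5
    ha_max: int = 28
    id_prefix: str = "BB"


@dataclass
class FixtureManifest:
    seed: int
    requests: list = field(default_factory=list)
    entries: list = field(default_factory=list)  # dicts with ground truth

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "requests": self.requests, "entries": self.entries},
            indent=1,
        )


def make_bb_collection(
    requests: list[CollectionRequest], seed: int = 0
) -> tuple[list[tuple[str, str, str]], FixtureManifest]:
    """Generate (bb_id, smiles, source) records plus the ground-truth manifest.

    Heavy-atom targets are drawn from a truncated normal per request; the
    chain length is solved so the assembled molecule hits the target, and
    duplicate structures are re-drawn (growing the chain as a last resort)
    so standardization never merges two records.  Regenerating with the same
    seed reproduces the collection byte-for-byte.
    """
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(seed=seed)
    records: list[tuple[str, str, str]] = []
    used: set[str] = set()
    counter = 0
    for req in requests:
        base_probe = assemble_bb_smiles(req.fg_ids, 2, np.random.default_rng(0))
        mol = Chem.MolFromSmiles(base_probe)
        if mol is None:
            raise FixtureError(f"template assembly failed for {req.fg_ids}")
        base_atoms = mol.GetNumHeavyAtoms() - 2  # atoms contributed by FG parts
        min_chain = 3 if len(req.fg_ids) == 3 else 1
        for _ in range(req.n):
            target = int(round(rng.normal(req.ha_mean, req.ha_sd)))
            target = max(req.ha_min, min(req.ha_max, target))
            chain = max(min_chain, target - base_atoms)
            smiles = None
            for attempt in range(200):
                cand = assemble_bb_smiles(req.fg_ids, chain, rng)
                mol = Chem.MolFromSmiles(cand)
                cand = Chem.MolToSmiles(mol)
                # keep fixture BBs inside the default curation thresholds
                if Descriptors.NumRotatableBonds(mol) > 10:
                    continue
                if cand not in used:
                    smiles = cand
                    break
                if attempt % 4 == 3 and base_atoms + chain < 30:
                    chain += 1  # escape exhausted small-isomer spaces
            if smiles is None:
                raise FixtureError(
                    f"could not generate a unique BB for {req.fg_ids} at chain {chain}"
                )
            used.add(smiles)
            counter += 1
            bb_id = f"{req.id_prefix}{counter:05d}"
            actual = Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()
            records.append((bb_id, smiles, req.source))
            manifest.entries.append(
                {
                    "bb_id": bb_id,
                    "smiles": smiles,
                    "fg_ids": list(req.fg_ids),
                    "heavy_atoms": actual,
                    "source": req.source,
                }
            )
        manifest.requests.append(
            {
                "fg_ids": list(req.fg_ids),
                "n": req.n,
                "source": req.source,
                "ha_mean": req.ha_mean,
                "ha_sd": req.ha_sd,
                "ha_min": req.ha_min,
                "ha_max": req.ha_max,
            }
        )
    return records, manifest


# ---------------------------------------------------------------------------
# Reference collections

_REF_SCAFFOLDS = [
    "CC(=O)Nc1ccc({r})cc1",
    "O=C(N{r})c1ccccc1",
    "c1ccc(OC{r})cc1",
    "CN1CCN({r})CC1",
    "O=C(C{r})N1CCCC1",
    "c1ccc2[nH]c(C{r})nc2c1",
    "CC(C)Oc1ccc({r})cn1",
    "O=S(=O)(N{r})c1ccc(C)cc1",
]


def make_reference_collection(
    n: int, mean_ha: float = 25.0, sd_ha: float = 4.0, seed: int = 0
) -> list[str]:
    """Drug-like reference set assembled from common pharmacophore scaffolds
    plus random alkyl decoration, targeting a configurable mean size."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    used: set[str] = set()
    while len(out) < n:
        template = _REF_SCAFFOLDS[int(rng.integers(len(_REF_SCAFFOLDS)))]
        base = Chem.MolFromSmiles(template.format(r="C")).GetNumHeavyAtoms() - 1
        target = int(round(rng.normal(mean_ha, sd_ha)))
        chain = max(1, target - base)
        smiles = template.format(r=_alkyl(chain, rng))
        smiles = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        if smiles in used:
            continue
        used.add(smiles)
        out.append(smiles)
    return out


# ---------------------------------------------------------------------------
# Toy systems


@dataclass
class ToySystem:
    ontology: FGOntology
    incompat: IncompatibilityMatrix
    reactions: ReactionSet
    matrices: ReactionFGMatrices
    bb_records: list[tuple[str, str, str]]
    manifest: FixtureManifest
    references: dict[str, list[str]]
    headpiece_fgs: list[int]
    disallowed_final_fgs: tuple[int, ...]
    filter_policy: FilterPolicy


def _subset_ontology(ids: list[int]) -> FGOntology:
    keep = set(ids)
    fgs = []
    for i, n, s, p, prot, t in _FGS:
        if i in keep:
            fgs.append(
                FG(id=i, name=n, smarts=s, parent_id=p if p in keep else None,
                   protected=prot, class_tags=t)
            )
    return FGOntology(fgs)


def make_toy_system(scale: str = "small", seed: int = 0) -> ToySystem:
    """Self-contained study systems.

    ``small``: 5 FGs (null, primary amine, acid, aldehyde, Boc-amine),
    3 reactions (acylation, reductive amination, Boc removal) and ~30 BBs —
    exhaustively checkable against brute-force oracles.

    ``medium``: the full default ontology and reaction set (triazine and
    benzimidazole motifs included) with a ~2,000-BB two-source collection
    and two synthetic reference sets, for end-to-end integration runs.
    """
    if scale == "small":
        ontology = _subset_ontology([3, 6, 7, 17])
        incompat = IncompatibilityMatrix.from_rules(
            ontology, class_rules=DEFAULT_CLASS_RULES
        )
        rxns = ReactionSet(
            [r for r in default_reactions() if r.rxn_id in
             ("c_acyl_pri", "c_red_am", "d_boc")]
        )
        requests = [
            CollectionRequest((6,), 10, "internal", 11, 2.5, 5, 20, "ACI"),
            CollectionRequest((7,), 8, "internal", 10, 2.5, 5, 20, "ALD"),
            CollectionRequest((6, 17), 8, "internal", 17, 2.5, 12, 24, "ABO"),
            CollectionRequest((7, 17), 4, "internal", 16, 2.5, 12, 24, "DBO"),
        ]
        records, manifest = make_bb_collection(requests, seed=seed)
        references = {"REF": make_reference_collection(15, 18.0, 3.0, seed + 1)}
        return ToySystem(
            ontology=ontology,
            incompat=incompat,
            reactions=rxns,
            matrices=ReactionFGMatrices(),
            bb_records=records,
            manifest=manifest,
            references=references,
            headpiece_fgs=[3],
            disallowed_final_fgs=(),
            filter_policy=FilterPolicy(),
        )
    if scale == "medium":
        ontology = default_ontology()
        incompat = default_incompatibility(ontology)
        internal = [
            CollectionRequest((6,), 260, "internal", 15, 4, 5, 28, "IAC"),
            CollectionRequest((3,), 150, "internal", 14, 4, 5, 28, "IAP"),
            CollectionRequest((4,), 90, "internal", 15, 4, 5, 28, "IAS"),
            CollectionRequest((7,), 120, "internal", 14, 4, 5, 28, "IAL"),
            CollectionRequest((9,), 110, "internal", 15, 4, 8, 28, "IPH"),
            CollectionRequest((15,), 40, "internal", 14, 3, 8, 26, "ISC"),
            CollectionRequest((6, 17), 90, "internal", 19, 3, 14, 28, "IBA"),
            CollectionRequest((6, 19), 70, "internal", 17, 3, 13, 28, "IOF"),
            CollectionRequest((9, 17), 50, "internal", 19, 3, 15, 28, "IPB"),
            CollectionRequest((7, 17), 40, "internal", 18, 3, 14, 28, "IDB"),
            CollectionRequest((6, 9, 17), 30, "internal", 22, 2.5, 18, 28, "ITR"),
        ]
        external = [
            CollectionRequest((6,), 220, "external", 11, 3, 5, 24, "XAC"),
            CollectionRequest((3,), 160, "external", 10, 3, 5, 24, "XAP"),
            CollectionRequest((4,), 80, "external", 11, 3, 5, 24, "XAS"),
            CollectionRequest((7,), 110, "external", 10, 3, 5, 24, "XAL"),
            CollectionRequest((9,), 90, "external", 12, 3, 8, 24, "XPH"),
            CollectionRequest((6, 17), 60, "external", 16, 3, 13, 26, "XBA"),
            CollectionRequest((6, 19), 40, "external", 15, 3, 13, 26, "XOF"),
            CollectionRequest((7, 17), 30, "external", 16, 3, 14, 26, "XDB"),
            CollectionRequest((6, 9, 17), 15, "external", 20, 2.5, 18, 27, "XTR"),
        ]
        records, manifest = make_bb_collection(internal + external, seed=seed)
        references = {
            "REF_DEL": make_reference_collection(120, 30.0, 5.0, seed + 1),
            "REF_SCREEN": make_reference_collection(150, 25.0, 4.0, seed + 2),
        }
        return ToySystem(
            ontology=ontology,
            incompat=incompat,
            reactions=default_reactions(),
            matrices=default_reaction_fg_matrices(),
            bb_records=records,
            manifest=manifest,
            references=references,
            headpiece_fgs=[3],
            disallowed_final_fgs=DISALLOWED_FINAL_FGS,
            filter_policy=FilterPolicy(),
        )
    raise FixtureError(f"unknown scale {scale!r}")


def headpiece_fragment(fg_id: int, target_atoms: int = 4) -> str:
    """Surrogate headpiece fragment carrying *fg_id*, sized to
    *target_atoms* heavy atoms when the template permits (the DNA and its
    linker are represented only by this stub)."""
    if fg_id == 3 and target_atoms == 4:
        return "NCCO"  # aminoethoxy stub standing in for the PEG linker
    if fg_id not in _TEMPLATES:
        raise FixtureError(f"no headpiece template for FG {fg_id}")
    prefix = _TEMPLATES[fg_id]["prefix"]
    best = None
    for k in range(1, max(2, target_atoms + 1)):
        smiles = prefix.format(chain="C" * k)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        atoms = mol.GetNumHeavyAtoms()
        if best is None or abs(atoms - target_atoms) < abs(best[1] - target_atoms):
            best = (smiles, atoms)
        if atoms >= target_atoms:
            break
    if best is None:
        raise FixtureError(f"could not build headpiece for FG {fg_id}")
    return Chem.MolToSmiles(Chem.MolFromSmiles(best[0]))


# ---------------------------------------------------------------------------
# Run-directory emission (CLI `fixtures` subcommand)


def write_run_inputs(directory: str | Path, scale: str = "medium", seed: int = 0) -> Path:
    """Emit a complete, file-based run directory for the CLI pipeline."""
    from .ontology import save_ontology
    from .reactions import save_reaction_fg_matrices, save_reactions
    import csv
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    system = make_toy_system(scale, seed=seed)
    save_ontology(system.ontology, directory / "ontology.yaml")
    save_reactions(system.reactions, directory / "reactions.yaml")
    save_reaction_fg_matrices(system.matrices, directory / "reaction_fg_matrices.yaml")
    with open(directory / "incompatibility.yaml", "w") as fh:
        yaml.safe_dump({"class_rules": [list(r) for r in DEFAULT_CLASS_RULES]}, fh)
    with open(directory / "bbs.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bb_id", "smiles", "source"])
        writer.writerows(system.bb_records)
    (directory / "manifest.json").write_text(system.manifest.to_json())
    refdir = directory / "references"
    refdir.mkdir(exist_ok=True)
    for name, smiles in system.references.items():
        with open(refdir / f"{name}.smi", "w") as fh:
            for i, s in enumerate(smiles):
                fh.write(f"{s}\t{name}_{i:05d}\n")
    params = {
        "n_cycles": 2,
        "reaction_scope": "production",
        "min_library_size": 20000,
        "target_median_atoms": 29,
        "headpiece_atoms": 4,
        "sample_size": 2000,
        "seed": seed,
        "headpiece_fgs": system.headpiece_fgs,
        "disallowed_final_fgs": list(system.disallowed_final_fgs),
        "ontology": "ontology.yaml",
        "reactions": "reactions.yaml",
        "reaction_fg_matrices": "reaction_fg_matrices.yaml",
        "incompatibility": "incompatibility.yaml",
        "bbs": "bbs.csv",
        "references": "references",
    }
    with open(directory / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)
    return directory
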