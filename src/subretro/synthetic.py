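"""Synthetic reaction corpora with known conserved cores.

The generator emulates the structural premise the whole pipeline exploits:
families of reactions share a conserved molecular core (an aromatic ring
system carrying short alkyl arms) while peripheral functional groups attached
at the arm ends vary between product and reactants.  Each reaction follows a
deterministic substitution rule — the attached group with the highest
template priority is the reactive one, and each product-side group maps to a
fixed reactant-side group plus an optional leaving/co-reactant species — so
the product determines its golden reactants exactly and the mapping is
learnable from data.

Distractor reactions are assembled from a disjoint atom alphabet
(fluorine/sulfur chains; family molecules contain no F or S), which
guarantees zero shared atom environments at radius >= 2 with any family
molecule.

A ground-truth manifest records, per reaction, the family core atoms and the
conserved atom set (everything except the reactive product-side group) as
indices into the canonical product, making substructure correctness
decidable without subgraph search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule, ReactionRecord, canonicalize
from .substructure import prune_atoms

# Aromatic ring systems used for cores (no S/F: those are distractor-only).
_RING_SYSTEMS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "c1ccoc1",
    "c1cnc2ccccc2c1",
)

# (product-side group, reactant-side group, extra co-reactant species or None),
# ordered by priority: the highest-priority group present in a product is the
# reactive site.  Groups attach through a single bond at their first atom.
GROUP_TEMPLATES: tuple[tuple[str, str, str | None], ...] = (
    ("OC", "Br", "CO"),  # methyl ether  <- bromide + methanol
    ("C#N", "Br", None),  # nitrile       <- bromide + cyanide source
    ("N(C)C", "Cl", "CNC"),  # dimethylamine <- chloride + amine
    ("OCC", "Cl", "CCO"),  # ethyl ether   <- chloride + ethanol
    ("c1ccccc1", "Br", "OB(O)c1ccccc1"),  # aryl coupling <- halide + boronic acid
    ("OC(C)=O", "O", "CC(O)=O"),  # acetate ester <- alcohol + acetic acid
    ("O", "OC(C)=O", None),  # alcohol       <- ester hydrolysis
    ("Cl", "O", None),  # chloride      <- alcohol
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_cores: int = 12
    core_size: tuple[int, int] = (8, 18)  # heavy atoms incl. arms
    n_fragment_types: int = 8
    max_attachments: int = 3
    n_reactions: int = 500
    distractor_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.distractor_fraction < 1):
            raise ValueError("distractor_fraction must be in [0, 1)")
        if min(self.n_cores, self.n_fragment_types, self.n_reactions) <= 0:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class Core:
    """A conserved scaffold: ring system plus alkyl arms ending in
    attachment atoms (indices into ``mol``)."""

    mol: Chem.Mol = field(repr=False)
    attachment_atoms: tuple[int, ...]
    family_id: int

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass(frozen=True)
class ManifestEntry:
    reaction_id: str
    family_id: int
    is_distractor: bool
    core_atoms: tuple[int, ...]  # canonical product atom indices
    conserved_atoms: tuple[int, ...]  # product minus reactive group
    reactive_group_atoms: tuple[int, ...]


@dataclass
class DatasetBundle:
    train: list[ReactionRecord]
    valid: list[ReactionRecord]
    test: list[ReactionRecord]
    manifest: dict[str, ManifestEntry]

    @property
    def all_records(self) -> list[ReactionRecord]:
        return self.train + self.valid + self.test


def _attach_chain(editable: Chem.RWMol, anchor: int, length: int) -> int:
    """Append an sp3 carbon chain to ``anchor``; return the terminal index."""
    previous = anchor
    for _ in range(length):
        idx = editable.AddAtom(Chem.Atom(6))
        editable.AddBond(previous, idx, Chem.BondType.SINGLE)
        previous = idx
    return previous


def _attach_group(
    editable: Chem.RWMol, anchor: int, group_smiles: str
) -> tuple[Chem.RWMol, list[int]]:
    """Attach a group (single bond at its first atom); returns the new
    editable mol and the group's atom indices."""
    group = Chem.MolFromSmiles(group_smiles)
    offset = editable.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(editable.GetMol(), group))
    combined.AddBond(anchor, offset, Chem.BondType.SINGLE)
    return combined, list(range(offset, offset + group.GetNumAtoms()))


def generate_core_library(config: GeneratorConfig) -> list[Core]:
    """Chemically valid cores: aromatic ring systems with 1..max_attachments
    alkyl arms (length >= 2, so ring environments at radius 2 are fragment
    independent) and optional methyl/methoxy decorations."""
    rng = np.random.default_rng(config.seed)
    cores: list[Core] = []
    seen: set[str] = set()
    attempts = 0
    while len(cores) < config.n_cores and attempts < 200 * config.n_cores:
        attempts += 1
        ring = Chem.MolFromSmiles(_RING_SYSTEMS[rng.integers(len(_RING_SYSTEMS))])
        editable = Chem.RWMol(ring)
        positions = [
            a.GetIdx()
            for a in ring.GetAtoms()
            if a.GetIsAromatic() and a.GetTotalNumHs() >= 1
            and a.GetAtomicNum() == 6
        ]
        n_attach = int(rng.integers(1, config.max_attachments + 1))
        if len(positions) < n_attach + 1:
            continue
        chosen = rng.choice(len(positions), size=n_attach + 1, replace=False)
        attach_positions = [positions[i] for i in chosen[:n_attach]]
        decoration_position = positions[chosen[n_attach]]
        attachment_atoms = []
        for anchor in attach_positions:
            length = int(rng.integers(2, 4))
            attachment_atoms.append(_attach_chain(editable, anchor, length))
        if rng.random() < 0.6:
            decoration = "C" if rng.random() < 0.5 else "OC"
            editable, _ = _attach_group(editable, decoration_position, decoration)
        mol = editable.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - templates are valid
            continue
        n_heavy = mol.GetNumHeavyAtoms()
        if not (config.core_size[0] <= n_heavy <= config.core_size[1]):
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        seen.add(smiles)
        cores.append(
            Core(
                mol=mol,
                attachment_atoms=tuple(attachment_atoms),
                family_id=len(cores),
            )
        )
    if len(cores) < config.n_cores:  # pragma: no cover - ample template space
        raise RuntimeError("could not generate the requested number of cores")
    return cores


def _canonical_index_map(built: Chem.Mol) -> tuple[str, list[int]]:
    """Canonical SMILES of ``built`` plus built-index -> canonical-index map."""
    smiles = Chem.MolToSmiles(built)
    output_order = list(
        map(int, built.GetProp("_smilesAtomOutputOrder")[1:-1].split(","))
    )
    inverse = [0] * built.GetNumAtoms()
    for canonical_pos, built_idx in enumerate(output_order):
        inverse[built_idx] = canonical_pos
    return smiles, inverse


def _assemble(core: Core, groups: Sequence[str]) -> tuple[Chem.Mol, list[list[int]]]:
    """Core with one group per attachment arm; returns built mol and the
    built-index lists of each group."""
    editable = Chem.RWMol(core.mol)
    group_atom_lists = []
    for anchor, group in zip(core.attachment_atoms, groups):
        editable, atoms = _attach_group(editable, anchor, group)
        group_atom_lists.append(atoms)
    mol = editable.GetMol()
    Chem.SanitizeMol(mol)
    return mol, group_atom_lists


def _reactive_site(groups: Sequence[str], priorities: dict[str, int]) -> int:
    """Deterministic substitution rule: highest-priority group reacts."""
    return min(range(len(groups)), key=lambda i: priorities[groups[i]])


def generate_reactions(
    cores: Sequence[Core],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[ReactionRecord], dict[str, ManifestEntry]]:
    """Family reactions plus distractors, with ground-truth manifest."""
    templates = GROUP_TEMPLATES[: config.n_fragment_types]
    priorities = {t[0]: i for i, t in enumerate(templates)}
    by_product = {t[0]: t for t in templates}
    group_pool = [t[0] for t in templates]

    n_distractors = int(round(config.n_reactions * config.distractor_fraction))
    n_family = config.n_reactions - n_distractors

    records: list[ReactionRecord] = []
    manifest: dict[str, ManifestEntry] = {}
    seen_products: set[str] = set()

    made, attempts = 0, 0
    while made < n_family and attempts < 50 * n_family:
        core = cores[attempts % len(cores)]
        attempts += 1
        groups = [
            group_pool[rng.integers(len(group_pool))]
            for _ in core.attachment_atoms
        ]
        site = _reactive_site(groups, priorities)
        p_group, r_group, extra = by_product[groups[site]]

        product_mol, group_atoms = _assemble(core, groups)
        product_smiles, index_map = _canonical_index_map(product_mol)
        if product_smiles in seen_products:
            continue
        reactant_groups = list(groups)
        reactant_groups[site] = r_group
        reactant_mol, _ = _assemble(core, reactant_groups)
        reactants = [canonicalize(Chem.MolToSmiles(reactant_mol))]
        if extra is not None:
            reactants.append(canonicalize(extra))

        seen_products.add(product_smiles)
        reaction_id = f"F{made:05d}"
        n_core = core.mol.GetNumAtoms()
        core_atoms = tuple(sorted(index_map[i] for i in range(n_core)))
        reactive_atoms = tuple(sorted(index_map[i] for i in group_atoms[site]))
        conserved = tuple(
            sorted(
                set(range(product_mol.GetNumAtoms())) - set(reactive_atoms)
            )
        )
        records.append(
            ReactionRecord(
                reactants=tuple(reactants),
                product=canonicalize(product_smiles),
                id=reaction_id,
            )
        )
        manifest[reaction_id] = ManifestEntry(
            reaction_id=reaction_id,
            family_id=core.family_id,
            is_distractor=False,
            core_atoms=core_atoms,
            conserved_atoms=conserved,
            reactive_group_atoms=reactive_atoms,
        )
        made += 1
    if made < n_family:  # pragma: no cover
        raise RuntimeError("failed to generate enough distinct family reactions")

    for k in range(n_distractors):
        product = _random_distractor(rng, seen_products)
        seen_products.add(product.canonical_smiles)
        reactant = _random_distractor(rng, set())
        reaction_id = f"D{k:05d}"
        records.append(
            ReactionRecord(reactants=(reactant,), product=product, id=reaction_id)
        )
        manifest[reaction_id] = ManifestEntry(
            reaction_id=reaction_id,
            family_id=-1,
            is_distractor=True,
            core_atoms=(),
            conserved_atoms=(),
            reactive_group_atoms=(),
        )
    return records, manifest


def _random_distractor(
    rng: np.random.Generator, taken: set[str]
) -> Molecule:
    """A fluorocarbon/sulfur chain; every atom is within radius 2 of an F or
    S atom, so no environment at radius >= 2 can occur in family molecules
    (which contain neither element)."""
    for _ in range(100):
        editable = Chem.RWMol()
        previous = None
        for _ in range(int(rng.integers(3, 7))):
            if rng.random() < 0.35:
                idx = editable.AddAtom(Chem.Atom(16))  # S
            else:
                idx = editable.AddAtom(Chem.Atom(6))
                for _ in range(2):
                    f = editable.AddAtom(Chem.Atom(9))
                    editable.AddBond(idx, f, Chem.BondType.SINGLE)
            if previous is not None:
                editable.AddBond(previous, idx, Chem.BondType.SINGLE)
            previous = idx
        mol = editable.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover
            continue
        if not any(a.GetAtomicNum() in (9, 16) for a in mol.GetAtoms()):
            continue
        molecule = canonicalize(Chem.MolToSmiles(mol))
        if molecule.canonical_smiles not in taken:
            return molecule
    raise RuntimeError("distractor generation failed")  # pragma: no cover


def _stratified_split(
    records: list[ReactionRecord],
    manifest: dict[str, ManifestEntry],
    rng: np.random.Generator,
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    """80/10/10 split stratified by family so every test family also has
    training members (retrieval can only succeed with in-pool relatives)."""
    by_family: dict[int, list[ReactionRecord]] = {}
    for record in records:
        by_family.setdefault(manifest[record.id].family_id, []).append(record)
    train, valid, test = [], [], []
    for family_records in by_family.values():
        order = rng.permutation(len(family_records))
        shuffled = [family_records[i] for i in order]
        n = len(shuffled)
        n_valid = max(1, round(0.1 * n)) if n >= 5 else 0
        n_test = max(1, round(0.1 * n)) if n >= 5 else 0
        test.extend(shuffled[:n_test])
        valid.extend(shuffled[n_test : n_test + n_valid])
        train.extend(shuffled[n_test + n_valid :])
    return train, valid, test


def generate_dataset(
    config: GeneratorConfig, out_dir=None
) -> DatasetBundle:
    """Deterministic train/valid/test reaction sets plus ground-truth manifest.

    With ``out_dir`` set, writes ``train.txt``/``valid.txt``/``test.txt``
    (one reaction SMILES per line) and ``manifest.json``.
    """
    rng = np.random.default_rng(config.seed)
    cores = generate_core_library(config)
    records, manifest = generate_reactions(cores, config, rng)
    train, valid, test = _stratified_split(records, manifest, rng)
    bundle = DatasetBundle(train=train, valid=valid, test=test, manifest=manifest)
    if out_dir is not None:
        from pathlib import Path

        from .chem import write_reaction_file

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reaction_file(train, out / "train.txt")
        write_reaction_file(valid, out / "valid.txt")
        write_reaction_file(test, out / "test.txt")
        payload = {
            rid: {
                "family_id": e.family_id,
                "is_distractor": e.is_distractor,
                "core_atoms": list(e.core_atoms),
                "conserved_atoms": list(e.conserved_atoms),
                "reactive_group_atoms": list(e.reactive_group_atoms),
            }
            for rid, e in manifest.items()
        }
        (out / "manifest.json").write_text(json.dumps(payload, indent=1))
    return bundle


# ---------------------------------------------------------------------------
# Valid split selections for round-trip exercising
# ---------------------------------------------------------------------------


def _selection_is_splittable(mol: Chem.Mol, selection: frozenset[int]) -> bool:
    """prune_atoms guarantees the substructure-side constraints; this adds
    the fragment-side one (no fragment atom with two crossing bonds)."""
    frag_crossings: dict[int, int] = {}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in selection) == (b in selection):
            continue
        frag = b if a in selection else a
        frag_crossings[frag] = frag_crossings.get(frag, 0) + 1
        if frag_crossings[frag] > 1:
            return False
    return True


def valid_split_selections(
    product: Molecule,
    manifest_entry: ManifestEntry,
    rng: np.random.Generator,
    n_random: int = 2,
) -> list[frozenset[int]]:
    """Valid substructure selections for a generated product: the family
    core, the conserved set, and pruned random subsets."""
    selections: list[frozenset[int]] = []
    n = product.mol.GetNumAtoms()
    candidates = [
        frozenset(manifest_entry.core_atoms),
        frozenset(manifest_entry.conserved_atoms),
    ]
    for _ in range(n_random):
        size = int(rng.integers(max(2, n // 3), n + 1))
        subset = frozenset(int(i) for i in rng.choice(n, size=size, replace=False))
        candidates.append(subset)
    for candidate in candidates:
        pruned = prune_atoms(product, candidate)
        if not pruned or len(pruned) == n:
            continue
        if _selection_is_splittable(product.mol, pruned):
            selections.append(pruned)
    return selections


def make_family_extraction_case(
    core: Core,
    config: GeneratorConfig,
    rng: np.random.Generator,
    n_candidates: int = 20,
):
    """A controlled extraction case: one product and ``n_candidates``
    same-family candidate reactant sets whose groups never include the
    product's reactive-site group, i.e. all reaction sites lie outside the
    conserved region shared with every candidate.

    Returns ``(product, conserved_atoms, candidates, golden_reactants)``
    where candidates are combined reactant-set molecules and
    ``golden_reactants`` follow the deterministic substitution rule.
    """
    templates = GROUP_TEMPLATES[: config.n_fragment_types]
    priorities = {t[0]: i for i, t in enumerate(templates)}
    by_product = {t[0]: t for t in templates}
    group_pool = [t[0] for t in templates]
    groups = [
        group_pool[rng.integers(len(group_pool))] for _ in core.attachment_atoms
    ]
    site = _reactive_site(groups, priorities)
    p_group = groups[site]
    product_mol, group_atoms = _assemble(core, groups)
    product_smiles, index_map = _canonical_index_map(product_mol)
    product = canonicalize(product_smiles)
    reactive_atoms = {index_map[i] for i in group_atoms[site]}
    conserved = frozenset(range(product_mol.GetNumAtoms())) - reactive_atoms

    _, r_group, extra = by_product[p_group]
    golden_groups = list(groups)
    golden_groups[site] = r_group
    golden_mol, _ = _assemble(core, golden_groups)
    golden = [canonicalize(Chem.MolToSmiles(golden_mol))]
    if extra is not None:
        golden.append(canonicalize(extra))

    other_groups = [g for g in group_pool if g != p_group]
    candidates: list[Molecule] = []
    while len(candidates) < n_candidates:
        cand_groups = [
            other_groups[rng.integers(len(other_groups))]
            for _ in core.attachment_atoms
        ]
        cand_mol, _ = _assemble(core, cand_groups)
        candidates.append(canonicalize(Chem.MolToSmiles(cand_mol)))
    return product, conserved, candidates, golden
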