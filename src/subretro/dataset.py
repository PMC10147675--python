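"""Substructure-level sequence-to-sequence examples.

Training example construction isolates the substructure on the reactant
side: the source string is the labeled substructure SMILES (written as it
appears in the reactants, hydrogen-complete, with virtual numbers at the
reactant-side cut atoms), then the ``|`` separator, then the product's
fragment SMILES labeled at the product-side cut atoms.  Cut atoms shared by
both sides carry one shared number, so the model sees consistent labels.
The target is the reactant fragment SMILES only (labeled fragments plus any
whole co-reactant species, dot-joined).  By construction
``merge(source substructure, target)`` reproduces the golden reactants
exactly — the corpus-wide integrity gate.

Products without any extracted substructure fall back to plain
SMILES-to-SMILES examples (``is_fallback``), handled by a vanilla
augmented-SMILES model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import (
    Molecule,
    ReactionRecord,
    canonicalize,
    randomize_smiles,
    tokenize,
)
from .split_assemble import SplitError, split
from .substructure import (
    SubstructureSpec,
    combine_molecules,
    substructure_query_mol,
    unique_specs,
)

SEPARATOR = "|"


@dataclass(frozen=True)
class Seq2SeqExample:
    """One source/target pair plus everything needed to merge predictions."""

    source: str
    target: str
    substructure_smiles: str  # labeled; empty for fallback examples
    bond_orders: dict[int, int]
    substructure_atoms: frozenset[int]  # product atom indices; empty = fallback
    reaction_id: str
    is_fallback: bool = False

    @property
    def source_tokens(self) -> tuple[str, ...]:
        return tokenize(self.source).tokens

    @property
    def target_tokens(self) -> tuple[str, ...]:
        return tokenize(self.target).tokens


@dataclass(frozen=True)
class Rejection:
    reaction_id: str
    reason: str


def _matches_in_reactants(
    product: Molecule, atoms: frozenset[int], reactants: Sequence[Molecule]
):
    """Embeddings of the substructure subgraph into the combined reactants.

    Returns (combined mol, ordered selected product atoms, match tuples).
    """
    query = substructure_query_mol(product, atoms)
    combined = combine_molecules(list(reactants))
    matches = combined.GetSubstructMatches(query, uniquify=True, maxMatches=64)
    return combined, sorted(atoms), matches


def _crossing_ok(mol: Chem.Mol, selection: frozenset[int]) -> int | None:
    """Number of crossing bonds, or None if the selection cannot be split
    (aromatic/stereo crossing or a doubly-cut atom on either side)."""
    sub_cuts: dict[int, int] = {}
    frag_cuts: dict[int, int] = {}
    n = 0
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in selection) == (b in selection):
            continue
        if bond.GetBondType() == Chem.BondType.AROMATIC:
            return None
        if (
            bond.GetStereo() != Chem.BondStereo.STEREONONE
            or bond.GetBondDir() != Chem.BondDir.NONE
        ):
            return None
        sub_atom, frag_atom = (a, b) if a in selection else (b, a)
        sub_cuts[sub_atom] = sub_cuts.get(sub_atom, 0) + 1
        frag_cuts[frag_atom] = frag_cuts.get(frag_atom, 0) + 1
        if sub_cuts[sub_atom] > 1 or frag_cuts[frag_atom] > 1:
            return None
        n += 1
    return n


def build_example(
    reaction: ReactionRecord, spec: SubstructureSpec
) -> Seq2SeqExample | Rejection:
    """A training example from one reaction and one (correct) substructure.

    The substructure must embed in the golden reactants; among multiple
    embeddings the one with fewest crossing bonds wins (ties by canonical
    rank order of the matched atoms).  Examples whose reactant-side split
    would cut aromatic or stereo bonds are rejected.
    """
    product = reaction.product
    atoms = spec.atom_indices
    if not atoms:
        return Rejection(reaction.id, "empty substructure")
    combined, query_atoms, matches = _matches_in_reactants(
        product, atoms, reaction.reactants
    )
    if not matches:
        return Rejection(reaction.id, "substructure not embeddable in reactants")

    viable: list[tuple[int, tuple[int, ...], frozenset[int]]] = []
    for match in matches:
        selection = frozenset(match)
        crossings = _crossing_ok(combined, selection)
        if crossings is None:
            continue
        viable.append((crossings, tuple(sorted(match)), frozenset(match)))
    if not viable:
        return Rejection(
            reaction.id, "every embedding cuts aromatic/stereo or doubly-cut bonds"
        )
    viable.sort(key=lambda t: (t[0], t[1]))
    _, _, reactant_selection = viable[0]
    chosen_match = next(m for m in matches if frozenset(m) == reactant_selection)

    # product-atom <-> reactant-atom correspondence for the substructure
    product_to_reactant = dict(zip(query_atoms, chosen_match))
    reactant_to_product = {v: k for k, v in product_to_reactant.items()}

    product_cut_atoms = _cut_sub_atoms(product.mol, atoms)
    reactant_cut_atoms = _cut_sub_atoms(combined, reactant_selection)
    # shared numbering over the union of cut sites, in product canonical order
    union = set(product_cut_atoms) | {
        reactant_to_product[a] for a in reactant_cut_atoms
    }
    ranks = list(Chem.CanonicalRankAtoms(product.mol, breakTies=True))
    ordered = sorted(union, key=lambda a: ranks[a])
    numbers = {atom: i + 1 for i, atom in enumerate(ordered)}

    combined_molecule = Molecule(
        canonical_smiles=Chem.MolToSmiles(combined), mol=combined
    )
    try:
        product_split = split(
            product, atoms, number_map={a: numbers[a] for a in product_cut_atoms}
        )
        reactant_split = split(
            combined_molecule,
            reactant_selection,
            number_map={
                a: numbers[reactant_to_product[a]] for a in reactant_cut_atoms
            },
        )
    except SplitError as exc:
        return Rejection(reaction.id, f"split failed: {exc}")

    source = reactant_split.substructure_smiles + SEPARATOR + product_split.fragment_smiles
    return Seq2SeqExample(
        source=source,
        target=reactant_split.fragment_smiles,
        substructure_smiles=reactant_split.substructure_smiles,
        bond_orders=reactant_split.bond_orders,
        substructure_atoms=atoms,
        reaction_id=reaction.id,
    )


def _cut_sub_atoms(mol: Chem.Mol, selection: frozenset[int]) -> list[int]:
    """Selected atoms with a bond crossing the partition."""
    out = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in selection) != (b in selection):
            out.append(a if a in selection else b)
    return out


def verify_example(example: Seq2SeqExample, golden: Sequence[Molecule]) -> bool:
    """Integrity gate: merging source substructure with the golden target
    fragments must reproduce the golden reactant multiset exactly."""
    from .chem import exact_match
    from .split_assemble import ChemistryError, MergeError, merge

    if example.is_fallback:
        predicted = [canonicalize(s) for s in example.target.split(".") if s]
        return exact_match(predicted, golden)
    try:
        predicted = merge(
            example.substructure_smiles, example.target, example.bond_orders
        )
    except (MergeError, ChemistryError):
        return False
    return exact_match(predicted, golden)


def _randomized_pieces(smiles: str, seed: int) -> str:
    """Randomize the writing of each dot-separated piece (labels preserved)."""
    pieces = [s for s in smiles.split(".") if s]
    out = []
    for i, piece in enumerate(pieces):
        out.append(randomize_smiles(canonicalize(piece), seed=seed + i))
    return ".".join(out)


def augment(
    example: Seq2SeqExample, n_random: int = 2, seed: int = 0
) -> list[Seq2SeqExample]:
    """The example plus ``n_random`` randomized-SMILES source variants.

    Only the source writing changes (substructure and product-fragment
    pieces re-written with random atom orderings); the target is unchanged.
    """
    out = [example]
    for r in range(n_random):
        base = seed + 1000 * r
        if example.is_fallback:
            source = _randomized_pieces(example.source, base)
            out.append(replace(example, source=source))
        else:
            sub_part, frag_part = example.source.split(SEPARATOR)
            sub_random = _randomized_pieces(sub_part, base)
            frag_random = (
                _randomized_pieces(frag_part, base + 500) if frag_part else ""
            )
            out.append(
                replace(example, source=sub_random + SEPARATOR + frag_random)
            )
    return out


def build_fallback_example(reaction: ReactionRecord) -> Seq2SeqExample:
    """Plain product -> reactants example (no-substructure path)."""
    return Seq2SeqExample(
        source=reaction.product.canonical_smiles,
        target=reaction.reactants_smiles,
        substructure_smiles="",
        bond_orders={},
        substructure_atoms=frozenset(),
        reaction_id=reaction.id,
        is_fallback=True,
    )


def build_training_corpus(
    reactions: Sequence[ReactionRecord],
    specs_by_reaction: dict[str, Sequence[SubstructureSpec]],
    n_random: int = 2,
    seed: int = 0,
    verify: bool = True,
) -> tuple[list[Seq2SeqExample], list[Rejection]]:
    """Training examples from correct, unique substructures, augmented.

    Every accepted example passes the merge integrity gate against its
    golden reactants.
    """
    examples: list[Seq2SeqExample] = []
    rejections: list[Rejection] = []
    for reaction in reactions:
        specs = unique_specs(list(specs_by_reaction.get(reaction.id, ())))
        for k, spec in enumerate(specs):
            built = build_example(reaction, spec)
            if isinstance(built, Rejection):
                rejections.append(built)
                continue
            if verify and not verify_example(built, list(reaction.reactants)):
                rejections.append(
                    Rejection(reaction.id, "integrity gate: merge != golden")
                )
                continue
            examples.extend(
                augment(built, n_random=n_random, seed=seed + 17 * k)
            )
    return examples, rejections


def build_inference_inputs(
    product: Molecule,
    specs: Sequence[SubstructureSpec],
    reaction_id: str = "",
    n_random: int = 0,
    seed: int = 0,
) -> list[Seq2SeqExample]:
    """One source (plus augmentations) per unique substructure; with no
    specs, a single fallback example carrying the plain product SMILES."""
    uniques = unique_specs(list(specs))
    inputs: list[Seq2SeqExample] = []
    for k, spec in enumerate(uniques):
        try:
            product_split = split(product, spec.atom_indices)
        except SplitError:
            continue
        example = Seq2SeqExample(
            source=product_split.substructure_smiles
            + SEPARATOR
            + product_split.fragment_smiles,
            target="",
            substructure_smiles=product_split.substructure_smiles,
            bond_orders=product_split.bond_orders,
            substructure_atoms=spec.atom_indices,
            reaction_id=reaction_id,
        )
        inputs.extend(augment(example, n_random=n_random, seed=seed + 17 * k))
    if not inputs:
        fallback = Seq2SeqExample(
            source=product.canonical_smiles,
            target="",
            substructure_smiles="",
            bond_orders={},
            substructure_atoms=frozenset(),
            reaction_id=reaction_id,
            is_fallback=True,
        )
        inputs.extend(augment(fallback, n_random=n_random, seed=seed))
    return inputs


def write_corpus(examples: Sequence[Seq2SeqExample], src_path, tgt_path) -> None:
    """Paired source/target token files, one example per line."""
    with open(src_path, "w") as src, open(tgt_path, "w") as tgt:
        for example in examples:
            src.write(" ".join(example.source_tokens) + "\n")
            tgt.write(" ".join(example.target_tokens) + "\n")
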