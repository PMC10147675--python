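"""Commonly preserved substructure extraction via circular-fingerprint
atom-environment alignment.

Each atom of the product and of the top retrieved candidate reactants is
annotated with unfolded Morgan (ECFP-style) integer identifiers at radii 0..6.
A product atom "aligns" with a candidate when at least one of its
(radius, identifier) pairs at radius >= 2 also occurs in that candidate; atoms
aligning with at least ``threshold`` (default 5) of the 20 candidates seed the
substructure.  Boundary atoms whose removal would destroy aromaticity or
stereochemistry — or that touch several non-substructure atoms — are pruned
iteratively to a fixed point.  A substructure is "correct" when its (possibly
disconnected) graph embeds as a subgraph in the golden reactant set.

Raw integer identifiers are compared directly (no folding into bit vectors):
folding introduces collisions without benefit at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import Molecule

DEFAULT_MAX_RADIUS = 6
DEFAULT_MIN_RADIUS = 2
DEFAULT_THRESHOLD = 5


@dataclass(frozen=True)
class AtomEnvironmentTable:
    """Per-atom sets of (radius, identifier) circular-fingerprint pairs."""

    environments: tuple[frozenset[tuple[int, int]], ...]

    def __len__(self) -> int:
        return len(self.environments)

    def pairs_at_least(self, min_radius: int) -> frozenset[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for env in self.environments:
            out.update(p for p in env if p[0] >= min_radius)
        return frozenset(out)

    def identifier_multiset(self) -> tuple[tuple[int, int], ...]:
        """All (radius, id) pairs with multiplicity, order-insensitively sorted."""
        pairs = [p for env in self.environments for p in sorted(env)]
        return tuple(sorted(pairs))


def compute_environments(
    mol: Molecule, max_radius: int = DEFAULT_MAX_RADIUS
) -> AtomEnvironmentTable:
    """Morgan identifiers for every atom at radii 0..max_radius.

    Identifiers come from RDKit's sparse Morgan generator (iterative
    neighborhood hashing); radii larger than the molecule simply stop
    producing new entries.
    """
    generator = rdFingerprintGenerator.GetMorganGenerator(
        radius=max_radius, includeRedundantEnvironments=True
    )
    output = rdFingerprintGenerator.AdditionalOutput()
    output.AllocateBitInfoMap()
    generator.GetSparseCountFingerprint(mol.mol, additionalOutput=output)
    per_atom: list[set[tuple[int, int]]] = [set() for _ in range(mol.mol.GetNumAtoms())]
    for identifier, sites in output.GetBitInfoMap().items():
        for atom_idx, radius in sites:
            per_atom[atom_idx].add((radius, identifier))
    return AtomEnvironmentTable(environments=tuple(frozenset(s) for s in per_atom))


def align_atoms(
    product_env: AtomEnvironmentTable,
    candidate_env: AtomEnvironmentTable,
    min_radius: int = DEFAULT_MIN_RADIUS,
) -> frozenset[int]:
    """Product atom indices sharing >=1 environment (radius >= min_radius)
    with the candidate."""
    candidate_pairs = candidate_env.pairs_at_least(min_radius)
    return frozenset(
        idx
        for idx, env in enumerate(product_env.environments)
        if any(p[0] >= min_radius and p in candidate_pairs for p in env)
    )


@dataclass(frozen=True)
class AlignmentCount:
    """Per product atom, how many candidates it aligned with."""

    counts: tuple[int, ...]
    num_candidates: int

    def atoms_at_least(self, threshold: int) -> frozenset[int]:
        return frozenset(i for i, c in enumerate(self.counts) if c >= threshold)


def count_alignments(
    product: Molecule,
    candidates: Sequence[Molecule],
    min_radius: int = DEFAULT_MIN_RADIUS,
    max_radius: int = DEFAULT_MAX_RADIUS,
) -> AlignmentCount:
    if not candidates:
        raise ValueError("empty candidate list")
    product_env = compute_environments(product, max_radius)
    counts = [0] * len(product_env)
    for candidate in candidates:
        aligned = align_atoms(
            product_env, compute_environments(candidate, max_radius), min_radius
        )
        for idx in aligned:
            counts[idx] += 1
    return AlignmentCount(counts=tuple(counts), num_candidates=len(candidates))


def _bond_has_stereo(bond: Chem.Bond) -> bool:
    return (
        bond.GetStereo() != Chem.BondStereo.STEREONONE
        or bond.GetBondDir() != Chem.BondDir.NONE
    )


def prune_atoms(product: Molecule, selected: frozenset[int]) -> frozenset[int]:
    """Iteratively drop boundary atoms until a fixed point.

    Removal rules: a selected atom is dropped when it (a) shares an aromatic
    bond with an unselected atom, (b) shares a stereo-designated bond with an
    unselected atom, or (c) is bonded to two or more unselected atoms.  All
    rules only remove atoms, so the fixed point is order-independent.
    """
    mol = product.mol
    current = set(selected)
    changed = True
    while changed:
        changed = False
        to_remove: set[int] = set()
        for idx in current:
            atom = mol.GetAtomWithIdx(idx)
            unselected_neighbors = 0
            for bond in atom.GetBonds():
                other = bond.GetOtherAtom(atom).GetIdx()
                if other in current:
                    continue
                unselected_neighbors += 1
                if bond.GetBondType() == Chem.BondType.AROMATIC:
                    to_remove.add(idx)
                if _bond_has_stereo(bond):
                    to_remove.add(idx)
            if unselected_neighbors >= 2:
                to_remove.add(idx)
        if to_remove:
            current -= to_remove
            changed = True
    return frozenset(current)


@dataclass(frozen=True)
class SubstructureSpec:
    """A candidate-derived substructure: a bond-induced subset of product atoms."""

    product: Molecule
    atom_indices: frozenset[int]
    source_candidate_id: str
    is_correct: bool | None = None


def extract_substructures(
    product: Molecule,
    candidates: Mapping[str, Molecule] | Sequence[Molecule],
    threshold: int = DEFAULT_THRESHOLD,
    min_radius: int = DEFAULT_MIN_RADIUS,
    max_radius: int = DEFAULT_MAX_RADIUS,
) -> list[SubstructureSpec]:
    """Per-candidate substructures intersected with the global threshold set.

    For each candidate the substructure is
    ``prune(aligned-with-candidate ∩ {alignment count >= threshold})``;
    empty results are dropped.  The full per-candidate list is returned
    (duplicates carry frequency information); :func:`unique_specs`
    deduplicates by atom set for model training.  An empty return signals
    "no substructure" and routes the product to the fallback path.
    """
    if isinstance(candidates, Mapping):
        items = list(candidates.items())
    else:
        items = [(str(i), c) for i, c in enumerate(candidates)]
    if not items:
        raise ValueError("empty candidate list")
    product_env = compute_environments(product, max_radius)
    aligned_sets = {
        cid: align_atoms(
            product_env, compute_environments(mol, max_radius), min_radius
        )
        for cid, mol in items
    }
    counts = [0] * len(product_env)
    for aligned in aligned_sets.values():
        for idx in aligned:
            counts[idx] += 1
    global_set = frozenset(i for i, c in enumerate(counts) if c >= threshold)
    specs: list[SubstructureSpec] = []
    for cid, aligned in aligned_sets.items():
        pruned = prune_atoms(product, frozenset(aligned & global_set))
        if pruned:
            specs.append(
                SubstructureSpec(
                    product=product, atom_indices=pruned, source_candidate_id=cid
                )
            )
    return specs


def unique_specs(specs: Sequence[SubstructureSpec]) -> list[SubstructureSpec]:
    """One spec per distinct atom set (first occurrence kept), for training."""
    seen: set[frozenset[int]] = set()
    out: list[SubstructureSpec] = []
    for spec in specs:
        if spec.atom_indices not in seen:
            seen.add(spec.atom_indices)
            out.append(spec)
    return out


def substructure_query_mol(product: Molecule, atoms: frozenset[int]) -> Chem.Mol:
    """The bond-induced subgraph of ``product`` on ``atoms`` as a query mol.

    Hydrogen counts are not constrained (bonds were broken at attachment
    points), so default substructure matching — element, charge, aromaticity,
    bond order — applies.
    """
    editable = Chem.RWMol(product.mol)
    for idx in sorted(
        (a.GetIdx() for a in editable.GetAtoms() if a.GetIdx() not in atoms),
        reverse=True,
    ):
        editable.RemoveAtom(idx)
    query = editable.GetMol()
    for atom in query.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    query.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(query)
    return query


def combine_molecules(molecules: Sequence[Molecule]) -> Chem.Mol:
    """Disjoint union of a reactant set as a single RDKit mol."""
    combined = molecules[0].mol
    for mol in molecules[1:]:
        combined = Chem.CombineMols(combined, mol.mol)
    return combined


def substructure_is_correct(
    spec: SubstructureSpec, golden_reactants: Sequence[Molecule]
) -> bool:
    """True iff the substructure embeds as a subgraph in the reactant set."""
    if not spec.atom_indices:
        return False
    query = substructure_query_mol(spec.product, spec.atom_indices)
    target = combine_molecules(list(golden_reactants))
    return target.HasSubstructMatch(query)


def coverage_curve(
    products_with_candidates: Sequence[tuple[Molecule, Sequence[Molecule]]],
    thresholds: Sequence[int],
    min_radius: int = DEFAULT_MIN_RADIUS,
    max_radius: int = DEFAULT_MAX_RADIUS,
) -> dict[int, int]:
    """Diagnostic threshold sweep: products yielding >=1 substructure per
    threshold.  Coverage is weakly decreasing in the threshold."""
    curve: dict[int, int] = {t: 0 for t in thresholds}
    for product, candidates in products_with_candidates:
        product_env = compute_environments(product, max_radius)
        aligned_sets = [
            align_atoms(
                product_env, compute_environments(c, max_radius), min_radius
            )
            for c in candidates
        ]
        counts = [0] * len(product_env)
        for aligned in aligned_sets:
            for idx in aligned:
                counts[idx] += 1
        for threshold in thresholds:
            global_set = frozenset(
                i for i, c in enumerate(counts) if c >= threshold
            )
            if any(
                prune_atoms(product, frozenset(a & global_set))
                for a in aligned_sets
            ):
                curve[threshold] += 1
    return curve
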