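import numpy as np
import pytest
from rdkit import Chem

from subretro.chem import canonicalize
from subretro.substructure import (
    SubstructureSpec,
    align_atoms,
    compute_environments,
    count_alignments,
    extract_substructures,
    prune_atoms,
    substructure_is_correct,
    unique_specs,
)
from subretro.synthetic import make_family_extraction_case


def test_methane_has_only_radius_zero():
    table = compute_environments(canonicalize("C"))
    assert len(table) == 1
    assert {r for r, _ in table.environments[0]} == {0}


def test_environment_identifiers_permutation_invariant(sample_molecules):
    for mol in sample_molecules:
        n = mol.mol.GetNumAtoms()
        if n < 2:
            continue
        rng = np.random.default_rng(5)
        permuted = Chem.RenumberAtoms(mol.mol, [int(i) for i in rng.permutation(n)])
        other = canonicalize(Chem.MolToSmiles(permuted, canonical=False))
        a = compute_environments(mol).identifier_multiset()
        b = compute_environments(other).identifier_multiset()
        assert a == b


def test_product_aligns_fully_with_itself(sample_molecules):
    for mol in sample_molecules:
        table = compute_environments(mol)
        aligned = align_atoms(table, table)
        assert aligned == frozenset(range(mol.mol.GetNumAtoms()))


def test_benzene_and_cyclohexane_do_not_align():
    benzene = compute_environments(canonicalize("c1ccccc1"))
    cyclohexane = compute_environments(canonicalize("C1CCCCC1"))
    assert align_atoms(benzene, cyclohexane) == frozenset()


def test_planted_core_alignment_covers_interior(cores, small_config, rng):
    product, conserved, candidates, golden = make_family_extraction_case(
        cores[0], small_config, rng
    )
    product_env = compute_environments(product)
    aligned = align_atoms(product_env, compute_environments(candidates[0]))
    # ring atoms (aromatic interior of the conserved core) must align
    ring = {
        a.GetIdx() for a in product.mol.GetAtoms() if a.GetIsAromatic()
    } & conserved
    assert ring <= aligned


def test_count_alignments_identical_candidates():
    product = canonicalize("COc1cc(CCCBr)ccn1")
    counts = count_alignments(product, [product] * 20)
    assert counts.counts == (20,) * product.mol.GetNumAtoms()


def test_count_alignments_disjoint_candidates_all_zero():
    product = canonicalize("COc1cc(CCCBr)ccn1")
    distractor = canonicalize("FC(F)(F)SC(F)(F)F")
    counts = count_alignments(product, [distractor] * 20)
    assert set(counts.counts) == {0}
    with pytest.raises(ValueError):
        count_alignments(product, [])


def test_count_alignments_planted_subset(cores, small_config, rng):
    product, conserved, family, golden = make_family_extraction_case(
        cores[1], small_config, rng
    )
    distractor = canonicalize("FC(F)(F)SC(F)(F)SC(F)(F)F")
    candidates = family[:7] + [distractor] * 13
    counts = count_alignments(product, candidates)
    ring = {
        a.GetIdx() for a in product.mol.GetAtoms() if a.GetIsAromatic()
    } & conserved
    for atom in ring:
        assert counts.counts[atom] == 7


def test_prune_whole_molecule_unchanged(sample_molecules):
    for mol in sample_molecules:
        everything = frozenset(range(mol.mol.GetNumAtoms()))
        assert prune_atoms(mol, everything) == everything


def brute_force_prune(mol, selected):
    """Exhaustive simulation of the removal rules to a fixed point."""
    current = set(selected)
    while True:
        removed = set()
        for idx in current:
            atom = mol.mol.GetAtomWithIdx(idx)
            outside = 0
            for bond in atom.GetBonds():
                other = bond.GetOtherAtom(atom).GetIdx()
                if other in current:
                    continue
                outside += 1
                if bond.GetBondType() == Chem.BondType.AROMATIC:
                    removed.add(idx)
                if bond.GetStereo() != Chem.BondStereo.STEREONONE or \
                        bond.GetBondDir() != Chem.BondDir.NONE:
                    removed.add(idx)
            if outside >= 2:
                removed.add(idx)
        if not removed:
            return frozenset(current)
        current -= removed


def test_prune_aromatic_boundary_cascades_whole_ring():
    benzene = canonicalize("c1ccccc1")
    five = frozenset(range(5))
    assert prune_atoms(benzene, five) == frozenset()
    assert brute_force_prune(benzene, five) == frozenset()


def test_prune_removes_atom_with_two_unselected_neighbors():
    chain = canonicalize("CCC")  # middle atom bonded to two outside atoms
    assert prune_atoms(chain, frozenset({1})) == frozenset()


def test_prune_stereo_boundary():
    mol = canonicalize("C/C=C/CC")
    # selecting one side of the stereo double bond forces removal
    double = next(
        b for b in mol.mol.GetBonds()
        if b.GetStereo() != Chem.BondStereo.STEREONONE
    )
    a = double.GetBeginAtomIdx()
    pruned = prune_atoms(mol, frozenset({a}))
    assert a not in pruned


@pytest.mark.parametrize("subset_seed", range(6))
def test_prune_matches_brute_force_and_is_idempotent(
    sample_molecules, subset_seed
):
    rng = np.random.default_rng(subset_seed)
    for mol in sample_molecules:
        n = mol.mol.GetNumAtoms()
        size = int(rng.integers(1, n + 1))
        subset = frozenset(int(i) for i in rng.choice(n, size=size, replace=False))
        pruned = prune_atoms(mol, subset)
        assert pruned == brute_force_prune(mol, subset)
        assert prune_atoms(mol, pruned) == pruned


def test_extract_identical_candidates_single_unique():
    product = canonicalize("COc1cc(CCCBr)ccn1")
    specs = extract_substructures(product, [product] * 20, threshold=5)
    assert len(specs) == 20
    assert len(unique_specs(specs)) == 1
    assert unique_specs(specs)[0].atom_indices == frozenset(
        range(product.mol.GetNumAtoms())
    )


def test_extract_no_shared_environments_returns_empty():
    product = canonicalize("COc1cc(CCCBr)ccn1")
    distractor = canonicalize("FC(F)(F)SC(F)(F)F")
    assert extract_substructures(product, [distractor] * 20) == []


def test_extract_threshold_monotonic_on_family(cores, small_config, rng):
    product, _, candidates, _golden = make_family_extraction_case(
        cores[2], small_config, rng
    )
    counts = [
        len(extract_substructures(product, candidates, threshold=t))
        for t in range(3, 11)
    ]
    nonempty = [c > 0 for c in counts]
    assert nonempty == sorted(nonempty, reverse=True)


def test_substructure_correctness_planted(cores, small_config, rng):
    product, conserved, candidates, golden = make_family_extraction_case(
        cores[3], small_config, rng
    )
    specs = extract_substructures(product, candidates, threshold=5)
    assert specs, "family candidates must yield a substructure"
    for spec in unique_specs(specs):
        assert spec.atom_indices <= conserved
        assert substructure_is_correct(spec, golden)


def test_substructure_with_foreign_atom_is_incorrect():
    product = canonicalize("CCOS(=O)(=O)C")  # sulfur absent from reactants below
    sulfur = {
        a.GetIdx() for a in product.mol.GetAtoms() if a.GetSymbol() == "S"
    }
    spec = SubstructureSpec(
        product=product, atom_indices=frozenset(sulfur), source_candidate_id="x"
    )
    assert not substructure_is_correct(spec, [canonicalize("CCO")])


def test_entire_reactant_as_substructure_is_correct():
    product = canonicalize("CCOC(C)=O")
    spec = SubstructureSpec(
        product=product,
        atom_indices=frozenset(range(product.mol.GetNumAtoms())),
        source_candidate_id="x",
    )
    assert substructure_is_correct(
        spec, [canonicalize("CCOC(C)=O"), canonicalize("O")]
    )
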