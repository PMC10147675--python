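import numpy as np
import pytest

from subretro.chem import canonicalize, reactant_set_key, tokenize
from subretro.dataset import (
    Rejection,
    SEPARATOR,
    augment,
    build_example,
    build_fallback_example,
    build_inference_inputs,
    build_training_corpus,
    verify_example,
    write_corpus,
)
from subretro.chem import ReactionRecord
from subretro.substructure import SubstructureSpec, extract_substructures


def _record(reactants, product, rid="r0"):
    return ReactionRecord(
        reactants=tuple(canonicalize(s) for s in reactants),
        product=canonicalize(product),
        id=rid,
    )


def _ring_spec(record):
    atoms = frozenset(
        a.GetIdx() for a in record.product.mol.GetAtoms() if a.GetIsAromatic()
    )
    return SubstructureSpec(
        product=record.product, atom_indices=atoms, source_candidate_id="c0"
    )


def test_build_example_fragment_swap():
    # reactants = product's core with Br in place of OMe, plus methanol
    record = _record(
        ["COc1cc(CCCBr)ccn1".replace("OC", "Br", 0)], "COc1cc(CCCOC)ccn1"
    )
    record = _record(["Brc1cc(CCCBr)ccn1"], "COc1cc(CCCOC)ccn1")
    spec = _ring_spec(record)
    example = build_example(record, spec)
    # ring embeds but peripheral groups differ on both arms: still valid
    assert not isinstance(example, Rejection)
    assert SEPARATOR in example.source
    assert verify_example(example, list(record.reactants))


def test_build_example_entire_product_inside_reactants():
    record = _record(["CCOC(C)=O", "O"], "CCOC(C)=O")
    spec = SubstructureSpec(
        product=record.product,
        atom_indices=frozenset(range(record.product.mol.GetNumAtoms())),
        source_candidate_id="c0",
    )
    example = build_example(record, spec)
    assert not isinstance(example, Rejection)
    # target carries only the leaving species
    assert canonicalize(example.target).canonical_smiles == "O"
    assert verify_example(example, list(record.reactants))


def test_build_example_rejects_unembeddable_substructure():
    record = _record(["CCO"], "c1ccccc1CCO")
    spec = _ring_spec(record)
    result = build_example(record, spec)
    assert isinstance(result, Rejection)


def test_source_and_target_token_round_trip(small_bundle):
    record = next(
        r for r in small_bundle.train
        if not small_bundle.manifest[r.id].is_distractor
    )
    entry = small_bundle.manifest[record.id]
    from subretro.substructure import prune_atoms

    atoms = prune_atoms(record.product, frozenset(entry.core_atoms))
    spec = SubstructureSpec(
        product=record.product, atom_indices=atoms, source_candidate_id="c0"
    )
    example = build_example(record, spec)
    assert not isinstance(example, Rejection)
    assert tokenize(example.source).detokenize() == example.source
    assert tokenize(example.target).detokenize() == example.target
    assert example.source.count(SEPARATOR) == 1


def test_augment_counts_and_identity():
    record = _record(["Brc1cc(CCCBr)ccn1"], "COc1cc(CCCOC)ccn1")
    example = build_example(record, _ring_spec(record))
    assert augment(example, n_random=0) == [example]
    three = augment(example, n_random=2, seed=5)
    assert len(three) == 3
    for variant in three:
        sub, frag = variant.source.split(SEPARATOR)
        base_sub, base_frag = example.source.split(SEPARATOR)
        assert sorted(
            canonicalize(p).canonical_smiles for p in sub.split(".")
        ) == sorted(canonicalize(p).canonical_smiles for p in base_sub.split("."))
        assert variant.target == example.target
    assert augment(example, n_random=2, seed=5) == three  # deterministic


def test_target_shorter_than_full_reactants(small_bundle):
    """Substructure-level targets reduce the atoms to predict."""
    manifest = small_bundle.manifest
    shorter = total = 0
    for record in small_bundle.train[:30]:
        entry = manifest[record.id]
        if entry.is_distractor:
            continue
        from subretro.substructure import prune_atoms

        atoms = prune_atoms(record.product, frozenset(entry.core_atoms))
        if not atoms:
            continue
        spec = SubstructureSpec(
            product=record.product, atom_indices=atoms, source_candidate_id="c"
        )
        example = build_example(record, spec)
        if isinstance(example, Rejection):
            continue
        total += 1
        full = sum(len(tokenize(m.canonical_smiles)) for m in record.reactants)
        shorter += len(tokenize(example.target)) < full
    assert total >= 10
    assert shorter == total


def test_fallback_inference_input():
    product = canonicalize("COc1cc(CCCOC)ccn1")
    inputs = build_inference_inputs(product, [], reaction_id="x")
    assert len(inputs) == 1
    assert inputs[0].is_fallback
    assert inputs[0].source == product.canonical_smiles


def test_inference_inputs_dedupe_specs():
    product = canonicalize("COc1cc(CCCOC)ccn1")
    atoms = frozenset(
        a.GetIdx() for a in product.mol.GetAtoms() if a.GetIsAromatic()
    )
    specs = [
        SubstructureSpec(product=product, atom_indices=atoms,
                         source_candidate_id=str(i))
        for i in range(4)
    ]
    inputs = build_inference_inputs(product, specs)
    assert len(inputs) == 1


def test_corpus_integrity_gate(small_bundle):
    """Every accepted example merges back to its golden reactants."""
    pool = small_bundle.train[:25]
    specs = {}
    for record in pool:
        entry = small_bundle.manifest[record.id]
        if entry.is_distractor:
            specs[record.id] = []
            continue
        family = [
            r for r in small_bundle.train
            if small_bundle.manifest[r.id].family_id == entry.family_id
            and r.id != record.id
        ][:20]
        if len(family) < 5:
            specs[record.id] = []
            continue
        specs[record.id] = extract_substructures(
            record.product,
            [canonicalize(r.reactants_smiles) for r in family],
            threshold=min(5, len(family)),
        )
    corpus, rejections = build_training_corpus(
        pool, specs, n_random=1, seed=0, verify=True
    )
    assert corpus
    golden = {r.id: list(r.reactants) for r in pool}
    for example in corpus:
        assert verify_example(example, golden[example.reaction_id])


def test_write_corpus_files(tmp_path):
    record = _record(["Brc1cc(CCCBr)ccn1"], "COc1cc(CCCOC)ccn1")
    example = build_example(record, _ring_spec(record))
    write_corpus([example], tmp_path / "src.txt", tmp_path / "tgt.txt")
    src = (tmp_path / "src.txt").read_text().strip()
    assert "".join(src.split(" ")) == example.source
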