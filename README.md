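# subretro

Substructure-level single-step retrosynthesis prediction.

Given a product molecule as a SMILES string, `subretro` proposes reactant
sets the way a chemist would start: by identifying the part of the molecule
that is likely to survive the reaction.  It retrieves similar known
reactions with a dual-encoder (two Transformer encoders aligning products
and reactants in one vector space, scored by inner product **S** = **XY**ᵀ),
extracts the *commonly preserved substructure* — product atoms whose Morgan
atom environments (radii 2–6) align with at least 5 of the top-20 retrieved
candidate reactants, pruned so no aromatic ring or stereo bond is broken —
and then predicts only the *fragments* of the reactants with a
sequence-to-sequence Transformer.  Broken bonds are tracked with virtual
numbers written as isotope labels (`[1SH]` ↔ `[1cH]`), so predicted
fragments snap back onto the substructure to give complete, valid reactant
molecules.  A pair-wise neural ranker aggregates predictions across
substructure variants (frequency, top-1/top-2 fractions, mean beam ranks)
into the final ranking, evaluated by top-k exact match of canonical SMILES
multisets.

The package is aimed at method developers: every stage is a plain Python
module with a tested contract, and a synthetic reaction generator with known
conserved cores makes the whole pipeline trainable and verifiable on one CPU
in minutes, without external reaction data.

## Worked example

Split a molecule at its aromatic core and put it back together:

```python
>>> from subretro import canonicalize, split, merge
>>> mol = canonicalize("COc1cc(CCCBr)ccn1")
>>> ring = frozenset(a.GetIdx() for a in mol.mol.GetAtoms() if a.GetIsAromatic())
>>> pieces = split(mol, ring)
>>> pieces.substructure_smiles
'c1cn[2cH]c[1cH]1'
>>> pieces.fragment_smiles
'C[2OH].[1CH3]CCBr'
>>> [m.canonical_smiles for m in merge(pieces.substructure_smiles,
...                                    pieces.fragment_smiles,
...                                    pieces.bond_orders)]
['COc1cc(CCCBr)ccn1']
```

(The exact labeled strings depend on canonical atom ranks; the round trip is
exact by construction.)  Run the whole pipeline on a synthetic corpus:

```python
from subretro.pipeline import PipelineConfig, run_pipeline
from subretro.synthetic import GeneratorConfig
result = run_pipeline(PipelineConfig(generator=GeneratorConfig(seed=1), seed=1))
print(result.metrics)
```

On the default 500-reaction corpus (seed 1) this prints, among others:

```
retrieval_alignment_accuracy  0.647  # in-batch alignment on validation (chance 0.02)
substructure_coverage         0.941  # test products with >=1 extracted substructure
substructure_accuracy         0.939  # extracted substructures embedded in golden reactants
beam_top1 / top5 / top10      0.255 / 0.431 / 0.549
reranked_top1 / top5 / top10  0.314 / 0.490 / 0.588
baseline_most_frequent_top1   0.0    # always predicting the most common fragment
```

Coverage says how often the extraction found a preserved substructure;
accuracy says how often that substructure really is part of the golden
reactants; the top-k rows are exact-match accuracies of the final ranked
reactant sets, with the reranker improving on raw beam order.

A thin CLI mirrors the main operations:

```bash
subretro synth --out data/ --n-reactions 500 --seed 0
subretro extract --product "COc1cc(CCCOC)ccn1" --candidates cands.txt --threshold 5
subretro split --smiles "COc1cc(CCCBr)ccn1" --atoms 2,3,4,5,6,11
subretro merge --substructure "[1cH]1ccccc1" --fragments "[1CH4]"
subretro validate --input data/train.txt
```

## Layout

- `subretro.chem` — SMILES parsing/canonicalization, regex tokenizer
  (virtual-label brackets are single tokens), reaction file I/O, exact match.
- `subretro.retrieval` — dual encoder, ranking/bag-of-words losses, exact
  maximum-inner-product index.
- `subretro.substructure` — Morgan atom-environment tables, alignment
  counting, pruning, extraction, correctness check, threshold-sweep
  diagnostic.
- `subretro.split_assemble` — virtual-number splitting and exact merging.
- `subretro.dataset` — substructure-level seq2seq examples, augmentation,
  integrity gate, fallback path.
- `subretro.model_infer` — Transformer seq2seq, beam search, assembly,
  grouping, top-k evaluation.
- `subretro.ranker` — feature extraction, pair collection, pair-wise ranker.
- `subretro.synthetic` — conserved-core reaction generator with ground-truth
  manifest.
- `subretro.pipeline` — end-to-end orchestration.
- `subretro.nn` — the NumPy autodiff/Transformer core.

See `docs/methods.md` for the model details, parameter choices, and the
limits of what the synthetic corpus demonstrates.
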