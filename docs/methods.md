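# Methods

`subretro` implements substructure-level single-step retrosynthesis: given a
product molecule, propose reactant sets by (1) retrieving structurally
similar known reactions, (2) extracting the portion of the product that those
retrieved reactions suggest is preserved, (3) predicting only the *fragments*
of the reactants around that preserved substructure with a
sequence-to-sequence model, (4) reassembling complete reactant molecules, and
(5) reranking the assembled candidates.  This note records the model, its
assumptions, the parameters that matter, and the design choices that were
genuinely open.

## Reaction retrieval (dual encoder)

Two independent Transformer encoder stacks map the tokenized product SMILES
and the tokenized reactant-set SMILES into one d-dimensional space; the
encoded `[BOS]` position is the sequence representation.  For a batch of B
aligned pairs with encoded matrices **X**, **Y** (B×d), the score matrix is
**S** = **XY**ᵀ.  Two objectives are minimized jointly:

- *ranking*: −log softmax(**S**ᵢ)ᵢ per row — the in-batch contrastive loss
  that drives the diagonal above the off-diagonal entries.  A literal
  variant, −softmax probability itself (without the log), is kept behind
  `variant="as_printed"`; it is not used for training because its gradient
  vanishes as the probability approaches 1.
- *bag of words*: from **X**ᵢ the model must assign probability to every
  token of reactant i through one shared linear projection + softmax, and
  symmetrically from **Y**ᵢ to the product tokens; both sums enter the loss
  as penalties.  Repeated tokens count once per occurrence.

The overall loss is the batch mean of (rank + bow).  Retrieval is maximum
inner product search over the pre-encoded reactants of the training and
validation reactions only; test reactions are never indexed, so a query can
never retrieve its own record.  Search is exact (brute-force inner products
with ties broken by ascending record id); an approximate index is an
efficiency device, not part of the method, and is not provided.

## Substructure extraction

Every atom of the product and of the top 20 retrieved candidate reactant
sets is annotated with unfolded Morgan integer identifiers at radii 0–6
(RDKit sparse Morgan generator with redundant environments retained, so
every atom has an identifier at every radius the molecule supports).  Raw
identifiers are compared directly; folding into fixed-length bit vectors
would only introduce collisions.

A product atom *aligns* with a candidate when at least one of its
(radius, identifier) pairs at radius ≥ 2 occurs in that candidate (radius
0–1 identifiers are computed but considered too promiscuous for matching; a
single-radius match suffices).  Atoms aligning with at least `threshold`
(default 5) of the 20 candidates seed the substructure; per candidate, the
substructure is the intersection of that candidate's aligned atoms with the
threshold set, then pruned.  Pruning iteratively removes selected atoms that
(a) share an aromatic bond with an unselected atom, (b) share a
stereo-designated bond with an unselected atom, or (c) touch ≥ 2 unselected
atoms, until a fixed point; since all rules only remove atoms, the fixed
point is order independent.  The surviving atom set is bond-induced: every
product bond between selected atoms belongs to the substructure, which may
be disconnected.  Raising the threshold can only shrink coverage — the
`coverage_curve` diagnostic sweeps 3→10 and the tests assert weak
monotonicity.

A substructure is *correct* when its (possibly disconnected) graph embeds as
a subgraph of the disjoint union of the golden reactants, matching element,
charge, aromaticity and bond order but not hydrogen counts (bonds were
broken at attachment points).  On training/validation data incorrect
substructures are filtered out with this check.

## Splitting, virtual numbers, and merging

Every bond crossing the substructure/fragment partition is cut.  Both cut
ends receive the same fresh virtual number and one padding hydrogen per unit
of the broken bond's order, so each piece serializes as a neutral
closed-shell molecule rather than a radical; the broken order is recorded so
merge can strip the padding and restore the bond.  Virtual numbers are
encoded as SMILES isotope labels — `[1SH]` is virtual atom 1 — which RDKit
parses and writes natively, which survive canonicalization, and which the
regex tokenizer treats as single tokens.  The cost of this encoding is that
genuine isotopic labelling is unsupported.  Numbering is deterministic:
crossing bonds are sorted by (substructure-atom canonical rank,
fragment-atom canonical rank) and numbered from 1.

Two structural limits follow from the labeling scheme: crossing bonds may
not be aromatic or stereo-designated (pruning guarantees this), and no atom
may carry two labels, so selections in which one atom has two crossing bonds
(e.g. cutting a single atom out of a non-aromatic ring) are rejected by
`split` and filtered upstream.

Merging parses both labeled SMILES, pairs equal virtual numbers across the
two sides (a number present on only one side is a contract violation and the
prediction is discarded), removes the padding hydrogens, restores the bond
at the recorded order — model-predicted fragments default to single bonds —
and returns the canonicalized molecules.  Valence violations surface as
chemistry errors and the prediction is dropped and counted.

## Substructure-level sequence-to-sequence learning

Training examples isolate the substructure on the *reactant* side: the
source is the labeled substructure SMILES as it appears in the reactants,
the `|` separator, then the product's fragments labeled at the product-side
cut atoms; cut atoms shared by both sides carry one shared number.  The
target is the reactant fragments only (plus whole co-reactant species as
unlabeled components).  Before anything is trained, every accepted example
must pass the integrity gate: merging its source substructure with its
golden target reproduces the golden reactant multiset exactly.  Each example
is augmented with two randomized-SMILES rewritings of the source.  Products
for which no substructure was extracted fall back to plain SMILES→SMILES
examples handled by a separately trained vanilla model with randomized-SMILES
augmentation.

The model is a standard Transformer encoder–decoder trained with
label-smoothed cross-entropy (0.1), Adam (β₁ = 0.9, β₂ = 0.998) and the Noam
schedule; training stops when training perplexity plateaus.  Decoding is
beam search; hypothesis scores are log-probabilities divided by emitted
length, because fragment lengths differ across substructures and
unnormalized scores are not comparable when predictions are aggregated over
substructure groups.  Checkpoint averaging is available as an optional
utility (`average_checkpoints`) and off by default.

Full-scale defaults follow the reference configuration (dual encoder:
embedding 512, hidden 256, feed-forward 2048, 3 blocks, 8 heads, warmup
4000; seq2seq: 512/512/2048, 10 blocks, 8 heads, warmup 8000, Noam scale 2,
dropout 0.1).  All neural components run on a small NumPy reverse-mode
autodiff core written for this package (float64, pre-layer-norm blocks,
learned positional embeddings); at the package's working scale this is fast,
exactly reproducible, and dependency-light.

## Pair-wise reranking

Per distinct assembled reactant set the ranker sees five symmetric
aggregates over substructure groups (groups weighted by how many retrieved
candidates produced that substructure): frequency, fraction of groups
ranking the set first, fraction ranking it in the top 2, and mean beam rank
over all and over unique substructures.  Ranks enter as reciprocal ranks,
frequency as log1p, and features are min–max scaled on the training pairs.
The network is three ReLU layers of width 400 with a scalar output, trained
pair-wise on (golden, non-golden) pairs collected from validation
predictions — at most 10 pairs per product, only from products whose pool
contains the golden set, split 60/40 into train/validation pairs — with a
label-smoothed two-way softmax; training stops when pair accuracy on the
40% split plateaus.  Reranking is a pure permutation of the candidate sets;
ties break by frequency, then mean unique rank, then lexicographic SMILES.

## Synthetic data: what it emulates and what it does not

The generator builds what the method assumes exists: families of reactions
sharing a conserved core.  A core is an aromatic ring system (benzene,
pyridine, furan, naphthalene, quinoline) with 1–3 sp³ alkyl arms of length
2–3 and optional methyl/methoxy decoration; arms keep every ring atom at
least two bonds from any variable group, so ring environments at radius 2
are identical across family members.  Peripheral groups attach at arm ends
through single bonds and substitute deterministically: the highest-priority
group present in a product is the reactive one, and each product-side group
maps to a fixed reactant-side group plus an optional co-reactant species
(ether ← halide + alcohol, nitrile ← bromide, amine ← chloride + amine,
aryl ← halide + boronic acid, ester ↔ alcohol, …).  The golden reactants
are therefore a learnable function of the product.  Distractor reactions
(default 10%) are fluorocarbon/sulfur chains; family molecules contain no F
or S, so every distractor atom environment at radius ≥ 2 is guaranteed
foreign — distractors can never align with family products.  The split is
80/10/10 stratified by family so every test family has training relatives.

What this does not emulate: real reaction-type diversity and class
imbalance, ambiguous products (several plausible reactant sets), reaction
sites inside conserved-looking regions (the error mode the threshold sweep
addresses on real data), stereochemistry changes, and noisy or unbalanced
reaction records.  Passing tests on this corpus demonstrates that the
machinery — retrieval, alignment, extraction, split/merge bookkeeping,
fragment decoding, reranking — is correct and end-to-end learnable, not that
the accuracy figures transfer to literature-scale reaction data.

## Desk-scale profiles and measured behavior

The default test/acceptance conditions are: 500 reactions, 12 cores, 8 group
templates, distractor fraction 0.1; dual encoder 48/32/64, 1 block, 2 heads,
360 steps, batch 16 pairs, lr 3e-3; seq2seq 64/64/128, 2+2 blocks, 2 heads,
3000 steps, batch 16, Noam scale 0.25 with warmup 200 (peak lr ≈ 2e-3);
fallback model 1000 steps; beam 10; ranker width 400, ≤ 60 epochs.  Batches
are length-bucketed to limit padding waste.  One end-to-end run takes
roughly 13 minutes on one CPU.

Numerical and degenerate-input choices: the ranking loss is evaluated via a
stable log-sum-exp; B = 1 makes the log-form rank loss exactly 0 (and the
printed form −1); empty token sequences are rejected by the bag-of-words
loss; MIPS ties break by ascending id; beam ties break by token tuple;
single-atom molecules have exactly one SMILES writing, so randomization
returns it unchanged; a substructure equal to the whole product produces an
empty fragment string, and a reactant set equal to the substructure produces
an empty target.

Known limitations: beam-10 output from the small desk-scale model still
contains a sizable share of malformed low-rank hypotheses (the assembly
report shows the dropped fraction, ~45% at desk scale; invalid merges are
dropped and counted, never silently repaired); selections that would require
two labels on one atom are rejected rather than encoded; and isotope labels
are reserved for virtual numbers.
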