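# Methods

## Residue and peptide chemistry

Each canonical amino acid is rendered from a fixed backbone template
`N[C@@H](R)C(=O)–` (glycine `NCC(=O)–`, proline `N1CCC[C@H]1C(=O)–`)
with a side-chain SMILES `R`; a free residue appends the terminal `–O`,
and a peptide chains the templates N→C so that each junction is an amide
bond and the molecule loses one water per bond. All output is
RDKit-canonicalized. The templates reproduce the textbook molecular
formula of all twenty free amino acids, and peptide formulas follow by
conservation (checked in the tests against pure formula arithmetic).

Stereochemistry: residues carry the L-configuration (plus the side-chain
centers of Ile and Thr) by default; `include_stereo=False` strips all
stereo marks. The choice of convention is a rendering option because
either form is a chemically faithful target for sequence models.

Masked-span fragments have free amine/acid termini (no caps): a masked
span is rendered as exactly the peptide its residues would form on
their own, which keeps formula conservation exact and requires no
capping convention.

## Covalent grafting

An adduct is a SMILES fragment with exactly one dummy atom `[*]`
attached by exactly one single bond — multi-attachment or higher-order
attachments are rejected, since a single sentinel-delimited residue
cannot express a bridge between two residues. Grafting removes the
dummy, bonds its neighbour to the residue's reactive side-chain atom
with a single bond, removes one hydrogen from that atom, and sanitizes.
This is direct molecular-graph editing with valence checking rather
than any grouped string grammar; it conserves heavy atoms exactly and
changes the hydrogen count by exactly one.

Reactive atoms are fixed per residue (Cys Sγ, Lys Nζ, Ser/Thr Og,
Tyr Oh, His Nε2, Asp/Glu carboxyl O, Arg Nη, Trp Nε1, Met Sδ) and are
marked in the side-chain templates with atom maps, so no post-hoc
substructure matching is needed. Methionine's thioether sulfur is a
defined attachment atom but carries no hydrogen, so grafting it raises
a valence error rather than silently producing a charged sulfonium; the
synthetic generator therefore draws covalent sites from the ten residues
that graft cleanly.

## Vocabulary and tokenization

The vocabulary is frozen at 203 entries: 3 special + 100 sentinels +
2 task tags + 20 amino-acid tokens + 78 SMILES characters, in that
index order. The 78-character SMILES inventory is all 52 ASCII letters,
the 10 digits, and 16 punctuation characters
(`( ) [ ] = # - + / \ @ % . * : ~`) — enough to cover canonical
SMILES including bracket atoms, isotopes, charges, stereo marks,
disconnection and the attachment dummy. Tokenization is strictly
character-level in both domains (`Cl` → `C`,`l`); amino acids become
`<P>X` tokens so the protein `S` can never collide with the sulfur
atom `S`. Sentinels, task tags and the basic special tokens are atomic
wherever they occur. Unknown characters map to `<unk>` with a logged
warning so corpus scans never abort; detokenization is the exact inverse
whenever no `<unk>` occurred.

## Span corruption

The sampler targets a masked fraction of 15% with mean span length 3.
For a sequence of `n` tokens the budget is `round(0.15·n)`; the number
of spans is `round(budget/3)` (capped at the 100-sentinel budget);
span lengths start from 1 + Poisson(mean − 1) draws and are rebalanced
by ±1 steps to meet the budget exactly; placement distributes the
remaining slack over the gaps with at least one unmasked token between
consecutive spans (adjacent spans would be indistinguishable from one
longer span, so they are merged). This makes the per-sequence masked
fraction exact up to rounding and the corpus-level mean span length
3.0 within ±0.1, as the acceptance suite verifies over ≥10⁵ tokens.

Span-Mask targets carry the masked runs verbatim, so splicing the
target back into the input restores the source exactly — a lossless-ness
property tested on 1,000 generated molecules. Chem-Mask extracts a
window of at most 128 residues (uniform random start) and renders each
masked residue span as SMILES; the decoder target covers only the
masked spans (sentinel-delimited), mirroring Span-Mask — the
whole-sequence alternative is available via the example construction
but span-only is the default for symmetry between the two objectives.
The masking rate is computed on the extracted window. Fragment rendering
defaults to the condensed (peptide-bonded) form; `per_residue` renders
dot-separated free residues instead.

Sentinels descend from `<extra_id_99>` left to right, and every input
sentinel reappears exactly once in the target in the same order.

## Covalent tasks

The generation task encodes input as
`Covalent:<protein>|<ligand SMILES>` (the tag and `|` separator are this
package's convention) and the target as the protein sequence with the
covalent residue replaced by `<extra_id_99><grafted SMILES><extra_id_98>`.
Parsing inverts this: position = residues before the opening sentinel
plus one (1-based, the biological convention); outputs with missing,
repeated, out-of-order sentinels or an empty adduct block are flagged
malformed and scored as incorrect, never raised.

Splits operate on unique (protein, ligand) pairs so replicated complex
chains cannot leak across partitions: validation and test each take
`round(0.1·n)` keys and train the remainder, which maps 4,251 unique
pairs to (3401, 425, 425). Negative mixing samples equally many
non-covalent pairs without replacement, uniformly from the pool
(negatives are not matched by protein), giving an exact 1:1 label ratio.

## Metrics

- **F_max** sweeps all distinct score values; at each threshold,
  precision is averaged only over proteins with ≥1 prediction at or
  above it and recall over all annotated proteins (the CAFA convention).
  A score of exactly zero counts as "no prediction" at every threshold,
  so an all-zero score matrix scores 0.
- **AUPRC** is micro-averaged over all (protein, class) cells with
  step-wise integration (scikit-learn's average precision).
- **CI** enumerates all pairs with strictly ordered true affinities:
  credit 1 for a concordant prediction, ½ for a predicted tie,
  normalized by the pair count. O(n²) vectorized — fine at evaluation
  sizes; cross-checked against an independent survival-analysis
  implementation in the tests.
- **Regression suite**: RMSE; Pearson r; r² as squared Pearson (the
  QSAR convention); r₀² as the coefficient of determination of the
  least-squares through-origin regression of observed on predicted
  (slope k = Σyŷ/Σŷ²), after Roy et al.; r_m² = r²·(1 − √(r² − r₀²))
  with the radicand clamped at zero so adversarial inputs cannot
  produce complex values. Zero-variance inputs are rejected.
- **Adduct/position accuracy**: adducts compare equal after RDKit
  canonicalization (atom ordering is irrelevant); positions compare as
  parsed integers; malformed or unparsable predictions are wrong on
  both counts.

## Synthetic data

Generators are deterministic under their seed and exist to give every
stage inputs with the structure it assumes, not to mimic real corpora:
proteins are i.i.d. uniform over the 20 residues (a log-normal length
option approximates database length distributions), molecules are
assembled by concatenating fragments from a frozen library whose members
all chain validly — so every output parses without a rejection loop —
and affinity tables expose the latent score that generated them, so
ranking metrics have exact ground truth. Consequently, passing tests
demonstrate correctness of the machinery, not performance on natural
sequence or chemical space: real proteins have composition bias and
domain structure, and real ligand sets have property distributions these
generators do not model.

Default condition sizes: corpus statistics use 1,000 sequences of
100–500 tokens (≈3×10⁵ tokens); property suites use 1,000 molecules,
1,000 proteins, and 500 covalent records; ranking metrics are checked
on 100 random small instances against brute force.

## Training harness

The harness model is a pre-norm encoder–decoder with RMS layer norms
(no biases anywhere), bias-free linear projections, one shared
relative-position bias table per stack (32 log-spaced buckets,
bidirectional for the encoder, causal for the decoder; none on
cross-attention), a gated feed-forward block (SiLU gate, three
projections), and the input embedding tied to the output head with the
customary 1/√d logit scaling. With 8 layers per stack, 10 heads of 64,
width 640, feed-forward 2048 and 203 tokens this totals 102,393,600
parameters; an ungated 2-projection block would give ≈81.5 M, so the
gated block is the configuration consistent with the ~102 M total, and
it is the default. Embedding tying changes the total by only 0.13 M,
below rounding at this scale.

`count_parameters` is a closed form over tensor shapes and is asserted
equal to instantiate-and-count on random configurations and on a
hand-enumerated minimal configuration. Autodiff is a small tape-based
reverse-mode engine over NumPy arrays, gradient-checked against central
finite differences at 10⁻⁶ tolerance in float64.

Smoke training is full-batch Adam (lr 3×10⁻³) on a 2-layer, width-64
configuration; ten protein-to-SMILES corruption examples are memorized
to cross entropy < 0.1 in well under 500 steps, and greedy decoding of
a memorized model reproduces its training target token-for-token —
the learnability evidence the harness exists to provide. Training is
bit-deterministic under its seed (pure NumPy). The full pretraining
recipe (142,599 steps, batch 2,880, lr 1.414×10⁻⁴) is recorded in
`PretrainingSchedule` as documentation of the target regime; it assumes
multi-GPU bf16 training and is not an executable path here.

## Known limitations

- Non-canonical amino acids appear only as grafted single-residue
  adducts; multi-site or doubly-bonded adducts are rejected by design.
- Protonation states, tautomer choice (His is rendered as the Nε2–H
  tautomer, which is also the grafting site) and 3-D structure are out
  of scope.
- The tokenizer covers canonical SMILES characters; exotic dialects
  (SELFIES, InChI) are not goals.
- The concordance index is O(n²) in memory; at n ≫ 10⁴ a
  tree-based implementation would be preferable.
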