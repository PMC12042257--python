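# atomspan

Data machinery for a unified protein/chemical sequence model: dual-domain
tokenization, span-corruption pretraining objectives that decode masked
protein spans as SMILES, covalent-binder task encoding, and the standard
drug–target evaluation metrics — with a smoke-scale encoder–decoder
harness that audits the architecture's parameter count and demonstrates
the objectives are learnable on a single CPU.

## The problem

Protein language models read amino acids; chemical language models read
SMILES. A covalent drug, which bonds irreversibly to a residue's side
chain, lives in both worlds at once: the resulting adduct is a
non-natural amino acid that a protein-only vocabulary cannot express.
`atomspan` implements the data side of a model that treats both languages
in one vocabulary and is pretrained to translate between them at the
atomic level, so that grafted residues are just more chemistry.

The pieces, in pipeline order:

- **`atomspan.chem`** — exact SMILES rendering of residues, peptides
  (condensation: one amide bond and one H₂O lost per bond), masked-span
  fragments, and covalent grafting: the adduct's attachment dummy atom
  `[*]` is replaced by a single bond to the residue's reactive side-chain
  atom (Cys Sγ, Lys Nζ, Ser/Thr/Tyr O, His Nε2, Asp/Glu carboxyl O,
  Arg Nη, Trp Nε1), removing one hydrogen there.
- **`atomspan.tokenizer`** — a frozen 203-token vocabulary: 3 special
  tokens (`<pad>`, `<unk>`, `<eos>`), 100 sentinels
  (`<extra_id_0>`–`<extra_id_99>`), 2 task tags (`Span-Mask:`,
  `Chem-Mask:`), 20 amino-acid tokens (`<P>A`…`<P>Y`) and a 78-character
  SMILES inventory. Tokenization is strictly character-level (`Cl` →
  `C`, `l`) and exactly reversible.
- **`atomspan.objectives`** — sentinel span corruption: ~15% of tokens
  masked in spans of mean length 3, sentinels descending from
  `<extra_id_99>`. `Span-Mask` targets reproduce the masked SMILES runs;
  `Chem-Mask` extracts a window of ≤128 residues and renders each masked
  residue span as the SMILES of its peptide fragment.
- **`atomspan.covalent`** — the covalent-binder tasks: seq2seq targets
  where the covalent residue is replaced by
  `<extra_id_99><grafted SMILES><extra_id_98>`, leakage-safe 80/10/10
  splits on unique (protein, ligand) pairs, and balanced negative mixing
  for binary classification.
- **`atomspan.metrics`** — protein-centric F_max and micro-AUPRC,
  concordance index CI (pairwise ranking, ties credit ½), RMSE, Pearson
  r, r², the through-origin r₀² of Roy et al. and
  r_m² = r²·(1 − √(r² − r₀²)), plus adduct/position exact-match
  accuracies under canonicalization.
- **`atomspan.synthetic`** — seeded generators for proteins, valid
  SMILES, affinity tables with a known latent ranking, and covalent
  records, so every stage is testable without external corpora.
- **`atomspan.harness`** — a NumPy encoder–decoder (pre-norm, relative
  position biases, gated feed-forward, tied embedding) with its own
  reverse-mode autodiff: a closed-form parameter count verified against
  instantiate-and-count (the published 8+8-layer, 10-head, width-640
  configuration totals 102,393,600 ≈ 102 M parameters), full-batch Adam
  smoke training, and greedy decoding.

## Worked example

```python
>>> from atomspan import AdductSpec, graft_adduct, build_adduct_example
>>> from atomspan.covalent import CovalentRecord, parse_adduct_prediction
>>> mod = graft_adduct("C", AdductSpec("[*]CC#N"))
>>> mod.product_smiles
'N#CCSC[C@H](N)C(=O)O'
>>> rec = CovalentRecord("GCG", "CCO", 2, AdductSpec("[*]CC#N"))
>>> build_adduct_example(rec)
('Covalent:GCG|CCO', 'G<extra_id_99>N#CCSC[C@H](N)C(=O)O<extra_id_98>G')
>>> parse_adduct_prediction(_[1])
(2, 'N#CCSC[C@H](N)C(=O)O')
```

The grafted cysteine keeps all 7 of its heavy atoms and gains the
adduct's 3; the parsed position (2) is the count of residues before the
opening sentinel plus one. The `examples/` directory holds one short
script per capability (`peptide_chemistry`, `span_corruption`,
`covalent_tasks`, `affinity_metrics`, `smoke_training`); each prints its
numbers with a line on what they mean. A thin CLI mirrors the same
operations (`atomspan vocab|corrupt|covalent|evaluate|synth|harness`).

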