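"""Build span-corruption training examples in both domains.

A SMILES string gets classic sentinel span masking (Span-Mask); a protein
gets the cross-domain variant (Chem-Mask) in which each masked residue
span must be decoded as the SMILES of those residues.  Sentinels count
down from <extra_id_99> left to right, and about 15% of tokens are masked
in spans averaging three tokens.
"""

import numpy as np

from atomspan import CorruptionConfig, corrupt_protein, corrupt_smiles

config = CorruptionConfig(seed=0)
rng = np.random.default_rng(0)

ex = corrupt_smiles("CCOC(=O)c1ccccc1N", config, rng)
print("Span-Mask input :", " ".join(ex.input_tokens))
print("Span-Mask target:", " ".join(ex.target_tokens))
print("  - the target lists each masked run after its sentinel;",
      "splicing them back restores the molecule exactly\n")

ex = corrupt_protein("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", config, rng)
print("Chem-Mask input :", " ".join(ex.input_tokens))
print("Chem-Mask target:", " ".join(ex.target_tokens))
print("  - each masked residue span is rendered as the SMILES of its",
      "peptide fragment, bridging the protein and chemical languages")
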