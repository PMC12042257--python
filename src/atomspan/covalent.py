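"""Sequence-level covalent-binder tasks: encoding, parsing, splitting.

A covalent drug bonds irreversibly to one residue of its target protein;
the residue plus the ligand-derived adduct forms a non-natural amino acid.
Two task encodings are built here:

* **adduct + position generation** — seq2seq: given the protein and the
  ligand SMILES, produce the protein sequence with the covalent residue
  replaced by its grafted SMILES, bounded by ``<extra_id_99>`` and
  ``<extra_id_98>``.  The residue position is read off as the number of
  residues preceding the opening sentinel.

* **binary classification** — covalent pairs mixed with an equal number
  of non-covalent pairs as negatives.

Splits are made on unique (protein, ligand) pairs so duplicated complex
chains can never leak across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import AdductSpec, REACTIVE_RESIDUES, graft_adduct
from .tokenizer import tokenize

__all__ = [
    "COVALENT_TAG",
    "SEPARATOR",
    "CovalentRecord",
    "Split",
    "LabeledExample",
    "build_adduct_example",
    "adduct_target_tokens",
    "parse_adduct_prediction",
    "make_splits",
    "mix_negatives",
]

COVALENT_TAG = "Covalent:"
SEPARATOR = "|"

_OPEN = "<extra_id_99>"
_CLOSE = "<extra_id_98>"


@dataclass(frozen=True)
class CovalentRecord:
    """One protein-ligand covalent pair with its binding site and adduct."""

    protein: str
    ligand_smiles: str
    position: int  # 1-based residue index of the covalent site
    adduct: AdductSpec

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.protein, self.ligand_smiles)

    def validate(self) -> None:
        if not self.protein:
            raise ValueError("empty protein sequence")
        if not 1 <= self.position <= len(self.protein):
            raise ValueError(
                f"position {self.position} outside 1..{len(self.protein)}"
            )
        res = self.protein[self.position - 1]
        if res not in REACTIVE_RESIDUES:
            raise ValueError(f"residue {res!r} at position {self.position} "
                             "has no reactive side-chain atom")
        self.adduct.validate()


def build_adduct_example(
    record: CovalentRecord, include_stereo: bool = True
) -> tuple[str, str]:
    """Input/target text of the adduct + position generation task.

    Input: ``Covalent:<protein>|<ligand SMILES>``.  Target: the protein
    sequence with the covalent residue replaced by
    ``<extra_id_99><grafted residue SMILES><extra_id_98>``.
    """
    record.validate()
    res = record.protein[record.position - 1]
    grafted = graft_adduct(res, record.adduct, include_stereo)
    input_text = f"{COVALENT_TAG}{record.protein}{SEPARATOR}{record.ligand_smiles}"
    before = record.protein[: record.position - 1]
    after = record.protein[record.position:]
    target_text = f"{before}{_OPEN}{grafted.product_smiles}{_CLOSE}{after}"
    return input_text, target_text


def adduct_target_tokens(target_text: str) -> tuple[str, ...]:
    """Tokenize an adduct-task target: residues as <P>X, the bounded
    adduct block as SMILES characters, sentinels atomic."""
    parsed = parse_adduct_prediction(target_text)
    if parsed is None:
        raise ValueError(f"malformed adduct target: {target_text!r}")
    head, tail = target_text.split(_OPEN, 1)
    mid, tail = tail.split(_CLOSE, 1)
    toks: list[str] = []
    if head:
        toks.extend(tokenize(head, "protein").tokens)
    toks.append(_OPEN)
    toks.extend(tokenize(mid, "smiles").tokens)
    toks.append(_CLOSE)
    if tail:
        toks.extend(tokenize(tail, "protein").tokens)
    return tuple(toks)


def parse_adduct_prediction(output_text: str) -> tuple[int, str] | None:
    """Read (position, adduct SMILES) from a generated target.

    Position is 1 + the number of residues preceding ``<extra_id_99>``;
    the adduct SMILES is the text between the two sentinels.  Returns
    ``None`` (malformed) when the sentinels are missing, repeated, or out
    of order — downstream accuracy counts malformed outputs as wrong.
    """
    if output_text.count(_OPEN) != 1 or output_text.count(_CLOSE) != 1:
        return None
    i, j = output_text.index(_OPEN), output_text.index(_CLOSE)
    if j < i:
        return None
    position = i + 1  # one character per residue before the open sentinel
    adduct_smiles = output_text[i + len(_OPEN): j]
    if not adduct_smiles:
        return None
    return position, adduct_smiles


@dataclass(frozen=True)
class Split:
    """Disjoint train/validation/test partitions of unique pair keys."""

    train: tuple[tuple[str, str], ...]
    validation: tuple[tuple[str, str], ...]
    test: tuple[tuple[str, str], ...]
    ratios: tuple[float, float, float]
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    def assign(self, key: tuple[str, str]) -> str:
        if key in set(self.train):
            return "train"
        if key in set(self.validation):
            return "validation"
        if key in set(self.test):
            return "test"
        raise KeyError(key)


def make_splits(
    records,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Split:
    """80/10/10 split on unique pair keys, grouping duplicates.

    Validation and test sizes are ``round(ratio * n)`` each and train
    takes the remainder, so 4251 unique pairs give (3401, 425, 425).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    keys: list[tuple[str, str]] = []
    seen = set()
    for r in records:
        key = r.pair_key if isinstance(r, CovalentRecord) else tuple(r)
        if key not in seen:
            seen.add(key)
            keys.append(key)
    if len(keys) < 3:
        raise ValueError("need at least as many unique pair keys as partitions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    shuffled = [keys[i] for i in order]
    n = len(shuffled)
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    test = shuffled[:n_test]
    val = shuffled[n_test:n_test + n_val]
    train = shuffled[n_test + n_val:]
    return Split(tuple(train), tuple(val), tuple(test), tuple(ratios), seed)


@dataclass(frozen=True)
class LabeledExample:
    protein: str
    ligand_smiles: str
    label: int  # 1 = covalent, 0 = non-covalent


def mix_negatives(positives, negative_pool, seed: int = 0) -> list[LabeledExample]:
    """Balance covalent positives with equally many sampled negatives.

    Negatives are drawn without replacement from ``negative_pool``
    (non-covalent (protein, ligand) pairs); the combined set is shuffled
    deterministically.  The result always has an exact 1:1 label ratio.
    """
    positives = list(positives)
    pool = list(negative_pool)
    if len(pool) < len(positives):
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than positives ({len(positives)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=len(positives), replace=False)

    def as_pair(item):
        if isinstance(item, CovalentRecord):
            return item.protein, item.ligand_smiles
        return tuple(item)

    examples = [LabeledExample(*as_pair(p), label=1) for p in positives]
    examples += [LabeledExample(*as_pair(pool[i]), label=0) for i in idx]
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]
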