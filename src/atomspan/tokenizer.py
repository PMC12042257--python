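"""Fixed dual-domain vocabulary and reversible character-level tokenization.

The model works on two languages at once: protein sequences and SMILES
strings.  To keep the domains unambiguous at the token level, every amino
acid is represented as a dedicated ``<P>X`` token (``<P>S`` is a single
token, distinct from the SMILES sulfur character ``S``), while SMILES text
is tokenized strictly character by character — two-letter element symbols
are deliberately split (``Cl`` -> ``C``, ``l``).

The vocabulary is a frozen 203-entry inventory:

========== =====  =========================================================
category   count  entries
========== =====  =========================================================
special        3  ``<pad>``, ``<unk>``, ``<eos>``
sentinel     100  ``<extra_id_0>`` ... ``<extra_id_99>``
task           2  ``Span-Mask:``, ``Chem-Mask:``
amino_acid    20  ``<P>A`` ... ``<P>Y`` (alphabetical)
smiles_char   78  ASCII letters (both cases), digits, 16 SMILES punctuation
                  characters ``( ) [ ] = # - + / \\ @ % . * : ~``
========== =====  =========================================================
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass

from .chem import CANONICAL_CODES

logger = logging.getLogger(__name__)

__all__ = [
    "PAD", "UNK", "EOS", "SPAN_MASK_TAG", "CHEM_MASK_TAG",
    "SMILES_CHARS", "Vocabulary", "TokenizedSequence",
    "build_vocabulary", "tokenize", "detokenize", "sentinel",
]

PAD = "<pad>"
UNK = "<unk>"
EOS = "<eos>"
SPAN_MASK_TAG = "Span-Mask:"
CHEM_MASK_TAG = "Chem-Mask:"

_SPECIAL = (PAD, UNK, EOS)
_TASK_TAGS = (SPAN_MASK_TAG, CHEM_MASK_TAG)
_SENTINELS = tuple(f"<extra_id_{k}>" for k in range(100))
_AA_TOKENS = tuple(f"<P>{c}" for c in sorted(CANONICAL_CODES))

_SMILES_PUNCT = "()[]=#-+/\\@%.*:~"
#: The frozen 78-character SMILES inventory: 52 ASCII letters, 10 digits,
#: and 16 punctuation characters covering ring closures, branches,
#: brackets, bond orders, charges, stereo marks, disconnection and the
#: attachment dummy.
SMILES_CHARS = tuple(string.ascii_uppercase) + tuple(string.ascii_lowercase) \
    + tuple(string.digits) + tuple(_SMILES_PUNCT)

# Multi-character tokens recognised atomically inside any text.
_ATOMIC_RE = re.compile(
    r"<extra_id_\d{1,2}>|<pad>|<unk>|<eos>|Span-Mask:|Chem-Mask:"
)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory with a category tag per entry."""

    entries: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self):
        if len(self.entries) != len(set(self.entries)):
            raise ValueError("duplicate vocabulary entries")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.entries)})

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        return self._index[token]

    def token(self, idx: int) -> str:
        return self.entries[idx]

    def encode(self, tokens: list[str]) -> list[int]:
        unk = self._index[UNK]
        return [self._index.get(t, unk) for t in tokens]

    def decode(self, ids: list[int]) -> list[str]:
        return [self.entries[i] for i in ids]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.categories:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.entries:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            entries = tuple(line.rstrip("\n") for line in fh if line.rstrip("\n"))
        ref = build_vocabulary()
        cats = tuple(
            ref.categories[ref.index(t)] if t in ref else "smiles_char"
            for t in entries
        )
        return cls(entries=entries, categories=cats)


@dataclass(frozen=True)
class TokenizedSequence:
    """A token list plus the domain it was tokenized under."""

    tokens: tuple[str, ...]
    domain: str  # 'protein' | 'smiles' | 'mixed'

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def build_vocabulary() -> Vocabulary:
    """The fixed 203-token vocabulary (3+100+2+20+78)."""
    entries = _SPECIAL + _SENTINELS + _TASK_TAGS + _AA_TOKENS + SMILES_CHARS
    categories = (
        ("special",) * len(_SPECIAL)
        + ("sentinel",) * len(_SENTINELS)
        + ("task",) * len(_TASK_TAGS)
        + ("amino_acid",) * len(_AA_TOKENS)
        + ("smiles_char",) * len(SMILES_CHARS)
    )
    return Vocabulary(entries=entries, categories=categories)


def sentinel(k: int) -> str:
    """The k-th sentinel token, ``<extra_id_k>`` with 0 <= k <= 99."""
    if not (isinstance(k, int) and 0 <= k <= 99):
        raise ValueError(f"sentinel index out of range [0, 99]: {k!r}")
    return f"<extra_id_{k}>"


_SMILES_SET = frozenset(SMILES_CHARS)
_AA_SET = frozenset(CANONICAL_CODES)


def tokenize(text: str, domain: str) -> TokenizedSequence:
    """Character-level tokenization of protein or SMILES text.

    Sentinels, task tags and the basic special tokens are always emitted
    as single tokens.  Characters outside the inventory map to ``<unk>``
    with a logged warning (the corpus scan keeps going).
    """
    if not text:
        raise ValueError("cannot tokenize empty text")
    if domain not in ("protein", "smiles"):
        raise ValueError(f"unknown domain: {domain!r}")
    tokens: list[str] = []
    i = 0
    while i < len(text):
        m = _ATOMIC_RE.match(text, i)
        if m:
            tokens.append(m.group())
            i = m.end()
            continue
        ch = text[i]
        if domain == "protein":
            if ch in _AA_SET:
                tokens.append(f"<P>{ch}")
            else:
                logger.warning("unknown protein character %r -> <unk>", ch)
                tokens.append(UNK)
        else:
            if ch in _SMILES_SET:
                tokens.append(ch)
            else:
                logger.warning("unknown SMILES character %r -> <unk>", ch)
                tokens.append(UNK)
        i += 1
    return TokenizedSequence(tokens=tuple(tokens), domain=domain)


def detokenize(seq: TokenizedSequence) -> str:
    """Exact inverse of :func:`tokenize` (rejects sequences with <unk>)."""
    parts: list[str] = []
    for tok in seq.tokens:
        if tok == UNK:
            raise ValueError("cannot detokenize a sequence containing <unk>")
        if tok.startswith("<P>") and len(tok) == 4:
            parts.append(tok[3:])
        else:
            parts.append(tok)
    return "".join(parts)
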