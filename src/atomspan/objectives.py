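"""Span-corruption training objectives over SMILES and protein sequences.

Two corruption modes share one span sampler:

* **Span-Mask** (SMILES denoising): contiguous token runs of a SMILES
  string are replaced by sentinel tokens and the target reproduces the
  masked runs, delimited by the same sentinels — classic seq2seq span
  corruption.

* **Chem-Mask** (protein-to-SMILES span corruption): a window of at most
  ``max_segment`` residues is cut from the protein, residue spans are
  masked the same way, and the target renders each masked span as the
  SMILES of its residues, bridging the two domains.

Sentinels run in *descending* order left-to-right (``<extra_id_99>``,
``<extra_id_98>``, ...), and each input sentinel reappears exactly once in
the target, in the same order.  Roughly 15% of the tokens are masked with
a mean span length of three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chem
from .tokenizer import (
    CHEM_MASK_TAG,
    EOS,
    SPAN_MASK_TAG,
    UNK,
    TokenizedSequence,
    sentinel,
    tokenize,
)

__all__ = [
    "CorruptionConfig",
    "CorruptionExample",
    "MaskStats",
    "sample_spans",
    "corrupt_smiles",
    "corrupt_protein",
    "corpus_mask_stats",
    "splice_back",
]

#: At most 100 sentinel tokens exist, so at most 100 spans per example.
MAX_SPANS = 100


@dataclass(frozen=True)
class CorruptionConfig:
    """Knobs of the span sampler and the protein window extraction.

    mask_rate
        Fraction of source tokens covered by masked spans (default 0.15).
    mean_span
        Mean masked-span length in tokens (default 3).
    max_segment
        Maximum protein window length in residues (default 128).
    fragment_mode
        How Chem-Mask renders a masked residue span as SMILES:
        ``condensed`` (one peptide-bonded fragment) or ``per_residue``
        (dot-separated free residues).
    """

    mask_rate: float = 0.15
    mean_span: float = 3.0
    max_segment: int = 128
    fragment_mode: str = "condensed"
    include_stereo: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask_rate must lie in (0, 1)")
        if self.mean_span < 1:
            raise ValueError("mean_span must be >= 1")
        if self.max_segment < 1:
            raise ValueError("max_segment must be >= 1")
        if self.fragment_mode not in ("condensed", "per_residue"):
            raise ValueError(f"unknown fragment_mode: {self.fragment_mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CorruptionExample:
    """One corrupted (input, target) pair.

    ``spans`` are (start, length) intervals in source coordinates
    (0-based, half-open over the tokenized source; for proteins the
    source is the extracted window).
    """

    input_tokens: TokenizedSequence
    target_tokens: TokenizedSequence
    spans: tuple[tuple[int, int], ...]
    n_source_tokens: int
    window: tuple[int, int] | None = None  # (start, length) for proteins

    def sentinels_used(self) -> tuple[str, ...]:
        return tuple(t for t in self.input_tokens if t.startswith("<extra_id_"))


def _merge_adjacent(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge touching/overlapping spans (logged-free normalization step)."""
    if not spans:
        return spans
    spans = sorted(spans)
    merged = [spans[0]]
    for s, l in spans[1:]:
        ps, pl = merged[-1]
        if s <= ps + pl:  # adjacent or overlapping
            merged[-1] = (ps, max(ps + pl, s + l) - ps)
        else:
            merged.append((s, l))
    return merged


def sample_spans(
    n_tokens: int,
    config: CorruptionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Draw non-overlapping, non-adjacent masked spans over ``n_tokens``.

    The total masked budget is ``round(mask_rate * n_tokens)`` and span
    lengths are drawn from 1 + Poisson(mean_span - 1), then adjusted so
    the budget is met exactly; placement is random with at least one
    unmasked token between consecutive spans.  Deterministic for a given
    generator state.
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    config = config or CorruptionConfig()
    rng = rng if rng is not None else config.rng()

    budget = int(round(config.mask_rate * n_tokens))
    if budget < 1:
        return []
    n_spans = max(1, int(round(budget / config.mean_span)))
    # sentinel budget, and room for a gap between consecutive spans
    n_spans = min(n_spans, MAX_SPANS, budget, (n_tokens + 1) // 2)
    budget = min(budget, n_tokens - (n_spans - 1))

    lengths = 1 + rng.poisson(config.mean_span - 1.0, size=n_spans)
    # Rebalance to hit the budget exactly while keeping every span >= 1.
    diff = budget - int(lengths.sum())
    while diff != 0:
        i = int(rng.integers(n_spans))
        if diff > 0:
            lengths[i] += 1
            diff -= 1
        elif lengths[i] > 1:
            lengths[i] -= 1
            diff += 1
    lengths = lengths[rng.permutation(n_spans)]

    # Place spans with >=1-token gaps: distribute the free slack over the
    # n_spans + 1 gaps around them.
    slack = n_tokens - budget - (n_spans - 1)
    extra = rng.multinomial(slack, np.full(n_spans + 1, 1.0 / (n_spans + 1)))
    spans: list[tuple[int, int]] = []
    pos = 0
    for i, length in enumerate(lengths):
        pos += extra[i] + (1 if i > 0 else 0)
        spans.append((pos, int(length)))
        pos += int(length)
    return _merge_adjacent(spans)


def _build_example(
    source_tokens: tuple[str, ...],
    spans: list[tuple[int, int]],
    tag: str,
    render_span,
    domain: str,
    window: tuple[int, int] | None = None,
) -> CorruptionExample:
    input_toks: list[str] = [tag]
    target_toks: list[str] = []
    pos = 0
    for k, (start, length) in enumerate(spans):
        s_tok = sentinel(99 - k)
        input_toks.extend(source_tokens[pos:start])
        input_toks.append(s_tok)
        target_toks.append(s_tok)
        target_toks.extend(render_span(start, length))
        pos = start + length
    input_toks.extend(source_tokens[pos:])
    target_toks.append(EOS)
    return CorruptionExample(
        input_tokens=TokenizedSequence(tuple(input_toks), domain),
        target_tokens=TokenizedSequence(tuple(target_toks), domain),
        spans=tuple(spans),
        n_source_tokens=len(source_tokens),
        window=window,
    )


def corrupt_smiles(
    smiles: str,
    config: CorruptionConfig | None = None,
    rng: np.random.Generator | None = None,
    spans: list[tuple[int, int]] | None = None,
) -> CorruptionExample:
    """Build a Span-Mask denoising example from a SMILES string.

    ``spans`` may be injected for deterministic construction; otherwise
    they are drawn by :func:`sample_spans`.
    """
    config = config or CorruptionConfig()
    source = tokenize(smiles, "smiles")
    if UNK in source.tokens:
        raise ValueError(f"SMILES contains characters outside the inventory: {smiles!r}")
    if spans is None:
        spans = sample_spans(len(source), config, rng)
    spans = _merge_adjacent(list(spans))
    toks = source.tokens
    return _build_example(
        toks, spans, SPAN_MASK_TAG,
        lambda s, l: toks[s:s + l],
        "smiles",
    )


def corrupt_protein(
    sequence: str,
    config: CorruptionConfig | None = None,
    rng: np.random.Generator | None = None,
    spans: list[tuple[int, int]] | None = None,
) -> CorruptionExample:
    """Build a Chem-Mask example: masked residue spans decode as SMILES.

    A contiguous window of at most ``max_segment`` residues is extracted
    (uniform random start), spans are sampled over the window's residue
    tokens, and each masked span's target is the SMILES rendering of its
    residues (``fragment_mode`` controls condensed vs per-residue).
    """
    config = config or CorruptionConfig()
    rng = rng if rng is not None else config.rng()
    for c in sequence:
        if c not in chem.CANONICAL_CODES:
            raise ValueError(f"non-canonical residue {c!r} in sequence")
    if not sequence:
        raise ValueError("empty sequence")

    w = min(len(sequence), config.max_segment)
    start = int(rng.integers(0, len(sequence) - w + 1))
    window_seq = sequence[start:start + w]
    if spans is None:
        spans = sample_spans(w, config, rng)
    spans = _merge_adjacent(list(spans))

    source = tokenize(window_seq, "protein").tokens

    def render(s: int, l: int) -> list[str]:
        frag = chem.span_fragment_smiles(
            window_seq[s:s + l], config.fragment_mode, config.include_stereo
        )
        return list(tokenize(frag, "smiles").tokens)

    return _build_example(source, spans, CHEM_MASK_TAG, render, "mixed",
                          window=(start, w))


def splice_back(example: CorruptionExample) -> tuple[str, ...]:
    """Reconstruct the source tokens of a Span-Mask example.

    Splices each sentinel-delimited run of the target back into the
    sentinel's slot in the input.  Only valid for Span-Mask examples,
    whose targets carry the masked tokens verbatim.
    """
    # split target into sentinel -> run mapping
    runs: dict[str, list[str]] = {}
    current: list[str] | None = None
    for tok in example.target_tokens:
        if tok == EOS:
            break
        if tok.startswith("<extra_id_"):
            current = runs.setdefault(tok, [])
        elif current is not None:
            current.append(tok)
    out: list[str] = []
    for tok in example.input_tokens:
        if tok == SPAN_MASK_TAG or tok == CHEM_MASK_TAG:
            continue
        if tok.startswith("<extra_id_"):
            out.extend(runs.get(tok, []))
        else:
            out.append(tok)
    return tuple(out)


@dataclass(frozen=True)
class MaskStats:
    masked_fraction: float
    mean_span: float
    n_spans: int


def corpus_mask_stats(examples: list[CorruptionExample]) -> MaskStats:
    """Empirical masked fraction and mean span length over a corpus."""
    if not examples:
        raise ValueError("empty corpus")
    total = sum(e.n_source_tokens for e in examples)
    masked = sum(l for e in examples for _, l in e.spans)
    n_spans = sum(len(e.spans) for e in examples)
    mean = masked / n_spans if n_spans else 0.0
    return MaskStats(masked / total, mean, n_spans)
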