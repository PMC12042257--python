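"""Span sampling and the two corruption objectives."""

import numpy as np
import pytest

from atomspan import chem, synthetic
from atomspan.objectives import (
    CorruptionConfig,
    corpus_mask_stats,
    corrupt_protein,
    corrupt_smiles,
    sample_spans,
)
from atomspan.tokenizer import EOS, tokenize


def splice(example):
    """Test-local inverse splice: rebuild the source from input+target."""
    runs, current = {}, None
    for tok in example.target_tokens:
        if tok == EOS:
            break
        if tok.startswith("<extra_id_"):
            runs[tok] = current = []
        elif current is not None:
            current.append(tok)
    out = []
    for tok in example.input_tokens:
        if tok in ("Span-Mask:", "Chem-Mask:"):
            continue
        if tok.startswith("<extra_id_"):
            out.extend(runs[tok])
        else:
            out.append(tok)
    return tuple(out)


# ---- sample_spans -----------------------------------------------------------

def test_boundary_single_token():
    spans = sample_spans(1, CorruptionConfig(), np.random.default_rng(0))
    assert spans in ([], [(0, 1)])
    assert sum(l for _, l in spans) <= 1


def test_determinism_same_seed():
    cfg = CorruptionConfig()
    a = sample_spans(200, cfg, np.random.default_rng(5))
    b = sample_spans(200, cfg, np.random.default_rng(5))
    assert a == b


def test_spans_disjoint_non_adjacent_within_bounds(rng):
    cfg = CorruptionConfig()
    for _ in range(200):
        n = int(rng.integers(1, 400))
        spans = sample_spans(n, cfg, rng)
        assert len(spans) <= 100
        prev_end = None
        for start, length in spans:
            assert length >= 1 and 0 <= start and start + length <= n
            if prev_end is not None:
                assert start > prev_end  # at least one unmasked token between
            prev_end = start + length


def test_mask_budget_tracks_rate(rng):
    cfg = CorruptionConfig()
    for n in (100, 257, 500):
        spans = sample_spans(n, cfg, rng)
        assert sum(l for _, l in spans) == round(cfg.mask_rate * n)


def test_config_validation():
    with pytest.raises(ValueError):
        CorruptionConfig(mask_rate=0.0)
    with pytest.raises(ValueError):
        CorruptionConfig(mean_span=0.5)
    with pytest.raises(ValueError):
        CorruptionConfig(fragment_mode="nope")


# ---- corrupt_smiles ---------------------------------------------------------

def test_span_mask_injected_spans_layout():
    smiles = "CCOC(=O)c1ccccc1NC(C)=O"[:20]  # 20 characters
    ex = corrupt_smiles(smiles, spans=[(3, 3), (12, 2)])
    src = list(tokenize(smiles, "smiles"))
    expected_input = (["Span-Mask:"] + src[:3] + ["<extra_id_99>"]
                      + src[6:12] + ["<extra_id_98>"] + src[14:])
    expected_target = (["<extra_id_99>"] + src[3:6]
                       + ["<extra_id_98>"] + src[12:14] + [EOS])
    assert list(ex.input_tokens) == expected_input
    assert list(ex.target_tokens) == expected_target


def test_span_mask_zero_spans():
    ex = corrupt_smiles("CCO", spans=[])
    assert list(ex.input_tokens) == ["Span-Mask:", "C", "C", "O"]
    assert list(ex.target_tokens) == [EOS]


def test_span_mask_rejects_unknown_characters():
    with pytest.raises(ValueError):
        corrupt_smiles("C|C")


def test_span_mask_splice_back_identity(rng):
    cfg = CorruptionConfig()
    gen = synthetic.GeneratorConfig(seed=21, n_items=200,
                                    smiles_fragment_count=(4, 12))
    for smi in synthetic.random_smiles(gen):
        ex = corrupt_smiles(smi, cfg, rng)
        assert splice(ex) == tuple(tokenize(smi, "smiles"))


def test_sentinel_pairing_and_descending_order(rng):
    cfg = CorruptionConfig()
    gen = synthetic.GeneratorConfig(seed=22, n_items=50)
    for smi in synthetic.random_smiles(gen):
        ex = corrupt_smiles(smi, cfg, rng)
        in_s = [t for t in ex.input_tokens if t.startswith("<extra_id_")]
        tgt_s = [t for t in ex.target_tokens if t.startswith("<extra_id_")]
        assert in_s == tgt_s
        ids = [int(t[10:-1]) for t in in_s]
        assert ids == list(range(99, 99 - len(ids), -1))


# ---- corrupt_protein --------------------------------------------------------

def test_chem_mask_forced_span_renders_fragment_smiles():
    ex = corrupt_protein("GAGG", CorruptionConfig(seed=0), spans=[(1, 2)])
    frag = chem.span_fragment_smiles("AG", "condensed")
    expected = ["<extra_id_99>"] + list(tokenize(frag, "smiles")) + [EOS]
    assert list(ex.target_tokens) == expected
    assert list(ex.input_tokens) == ["Chem-Mask:", "<P>G", "<extra_id_99>", "<P>G"]


def test_chem_mask_per_residue_mode():
    cfg = CorruptionConfig(fragment_mode="per_residue")
    ex = corrupt_protein("GGGG", cfg, spans=[(0, 2)])
    frag = chem.span_fragment_smiles("GG", "per_residue")
    assert list(ex.target_tokens) == \
        ["<extra_id_99>"] + list(tokenize(frag, "smiles")) + [EOS]


def test_chem_mask_window_bounded_by_max_segment(rng):
    seq = "".join(np.random.default_rng(3).choice(list(chem.CANONICAL_CODES), 300))
    ex = corrupt_protein(seq, CorruptionConfig(), rng)
    start, width = ex.window
    assert width <= 128
    assert 0 <= start <= len(seq) - width
    assert ex.n_source_tokens == width


def test_chem_mask_zero_spans_and_bad_residue():
    ex = corrupt_protein("GAG", CorruptionConfig(), spans=[])
    assert list(ex.target_tokens) == [EOS]
    with pytest.raises(ValueError):
        corrupt_protein("GAX", CorruptionConfig())


def test_chem_mask_targets_are_valid_formula_conserving_smiles(rng):
    """Every target span decodes to SMILES whose formula matches the
    condensation of the masked residues."""
    from tests_util_formulas import peptide_formula  # local helper below

    cfg = CorruptionConfig(seed=7)
    gen = synthetic.GeneratorConfig(seed=23, n_items=40,
                                    protein_length_range=(20, 80))
    for seq in synthetic.random_proteins(gen):
        ex = corrupt_protein(seq, cfg, rng)
        start, width = ex.window
        window = seq[start:start + width]
        # carve target into sentinel-delimited SMILES chunks
        chunks, current = [], None
        for tok in ex.target_tokens:
            if tok == EOS:
                break
            if tok.startswith("<extra_id_"):
                current = []
                chunks.append(current)
            else:
                current.append(tok)
        assert len(chunks) == len(ex.spans)
        for (s, l), chunk in zip(ex.spans, chunks):
            smi = "".join(chunk)
            assert chem.mol_formula(smi) == peptide_formula(window[s:s + l])


def test_corpus_mask_stats_arithmetic():
    ex1 = corrupt_smiles("CCOCCOCCON", spans=[(0, 2)])  # 10 tokens, span of 2
    stats = corpus_mask_stats([ex1])
    assert stats.masked_fraction == pytest.approx(0.2)
    assert stats.mean_span == pytest.approx(2.0)
    empty = corpus_mask_stats([corrupt_smiles("CCO", spans=[])])
    assert empty.masked_fraction == 0.0 and empty.mean_span == 0.0
    with pytest.raises(ValueError):
        corpus_mask_stats([])
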