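"""Parameter accounting, autodiff gradients, and training/decoding contracts."""

import numpy as np
import pytest

from atomspan import objectives as obj
from atomspan import synthetic as syn
from atomspan.harness import (
    ArchitectureConfig,
    count_parameters,
    forward_logits,
    greedy_decode,
    init_params,
    param_shapes,
    smoke_train,
)
from atomspan.harness.autodiff import cross_entropy

TINY = ArchitectureConfig(n_layers=1, n_heads=2, d_model=8, d_ff=16,
                          vocab_size=11, head_dim=4, rel_pos_buckets=8,
                          rel_pos_max_distance=8)


def instantiate_and_count(config):
    """Brute-force oracle: allocate every tensor and sum element counts."""
    return sum(p.data.size for p in init_params(config, zeros=True).values())


def random_small_config(rng):
    heads = int(rng.integers(1, 4))
    head_dim = int(rng.integers(1, 6))
    return ArchitectureConfig(
        n_layers=int(rng.integers(1, 4)),
        n_heads=heads,
        head_dim=head_dim,
        d_model=heads * head_dim,
        d_ff=int(rng.integers(2, 20)),
        vocab_size=int(rng.integers(4, 50)),
        ffn_gated=bool(rng.integers(0, 2)),
        tie_embedding=bool(rng.integers(0, 2)),
        rel_pos_buckets=int(rng.integers(2, 16)),
    )


def test_closed_form_matches_instantiation_on_random_configs(rng):
    for _ in range(8):
        config = random_small_config(rng)
        assert count_parameters(config) == instantiate_and_count(config)


def test_minimal_config_exhaustive_enumeration():
    cfg = ArchitectureConfig(n_layers=1, n_heads=1, d_model=2, d_ff=2,
                             vocab_size=4, head_dim=2, rel_pos_buckets=4)
    # enumerate tensor sizes by hand: embedding 4*2; per stack rel bias 4*1
    # and final norm 2; encoder layer: 4 attn mats (2*2) + 3 gated ffn mats
    # (2*2) + 2 norms (2); decoder layer: 8 attn + 3 ffn mats + 3 norms
    expected = (4 * 2) + 2 * (4 * 1 + 2) \
        + (4 * 4 + 3 * 4 + 2 * 2) \
        + (8 * 4 + 3 * 4 + 3 * 2)
    assert count_parameters(cfg) == expected == instantiate_and_count(cfg)


def test_vocab_linearity_with_tied_embedding():
    a = ArchitectureConfig()
    b = ArchitectureConfig(vocab_size=a.vocab_size * 2)
    assert count_parameters(b) - count_parameters(a) == a.d_model * a.vocab_size


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ArchitectureConfig(n_heads=3, head_dim=64, d_model=640)
    with pytest.raises(ValueError):
        ArchitectureConfig(n_layers=0)


def test_param_shapes_cover_count():
    cfg = TINY
    total = sum(int(np.prod(s)) for s in param_shapes(cfg).values())
    assert total == count_parameters(cfg)


def test_analytic_gradients_match_finite_differences(rng):
    params = init_params(TINY, seed=3)
    src = rng.integers(0, 11, size=(2, 5))
    tgt_in = rng.integers(0, 11, size=(2, 4))
    tgt_out = rng.integers(0, 11, size=(2, 4))
    smask = np.array([[1, 1, 1, 1, 0], [1, 1, 1, 0, 0]], dtype=bool)

    def loss_value():
        return float(cross_entropy(
            forward_logits(params, TINY, src, tgt_in, smask), tgt_out).data)

    loss = cross_entropy(forward_logits(params, TINY, src, tgt_in, smask), tgt_out)
    loss.backward()
    for name in ("embedding", "enc.0.attn.q", "dec.0.cross_attn.o",
                 "enc.rel_bias", "dec.0.norm1", "enc.0.ffn.wi0"):
        flat = params[name].data.ravel()
        for idx in rng.choice(flat.size, size=2, replace=False):
            eps, old = 1e-6, flat[idx]
            flat[idx] = old + eps
            up = loss_value()
            flat[idx] = old - eps
            down = loss_value()
            flat[idx] = old
            numeric = (up - down) / (2 * eps)
            analytic = params[name].grad.ravel()[idx]
            assert analytic == pytest.approx(numeric, abs=1e-6)


def _tiny_corpus(n=6, domain="protein", seed=1):
    rng = np.random.default_rng(seed)
    gcfg = syn.GeneratorConfig(seed=seed, n_items=n,
                               protein_length_range=(6, 10),
                               smiles_fragment_count=(2, 3))
    ccfg = obj.CorruptionConfig(seed=seed)
    if domain == "protein":
        return [obj.corrupt_protein(p, ccfg, rng)
                for p in syn.random_proteins(gcfg)]
    return [obj.corrupt_smiles(s, ccfg, rng) for s in syn.random_smiles(gcfg)]


def test_zero_steps_and_empty_corpus():
    assert smoke_train(_tiny_corpus(2), steps=0) == []
    with pytest.raises(ValueError):
        smoke_train([], steps=10)


def test_training_is_deterministic_under_seed():
    corpus = _tiny_corpus(3)
    a = smoke_train(corpus, steps=2, seed=5)
    b = smoke_train(corpus, steps=2, seed=5)
    assert a == b


@pytest.mark.parametrize("domain", ["protein", "smiles"])
def test_loss_decreases_on_both_objectives(domain):
    trace = smoke_train(_tiny_corpus(6, domain), steps=60, seed=0)
    q = len(trace) // 4
    assert np.mean(trace[-q:]) < np.mean(trace[:q])


def test_greedy_decode_contracts():
    corpus = _tiny_corpus(2)
    smoke_train(corpus, steps=1, seed=0)
    params, config = smoke_train.last_params, smoke_train.last_config
    out = greedy_decode(params, config, list(corpus[0].input_tokens), max_len=1)
    assert len(out) == 1
    again = greedy_decode(params, config, list(corpus[0].input_tokens), max_len=1)
    assert out == again
    with pytest.raises(ValueError):
        greedy_decode(params, config, ["not-a-token"], max_len=1)
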