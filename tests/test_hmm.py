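"""Forward algorithm, pruning, posteriors and full-reference Bayesian
classification, checked against dense and physical-state oracles."""

import numpy as np
import pytest

from oracles import PhysicalHMM

from fluoroseq.hmm import (
    PeptideHMM,
    build_models,
    classify_bayes,
    classify_bayes_batch,
    posterior_scores,
)
from fluoroseq.params import SequencingParams
from fluoroseq.proteome import DyeSeq
from fluoroseq.simulator import RawRead, emit_raw_reads, simulate_dye_tracks
from fluoroseq.states import (
    dense_transition_matrix,
    emission_weights,
    enumerate_states,
    initial_distribution,
)


def dense_forward(code, n_channels, params, read):
    """Full-matrix forward pass over the flat state space."""
    sp = enumerate_states(DyeSeq.from_code(code, n_channels), params.num_timesteps)
    M = dense_transition_matrix(sp, params)
    f = initial_distribution(sp, params) * emission_weights(sp, read[0], params)
    for t in range(1, params.num_timesteps):
        f = emission_weights(sp, read[t], params) * (M @ f)
    return float(f.sum())


def test_forward_single_timestep_closed_form():
    """T=1, one label: likelihood = (1-m) N(y; mu, sd1) + m N(y; 0, bg)."""
    params = SequencingParams.create(1, num_timesteps=1)
    hmm = PeptideHMM(DyeSeq.from_code("0", 1), params)
    lik = hmm.forward_likelihood(np.array([[1.0]]))
    sd1 = np.sqrt(0.00667**2 + 0.16**2)
    expected = 0.93 / (sd1 * np.sqrt(2 * np.pi)) + 0.07 * float(
        np.exp(-0.5 * (1.0 / 0.00667) ** 2) / (0.00667 * np.sqrt(2 * np.pi))
    )
    assert lik == pytest.approx(expected, rel=1e-12)
    assert lik == pytest.approx(2.317, abs=2e-3)


def test_forward_matches_dense_full_matrix():
    rng = np.random.default_rng(1)
    params = SequencingParams.create(2, num_timesteps=5)
    for code in ["0", ".0", "01", "0.10", "1..0.1"]:
        ds = DyeSeq.from_code(code, 2)
        hmm = PeptideHMM(ds, params)
        counts = simulate_dye_tracks(ds, 8, params, rng)
        reads = emit_raw_reads(counts, params, rng)
        ll = hmm.log_forward(reads)
        for i in range(8):
            ref = dense_forward(code, 2, params, reads[i])
            assert np.exp(ll[i]) == pytest.approx(ref, rel=1e-12)


def test_forward_matches_physical_state_oracle():
    """Reduced counts-only states reproduce the explicit per-position
    fluorophore model exactly (exchangeability of duds and bleaching)."""
    rng = np.random.default_rng(2)
    params = SequencingParams.create(2, num_timesteps=5)
    for code in ["0", "00", "0.1", "01.0", ".0.1."]:
        ds = DyeSeq.from_code(code, 2)
        hmm = PeptideHMM(ds, params)
        phys = PhysicalHMM(code, 2, params)
        counts = simulate_dye_tracks(ds, 10, params, rng)
        reads = emit_raw_reads(counts, params, rng)
        ll = hmm.log_forward(reads)
        for i in range(10):
            ref = phys.likelihood(reads[i])
            assert abs(np.exp(ll[i]) - ref) / ref < 1e-9


def test_likelihood_invariant_to_trailing_unlabeled():
    rng = np.random.default_rng(3)
    params = SequencingParams.create(1, num_timesteps=4)
    a = PeptideHMM(DyeSeq.from_code("0.0", 1), params)
    # same labels, extra dark C-terminal residues trimmed at construction
    b = PeptideHMM(DyeSeq.from_code("0.0...", 1), params)
    reads = rng.normal(1.0, 0.3, size=(5, 4, 1))
    np.testing.assert_allclose(a.log_forward(reads), b.log_forward(reads), rtol=1e-12)


def test_pruning_fidelity_and_soundness():
    rng = np.random.default_rng(4)
    params = SequencingParams.create(2, num_timesteps=6)
    ds = DyeSeq.from_code("01.0", 2)
    hmm = PeptideHMM(ds, params)
    counts = simulate_dye_tracks(ds, 200, params, rng)
    reads = emit_raw_reads(counts, params, rng)
    full = hmm.log_forward(reads)
    pruned = hmm.log_forward(reads, cutoff=5.0)
    assert np.all(np.isfinite(pruned))
    # pruning only removes probability mass
    assert np.all(pruned <= full + 1e-9)
    assert np.mean(np.abs(pruned - full) <= 0.01) >= 0.99
    # infinite cutoff is exactly the unpruned path
    np.testing.assert_array_equal(hmm.log_forward(reads, cutoff=np.inf), full)


def test_forward_shape_validation():
    params = SequencingParams.create(1, num_timesteps=3)
    hmm = PeptideHMM(DyeSeq.from_code("0", 1), params)
    with pytest.raises(ValueError):
        hmm.log_forward(np.zeros((2, 4, 1)))
    with pytest.raises(ValueError):
        hmm.log_forward(np.full((2, 3, 1), np.nan))


@pytest.mark.parametrize(
    "lik,pri,expected",
    [
        ({0: 2.0, 1: 1.0, 2: 1.0}, None, [0.5, 0.25, 0.25]),
        ({0: 7.5}, None, [1.0]),
        ({0: 1.0, 1: 9.0}, {0: 0.9, 1: 0.1}, [0.5, 0.5]),
    ],
)
def test_posterior_scores(lik, pri, expected):
    post = posterior_scores(lik, pri)
    np.testing.assert_allclose([post[k] for k in sorted(post)], expected, atol=1e-12)
    assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)


def test_posterior_all_zero_uniform_with_warning():
    with pytest.warns(UserWarning):
        post = posterior_scores({0: 0.0, 1: 0.0})
    assert post == {0: 0.5, 1: 0.5}


def test_classify_bayes_dominant_candidate():
    """A noiseless read from '0' against {'0', '00'} picks '0' with score
    approaching 1 (the two-dye model cannot explain a one-dye trace)."""
    params = SequencingParams.create(
        1, p=0.0, m=0.0, e=0.0, d=0.0, num_timesteps=3
    )
    a = DyeSeq.from_code("0", 1)
    a.dye_seq_id = 0
    b = DyeSeq.from_code("00", 1)
    b.dye_seq_id = 1
    models = build_models([a, b], params)
    counts = simulate_dye_tracks(a, 1, params, np.random.default_rng(5))
    read = RawRead(emit_raw_reads(counts, params, np.random.default_rng(6))[0])
    prm = classify_bayes(read, models)
    assert prm.dye_seq_id == 0
    assert prm.score > 0.999


def test_classify_single_reference_scores_one():
    params = SequencingParams.create(1, num_timesteps=2)
    a = DyeSeq.from_code("0", 1)
    a.dye_seq_id = 7
    models = build_models([a], params)
    prm = classify_bayes(RawRead(np.ones((2, 1))), models)
    assert prm.dye_seq_id == 7
    assert prm.score == 1.0


def test_classify_batch_matches_single(ref20, models20, default_params, test20_10k):
    prms_batch = classify_bayes_batch(
        test20_10k.intensities[:5], models20, cutoff=5.0, truth=test20_10k.truth[:5]
    )
    for i in range(5):
        single = classify_bayes(
            RawRead(test20_10k.intensities[i]), models20, cutoff=5.0
        )
        assert single.dye_seq_id == prms_batch[i].dye_seq_id
        assert single.score == pytest.approx(prms_batch[i].score, rel=1e-12)
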