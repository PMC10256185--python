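"""Monte Carlo simulator: deterministic limits, marginal rates, and
dataset bookkeeping."""

import numpy as np
import pytest
from scipy.stats import binom

from fluoroseq.params import SequencingParams
from fluoroseq.proteome import DyeSeq
from fluoroseq.simulator import (
    emit_raw_reads,
    generate_test_set,
    generate_training_set,
    simulate_dye_track,
    simulate_dye_tracks,
)

ONE = DyeSeq.from_code("0", 1)


def perfect(n_channels=1, **kw):
    kw.setdefault("p", 0.0)
    kw.setdefault("m", 0.0)
    kw.setdefault("e", 0.0)
    kw.setdefault("d", 0.0)
    return SequencingParams.create(n_channels, **kw)


def test_error_free_track_is_deterministic():
    params = perfect(num_timesteps=3)
    counts = simulate_dye_tracks(ONE, 10, params, np.random.default_rng(0))
    # the single labeled residue is removed after the first cycle
    assert np.all(counts[:, 0, 0] == 1)
    assert np.all(counts[:, 1:, :] == 0)


def test_certain_detachment_zeroes_everything_after_t0():
    params = perfect(d=1.0, m=0.3, num_timesteps=3)
    ds = DyeSeq.from_code("000", 1)
    counts = simulate_dye_tracks(ds, 200, params, np.random.default_rng(1))
    assert np.all(counts[:, 1:, :] == 0)
    assert np.all(counts[:, 0, 0] <= 3)


def test_dud_rate_fraction_dark():
    params = perfect(m=0.07, num_timesteps=1)
    n = 50_000
    counts = simulate_dye_tracks(ONE, n, params, np.random.default_rng(2))
    frac_dark = np.mean(counts[:, 0, 0] == 0)
    se = np.sqrt(0.07 * 0.93 / n)
    assert abs(frac_dark - 0.07) < 3 * se


def test_counts_non_increasing_and_bounded():
    params = SequencingParams.create(2, num_timesteps=6)
    ds = DyeSeq.from_code("0101.0", 2)
    counts = simulate_dye_tracks(ds, 500, params, np.random.default_rng(3))
    assert np.all(np.diff(counts, axis=1) <= 0)
    assert np.all(counts[:, :, 0] <= 3)
    assert np.all(counts[:, :, 1] <= 2)


def test_single_dye_survival_curve():
    """With Edman always failing and no detachment, a single dye survives
    to timestep t with probability (1-m)(1-p)^t."""
    m, p = 0.07, 0.05
    params = SequencingParams.create(1, m=m, p=p, e=1.0, d=0.0, num_timesteps=5)
    n = 100_000
    counts = simulate_dye_tracks(ONE, n, params, np.random.default_rng(4))
    for t in range(5):
        expected = (1 - m) * (1 - p) ** t
        frac = np.mean(counts[:, t, 0] == 1)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se, f"t={t}"


def test_raw_read_moments_match_closed_form():
    params = SequencingParams.create(1, m=0.0, num_timesteps=1)
    rng = np.random.default_rng(5)
    n = 100_000
    # lam = 0 cell
    y0 = emit_raw_reads(np.zeros((n, 1, 1)), params, rng)[:, 0, 0]
    assert abs(y0.mean()) < 3 * 0.00667 / np.sqrt(n)
    assert abs(y0.std(ddof=1) - 0.00667) < 0.0002
    # lam = 1 cell
    y1 = emit_raw_reads(np.ones((n, 1, 1)), params, rng)[:, 0, 0]
    sd = np.sqrt(0.00667**2 + 0.16**2)
    assert abs(y1.mean() - 1.0) < 3 * sd / np.sqrt(n)
    assert abs(y1.std(ddof=1) - sd) < 0.002


def test_noiseless_intensity_limit():
    params = SequencingParams.create(1, sigma=1e-12, sigma_bg=1e-12, num_timesteps=1)
    y = emit_raw_reads(np.array([[[2.0]]]), params, np.random.default_rng(0))
    assert y[0, 0, 0] == pytest.approx(2.0, abs=1e-9)


def test_training_set_deterministic_track_merges():
    params = perfect(num_timesteps=3)
    ds = DyeSeq.from_code("0", 1)
    ds.dye_seq_id = 0
    train = generate_training_set([ds], 5, params, np.random.default_rng(6))
    assert len(train) == 1
    assert train.entries[0].multiplicity == 5
    assert train.entries[0].peptide_counts == {0: 5}


def test_training_set_conservation():
    rng = np.random.default_rng(7)
    params = SequencingParams.create(1, num_timesteps=4)
    seqs = []
    for i, code in enumerate(["0", "00", "0.0", ".0", "000", "0..0", "0.00", "00.0", ".00", "0000"]):
        ds = DyeSeq.from_code(code, 1)
        ds.dye_seq_id = i
        seqs.append(ds)
    train = generate_training_set(seqs, 1000, params, rng)
    total = sum(sum(e.peptide_counts.values()) for e in train.entries)
    assert total + train.n_discarded == 10_000
    assert all(sum(e.peptide_counts.values()) == e.multiplicity for e in train.entries)
    # dedup key is the full tensor: all entries distinct
    keys = {e.counts.tobytes() for e in train.entries}
    assert len(keys) == len(train)


def test_shared_track_votes_for_both_dye_seqs():
    """Two dye seqs that can emit the same track both appear in that
    track's production counts."""
    params = SequencingParams.create(1, m=0.5, p=0.0, e=0.0, d=0.0, num_timesteps=2)
    a = DyeSeq.from_code("0", 1)
    a.dye_seq_id = 0
    b = DyeSeq.from_code("00", 1)
    b.dye_seq_id = 1
    train = generate_training_set([a, b], 2000, params, np.random.default_rng(8))
    # the track [1, 0] arises from "0" intact and from "00" with one dud
    target = None
    for e in train.entries:
        if e.counts[0, 0] == 1 and e.counts[1, 0] == 0:
            target = e
    assert target is not None
    assert set(target.peptide_counts) == {0, 1}
    assert sum(target.peptide_counts.values()) == target.multiplicity


def test_test_set_error_free_counts():
    params = perfect(2, sigma=1e-9, sigma_bg=1e-9, num_timesteps=2)
    seqs = []
    for i, code in enumerate(["01", "0", "11"]):
        ds = DyeSeq.from_code(code, 2)
        ds.dye_seq_id = i
        seqs.append(ds)
    test = generate_test_set(seqs, 50, params, np.random.default_rng(9))
    assert len(test) == 50
    for read in test:
        ds = seqs[read.true_dye_seq_id]
        np.testing.assert_allclose(
            read.intensities[0], ds.initial_counts.astype(float), atol=0.1
        )


def test_test_set_all_dark_rejected():
    params = SequencingParams.create(1, m=1.0, num_timesteps=2)
    ds = DyeSeq.from_code("0", 1)
    ds.dye_seq_id = 0
    with pytest.raises(RuntimeError):
        generate_test_set([ds], 10, params, np.random.default_rng(10), max_rounds=5)


def test_test_set_conditional_dark_fraction():
    """P(dark at t=0 | retained) for a two-label dye seq matches the exact
    conditional binomial: dark-at-0 reads survive only if a dye appears
    later, which cannot happen — so retained reads are never dark at 0
    unless both dyes are duds... i.e. P(dark at 0 | retained) = 0; the
    nontrivial check is P(exactly one dud | retained)."""
    m = 0.07
    params = SequencingParams.create(
        1, m=m, p=0.0, e=1.0, d=0.0, sigma=1e-9, sigma_bg=1e-9, num_timesteps=2
    )
    ds = DyeSeq.from_code("00", 1)
    ds.dye_seq_id = 0
    n = 100_000
    test = generate_test_set([ds], n, params, np.random.default_rng(11))
    counts_t0 = np.round(test.intensities[:, 0, 0]).astype(int)
    # retention excludes the both-duds outcome (probability m^2)
    p_one = 2 * m * (1 - m) / (1 - m**2)
    frac_one = np.mean(counts_t0 == 1)
    se = np.sqrt(p_one * (1 - p_one) / n)
    assert np.all(counts_t0 >= 1)
    assert abs(frac_one - p_one) < 3 * se


def test_single_track_wrapper():
    params = SequencingParams.create(1, num_timesteps=3)
    track = simulate_dye_track(ONE, params, np.random.default_rng(12))
    assert track.counts.shape == (3, 1)
    assert track.multiplicity == 1
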