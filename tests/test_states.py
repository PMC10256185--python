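"""State-space enumeration, transition factors, emissions and pruning."""

import numpy as np
import pytest

from fluoroseq.params import SequencingParams
from fluoroseq.proteome import DyeSeq
from fluoroseq.states import (
    composed_transition_matrix,
    dense_transition_matrix,
    detach_factor,
    dye_loss_factor,
    edman_factor,
    emission_weights,
    enumerate_states,
    initial_distribution,
    prune_ranges,
    transition_factors,
)


def params1(**kw):
    kw.setdefault("num_timesteps", 5)
    return SequencingParams.create(1, **kw)


@pytest.mark.parametrize(
    "code,C,T,expected",
    [
        (".00.1", 2, 6, 22),  # 6+6+4+2+2+1 attached + DETACHED
        ("0", 1, 2, 4),  # (0,1),(0,0),(1,0),DETACHED
        ("0", 1, 1, 3),  # no Edman possible: 2 level-0 states + DETACHED
        ("012", 3, 1, 9),  # prod(n_c+1) + 1 = 2*2*2 + 1
    ],
)
def test_state_counts(code, C, T, expected):
    sp = enumerate_states(DyeSeq.from_code(code, C), T)
    assert sp.n_states == expected


def test_state_count_closed_form():
    sp = enumerate_states(DyeSeq.from_code(".00.1", 2), 6)
    total = sum(np.prod([n + 1 for n in sp.n_table[e]]) for e in range(sp.e_max + 1))
    assert sp.n_states == total + 1


def test_index_unindex_bijective():
    sp = enumerate_states(DyeSeq.from_code("0.1.0", 2), 6)
    seen = set()
    for idx, e, counts in sp.states():
        assert sp.index(e, counts) == idx
        assert sp.unindex(idx) == (e, counts)
        seen.add(idx)
    assert len(seen) == sp.n_states - 1
    assert sp.unindex(sp.detached_index) == "DETACHED"


@pytest.mark.parametrize(
    "n,m,expected",
    [
        (1, 0.07, [0.07, 0.93]),
        (1, 0.0, [0.0, 1.0]),
        (2, 0.5, [0.25, 0.5, 0.25]),
    ],
)
def test_initial_distribution(n, m, expected):
    sp = enumerate_states(DyeSeq.from_code("0" * n, 1), 3)
    pi = initial_distribution(sp, params1(m=m, num_timesteps=3))
    np.testing.assert_allclose(pi[: n + 1], expected, atol=1e-12)
    assert pi.sum() == pytest.approx(1.0)
    assert np.all(pi[n + 1 :] == 0)  # mass only on the e=0 level


def test_dye_loss_factor_binomial():
    sp = enumerate_states(DyeSeq.from_code("00", 1), 1)
    F = dye_loss_factor(sp, 0, 0.05).toarray()
    col = F[:, sp.index(0, (2,))]
    assert col[sp.index(0, (0,))] == pytest.approx(0.0025)
    assert col[sp.index(0, (1,))] == pytest.approx(0.095)
    assert col[sp.index(0, (2,))] == pytest.approx(0.9025)


@pytest.mark.parametrize("p,check", [(0.0, "identity"), (1.0, "all_to_zero")])
def test_dye_loss_factor_limits(p, check):
    sp = enumerate_states(DyeSeq.from_code("00", 1), 2)
    F = dye_loss_factor(sp, 0, p).toarray()
    if check == "identity":
        np.testing.assert_allclose(F, np.eye(sp.n_states))
    else:
        col = F[:, sp.index(0, (2,))]
        assert col[sp.index(0, (0,))] == 1.0


def test_edman_factor_hypergeometric_split():
    sp = enumerate_states(DyeSeq.from_code("00", 1), 3)
    F = edman_factor(sp, 0.06).toarray()
    # full counts: removal of a labeled residue must remove a dye
    col = F[:, sp.index(0, (2,))]
    assert col[sp.index(0, (2,))] == pytest.approx(0.06)
    assert col[sp.index(1, (1,))] == pytest.approx(0.94)
    # one dye on two labeled positions: removed residue carries it w.p. 1/2
    col = F[:, sp.index(0, (1,))]
    assert col[sp.index(0, (1,))] == pytest.approx(0.06)
    assert col[sp.index(1, (0,))] == pytest.approx(0.47)
    assert col[sp.index(1, (1,))] == pytest.approx(0.47)


def test_edman_factor_unlabeled_removal():
    sp = enumerate_states(DyeSeq.from_code(".0", 1), 3)
    F = edman_factor(sp, 0.06).toarray()
    col = F[:, sp.index(0, (1,))]
    assert col[sp.index(0, (1,))] == pytest.approx(0.06)
    assert col[sp.index(1, (1,))] == pytest.approx(0.94)


@pytest.mark.parametrize("d", [0.0, 0.05, 1.0])
def test_detach_factor(d):
    sp = enumerate_states(DyeSeq.from_code("0", 1), 2)
    F = detach_factor(sp, d).toarray()
    for idx, _, _ in sp.states():
        assert F[idx, idx] == pytest.approx(1.0 - d)
        assert F[sp.detached_index, idx] == pytest.approx(d)
    assert F[sp.detached_index, sp.detached_index] == 1.0


def test_factors_are_column_stochastic():
    params = SequencingParams.create(2, num_timesteps=6)
    sp = enumerate_states(DyeSeq.from_code(".00.1", 2), 6)
    for F in transition_factors(sp, params):
        np.testing.assert_allclose(
            np.asarray(F.sum(axis=0)).ravel(), 1.0, atol=1e-12
        )


def random_dye_seq(rng, max_len=8, n_channels=2):
    while True:
        chars = rng.choice(
            ["."] + [str(c) for c in range(n_channels)], size=rng.integers(1, max_len + 1)
        )
        code = "".join(chars).rstrip(".")
        if code:
            return DyeSeq.from_code(code, n_channels)


def test_factored_product_equals_dense_enumeration():
    """Composed sparse factors reproduce the directly-enumerated one-step
    matrix elementwise, for 50 random dye seqs."""
    rng = np.random.default_rng(42)
    params = SequencingParams.create(2, num_timesteps=6)
    for _ in range(50):
        ds = random_dye_seq(rng)
        sp = enumerate_states(ds, 6)
        M_fact = composed_transition_matrix(sp, params)
        M_dense = dense_transition_matrix(sp, params)
        assert np.abs(M_fact - M_dense).max() <= 1e-12
        np.testing.assert_allclose(M_fact.sum(axis=0), 1.0, atol=1e-12)


@pytest.mark.parametrize(
    "y,lam,expected",
    [
        (1.0, 1, 2.4912),  # at the mean, sd = sqrt(0.00667^2 + 0.16^2)
        (0.0, 0, 59.8175),  # background-only density
    ],
)
def test_emission_weights_closed_form(y, lam, expected):
    sp = enumerate_states(DyeSeq.from_code("0", 1), 1)
    w = emission_weights(sp, np.array([y]), params1(num_timesteps=1))
    assert w[sp.index(0, (lam,))] == pytest.approx(expected, rel=1e-3)


def test_emission_weights_product_over_channels():
    params = SequencingParams.create(2, num_timesteps=1)
    sp = enumerate_states(DyeSeq.from_code("01", 2), 1)
    y = np.array([0.8, 1.3])
    w = emission_weights(sp, y, params)
    sp1 = enumerate_states(DyeSeq.from_code("0", 1), 1)
    p1 = SequencingParams.create(1, num_timesteps=1)
    w0 = emission_weights(sp1, y[:1], p1)
    w1 = emission_weights(sp1, y[1:], p1)
    assert w[sp.index(0, (1, 1))] == pytest.approx(
        w0[sp1.index(0, (1,))] * w1[sp1.index(0, (1,))]
    )


def test_emission_rejects_non_finite():
    sp = enumerate_states(DyeSeq.from_code("0", 1), 1)
    with pytest.raises(ValueError):
        emission_weights(sp, np.array([np.nan]), params1())


def test_prune_ranges_z_test():
    params = SequencingParams.create(1, num_timesteps=1)
    lo, hi = prune_ranges(np.array([2.0]), params, 5.0, [6])[0]
    assert (lo, hi) == (2, 3)  # counts 2 and 3 are within 5 emission sds


def test_prune_ranges_infinite_cutoff_and_exact_hit():
    params = SequencingParams.create(1, num_timesteps=1)
    assert prune_ranges(np.array([1.5]), params, np.inf, [4])[0] == (0, 4)
    for lam in range(5):
        lo, hi = prune_ranges(np.array([float(lam)]), params, 5.0, [4])[0]
        assert lo <= lam <= hi


def test_prune_ranges_never_empty():
    params = SequencingParams.create(1, num_timesteps=1)
    # observation far above any reachable count: nearest count kept
    assert prune_ranges(np.array([50.0]), params, 1.0, [3])[0] == (3, 3)
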