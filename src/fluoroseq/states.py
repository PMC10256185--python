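"""Reduced HMM state space and factored transition operators.

Instead of tracking which specific residues still carry a dye (a space
exponential in the label count), a state records only the number of
successful Edman removals ``e`` and the surviving fluorophore count per
channel ``l_c``, plus one absorbing DETACHED state. Exchangeability of
i.i.d. dud and bleaching events over the remaining labeled positions makes
this reduction exact; the physical-state equivalence is enforced by tests
against a brute-force per-position model.

The one-cycle transition matrix factors into one sparse operator per
independent effect — peptide detachment, Edman degradation, and per-channel
dye loss — applied in the same order the simulator draws its events.
All matrices here are column-stochastic: entry ``[i, j]`` is
``P(next = i | current = j)`` and a forward step is ``f' = M @ f``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.special import comb
from scipy.stats import binom, norm

from fluoroseq.params import SequencingParams
from fluoroseq.proteome import DyeSeq


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of reduced states for one dye seq and T timesteps.

    Flat indexing: levels ``e = 0..E_max`` in order, each level a
    row-major block over per-channel counts ``(l_1, ..., l_C)`` with
    ``l_c`` in ``0..n_c(e)``; the DETACHED state is the last index.
    """

    code: str
    n_channels: int
    num_timesteps: int
    e_max: int
    n_table: np.ndarray  # (e_max + 1, C): labels of channel c after e removals
    level_shapes: tuple
    level_offsets: tuple
    n_states: int

    @property
    def detached_index(self) -> int:
        return self.n_states - 1

    def index(self, e: int, counts: Sequence[int]) -> int:
        shape = self.level_shapes[e]
        return self.level_offsets[e] + int(
            np.ravel_multi_index(tuple(int(c) for c in counts), shape)
        )

    def unindex(self, i: int):
        """Flat index -> (e, counts) or the string 'DETACHED'."""
        if i == self.detached_index:
            return "DETACHED"
        for e in range(self.e_max, -1, -1):
            if i >= self.level_offsets[e]:
                counts = np.unravel_index(i - self.level_offsets[e], self.level_shapes[e])
                return e, tuple(int(c) for c in counts)
        raise IndexError(i)

    def states(self):
        """Iterate (flat index, e, counts) over attached states."""
        for e in range(self.e_max + 1):
            off = self.level_offsets[e]
            for k, counts in enumerate(np.ndindex(self.level_shapes[e])):
                yield off + k, e, counts

    def labeled_channel(self, e: int) -> Optional[int]:
        """Channel of the residue removed by the Edman step out of level e."""
        ch = self.code[e]
        return None if ch == "." else int(ch, 36)


def enumerate_states(dye_seq: DyeSeq, num_timesteps: int) -> StateSpace:
    """Build the reduced state space.

    ``e`` never exceeds ``min(len(code), T - 1)``: there are only T - 1
    Edman cycles between the T observations, and once every residue of the
    (trailing-trimmed) code is gone no observable change remains.
    """
    if num_timesteps < 1:
        raise ValueError("need at least one timestep")
    code = dye_seq.code
    C = dye_seq.n_channels
    e_max = min(len(code), num_timesteps - 1)
    full_table = dye_seq.n_table()  # (len+1, C)
    n_table = full_table[: e_max + 1]
    shapes = tuple(tuple(int(n) + 1 for n in n_table[e]) for e in range(e_max + 1))
    offsets = []
    total = 0
    for s in shapes:
        offsets.append(total)
        total += int(np.prod(s))
    return StateSpace(
        code=code,
        n_channels=C,
        num_timesteps=num_timesteps,
        e_max=e_max,
        n_table=n_table,
        level_shapes=shapes,
        level_offsets=tuple(offsets),
        n_states=total + 1,
    )


def initial_distribution(space: StateSpace, params: SequencingParams) -> np.ndarray:
    """Start-of-run distribution: no removals, per-channel surviving counts
    Binomial(n_c(0), 1 - m_c), channels independent, DETACHED empty."""
    pi = np.zeros(space.n_states)
    shape0 = space.level_shapes[0]
    block = np.ones(shape0)
    for c, size in enumerate(shape0):
        n = size - 1
        pmf = binom.pmf(np.arange(size), n, 1.0 - params.m[c])
        block = block * pmf.reshape((1,) * c + (size,) + (1,) * (len(shape0) - c - 1))
    pi[: block.size] = block.ravel()
    return pi


def _binomial_survival_matrix(n: int, p_loss: float) -> np.ndarray:
    """(n+1, n+1) matrix B with B[j, l] = P(j of l dyes survive), each dye
    surviving independently with probability 1 - p_loss."""
    B = np.zeros((n + 1, n + 1))
    for l in range(n + 1):
        j = np.arange(l + 1)
        B[: l + 1, l] = comb(l, j) * (1.0 - p_loss) ** j * p_loss ** (l - j)
    return B


def dye_loss_factor(space: StateSpace, channel: int, p_loss: float) -> sparse.csr_matrix:
    """Sparse operator for photobleaching on one channel: within a level,
    ``l_c -> j`` with Binomial(l_c, 1 - p) survivors; identity elsewhere."""
    rows, cols, vals = [], [], []
    for idx, e, counts in space.states():
        l = counts[channel]
        if l == 0:
            rows.append(idx)
            cols.append(idx)
            vals.append(1.0)
            continue
        for j in range(l + 1):
            pr = comb(l, j) * (1.0 - p_loss) ** j * p_loss ** (l - j)
            if pr == 0.0:
                continue
            tgt = list(counts)
            tgt[channel] = j
            rows.append(space.index(e, tgt))
            cols.append(idx)
            vals.append(pr)
    det = space.detached_index
    rows.append(det)
    cols.append(det)
    vals.append(1.0)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(space.n_states, space.n_states)
    )


def edman_factor(space: StateSpace, e_rate: float) -> sparse.csr_matrix:
    """Sparse operator for one Edman cycle.

    With probability ``e_rate`` the cycle fails (state unchanged). With
    probability ``1 - e_rate`` the removal count advances; if the removed
    residue is labeled with channel ``c``, one of the ``n_c(e)`` remaining
    channel-``c`` labeled positions is the one removed, and by
    exchangeability it still carries a surviving dye with probability
    ``l_c / n_c(e)``. Levels at ``e_max`` are absorbing for this factor.
    """
    rows, cols, vals = [], [], []

    def add(i, j, v):
        if v > 0.0:
            rows.append(i)
            cols.append(j)
            vals.append(v)

    for idx, e, counts in space.states():
        if e == space.e_max:
            add(idx, idx, 1.0)
            continue
        add(idx, idx, e_rate)
        c = space.labeled_channel(e)
        if c is None:
            add(space.index(e + 1, counts), idx, 1.0 - e_rate)
        else:
            n = int(space.n_table[e, c])
            l = counts[c]
            if l > 0:
                tgt = list(counts)
                tgt[c] = l - 1
                add(space.index(e + 1, tgt), idx, (1.0 - e_rate) * l / n)
            if l < n:
                add(space.index(e + 1, counts), idx, (1.0 - e_rate) * (1.0 - l / n))
    det = space.detached_index
    add(det, det, 1.0)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(space.n_states, space.n_states)
    )


def detach_factor(space: StateSpace, d: float) -> sparse.csr_matrix:
    """Every attached state moves to DETACHED with probability ``d``."""
    det = space.detached_index
    rows, cols, vals = [], [], []
    for idx, _, _ in space.states():
        if d < 1.0:
            rows.append(idx)
            cols.append(idx)
            vals.append(1.0 - d)
        if d > 0.0:
            rows.append(det)
            cols.append(idx)
            vals.append(d)
    rows.append(det)
    cols.append(det)
    vals.append(1.0)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(space.n_states, space.n_states)
    )


def transition_factors(space: StateSpace, params: SequencingParams) -> list:
    """Ordered sparse factors for one cycle: detachment, then Edman, then
    per-channel dye loss — the simulator's event order. The one-step
    transition is their product applied right-to-left."""
    factors = [detach_factor(space, params.d), edman_factor(space, params.e)]
    for c in range(space.n_channels):
        factors.append(dye_loss_factor(space, c, float(params.p[c])))
    return factors


def composed_transition_matrix(space: StateSpace, params: SequencingParams) -> np.ndarray:
    """Dense product of the sparse factors (dye loss @ ... @ edman @ detach)."""
    factors = transition_factors(space, params)
    M = factors[0]
    for f in factors[1:]:
        M = f @ M
    return np.asarray(M.todense())


def dense_transition_matrix(space: StateSpace, params: SequencingParams) -> np.ndarray:
    """One-step transition matrix built by direct enumeration of all
    per-cycle outcomes (detach / Edman / bleach jointly), without any
    matrix factoring — the independent check for the factored product."""
    n_states = space.n_states
    det = space.detached_index
    M = np.zeros((n_states, n_states))
    M[det, det] = 1.0
    d, e_rate = params.d, params.e
    for idx, e, counts in space.states():
        if d > 0.0:
            M[det, idx] += d
        stay = 1.0 - d
        if stay == 0.0:
            continue
        # outcomes after detach + Edman, before bleaching
        pre: list = []
        if e == space.e_max:
            pre.append((e, counts, stay))
        else:
            pre.append((e, counts, stay * e_rate))
            c = space.labeled_channel(e)
            if c is None:
                pre.append((e + 1, counts, stay * (1.0 - e_rate)))
            else:
                n = int(space.n_table[e, c])
                l = counts[c]
                if l > 0:
                    tgt = list(counts)
                    tgt[c] = l - 1
                    pre.append((e + 1, tuple(tgt), stay * (1.0 - e_rate) * l / n))
                if l < n:
                    pre.append((e + 1, counts, stay * (1.0 - e_rate) * (1.0 - l / n)))
        for e2, counts2, pr in pre:
            if pr == 0.0:
                continue
            # joint bleaching across channels
            dist = {tuple(counts2): pr}
            for c in range(space.n_channels):
                p_loss = float(params.p[c])
                new: dict = {}
                for cts, q in dist.items():
                    l = cts[c]
                    for j in range(l + 1):
                        b = comb(l, j) * (1.0 - p_loss) ** j * p_loss ** (l - j)
                        if b == 0.0:
                            continue
                        t2 = list(cts)
                        t2[c] = j
                        t2 = tuple(t2)
                        new[t2] = new.get(t2, 0.0) + q * b
                dist = new
            for cts, q in dist.items():
                M[space.index(e2, cts), idx] += q
    return M


def emission_weights(
    space: StateSpace, observation: np.ndarray, params: SequencingParams
) -> np.ndarray:
    """Diagonal emission weights: for each state the product over channels
    of Normal(y_c; l_c mu_c, sigma_bg_c^2 + l_c sigma_c^2) densities.
    DETACHED emits background (all counts zero)."""
    y = np.asarray(observation, dtype=float)
    if y.shape != (space.n_channels,):
        raise ValueError("observation must have one value per channel")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite observation")
    out = np.empty(space.n_states)
    n_max = space.n_table[0]
    # per-channel density table over all possible counts
    pdf = [
        norm.pdf(
            y[c],
            np.arange(n_max[c] + 1) * params.mu[c],
            np.sqrt(params.sigma_bg[c] ** 2 + np.arange(n_max[c] + 1) * params.sigma[c] ** 2),
        )
        for c in range(space.n_channels)
    ]
    for idx, _, counts in space.states():
        w = 1.0
        for c, l in enumerate(counts):
            w *= pdf[c][l]
        out[idx] = w
    out[space.detached_index] = np.prod([pdf[c][0] for c in range(space.n_channels)])
    return out


def prune_ranges(
    observation: np.ndarray,
    params: SequencingParams,
    cutoff: float,
    n_max: Sequence[int],
) -> list:
    """Per-channel contiguous count range kept by emission pruning.

    Channel ``c`` keeps counts ``l`` with
    ``|y_c - l mu_c| <= cutoff * sqrt(sigma_bg_c^2 + l sigma_c^2)`` —
    a z-score test against each state's own emission sd. The kept set is
    closed to a contiguous ``[lo, hi]`` and is never empty: if no count
    passes, the count nearest the observation is kept.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    y = np.asarray(observation, dtype=float)
    ranges = []
    for c in range(len(n_max)):
        ell = np.arange(n_max[c] + 1)
        sd = np.sqrt(params.sigma_bg[c] ** 2 + ell * params.sigma[c] ** 2)
        keep = np.abs(y[c] - ell * params.mu[c]) <= cutoff * sd
        if keep.any():
            kept = np.flatnonzero(keep)
            ranges.append((int(kept[0]), int(kept[-1])))
        else:
            nearest = int(np.clip(np.round(y[c] / params.mu[c]), 0, n_max[c]))
            ranges.append((nearest, nearest))
    return ranges
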