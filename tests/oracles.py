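"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's reduced state space, factored
transition operators and KD-tree: the physical-state HMM enumerates every
per-position fluorophore configuration explicitly, kNN is a linear scan,
and the PR sweep enumerates thresholds directly.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


# --------------------------------------------------------------------- #
# physical-state HMM: states are (removed_count, frozenset of labeled
# positions that still carry a surviving dye), plus DETACHED.


def _normal_pdf(x, mean, sd):
    return math.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * math.sqrt(2.0 * math.pi))


class PhysicalHMM:
    """Explicit per-position fluorophore model for one dye seq code."""

    def __init__(self, code: str, n_channels: int, params):
        self.code = code.rstrip(".")
        self.C = n_channels
        self.params = params
        self.T = params.num_timesteps
        self.labels = [(i, int(ch, 36)) for i, ch in enumerate(self.code) if ch != "."]
        self.L = len(self.code)
        self.r_max = min(self.L, self.T - 1)
        self.states = []  # (r, frozenset of surviving labeled positions)
        for r in range(self.r_max + 1):
            positions = [i for i, _ in self.labels if i >= r]
            for mask in product([False, True], repeat=len(positions)):
                self.states.append(
                    (r, frozenset(p for p, on in zip(positions, mask) if on))
                )
        self.index = {s: i for i, s in enumerate(self.states)}
        self.detached = len(self.states)
        self.n_states = len(self.states) + 1

    def channel_counts(self, state):
        counts = [0] * self.C
        if state == "DETACHED":
            return counts
        _, surviving = state
        chan = dict(self.labels)
        for p in surviving:
            counts[chan[p]] += 1
        return counts

    def initial(self):
        pi = np.zeros(self.n_states)
        m = self.params.m
        for i, (r, surviving) in enumerate(self.states):
            if r != 0:
                continue
            pr = 1.0
            for p, c in self.labels:
                pr *= (1.0 - m[c]) if p in surviving else m[c]
            pi[i] = pr
        return pi

    def transition(self):
        """Column-stochastic one-cycle matrix: detach, then Edman, then
        independent per-dye loss."""
        p, e_rate, d = self.params.p, self.params.e, self.params.d
        chan = dict(self.labels)
        M = np.zeros((self.n_states, self.n_states))
        M[self.detached, self.detached] = 1.0
        for j, (r, surviving) in enumerate(self.states):
            M[self.detached, j] += d
            stay = 1.0 - d
            if stay == 0.0:
                continue
            if r == self.r_max:
                posts = [((r, surviving), stay)]
            else:
                adv = frozenset(q for q in surviving if q >= r + 1)
                posts = [((r, surviving), stay * e_rate), ((r + 1, adv), stay * (1.0 - e_rate))]
            for (r2, surv2), pr in posts:
                if pr == 0.0:
                    continue
                # each surviving dye bleaches independently
                positions = sorted(surv2)
                for mask in product([False, True], repeat=len(positions)):
                    keep = frozenset(q for q, on in zip(positions, mask) if on)
                    b = 1.0
                    for q in positions:
                        pc = p[chan[q]]
                        b *= (1.0 - pc) if q in keep else pc
                    if b > 0.0:
                        M[self.index[(r2, keep)], j] += pr * b
        return M

    def emission(self, y_t):
        prm = self.params
        out = np.empty(self.n_states)
        for i, s in enumerate(self.states):
            counts = self.channel_counts(s)
            w = 1.0
            for c in range(self.C):
                sd = math.sqrt(prm.sigma_bg[c] ** 2 + counts[c] * prm.sigma[c] ** 2)
                w *= _normal_pdf(y_t[c], counts[c] * prm.mu[c], sd)
            out[i] = w
        w = 1.0
        for c in range(self.C):
            w *= _normal_pdf(y_t[c], 0.0, prm.sigma_bg[c])
        out[self.detached] = w
        return out

    def likelihood(self, read: np.ndarray) -> float:
        if not hasattr(self, "_M"):
            self._M = self.transition()
        M = self._M
        f = self.initial() * self.emission(read[0])
        for t in range(1, self.T):
            f = self.emission(read[t]) * (M @ f)
        return float(f.sum())


# --------------------------------------------------------------------- #
# linear-scan kNN


def linear_scan_knn(vectors: np.ndarray, query: np.ndarray, k: int):
    """Indices and distances of the k nearest vectors, ties by index."""
    d = np.sqrt(((vectors - query[None, :]) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(len(d)), d))[: min(k, len(d))]
    return order, d[order]


def brute_force_vote(entries, vectors, query, k, sigma):
    """Top-voted dye seq and normalized score via linear scan."""
    idx, dist = linear_scan_knn(vectors, query, k)
    votes = {}
    for i, delta in zip(idx, dist):
        e = entries[i]
        w = e.multiplicity * math.exp(-(delta**2) / (2.0 * sigma**2))
        total = sum(e.peptide_counts.values())
        for pid, cnt in e.peptide_counts.items():
            votes[pid] = votes.get(pid, 0.0) + w * cnt / total
    total = sum(votes.values())
    best = min(votes, key=lambda pid: (-votes[pid], pid))
    return best, votes[best] / total


# --------------------------------------------------------------------- #
# brute-force PR sweep


def brute_force_pr(scores, correct, denom=None):
    """(recall, precision) at every distinct threshold, descending."""
    scores = np.asarray(scores, dtype=float)
    correct = np.asarray(correct, dtype=float)
    denom = float(len(scores) if denom is None else denom)
    points = []
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        points.append(
            (correct[sel].sum() / denom, correct[sel].sum() / sel.sum(), thr)
        )
    return points


# --------------------------------------------------------------------- #
# exact dye-track distribution by chaining the reduced model's factors


def exact_track_distribution(dye_seq, params):
    """Probability of every possible dye track (tuple of T count-tuples),
    computed by running the reduced-state transition factors with
    indicator 'emissions' that condition on the logged counts."""
    from fluoroseq.states import (
        enumerate_states,
        initial_distribution,
        transition_factors,
    )

    space = enumerate_states(dye_seq, params.num_timesteps)
    M = transition_factors(space, params)
    step = M[0]
    for f in M[1:]:
        step = f @ step
    step = np.asarray(step.todense())
    pi = initial_distribution(space, params)

    # observable counts for each state
    state_counts = np.zeros((space.n_states, space.n_channels), dtype=int)
    for idx, _, counts in space.states():
        state_counts[idx] = counts
    state_counts[space.detached_index] = 0

    dist = {}

    def recurse(t, f, prefix):
        obs = {}
        for idx in np.flatnonzero(f > 0.0):
            key = tuple(state_counts[idx])
            obs.setdefault(key, np.zeros_like(f))[idx] = f[idx]
        for key, fk in obs.items():
            path = prefix + (key,)
            if t == params.num_timesteps - 1:
                dist[path] = dist.get(path, 0.0) + fk.sum()
            else:
                recurse(t + 1, step @ fk, path)

    recurse(0, pi, ())
    return dist
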