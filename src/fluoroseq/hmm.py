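"""Forward algorithm and Bayesian classification over reduced HMMs.

``PeptideHMM`` runs the forward algorithm for one dye seq on a *batch* of
raw reads at once. Rather than materializing the sparse factor matrices of
:mod:`fluoroseq.states` (which remain the reference implementation, tested
to agree), the per-Edman-level block structure of the state space is kept
explicit: the forward vector is a list of count tensors, one per level,
and each factor is a small dense operator applied along one axis. This is
algebraically identical to multiplying by the sparse factors and
vectorizes cleanly over reads.

Emission pruning (the ``cutoff`` argument) zeroes per-channel counts whose
z-score against the observation exceeds the cutoff, restricting each
step's active states to a contiguous per-channel range; ``cutoff=None``
disables pruning. Underflow is handled by per-step renormalization with
the log of the scale accumulated, so likelihoods are returned in log
space.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from fluoroseq.params import SequencingParams
from fluoroseq.prm import PRM
from fluoroseq.proteome import DyeSeq
from fluoroseq.states import (
    StateSpace,
    enumerate_states,
    _binomial_survival_matrix,
)

def _apply_along_axis(arr: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    """out[..., j, ...] = sum_l M[j, l] arr[..., l, ...] along ``axis``."""
    moved = np.moveaxis(arr, axis, -1)
    out = moved @ M.T
    return np.moveaxis(out, -1, axis)


class PeptideHMM:
    """Reduced-state HMM for one dye sequence under fixed parameters."""

    def __init__(self, dye_seq: DyeSeq, params: SequencingParams):
        if dye_seq.n_channels != params.n_channels:
            raise ValueError("channel count mismatch between dye seq and params")
        self.dye_seq = dye_seq
        self.params = params
        self.space: StateSpace = enumerate_states(dye_seq, params.num_timesteps)
        sp = self.space
        self.C = sp.n_channels
        self.T = params.num_timesteps
        self.n_max = sp.n_table[0].astype(int)  # initial label counts per channel

        # initial level-0 block: independent Binomial(n_c, 1-m_c) counts
        shape0 = sp.level_shapes[0]
        block = np.ones(shape0)
        for c, size in enumerate(shape0):
            pmf = binom.pmf(np.arange(size), size - 1, 1.0 - params.m[c])
            block = block * pmf.reshape(
                (1,) * c + (size,) + (1,) * (len(shape0) - c - 1)
            )
        self._init_block = block

        # per-level dye-loss operators (skip channels with zero labels)
        self._loss_ops: list = []
        surv_cache: dict = {}
        for e in range(sp.e_max + 1):
            ops = []
            for c, size in enumerate(sp.level_shapes[e]):
                n = size - 1
                if n == 0 or params.p[c] == 0.0:
                    continue
                key = (c, n)
                if key not in surv_cache:
                    surv_cache[key] = _binomial_survival_matrix(n, float(params.p[c]))
                ops.append((c, surv_cache[key]))
            self._loss_ops.append(ops)

        # per-level Edman info: (labeled channel or None, removal operator)
        self._edman_ops: list = []
        for e in range(sp.e_max):
            c = sp.labeled_channel(e)
            if c is None:
                self._edman_ops.append((None, None))
            else:
                n = int(sp.n_table[e, c])
                # new[j] = old[j+1]*(j+1)/n + old[j]*(1 - j/n), j = 0..n-1
                M = np.zeros((n, n + 1))
                for j in range(n):
                    M[j, j + 1] = (j + 1) / n
                    M[j, j] = 1.0 - j / n
                self._edman_ops.append((c, M))

    # ------------------------------------------------------------------ #

    def _emission_tables(self, y_t: np.ndarray, cutoff: Optional[float]) -> list:
        """Per-channel (N, n_c+1) emission density tables for one timestep,
        with pruned counts zeroed. ``y_t`` has shape (N, C)."""
        N = y_t.shape[0]
        p = self.params
        tables = []
        for c in range(self.C):
            ell = np.arange(self.n_max[c] + 1)
            var = p.sigma_bg[c] ** 2 + ell * p.sigma[c] ** 2
            dev = y_t[:, c : c + 1] - ell[None, :] * p.mu[c]
            pdf = np.exp(-0.5 * dev**2 / var[None, :]) / np.sqrt(2.0 * np.pi * var)
            if cutoff is not None and np.isfinite(cutoff):
                keep = np.abs(dev) <= cutoff * np.sqrt(var)[None, :]
                none_kept = ~keep.any(axis=1)
                if none_kept.any():
                    nearest = np.clip(
                        np.round(y_t[none_kept, c] / p.mu[c]), 0, self.n_max[c]
                    ).astype(int)
                    keep[none_kept, nearest] = True
                # close to a contiguous [lo, hi] range
                lo = keep.argmax(axis=1)
                hi = keep.shape[1] - 1 - keep[:, ::-1].argmax(axis=1)
                idx = ell[None, :]
                keep = (idx >= lo[:, None]) & (idx <= hi[:, None])
                pdf = np.where(keep, pdf, 0.0)
            tables.append(pdf)
        return tables

    def _apply_emission(
        self, blocks: list, detached: np.ndarray, tables: list
    ) -> None:
        sp = self.space
        N = detached.shape[0]
        for e, b in enumerate(blocks):
            if b is None:
                continue
            shape = sp.level_shapes[e]
            w = np.ones((N,) + shape)
            for c, size in enumerate(shape):
                w = w * tables[c][:, :size].reshape(
                    (N,) + (1,) * c + (size,) + (1,) * (len(shape) - c - 1)
                )
            blocks[e] = b * w
        bg = np.ones(N)
        for c in range(self.C):
            bg = bg * tables[c][:, 0]
        detached *= bg

    def log_forward(
        self, reads: np.ndarray, cutoff: Optional[float] = None
    ) -> np.ndarray:
        """Log-likelihood log p(y_{0:T-1} | dye seq) for a batch of reads.

        ``reads`` has shape (N, T, C) (a single (T, C) read is promoted).
        """
        y = np.asarray(reads, dtype=float)
        single = y.ndim == 2
        if single:
            y = y[None]
        if y.shape[1:] != (self.T, self.C):
            raise ValueError(
                f"reads must be (N, {self.T}, {self.C}); got {y.shape}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite intensities")
        N = y.shape[0]
        sp = self.space

        blocks: list = [None] * (sp.e_max + 1)
        blocks[0] = np.broadcast_to(self._init_block, (N,) + sp.level_shapes[0]).copy()
        detached = np.zeros(N)
        log_scale = np.zeros(N)
        dead = np.zeros(N, dtype=bool)

        sum_axes = lambda b: b.reshape(N, -1).sum(axis=1)

        def rescale():
            nonlocal detached, log_scale, dead
            total = detached.copy()
            for b in blocks:
                if b is not None:
                    total += sum_axes(b)
            dead = dead | (total <= 0.0)
            safe = np.where(dead, 1.0, total)
            log_scale = log_scale + np.where(dead, 0.0, np.log(safe))
            detached = detached / safe
            for e, b in enumerate(blocks):
                if b is not None:
                    blocks[e] = b / safe.reshape((N,) + (1,) * (b.ndim - 1))

        self._apply_emission(blocks, detached, self._emission_tables(y[:, 0], cutoff))
        rescale()

        d, e_rate = self.params.d, self.params.e
        for t in range(1, self.T):
            # detachment
            attached_mass = np.zeros(N)
            for b in blocks:
                if b is not None:
                    attached_mass += sum_axes(b)
            detached += d * attached_mass
            if d > 0.0:
                for e, b in enumerate(blocks):
                    if b is not None:
                        blocks[e] = b * (1.0 - d)
            # Edman degradation, highest level first so each level moves once
            for e in range(min(sp.e_max, len(self._edman_ops)) - 1, -1, -1):
                b = blocks[e]
                if b is None:
                    continue
                moved = (1.0 - e_rate) * b
                blocks[e] = e_rate * b
                c, M = self._edman_ops[e]
                if c is not None:
                    moved = _apply_along_axis(moved, M, axis=c + 1)
                if blocks[e + 1] is None:
                    blocks[e + 1] = moved
                else:
                    blocks[e + 1] = blocks[e + 1] + moved
            # per-channel dye loss
            for e, b in enumerate(blocks):
                if b is None:
                    continue
                for c, M in self._loss_ops[e]:
                    b = _apply_along_axis(b, M, axis=c + 1)
                blocks[e] = b
            self._apply_emission(
                blocks, detached, self._emission_tables(y[:, t], cutoff)
            )
            rescale()

        out = np.where(dead, -np.inf, log_scale)
        return out[0] if single else out

    def forward_likelihood(
        self, read, cutoff: Optional[float] = None
    ) -> float:
        """Linear-scale likelihood p(y | dye seq) of a single read."""
        y = read.intensities if hasattr(read, "intensities") else read
        return float(np.exp(self.log_forward(np.asarray(y), cutoff)))


def build_models(
    dye_seqs: Sequence[DyeSeq], params: SequencingParams
) -> list:
    """One PeptideHMM per reference dye seq, in dye_seq_id order."""
    ordered = sorted(dye_seqs, key=lambda ds: (ds.dye_seq_id is None, ds.dye_seq_id))
    return [PeptideHMM(ds, params) for ds in ordered]


def posterior_scores(likelihoods: dict, priors: Optional[dict] = None) -> dict:
    """Bayesian inversion: posterior(z) proportional to likelihood(z) *
    prior(z), normalized over the provided candidate set. A degenerate
    all-zero product falls back to uniform with a warning."""
    keys = list(likelihoods)
    if not keys:
        raise ValueError("no candidates")
    lik = np.array([float(likelihoods[k]) for k in keys])
    if priors is None:
        pri = np.ones(len(keys))
    else:
        pri = np.array([float(priors[k]) for k in keys])
    weights = lik * pri
    total = weights.sum()
    if total <= 0.0:
        warnings.warn("all posterior weights are zero; returning uniform scores")
        weights = np.ones(len(keys))
        total = float(len(keys))
    return {k: float(w / total) for k, w in zip(keys, weights)}


def log_posterior_matrix(
    log_lik: np.ndarray, log_priors: Optional[np.ndarray] = None
) -> np.ndarray:
    """Column-wise softmax of a (R, N) log-likelihood matrix (+ priors):
    posterior over R candidates for each of N reads."""
    ll = log_lik if log_priors is None else log_lik + log_priors[:, None]
    with np.errstate(invalid="ignore"):
        m = np.max(ll, axis=0)
        finite = np.isfinite(m)
        shifted = np.where(finite[None, :], ll - np.where(finite, m, 0.0)[None, :], 0.0)
        w = np.exp(shifted)
        w[:, ~finite] = 1.0  # all-zero likelihoods: uniform fallback
    return w / w.sum(axis=0, keepdims=True)


def classify_bayes_batch(
    reads: np.ndarray,
    models: Sequence[PeptideHMM],
    cutoff: Optional[float] = None,
    priors: Optional[dict] = None,
    truth: Optional[np.ndarray] = None,
    n_candidates: int = 1,
) -> list:
    """Full-database Bayesian classification of a read batch.

    Runs the forward algorithm of every model on every read, normalizes
    posteriors over the whole reference, and returns one PRM per read
    (argmax posterior; ties go to the lowest dye_seq_id).
    """
    if not models:
        raise ValueError("empty model set")
    y = np.asarray(reads, dtype=float)
    if y.ndim == 2:
        y = y[None]
    N = y.shape[0]
    ids = np.array([m.dye_seq.dye_seq_id for m in models])
    order = np.argsort(ids, kind="stable")
    models = [models[i] for i in order]
    ids = ids[order]
    log_lik = np.empty((len(models), N))
    for r, model in enumerate(models):
        log_lik[r] = model.log_forward(y, cutoff)
    log_pri = None
    if priors is not None:
        pri = np.array([float(priors[int(i)]) for i in ids])
        with np.errstate(divide="ignore"):
            log_pri = np.log(pri)
    prms = []
    for i in range(N):
        # normalize one read at a time so the arithmetic (and hence the
        # bits) is independent of how reads are batched
        post_i = log_posterior_matrix(log_lik[:, i : i + 1], log_pri)[:, 0]
        best = int(np.argmax(post_i))  # first max = lowest id
        cand = []
        if n_candidates > 1:
            top = np.argsort(-post_i, kind="stable")[:n_candidates]
            cand = [(int(ids[j]), float(post_i[j])) for j in top]
        prms.append(
            PRM(
                read_id=i,
                dye_seq_id=int(ids[best]),
                score=float(post_i[best]),
                truth=None if truth is None else int(truth[i]),
                candidates=cand,
            )
        )
    return prms


def classify_bayes(
    read,
    models: Sequence[PeptideHMM],
    cutoff: Optional[float] = None,
    priors: Optional[dict] = None,
) -> PRM:
    """Classify a single raw read against the full reference."""
    y = read.intensities if hasattr(read, "intensities") else np.asarray(read)
    truth = getattr(read, "true_dye_seq_id", None)
    return classify_bayes_batch(
        y[None], models, cutoff=cutoff, priors=priors,
        truth=None if truth is None else np.array([truth]),
    )[0]
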