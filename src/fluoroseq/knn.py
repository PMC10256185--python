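"""KD-tree k-nearest-neighbor classification over deduplicated dye tracks.

Training points are the unique simulated dye tracks, flattened to T*C
vectors with counts scaled by the per-channel mean intensity mu_c so that
they live in the same space as raw-read intensities (with mu=1 the two
coincide). Neighbors vote with a Gaussian kernel exp(-delta^2 / (2
sigma_knn^2)) times the entry's multiplicity, each entry splitting its
weight among the dye seqs that produced it in proportion to their
production counts; algebraically a neighbor therefore contributes
``kernel(delta) * production_count`` to each of its dye seqs.

Two code paths compute the same votes: a per-read reference path
(`query_neighbors` + `weight_votes`, matching the definitions above
literally) and a batched path (`vote_matrix`) that assembles a sparse
kernel-weight matrix per read chunk and multiplies it against the
entry-by-dye-seq production-count matrix. The batched path shifts the
kernel by each read's nearest-neighbor distance before exponentiating;
this per-read positive rescaling leaves scores (weight ratios), rankings
and shortlists unchanged while avoiding underflow for distant neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from fluoroseq.params import SequencingParams
from fluoroseq.prm import PRM
from fluoroseq.simulator import TrainingSet

DEFAULT_K = 10
DEFAULT_SIGMA_KNN = 0.5


@dataclass(frozen=True)
class KnnConfig:
    k: int = DEFAULT_K
    sigma_knn: float = DEFAULT_SIGMA_KNN

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sigma_knn <= 0:
            raise ValueError("sigma_knn must be positive")


class KnnIndex:
    """Immutable KD-tree over a deduplicated training set.

    The tree is built once (median splits on the widest dimension) and
    never edited; lookups are exact nearest neighbors under the Euclidean
    norm.
    """

    def __init__(self, training: TrainingSet, params: SequencingParams):
        if len(training) == 0:
            raise ValueError("empty training set")
        self.num_timesteps = training.num_timesteps
        self.n_channels = training.n_channels
        self.entries = list(training.entries)
        vectors = np.stack(
            [(e.counts.astype(float) * params.mu).ravel() for e in self.entries]
        )
        self.vectors = vectors
        self.tree = cKDTree(vectors, balanced_tree=True)
        # entry-by-dye-seq production counts, for batched voting
        pid_set = sorted({pid for e in self.entries for pid in e.peptide_counts})
        self.pids = np.array(pid_set, dtype=np.int64)
        col_of = {pid: j for j, pid in enumerate(pid_set)}
        rows, cols, vals = [], [], []
        for i, e in enumerate(self.entries):
            for pid, cnt in e.peptide_counts.items():
                rows.append(i)
                cols.append(col_of[pid])
                vals.append(float(cnt))
        self.production = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.entries), len(pid_set))
        )

    def __len__(self) -> int:
        return len(self.entries)

    def query_vector(self, read) -> np.ndarray:
        y = read.intensities if hasattr(read, "intensities") else np.asarray(read)
        if y.shape != (self.num_timesteps, self.n_channels):
            raise ValueError(
                f"read shape {y.shape} does not match index "
                f"({self.num_timesteps}, {self.n_channels})"
            )
        return np.asarray(y, dtype=float).ravel()


def build_index(training: TrainingSet, params: SequencingParams) -> KnnIndex:
    return KnnIndex(training, params)


def query_neighbors(index: KnnIndex, read, k: int) -> list:
    """The min(k, n) nearest entries, sorted by (distance, entry id) so
    duplicate distances resolve deterministically; returns (entry, delta)."""
    x = index.query_vector(read)
    k_eff = min(k, len(index))
    dist, idx = index.tree.query(x, k=k_eff)
    dist = np.atleast_1d(dist)
    idx = np.atleast_1d(idx)
    order = np.lexsort((idx, dist))
    return [(index.entries[idx[i]], float(dist[i])) for i in order]


def weight_votes(neighbors: Sequence, sigma_knn: float) -> dict:
    """Gaussian-kernel weighted voting: each neighbor entry contributes
    multiplicity * exp(-delta^2 / (2 sigma^2)), split across the dye seqs
    that produced it proportionally to their production counts."""
    if not neighbors:
        raise ValueError("empty neighbor list")
    votes: dict = {}
    inv = 1.0 / (2.0 * sigma_knn**2)
    for entry, delta in neighbors:
        w = entry.multiplicity * np.exp(-(delta**2) * inv)
        total = sum(entry.peptide_counts.values())
        for pid, cnt in entry.peptide_counts.items():
            votes[pid] = votes.get(pid, 0.0) + w * cnt / total
    return votes


def vote_matrix(
    index: KnnIndex,
    reads: np.ndarray,
    k: int,
    sigma_knn: float,
    chunk: int = 2048,
) -> np.ndarray:
    """Dense (N, n_dye_seqs) vote weights (columns follow ``index.pids``),
    scaled per read by the nearest neighbor's kernel value."""
    y = np.asarray(reads, dtype=float).reshape(len(reads), -1)
    N = y.shape[0]
    k_eff = min(k, len(index))
    inv = 1.0 / (2.0 * sigma_knn**2)
    out = np.empty((N, index.production.shape[1]))
    for start in range(0, N, chunk):
        stop = min(start + chunk, N)
        dist, idx = index.tree.query(y[start:stop], k=k_eff)
        if k_eff == 1:
            dist, idx = dist[:, None], idx[:, None]
        d2 = dist**2
        kern = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) * inv)
        B = stop - start
        W = sparse.csr_matrix(
            (
                kern.ravel(),
                idx.ravel(),
                np.arange(0, B * k_eff + 1, k_eff),
            ),
            shape=(B, len(index)),
        )
        out[start:stop] = (W @ index.production).toarray()
    return out


def _top_vote(votes: dict):
    """(winner id, winner weight, total weight); ties -> lowest id."""
    total = sum(votes.values())
    best_id, best_w = None, -1.0
    for pid in sorted(votes):
        w = votes[pid]
        if w > best_w:
            best_id, best_w = pid, w
    return best_id, best_w, total


def classify_knn(
    index: KnnIndex,
    read,
    config: KnnConfig = KnnConfig(),
    read_id: int = 0,
    truth: Optional[int] = None,
) -> PRM:
    """kNN classification of one raw read: retrieve k nearest entries,
    vote, return the top dye seq with score = its weight / total weight."""
    neighbors = query_neighbors(index, read, config.k)
    votes = weight_votes(neighbors, config.sigma_knn)
    best_id, best_w, total = _top_vote(votes)
    if total <= 0.0:
        # all kernel weights underflowed: fall back to the nearest entry
        votes = dict(neighbors[0][0].peptide_counts)
        best_id, best_w, total = _top_vote(votes)
    if truth is None:
        truth = getattr(read, "true_dye_seq_id", None)
    return PRM(
        read_id=read_id,
        dye_seq_id=int(best_id),
        score=float(best_w / total),
        truth=truth,
    )


def classify_knn_batch(
    index: KnnIndex,
    reads: np.ndarray,
    config: KnnConfig = KnnConfig(),
    truth: Optional[np.ndarray] = None,
) -> list:
    votes = vote_matrix(index, reads, config.k, config.sigma_knn)
    totals = votes.sum(axis=1)
    best = np.argmax(votes, axis=1)  # first max = lowest pid (columns sorted)
    prms = []
    for i in range(votes.shape[0]):
        prms.append(
            PRM(
                read_id=i,
                dye_seq_id=int(index.pids[best[i]]),
                score=float(votes[i, best[i]] / totals[i]),
                truth=None if truth is None else int(truth[i]),
            )
        )
    return prms
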