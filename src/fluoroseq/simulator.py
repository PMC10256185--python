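"""Monte Carlo simulation of the fluorosequencing error process.

Each molecule of a labeled peptide is simulated with explicit per-position
fluorophore booleans. Before sequencing every fluorophore is a dud
(missing) with probability ``m_c``. Then, per imaging timestep, the
current fluorophore counts are logged, after which three random events
occur in fixed order: the whole peptide detaches with probability ``d``
(absorbing, all signal lost), Edman degradation removes the N-terminal
residue (and any dye on it) with probability ``1 - e``, and every
surviving fluorophore is destroyed independently with probability ``p_c``.

A *dye track* is the T x C integer matrix of logged counts; a *raw read*
converts each count ``lam`` into a Gaussian intensity with mean
``lam * mu_c`` and variance ``sigma_bg_c**2 + lam * sigma_c**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from fluoroseq.params import SequencingParams
from fluoroseq.proteome import DyeSeq


@dataclass
class DyeTrack:
    """A deduplicated dye track: T x C counts, how many simulated molecules
    produced it (``multiplicity``) and from which dye seqs
    (``peptide_counts``: dye_seq_id -> occurrence count)."""

    counts: np.ndarray
    multiplicity: int = 1
    peptide_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int32)
        if self.counts.ndim != 2:
            raise ValueError("counts must be T x C")
        if np.any(self.counts < 0):
            raise ValueError("negative fluorophore count")
        if not self.peptide_counts:
            self.peptide_counts = {}

    @property
    def is_dark(self) -> bool:
        return not self.counts.any()


@dataclass
class RawRead:
    """T x C fluorescence intensities; negative values are legitimate
    (Gaussian background noise). ``true_dye_seq_id`` is set for simulated
    test data only."""

    intensities: np.ndarray
    true_dye_seq_id: Optional[int] = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be T x C")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity")


def simulate_dye_tracks(
    dye_seq: DyeSeq,
    n: int,
    params: SequencingParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n`` molecules of one dye seq; returns counts (n, T, C).

    Vectorized over molecules; the physical state (per labeled position:
    dye surviving yes/no) is tracked explicitly, so correlations induced
    by Edman removal of specific positions are exact.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    T, C = params.num_timesteps, params.n_channels
    if dye_seq.n_channels != C:
        raise ValueError("dye seq channel count does not match params")
    labels = dye_seq.label_positions()
    pos = np.array([i for i, _ in labels], dtype=np.int64)
    chan = np.array([c for _, c in labels], dtype=np.int64)
    K = len(pos)

    counts = np.zeros((n, T, C), dtype=np.int32)
    # dud dyes are missing from the start
    present = rng.random((n, K)) >= params.m[chan]
    attached = np.ones(n, dtype=bool)
    front = np.zeros(n, dtype=np.int64)  # residues successfully removed

    chan_masks = [chan == c for c in range(C)]
    for t in range(T):
        for c in range(C):
            counts[:, t, c] = present[:, chan_masks[c]].sum(axis=1)
        if t == T - 1:
            break
        # detachment (absorbing)
        detach = rng.random(n) < params.d
        attached &= ~detach
        present[~attached] = False
        # Edman degradation succeeds with probability 1 - e
        front += rng.random(n) >= params.e
        present &= pos[None, :] >= front[:, None]
        # per-fluorophore photobleaching / chemical destruction
        present &= rng.random((n, K)) >= params.p[chan]
    return counts


def simulate_dye_track(
    dye_seq: DyeSeq, params: SequencingParams, rng: np.random.Generator
) -> DyeTrack:
    """Simulate a single molecule's dye track."""
    counts = simulate_dye_tracks(dye_seq, 1, params, rng)[0]
    pid = dye_seq.dye_seq_id if dye_seq.dye_seq_id is not None else 0
    return DyeTrack(counts=counts, multiplicity=1, peptide_counts={pid: 1})


def emit_raw_reads(
    counts: np.ndarray, params: SequencingParams, rng: np.random.Generator
) -> np.ndarray:
    """Convert dye-track counts (..., T, C) into Gaussian intensities."""
    counts = np.asarray(counts, dtype=float)
    mean = counts * params.mu
    sd = params.cell_sd(counts)
    return rng.normal(mean, sd)


def emit_raw_read(
    track: DyeTrack, params: SequencingParams, rng: np.random.Generator
) -> RawRead:
    return RawRead(intensities=emit_raw_reads(track.counts, params, rng))


@dataclass
class TrainingSet:
    """Deduplicated dye tracks for kNN training.

    ``entries`` hold unique count tensors; multiplicities plus
    ``n_discarded`` (all-dark tracks) account for every simulated molecule.
    """

    entries: list
    num_timesteps: int
    n_channels: int
    n_simulated: int = 0
    n_discarded: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DyeTrack]:
        return iter(self.entries)


def generate_training_set(
    dye_seqs: Sequence[DyeSeq],
    n_per_peptide: int,
    params: SequencingParams,
    rng: np.random.Generator,
) -> TrainingSet:
    """Simulate ``n_per_peptide`` dye tracks per dye seq, drop all-dark
    tracks, and merge identical tracks into single entries with
    per-dye-seq production counts."""
    if n_per_peptide < 1:
        raise ValueError("n_per_peptide must be >= 1")
    if not dye_seqs:
        raise ValueError("empty dye-seq reference")
    T, C = params.num_timesteps, params.n_channels
    table: dict = {}
    n_discarded = 0
    for ds in dye_seqs:
        pid = ds.dye_seq_id if ds.dye_seq_id is not None else 0
        counts = simulate_dye_tracks(ds, n_per_peptide, params, rng)
        for i in range(n_per_peptide):
            track = counts[i]
            if not track.any():
                n_discarded += 1
                continue
            key = track.tobytes()
            entry = table.get(key)
            if entry is None:
                table[key] = DyeTrack(
                    counts=track.copy(), multiplicity=1, peptide_counts={pid: 1}
                )
            else:
                entry.multiplicity += 1
                entry.peptide_counts[pid] = entry.peptide_counts.get(pid, 0) + 1
    return TrainingSet(
        entries=list(table.values()),
        num_timesteps=T,
        n_channels=C,
        n_simulated=n_per_peptide * len(dye_seqs),
        n_discarded=n_discarded,
    )


@dataclass
class TestSet:
    """Simulated raw reads with truth labels, as dense arrays."""

    intensities: np.ndarray  # (N, T, C)
    truth: np.ndarray  # (N,) dye_seq_id

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[RawRead]:
        for i in range(len(self)):
            yield RawRead(self.intensities[i], true_dye_seq_id=int(self.truth[i]))


def generate_test_set(
    dye_seqs: Sequence[DyeSeq],
    n_reads: int,
    params: SequencingParams,
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> TestSet:
    """Draw dye seqs uniformly with replacement, simulate raw reads, and
    discard reads whose underlying track is all-dark (such molecules are
    never detected in a real experiment); resample until exactly
    ``n_reads`` survive."""
    if not dye_seqs:
        raise ValueError("empty dye-seq reference")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    T, C = params.num_timesteps, params.n_channels
    kept_y: list = []
    kept_truth: list = []
    have = 0
    for _ in range(max_rounds):
        need = n_reads - have
        if need <= 0:
            break
        ids = rng.integers(0, len(dye_seqs), size=need)
        counts = np.zeros((need, T, C), dtype=np.int32)
        for uid in np.unique(ids):
            sel = np.flatnonzero(ids == uid)
            counts[sel] = simulate_dye_tracks(
                dye_seqs[uid], len(sel), params, rng
            )
        bright = counts.reshape(need, -1).any(axis=1)
        if not bright.any():
            continue
        y = emit_raw_reads(counts[bright], params, rng)
        kept_y.append(y)
        kept_truth.append(ids[bright])
        have += int(bright.sum())
    if have < n_reads:
        raise RuntimeError(
            "could not generate enough observable reads "
            f"({have}/{n_reads} after {max_rounds} rounds); "
            "are all dye tracks dark under these parameters?"
        )
    intensities = np.concatenate(kept_y)[:n_reads]
    truth = np.concatenate(kept_truth)[:n_reads]
    return TestSet(intensities=intensities, truth=truth.astype(np.int64))
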