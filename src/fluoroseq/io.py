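"""On-disk formats: FASTA in; dye-seq / dye-track / raw-read / PRM TSV;
YAML run configuration.

The TSV dialects are self-defined (the upstream instrument formats are not
standardized): every file opens with a small header line carrying the
tensor shape, floats are serialized with 17 significant digits so
write-then-read round trips are bit-exact, and dye-track entries carry
their multiplicity and per-dye-seq production counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from Bio import SeqIO

from fluoroseq.params import SequencingParams
from fluoroseq.prm import PRM
from fluoroseq.proteome import DyeSeq, LabelScheme
from fluoroseq.simulator import DyeTrack, TestSet, TrainingSet


# --------------------------------------------------------------------- #
# FASTA


def read_fasta_proteome(path) -> List[Tuple[str, str]]:
    """(protein_id, sequence) pairs; ids from the header up to the first
    whitespace, sequences uppercased with '*' stops stripped. Duplicate
    ids and malformed leading lines are rejected."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if not pid:
            raise ValueError(f"{path}: record with empty id")
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        records.append((pid, str(rec.seq).upper().replace("*", "")))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


# --------------------------------------------------------------------- #
# dye seqs


def write_dye_seqs(dye_seqs: Sequence[DyeSeq], path) -> None:
    with open(path, "w") as fh:
        fh.write("dye_seq_id\tcode\tpeptides\tproteins\n")
        for ds in dye_seqs:
            peps = ",".join(pep for pep, _ in ds.sources)
            prots = ",".join(prot for _, prot in ds.sources)
            fh.write(f"{ds.dye_seq_id}\t{ds.code}\t{peps}\t{prots}\n")


def read_dye_seqs(path, n_channels: Optional[int] = None) -> List[DyeSeq]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("dye_seq_id"):
            raise ValueError(f"{path}: missing dye-seq header")
        for line in fh:
            if not line.strip():
                continue
            ds_id, code, peps, prots = line.rstrip("\n").split("\t")
            sources = list(zip(peps.split(","), prots.split(",")))
            ds = DyeSeq(
                code=code,
                n_channels=n_channels
                if n_channels is not None
                else _channels_in_code(code),
                sources=sources,
                dye_seq_id=int(ds_id),
            )
            out.append(ds)
    if n_channels is None and out:
        C = max(ds.n_channels for ds in out)
        for ds in out:
            ds.n_channels = C
    return out


def _channels_in_code(code: str) -> int:
    labels = [int(ch, 36) for ch in code if ch != "."]
    return (max(labels) + 1) if labels else 1


# --------------------------------------------------------------------- #
# dye tracks (training data)


def write_dye_tracks(training: TrainingSet, path) -> None:
    T, C = training.num_timesteps, training.n_channels
    with open(path, "w") as fh:
        fh.write(
            f"#dye_tracks\t{T}\t{C}\t{len(training)}\t"
            f"{training.n_simulated}\t{training.n_discarded}\n"
        )
        for entry in training.entries:
            flat = " ".join(str(int(v)) for v in entry.counts.ravel())
            pairs = ",".join(
                f"{pid}:{cnt}" for pid, cnt in sorted(entry.peptide_counts.items())
            )
            fh.write(f"{flat}\t{entry.multiplicity}\t{pairs}\n")


def read_dye_tracks(path) -> TrainingSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#dye_tracks" or len(header) != 6:
            raise ValueError(f"{path}: bad dye-track header")
        T, C, n_entries, n_sim, n_disc = (int(x) for x in header[1:])
        entries = []
        for line in fh:
            if not line.strip():
                continue
            flat, mult, pairs = line.rstrip("\n").split("\t")
            counts = np.array([int(v) for v in flat.split()], dtype=np.int32)
            if counts.size != T * C:
                raise ValueError(f"{path}: entry shape mismatch")
            pc = {}
            if pairs:
                for item in pairs.split(","):
                    pid, cnt = item.split(":")
                    pc[int(pid)] = int(cnt)
            entries.append(
                DyeTrack(
                    counts=counts.reshape(T, C),
                    multiplicity=int(mult),
                    peptide_counts=pc,
                )
            )
    if len(entries) != n_entries:
        raise ValueError(f"{path}: expected {n_entries} entries, found {len(entries)}")
    return TrainingSet(
        entries=entries,
        num_timesteps=T,
        n_channels=C,
        n_simulated=n_sim,
        n_discarded=n_disc,
    )


# --------------------------------------------------------------------- #
# raw reads (test data)


def write_raw_reads(
    intensities: np.ndarray, path, truth: Optional[np.ndarray] = None
) -> None:
    y = np.asarray(intensities, dtype=float)
    N, T, C = y.shape
    has_truth = int(truth is not None)
    with open(path, "w") as fh:
        fh.write(f"#raw_reads\t{T}\t{C}\t{N}\t{has_truth}\n")
        for i in range(N):
            vals = " ".join(format(v, ".17g") for v in y[i].ravel())
            if truth is not None:
                fh.write(f"{vals}\t{int(truth[i])}\n")
            else:
                fh.write(f"{vals}\n")


def read_raw_reads(path) -> TestSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#raw_reads" or len(header) != 5:
            raise ValueError(f"{path}: bad raw-read header")
        T, C, N, has_truth = (int(x) for x in header[1:])
        y = np.empty((N, T, C))
        truth = np.full(N, -1, dtype=np.int64)
        i = 0
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            vals = np.array([float(v) for v in parts[0].split()])
            if vals.size != T * C:
                raise ValueError(f"{path}: read shape mismatch at entry {i}")
            y[i] = vals.reshape(T, C)
            if has_truth:
                truth[i] = int(parts[1])
            i += 1
    if i != N:
        raise ValueError(f"{path}: expected {N} reads, found {i}")
    return TestSet(intensities=y, truth=truth if has_truth else np.full(N, -1))


# --------------------------------------------------------------------- #
# peptide-read matches


def write_prms(prms: Sequence[PRM], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\trank\tdye_seq_id\tscore\ttruth\n")
        for p in prms:
            ranked = p.candidates if p.candidates else [(p.dye_seq_id, p.score)]
            truth = "" if p.truth is None else str(p.truth)
            for rank, (ds_id, score) in enumerate(ranked):
                fh.write(f"{p.read_id}\t{rank}\t{ds_id}\t{format(score, '.17g')}\t{truth}\n")


def read_prms(path) -> List[PRM]:
    by_read: Dict[int, PRM] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing PRM header")
        for line in fh:
            if not line.strip():
                continue
            read_id, rank, ds_id, score, truth = line.rstrip("\n").split("\t")
            read_id, rank, ds_id = int(read_id), int(rank), int(ds_id)
            score = float(score)
            t = None if truth == "" else int(truth)
            if rank == 0:
                by_read[read_id] = PRM(
                    read_id=read_id, dye_seq_id=ds_id, score=score, truth=t,
                    candidates=[(ds_id, score)],
                )
            else:
                by_read[read_id].candidates.append((ds_id, score))
    prms = [by_read[k] for k in sorted(by_read)]
    for p in prms:
        if len(p.candidates) == 1:
            p.candidates = []
    return prms


# --------------------------------------------------------------------- #
# PR curves / calibration CSV


def write_pr_curve(curve, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold,recall,precision\n")
        for t, r, p in zip(curve.thresholds, curve.recall, curve.precision):
            fh.write(f"{format(t, '.17g')},{format(r, '.17g')},{format(p, '.17g')}\n")


def write_calibration(table, path) -> None:
    with open(path, "w") as fh:
        fh.write("bucket,mean_predicted,empirical_accuracy,n\n")
        for i, (pred, emp, n) in enumerate(
            zip(table.predicted, table.empirical, table.counts)
        ):
            fh.write(f"{i},{format(pred, '.17g')},{format(emp, '.17g')},{n}\n")


# --------------------------------------------------------------------- #
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run: the labeling scheme,
    error-model parameters, classifier choice and its parameters, and the
    master seed (train/test streams are derived from it)."""

    protease: str = "trypsin"
    channels: List[str] = field(default_factory=lambda: ["DE", "C", "Y"])
    params: Dict = field(default_factory=dict)  # SequencingParams overrides
    mode: str = "hybrid"
    classifier: Dict = field(default_factory=dict)
    seed: int = 0

    def scheme(self) -> LabelScheme:
        return LabelScheme(self.protease, [set(ch) for ch in self.channels])

    def sequencing_params(self) -> SequencingParams:
        return SequencingParams.create(len(self.channels), **self.params)

    def to_dict(self) -> Dict:
        return {
            "protease": self.protease,
            "channels": list(self.channels),
            "params": dict(self.params),
            "mode": self.mode,
            "classifier": dict(self.classifier),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        return cls(
            protease=d.get("protease", "trypsin"),
            channels=list(d.get("channels", ["DE", "C", "Y"])),
            params=dict(d.get("params", {})),
            mode=d.get("mode", "hybrid"),
            classifier=dict(d.get("classifier", {})),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
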