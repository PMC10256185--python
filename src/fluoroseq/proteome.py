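"""Protease digestion and dye labeling of a reference proteome.

A protein is cleaved in silico into peptides (zero missed cleavages,
cleavage strictly after the recognition residues), each peptide is turned
into a *dye sequence* — one character per residue giving the fluorophore
channel that labels it ('.' for unlabeled) — and dye sequences that are
indistinguishable to the instrument are merged into a single reference
entry carrying full peptide/protein provenance.

Two normalizations make "indistinguishable" precise: trailing unlabeled
residues are trimmed (the instrument cannot see residues after the last
dye), and peptides with no labeled residue at all are dropped (they are
dark throughout and would never be observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

# cleavage is strictly after these residues, by identity alone
PROTEASES = {
    "trypsin": frozenset("KR"),
    "cyanogen_bromide": frozenset("M"),
    "endopro": frozenset("AP"),
}

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# channel index -> code character; up to 36 channels, far beyond practice
_CODE_CHARS = "0123456789abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class LabelScheme:
    """A protease plus an ordered list of labeled amino-acid sets.

    ``channels[c]`` is the set of amino acids carrying the color-``c``
    fluorophore. Amino acids sharing a fluorophore color (e.g. D and E)
    belong to one set. Sets must be pairwise disjoint.
    """

    protease: str
    channels: tuple[frozenset, ...]

    def __init__(self, protease: str, channels: Sequence[Iterable[str]]):
        if protease not in PROTEASES:
            raise ValueError(f"unknown protease {protease!r}; options: {sorted(PROTEASES)}")
        ch = tuple(frozenset(s) for s in channels)
        if len(ch) < 1:
            raise ValueError("need at least one labeled channel")
        seen: set = set()
        for c, s in enumerate(ch):
            if not s:
                raise ValueError(f"channel {c} labels no amino acid")
            bad = s - AMINO_ACIDS
            if bad:
                raise ValueError(f"channel {c} labels unknown residues {sorted(bad)}")
            if s & seen:
                raise ValueError("channel sets must be pairwise disjoint")
            seen |= s
        object.__setattr__(self, "protease", protease)
        object.__setattr__(self, "channels", ch)

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class DyeSeq:
    """A labeled-peptide equivalence class.

    ``code`` has one character per residue ('.' = unlabeled, otherwise the
    channel's code character), with trailing '.' trimmed. ``sources`` lists
    the (peptide, protein) pairs that produce this code.
    """

    code: str
    n_channels: int
    sources: list = field(default_factory=list)
    dye_seq_id: Optional[int] = None

    def __post_init__(self):
        if not self.code or self.code.endswith("."):
            raise ValueError("dye-seq code must be non-empty with trailing '.' trimmed")
        if not self.sources:
            raise ValueError("dye seq needs at least one source peptide")

    def __len__(self) -> int:
        return len(self.code)

    @classmethod
    def from_code(
        cls,
        code: str,
        n_channels: Optional[int] = None,
        peptide: Optional[str] = None,
        protein: str = "",
    ) -> "DyeSeq":
        """Build a bare dye seq straight from a code string (handy for
        simulations that do not start from a proteome)."""
        code = code.rstrip(".")
        if n_channels is None:
            labels = [_CODE_CHARS.index(ch) for ch in code if ch != "."]
            n_channels = (max(labels) + 1) if labels else 1
        return cls(
            code=code,
            n_channels=n_channels,
            sources=[(peptide if peptide is not None else code, protein)],
        )

    def channel_of(self, position: int) -> Optional[int]:
        ch = self.code[position]
        return None if ch == "." else _CODE_CHARS.index(ch)

    def label_positions(self) -> list:
        """(position, channel) for every labeled residue."""
        return [
            (i, _CODE_CHARS.index(ch))
            for i, ch in enumerate(self.code)
            if ch != "."
        ]

    def n_table(self) -> np.ndarray:
        """``n[e, c]`` = number of channel-``c`` labels strictly after the
        first ``e`` residues; shape (len+1, C), ``n[len] == 0``."""
        L, C = len(self.code), self.n_channels
        n = np.zeros((L + 1, C), dtype=int)
        for e in range(L - 1, -1, -1):
            n[e] = n[e + 1]
            c = self.channel_of(e)
            if c is not None:
                n[e, c] += 1
        return n

    @property
    def initial_counts(self) -> np.ndarray:
        return self.n_table()[0]

    @property
    def peptides(self) -> list:
        return [pep for pep, _ in self.sources]

    @property
    def proteins(self) -> list:
        return [prot for _, prot in self.sources]


def digest(protein_sequence: str, protease: str) -> list:
    """Cleave a protein sequence after every recognition residue.

    Zero missed cleavages; the concatenation of the output equals the
    input. Non-canonical letters are carried through but never cleaved.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    sites = PROTEASES[protease]
    peptides = []
    start = 0
    for i, aa in enumerate(protein_sequence):
        if aa in sites:
            peptides.append(protein_sequence[start : i + 1])
            start = i + 1
    if start < len(protein_sequence):
        peptides.append(protein_sequence[start:])
    return peptides


def label_code(peptide: str, scheme: LabelScheme) -> Optional[str]:
    """Dye-seq code for a peptide, trailing '.' trimmed; None if all-dark."""
    chars = []
    for aa in peptide:
        code = "."
        for c, residues in enumerate(scheme.channels):
            if aa in residues:
                code = _CODE_CHARS[c]
                break
        chars.append(code)
    trimmed = "".join(chars).rstrip(".")
    return trimmed or None


def label_peptide(
    peptide: str, scheme: LabelScheme, protein_id: str = ""
) -> Optional[DyeSeq]:
    """Label one peptide under a scheme; None when no residue is labeled
    (such peptides are unobservable and never enter the reference)."""
    code = label_code(peptide, scheme)
    if code is None:
        return None
    return DyeSeq(code=code, n_channels=scheme.n_channels, sources=[(peptide, protein_id)])


def merge_dye_seqs(dye_seqs: Iterable[DyeSeq]) -> list:
    """Merge dye seqs with identical codes, concatenating their sources.

    Output is sorted by code and assigned sequential ``dye_seq_id`` so a
    given proteome + scheme always yields the same reference, independent
    of input order.
    """
    by_code: dict = {}
    for ds in dye_seqs:
        if ds.code in by_code:
            by_code[ds.code].sources.extend(ds.sources)
        else:
            by_code[ds.code] = DyeSeq(
                code=ds.code, n_channels=ds.n_channels, sources=list(ds.sources)
            )
    merged = [by_code[code] for code in sorted(by_code)]
    for i, ds in enumerate(merged):
        ds.sources.sort()
        ds.dye_seq_id = i
    return merged


def build_reference(
    proteins: Iterable, scheme: LabelScheme
) -> list:
    """Digest + label + merge a proteome given as (protein_id, sequence)
    pairs; returns the deduplicated dye-seq reference."""
    singles = []
    for protein_id, seq in proteins:
        seq = seq.upper().replace("*", "")
        for pep in digest(seq, scheme.protease):
            ds = label_peptide(pep, scheme, protein_id)
            if ds is not None:
                singles.append(ds)
    if not singles:
        raise ValueError("no labelable peptides in the proteome under this scheme")
    return merge_dye_seqs(singles)
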