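"""Peptide-read matches: the classifier output record."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class PRM:
    """A peptide-read match: the winning dye seq for one raw read with a
    normalized score in (0, 1], an optional ranked candidate list, and the
    generating dye seq when known (simulated data)."""

    read_id: int
    dye_seq_id: int
    score: float
    truth: Optional[int] = None
    candidates: list = field(default_factory=list)  # [(dye_seq_id, score) desc]

    @property
    def correct(self) -> Optional[bool]:
        if self.truth is None:
            return None
        return self.dye_seq_id == self.truth
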