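"""Synthetic random proteomes for simulation studies.

Residues are drawn i.i.d. from average amino-acid frequencies observed
across well-characterized proteomes (Swiss-Prot composition statistics,
rounded), so digests produce realistic peptide-length and label-count
distributions. Real proteins differ in ways that do not matter to the
classifier benchmarks here (domain structure, repeats, homology between
proteins); see the methods note for what that implies.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

# average composition of Swiss-Prot sequences (fractions, rounded)
AA_FREQUENCIES = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


def random_protein(length: int, rng: np.random.Generator) -> str:
    letters = list(AA_FREQUENCIES)
    probs = np.array(list(AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def random_proteome(
    n_proteins: int,
    mean_length: int = 300,
    rng: np.random.Generator = None,
) -> List[Tuple[str, str]]:
    """(protein_id, sequence) pairs with lengths ~ Poisson(mean_length)
    (min 20 residues)."""
    if rng is None:
        rng = np.random.default_rng()
    out = []
    for i in range(n_proteins):
        length = max(20, int(rng.poisson(mean_length)))
        out.append((f"prot{i:04d}", random_protein(length, rng)))
    return out
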