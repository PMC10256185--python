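"""Digest a synthetic proteome and build the dye-sequence reference.

Trypsin cleaves after K and R; aspartate/glutamate share one fluorophore
color, cysteine and tyrosine get their own. Peptides indistinguishable to
the instrument (same labeled positions after trimming unlabeled C-terminal
residues) are merged into a single dye sequence with full provenance.
"""

import numpy as np

from fluoroseq.proteome import LabelScheme, build_reference
from fluoroseq.synthetic import random_proteome

rng = np.random.default_rng(0)
proteome = random_proteome(5, 200, rng)
scheme = LabelScheme("trypsin", [{"D", "E"}, {"C"}, {"Y"}])
reference = build_reference(proteome, scheme)

print(f"{len(proteome)} proteins -> {len(reference)} unique dye sequences")
print("first five entries (code / peptides / proteins):")
for ds in reference[:5]:
    peps = ",".join(sorted(set(ds.peptides)))
    prots = ",".join(sorted(set(ds.proteins)))
    print(f"  {ds.dye_seq_id:3d}  {ds.code:12s}  {peps}  [{prots}]")
shared = [ds for ds in reference if len(ds.sources) > 1]
print(f"{len(shared)} dye sequences are shared by more than one peptide;")
print("a classifier can only identify such peptides up to this equivalence.")
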