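"""Score calibration and peptide/protein roll-up.

Classifier scores are posterior probabilities; if they are well
calibrated, the mean score inside any bucket of reads should match the
fraction classified correctly, and a precision/recall curve can be
predicted without truth labels. Reads are then rolled up to peptides and
proteins with a max rule that penalizes ambiguous identifications.
"""

import numpy as np

from fluoroseq.evaluate import (
    calibration_table,
    entity_pr_curve,
    peptide_protein_map,
    pr_curve,
    predicted_pr_curve,
    score_peptides,
    score_proteins,
)
from fluoroseq.hmm import build_models
from fluoroseq.hybrid import HybridConfig, classify_hybrid_batch
from fluoroseq.knn import KnnIndex
from fluoroseq.params import SequencingParams
from fluoroseq.proteome import LabelScheme, build_reference
from fluoroseq.simulator import generate_test_set, generate_training_set
from fluoroseq.synthetic import random_proteome

rng = np.random.default_rng(3)
proteome = random_proteome(10, 250, rng)
scheme = LabelScheme("trypsin", [{"D", "E"}, {"C"}, {"Y"}])
reference = build_reference(proteome, scheme)
params = SequencingParams.create(3)
training = generate_training_set(reference, 1000, params, rng)
index = KnnIndex(training, params)
models = build_models(reference, params)
test = generate_test_set(reference, 2000, params, rng)
prms = classify_hybrid_batch(test.intensities, index, models, HybridConfig(),
                             truth=test.truth)

table = calibration_table(prms, n_buckets=20)
print("calibration (20 buckets): mean predicted score vs empirical accuracy")
for i in [0, 5, 10, 15, 19]:
    print(f"  bucket {i:2d}: predicted {table.predicted[i]:.3f}  "
          f"empirical {table.empirical[i]:.3f}  (n={table.counts[i]})")
print(f"mean |predicted - empirical| = {table.mean_absolute_deviation():.4f}")

truth_curve = pr_curve(prms)
pred_curve = predicted_pr_curve(prms)
print(f"average precision: truth-based {truth_curve.average_precision():.3f}, "
      f"predicted {pred_curve.average_precision():.3f}")

pep_scores = score_peptides(prms, reference)
pep_to_prot = peptide_protein_map(reference)
prot_scores = score_proteins(pep_scores, pep_to_prot)
by_id = {ds.dye_seq_id: ds for ds in reference}
present_peps = {p for t in set(test.truth.tolist()) for p in by_id[t].peptides}
present_prots = {pr for p in present_peps for pr in pep_to_prot[p]}
ap_read = truth_curve.average_precision()
ap_pep = entity_pr_curve(pep_scores, present_peps).average_precision()
ap_prot = entity_pr_curve(prot_scores, present_prots).average_precision()
print(f"average precision by level: reads {ap_read:.3f} < peptides {ap_pep:.3f} "
      f"< proteins {ap_prot:.3f}")
print("aggregating evidence across reads and peptides makes protein calls")
print("much more reliable than individual read calls.")
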