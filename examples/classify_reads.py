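"""Classify simulated raw reads three ways: kNN, full Bayesian HMM, and
the hybrid (kNN shortlist + HMM rescoring).

The hybrid keeps the HMM's accuracy at close to the kNN's cost: the
KD-tree query shortlists candidate dye sequences per read and the
Bayesian posterior is computed over the shortlist only.
"""

import time

import numpy as np

from fluoroseq.hmm import build_models, classify_bayes_batch
from fluoroseq.hybrid import HybridConfig, classify_hybrid_batch
from fluoroseq.knn import KnnConfig, KnnIndex, classify_knn_batch
from fluoroseq.params import SequencingParams
from fluoroseq.proteome import LabelScheme, build_reference
from fluoroseq.simulator import generate_test_set, generate_training_set
from fluoroseq.synthetic import random_proteome

rng = np.random.default_rng(2)
proteome = random_proteome(10, 250, rng)
scheme = LabelScheme("trypsin", [{"D", "E"}, {"C"}, {"Y"}])
reference = build_reference(proteome, scheme)
params = SequencingParams.create(3)

training = generate_training_set(reference, 1000, params, rng)
index = KnnIndex(training, params)
models = build_models(reference, params)
test = generate_test_set(reference, 500, params, rng)
print(f"reference: {len(reference)} dye seqs; "
      f"training: {len(index)} unique dye tracks; test: {len(test)} reads")

for name, run in [
    ("kNN (k=10, sigma=0.5)",
     lambda: classify_knn_batch(index, test.intensities, KnnConfig(), truth=test.truth)),
    ("full Bayes (cutoff=5)",
     lambda: classify_bayes_batch(test.intensities, models, cutoff=5.0, truth=test.truth)),
    ("hybrid (k=10000, h=1000)",
     lambda: classify_hybrid_batch(test.intensities, index, models, HybridConfig(),
                                   truth=test.truth)),
]:
    t0 = time.perf_counter()
    prms = run()
    dt = time.perf_counter() - t0
    acc = np.mean([p.correct for p in prms])
    print(f"{name:28s} accuracy {acc:.3f}   {dt:6.2f} s")
print("accuracy = fraction of reads whose top-scoring dye sequence is the")
print("one that generated them; the hybrid should track the full Bayes.")
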