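"""Shared fixtures: a synthetic 20-protein benchmark (trypsin digestion,
three-color D/E, C, Y labeling, default error rates) with simulated
training and test data, reused across the classifier tests."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fluoroseq.hmm import build_models
from fluoroseq.knn import KnnIndex
from fluoroseq.params import SequencingParams
from fluoroseq.proteome import LabelScheme, build_reference
from fluoroseq.simulator import generate_test_set, generate_training_set
from fluoroseq.synthetic import random_proteome

# master seed for all benchmark fixtures; individual streams are spawned
MASTER_SEED = 20230530


def spawn_rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([MASTER_SEED, *key]))


@pytest.fixture(scope="session")
def scheme3() -> LabelScheme:
    return LabelScheme("trypsin", [{"D", "E"}, {"C"}, {"Y"}])


@pytest.fixture(scope="session")
def default_params() -> SequencingParams:
    return SequencingParams.create(3)


@pytest.fixture(scope="session")
def ref20(scheme3):
    proteome = random_proteome(20, 300, spawn_rng(1))
    return build_reference(proteome, scheme3)


@pytest.fixture(scope="session")
def models20(ref20, default_params):
    return build_models(ref20, default_params)


@pytest.fixture(scope="session")
def train20(ref20, default_params):
    return generate_training_set(ref20, 1000, default_params, spawn_rng(2))


@pytest.fixture(scope="session")
def index20(train20, default_params):
    return KnnIndex(train20, default_params)


@pytest.fixture(scope="session")
def test20_10k(ref20, default_params):
    return generate_test_set(ref20, 10_000, default_params, spawn_rng(3))


@pytest.fixture(scope="session")
def bayes1k_cut5(models20, test20_10k):
    """Full-reference Bayesian matches, prune cutoff 5, first 1000 reads."""
    from fluoroseq.hmm import classify_bayes_batch

    return classify_bayes_batch(
        test20_10k.intensities[:1000], models20, cutoff=5.0,
        truth=test20_10k.truth[:1000],
    )


@pytest.fixture(scope="session")
def bayes1k_nocut(models20, test20_10k):
    """Full-reference Bayesian matches without pruning, first 1000 reads."""
    from fluoroseq.hmm import classify_bayes_batch

    return classify_bayes_batch(
        test20_10k.intensities[:1000], models20, cutoff=None,
        truth=test20_10k.truth[:1000],
    )


@pytest.fixture(scope="session")
def hybrid10k(index20, models20, test20_10k):
    """Hybrid matches at default settings on all 10,000 reads."""
    from fluoroseq.hybrid import HybridConfig, classify_hybrid_batch

    return classify_hybrid_batch(
        test20_10k.intensities, index20, models20, HybridConfig(),
        truth=test20_10k.truth,
    )


@pytest.fixture(scope="session")
def bench100(scheme3, default_params):
    """100-protein experiment for peptide/protein roll-up: reference,
    training index, test reads and hybrid matches."""
    from fluoroseq.hybrid import HybridConfig, classify_hybrid_batch

    proteome = random_proteome(100, 300, spawn_rng(4))
    ref = build_reference(proteome, scheme3)
    train = generate_training_set(ref, 1000, default_params, spawn_rng(5))
    index = KnnIndex(train, default_params)
    models = build_models(ref, default_params)
    test = generate_test_set(ref, 3000, default_params, spawn_rng(6))
    prms = classify_hybrid_batch(
        test.intensities, index, models, HybridConfig(), truth=test.truth
    )
    return ref, test, prms
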