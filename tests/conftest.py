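import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqlda import (
    AnalysisConfig,
    classify_reading_frames,
    fit_lda,
    pool_samples,
    simulate_cds,
    skewed_codon_weights,
    topic_label_scores,
)
from seqlda.features import build_frame_matrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def run_frame_pipeline(
    pack: int,
    seed: int,
    n_train: int = 3000,
    n_test: int = 500,
    n_codons=(100, 300),
    k: int = 6,
):
    """Simulate CDS, fit a 3-topic frame model, classify held-out sequences.

    Returns (accuracy, model, scores, test records).
    """
    w = skewed_codon_weights(seed=0)
    train = simulate_cds(w, n_train, n_codons, seed=seed)
    test = simulate_cds(w, n_test, n_codons, seed=seed + 1000, id_prefix="test")
    m, labels = build_frame_matrix(train, k)
    pooled, plabels = pool_samples(m, labels, pack, seed=seed)
    cfg = AnalysisConfig(k=k, pack=pack, n_topics=3, seed=seed)
    model, mem = fit_lda(pooled, cfg, n_init=3)
    scores = topic_label_scores(mem, plabels)
    preds = [
        classify_reading_frames(r.seq, model, scores, k, sequence_id=r.id)
        for r in test
    ]
    acc = float(np.mean([p.all_correct for p in preds]))
    return acc, model, scores, test


@pytest.fixture(scope="session")
def frame_pipeline_small():
    """A quick, smaller frame pipeline shared by unit tests."""
    return run_frame_pipeline(pack=10, seed=7, n_train=300, n_test=60, n_codons=(60, 120))
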