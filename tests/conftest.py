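import numpy as np
import pytest

from pigcough.backbone import embed_corpus
from pigcough.config import RunConfig, stage_seed
from pigcough.experiment import build_backbone, extract_features
from pigcough.metrics import onehot_to_int, stratified_split
from pigcough.synth import generate_segments

RUN_SEED = 7


@pytest.fixture(scope="session")
def small_corpus():
    """16 cough + 24 noise clips with Log-Mel features, for fast unit tests."""
    segments, _ = generate_segments(16, 24, master_seed=11)
    batch = extract_features(segments)
    return batch


@pytest.fixture(scope="session")
def study_corpus():
    """The default-scale study corpus (107 cough / 590 noise) with features,
    frozen-backbone embeddings and the 85:15 partition.  Session-scoped:
    the backbone embedding pass is the expensive step and is shared."""
    cfg = RunConfig(run_seed=RUN_SEED)
    segments, _ = generate_segments(
        cfg.synthesis.n_cough, cfg.synthesis.n_noise,
        master_seed=stage_seed(RUN_SEED, "corpus"))
    batch = extract_features(segments, cfg)
    y = onehot_to_int(batch.labels)
    tv_idx, test_idx = stratified_split(y, cfg.evaluation.test_frac,
                                        seed=stage_seed(RUN_SEED, "split"))
    weights = build_backbone(cfg, batch.tensor[tv_idx],
                             seed=stage_seed(RUN_SEED, "backbone"))
    g14 = embed_corpus(batch.tensor, weights, cfg.backbone)
    return {"cfg": cfg, "features": batch.tensor, "labels": batch.labels,
            "y": y, "tv_idx": tv_idx, "test_idx": test_idx,
            "weights": weights, "g14": g14}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
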