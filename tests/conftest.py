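"""Shared fixtures: synthetic corpora and trained tiny models.

Expensive fixtures (corpus generation, training runs) are session-scoped
so several tests can share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ssrnet.model import ModelConfig, SSRNet
from ssrnet.synthdata import SynthSpec, generate_corpus, generate_utterance
from ssrnet.toneme import build_inventory
from ssrnet.training import TrainConfig, prepare_corpus, train


@pytest.fixture(scope="session")
def corpus50():
    """50-utterance synthetic corpus with prepared train/val/test splits."""
    spec = SynthSpec(seed=11, n_utterances=50)
    corpus = generate_corpus(spec)
    syllables = sorted(
        {s for split in ("train", "val", "test") for u in corpus[split] for s in u.transcript}
    )
    inventory = build_inventory(syllables)
    tr, norm = prepare_corpus(corpus["train"], inventory)
    va, _ = prepare_corpus(corpus["val"], inventory, norm)
    te, _ = prepare_corpus(corpus["test"], inventory, norm)
    return {
        "raw": corpus,
        "inventory": inventory,
        "train": tr,
        "val": va,
        "test": te,
        "norm": norm,
    }


@pytest.fixture(scope="session")
def trained_tiny(corpus50):
    """Tiny-configuration model trained on the 50-utterance corpus."""
    cfg = ModelConfig.tiny(inventory_size=len(corpus50["inventory"]), seed=0)
    model = SSRNet(cfg)
    tc = TrainConfig(batch_size=8, step_w=200, max_epochs=100, seed=0)
    model, log = train(
        corpus50["train"], model, tc, val_corpus=corpus50["val"]
    )
    return {"model": model, "log": log, "train_cfg": tc}


@pytest.fixture(scope="session")
def overfit_run():
    """Tiny model overfit on 5 synthetic utterances (single-batch steps)."""
    spec = SynthSpec(seed=1)
    samples = [generate_utterance(spec, seed=100 + i) for i in range(5)]
    inventory = build_inventory(sorted({s for u in samples for s in u.transcript}))
    prepped, norm = prepare_corpus(samples, inventory)
    cfg = ModelConfig.tiny(inventory_size=len(inventory), seed=0)
    model = SSRNet(cfg)
    tc = TrainConfig(batch_size=5, step_w=200, max_epochs=800, seed=0)
    model, log = train(prepped, model, tc)
    return {"model": model, "log": log, "corpus": prepped, "norm": norm}


def toneme_accuracy(model: SSRNet, corpus, exclude_sil: bool = True) -> float:
    """Frame-level toneme accuracy with ground-truth-duration length matching."""
    ok = tot = 0
    for u in corpus:
        out = model.forward_train(u.X, u.durations, training=False)
        pred = np.argmax(out.toneme_logits.data, axis=1)
        mask = u.tm_ids != 0 if exclude_sil else np.ones_like(u.tm_ids, bool)
        ok += int(np.sum(pred[mask] == u.tm_ids[mask]))
        tot += int(mask.sum())
    return ok / tot
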