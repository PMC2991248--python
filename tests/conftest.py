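"""Shared fixtures: small synthetic cohorts and a trained model bundle."""

from __future__ import annotations

import numpy as np
import pytest

from bpscan.agez import BPCandidate
from bpscan.motif import fit_mm1
from bpscan.ppt import find_ppts
from bpscan.predictor import (
    ModelBundle,
    extract_features,
    sample_negatives,
    train,
)
from bpscan.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """300 synthetic introns with truth (used by several test modules)."""
    cfg = GeneratorConfig(seed=7, n_introns=300)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def trained_bundle(small_cohort):
    """A model bundle trained on the small synthetic cohort."""
    cfg, records, truth = small_cohort
    by_id = {r.id: r for r in records}
    positives = list(truth.ninemer)
    exclude = set(zip(truth.intron_id, truth.bp_pos))
    negs = sample_negatives(records, len(positives), seed=99, exclude=exclude)
    negatives = [nm for _, _, nm in negs]
    pos_mm1 = fit_mm1(positives)
    neg_mm1 = fit_mm1(negatives)
    tracts = {}

    def feats(intron, pos, nm):
        if intron.id not in tracts:
            tracts[intron.id] = find_ppts(intron.sequence[-500:])
        cand = BPCandidate(ninemer=nm, bp_pos=pos)
        return extract_features(
            cand, intron, tracts[intron.id], pos_mm1, neg_mm1
        ).as_array()

    Xp = np.array(
        [
            feats(by_id[i], p, nm)
            for i, p, nm in zip(truth.intron_id, truth.bp_pos, truth.ninemer)
        ]
    )
    Xn = np.array([feats(by_id[i], p, nm) for i, p, nm in negs])
    svm = train(Xp, Xn, seed=99)
    return ModelBundle(pos_mm1=pos_mm1, neg_mm1=neg_mm1, svm=svm)
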