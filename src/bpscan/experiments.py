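"""Self-contained evaluation experiments on synthetic data.

These drive both the test suite and the results-reproduction script: they
generate a synthetic cohort with planted truth, train the models exactly as
the prediction pipeline prescribes, and measure recovery and discrimination
statistics from scratch.
"""

from __future__ import annotations

import numpy as np

from .agez import BPCandidate, tna_pentamer_patterns
from .compare import evaluate, hamming_rank
from .motif import fit_frequency_model, fit_mm1, mm1_score, pwm_score
from .ppt import find_ppts
from .predictor import (
    ModelBundle,
    cross_validate,
    extract_features,
    predict_intron,
    sample_negatives,
    train,
)
from .synthetic import (
    GeneratorConfig,
    generate_alignment_dataset,
    generate_dataset,
    planted_pentamer_counts,
)
from .trainset import classify_all, collect_profiles


def planted_recovery_experiment(
    seed: int,
    n_introns: int = 5000,
    cv_folds: int = 10,
    kernel: str = "linear",
) -> dict:
    """Train on a synthetic cohort and measure planted-BP recovery.

    Returns top-1 recovery of the planted branch points, baseline
    sensitivities (consensus Hamming search and PWM ranking in the AGEZ),
    the Fig-6B-style category counts, and k-fold cross-validated
    accuracy/AUC of the SVM against MM1-only and PWM-only scoring.
    """
    cfg = GeneratorConfig(seed=seed, n_introns=n_introns)
    records, truth = generate_dataset(cfg)
    by_id = {r.id: r for r in records}

    positives = list(truth.ninemer)
    exclude = set(zip(truth.intron_id, truth.bp_pos))
    neg_seed = (seed + 1) % 2**31
    negs = sample_negatives(records, len(positives), seed=neg_seed, exclude=exclude)
    negatives = [nm for _, _, nm in negs]

    pos_mm1 = fit_mm1(positives)
    neg_mm1 = fit_mm1(negatives)
    pos_pwm = fit_frequency_model(positives)
    neg_pwm = fit_frequency_model(negatives)

    tract_cache: dict[str, list] = {}

    def tracts(rec):
        if rec.id not in tract_cache:
            tract_cache[rec.id] = find_ppts(rec.sequence[-500:])
        return tract_cache[rec.id]

    def entry(rec, pos, nm):
        cand = BPCandidate(ninemer=nm, bp_pos=pos)
        fv = extract_features(cand, rec, tracts(rec), pos_mm1, neg_mm1)
        return (nm, fv.py_content, fv.ppt_distance, fv.ppt_score)

    pos_entries = [
        entry(by_id[i], p, nm)
        for i, p, nm in zip(truth.intron_id, truth.bp_pos, truth.ninemer)
    ]
    neg_entries = [entry(by_id[i], p, nm) for i, p, nm in negs]

    def matrix(entries):
        return np.array(
            [[mm1_score(pos_mm1, neg_mm1, e[0]), e[1], e[2], e[3]] for e in entries]
        )

    svm = train(matrix(pos_entries), matrix(neg_entries), kernel=kernel, seed=neg_seed)
    bundle = ModelBundle(
        pos_mm1=pos_mm1, neg_mm1=neg_mm1, svm=svm, pos_pwm=pos_pwm, neg_pwm=neg_pwm
    )

    truth_map = {i: [p] for i, p in zip(truth.intron_id, truth.bp_pos)}
    svm_preds: dict[str, list[int]] = {}
    pwm_preds: dict[str, list[int]] = {}
    ham_preds: dict[str, list[int]] = {}
    categories: dict[str, int] = {}
    for rec in records:
        pred = predict_intron(rec, bundle)
        categories[pred.category] = categories.get(pred.category, 0) + 1
        svm_preds[rec.id] = [c.bp_pos for c in pred.candidates[:1]]
        ranked = sorted(
            pred.candidates,
            key=lambda c: (-pwm_score(pos_pwm, neg_pwm, c.ninemer), -c.bp_pos),
        )
        pwm_preds[rec.id] = [c.bp_pos for c in ranked[:1]]
        ham_preds[rec.id] = [
            h.bp_pos for h in hamming_rank(rec, window=100, max_distance=2)[:1]
        ]

    res_svm = evaluate(svm_preds, truth_map)
    res_pwm = evaluate(pwm_preds, truth_map)
    res_ham = evaluate(ham_preds, truth_map)
    cv = cross_validate(
        pos_entries, neg_entries, n_folds=cv_folds, kernel=kernel, seed=neg_seed
    )

    return {
        "n_introns": n_introns,
        "top1_recovery": res_svm.sensitivity,
        "sensitivity_pwm_agez": res_pwm.sensitivity,
        "sensitivity_hamming100": res_ham.sensitivity,
        "categories": categories,
        "positive_scoring_fraction": categories.get("positive_scoring", 0) / n_introns,
        "accuracy_svm": cv["accuracy_svm"][0],
        "accuracy_svm_sd": cv["accuracy_svm"][1],
        "auc_svm": cv["auc_svm"][0],
        "auc_svm_sd": cv["auc_svm"][1],
        "auc_mm1": cv["auc_mm1"][0],
        "auc_mm1_sd": cv["auc_mm1"][1],
        "auc_pwm": cv["auc_pwm"][0],
        "auc_pwm_sd": cv["auc_pwm"][1],
        "n_cv": 2 * len(pos_entries),
    }


def pentamer_recovery_experiment(
    seed: int,
    n_blocks: int = 2000,
    alpha: float = 0.001,
    min_family_count: int = 20,
) -> dict:
    """Classify the TNA pentamer space on synthetic alignment blocks.

    The planted family is the set of pentamers planted at least
    ``min_family_count`` times (below that, positional tests lack power by
    design); background pentamers are those never planted.  Reports the
    fraction of each group labelled branch-point-associated.
    """
    cfg = GeneratorConfig(seed=seed, n_introns=n_blocks)
    blocks, truths = generate_alignment_dataset(cfg)
    counts = planted_pentamer_counts(truths)
    profiles = collect_profiles(blocks)
    labels = classify_all(profiles, alpha=alpha)

    family = sorted(p for p, c in counts.items() if c >= min_family_count)
    background = sorted(set(tna_pentamer_patterns()) - set(counts))
    family_bp = sum(1 for p in family if labels[p] == "bp")
    background_bp = sum(1 for p in background if labels[p] == "bp")
    return {
        "n_blocks": n_blocks,
        "n_family": len(family),
        "n_background": len(background),
        "family_bp_recovery": family_bp / len(family) if family else float("nan"),
        "background_bp_rate": background_bp / len(background)
        if background
        else float("nan"),
        "labels": labels,
    }
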