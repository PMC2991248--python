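"""Branch-point prediction: features, SVM training and per-intron ranking.

Every candidate is described by four features: the MM1 log-odds of its
9-mer, the pyrimidine content between the branch adenosine and the 3SS
(excluding the 3SS AG), and the distance to / score of the closest
downstream polypyrimidine tract.  A support vector machine trained on
balanced positive/negative sets turns these into a single score; its sign
at the zero threshold is the predicted label and its magnitude the
confidence.  Candidates are searched in the first AG exclusion zone and
ranked by SVM score, ties going to the candidate closest to the 3SS.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from sklearn.svm import SVC

from .agez import AGEZ, BPCandidate, enumerate_candidates, find_agez
from .motif import (
    FrequencyModel,
    MM1Model,
    fit_frequency_model,
    fit_mm1,
    load_model,
    mm1_score,
    pwm_score,
    save_model,
)
from .ppt import NO_PPT_SENTINEL, PPTTract, closest_downstream_ppt, find_ppts
from .seqio import IntronRecord

FEATURE_NAMES = ("motif_score", "py_content", "ppt_distance", "ppt_score")

CATEGORIES = ("no_candidates", "none_in_agez", "negative_scoring", "positive_scoring")

#: Predicted branch points beyond this distance from the 3SS are "distant"
#: (about 4 times the average BP-3SS distance).
DISTANT_BP_THRESHOLD = 100


@dataclass
class FeatureVector:
    motif_score: float
    py_content: float
    ppt_distance: float
    ppt_score: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.motif_score, self.py_content, self.ppt_distance, self.ppt_score],
            dtype=float,
        )


def extract_features(
    candidate: BPCandidate,
    intron: Union[IntronRecord, str],
    tracts: Sequence[PPTTract],
    pos_model: MM1Model,
    neg_model: MM1Model,
    sentinel: int = NO_PPT_SENTINEL,
) -> FeatureVector:
    """Compute the four SVM features for one candidate (also stored on it).

    Pyrimidine content is taken over the open-ended interval between the
    branch adenosine and the 3SS AG, i.e. positions (bp_pos, -3]; N bases
    are excluded from the denominator.
    """
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    L = len(seq)
    motif = mm1_score(pos_model, neg_model, candidate.ninemer)
    gap = seq[L + candidate.bp_pos + 1 : L - 2]
    informative = [c for c in gap if c != "N"]
    py = (
        sum(1 for c in informative if c in "CT") / len(informative)
        if informative
        else 0.0
    )
    dist, score = closest_downstream_ppt(candidate, tracts, sentinel)
    fv = FeatureVector(motif, py, dist, score)
    candidate.motif_score = motif
    candidate.py_content = py
    candidate.ppt_distance = dist
    candidate.ppt_score = score
    return fv


def sample_negatives(
    introns: Sequence[Union[IntronRecord, str]],
    n: int,
    seed: int,
    exclude: Optional[set] = None,
    region_n: int = 500,
    min_dist: int = 15,
) -> list[tuple[str, int, str]]:
    """Sample negative 9-mers: random canonical TNA nonamers from the introns.

    The pool is every canonical candidate in the last ``region_n`` nt of
    every intron, minus the excluded (intron_id, bp_pos) positives; ``n``
    are drawn without replacement, reproducibly for a fixed seed.
    """
    exclude = exclude or set()
    pool: list[tuple[str, int, str]] = []
    for k, intron in enumerate(introns):
        iid = intron.id if isinstance(intron, IntronRecord) else f"intron{k}"
        seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
        lo = -min(region_n, len(seq))
        for cand in enumerate_candidates(seq, region=(lo, -min_dist), min_dist=min_dist):
            if (iid, cand.bp_pos) not in exclude:
                pool.append((iid, cand.bp_pos, cand.ninemer))
    if len(pool) < n:
        raise ValueError(f"negative pool of size {len(pool)} smaller than n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


@dataclass
class SVMModel:
    """A trained SVM with feature standardization, serializable to JSON.

    The decision function is re-implemented in numpy from the extracted
    parameters, so scoring is deterministic and a saved model is portable
    plain text.  The decision threshold is 0: positive scores are predicted
    branch points.
    """

    kernel: str
    C: float
    gamma: Optional[float]
    mean: np.ndarray
    scale: np.ndarray
    intercept: float
    coef: Optional[np.ndarray] = None  # linear kernel
    support_vectors: Optional[np.ndarray] = None  # rbf kernel
    dual_coef: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.mean) / self.scale
        if self.kernel == "linear":
            return Z @ self.coef + self.intercept
        if self.kernel == "rbf":
            d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
            return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept
        raise ValueError(f"unsupported kernel {self.kernel!r}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def to_dict(self) -> dict:
        d = {
            "format": "bpscan-svm",
            "version": 1,
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "intercept": self.intercept,
            "metadata": self.metadata,
        }
        if self.coef is not None:
            d["coef"] = self.coef.tolist()
        if self.support_vectors is not None:
            d["support_vectors"] = self.support_vectors.tolist()
            d["dual_coef"] = self.dual_coef.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SVMModel":
        if d.get("format") != "bpscan-svm" or d.get("version") != 1:
            raise ValueError("unsupported SVM model file")
        return cls(
            kernel=d["kernel"],
            C=float(d["C"]),
            gamma=None if d.get("gamma") is None else float(d["gamma"]),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            intercept=float(d["intercept"]),
            coef=None if "coef" not in d else np.asarray(d["coef"], dtype=float),
            support_vectors=None
            if "support_vectors" not in d
            else np.asarray(d["support_vectors"], dtype=float),
            dual_coef=None
            if "dual_coef" not in d
            else np.asarray(d["dual_coef"], dtype=float),
            metadata=d.get("metadata", {}),
        )


def train(
    features_pos: Union[np.ndarray, Sequence[FeatureVector]],
    features_neg: Union[np.ndarray, Sequence[FeatureVector]],
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> SVMModel:
    """Balanced SVM training with feature standardization.

    The majority class is randomly downsampled (seeded) so both classes
    contribute equally; features are standardized to mean 0 / sd 1 on the
    training set and the statistics stored in the model.
    """
    Xp = _to_matrix(features_pos)
    Xn = _to_matrix(features_neg)
    if len(Xp) == 0 or len(Xn) == 0:
        raise ValueError("both positive and negative classes must be non-empty")
    if not (np.isfinite(Xp).all() and np.isfinite(Xn).all()):
        raise ValueError("features must be finite")
    rng = np.random.default_rng(seed)
    m = min(len(Xp), len(Xn))
    if len(Xp) > m:
        Xp = Xp[np.sort(rng.choice(len(Xp), size=m, replace=False))]
    if len(Xn) > m:
        Xn = Xn[np.sort(rng.choice(len(Xn), size=m, replace=False))]
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(m), np.zeros(m)])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    svc = SVC(kernel=kernel, C=C, gamma="scale", random_state=seed)
    svc.fit(Z, y)
    gamma = float(svc._gamma) if kernel == "rbf" else None
    meta = {"seed": seed, "n_pos": int(m), "n_neg": int(m)}
    if kernel == "linear":
        return SVMModel(
            kernel=kernel,
            C=C,
            gamma=None,
            mean=mean,
            scale=scale,
            intercept=float(svc.intercept_[0]),
            coef=svc.coef_.ravel().astype(float),
            metadata=meta,
        )
    return SVMModel(
        kernel=kernel,
        C=C,
        gamma=gamma,
        mean=mean,
        scale=scale,
        intercept=float(svc.intercept_[0]),
        support_vectors=svc.support_vectors_.astype(float),
        dual_coef=svc.dual_coef_.ravel().astype(float),
        metadata=meta,
    )


def _to_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features.astype(float))
    return np.array([f.as_array() for f in features], dtype=float)


@dataclass
class ModelBundle:
    """The trained models needed to score an intron, savable as a directory."""

    pos_mm1: MM1Model
    neg_mm1: MM1Model
    svm: SVMModel
    pos_pwm: Optional[FrequencyModel] = None
    neg_pwm: Optional[FrequencyModel] = None
    ppt_weights: Optional[dict] = None
    sentinel: int = NO_PPT_SENTINEL

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_model(self.pos_mm1, directory / "mm1_pos.json")
        save_model(self.neg_mm1, directory / "mm1_neg.json")
        if self.pos_pwm is not None:
            save_model(self.pos_pwm, directory / "pwm_pos.json")
            save_model(self.neg_pwm, directory / "pwm_neg.json")
        with open(directory / "svm.json", "w") as fh:
            json.dump(self.svm.to_dict(), fh, indent=1)
        meta = {
            "format": "bpscan-bundle",
            "version": 1,
            "sentinel": self.sentinel,
            "ppt_weights": self.ppt_weights,
        }
        with open(directory / "bundle.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        with open(directory / "bundle.json") as fh:
            meta = json.load(fh)
        if meta.get("format") != "bpscan-bundle" or meta.get("version") != 1:
            raise ValueError(f"{directory}: not a compatible model bundle")
        with open(directory / "svm.json") as fh:
            svm = SVMModel.from_dict(json.load(fh))
        pwm_pos = pwm_neg = None
        if (directory / "pwm_pos.json").exists():
            pwm_pos = load_model(directory / "pwm_pos.json")
            pwm_neg = load_model(directory / "pwm_neg.json")
        return cls(
            pos_mm1=load_model(directory / "mm1_pos.json"),
            neg_mm1=load_model(directory / "mm1_neg.json"),
            svm=svm,
            pos_pwm=pwm_pos,
            neg_pwm=pwm_neg,
            ppt_weights=meta.get("ppt_weights"),
            sentinel=int(meta.get("sentinel", NO_PPT_SENTINEL)),
        )


def train_bundle(
    positives: Sequence[str],
    negatives: Sequence[str],
    features_pos,
    features_neg,
    kernel: str = "linear",
    C: float = 1.0,
    pseudocount: float = 1.0,
    seed: int = 0,
    ppt_weights: Optional[dict] = None,
) -> ModelBundle:
    """Fit MM1 positive/negative models plus the SVM in one step."""
    return ModelBundle(
        pos_mm1=fit_mm1(positives, pseudocount=pseudocount),
        neg_mm1=fit_mm1(negatives, pseudocount=pseudocount),
        pos_pwm=fit_frequency_model(positives, pseudocount=pseudocount),
        neg_pwm=fit_frequency_model(negatives, pseudocount=pseudocount),
        svm=train(features_pos, features_neg, kernel=kernel, C=C, seed=seed),
        ppt_weights=ppt_weights,
    )


@dataclass
class IntronPrediction:
    """Per-intron outcome: category, ranked AGEZ candidates, best hit."""

    intron_id: str
    category: str
    candidates: list[BPCandidate]
    best: Optional[BPCandidate]
    is_distant: bool
    agez: Optional[AGEZ] = None

    @property
    def bp_pos(self) -> Optional[int]:
        return None if self.best is None else self.best.bp_pos


def _score_candidates(
    intron: Union[IntronRecord, str],
    candidates: list[BPCandidate],
    bundle: ModelBundle,
    tracts: Sequence[PPTTract],
) -> None:
    if not candidates:
        return
    fvs = [
        extract_features(
            c, intron, tracts, bundle.pos_mm1, bundle.neg_mm1, bundle.sentinel
        )
        for c in candidates
    ]
    X = np.array([f.as_array() for f in fvs])
    scores = bundle.svm.decision_function(X)
    for c, s in zip(candidates, scores):
        c.svm_score = float(s)


def _tracts_for(intron, bundle: ModelBundle, scan_n: int) -> list[PPTTract]:
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    window = seq[-min(scan_n, len(seq)) :]
    return find_ppts(window, weights=bundle.ppt_weights)


def predict_intron(
    intron: Union[IntronRecord, str],
    bundle: ModelBundle,
    grace: int = 12,
    min_dist: int = 15,
    scan_n: int = 500,
    max_extent: int = 500,
    distant_threshold: int = DISTANT_BP_THRESHOLD,
) -> IntronPrediction:
    """Predict the branch point of one intron.

    Candidates in the last ``scan_n`` nt determine whether the intron has
    any canonical 9-mer at all; the prediction itself is the top-ranked
    candidate inside the first AGEZ.  Categories partition the introns:
    ``no_candidates``, ``none_in_agez``, ``negative_scoring`` and
    ``positive_scoring``.
    """
    iid = intron.id if isinstance(intron, IntronRecord) else "<intron>"
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    L = len(seq)
    lo = -min(scan_n, L)
    scan_cands = enumerate_candidates(seq, region=(lo, -min_dist), min_dist=min_dist)
    if not scan_cands:
        return IntronPrediction(iid, "no_candidates", [], None, False)
    zone = find_agez(seq, grace=grace, max_extent=max_extent)
    in_zone = [c for c in scan_cands if c.bp_pos in zone]
    if not in_zone:
        return IntronPrediction(iid, "none_in_agez", [], None, False, agez=zone)
    tracts = _tracts_for(intron, bundle, scan_n)
    _score_candidates(intron, in_zone, bundle, tracts)
    ranked = sorted(in_zone, key=lambda c: (-c.svm_score, -c.bp_pos))
    for r, c in enumerate(ranked, 1):
        c.rank = r
    best = ranked[0]
    category = "positive_scoring" if best.svm_score > 0 else "negative_scoring"
    return IntronPrediction(
        iid,
        category,
        ranked,
        best,
        is_distant=best.bp_pos < -distant_threshold,
        agez=zone,
    )


def scan_last_n(
    intron: Union[IntronRecord, str],
    bundle: ModelBundle,
    n: int = 500,
    min_dist: int = 15,
) -> list[BPCandidate]:
    """Score every canonical candidate in the last ``n`` nt (no AGEZ limit).

    Introns shorter than ``n`` are scanned in full.  Candidates are
    returned 5'->3'.
    """
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    lo = -min(n, len(seq))
    cands = enumerate_candidates(seq, region=(lo, -min_dist), min_dist=min_dist)
    tracts = _tracts_for(intron, bundle, n)
    _score_candidates(intron, cands, bundle, tracts)
    return cands


def position_histogram(
    predictions: Iterable[IntronPrediction], anchor: str = "3ss"
) -> dict[int, int]:
    """Counts of best-candidate positions, anchored at the 3SS or at the
    AGEZ-defining AG (position of the branch A minus the defining AG's A)."""
    if anchor not in ("3ss", "defining_ag"):
        raise ValueError(f"unknown anchor {anchor!r}")
    hist: dict[int, int] = {}
    for pred in predictions:
        if pred.best is None:
            continue
        pos = pred.best.bp_pos
        if anchor == "defining_ag":
            if pred.agez is None or pred.agez.defining_ag is None:
                continue
            pos = pos - pred.agez.defining_ag
        hist[pos] = hist.get(pos, 0) + 1
    return dict(sorted(hist.items()))


def cross_validate(
    entries_pos: Sequence[tuple],
    entries_neg: Sequence[tuple],
    n_folds: int = 10,
    kernel: str = "linear",
    C: float = 1.0,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> dict:
    """K-fold cross-validation of the SVM against MM1-only and PWM-only.

    Each entry is ``(ninemer, py_content, ppt_distance, ppt_score)``.  Per
    fold, MM1 and PWM positive/negative models are refit on the training
    split (so the motif feature never sees test 9-mers), the SVM is trained
    on the four features, and AUC/accuracy are measured on the held-out
    split for all three scoring schemes.  Returns mean and sd across folds.
    """
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    pos = list(entries_pos)
    neg = list(entries_neg)
    fold_pos = rng.permuted(np.arange(len(pos))) % n_folds
    fold_neg = rng.permuted(np.arange(len(neg))) % n_folds
    aucs = {"svm": [], "mm1": [], "pwm": []}
    accs = []
    for f in range(n_folds):
        tr_p = [pos[i] for i in range(len(pos)) if fold_pos[i] != f]
        te_p = [pos[i] for i in range(len(pos)) if fold_pos[i] == f]
        tr_n = [neg[i] for i in range(len(neg)) if fold_neg[i] != f]
        te_n = [neg[i] for i in range(len(neg)) if fold_neg[i] == f]
        pos_mm1 = fit_mm1([e[0] for e in tr_p], pseudocount=pseudocount)
        neg_mm1 = fit_mm1([e[0] for e in tr_n], pseudocount=pseudocount)
        pos_pwm = fit_frequency_model([e[0] for e in tr_p], pseudocount=pseudocount)
        neg_pwm = fit_frequency_model([e[0] for e in tr_n], pseudocount=pseudocount)

        def feats(entries):
            return np.array(
                [
                    [mm1_score(pos_mm1, neg_mm1, e[0]), e[1], e[2], e[3]]
                    for e in entries
                ]
            )

        Xtr = np.vstack([feats(tr_p), feats(tr_n)])
        ytr = np.r_[np.ones(len(tr_p)), np.zeros(len(tr_n))]
        Xte = np.vstack([feats(te_p), feats(te_n)])
        yte = np.r_[np.ones(len(te_p)), np.zeros(len(te_n))]
        model = train(Xtr[ytr == 1], Xtr[ytr == 0], kernel=kernel, C=C, seed=seed)
        dec = model.decision_function(Xte)
        aucs["svm"].append(roc_auc_score(yte, dec))
        accs.append(float(np.mean((dec > 0) == (yte == 1))))
        aucs["mm1"].append(roc_auc_score(yte, Xte[:, 0]))
        pwm_sc = np.array(
            [pwm_score(pos_pwm, neg_pwm, e[0]) for e in list(te_p) + list(te_n)]
        )
        aucs["pwm"].append(roc_auc_score(yte, pwm_sc))
    return {
        "accuracy_svm": (float(np.mean(accs)), float(np.std(accs))),
        "auc_svm": (float(np.mean(aucs["svm"])), float(np.std(aucs["svm"]))),
        "auc_mm1": (float(np.mean(aucs["mm1"])), float(np.std(aucs["mm1"]))),
        "auc_pwm": (float(np.mean(aucs["pwm"])), float(np.std(aucs["pwm"]))),
        "n_folds": n_folds,
    }
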