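"""Feature extraction, SVM training, per-intron prediction and ranking."""

import numpy as np
import pytest
from scipy import stats

from bpscan.agez import BPCandidate
from bpscan.motif import fit_mm1
from bpscan.ppt import find_ppts
from bpscan.predictor import (
    FEATURE_NAMES,
    SVMModel,
    extract_features,
    position_histogram,
    predict_intron,
    sample_negatives,
    scan_last_n,
    train,
)
from bpscan.seqio import IntronRecord


@pytest.fixture
def toy_models():
    pos = fit_mm1(["TACTAACAC", "TGCTAACAC", "TACTGACAC"])
    neg = fit_mm1(["AAATAAAAA", "CCCTCACCC", "GGGTGAGGG"])
    return pos, neg


class TestExtractFeatures:
    def test_all_pyrimidine_gap_gives_full_py_content(self, toy_models):
        pos, neg = toy_models
        # everything between the branch A and the 3SS AG is pyrimidine
        seq = "G" * 30 + "TACTAACTC" + "TTTCTTCT" + "CAG"
        intron = IntronRecord(id="x", sequence=seq)
        bp_pos = 35 - len(seq)  # index of the planted branch A
        cand = BPCandidate(ninemer="TACTAACTC", bp_pos=bp_pos)
        fv = extract_features(cand, intron, find_ppts(seq), pos, neg)
        assert fv.py_content == pytest.approx(1.0)

    def test_no_downstream_tract_returns_sentinel(self, toy_models):
        pos, neg = toy_models
        seq = "G" * 20 + "TACTAACAC" + "A" * 20 + "AG"
        cand = BPCandidate(ninemer="TACTAACAC", bp_pos=-26)
        fv = extract_features(cand, seq, find_ppts(seq), pos, neg)
        assert fv.ppt_distance == 500.0 and fv.ppt_score == 0.0

    def test_features_match_independent_recomputation(self, small_cohort, toy_models):
        cfg, records, truth = small_cohort
        pos, neg = toy_models
        from bpscan.motif import mm1_score
        from bpscan.ppt import closest_downstream_ppt

        for rec, (_, row) in list(zip(records, truth.iterrows()))[:100]:
            tracts = find_ppts(rec.sequence[-500:])
            cand = BPCandidate(ninemer=row.ninemer, bp_pos=row.bp_pos)
            fv = extract_features(cand, rec, tracts, pos, neg)
            # independent recomputation from first principles
            assert fv.motif_score == pytest.approx(mm1_score(pos, neg, row.ninemer))
            gap = rec.sequence[len(rec) + row.bp_pos + 1 : len(rec) - 2]
            assert fv.py_content == pytest.approx(
                sum(1 for c in gap if c in "CT") / len(gap)
            )
            d, s = closest_downstream_ppt(row.bp_pos, tracts)
            assert (fv.ppt_distance, fv.ppt_score) == (d, s)


class TestSampleNegatives:
    def test_fixed_seed_reproduces_sample(self, small_cohort):
        _, records, _ = small_cohort
        a = sample_negatives(records, 50, seed=5)
        b = sample_negatives(records, 50, seed=5)
        assert a == b
        c = sample_negatives(records, 50, seed=6)
        assert a != c

    def test_excluded_positions_never_sampled(self, small_cohort):
        _, records, truth = small_cohort
        exclude = set(zip(truth.intron_id, truth.bp_pos))
        sample = sample_negatives(records, 200, seed=5, exclude=exclude)
        assert all((iid, pos) not in exclude for iid, pos, _ in sample)

    def test_pool_smaller_than_n_is_an_error(self, small_cohort):
        _, records, _ = small_cohort
        with pytest.raises(ValueError, match="pool"):
            sample_negatives(records[:2], 10**6, seed=0)

    def test_sampling_is_uniform_over_pool(self):
        """Chi-square on repeated draws from a small pool."""
        introns = [IntronRecord(id=f"i{k}", sequence="G" * 30 + "TACTAACAC" + "G" * 13 + "AG")
                   for k in range(10)]
        counts = {}
        for s in range(300):
            for iid, pos, _ in sample_negatives(introns, 4, seed=s):
                counts[iid] = counts.get(iid, 0) + 1
        obs = np.array([counts.get(f"i{k}", 0) for k in range(10)])
        chi = stats.chisquare(obs)
        assert chi.pvalue > 1e-4  # not grossly non-uniform


class TestTrain:
    def test_separable_features_reach_training_accuracy_one(self, rng):
        Xp = rng.normal(5, 0.5, (60, 4))
        Xn = rng.normal(-5, 0.5, (60, 4))
        model = train(Xp, Xn, seed=0)
        assert (model.decision_function(Xp) > 0).all()
        assert (model.decision_function(Xn) < 0).all()

    def test_retraining_with_same_seed_is_deterministic(self, rng):
        Xp = rng.normal(1, 1, (80, 4))
        Xn = rng.normal(0, 1, (100, 4))  # majority class downsampled
        m1 = train(Xp, Xn, seed=3)
        m2 = train(Xp, Xn, seed=3)
        X = rng.normal(0, 1, (20, 4))
        assert np.allclose(m1.decision_function(X), m2.decision_function(X))
        assert m1.metadata["n_pos"] == m1.metadata["n_neg"] == 80

    def test_single_class_input_is_an_error(self, rng):
        X = rng.normal(0, 1, (10, 4))
        with pytest.raises(ValueError):
            train(X, np.empty((0, 4)))

    def test_json_round_trip_preserves_decisions(self, rng):
        for kernel in ("linear", "rbf"):
            Xp = rng.normal(1, 1, (50, 4))
            Xn = rng.normal(0, 1, (50, 4))
            m = train(Xp, Xn, kernel=kernel, seed=1)
            back = SVMModel.from_dict(m.to_dict())
            X = rng.normal(0, 1, (20, 4))
            assert np.allclose(back.decision_function(X), m.decision_function(X))


class TestPredictIntron:
    def test_intron_without_canonical_ninemer_has_no_candidates(self, trained_bundle):
        pred = predict_intron("C" * 80 + "AG", trained_bundle)
        assert pred.category == "no_candidates"
        assert pred.best is None and pred.candidates == []

    def test_candidates_outside_agez_only(self, trained_bundle):
        # canonical 9-mer far upstream, AG wall right after it
        seq = "C" * 30 + "TACTAACAC" + "CAGC" * 5 + "C" * 10 + "AG"
        pred = predict_intron(seq, trained_bundle)
        assert pred.category == "none_in_agez"
        assert pred.best is None

    def test_negative_scoring_still_reports_best(self, trained_bundle):
        # a weak candidate with no PPT anywhere: SVM should score it negative
        seq = "G" * 60 + "AG" + "GGGTGAGGG".replace("G", "A", 0) + "A" * 0
        seq = "G" * 40 + "AG" + "G" * 5 + "AATTAAAAA" + "A" * 12 + "AG"
        pred = predict_intron(seq, trained_bundle)
        if pred.category in ("negative_scoring", "positive_scoring"):
            assert pred.best is not None
            assert (pred.best.svm_score > 0) == (pred.category == "positive_scoring")

    def test_planted_branch_points_recovered_with_ranks(
        self, small_cohort, trained_bundle
    ):
        cfg, records, truth = small_cohort
        by_id = {r.id: r for r in records}
        hits = 0
        for _, row in truth.iterrows():
            pred = predict_intron(by_id[row.intron_id], trained_bundle)
            assert pred.category in ("positive_scoring", "negative_scoring")
            assert [c.rank for c in pred.candidates] == list(
                range(1, len(pred.candidates) + 1)
            )
            assert pred.candidates[0].svm_score == max(
                c.svm_score for c in pred.candidates
            )
            if pred.best.bp_pos == row.bp_pos:
                hits += 1
        assert hits / len(truth) > 0.7  # small-cohort sanity, looser than acceptance

    def test_ranking_invariant_under_candidate_order(self, trained_bundle):
        seq = ("C" * 40 + "TACTAACAC" + "CC" + "TGCTAACTT" + "TTTCTTTCTT" + "C" * 6 + "AG")
        pred1 = predict_intron(seq, trained_bundle)
        pred2 = predict_intron(seq, trained_bundle)
        assert [c.bp_pos for c in pred1.candidates] == [
            c.bp_pos for c in pred2.candidates
        ]

    def test_distant_flag_beyond_100nt(self, trained_bundle):
        seq = "C" * 200 + "TACTAACAC" + "TTTTCTTTTC" + ("CTTC" * 30) + "C" * 2 + "AG"
        pred = predict_intron(seq, trained_bundle)
        if pred.best is not None:
            assert pred.is_distant == (pred.best.bp_pos < -100)


class TestScanLastN:
    def test_short_intron_scanned_in_full(self, trained_bundle):
        seq = "C" * 20 + "TACTAACAC" + "TTTTTTTCT" + "C" * 4 + "AG"
        cands = scan_last_n(seq, trained_bundle, n=500)
        assert len(cands) >= 1
        assert all(c.svm_score is not None for c in cands)

    def test_scan_is_superset_of_agez_candidates(self, small_cohort, trained_bundle):
        _, records, _ = small_cohort
        for rec in records[:30]:
            scan = {c.bp_pos for c in scan_last_n(rec, trained_bundle)}
            pred = predict_intron(rec, trained_bundle)
            assert {c.bp_pos for c in pred.candidates} <= scan

    def test_counts_match_bruteforce(self, small_cohort, trained_bundle):
        _, records, _ = small_cohort
        for rec in records[:20]:
            seq = rec.sequence
            L = len(seq)
            expected = sum(
                1
                for i in range(max(5, L - 500), L - 14)
                if seq[i] == "A"
                and seq[i - 2] == "T"
                and i + 4 <= L
                and "N" not in seq[i - 5 : i + 4]
                and i - L <= -15
            )
            assert len(scan_last_n(rec, trained_bundle)) == expected


class TestPositionHistogram:
    def test_single_prediction_gives_unit_mass(self, small_cohort, trained_bundle):
        _, records, _ = small_cohort
        pred = predict_intron(records[0], trained_bundle)
        hist = position_histogram([pred])
        assert sum(hist.values()) == 1
        assert hist == {pred.best.bp_pos: 1}

    def test_anchor_switch_preserves_total(self, small_cohort, trained_bundle):
        _, records, _ = small_cohort
        preds = [predict_intron(r, trained_bundle) for r in records[:50]]
        h3 = position_histogram(preds, anchor="3ss")
        hd = position_histogram(preds, anchor="defining_ag")
        n_with_ag = sum(
            1
            for p in preds
            if p.best is not None
            and p.agez is not None
            and p.agez.defining_ag is not None
        )
        assert sum(h3.values()) == sum(1 for p in preds if p.best is not None)
        assert sum(hd.values()) == n_with_ag

    def test_mode_matches_planted_position_distribution(
        self, small_cohort, trained_bundle
    ):
        _, records, truth = small_cohort
        preds = [predict_intron(r, trained_bundle) for r in records]
        hist = position_histogram(preds)
        mode = max(hist, key=hist.get)
        assert -30 <= mode <= -18  # planted peak is at -24
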