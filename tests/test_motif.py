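"""Frequency/MM1 models, information content, mutual information, scores."""

import itertools
import json
import math

import numpy as np
import pytest

from bpscan.motif import (
    DEFAULT_CHAIN,
    FeatureUnavailableError,
    FrequencyModel,
    MM1Model,
    RNAcofoldBackend,
    fit_frequency_model,
    fit_mm1,
    information_content,
    load_model,
    mm1_score,
    mutual_information,
    pwm_score,
    save_model,
    u2_duplex_energy,
)

CANONICAL_SPACE = [
    c[0] + c[1] + c[2] + "T" + c[3] + "A" + c[4] + c[5] + c[6]
    for c in itertools.product("ACGT", repeat=7)
]


def _random_canonical(rng, n):
    idx = rng.integers(0, len(CANONICAL_SPACE), size=n)
    return [CANONICAL_SPACE[i] for i in idx]


class TestFrequencyModel:
    def test_probabilities_follow_pseudocount_arithmetic(self):
        m = fit_frequency_model(["AAATAAAAA", "AAATAAAAA"], pseudocount=1.0)
        # position 1: A seen twice -> (2+1)/(2+4), others 1/6
        assert m.probs[0][0] == pytest.approx(3 / 6)
        assert m.probs[0][1] == pytest.approx(1 / 6)

    def test_rows_sum_to_one(self, rng):
        m = fit_frequency_model(_random_canonical(rng, 50))
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_counts_equal_bruteforce_tally(self, rng):
        seqs = _random_canonical(rng, 40)
        m = fit_frequency_model(seqs)
        for i in range(9):
            for k, nuc in enumerate("ACGT"):
                assert m.counts[i, k] == sum(1 for s in seqs if s[i] == nuc)

    def test_empty_input_and_bad_length_are_errors(self):
        with pytest.raises(ValueError):
            fit_frequency_model([])
        with pytest.raises(ValueError):
            fit_frequency_model(["ACGT"])


class TestInformationContent:
    def test_uniform_column_is_zero_bits(self):
        m = fit_frequency_model(["ACGTTAAAA", "CGTTTAGAA", "GTATTACAA", "TACTTATAA"],
                                pseudocount=0.0)
        per_pos, _ = information_content(m)
        assert per_pos[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_column_is_two_bits(self):
        m = fit_frequency_model(["AAATAAAAA", "AAATAAAAA"], pseudocount=0.0)
        per_pos, total = information_content(m)
        assert np.allclose(per_pos, 2.0)
        assert total == pytest.approx(18.0)

    def test_bounded_between_zero_and_two(self, rng):
        for _ in range(20):
            m = fit_frequency_model(_random_canonical(rng, int(rng.integers(2, 30))))
            per_pos, total = information_content(m)
            assert np.all(per_pos >= -1e-12) and np.all(per_pos <= 2.0 + 1e-12)
            assert total == pytest.approx(per_pos.sum())


class TestMutualInformation:
    def test_identical_half_half_columns_share_one_bit(self):
        # positions 1 and 2 always equal, each 50% A / 50% C
        seqs = ["AAATAAAAA"] * 10 + ["CCATAAAAA"] * 10
        mi = mutual_information(seqs)
        assert mi[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_blank_fixed_positions(self, rng):
        mi = mutual_information(_random_canonical(rng, 60))
        for i in range(9):
            for j in range(9):
                if i in (3, 5) or j in (3, 5):
                    assert math.isnan(mi[i, j])
                else:
                    assert mi[i, j] == pytest.approx(mi[j, i])

    def test_independent_columns_have_near_zero_mi(self, rng):
        seqs = _random_canonical(rng, 4000)
        mi = mutual_information(seqs)
        off_diag = [
            mi[i, j]
            for i in range(9)
            for j in range(9)
            if i != j and not math.isnan(mi[i, j])
        ]
        # plug-in MI is positively biased ~ 9/(2 n ln 2) for a 4x4 table
        assert max(off_diag) < 0.01


class TestMM1Model:
    def test_single_sequence_without_pseudocount_has_probability_one(self):
        m = fit_mm1(["GCATCACTG"], pseudocount=0.0)
        assert m.prob("GCATCACTG") == pytest.approx(1.0)

    def test_probability_mass_over_canonical_space_is_one(self, rng):
        m = fit_mm1(_random_canonical(rng, 25))
        total = sum(m.prob(nm) for nm in CANONICAL_SPACE)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_transitions_match_bruteforce_bigram_tally(self, rng):
        seqs = _random_canonical(rng, 30)
        m = fit_mm1(seqs, pseudocount=1.0)
        chain = m.chain
        for prev, cur in zip(chain, chain[1:]):
            for a, na in enumerate("ACGT"):
                n_prev = sum(1 for s in seqs if s[prev - 1] == na)
                for b, nb in enumerate("ACGT"):
                    n_pair = sum(
                        1 for s in seqs if s[prev - 1] == na and s[cur - 1] == nb
                    )
                    assert m.transitions[cur][a, b] == pytest.approx(
                        (n_pair + 1.0) / (n_prev + 4.0)
                    )

    def test_non_canonical_training_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="non-canonical"):
            fit_mm1(["GCACCACTG"])  # C at position 4

    def test_alternative_chain_is_accepted(self):
        m = fit_mm1(["GCATCACTG", "TTCTGACAA"], chain=(9, 8, 7, 5, 3, 2, 1))
        assert m.chain == (9, 8, 7, 5, 3, 2, 1)
        total = sum(m.prob(nm) for nm in CANONICAL_SPACE)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestScores:
    def test_identical_models_score_zero(self, rng):
        seqs = _random_canonical(rng, 20)
        m = fit_mm1(seqs)
        f = fit_frequency_model(seqs)
        for nm in _random_canonical(rng, 10):
            assert mm1_score(m, m, nm) == pytest.approx(0.0)
            assert pwm_score(f, f, nm) == pytest.approx(0.0)

    def test_doubling_positive_probability_adds_one_bit(self, rng):
        seqs = _random_canonical(rng, 20)
        pos = fit_mm1(seqs)
        neg = fit_mm1(_random_canonical(rng, 20))
        nm = seqs[0]
        base = mm1_score(pos, neg, nm)
        boosted = MM1Model(
            chain=pos.chain,
            initial=pos.initial * 2.0,  # doubles every 9-mer probability
            transitions=pos.transitions,
            pseudocount=pos.pseudocount,
            n_seqs=pos.n_seqs,
        )
        assert mm1_score(boosted, neg, nm) == pytest.approx(base + 1.0)

    def test_two_sequence_models_match_hand_computation(self):
        pos = fit_mm1(["GCATCACTG", "TTCTGACAA"], pseudocount=0.0)
        neg = fit_mm1(["CCCTCACCC", "AAATAAAAA"], pseudocount=0.0)
        nm = "GCATCACTG"
        # hand: initial P(G)=1/2; every transition is deterministic except
        # position 8 given position 7 = C, shared by both 9-mers (P(T|C)=1/2)
        assert pos.prob(nm) == pytest.approx(0.25)
        assert neg.prob(nm) == pytest.approx(0.0, abs=1e-12)

    def test_pwm_equals_mm1_when_transitions_factorize(self, rng):
        """An MM1 whose transitions ignore the previous position is a PWM."""
        seqs = _random_canonical(rng, 30)
        f_pos = fit_frequency_model(seqs, pseudocount=1.0)
        f_neg = fit_frequency_model(_random_canonical(rng, 30), pseudocount=1.0)

        def factorized(freq):
            init = freq.probs[DEFAULT_CHAIN[0] - 1]
            trans = {
                pos: np.tile(freq.probs[pos - 1], (4, 1)) for pos in DEFAULT_CHAIN[1:]
            }
            return MM1Model(
                chain=DEFAULT_CHAIN,
                initial=init,
                transitions=trans,
                pseudocount=freq.pseudocount,
                n_seqs=freq.n_seqs,
            )

        m_pos, m_neg = factorized(f_pos), factorized(f_neg)
        for nm in _random_canonical(rng, 25):
            assert mm1_score(m_pos, m_neg, nm) == pytest.approx(
                pwm_score(f_pos, f_neg, nm), abs=1e-9
            )

    def test_scores_reject_non_canonical_ninemers(self, rng):
        seqs = _random_canonical(rng, 10)
        m, f = fit_mm1(seqs), fit_frequency_model(seqs)
        with pytest.raises(ValueError):
            mm1_score(m, m, "AAAAAAAAA")
        with pytest.raises(ValueError):
            pwm_score(f, f, "AAAAAAAAA")

    def test_discrimination_sanity_on_planted_sets(self, rng):
        """A set scored against itself beats a uniform-background model."""
        planted = ["TACTAACAC"] * 30 + _random_canonical(rng, 10)
        background = _random_canonical(rng, 40)
        pos, neg = fit_mm1(planted), fit_mm1(background)
        mean = np.mean([mm1_score(pos, neg, nm) for nm in planted])
        assert mean > 0


class TestSerialization:
    def test_mm1_round_trip(self, tmp_path, rng):
        m = fit_mm1(_random_canonical(rng, 15))
        p = tmp_path / "m.json"
        save_model(m, p)
        back = load_model(p)
        assert isinstance(back, MM1Model)
        for nm in _random_canonical(rng, 5):
            assert back.log2_prob(nm) == pytest.approx(m.log2_prob(nm))

    def test_frequency_round_trip(self, tmp_path, rng):
        f = fit_frequency_model(_random_canonical(rng, 15))
        p = tmp_path / "f.json"
        save_model(f, p)
        back = load_model(p)
        assert np.allclose(back.probs, f.probs)

    def test_version_mismatch_is_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"format": "bpscan-model", "version": 99, "type": "mm1"}))
        with pytest.raises(ValueError, match="unsupported"):
            load_model(p)


class TestU2DuplexEnergy:
    def test_missing_backend_is_an_explicit_error(self):
        with pytest.raises(FeatureUnavailableError):
            u2_duplex_energy("TACTAACAC")
        ghost = RNAcofoldBackend(executable="no-such-rnacofold-binary")
        with pytest.raises(FeatureUnavailableError):
            u2_duplex_energy("TACTAACAC", ghost)

    def test_perfect_complement_is_most_stable_and_deterministic(self):
        backend = RNAcofoldBackend()
        if not backend.available():
            pytest.fail("RNAcofold executable expected on PATH")
        perfect = "TACTAACAC"  # reverse complement of the U2 oligo
        e0 = u2_duplex_energy(perfect, backend)
        assert e0 == u2_duplex_energy(perfect, backend)  # deterministic
        for variant in ("TACTAACAA", "TCCTAACAC", "GACTAACAC"):
            assert e0 <= u2_duplex_energy(variant, backend)
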