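"""RNA design models, dot-bracket parsing, and motif automata."""

import itertools
import math
import random

import pytest
from hypothesis import given, strategies as st

from treefeat import solvers
from treefeat.model import ModelError
from treefeat.rna import (CANONICAL_PAIRS, SecondaryStructure, accepts,
                          add_dfa_track, aho_corasick_dfa, bp_energy,
                          design_model, dfa_model, gc_count,
                          parse_dotbracket, sequence_of, to_dotbracket)

import oracles

STOP_CODONS = ["UGA", "UUA", "UUG"]
TABLE = {"GC": -3.0, "CG": -3.0, "AU": -2.0, "UA": -2.0, "GU": -1.0, "UG": -1.0}


class TestParseDotbracket:
    @pytest.mark.parametrize("text,pairs,crossing", [
        ("((..))", {(1, 6), (2, 5)}, False),
        ("([)]", {(1, 3), (2, 4)}, True),
        ("....", set(), False),
    ])
    def test_examples(self, text, pairs, crossing):
        s = parse_dotbracket(text)
        assert s.pairs == frozenset(pairs)
        assert s.crossing == crossing

    @pytest.mark.parametrize("text", ["((", "))", "(]", "(.))"])
    def test_unbalanced_rejected(self, text):
        with pytest.raises(ModelError):
            parse_dotbracket(text)

    def test_base_triplet_rejected(self):
        with pytest.raises(ModelError):
            SecondaryStructure(4, frozenset([(1, 3), (1, 4)]))

    @given(st.integers(0, 400))
    def test_round_trip_random_structures(self, seed):
        from treefeat.fixtures import random_structures
        (s,) = random_structures(12, crossing=seed % 2 == 0, seed=seed)
        assert parse_dotbracket(to_dotbracket(s)) == s


class TestSequenceScores:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 4), ("AAAA", 0), ("AUGC", 2)])
    def test_gc_count(self, seq, expected):
        assert gc_count(seq) == expected

    def test_gc_count_rejects_alien_symbols(self):
        with pytest.raises(ModelError):
            gc_count("AXGC")

    def test_empty_structure_has_zero_energy(self):
        assert bp_energy("AUGC", SecondaryStructure(4, frozenset()), TABLE) == 0.0

    def test_single_pair_energy(self):
        s = SecondaryStructure(6, frozenset([(1, 6)]))
        assert bp_energy("GAAAAC", s, TABLE) == -3.0

    def test_non_canonical_pair_is_infinite(self):
        s = SecondaryStructure(4, frozenset([(1, 4)]))
        assert bp_energy("AAAA", s, TABLE) == math.inf

    def test_energy_matches_manual_sum_on_random_inputs(self):
        from treefeat.fixtures import random_structures
        rng = random.Random(0)
        for seed in range(20):
            (s,) = random_structures(10, seed=seed)
            seq = "".join(rng.choice("ACGU") for _ in range(10))
            manual = 0.0
            for i, j in s.pairs:
                key = seq[i - 1] + seq[j - 1]
                if key not in TABLE:
                    manual = math.inf
                    break
                manual += TABLE[key]
            assert bp_energy(seq, s, TABLE) == manual


class TestDesignModel:
    def test_sequence_count_on_noncrossing_structure(self):
        # independent pairs: 6 canonical choices per pair, 4 per free position
        for db in ["((...))", "(.)(.)", "......"]:
            s = parse_dotbracket(db)
            net = design_model([s], table=TABLE)
            z = solvers.partition(net, {name: 0.0 for name in net.features})
            p, u = len(s.pairs), s.length - 2 * len(s.pairs)
            assert z == 6 ** p * 4 ** u

    def test_count_matches_enumeration_with_multiple_targets(self):
        s1 = parse_dotbracket("((..))..")
        s2 = parse_dotbracket("..((..))")
        net = design_model([s1, s2], table=TABLE)
        zero = {name: 0.0 for name in net.features}
        assert solvers.partition(net, zero) == oracles.brute_force_partition(net, zero)

    def test_sampled_sequences_have_canonical_pairs_everywhere(self):
        s1 = parse_dotbracket("((....))")
        s2 = parse_dotbracket(".((..)).")
        net = design_model([s1, s2], table=TABLE)
        from treefeat.rna import encode_sequence
        for x in solvers.sample(net, {"gc": 0.0, "E1": 0.0, "E2": 0.0}, n=50, seed=4):
            seq = sequence_of(net, x)
            codes = encode_sequence(seq)
            for s in (s1, s2):
                for i, j in s.pairs:
                    assert (codes[i - 1], codes[j - 1]) in CANONICAL_PAIRS

    def test_sampling_distribution_matches_problem_formula(self):
        # P(s) prop. exp(a_gc #GC) * exp(a_1 E(s,S1)), verified by enumeration
        s = parse_dotbracket("((..))")
        net = design_model([s], table=TABLE)
        w = {"gc": 0.5, "E1": -0.4}
        probs, index_of = oracles.boltzmann_probabilities(net, w)
        solver = solvers.TreeSolver(net, seed=0)
        xs = solver.sample(w, n=20_000, seed=8)
        counts = {}
        for x in xs:
            counts[index_of(x)] = counts.get(index_of(x), 0) + 1
        from scipy import stats
        idx = [i for i, p in enumerate(probs) if p > 0]
        observed = [counts.get(i, 0) for i in idx]
        expected = [probs[i] * len(xs) for i in idx]
        observed, expected = oracles.merge_small_bins(observed, expected)
        p_value = stats.chisquare(observed, expected).pvalue
        assert p_value > 0.001

    def test_crossing_target_requires_flag(self):
        s = parse_dotbracket("([)]")
        with pytest.raises(ModelError):
            design_model([s], table=TABLE)
        net = design_model([s], table=TABLE, allow_crossing=True)
        assert net.n_variables == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelError):
            design_model([parse_dotbracket("...."), parse_dotbracket("...")])


class TestAhoCorasick:
    def test_stop_codon_automaton_has_five_states(self):
        dfa = aho_corasick_dfa(STOP_CODONS)
        assert dfa.n_states == 5

    def test_exact_word_acceptance_at_motif_length(self):
        dfa = aho_corasick_dfa(STOP_CODONS, word_length=3)
        accepted = ["".join(w) for w in itertools.product("ACGU", repeat=3)
                    if accepts(dfa, "".join(w))]
        assert sorted(accepted) == sorted(STOP_CODONS)

    @pytest.mark.parametrize("word,expected", [("UGA", True), ("AAA", False)])
    def test_single_words(self, word, expected):
        assert accepts(aho_corasick_dfa(STOP_CODONS), word) == expected

    def test_empty_word_accepted_iff_initial_state_accepting(self):
        dfa = aho_corasick_dfa(STOP_CODONS, mode="accept")
        assert not accepts(dfa, "")
        assert accepts(aho_corasick_dfa(STOP_CODONS, mode="forbid"), "")

    def test_forbid_mode_matches_substring_scan(self):
        motifs = ["UGA", "AAU", "GG"]
        dfa = aho_corasick_dfa(motifs, mode="forbid")
        rng = random.Random(1)
        for _ in range(1000):
            n = rng.randint(0, 12)
            w = "".join(rng.choice("ACGU") for _ in range(n))
            clean = not any(m in w for m in motifs)
            assert accepts(dfa, w) == clean

    def test_bad_motifs_rejected(self):
        with pytest.raises(ModelError):
            aho_corasick_dfa([""])
        with pytest.raises(ModelError):
            aho_corasick_dfa(["AXU"])


class TestDfaModel:
    def test_stop_codon_accept_count(self):
        net = dfa_model(aho_corasick_dfa(STOP_CODONS), 3)
        assert solvers.partition(net, {}) == 3.0

    def test_stop_codon_forbid_count(self):
        net = dfa_model(aho_corasick_dfa(STOP_CODONS, mode="forbid"), 3)
        assert solvers.partition(net, {}) == 61.0  # 4^3 - 3

    @pytest.mark.parametrize("mode", ["accept", "forbid"])
    def test_counts_match_direct_enumeration(self, mode):
        motifs = ["GCA", "AU"]
        dfa = aho_corasick_dfa(motifs, mode=mode)
        for n in range(1, 6):
            direct = sum(
                1 for w in itertools.product("ACGU", repeat=n)
                if accepts(dfa, "".join(w)))
            net = dfa_model(dfa, n)
            assert solvers.partition(net, {}) == float(direct)

    def test_sampled_words_are_accepted(self):
        dfa = aho_corasick_dfa(STOP_CODONS, mode="forbid")
        net = dfa_model(dfa, 8)
        for x in solvers.sample(net, {}, n=30, seed=3):
            assert accepts(dfa, sequence_of(net, x))


class TestMergedDesignAndAutomaton:
    def test_design_with_forbidden_motifs(self):
        s = parse_dotbracket("((...))")
        net = design_model([s], table=TABLE)
        dfa = aho_corasick_dfa(["GG", "UUU"], mode="forbid")
        add_dfa_track(net, dfa)
        zero = {name: 0.0 for name in net.features}
        xs = solvers.sample(net, zero, n=40, seed=6)
        from treefeat.rna import encode_sequence
        for x in xs:
            seq = sequence_of(net, x)
            assert accepts(dfa, seq)
            assert "GG" not in seq and "UUU" not in seq
            codes = encode_sequence(seq)
            for i, j in s.pairs:
                assert (codes[i - 1], codes[j - 1]) in CANONICAL_PAIRS

    def test_merged_count_matches_enumeration(self):
        s = parse_dotbracket("(...)")
        net = design_model([s], table=TABLE)
        dfa = aho_corasick_dfa(["GC"], mode="forbid")
        add_dfa_track(net, dfa)
        zero = {name: 0.0 for name in net.features}
        direct = 0
        from treefeat.rna import encode_sequence
        for w in itertools.product("ACGU", repeat=5):
            word = "".join(w)
            codes = encode_sequence(word)
            if (codes[0], codes[4]) in CANONICAL_PAIRS and accepts(dfa, word):
                direct += 1
        assert solvers.partition(net, zero) == float(direct)
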