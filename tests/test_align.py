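"""Alignment models: encoding, scoring, oracles, affine gaps, structure bonus."""

import itertools
import random

import pytest

from treefeat import solvers
from treefeat.align import (GAP, ScoringScheme, affine_model,
                            affine_model_xonly, decode, encode, gotoh_score,
                            linear_model, nw_score, score_columns,
                            structure_model)
from treefeat.model import ModelError
from treefeat.rna import SecondaryStructure, parse_dotbracket

# the worked alignment example and its reference encoding
A_EX, B_EX = "AAACUGG", "ACGAGGC"
ENC_EX = (0, 0, 1, 4, 5, 5, 5, 6, 8)
SCHEME = ScoringScheme(match=2, mismatch=0, gap_gamma=-1)


def random_pair(rng, max_len=8, alphabet="ACGU"):
    n, m = rng.randint(1, max_len), rng.randint(1, max_len)
    return ("".join(rng.choice(alphabet) for _ in range(n)),
            "".join(rng.choice(alphabet) for _ in range(m)))


def random_columns(rng, a, b):
    """A uniformly scrambled valid alignment of a and b (canonical order:
    insertions precede the match/deletion they sit in front of)."""
    i = j = 0
    cols = []
    while i < len(a) or j < len(b):
        moves = []
        if i < len(a) and j < len(b):
            moves.append("m")
        if i < len(a):
            moves.append("d")
        if j < len(b):
            moves.append("i")
        mv = rng.choice(moves)
        if mv == "m":
            cols.append((a[i], b[j]))
            i += 1
            j += 1
        elif mv == "d":
            cols.append((a[i], GAP))
            i += 1
        else:
            cols.append((GAP, b[j]))
            j += 1
    return cols


class TestWorkedExample:
    def test_reference_encoding_scores_zero(self):
        net = linear_model(A_EX, B_EX, SCHEME)
        assert net.evaluate(ENC_EX) == 0.0

    def test_decoded_alignment_has_three_of_each_event(self):
        cols = decode(ENC_EX, A_EX, B_EX)
        assert len(cols) == 10
        assert sum(1 for _, cb in cols if cb == GAP) == 3   # deletions
        assert sum(1 for ca, _ in cols if ca == GAP) == 3   # insertions
        matches = sum(1 for ca, cb in cols if GAP not in (ca, cb) and ca == cb)
        assert matches == 3
        assert score_columns(cols, SCHEME) == 0.0


class TestLinearModel:
    def test_identity_alignment_is_optimal_for_equal_sequences(self):
        scheme = ScoringScheme(match=1, mismatch=0, gap_gamma=-1)
        a = "ACGUG"
        value, x = solvers.optimize(linear_model(a, a, scheme), seed=0)
        assert value == len(a)
        assert [x[i] for i in range(len(a) + 2)] == list(range(len(a) + 2))

    def test_optimum_matches_needleman_wunsch_oracle(self):
        rng = random.Random(42)
        for _ in range(30):  # the 100-instance sweep runs in the acceptance suite
            a, b = random_pair(rng)
            net = linear_model(a, b, SCHEME)
            value, x = solvers.optimize(net, seed=1)
            assert value == nw_score(a, b, SCHEME)
            assert net.evaluate(x) == value

    def test_banding_keeps_the_optimum_when_wide_enough(self):
        rng = random.Random(7)
        for _ in range(10):
            a, b = random_pair(rng, max_len=7)
            full = solvers.optimize(linear_model(a, b, SCHEME), seed=1)[0]
            banded = solvers.optimize(
                linear_model(a, b, SCHEME, band=max(len(a), len(b))), seed=1)[0]
            assert banded == full

    def test_mismatch_scores_are_applied_to_aligned_pairs(self):
        scheme = ScoringScheme(match=2, mismatch=-1, gap_gamma=-10)
        value, _ = solvers.optimize(linear_model("AC", "AG", scheme), seed=0)
        assert value == 2 - 1  # forced match + mismatch under huge gap penalty


class TestAffineModel:
    AFFINE = ScoringScheme(match=2, mismatch=0, gap_gamma=-1, gap_open_beta=-2)

    def test_one_long_gap_beats_scattered_gaps(self):
        # deleting GGG as one run costs beta+3*gamma
        a, b = "AGGGA", "AA"
        value, x = solvers.optimize(affine_model(a, b, self.AFFINE), seed=0)
        assert value == 2 + 2 + (-2 - 3)
        cols = decode(x, a, b)
        assert score_columns(cols, self.AFFINE) == value

    def test_isolated_gaps_each_pay_opening(self):
        cols = [("A", "A"), ("G", GAP), ("A", "A"), ("G", GAP), ("A", "A"),
                ("G", GAP), ("A", "A")]
        assert score_columns(cols, self.AFFINE) == 8 + 3 * (-2 - 1)
        single = [("A", "A"), ("G", GAP), ("G", GAP), ("G", GAP), ("A", "A")]
        assert score_columns(single, self.AFFINE) == 4 + (-2 - 3)

    def test_beta_zero_degenerates_to_linear(self):
        rng = random.Random(3)
        zero_open = ScoringScheme(match=2, mismatch=0, gap_gamma=-1, gap_open_beta=0)
        for _ in range(15):
            a, b = random_pair(rng, max_len=6)
            affine = solvers.optimize(affine_model(a, b, zero_open), seed=1)[0]
            linear = solvers.optimize(linear_model(a, b, SCHEME), seed=1)[0]
            assert affine == linear

    def test_optimum_matches_gotoh_oracle(self):
        rng = random.Random(11)
        for _ in range(20):
            a, b = random_pair(rng, max_len=7)
            net = affine_model(a, b, self.AFFINE)
            value, x = solvers.optimize(net, seed=1)
            assert value == gotoh_score(a, b, self.AFFINE)
            assert net.evaluate(x) == value

    def test_ternary_xonly_variant_agrees_with_default_model(self):
        rng = random.Random(19)
        for _ in range(15):
            a, b = random_pair(rng, max_len=6)
            xonly = solvers.optimize(affine_model_xonly(a, b, self.AFFINE), seed=1)[0]
            assert xonly == gotoh_score(a, b, self.AFFINE)


class TestStructureModel:
    def test_zero_bonus_equals_linear_optimum(self):
        rng = random.Random(5)
        scheme = ScoringScheme(match=2, mismatch=0, gap_gamma=-1, arc_bonus_tau=0.0)
        for _ in range(10):
            a, b = random_pair(rng, max_len=6)
            s = SecondaryStructure(len(a), frozenset([(1, len(a))]) if len(a) > 1
                                   else frozenset())
            sv = solvers.optimize(structure_model(a, s, b, scheme), seed=1)[0]
            lv = solvers.optimize(linear_model(a, b, SCHEME), seed=1)[0]
            assert sv == lv

    def test_single_arc_bonus_matches_brute_force(self):
        rng = random.Random(9)
        tau = 3.0
        scheme = ScoringScheme(match=2, mismatch=0, gap_gamma=-1, arc_bonus_tau=tau)
        for _ in range(8):
            a, b = random_pair(rng, max_len=6)
            if len(a) < 2:
                continue
            s = SecondaryStructure(len(a), frozenset([(1, len(a))]))
            value, _ = solvers.optimize(structure_model(a, s, b, scheme), seed=1)
            assert value == brute_force_structure(a, s, b, scheme)

    def test_crossing_annotation_is_solved_exactly(self):
        a, b = "GACGUC", "GACGUC"
        s = parse_dotbracket("([.)].")
        scheme = ScoringScheme(match=2, mismatch=0, gap_gamma=-1, arc_bonus_tau=1.0)
        net = structure_model(a, s, b, scheme)
        value, x = solvers.optimize(net, seed=1)
        assert value == brute_force_structure(a, s, b, scheme)
        assert net.evaluate(x) == value

    def test_deleted_arc_endpoint_earns_no_bonus(self):
        # a's two positions pair; force deletion of position 1 via tiny b
        a, b = "GC", "C"
        s = SecondaryStructure(2, frozenset([(1, 2)]))
        scheme = ScoringScheme(match=5, mismatch=0, gap_gamma=-1, arc_bonus_tau=100.0)
        value, x = solvers.optimize(structure_model(a, s, b, scheme), seed=0)
        # one match + one deletion; the arc cannot score because an endpoint is gone
        assert value == 5 - 1


def brute_force_structure(a, s, b, scheme):
    """Enumerate all monotone encodings and score columns + arc bonuses."""
    n, m = len(a), len(b)
    best = float("-inf")
    base = ScoringScheme(match=scheme.match, mismatch=scheme.mismatch,
                         gap_gamma=scheme.gap_gamma, sigma=scheme.sigma)
    from treefeat.rna import CANONICAL_PAIRS, _BASE_INDEX
    for xs in itertools.product(range(m + 1), repeat=n):
        x = (0,) + xs + (m + 1,)
        if any(x[i] > x[i + 1] for i in range(n + 1)):
            continue
        total = score_columns(decode(x, a, b), base)
        for i, j in s.pairs:
            mi = x[i - 1] < x[i]
            mj = x[j - 1] < x[j]
            if mi and mj and (_BASE_INDEX.get(b[x[i] - 1]),
                              _BASE_INDEX.get(b[x[j] - 1])) in CANONICAL_PAIRS:
                total += scheme.arc_bonus_tau
        best = max(best, total)
    return best


class TestEncodeDecode:
    def test_reference_encoding_round_trip(self):
        cols = decode(ENC_EX, A_EX, B_EX)
        assert encode(cols, A_EX, B_EX) == {i: v for i, v in enumerate(ENC_EX)}

    def test_identity_assignment_decodes_to_matches_only(self):
        a = "ACGU"
        cols = decode(list(range(6)), a, a)
        assert cols == [(c, c) for c in a]

    def test_leq_violation_is_rejected(self):
        with pytest.raises(ModelError):
            decode((0, 2, 1, 5), "AC", "ACGU")

    def test_bijection_on_random_alignments(self):
        rng = random.Random(17)
        for _ in range(200):
            a, b = random_pair(rng, max_len=6)
            cols = random_columns(rng, a, b)
            x = encode(cols, a, b)
            # decode yields the canonical column order (insertions first);
            # re-encoding is the identity on encodings
            assert encode(decode(x, a, b), a, b) == x

    def test_decode_encode_identity_on_valid_assignments(self):
        rng = random.Random(23)
        scheme = SCHEME
        for _ in range(50):
            a, b = random_pair(rng, max_len=5)
            net = linear_model(a, b, scheme)
            xs = solvers.sample(net, {f: 0.0 for f in net.features}, n=4, seed=rng.randint(0, 10**6))
            for x in xs:
                cols = decode(x, a, b)
                assert encode(cols, a, b) == {k: x[k] for k in sorted(x)}


class TestScoreColumns:
    def test_equal_sequences_all_matches(self):
        scheme = ScoringScheme(match=2, mismatch=0, gap_gamma=-1)
        cols = [(c, c) for c in "ACGU"]
        assert score_columns(cols, scheme) == 8.0

    def test_model_evaluation_agrees_with_direct_score(self):
        rng = random.Random(31)
        for _ in range(60):
            a, b = random_pair(rng, max_len=6)
            net = linear_model(a, b, SCHEME)
            for x in solvers.sample(net, {f: 0.0 for f in net.features}, n=3,
                                    seed=rng.randint(0, 10**6)):
                assert net.evaluate(x) == score_columns(decode(x, a, b), SCHEME)

    def test_affine_model_evaluation_agrees_with_direct_score(self):
        rng = random.Random(37)
        scheme = ScoringScheme(match=2, mismatch=0, gap_gamma=-1, gap_open_beta=-3)
        for _ in range(40):
            a, b = random_pair(rng, max_len=6)
            net = affine_model(a, b, scheme)
            for x in solvers.sample(net, {f: 0.0 for f in net.features}, n=3,
                                    seed=rng.randint(0, 10**6)):
                assert net.evaluate(x) == score_columns(decode(x, a, b), scheme)
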