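import random
from fractions import Fraction

import pytest

from chromorr.model import (UNIT_WEIGHTS, case2_weights, parse_structure,
                            CIRCULAR_DEFAULT_WEIGHTS)
from chromorr.oracles import (bfs_shortest_sequence, explicit_insertion_search,
                              oracle_distance)
from conftest import random_pair


class TestKnownDistances:
    def test_identity_is_zero(self):
        a = parse_structure("g1 g2 g3 $")
        w, recs = bfs_shortest_sequence(a, a, UNIT_WEIGHTS, with_scenario=True)
        assert w == 0 and recs == []

    @pytest.mark.parametrize("a_txt,b_txt,expect", [
        ("g1 g2 g3 $", "g1 -g2 g3 $", 1),    # one inversion
        ("g1 g2 $", "g1 $\ng2 $", 1),        # one fission cut
        ("g1 x g2 $", "g1 g2 $", 1),         # one region deletion
        ("g1 g2 g3 @", "g1 g2 g3 $", 1),     # open a circle
    ])
    def test_small_cases(self, a_txt, b_txt, expect):
        a, b = parse_structure(a_txt), parse_structure(b_txt)
        assert oracle_distance(a, b, UNIT_WEIGHTS) == expect

    def test_insertion_weight_applied(self):
        a, b = parse_structure("g1 g2 $"), parse_structure("g1 x g2 $")
        assert oracle_distance(a, b, case2_weights(Fraction(3, 2))) == \
            Fraction(3, 2)

    def test_merged_insertion_cheaper_when_insertions_expensive(self):
        # inserting two private regions as one piece and cutting apart beats
        # two separate insertions when the insertion weight exceeds d
        a = parse_structure("g1 @\ng2 @")
        b = parse_structure("q1 g1 $\nq2 g2 $")
        d = oracle_distance(a, b, case2_weights(Fraction(3, 2)))
        assert d < 2 * Fraction(3, 2) + 2    # strictly below separate route


class TestConsistency:
    def test_symmetric_under_equal_weights(self):
        rng = random.Random(5)
        for _ in range(12):
            pair = random_pair(rng, max_genes=3)
            if pair is None:
                continue
            a, b = pair
            assert oracle_distance(a, b, UNIT_WEIGHTS) == \
                oracle_distance(b, a, UNIT_WEIGHTS)

    def test_agrees_with_explicit_insertion_search(self):
        # the bidirectional solver meets a forward-only search that
        # enumerates insertion contents explicitly
        rng = random.Random(9)
        checked = 0
        for _ in range(40):
            pair = random_pair(rng, max_genes=3)
            if pair is None:
                continue
            a, b = pair
            if len(set(b.gene_keys()) - set(a.gene_keys())) > 2:
                continue
            for w in (UNIT_WEIGHTS, case2_weights(Fraction(7, 5))):
                d1 = oracle_distance(a, b, w)
                d2 = explicit_insertion_search(a, b, w, max_weight=d1 + 1)
                assert d1 == d2, (a, b, w)
            checked += 1
        assert checked >= 10

    def test_minimal_length_weight_at_least_plain_optimum(self):
        rng = random.Random(4)
        for _ in range(10):
            pair = random_pair(rng, max_genes=3, shared_range=(3, 3))
            if pair is None:
                continue
            a, b = pair
            w = CIRCULAR_DEFAULT_WEIGHTS
            plain = oracle_distance(a, b, w)
            lex = oracle_distance(a, b, w, minimal_length=True)
            assert lex >= plain
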