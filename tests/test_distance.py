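import random
from fractions import Fraction

import pytest

from chromorr import ops as _ops
from chromorr.distance import (ExactnessClass, biological_distance,
                               breakpoint_distance, compute_invariants,
                               transform_to_final)
from chromorr.model import (CIRCULAR_DEFAULT_WEIGHTS, LINEAR_DEFAULT_WEIGHTS,
                            OpKind, UNIT_WEIGHTS, case2_weights,
                            parse_structure)
from chromorr.oracles import oracle_distance
from conftest import random_pair, random_structure_over


def assert_valid_scenario(a, b, scenario):
    """Replay check: snapshots start after one op from `a`, end at `b`, and
    every consecutive pair is one operation of the recorded kind apart.

    The adjacency-level move generator used here is independent of the
    common-graph transformation that produced the scenario.
    """
    prev = a
    for rec in scenario.ops:
        nxt = rec.structure_after
        assert nxt is not None
        if rec.kind in (OpKind.DOUBLE, OpKind.SESQUI, OpKind.CUTJOIN):
            state = _ops.to_adjacencies(prev)
            kinds = {OpKind.DOUBLE: {"double"}, OpKind.SESQUI: {"sesqui"},
                     OpKind.CUTJOIN: {"cut", "join"}}[rec.kind]
            moves = {_ops.to_structure(ns)
                     for k, ns in _ops.standard_moves(state, frozenset())
                     if k in kinds}
            assert nxt in moves, f"invalid {rec.kind} step"
        elif rec.kind is OpKind.DELETE_REGION:
            gone = set(prev.gene_keys()) - set(nxt.gene_keys())
            state = _ops.to_adjacencies(prev)
            results = {_ops.to_structure(_ops.apply_delete_region(state, run,
                                                                  lf, rt))
                       for run, lf, rt, _c in
                       _ops.special_regions(state, frozenset(gone))}
            assert nxt in results, "invalid deletion step"
        else:                                   # insertion: check the reverse
            gained = set(nxt.gene_keys()) - set(prev.gene_keys())
            state = _ops.to_adjacencies(nxt)
            results = {_ops.to_structure(_ops.apply_delete_region(state, run,
                                                                  lf, rt))
                       for run, lf, rt, _c in
                       _ops.special_regions(state, frozenset(gained))}
            assert prev in results, "invalid insertion step"
        prev = nxt
    assert prev == b, "scenario does not end at the target"


class TestScenarios:
    def test_identity_empty_scenario(self):
        a = parse_structure("g1 g2 @")
        scen = transform_to_final(a, a, UNIT_WEIGHTS)
        assert scen.total_weight == 0 and len(scen) == 0

    def test_single_inversion_is_one_double(self):
        a = parse_structure("g1 g2 g3 $")
        b = parse_structure("g1 -g2 g3 $")
        scen = transform_to_final(a, b, UNIT_WEIGHTS)
        assert [r.kind for r in scen.ops] == [OpKind.DOUBLE]
        assert scen.total_weight == oracle_distance(a, b, UNIT_WEIGHTS)

    def test_deletion_records_region_content(self):
        a = parse_structure("g1 x y g2 $")
        b = parse_structure("g1 g2 $")
        scen = transform_to_final(a, b, UNIT_WEIGHTS)
        (rec,) = scen.ops
        assert rec.kind is OpKind.DELETE_REGION
        assert sorted(g.family for g in rec.operands[0]) == ["x", "y"]

    def test_replay_validity_random(self):
        rng = random.Random(21)
        checked = 0
        for _ in range(40):
            pair = random_pair(rng, max_genes=4)
            if pair is None:
                continue
            a, b = pair
            for w in (UNIT_WEIGHTS, case2_weights(Fraction(3, 2))):
                scen = transform_to_final(a, b, w)
                assert_valid_scenario(a, b, scen)
                assert scen.total_weight == sum(r.weight for r in scen.ops)
            checked += 1
        assert checked >= 15


class TestExactness:
    def test_equal_content_pattern_weights(self):
        # case (1): equal gene content, circular/linear pattern; the output
        # weight is minimal among minimal-length sequences
        rng = random.Random(31)
        for _ in range(30):
            fams = [f"g{i}" for i in range(1, rng.randint(2, 4) + 1)]
            a = random_structure_over(rng, fams)
            b = random_structure_over(rng, fams)
            for w in (CIRCULAR_DEFAULT_WEIGHTS, LINEAR_DEFAULT_WEIGHTS):
                alg = transform_to_final(a, b, w, record_scenario=False)
                opt = oracle_distance(a, b, w, max_weight=alg.total_weight,
                                      minimal_length=True)
                assert opt is not None and alg.total_weight == opt, (a, b, w)

    def test_uniform_weights_within_additive_d(self):
        # case (2): five weights equal d, d <= c <= 2d
        rng = random.Random(32)
        checked = 0
        for _ in range(25):
            pair = random_pair(rng, max_genes=4)
            if pair is None:
                continue
            a, b = pair
            c = Fraction(rng.randint(10, 20), 10)
            w = case2_weights(c)
            alg = transform_to_final(a, b, w, record_scenario=False)
            opt = oracle_distance(a, b, w, max_weight=alg.total_weight)
            assert opt is not None
            assert 0 <= alg.total_weight - opt <= 1, (a, b, c)
            checked += 1
        assert checked >= 10

    def test_heuristic_regime_close_to_optimal(self):
        from chromorr.model import WeightScheme
        rng = random.Random(33)
        checked = 0
        for _ in range(15):
            pair = random_pair(rng, max_genes=3)
            if pair is None:
                continue
            a, b = pair
            vals = [Fraction(rng.randint(8, 15), 10) for _ in range(6)]
            w = WeightScheme(*vals)
            alg = transform_to_final(a, b, w, record_scenario=False)
            opt = oracle_distance(a, b, w, max_weight=alg.total_weight)
            assert opt is not None
            assert alg.total_weight <= Fraction(3, 2) * opt
            checked += 1
        assert checked >= 8


class TestDistanceReport:
    def test_identity_report(self):
        a = parse_structure("g1 g2 @")
        rep = biological_distance(a, a, CIRCULAR_DEFAULT_WEIGHTS)
        assert rep.symmetric == 0
        assert rep.exactness_class is ExactnessClass.EXACT_CASE1

    def test_symmetric_is_mean(self):
        a = parse_structure("g1 x g2 $")
        b = parse_structure("g1 g2 $")
        rep = biological_distance(a, b, case2_weights(Fraction(3, 2)))
        assert rep.symmetric == (rep.one_way_ab + rep.one_way_ba) / 2
        assert rep.one_way_ab != rep.one_way_ba   # delete vs insert

    def test_triangle_inequality_symmetric_distance(self):
        rng = random.Random(41)
        w = case2_weights(Fraction(3, 2))
        for _ in range(10):
            fams = [f"g{i}" for i in range(1, 4)]
            xs = [random_structure_over(rng, fams) for _ in range(3)]
            d01 = biological_distance(xs[0], xs[1], w).symmetric
            d12 = biological_distance(xs[1], xs[2], w).symmetric
            d02 = biological_distance(xs[0], xs[2], w).symmetric
            assert d02 <= d01 + d12


class TestBreakpoint:
    def test_identity_zero(self):
        a = parse_structure("g1 g2 g3 @")
        assert breakpoint_distance(a, a) == 0

    def test_piroplasmid_rows(self, mito_structures):
        # independent adjacency-set computation for the two Theileria rows:
        # one gene private to annulata, one adjacency private to parva,
        # two adjacencies private to annulata
        parva = mito_structures["Theileria_parva"]
        annulata = mito_structures["Theileria_annulata"]

        def adjacency_set(s):
            out = set()
            for c in s.chromosomes:
                seq = list(c.genes) + ([c.genes[0]] if c.circular else [])
                for g, h in zip(seq, seq[1:]):
                    left = (g.family, "head" if g.orient > 0 else "tail")
                    right = (h.family, "tail" if h.orient > 0 else "head")
                    out.add(frozenset((left + ("L",), right + ("R",))))
            return out

        sa, sb = adjacency_set(parva), adjacency_set(annulata)
        expected = len(sa ^ sb) + 1          # ls2 is present only in annulata
        assert expected == 4
        assert breakpoint_distance(parva, annulata) == expected

    def test_private_gene_counts(self):
        a = parse_structure("g1 g2 $")
        b = parse_structure("g1 $")
        # adjacency g1-g2 only in a; gene g2 only in a
        assert breakpoint_distance(a, b) == 2

    def test_symmetry(self):
        rng = random.Random(51)
        for _ in range(20):
            pair = random_pair(rng, max_genes=4)
            if pair is None:
                continue
            a, b = pair
            assert breakpoint_distance(a, b) == breakpoint_distance(b, a)


class TestInvariants:
    def test_final_form_zero(self):
        a = parse_structure("g1 g2 @")
        inv = compute_invariants(a, a, UNIT_WEIGHTS)
        assert (inv.B, inv.D, inv.P, inv.B_prime, inv.n_small) == (0, 0, 0, 0, 0)
        assert inv.predicted_total() == 0

    def test_single_target_circle_contributes_epsilon(self):
        a = parse_structure("g1 g2 $")
        b = parse_structure("g1 q g2 $")
        w = case2_weights(Fraction(3, 2))
        inv = compute_invariants(a, b, w)
        assert inv.B_prime + inv.n_small == 1
        assert inv.predicted_total() == \
            transform_to_final(a, b, w, record_scenario=False).total_weight

    def test_formula_matches_emitted_weight(self):
        rng = random.Random(61)
        checked = 0
        for _ in range(35):
            pair = random_pair(rng, max_genes=4)
            if pair is None:
                continue
            a, b = pair
            w = case2_weights(Fraction(rng.randint(10, 20), 10))
            inv = compute_invariants(a, b, w)
            total = transform_to_final(a, b, w,
                                       record_scenario=False).total_weight
            assert inv.predicted_total() == total, (a, b, w.insert)
            checked += 1
        assert checked >= 15
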