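import itertools
import random
from fractions import Fraction

import pytest

from chromorr.engine import Engine
from chromorr.ilp import (Bijections, breakpoint_matching, build_matching_ilp,
                          close_paths, distance_with_paths, relabel_matched,
                          solve_paralog_matching, _paralog_sets)
from chromorr.model import (Chromosome, ChromosomeStructure, GeneToken,
                            UNIT_WEIGHTS, parse_structure)
from chromorr.oracles import oracle_distance


def random_paralog_circular(rng, n_families, max_copies=2, n_chroms=None):
    toks = []
    for f in range(n_families):
        for i in range(1, rng.randint(1, max_copies) + 1):
            toks.append(GeneToken(f"g{f}", i, rng.choice((1, -1))))
    rng.shuffle(toks)
    k = n_chroms or rng.randint(1, max(1, len(toks) // 2))
    cuts = sorted(rng.sample(range(1, len(toks)), k - 1)) if k > 1 else []
    chroms, prev = [], 0
    for cut in cuts + [len(toks)]:
        part = tuple(toks[prev:cut])
        prev = cut
        if part:
            chroms.append(Chromosome(part, circular=True))
    return ChromosomeStructure(tuple(chroms)).canonical()


def exhaustive_bijection_minimum(a, b, score):
    """Minimum of `score(a2, b2)` over all per-family partial bijections."""
    pa, pb = _paralog_sets(a), _paralog_sets(b)
    fams = sorted(set(pa) | set(pb))

    def options(fam):
        A, B = pa.get(fam, []), pb.get(fam, [])
        for r in range(min(len(A), len(B)) + 1):
            for asub in itertools.combinations(A, r):
                for bperm in itertools.permutations(B, r):
                    yield dict(zip(asub, bperm))

    best = None
    for combo in itertools.product(*[list(options(f)) for f in fams]):
        bij = Bijections({f: m for f, m in zip(fams, combo) if m})
        val = score(*relabel_matched(a, b, bij))
        if best is None or val < best:
            best = val
    return best


class TestConstructionCounts:
    def test_variable_formulas_small_instance(self):
        # 10 families x 3 copies on each side, one circular chromosome each
        rng = random.Random(2)
        a = random_paralog_circular(rng, 10, max_copies=3, n_chroms=1)
        b = random_paralog_circular(rng, 10, max_copies=3, n_chroms=1)
        prob = build_matching_ilp(a, b)
        pa, pb = _paralog_sets(a), _paralog_sets(b)
        z_expected = sum(len(pa[f]) * len(pb[f]) for f in set(pa) & set(pb))
        assert prob.counts["z_vars"] == z_expected
        assert prob.counts["z_constraints"] == \
            sum(len(pa[f]) + len(pb[f]) for f in set(pa) & set(pb))
        assert prob.counts["x_vars_a"] == a.n_genes      # circular: one per gene
        assert prob.counts["y_vars"] == a.n_genes + b.n_genes
        assert prob.counts["x_constraints"] == 2 * (a.n_genes + b.n_genes)

    def test_linear_chromosome_rejected(self):
        a = parse_structure("g1 $")
        with pytest.raises(ValueError):
            build_matching_ilp(a, a)


class TestMatchingOptimum:
    def test_identical_structures_distance_zero(self):
        a = parse_structure("x.1 g x.2 @")
        bij, d = solve_paralog_matching(a, a)
        assert d == 0
        assert bij.maps["x"] in ({1: 1, 2: 2}, {1: 2, 2: 1})

    def test_no_paralogs_reduces_to_edit_distance(self):
        # with a single copy per family the optimum is the edit distance,
        # except where leaving a copy unmatched (one loss plus one emergence)
        # is cheaper than rearranging it -- partial bijections are allowed
        rng = random.Random(3)
        for _ in range(10):
            a = random_paralog_circular(rng, 4, max_copies=1)
            b = random_paralog_circular(rng, 4, max_copies=1)
            _bij, d = solve_paralog_matching(a, b)
            eng = Engine(a, b, UNIT_WEIGHTS, record_scenario=False).run()
            assert d <= eng.total_weight

            def score(a2, b2):
                return Engine(a2, b2, UNIT_WEIGHTS,
                              record_scenario=False).run().total_weight
            assert d == exhaustive_bijection_minimum(a, b, score)

    def test_matches_exhaustive_bijection_oracle(self):
        rng = random.Random(5)
        checked = 0
        for _ in range(25):
            nf = rng.randint(1, 3)
            a = random_paralog_circular(rng, nf, max_copies=2)
            b = random_paralog_circular(rng, nf, max_copies=2)
            if a.n_genes > 5 or b.n_genes > 5:
                continue
            _bij, d_ilp = solve_paralog_matching(a, b)

            def score(a2, b2):
                return Engine(a2, b2, UNIT_WEIGHTS,
                              record_scenario=False).run().total_weight
            d_oracle = exhaustive_bijection_minimum(a, b, score)
            assert d_ilp == d_oracle, (a, b)
            checked += 1
        assert checked >= 12

    def test_similarity_zero_blocks_pairing(self):
        a = parse_structure("x.1 g @")
        b = parse_structure("x.1 g @")
        sim = {("x", 1, 1): 0.0}
        prob = build_matching_ilp(a, b, sim)
        assert ("x", 1, 1) not in prob.z_index

    def test_similarity_penalty_in_objective(self):
        a = parse_structure("x.1 g @")
        b = parse_structure("x.1 g @")
        sim = {("x", 1, 1): 0.25, ("g", 0, 0): 1.0}
        prob = build_matching_ilp(a, b, sim)
        col = prob.z_index[("x", 1, 1)]
        assert prob.objective[col] == pytest.approx(0.75)


class TestPaths:
    def test_close_paths_counts(self):
        s = parse_structure("g1 g2 $\ng3 $\ng4 @")
        closed, n = close_paths(s)
        assert n == 2
        assert all(c.circular for c in closed.chromosomes)

    def test_all_circular_unchanged(self):
        s = parse_structure("g1 g2 @")
        closed, n = close_paths(s)
        assert n == 0 and closed == s

    def test_path_closure_error_bound(self):
        rng = random.Random(6)
        checked = 0
        for _ in range(20):
            a = random_paralog_circular(rng, 3, max_copies=1)
            b = random_paralog_circular(rng, 3, max_copies=1)
            # reopen some chromosomes to make them linear
            def reopen(s):
                chroms = [Chromosome(c.genes, rng.random() < 0.5)
                          for c in s.chromosomes]
                return ChromosomeStructure(tuple(chroms)).canonical()
            a, b = reopen(a), reopen(b)
            val, bound = distance_with_paths(a, b)
            opt = oracle_distance(a, b, UNIT_WEIGHTS, max_weight=val + bound)
            assert opt is not None
            assert abs(val - opt) <= bound, (a, b)
            checked += 1
        assert checked >= 15

    def test_circularization_example(self):
        a = parse_structure("g1 g2 $")
        b, _ = close_paths(a)
        val, bound = distance_with_paths(a, b)
        assert val == 1 and bound == 2


class TestBreakpointMatching:
    def test_no_paralogs_plain_distance(self):
        from chromorr.distance import breakpoint_distance
        a = parse_structure("g1 g2 g3 $")
        b = parse_structure("g2 g1 g3 $")
        bij, d = breakpoint_matching(a, b)
        assert d == breakpoint_distance(a, b)

    def test_disjoint_content(self):
        a = parse_structure("p1 p2 $")
        b = parse_structure("q1 @")
        _bij, d = breakpoint_matching(a, b)
        # one a-adjacency, one b-adjacency (the wrap), three private genes
        assert d == 1 + 1 + 3

    def test_matches_enumeration(self):
        from chromorr.distance import breakpoint_distance
        rng = random.Random(8)
        checked = 0
        for _ in range(15):
            a = random_paralog_circular(rng, 2, max_copies=2)
            b = random_paralog_circular(rng, 2, max_copies=2)
            if a.n_genes > 4 or b.n_genes > 4:
                continue
            _bij, d = breakpoint_matching(a, b)
            best = exhaustive_bijection_minimum(a, b, breakpoint_distance)
            assert d == best, (a, b)
            checked += 1
        assert checked >= 8
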