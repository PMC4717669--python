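import random

import pytest

from chromorr.graph import CommonGraph
from chromorr.model import parse_structure, write_structure
from conftest import random_pair

KNOWN_TYPES = {
    "a-circle", "b-circle", "circle", "loop", "a-loop",
    "1a", "2a", "2a'", "3a", "3a'", "1b", "2b", "2b'", "3b", "3b'",
    "1_a", "1_b", "1'", "1''", "2", "2'", "3",
    "final", "isolated_conv", "conv-circle",
}


def classified(a_text, b_text):
    g = CommonGraph(parse_structure(a_text), parse_structure(b_text))
    return g, [(c.classify(), c) for c in g.components()]


class TestConstruction:
    def test_identical_circles_give_final_two_circles(self):
        g, comps = classified("g1 g2 @", "g1 g2 @")
        assert [t for t, _ in comps] == ["final", "final"]

    def test_private_region_between_shared_genes(self):
        # the region node sits between the g1/g2 extremities on the a side
        # while a b-edge joins them directly: a 2-circle with an a-node
        g, comps = classified("g1 x g2 $", "g1 g2 $")
        types = sorted(t for t, _ in comps)
        assert types == ["a-circle", "isolated_conv", "isolated_conv"]

    def test_private_circular_chromosome_is_loop(self):
        g, comps = classified("x @\ng1 $", "g1 $")
        assert "a-loop" in [t for t, _ in comps]
        g, comps = classified("g1 $", "x @\ng1 $")
        assert "loop" in [t for t, _ in comps]

    def test_unresolved_paralogs_rejected(self):
        from chromorr.model import Chromosome, ChromosomeStructure, GeneToken
        a = parse_structure("x.1 x.2 $")
        b = parse_structure("x.1 $")
        CommonGraph(a, b)    # indexed paralogs are fine
        dup = ChromosomeStructure((Chromosome((
            GeneToken("x"), GeneToken("x")), False),))
        with pytest.raises(ValueError):
            CommonGraph(dup, b)

    def test_extraction_returns_inputs(self):
        a = parse_structure("g1 x g2 $\n-g3 @")
        b = parse_structure("g3 g1 y @")
        g = CommonGraph(a, b)
        assert g.extract("a") == a
        assert g.extract("b") == b


class TestClassification:
    def test_isolated_private_target_node(self):
        # an isolated region node of the target structure
        g, comps = classified("g1 $", "g1 $\nq $")
        assert "2a'" in [t for t, _ in comps]

    def test_isolated_private_source_node(self):
        g, comps = classified("g1 $\np $", "g1 $")
        assert "2b'" in [t for t, _ in comps]

    def test_two_hanging_only_path(self):
        # source region - extremity - target region: an even path with
        # exactly its two hanging edges
        g, comps = classified("p g1 $", "q g1 $")
        assert "2'" in [t for t, _ in comps]

    def test_degree_bound_per_side(self):
        rng = random.Random(11)
        for _ in range(50):
            pair = random_pair(rng, max_genes=4)
            if pair is None:
                continue
            g = CommonGraph(*pair)
            for (key, end), slots in g.conv_slots.items():
                assert sum(1 for e in slots.values() if e) <= 2

    def test_classification_total_after_closures(self):
        # the type system covers every component remaining once the
        # conventional-edge closures of steps 1-2 have run
        from chromorr.engine import Engine
        from chromorr.model import UNIT_WEIGHTS
        rng = random.Random(7)
        for _ in range(250):
            pair = random_pair(rng, max_genes=5)
            if pair is None:
                continue
            eng = Engine(*pair, UNIT_WEIGHTS, record_scenario=False)
            eng.run(stop_after="step2")
            for comp in eng.g.components():
                t = comp.classify()
                assert t in KNOWN_TYPES, (
                    t, write_structure(pair[0]), write_structure(pair[1]))

    def test_dot_export_mentions_all_edges(self):
        g = CommonGraph(parse_structure("g1 x g2 $"),
                        parse_structure("g1 g2 $"))
        dot = g.to_dot()
        assert dot.startswith("graph") and dot.count("--") == len(g.edges)

    def test_length_definition(self):
        # length = internal special nodes + conventional edges
        g, comps = classified("g1 x g2 $", "g1 g2 $")
        circle = next(c for t, c in comps if t == "a-circle")
        assert circle.length == 2
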