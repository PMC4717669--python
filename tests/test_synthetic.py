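import random

import pytest

from chromorr.engine import Engine
from chromorr.model import UNIT_WEIGHTS
from chromorr.synthetic import (EvolutionConfig, mutate, random_structure,
                                simulate_evolution)


class TestRandomStructure:
    def test_seed_reproducibility(self):
        cfg = EvolutionConfig(seed=42, gene_alphabet=6)
        assert random_structure(cfg) == random_structure(cfg)

    def test_different_seeds_differ_somewhere(self):
        outs = {random_structure(EvolutionConfig(seed=s)).canonical_key
                for s in range(12)}
        assert len(outs) > 1

    def test_alphabet_size(self):
        cfg = EvolutionConfig(seed=1, gene_alphabet=5)
        s = random_structure(cfg)
        assert s.n_genes == 5

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            EvolutionConfig(seed=None)


class TestSimulation:
    def test_zero_events_keeps_root_everywhere(self):
        cfg = EvolutionConfig(seed=5, gene_alphabet=4, events_per_edge=0)
        root = random_structure(cfg)
        leaves, truth = simulate_evolution(root, (("A", "B"), "C"), cfg)
        assert all(s == root for s in leaves.values())

    def test_reproducible(self):
        cfg = EvolutionConfig(seed=9, gene_alphabet=5, events_per_edge=2)
        root = random_structure(cfg)
        l1, _ = simulate_evolution(root, ("A", ("B", "C")), cfg)
        l2, _ = simulate_evolution(root, ("A", ("B", "C")), cfg)
        assert l1 == l2

    def test_leaf_distance_bounded_by_event_count(self):
        # with unit weights, each simulated event moves the structure by at
        # most one operation, so the path event count bounds the distance
        rng = random.Random(13)
        for trial in range(5):
            cfg = EvolutionConfig(seed=rng.randint(0, 2**30), gene_alphabet=4,
                                  events_per_edge=2,
                                  op_rates={"double": 0.5, "sesqui": 0.2,
                                            "cutjoin": 0.3, "delete": 0.0,
                                            "insert": 0.0})
            root = random_structure(cfg)
            leaves, truth = simulate_evolution(root, ("A", "B"), cfg)
            d = Engine(leaves["A"], leaves["B"], UNIT_WEIGHTS,
                       record_scenario=False).run().total_weight
            assert d <= 2 * cfg.events_per_edge

    def test_truth_contains_internal_nodes(self):
        cfg = EvolutionConfig(seed=3, gene_alphabet=4, events_per_edge=1)
        root = random_structure(cfg)
        leaves, truth = simulate_evolution(root, (("A", "B"), ("C", "D")), cfg)
        assert "root" in truth and {"A", "B", "C", "D"} <= set(truth)

    def test_mutate_applies_requested_number(self):
        cfg = EvolutionConfig(seed=11, gene_alphabet=5)
        root = random_structure(cfg)
        out = mutate(root, 3, random.Random(2), cfg, [1])
        assert out.families()  # still a valid structure
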