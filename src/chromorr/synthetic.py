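"""Seeded generation of random structures and simulated evolution.

The generator draws a random arrangement of a gene alphabet into linear and
circular chromosomes; the simulator applies randomly chosen operations of the
six kinds along the edges of a phylogeny, recording the true ancestral
arrangement so that reconstruction algorithms can be scored against it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import Chromosome, ChromosomeStructure, GeneToken
from . import ops as _ops


@dataclass
class EvolutionConfig:
    """Parameters of the random generator and the edge-wise simulator.

    ``op_rates`` are relative probabilities of the operation kinds applied on
    an edge; ``events_per_edge`` is the (mean) number of events per tree edge;
    ``gene_alphabet`` the number of gene families in the root; ``p_circular``
    the chance a generated chromosome is circular.
    """

    seed: int
    gene_alphabet: int = 6
    n_chromosomes: int = 2
    p_circular: float = 0.5
    events_per_edge: int = 2
    poisson_events: bool = False
    op_rates: Dict[str, float] = field(default_factory=lambda: {
        "double": 0.45, "sesqui": 0.15, "cutjoin": 0.2,
        "delete": 0.1, "insert": 0.1})
    paralog_birth_prob: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for k, v in self.op_rates.items():
            if not 0 <= v:
                raise ValueError(f"negative rate for {k}")


def random_structure(cfg: EvolutionConfig,
                     rng: Optional[random.Random] = None,
                     name: str = "") -> ChromosomeStructure:
    """A random structure over families g1..gN, reproducible from the seed."""
    rng = rng or random.Random(cfg.seed)
    genes = [GeneToken(f"g{i + 1}", None, rng.choice((1, -1)))
             for i in range(cfg.gene_alphabet)]
    rng.shuffle(genes)
    k = max(1, min(cfg.n_chromosomes, len(genes)))
    cuts = sorted(rng.sample(range(1, len(genes)), k - 1)) if k > 1 else []
    chroms = []
    prev = 0
    for cut in cuts + [len(genes)]:
        part = tuple(genes[prev:cut])
        prev = cut
        if part:
            chroms.append(Chromosome(part, rng.random() < cfg.p_circular))
    return ChromosomeStructure(tuple(chroms), name).canonical()


def random_content_pair(rng: random.Random, n_universe: int,
                        p_shared: float = 0.6
                        ) -> Tuple[ChromosomeStructure, ChromosomeStructure]:
    """A random structure pair over a small gene universe.

    Each gene is shared by both structures with probability ``p_shared``,
    otherwise private to one side (equally likely); the arrangements are
    independent random chromosome sets.
    """
    fams_a, fams_b = [], []
    for i in range(n_universe):
        r = rng.random()
        if r < p_shared:
            fams_a.append(f"g{i}")
            fams_b.append(f"g{i}")
        elif r < p_shared + (1 - p_shared) / 2:
            fams_a.append(f"p{i}")
        else:
            fams_b.append(f"q{i}")
    if not fams_a or not fams_b:
        return random_content_pair(rng, n_universe, p_shared)

    def arrange(fams):
        toks = [GeneToken(f, None, rng.choice((1, -1))) for f in fams]
        rng.shuffle(toks)
        k = rng.randint(1, len(toks))
        cuts = sorted(rng.sample(range(1, len(toks)), k - 1)) if k > 1 else []
        chroms, prev = [], 0
        for cut in cuts + [len(toks)]:
            part = tuple(toks[prev:cut])
            prev = cut
            if part:
                chroms.append(Chromosome(part, rng.random() < 0.5))
        return ChromosomeStructure(tuple(chroms)).canonical()

    return arrange(fams_a), arrange(fams_b)


def _random_op(state: _ops.AdjacencyState, rng: random.Random,
               cfg: EvolutionConfig, fresh: List[int]) -> _ops.AdjacencyState:
    """Apply one random operation; special-set is empty (all genes kept
    nameable), deletions remove a random single gene, insertions add a fresh
    one."""
    kinds, weights = zip(*sorted(cfg.op_rates.items()))
    kind = rng.choices(kinds, weights)[0]
    adjs = sorted(state.adjacencies, key=sorted)
    telos = sorted(state.telomeres())
    empty = frozenset()
    if kind == "double" and len(adjs) >= 2:
        a, b = rng.sample(adjs, 2)
        (x, y), (u, v) = (tuple(a) * 2)[:2], (tuple(b) * 2)[:2]
        pairs = rng.choice((((x, u), (y, v)), ((x, v), (y, u))))
        new = set(state.adjacencies) - {a, b}
        for p in pairs:
            if p[0] != p[1]:
                new.add(frozenset(p))
        return _ops.AdjacencyState(state.genes, frozenset(new))
    if kind == "sesqui" and adjs and telos:
        a = rng.choice(adjs)
        z = rng.choice(telos)
        keep = rng.choice(tuple(a))
        return _ops.AdjacencyState(
            state.genes, (state.adjacencies - {a}) | {frozenset((keep, z))})
    if kind == "cutjoin":
        if adjs and (not telos or rng.random() < 0.5):
            a = rng.choice(adjs)
            return _ops.AdjacencyState(state.genes, state.adjacencies - {a})
        if len(telos) >= 2:
            x, y = rng.sample(telos, 2)
            return _ops.AdjacencyState(
                state.genes, state.adjacencies | {frozenset((x, y))})
    if kind == "delete" and len(state.genes) > 1:
        g = rng.choice(sorted(state.genes))
        run, left, right, _circ = _ops.special_regions(
            state, frozenset({g}))[0]
        return _ops.apply_delete_region(state, run, left, right)
    if kind == "insert":
        gid = fresh[0]
        fresh[0] += 1
        key = (f"n{gid}", 0)
        new_genes = state.genes | {key}
        adj = set(state.adjacencies)
        mode = rng.random()
        if telos and mode < 0.4:
            adj.add(frozenset(((key, 1), rng.choice(telos))))
        elif adjs and mode < 0.8:
            a = rng.choice(adjs)
            x, y = (tuple(a) * 2)[:2]
            adj.discard(a)
            adj.add(frozenset(((key, 1), x)))
            if y != x:
                adj.add(frozenset(((key, 2), y)))
        # else: new single-gene linear chromosome
        return _ops.AdjacencyState(frozenset(new_genes), frozenset(adj))
    return state


def mutate(s: ChromosomeStructure, n_events: int, rng: random.Random,
           cfg: EvolutionConfig, fresh: List[int]) -> ChromosomeStructure:
    state = _ops.to_adjacencies(s)
    for _ in range(n_events):
        state = _random_op(state, rng, cfg, fresh)
    return _ops.to_structure(state)


def simulate_evolution(root: ChromosomeStructure, tree,
                       cfg: EvolutionConfig):
    """Evolve `root` along a tree given as nested tuples (or leaf names).

    Returns ``(leaves, truth)`` where leaves maps leaf name -> structure and
    truth maps every node id -> structure (the true arrangement).  Node ids
    are leaf names for leaves and dotted paths ("", "0", "0.1", ...) for
    internal nodes.
    """
    rng = random.Random(cfg.seed)
    fresh = [1 + max((0, *(int(k[0][1:]) for k in _ops.to_adjacencies(root).genes
                           if k[0].startswith("n") and k[0][1:].isdigit())))]
    leaves: Dict[str, ChromosomeStructure] = {}
    truth: Dict[str, ChromosomeStructure] = {}

    def n_events():
        if cfg.poisson_events:
            # inverse-transform sampling keeps the dependency surface small
            import math
            lam, u, k, p = cfg.events_per_edge, rng.random(), 0, None
            p = math.exp(-lam)
            cum = p
            while u > cum and k < 10 * lam + 10:
                k += 1
                p *= lam / k
                cum += p
            return k
        return cfg.events_per_edge

    def descend(node, structure, path):
        truth[path if path else "root"] = structure
        if not isinstance(node, tuple):
            named = ChromosomeStructure(structure.chromosomes, str(node))
            leaves[str(node)] = named
            truth[str(node)] = named
            return
        for i, child in enumerate(node):
            child_struct = mutate(structure, n_events(), rng, cfg, fresh)
            descend(child, child_struct, f"{path}.{i}" if path else str(i))

    descend(tree, root, "")
    return leaves, truth
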