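"""Ancestral-structure reconstruction on trees.

The reconstruction problem asks for a binary tree over the given structures
plus an assignment of a structure to every internal node minimising the sum
of edge distances (the arrangement weight).  It reduces to the minimum
Steiner tree problem in the metric space of all structures: the first
algorithm takes the minimum spanning tree over the terminals (approximation
ratio 2); the second adds medians of triplets greedily in the style of the
11/6-ratio Steiner algorithm; greedy descent then improves any arrangement by
single-operation moves at internal nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .model import (Chromosome, ChromosomeStructure, GeneToken, WeightScheme,
                    UNIT_WEIGHTS)
from .engine import Engine
from .distance import breakpoint_distance
from . import ops as _ops

__all__ = [
    "DistanceMatrix", "ArrangedTree", "distance_matrix", "pairwise_distance",
    "build_tree_upgma", "build_tree_nj", "steiner_first", "median_three",
    "zelikovsky_second", "descent_refine", "root_by_oneway",
]


def _has_paralogs(s: ChromosomeStructure) -> bool:
    keys = s.gene_keys()
    return len(keys) != len({k[0] for k in keys})


def pairwise_distance(a: ChromosomeStructure, b: ChromosomeStructure,
                      metric: str = "breakpoint",
                      w: Optional[WeightScheme] = None) -> Fraction:
    """Symmetric distance between two structures under the chosen metric.

    Paralogs are resolved on the fly: by the breakpoint 0/1 programme for the
    breakpoint metric, by the circular-closure ILP for the biological one.
    """
    if metric == "breakpoint":
        if _has_paralogs(a) or _has_paralogs(b):
            from .ilp import breakpoint_matching
            return Fraction(breakpoint_matching(a, b)[1])
        return Fraction(breakpoint_distance(a, b))
    w = w or UNIT_WEIGHTS
    if _has_paralogs(a) or _has_paralogs(b):
        from .ilp import close_paths, solve_paralog_matching, relabel_matched
        a2, _ = close_paths(a)
        b2, _ = close_paths(b)
        bij, _d = solve_paralog_matching(a2, b2)
        a, b = relabel_matched(a, b, bij)
    d_ab = Engine(a, b, w, record_scenario=False).run().total_weight
    d_ba = Engine(b, a, w, record_scenario=False).run().total_weight
    return (d_ab + d_ba) / 2


def one_way_distance(a, b, w: WeightScheme) -> Fraction:
    if _has_paralogs(a) or _has_paralogs(b):
        from .ilp import close_paths, solve_paralog_matching, relabel_matched
        bij, _ = solve_paralog_matching(close_paths(a)[0], close_paths(b)[0])
        a, b = relabel_matched(a, b, bij)
    return Engine(a, b, w, record_scenario=False).run().total_weight


@dataclass
class DistanceMatrix:
    labels: List[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric, zero diagonal")

    def triangle_violations(self) -> List[tuple]:
        out = []
        n = len(self.labels)
        for i, j, k in itertools.permutations(range(n), 3):
            if self.d[i, j] > self.d[i, k] + self.d[k, j] + 1e-9:
                out.append((self.labels[i], self.labels[j], self.labels[k]))
        return out

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + " ".join(f"{x:.4f}" for x in row))
        return "\n".join(lines) + "\n"


def distance_matrix(structures: Sequence[ChromosomeStructure],
                    metric: str = "breakpoint",
                    w: Optional[WeightScheme] = None) -> DistanceMatrix:
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    labels = [s.name or f"s{i}" for i, s in enumerate(structures)]
    n = len(structures)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(
                pairwise_distance(structures[i], structures[j], metric, w))
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# tree building from a distance matrix

def build_tree_upgma(dm: DistanceMatrix) -> str:
    """Average-linkage agglomeration; deterministic tie-break by label order.

    Returns a rooted Newick string with branch lengths.
    """
    clusters = {i: ([i], dm.labels[i], 0.0) for i in range(len(dm.labels))}
    dist = {(i, j): dm.d[i, j] for i in clusters for j in clusters if i < j}
    nxt = len(dm.labels)
    while len(clusters) > 1:
        (i, j), dmin = min(
            dist.items(),
            key=lambda kv: (kv[1], clusters[kv[0][0]][1], clusters[kv[0][1]][1]))
        mi, ni, hi = clusters.pop(i)
        mj, nj, hj = clusters.pop(j)
        h = dmin / 2
        newick = f"({ni}:{h - hi:.6g},{nj}:{h - hj:.6g})"
        members = mi + mj
        for k in list(clusters):
            a, b = min(i, k), max(i, k)
            c, e = min(j, k), max(j, k)
            dk = (len(mi) * dist.pop((a, b) if (a, b) in dist else (b, a))
                  + len(mj) * dist.pop((c, e) if (c, e) in dist else (e, c))) \
                / (len(mi) + len(mj))
            dist[(min(nxt, k), max(nxt, k))] = dk
        clusters[nxt] = (members, newick, h)
        dist = {k: v for k, v in dist.items()
                if k[0] in clusters and k[1] in clusters}
        nxt += 1
    return next(iter(clusters.values()))[1] + ";"


def build_tree_nj(dm: DistanceMatrix) -> str:
    """Neighbour joining (unrooted, written rooted at the last join)."""
    ids = list(range(len(dm.labels)))
    names = {i: dm.labels[i] for i in ids}
    d = {(i, j): dm.d[i, j] for i in ids for j in ids if i != j}
    nxt = len(ids)
    while len(ids) > 2:
        n = len(ids)
        r = {i: sum(d[(i, j)] for j in ids if j != i) for i in ids}
        best = min(((i, j) for i in ids for j in ids if i < j),
                   key=lambda p: ((n - 2) * d[p] - r[p[0]] - r[p[1]],
                                  names[p[0]], names[p[1]]))
        i, j = best
        vi = d[(i, j)] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        vj = d[(i, j)] - vi
        names[nxt] = f"({names[i]}:{max(vi,0):.6g},{names[j]}:{max(vj,0):.6g})"
        for k in ids:
            if k in (i, j):
                continue
            d[(nxt, k)] = d[(k, nxt)] = (d[(i, k)] + d[(j, k)] - d[(i, j)]) / 2
        ids = [k for k in ids if k not in (i, j)] + [nxt]
        nxt += 1
    i, j = ids
    return f"({names[i]}:{d[(i, j)]:.6g},{names[j]}:0);"


# ---------------------------------------------------------------------------
# arranged trees

@dataclass
class ArrangedTree:
    """Rooted binary tree with a structure at every node."""

    tree: nx.DiGraph                      # edges parent -> child
    arrangement: Dict[str, ChromosomeStructure]
    root: str

    def leaves(self) -> List[str]:
        return sorted(n for n in self.tree if self.tree.out_degree(n) == 0)

    def internal(self) -> List[str]:
        return sorted(n for n in self.tree if self.tree.out_degree(n) > 0)

    def weight(self, metric: str = "breakpoint",
               w: Optional[WeightScheme] = None) -> Fraction:
        total = Fraction(0)
        for u, v in self.tree.edges:
            total += Fraction(pairwise_distance(
                self.arrangement[u], self.arrangement[v], metric, w))
        return total

    def newick(self) -> str:
        def rec(n):
            kids = sorted(self.tree.successors(n))
            if not kids:
                return n
            return "(" + ",".join(rec(k) for k in kids) + ")" + n
        return rec(self.root) + ";"


def _mst_to_arranged(G: nx.Graph,
                     structures: Dict[str, ChromosomeStructure],
                     terminals: List[str]) -> ArrangedTree:
    """Backward transform of a Steiner/spanning tree into a binary rooted
    leaf-labelled tree; duplicated nodes carry the same structure, so the
    tree weight never exceeds the spanning tree weight."""
    T = nx.minimum_spanning_tree(G, algorithm="prim", weight="weight")
    if len(T) == 1:
        only = next(iter(T))
        D = nx.DiGraph()
        D.add_node(only)
        return ArrangedTree(D, {only: structures[only]}, only)

    arrangement: Dict[str, ChromosomeStructure] = {}
    work = nx.Graph()
    rename = {n: (f"{n}#anc" if n in terminals and T.degree(n) > 1 else n)
              for n in T.nodes}
    for u, v in T.edges:
        work.add_edge(rename[u], rename[v])
    for n in T.nodes:
        arrangement[rename[n]] = structures[n]
        if rename[n] != n:                 # internal terminal: add leaf copy
            work.add_edge(rename[n], n)
            arrangement[n] = structures[n]

    term_set = set(terminals)
    changed = True                          # drop Steiner points left as leaves
    while changed and work.number_of_nodes() > 1:
        changed = False
        for n in list(work.nodes):
            if work.degree(n) <= 1 and n not in term_set \
                    and not n.endswith("#anc"):
                work.remove_node(n)
                changed = True

    deg2 = sorted(n for n in work if work.degree(n) == 2)
    root = deg2[0] if deg2 else \
        sorted(work.nodes, key=lambda n: (work.degree(n) == 1, n))[0]
    D = nx.bfs_tree(work, root)
    out = nx.DiGraph()
    out.add_node(root)
    serial = itertools.count()

    def expand(parent_out, n):
        kids = sorted(D.successors(n))
        cur = n
        while len(kids) > 2:
            extra = f"{n}#b{next(serial)}"
            arrangement[extra] = arrangement[n]
            out.add_edge(cur, kids[0])
            expand(kids[0], kids[0])
            out.add_edge(cur, extra)
            cur = extra
            kids = kids[1:]
        for k in kids:
            out.add_edge(cur, k)
            expand(k, k)

    expand(root, root)
    arrangement = {k: v for k, v in arrangement.items() if k in out}
    return ArrangedTree(out, arrangement, root)


def steiner_first(structures: Sequence[ChromosomeStructure],
                  metric: str = "breakpoint",
                  w: Optional[WeightScheme] = None) -> ArrangedTree:
    """MST-based reconstruction: within a factor 2 of the optimum."""
    labels = [s.name or f"s{i}" for i, s in enumerate(structures)]
    dm = distance_matrix(structures, metric, w)
    G = nx.Graph()
    for i, li in enumerate(labels):
        G.add_node(li)
        for j in range(i + 1, len(labels)):
            G.add_edge(li, labels[j], weight=dm.d[i, j])
    named = {l: s for l, s in zip(labels, structures)}
    return _mst_to_arranged(G, named, labels)


# ---------------------------------------------------------------------------
# medians and the triple-contraction algorithm

def _all_structures(universe: Sequence[str], max_genes: Optional[int] = None):
    """Every structure over subsets of a small gene universe."""
    universe = sorted(universe)
    for r in range(len(universe) + 1):
        if max_genes is not None and r > max_genes:
            break
        for subset in itertools.combinations(universe, r):
            exts = [((g, 0), e) for g in subset for e in (1, 2)]
            for matching in _matchings(exts):
                st = _ops.AdjacencyState(frozenset((g, 0) for g in subset),
                                         frozenset(matching))
                yield _ops.to_structure(st)


def _matchings(elems):
    if not elems:
        yield []
        return
    first = elems[0]
    rest = elems[1:]
    for m in _matchings(rest):
        yield m
    for i, other in enumerate(rest):
        for m in _matchings(rest[:i] + rest[i + 1:]):
            yield m + [frozenset((first, other))]


def median_three(a: ChromosomeStructure, b: ChromosomeStructure,
                 c: ChromosomeStructure, metric: str = "breakpoint",
                 w: Optional[WeightScheme] = None,
                 exhaustive_limit: int = 3
                 ) -> Tuple[ChromosomeStructure, Fraction]:
    """A structure close to minimising d(v,a) + d(v,b) + d(v,c).

    Breakpoint metric: exact by exhaustive search when the united gene set is
    small.  Biological metric: the scenario-walk heuristic — score every
    intermediate of the pairwise transformations against the third structure
    and keep the best structure encountered.
    """
    fams = sorted({k[0] for s in (a, b, c) for k in s.gene_keys()})
    if metric == "breakpoint" and len(fams) <= exhaustive_limit:
        best, best_d = None, None
        for v in _all_structures(fams):
            d = sum(pairwise_distance(v, s, "breakpoint") for s in (a, b, c))
            if best_d is None or d < best_d:
                best, best_d = v, d
        return best, Fraction(best_d)
    if metric == "breakpoint":
        return _median_breakpoint_ilp(a, b, c)
    return _median_biological_walk(a, b, c, w or UNIT_WEIGHTS)


def _median_breakpoint_ilp(a, b, c):
    """0/1 programme: majority gene content, then a maximum-agreement
    matching on extremities (each adjacency scores its support among the
    three structures)."""
    from scipy import sparse
    from scipy.optimize import Bounds, LinearConstraint, milp
    states = [_ops.to_adjacencies(s) for s in (a, b, c)]
    support_g: Dict[tuple, int] = {}
    for st in states:
        for g in st.genes:
            support_g[g] = support_g.get(g, 0) + 1
    genes = sorted(g for g, k in support_g.items() if k >= 2)
    gene_set = frozenset(genes)
    cand: Dict[frozenset, int] = {}
    for st in states:
        for adj in st.adjacencies:
            if all(e[0] in gene_set for e in adj):
                cand[adj] = cand.get(adj, 0) + 1
    cand_list = sorted(cand, key=sorted)
    n = len(cand_list)
    if n == 0:
        med = _ops.to_structure(_ops.AdjacencyState(gene_set, frozenset()))
        d = sum(pairwise_distance(med, s, "breakpoint") for s in (a, b, c))
        return med, Fraction(d)
    obj = np.array([3.0 - 2.0 * cand[adj] for adj in cand_list])
    rows, lbs, ubs, data, ri, ci = [], [], [], [], [], []
    ext_rows: Dict[tuple, int] = {}
    for col, adj in enumerate(cand_list):
        for e in adj:
            r = ext_rows.setdefault(e, len(ext_rows))
            ri.append(r)
            ci.append(col)
            data.append(1.0)
    A = sparse.csr_matrix((data, (ri, ci)), shape=(len(ext_rows), n))
    res = milp(c=obj, constraints=LinearConstraint(
        A, np.full(len(ext_rows), -np.inf), np.ones(len(ext_rows))),
        integrality=np.ones(n), bounds=Bounds(np.zeros(n), np.ones(n)))
    xs = np.round(res.x).astype(int)
    chosen = frozenset(adj for col, adj in enumerate(cand_list) if xs[col])
    med = _ops.to_structure(_ops.AdjacencyState(gene_set, chosen))
    d = sum(pairwise_distance(med, s, "breakpoint") for s in (a, b, c))
    return med, Fraction(d)


def _median_biological_walk(a, b, c, w: WeightScheme):
    from .distance import transform_to_final
    candidates = {a, b, c}
    for x, y in ((a, b), (a, c), (b, c)):
        try:
            scen = transform_to_final(x, y, w)
        except Exception:
            continue
        for rec in scen.ops:
            if rec.structure_after is not None:
                candidates.add(rec.structure_after)
    best, best_d = None, None
    for v in candidates:
        d = sum(pairwise_distance(v, s, "biological", w) for s in (a, b, c))
        if best_d is None or d < best_d:
            best, best_d = v, d
    return best, Fraction(best_d)


def zelikovsky_second(structures: Sequence[ChromosomeStructure],
                      metric: str = "breakpoint",
                      w: Optional[WeightScheme] = None) -> ArrangedTree:
    """Triple-contraction reconstruction (ratio 11/6 for breakpoint).

    Greedily contracts the terminal triplet whose median saves the most
    spanning-tree weight, then spans terminals plus accepted medians.
    """
    labels = [s.name or f"s{i}" for i, s in enumerate(structures)]
    named: Dict[str, ChromosomeStructure] = dict(zip(labels, structures))
    if len(structures) < 3:
        return steiner_first(structures, metric, w)
    dm = distance_matrix(structures, metric, w)
    G1 = nx.Graph()
    for i, li in enumerate(labels):
        for j in range(i + 1, len(labels)):
            G1.add_edge(li, labels[j], weight=float(dm.d[i, j]))

    medians = {}
    for z in itertools.combinations(sorted(labels), 3):
        v, dz = median_three(named[z[0]], named[z[1]], named[z[2]], metric, w)
        medians[z] = (v, float(dz))

    def mst_weight(graph):
        return sum(d["weight"] for *_e, d in
                   nx.minimum_spanning_edges(graph, algorithm="prim",
                                             data=True))

    accepted = []
    Gp = G1.copy()
    for _ in range(len(labels)):
        base = mst_weight(Gp)
        best = None
        for z in sorted(medians):
            v, dz = medians[z]
            Gz = Gp.copy()
            e1, e2 = (z[0], z[1]), (z[0], z[2])
            Gz[e1[0]][e1[1]]["weight"] = 0.0
            Gz[e2[0]][e2[1]]["weight"] = 0.0
            gain = base - mst_weight(Gz) - dz
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, z, Gz, v)
        if best is None:
            break
        _gain, z, Gz, v = best
        Gp = Gz
        accepted.append((z, v))

    # final spanning graph over terminals plus accepted medians
    G2 = nx.Graph()
    all_named = dict(named)
    for idx, (z, v) in enumerate(accepted):
        all_named[f"median{idx}"] = v
    keys = sorted(all_named)
    for i, ki in enumerate(keys):
        for j in range(i + 1, len(keys)):
            G2.add_edge(ki, keys[j], weight=float(
                pairwise_distance(all_named[ki], all_named[keys[j]],
                                  metric, w)))
    return _mst_to_arranged(G2, all_named, labels)


# ---------------------------------------------------------------------------
# greedy descent refinement

def _neighbour_structures(s: ChromosomeStructure,
                          insert_pool: Sequence[tuple]) -> List[ChromosomeStructure]:
    """All structures one operation away (standard ops, single-gene deletions
    and insertions of pool genes not present)."""
    state = _ops.to_adjacencies(s)
    out = set()
    empty = frozenset()
    for _kind, ns in _ops.standard_moves(state, empty):
        out.add(_ops.to_structure(ns))
    for g in sorted(state.genes):
        run, left, right, _c = _ops.special_regions(state, frozenset({g}))[0]
        out.add(_ops.to_structure(
            _ops.apply_delete_region(state, run, left, right)))
    telos = sorted(state.telomeres())
    adjs = sorted(state.adjacencies, key=sorted)
    for key in sorted(set(insert_pool) - set(state.genes)):
        genes2 = state.genes | {key}
        for ends in (((key, 1),), ):
            head, tail = (key, 1), (key, 2)
            out.add(_ops.to_structure(
                _ops.AdjacencyState(genes2, state.adjacencies)))
            out.add(_ops.to_structure(_ops.AdjacencyState(
                genes2, state.adjacencies | {frozenset((head, tail))})))
            for t in telos:
                out.add(_ops.to_structure(_ops.AdjacencyState(
                    genes2, state.adjacencies | {frozenset((t, head))})))
            for adj in adjs:
                x, y = (tuple(adj) * 2)[:2]
                new = (state.adjacencies - {adj}) | \
                    {frozenset((x, head)), frozenset((tail, y))}
                out.add(_ops.to_structure(
                    _ops.AdjacencyState(genes2, frozenset(new))))
    out.discard(s)
    return sorted(out, key=lambda t: t.canonical_key)


def descent_refine(tree: ArrangedTree, w: WeightScheme,
                   max_rounds: int = 200) -> ArrangedTree:
    """Greedy local search: repeatedly apply the single-operation replacement
    at an internal node that decreases the total biological tree distance G
    the most; stop at a local minimum."""
    arr = dict(tree.arrangement)
    edges = list(tree.tree.edges)

    def edge_cost(u, v):
        return pairwise_distance(arr[u], arr[v], "biological", w)

    cost = {e: edge_cost(*e) for e in edges}
    incident = {}
    for e in edges:
        for n in e:
            incident.setdefault(n, []).append(e)
    leaves = set(tree.leaves())
    pool = sorted({k for s in arr.values() for k in s.gene_keys()})

    for _round in range(max_rounds):
        best = None
        for node in tree.internal():
            local = incident.get(node, [])
            base = sum(cost[e] for e in local)
            for cand in _neighbour_structures(arr[node], pool):
                tot = Fraction(0)
                for e in local:
                    other = e[1] if e[0] == node else e[0]
                    tot += pairwise_distance(cand, arr[other], "biological", w)
                gain = base - tot
                if gain > 0 and (best is None or gain > best[0]):
                    best = (gain, node, cand)
        if best is None:
            break
        _g, node, cand = best
        arr[node] = cand
        for e in incident.get(node, []):
            cost[e] = edge_cost(*e)
    return ArrangedTree(tree.tree, arr, tree.root)


def root_by_oneway(tree: ArrangedTree, w: WeightScheme) -> Tuple[str, Fraction]:
    """The node whose rooting minimises the total one-way distance from the
    root outwards along every edge."""
    und = tree.tree.to_undirected()
    best = None
    for root in sorted(und.nodes):
        total = Fraction(0)
        for u, v in nx.bfs_tree(und, root).edges:
            total += one_way_distance(tree.arrangement[u],
                                      tree.arrangement[v], w)
        if best is None or (total, root) < best:
            best = (total, root)
    return best[1], best[0]
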