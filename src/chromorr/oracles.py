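"""Brute-force reference solvers for the minimum-weight operation sequence.

The main solver, :func:`bfs_shortest_sequence`, is a bidirectional uniform-cost
search: from the source it applies cuts, joins, sesqui- and double-cut-and-
pastes and deletions of maximal source-private regions; from the target it does
the same with mirrored weights (a deletion seen from the target is an insertion
of the forward sequence, a cut is a forward join and vice versa).  The two
frontiers meet on structures whose gene content is exactly the shared genes.
This relies on the reordering fact that some minimum-weight sequence performs
all deletions before all insertions, which
:func:`explicit_insertion_search` — a unidirectional search that enumerates
insertion contents explicitly — verifies independently on tiny instances.

Moves are derived directly from structures, never from the common graph, so
the oracle shares no code path with the algorithm it checks.
"""

from __future__ import annotations

import heapq
import itertools
from fractions import Fraction
from math import gcd as _gcd
from typing import Dict, FrozenSet, List, Optional, Tuple

from .model import (ChromosomeStructure, OperationRecord, OpKind, WeightScheme)
from . import ops as _ops

# ---------------------------------------------------------------------------
# integer-encoded states: (genes bitmask, frozenset of adjacency codes)

State = Tuple[int, FrozenSet[int]]


class _Universe:
    """Id assignment for the genes of one structure pair."""

    def __init__(self, a: ChromosomeStructure, b: ChromosomeStructure):
        keys = sorted(set(a.gene_keys()) | set(b.gene_keys()))
        if len(keys) != len(set(a.gene_keys())) + len(set(b.gene_keys())) - len(
                set(a.gene_keys()) & set(b.gene_keys())):
            raise ValueError("paralogs must be resolved before oracle search")
        self.keys = keys
        self.index = {k: i for i, k in enumerate(keys)}
        self.mask_a = self._mask(a)
        self.mask_b = self._mask(b)
        self.common = self.mask_a & self.mask_b

    def _mask(self, s: ChromosomeStructure) -> int:
        m = 0
        for k in s.gene_keys():
            m |= 1 << self.index[k]
        return m

    def encode(self, s: ChromosomeStructure) -> State:
        st = _ops.to_adjacencies(s)
        mask = 0
        for g in st.genes:
            mask |= 1 << self.index[g]
        adj = frozenset(self._code(x, y) for x, y in
                        (sorted(a) if len(a) == 2 else (tuple(a)[0],) * 2
                         for a in st.adjacencies))
        return (mask, adj)

    def _ext_id(self, ext) -> int:
        return 2 * self.index[ext[0]] + (ext[1] - 1)

    def _code(self, x, y) -> int:
        i, j = sorted((self._ext_id(x), self._ext_id(y)))
        return (i << 6) | j

    def decode(self, state: State) -> ChromosomeStructure:
        genes = frozenset(self.keys[i] for i in range(len(self.keys))
                          if state[0] >> i & 1)
        adjs = set()
        for code in state[1]:
            i, j = code >> 6, code & 63
            x = (self.keys[i // 2], i % 2 + 1)
            y = (self.keys[j // 2], j % 2 + 1)
            adjs.add(frozenset((x, y)))
        return _ops.to_structure(_ops.AdjacencyState(genes, frozenset(adjs)))


def _adj_exts(code: int) -> Tuple[int, int]:
    return code >> 6, code & 63


def _telomeres(state: State, n: int) -> List[int]:
    used = set()
    for code in state[1]:
        i, j = _adj_exts(code)
        used.add(i)
        used.add(j)
    out = []
    mask = state[0]
    for g in range(n):
        if mask >> g & 1:
            for e in (2 * g, 2 * g + 1):
                if e not in used:
                    out.append(e)
    return out


def _mk(i: int, j: int) -> int:
    return (i << 6) | j if i <= j else (j << 6) | i


def _creates_special_circle(state: State, special_mask: int, adj,
                            new_codes) -> bool:
    """Does a newly added adjacency close a circle of special genes only?

    Pre-existing special circles are legitimate (they are deleted or, seen
    from the target, inserted whole); only closing a fresh one is the
    excluded "unnatural" variant.
    """
    if not special_mask:
        return False
    nbr: Dict[int, int] = {}
    for code in adj:
        i, j = _adj_exts(code)
        nbr[i], nbr[j] = j, i
    n_genes = state[0].bit_count()
    for code in new_codes:
        i, j = _adj_exts(code)
        if not (special_mask >> (i // 2) & 1 and special_mask >> (j // 2) & 1):
            continue
        start, ext, pure, circular = i, i, True, False
        for _ in range(n_genes + 1):
            if not special_mask >> (ext // 2) & 1:
                pure = False
                break
            nxt = nbr.get(ext ^ 1)
            if nxt is None:
                break
            if nxt == start:
                circular = True
                break
            ext = nxt
        if pure and circular:
            return True
    return False


def _int_special_regions(state: State, special_mask: int):
    """Maximal special runs: (genes_mask, left_ext|None, right_ext|None)."""
    nbr: Dict[int, int] = {}
    for code in state[1]:
        i, j = _adj_exts(code)
        nbr[i], nbr[j] = j, i
    todo = state[0] & special_mask
    out = []
    while todo:
        g = (todo & -todo).bit_length() - 1
        todo &= todo - 1
        run_mask = 1 << g
        flanks: List[Optional[int]] = [None, None]
        circular = False
        for side, ext0 in enumerate((2 * g, 2 * g + 1)):
            ext = ext0
            while True:
                nxt = nbr.get(ext)
                if nxt is None:
                    break
                ng = nxt // 2
                if not special_mask >> ng & 1:
                    flanks[side] = nxt
                    break
                if run_mask >> ng & 1:
                    circular = True
                    break
                run_mask |= 1 << ng
                todo &= ~(1 << ng)
                ext = nxt ^ 1
            if circular:
                break
        out.append((run_mask, flanks[0], flanks[1], circular))
    return out


def _one_side_moves(state: State, special_mask: int, w: dict, n: int,
                    restrict: bool = True):
    """Yield (kind, weight, new_state) for one search direction.

    With ``restrict`` the source-side exclusions apply: no cut inside a
    special region and no closing of a region into a fresh special circle.
    The target-side search runs unrestricted (its mirrored exclusions concern
    genes that do not exist on that side).
    """
    adj = state[1]
    if restrict:
        cuttable = [c for c in adj
                    if not (special_mask >> ((c >> 6) // 2) & 1
                            and special_mask >> ((c & 63) // 2) & 1)]
    else:
        cuttable = list(adj)
    telos = _telomeres(state, n)
    genes_mask = state[0]

    def banned(new, fresh):
        return restrict and _creates_special_circle(state, special_mask,
                                                    new, fresh)

    for c in cuttable:
        yield ("cut", w["cut"], (genes_mask, adj - {c}))

    for x, y in itertools.combinations(telos, 2):
        code = _mk(x, y)
        new = adj | {code}
        if not banned(new, (code,)):
            yield ("join", w["join"], (genes_mask, new))

    for c in cuttable:
        i, j = _adj_exts(c)
        if i == j:
            continue
        for keep in (i, j):
            for z in telos:
                code = _mk(keep, z)
                new = (adj - {c}) | {code}
                if not banned(new, (code,)):
                    yield ("sesqui", w["sesqui"], (genes_mask, new))

    for c1, c2 in itertools.combinations(cuttable, 2):
        x, y = _adj_exts(c1)
        u, v = _adj_exts(c2)
        for p, q in (((x, u), (y, v)), ((x, v), (y, u))):
            if p[0] == p[1] or q[0] == q[1]:
                continue
            cp, cq = _mk(*p), _mk(*q)
            new = (adj - {c1, c2}) | {cp, cq}
            if not banned(new, (cp, cq)):
                yield ("double", w["double"], (genes_mask, new))

    for run_mask, left, right, _circ in _int_special_regions(state, special_mask):
        new_adj = frozenset(
            c for c in adj
            if not (run_mask >> ((c >> 6) // 2) & 1
                    or run_mask >> ((c & 63) // 2) & 1))
        if left is not None and right is not None:
            new_adj = new_adj | {_mk(left, right)}
        yield ("delete", w["delete"], (genes_mask & ~run_mask, new_adj))


class _LexCost:
    """(operation count, total weight) with lexicographic ordering."""

    __slots__ = ("count", "weight")

    def __init__(self, count, weight):
        self.count = count
        self.weight = Fraction(weight)

    def _key(self):
        return (self.count, self.weight)

    def __add__(self, other):
        return _LexCost(self.count + other.count, self.weight + other.weight)

    def __mul__(self, k):
        return _LexCost(self.count * k, self.weight * k)

    def __lt__(self, other):
        return self._key() < other._key()

    def __le__(self, other):
        return self._key() <= other._key()

    def __gt__(self, other):
        return self._key() > other._key()

    def __eq__(self, other):
        return isinstance(other, _LexCost) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    def __repr__(self):
        return f"LexCost({self.count}, {self.weight})"


def _region_count(state: State, special_mask: int) -> int:
    """Number of maximal private regions; each needs >= 1 operation."""
    todo = state[0] & special_mask
    if not todo:
        return 0
    nbr: Dict[int, int] = {}
    for code in state[1]:
        i, j = _adj_exts(code)
        nbr[i], nbr[j] = j, i
    count = 0
    while todo:
        g = (todo & -todo).bit_length() - 1
        todo &= ~(1 << g)
        count += 1
        for ext0 in (2 * g, 2 * g + 1):
            ext = ext0
            while True:
                nxt = nbr.get(ext)
                if nxt is None or not special_mask >> (nxt // 2) & 1 \
                        or not todo >> (nxt // 2) & 1:
                    break
                todo &= ~(1 << (nxt // 2))
                ext = nxt ^ 1
    return count


def _dijkstra(start: State, special_mask: int, w: dict, n: int,
              cap, want_parents: bool, restrict: bool = True):
    zero = cap * 0
    min_w = min(w.values())
    dist: Dict[State, object] = {start: zero}
    parent: Dict[State, tuple] = {}
    pq = [(zero, 0, start)]
    counter = 1
    while pq:
        d, _, s = heapq.heappop(pq)
        if d > dist[s]:
            continue
        if d > cap:
            break
        for kind, wt, ns in _one_side_moves(s, special_mask, w, n, restrict):
            nd = d + wt
            if nd > cap:
                continue
            if ns not in dist or nd < dist[ns]:
                # admissible pruning: every surviving private region still
                # costs at least one operation before the frontiers can meet
                r = _region_count(ns, special_mask)
                if r and nd + min_w * r > cap:
                    continue
                dist[ns] = nd
                if want_parents:
                    parent[ns] = (s, kind)
                heapq.heappush(pq, (nd, counter, ns))
                counter += 1
    return dist, parent


def _bidirectional(sa: State, sb: State, uni, fw: dict, bw: dict, n: int,
                   cap, want_parents: bool):
    """Interleaved bidirectional uniform-cost search.

    The frontiers meet only on states whose gene content is exactly the
    shared genes; expansion stops once the two frontier minima cannot beat
    the best meeting found.
    """
    zero = cap * 0
    sides = []
    for start, special, w, restrict in (
            (sa, uni.mask_a & ~uni.common, fw, True),
            (sb, uni.mask_b & ~uni.common, bw, False)):
        sides.append({
            "dist": {start: zero}, "parent": {}, "settled": set(),
            "pq": [(zero, 0, start)], "special": special, "w": w,
            "min_w": min(w.values()), "restrict": restrict, "counter": 1,
        })
    best, meet = None, None
    common = uni.common

    while True:
        tops = []
        for side in sides:
            pq = side["pq"]
            while pq and pq[0][2] in side["settled"]:
                heapq.heappop(pq)
            tops.append(pq[0][0] if pq else None)
        if tops[0] is None and tops[1] is None:
            break
        if best is not None:
            reach = [t if t is not None else best for t in tops]
            if reach[0] + reach[1] >= best:
                break
        idx = 0 if (tops[1] is None or
                    (tops[0] is not None and tops[0] <= tops[1])) else 1
        side, other = sides[idx], sides[1 - idx]
        d, _, s = heapq.heappop(side["pq"])
        if s in side["settled"]:
            continue
        side["settled"].add(s)
        if d > cap:
            break
        if s[0] == common:
            do = other["dist"].get(s)
            if do is not None:
                tot = d + do
                if tot <= cap and (best is None or tot < best):
                    best, meet = tot, s
        for kind, wt, ns in _one_side_moves(s, side["special"], side["w"], n,
                                            side["restrict"]):
            nd = d + wt
            if nd > cap or ns in side["settled"]:
                continue
            dist = side["dist"]
            if ns not in dist or nd < dist[ns]:
                r = _region_count(ns, side["special"])
                if r and nd + side["min_w"] * r > cap:
                    continue
                dist[ns] = nd
                if want_parents:
                    side["parent"][ns] = (s, kind)
                heapq.heappush(side["pq"], (nd, side["counter"], ns))
                side["counter"] += 1
    return best, meet, sides[0]["parent"], sides[1]["parent"]


def _forward_weights(w: WeightScheme) -> dict:
    return {"cut": w.cut, "join": w.join, "sesqui": w.sesqui,
            "double": w.double, "delete": w.delete}


def _backward_weights(w: WeightScheme) -> dict:
    # seen from the target: its deletions are forward insertions, its cuts are
    # forward joins and vice versa
    return {"cut": w.join, "join": w.cut, "sesqui": w.sesqui,
            "double": w.double, "delete": w.insert}


_BACK_KIND = {"cut": "join", "join": "cut", "sesqui": "sesqui",
              "double": "double", "delete": "insert"}

_REC_KIND = {"cut": OpKind.CUTJOIN, "join": OpKind.CUTJOIN,
             "sesqui": OpKind.SESQUI, "double": OpKind.DOUBLE,
             "delete": OpKind.DELETE_REGION, "insert": OpKind.INSERT_REGION}


def default_weight_cap(a: ChromosomeStructure, b: ChromosomeStructure,
                       w: WeightScheme) -> Fraction:
    """A coarse but safe upper bound on the optimal total weight."""
    wmax = max(w.double, w.sesqui, w.cut, w.join, w.delete, w.insert)
    n_adj = sum(len(c) for c in a.chromosomes) + sum(len(c) for c in b.chromosomes)
    return wmax * (n_adj + 4)


def bfs_shortest_sequence(a: ChromosomeStructure, b: ChromosomeStructure,
                          w: WeightScheme,
                          max_weight: Optional[Fraction] = None,
                          with_scenario: bool = False,
                          minimal_length: bool = False):
    """Minimum total weight transforming a into b, by exhaustive search.

    With ``minimal_length`` the search minimises the operation count first and
    the total weight second (the regime in which the pattern-weight algorithm
    is exact).  Returns ``(weight, records)`` (records ``None`` unless
    requested) or ``None`` if no sequence within ``max_weight`` exists.
    """
    uni = _Universe(a, b)
    cap = Fraction(max_weight) if max_weight is not None else \
        default_weight_cap(a, b, w)
    n = len(uni.keys)
    sa, sb = uni.encode(a), uni.encode(b)
    fw, bw = _forward_weights(w), _backward_weights(w)
    # integer-scaled weights keep the inner Dijkstra loop cheap
    denom = 1
    for v in list(fw.values()) + [w.insert]:
        denom = denom * v.denominator // _gcd(denom, v.denominator)
    scale = Fraction(denom)
    fw_i = {k: int(v * denom) for k, v in fw.items()}
    bw_i = {k: int(v * denom) for k, v in bw.items()}
    cap_i = int(cap * denom)
    if minimal_length:
        fw_i = {k: _LexCost(1, v) for k, v in fw_i.items()}
        bw_i = {k: _LexCost(1, v) for k, v in bw_i.items()}
        cap_i = _LexCost(cap_i * 2 + 4, cap_i)
    best, meet, fpar, bpar = _bidirectional(
        sa, sb, uni, fw_i, bw_i, n, cap_i, with_scenario)
    if best is None:
        return None
    if minimal_length:
        best = best.weight
    best = Fraction(best) / scale
    if not with_scenario:
        return best, None
    recs: List[OperationRecord] = []
    chain = []
    s = meet
    while s != sa:
        prev, kind = fpar[s]
        chain.append((kind, s))
        s = prev
    for kind, st in reversed(chain):
        recs.append(OperationRecord(_REC_KIND[kind], (),
                                    _forward_weights(w)[kind], uni.decode(st)))
    s = meet
    back = []
    while s != sb:
        prev, kind = bpar[s]
        back.append((kind, prev))
        s = prev
    for kind, st in back:
        fk = _BACK_KIND[kind]
        wt = w.insert if fk == "insert" else _forward_weights(w)[fk]
        recs.append(OperationRecord(_REC_KIND[fk], (), wt, uni.decode(st)))
    return best, recs


def oracle_distance(a, b, w, max_weight=None,
                    minimal_length=False) -> Optional[Fraction]:
    res = bfs_shortest_sequence(a, b, w, max_weight,
                                minimal_length=minimal_length)
    return None if res is None else res[0]


# ---------------------------------------------------------------------------
# unidirectional cross-check with explicit insertions (tiny instances only)

def explicit_insertion_search(a: ChromosomeStructure, b: ChromosomeStructure,
                              w: WeightScheme,
                              max_weight: Optional[Fraction] = None
                              ) -> Optional[Fraction]:
    """Forward-only uniform-cost search enumerating insertion contents.

    Exponential in the number of target-private genes; used to validate the
    bidirectional solver on very small cases.
    """
    uni = _Universe(a, b)
    n = len(uni.keys)
    cap = Fraction(max_weight) if max_weight is not None else \
        default_weight_cap(a, b, w)
    goal = uni.encode(b)
    start = uni.encode(a)
    wmap = _forward_weights(w)
    dist = {start: Fraction(0)}
    pq = [(Fraction(0), 0, start)]
    counter = 1
    while pq:
        d, _, s = heapq.heappop(pq)
        if d > dist[s] or d > cap:
            if d > cap:
                break
            continue
        if s == goal:
            return d
        not_in_b = s[0] & ~uni.mask_b
        moves = list(_one_side_moves(s, not_in_b, wmap, n))
        missing = uni.mask_b & ~s[0]
        moves.extend(("insert", w.insert, ns)
                     for ns in _insertions(s, missing, not_in_b, n))
        for kind, wt, ns in moves:
            nd = d + wt
            if nd <= cap and (ns not in dist or nd < dist[ns]):
                dist[ns] = nd
                heapq.heappush(pq, (nd, counter, ns))
                counter += 1
    return None


def _insertions(state: State, missing_mask: int, special_mask: int, n: int):
    """All natural placements of any signed ordering of missing-gene subsets."""
    missing = [g for g in range(n) if missing_mask >> g & 1]
    adj = state[1]
    telos = _telomeres(state, n)
    for r in range(1, len(missing) + 1):
        for combo in itertools.permutations(missing, r):
            for signs in itertools.product((0, 1), repeat=r):
                # chain of extremities: entry_i .. exit_i
                entries = [2 * g + s for g, s in zip(combo, signs)]
                exits = [e ^ 1 for e in entries]
                inner = frozenset(_mk(exits[i], entries[i + 1])
                                  for i in range(r - 1))
                gmask = state[0]
                for g in combo:
                    gmask |= 1 << g
                head, tail = entries[0], exits[-1]
                # as a new linear chromosome
                yield (gmask, adj | inner)
                # as a new circular chromosome
                yield (gmask, adj | inner | {_mk(tail, head)})
                # at a telomere
                for t in telos:
                    yield (gmask, adj | inner | {_mk(t, head)})
                # inside an existing adjacency (not within a special region)
                for c in adj:
                    i, j = _adj_exts(c)
                    if (special_mask >> (i // 2) & 1
                            and special_mask >> (j // 2) & 1):
                        continue
                    yield (gmask, (adj - {c}) | inner
                           | {_mk(i, head), _mk(tail, j)})


# ---------------------------------------------------------------------------
# Steiner-tree oracles for the reconstruction algorithms

def _metric_fn(metric, w):
    from .reconstruct import pairwise_distance
    cache = {}

    def d(x, y):
        kx, ky = x.canonical_key, y.canonical_key
        if kx == ky:
            return 0.0
        key = (kx, ky) if kx <= ky else (ky, kx)
        if key not in cache:
            cache[key] = float(pairwise_distance(x, y, metric, w))
        return cache[key]
    return d


def _candidate_structures(universe):
    from .reconstruct import _all_structures
    seen = set()
    out = []
    for s in _all_structures(sorted(universe)):
        if s.canonical_key not in seen:
            seen.add(s.canonical_key)
            out.append(s)
    return out


def brute_force_steiner(terminals, metric: str = "breakpoint",
                        gene_universe=None, w=None,
                        max_terminals: int = 5, max_genes: int = 3):
    """Minimum Steiner tree weight over the full structure space.

    Enumerates every structure on the (small) gene universe as a candidate
    Steiner point; since at most m-2 Steiner points are needed and the edge
    weights form a metric, the optimum is the best MST over the terminals
    plus any subset of at most m-2 candidates.
    """
    import networkx as nx

    terminals = list(terminals)
    if gene_universe is None:
        gene_universe = sorted({k[0] for t in terminals for k in t.gene_keys()})
    if len(terminals) > max_terminals or len(gene_universe) > max_genes:
        raise ValueError("instance too large for exhaustive Steiner search")
    d = _metric_fn(metric, w)
    cands = _candidate_structures(gene_universe)
    m = len(terminals)

    def mst_weight(nodes):
        G = nx.Graph()
        for i in range(len(nodes)):
            G.add_node(i)
            for j in range(i + 1, len(nodes)):
                G.add_edge(i, j, weight=d(nodes[i], nodes[j]))
        return sum(dd["weight"] for *_e, dd in nx.minimum_spanning_edges(
            G, algorithm="prim", data=True))

    best = mst_weight(terminals)
    for r in range(1, max(0, m - 2) + 1):
        for extra in itertools.combinations(cands, r):
            wgt = mst_weight(terminals + list(extra))
            if wgt < best:
                best = wgt
    return best


def dreyfus_wagner_steiner(terminals, metric: str = "breakpoint",
                           gene_universe=None, w=None,
                           max_genes: int = 3):
    """Independent check: the Dreyfus-Wagner dynamic programme on the
    complete graph of all structures over the universe."""
    terminals = list(terminals)
    if gene_universe is None:
        gene_universe = sorted({k[0] for t in terminals for k in t.gene_keys()})
    if len(gene_universe) > max_genes:
        raise ValueError("universe too large for the DP oracle")
    d = _metric_fn(metric, w)
    nodes = _candidate_structures(gene_universe)
    key_of = {s.canonical_key: i for i, s in enumerate(nodes)}
    term_ids = []
    for t in terminals:
        if t.canonical_key not in key_of:
            key_of[t.canonical_key] = len(nodes)
            nodes.append(t)
        term_ids.append(key_of[t.canonical_key])
    n = len(nodes)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            dist[i][j] = dist[j][i] = d(nodes[i], nodes[j])

    m = len(term_ids)
    full = (1 << m) - 1
    INF = float("inf")
    # S[mask][v]: weight of an optimal tree spanning terminals in mask plus v
    S = [[INF] * n for _ in range(full + 1)]
    for t in range(m):
        for v in range(n):
            S[1 << t][v] = dist[term_ids[t]][v]
    masks = sorted(range(1, full + 1), key=lambda x: bin(x).count("1"))
    for mask in masks:
        if bin(mask).count("1") < 2:
            continue
        base = [INF] * n
        sub = (mask - 1) & mask
        while sub:
            rest = mask ^ sub
            if rest:
                rowA, rowB = S[sub], S[rest]
                for v in range(n):
                    s = rowA[v] + rowB[v]
                    if s < base[v]:
                        base[v] = s
            sub = (sub - 1) & mask
        # relax through intermediate vertices
        row = S[mask]
        for v in range(n):
            bv = base[v]
            if bv < row[v]:
                row[v] = bv
        for v in range(n):
            dv = dist[v]
            bv = row[v]
            for u in range(n):
                cand = bv + dv[u]
                if cand < row[u]:
                    row[u] = cand
    return min(S[full][term_ids[0]], min(S[full]))
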