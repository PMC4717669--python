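"""Adjacency-level view of structures and application of the six operations.

A chromosome structure is equivalently a set of genes plus a partial perfect
matching on their extremities: extremity ``(key, 1)`` is the tail (start of
the arrow) and ``(key, 2)`` the head.  Consecutive genes on a chromosome
contribute one adjacency; telomeres are unmatched extremities.  This view is
canonical: rotations and reversals of a chromosome leave it unchanged, so two
structures are equal iff their gene sets and adjacency sets are equal.

"Unnatural" operation variants are excluded throughout, mirroring the model:
no cut severs an adjacency between two special genes (no cutting inside a
special region), no operation closes a chromosome consisting only of special
genes into a circle, and insertions never land inside a special region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterator, Optional, Set, Tuple

from .model import Chromosome, ChromosomeStructure, GeneToken

Ext = Tuple[tuple, int]           # ((family, paralog_or_0), 1|2)
Adj = FrozenSet[Ext]


def other_end(ext: Ext) -> Ext:
    return (ext[0], 3 - ext[1])


def _neighbour_map(adjacencies) -> Dict[Ext, Ext]:
    nbr: Dict[Ext, Ext] = {}
    for a in adjacencies:
        ab = tuple(a)
        if len(ab) == 1:          # head-to-tail adjacency of a one-gene circle
            nbr[ab[0]] = ab[0]
        else:
            nbr[ab[0]], nbr[ab[1]] = ab[1], ab[0]
    return nbr


@dataclass(frozen=True)
class AdjacencyState:
    """Gene set + adjacency matching; hashable canonical form of a structure."""

    genes: FrozenSet[tuple]
    adjacencies: FrozenSet[Adj]

    def telomeres(self) -> Set[Ext]:
        used = {e for a in self.adjacencies for e in a}
        return {(g, end) for g in self.genes for end in (1, 2)} - used


def to_adjacencies(s: ChromosomeStructure) -> AdjacencyState:
    genes: Set[tuple] = set()
    adj: Set[Adj] = set()
    for c in s.chromosomes:
        ends = []                 # (entry, exit) extremity per gene
        for g in c.genes:
            k = g.key
            if k in genes:
                raise ValueError(f"unresolved paralog collision on {k}")
            genes.add(k)
            ends.append(((k, 1), (k, 2)) if g.orient > 0 else ((k, 2), (k, 1)))
        for (_, prev_exit), (nxt_entry, _) in zip(ends, ends[1:]):
            adj.add(frozenset((prev_exit, nxt_entry)))
        if c.circular:
            adj.add(frozenset((ends[-1][1], ends[0][0])))
    return AdjacencyState(frozenset(genes), frozenset(adj))


def to_structure(state: AdjacencyState, name: str = "") -> ChromosomeStructure:
    """Rebuild chromosomes by walking the adjacency matching."""
    nbr = _neighbour_map(state.adjacencies)
    seen: Set[tuple] = set()
    chroms = []

    def walk(start: Ext, circular: bool) -> Chromosome:
        tokens = []
        ext = start
        while True:
            key = ext[0]
            seen.add(key)
            tokens.append(GeneToken(key[0], key[1] or None, 1 if ext[1] == 1 else -1))
            nxt = nbr.get(other_end(ext))
            if nxt is None or nxt[0] in seen:
                break
            ext = nxt
        return Chromosome(tuple(tokens), circular)

    for t in sorted(state.telomeres()):
        if t[0] not in seen:
            chroms.append(walk(t, circular=False))
    for g in sorted(state.genes):
        if g not in seen:
            chroms.append(walk((g, 1), circular=True))
    return ChromosomeStructure(tuple(chroms), name).canonical()


def is_cuttable(a: Adj, special: FrozenSet[tuple]) -> bool:
    """An adjacency may be cut unless it lies inside a special region."""
    return not all(e[0] in special for e in a)


def creates_special_circle(genes, adjacencies, special, new_adjs) -> bool:
    """Does one of the freshly added adjacencies close an all-special circle?

    Pre-existing special circles are legitimate; only circularising a cut
    region is the excluded variant.
    """
    if not special:
        return False
    nbr = _neighbour_map(adjacencies)
    for a in new_adjs:
        ab = tuple(a)
        if not all(e[0] in special for e in ab):
            continue
        start = ab[0]
        ext, pure, circular = start, True, False
        for _ in range(len(genes) + 1):
            if ext[0] not in special:
                pure = False
                break
            nxt = nbr.get(other_end(ext))
            if nxt is None:
                break
            if nxt == start:
                circular = True
                break
            ext = nxt
        if pure and circular:
            return True
    return False


def special_regions(state: AdjacencyState, special: FrozenSet[tuple]):
    """Maximal runs of special genes, as deletion candidates.

    Yields ``(genes, left_flank, right_flank, is_circle)`` where the flanks
    are the common-gene extremities adjacent to the region ends (``None`` at a
    telomere) and ``is_circle`` marks a region forming a whole circular
    chromosome.
    """
    nbr = _neighbour_map(state.adjacencies)
    todo = {g for g in state.genes if g in special}
    out = []
    while todo:
        g = todo.pop()
        run = [g]
        flanks = [None, None]
        circular = False
        for side, end in enumerate((1, 2)):
            ext: Ext = (g, end)
            while True:
                nxt = nbr.get(ext)
                if nxt is None:
                    break
                if nxt[0] not in special:
                    flanks[side] = nxt
                    break
                if nxt[0] in run and nxt[0] not in todo:
                    circular = True
                    break
                todo.discard(nxt[0])
                if side == 0:
                    run.insert(0, nxt[0])
                else:
                    run.append(nxt[0])
                ext = other_end(nxt)
            if circular:
                break
        out.append((tuple(run), flanks[0], flanks[1], circular))
    return out


def apply_delete_region(state: AdjacencyState, region_genes: tuple,
                        left: Optional[Ext], right: Optional[Ext]) -> AdjacencyState:
    """Delete a maximal special region, healing the flanks if interior."""
    rg = set(region_genes)
    adj = {a for a in state.adjacencies if not any(e[0] in rg for e in a)}
    if left is not None and right is not None:
        adj.add(frozenset((left, right)))
    return AdjacencyState(frozenset(state.genes - rg), frozenset(adj))


def standard_moves(state: AdjacencyState, special: FrozenSet[tuple]
                   ) -> Iterator[Tuple[str, AdjacencyState]]:
    """All natural cut / join / sesqui / double results, tagged by kind."""
    adjs = sorted(state.adjacencies, key=sorted)
    cuttable = [a for a in adjs if is_cuttable(a, special)]
    telos = sorted(state.telomeres())

    for a in cuttable:
        yield "cut", AdjacencyState(state.genes, state.adjacencies - {a})

    for i, x in enumerate(telos):
        for y in telos[i + 1:]:
            fresh = frozenset((x, y))
            new = state.adjacencies | {fresh}
            if not creates_special_circle(state.genes, new, special, (fresh,)):
                yield "join", AdjacencyState(state.genes, new)

    for a in cuttable:
        ab = tuple(a)
        if len(ab) == 1:
            continue
        for keep in ab:
            for z in telos:
                fresh = frozenset((keep, z))
                new = (state.adjacencies - {a}) | {fresh}
                if not creates_special_circle(state.genes, new, special,
                                              (fresh,)):
                    yield "sesqui", AdjacencyState(state.genes, new)

    for i, a in enumerate(cuttable):
        for b in cuttable[i + 1:]:
            ta, tb = tuple(a), tuple(b)
            if len(ta) == 1 or len(tb) == 1:
                # a one-gene circle's self adjacency recombines like any other
                ta = ta * 2 if len(ta) == 1 else ta
                tb = tb * 2 if len(tb) == 1 else tb
            (x, y), (u, v) = ta, tb
            for new_pair in ((frozenset((x, u)), frozenset((y, v))),
                             (frozenset((x, v)), frozenset((y, u)))):
                if any(len(p) < 2 for p in new_pair):
                    continue
                new = (state.adjacencies - {a, b}) | set(new_pair)
                if not creates_special_circle(state.genes, new, special,
                                              new_pair):
                    yield "double", AdjacencyState(state.genes, new)


def deletion_moves(state: AdjacencyState, special: FrozenSet[tuple]
                   ) -> Iterator[Tuple[tuple, AdjacencyState]]:
    for run, left, right, _circ in special_regions(state, special):
        yield run, apply_delete_region(state, run, left, right)
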