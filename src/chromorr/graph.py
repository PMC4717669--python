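"""The common graph of two chromosome structures.

Nodes are the extremities of shared ("common") genes plus one node per maximal
region of private ("special") genes; edges record adjacencies, coloured by the
source structure.  An edge between two extremity nodes is *conventional*; an
edge between an extremity and a region node is *special*; a region that forms
a whole circular chromosome carries a *special loop*.  A marginal edge of a
path whose outer endpoint is a region node is *hanging*.

Every extremity has at most one a-coloured and one b-coloured incidence; every
region node has two attachment stubs (its two flanks) carrying edges of its
own colour only.  The distance algorithm transforms this graph into its final
form: isolated extremities and final 2-circles (two extremities joined by one
a- and one b-edge).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .model import Chromosome, ChromosomeStructure, GeneToken

ConvRef = Tuple[str, tuple, int]          # ('c', gene_key, end)


def conv(key, end) -> ConvRef:
    return ("c", key, end)


@dataclass
class SpecialNode:
    id: int
    source: str                            # 'a' | 'b'
    genes: Tuple[GeneToken, ...]           # read from stub 0 towards stub 1
    loop: bool = False

    @property
    def ref(self):
        return ("s", self.id)


@dataclass
class Edge:
    id: int
    color: str                             # 'a' | 'b'
    u: tuple                               # ConvRef or ('s', id)
    v: tuple
    u_stub: Optional[int] = None           # stub index when endpoint special
    v_stub: Optional[int] = None
    loop: bool = False

    @property
    def kind(self) -> str:
        if self.loop:
            return "loop"
        return "spec" if (self.u[0] == "s" or self.v[0] == "s") else "conv"

    def endpoints(self):
        return (self.u, self.v)

    def other(self, node):
        return self.v if node == self.u else self.u


class CommonGraph:
    """Mutable common graph a+b with the operation primitives."""

    def __init__(self, a: ChromosomeStructure, b: ChromosomeStructure):
        akeys, bkeys = set(a.gene_keys()), set(b.gene_keys())
        if len(a.gene_keys()) != len(akeys) or len(b.gene_keys()) != len(bkeys):
            raise ValueError(
                "duplicate gene occurrences: resolve paralogs (paralog_ilp) first")
        self.common: Set[tuple] = akeys & bkeys
        self.source_a, self.source_b = a, b
        self.specials: Dict[int, SpecialNode] = {}
        self.edges: Dict[int, Edge] = {}
        # conventional incidences: (key, end) -> {'a': Edge|None, 'b': Edge|None}
        self.conv_slots: Dict[tuple, Dict[str, Optional[Edge]]] = {
            (k, e): {"a": None, "b": None} for k in self.common for e in (1, 2)}
        # special incidences: id -> [Edge|None, Edge|None]
        self.spec_slots: Dict[int, List[Optional[Edge]]] = {}
        self._next_special = itertools.count()
        self._next_edge = itertools.count()
        self._ingest(a, "a")
        self._ingest(b, "b")

    # -- construction -----------------------------------------------------

    def _new_special(self, source, genes, loop=False) -> SpecialNode:
        node = SpecialNode(next(self._next_special), source, tuple(genes), loop)
        self.specials[node.id] = node
        self.spec_slots[node.id] = [None, None]
        return node

    def _ingest(self, s: ChromosomeStructure, color: str):
        for chrom in s.chromosomes:
            self._ingest_chromosome(chrom, color)

    def _ingest_chromosome(self, chrom: Chromosome, color: str):
        # split into runs of special genes and single common genes
        items: List[tuple] = []          # ('g', token) | ('r', [tokens])
        for g in chrom.genes:
            if g.key in self.common:
                items.append(("g", g))
            else:
                if items and items[-1][0] == "r":
                    items[-1][1].append(g)
                else:
                    items.append(("r", [g]))
        if chrom.circular and len(items) > 1 \
                and items[0][0] == "r" and items[-1][0] == "r":
            items[-1][1].extend(items[0][1])
            items.pop(0)
        if all(kind == "r" for kind, _ in items):
            node = self._new_special(color, items[0][1], loop=chrom.circular)
            if chrom.circular:
                e = Edge(next(self._next_edge), color, node.ref, node.ref,
                         0, 1, loop=True)
                self.edges[e.id] = e
                self.spec_slots[node.id] = [e, e]
            return
        # attachment points: exit extremity of each item towards the next
        refs = []                         # (entry_ref, exit_ref, node_or_None)
        for kind, payload in items:
            if kind == "g":
                g = payload
                ent = (g.key, 1 if g.orient > 0 else 2)
                ext = (g.key, 2 if g.orient > 0 else 1)
                refs.append((conv(*ent), conv(*ext), None))
            else:
                node = self._new_special(color, payload)
                refs.append(((node.ref, 0), (node.ref, 1), node))
        pairs = list(zip(refs, refs[1:]))
        if chrom.circular:
            pairs.append((refs[-1], refs[0]))
        for (_, exit_ref, n1), (entry_ref, _, n2) in pairs:
            self._connect(exit_ref, entry_ref, color)

    def _connect(self, x, y, color):
        """Add the adjacency edge between two attachment references."""
        def unpack(r):
            if r[0] == "c":
                return r, None
            return r[0], r[1]             # (('s', id), stub)
        (xu, xs), (yu, ys) = unpack(x), unpack(y)
        self.add_edge(xu, yu, color, xs, ys)

    # -- primitives -------------------------------------------------------

    def add_edge(self, u, v, color: str, u_stub=None, v_stub=None):
        """Join two nodes.  Two special endpoints merge instead (returning the
        merged :class:`SpecialNode` rather than an :class:`Edge`)."""
        if u[0] == "s" and v[0] == "s":
            if u == v:
                # a region joined to itself becomes a special loop
                e = Edge(next(self._next_edge), color, u, v, 0, 1, loop=True)
                assert self.spec_slots[u[1]] == [None, None]
                self.spec_slots[u[1]] = [e, e]
                self.specials[u[1]].loop = True
                self.edges[e.id] = e
                return e
            return self.merge_specials(u[1], v[1], u_stub, v_stub)
        e = Edge(next(self._next_edge), color, u, v, u_stub, v_stub)
        for node, stub in ((u, u_stub), (v, v_stub)):
            if node[0] == "c":
                assert self.conv_slots[node[1:]][color] is None, \
                    f"slot {node}/{color} occupied"
                self.conv_slots[node[1:]][color] = e
            else:
                sid = node[1]
                assert self.specials[sid].source == color
                if stub is None:
                    stub = self.free_stub(sid)
                    if node == u:
                        e.u_stub = stub
                    else:
                        e.v_stub = stub
                assert self.spec_slots[sid][stub] is None
                self.spec_slots[sid][stub] = e
        self.edges[e.id] = e
        return e

    def free_stub(self, sid: int) -> int:
        slots = self.spec_slots[sid]
        for i in (0, 1):
            if slots[i] is None:
                return i
        raise AssertionError(f"special node {sid} has no free stub")

    def remove_edge(self, e: Edge):
        del self.edges[e.id]
        if e.loop:
            self.spec_slots[e.u[1]] = [None, None]
            self.specials[e.u[1]].loop = False
            return
        for node, stub in ((e.u, e.u_stub), (e.v, e.v_stub)):
            if node[0] == "c":
                self.conv_slots[node[1:]][e.color] = None
            else:
                self.spec_slots[node[1]][stub] = None

    def merge_specials(self, sid: int, tid: int, s_stub=None, t_stub=None
                       ) -> SpecialNode:
        """Join two region nodes of one colour; the regions concatenate."""
        S, T = self.specials[sid], self.specials[tid]
        assert S.source == T.source and not S.loop and not T.loop
        assert sid != tid, "closing a region into a special circle is unnatural"
        if s_stub is None:
            s_stub = self.free_stub(sid)
        if t_stub is None:
            t_stub = self.free_stub(tid)
        assert self.spec_slots[sid][s_stub] is None
        assert self.spec_slots[tid][t_stub] is None
        sg = S.genes if s_stub == 1 else tuple(g.flipped() for g in reversed(S.genes))
        tg = T.genes if t_stub == 0 else tuple(g.flipped() for g in reversed(T.genes))
        merged = self._new_special(S.source, sg + tg)
        # re-point surviving edges: S's other stub -> merged stub 0,
        # T's other stub -> merged stub 1
        for (old, old_stub, new_stub) in ((S, 1 - s_stub, 0), (T, 1 - t_stub, 1)):
            e = self.spec_slots[old.id][old_stub]
            if e is not None:
                if e.u == old.ref:
                    e.u, e.u_stub = merged.ref, new_stub
                else:
                    e.v, e.v_stub = merged.ref, new_stub
                self.spec_slots[merged.id][new_stub] = e
        del self.specials[sid], self.specials[tid]
        del self.spec_slots[sid], self.spec_slots[tid]
        return merged

    def delete_special(self, sid: int) -> Tuple[tuple, Optional[Edge]]:
        """Remove a region node; reconnect two conventional neighbours."""
        node = self.specials[sid]
        incident = [e for e in self.spec_slots[sid] if e is not None]
        seen = []
        for e in incident:
            if e not in seen:
                seen.append(e)
        neighbours = []
        for e in seen:
            self.remove_edge(e)
            if not e.loop:
                neighbours.append(e.other(node.ref))
        del self.specials[sid], self.spec_slots[sid]
        new_edge = None
        if len(neighbours) == 2:
            new_edge = self.add_edge(neighbours[0], neighbours[1], node.source)
        return node.genes, new_edge

    # -- queries ----------------------------------------------------------

    def conv_edge_list(self) -> List[Edge]:
        return sorted((e for e in self.edges.values() if e.kind == "conv"),
                      key=self.edge_key)

    def node_key(self, ref):
        if ref[0] == "c":
            return (0, ref[1], ref[2])
        n = self.specials[ref[1]]
        return (1, n.source, tuple(g._sort_key() for g in n.genes), n.id)

    def edge_key(self, e: Edge):
        return (e.color,) + tuple(sorted((self.node_key(e.u), self.node_key(e.v))))

    def degree(self, ref) -> int:
        if ref[0] == "c":
            return sum(1 for x in self.conv_slots[ref[1:]].values() if x)
        return sum(1 for x in self.spec_slots[ref[1]] if x)

    def incident(self, ref) -> List[Edge]:
        if ref[0] == "c":
            return [e for e in self.conv_slots[ref[1:]].values() if e]
        out = []
        for e in self.spec_slots[ref[1]]:
            if e is not None and e not in out:
                out.append(e)
        return out

    def in_two_circle(self, e: Edge) -> bool:
        """Is this conventional edge part of a circle of length 2?

        Final 2-circle: a parallel conventional edge of the other colour.
        a-/b-circle: both endpoints attached to the same special node.
        """
        if e.kind != "conv":
            return False
        u, v = e.u, e.v
        for o in self.conv_slots[u[1:]].values():
            if o is not None and o is not e and o.kind == "conv" \
                    and {o.u, o.v} == {u, v}:
                return True
        su = [x.other(u) for x in self.incident(u) if x is not e and x.kind == "spec"]
        sv = [x.other(v) for x in self.incident(v) if x is not e and x.kind == "spec"]
        return any(n in sv and self.degree(n) == 2 for n in su)

    def is_final(self) -> bool:
        if self.specials:
            return False
        for e in self.edges.values():
            u, v = e.u, e.v
            mate = [o for o in self.conv_slots[u[1:]].values()
                    if o is not None and o is not e]
            if not (len(mate) == 1 and {mate[0].u, mate[0].v} == {u, v}):
                return False
        return True

    # -- components -------------------------------------------------------

    def components(self) -> List["Component"]:
        seen_nodes: Set[tuple] = set()
        comps = []
        all_nodes = [conv(k, end) for (k, end) in sorted(self.conv_slots)] + \
                    [("s", i) for i in sorted(self.specials)]
        for start in all_nodes:
            if start in seen_nodes:
                continue
            comp = self._trace(start)
            seen_nodes.update(comp.nodes)
            comps.append(comp)
        return sorted(comps, key=lambda c: c.sort_key)

    def _trace(self, start) -> "Component":
        # gather the connected component of `start`
        nodes = {start}
        frontier = [start]
        edges: List[Edge] = []
        while frontier:
            n = frontier.pop()
            for e in self.incident(n):
                if e not in edges:
                    edges.append(e)
                o = e.other(n)
                if o not in nodes:
                    nodes.add(o)
                    frontier.append(o)
        return Component(self, nodes, edges)

    # -- extraction -------------------------------------------------------

    def extract(self, color: str, name: str = "") -> ChromosomeStructure:
        """Current structure seen by one side of the graph.

        The side structure consists of the common genes, the colour's region
        nodes, and the colour's adjacency edges; walking attachment points
        alternately through genes and adjacencies rebuilds its chromosomes.
        """
        chroms: List[Chromosome] = []
        visited_genes: Set[tuple] = set()
        visited_specials: Set[int] = set()

        def attachment_edge(node, stub):
            if node[0] == "c":
                return self.conv_slots[node[1:]][color]
            return self.spec_slots[node[1]][stub]

        def side_next(node, stub):
            """Follow the colour adjacency out of an attachment point."""
            e = attachment_edge(node, stub)
            if e is None or e.loop:
                return None
            if e.u == node:
                return (e.v, e.v_stub)
            return (e.u, e.u_stub)

        def walk(node, stub, circular) -> Chromosome:
            tokens: List[GeneToken] = []
            while True:
                if node[0] == "c":
                    key, end = node[1], node[2]
                    visited_genes.add(key)
                    tokens.append(GeneToken(key[0], key[1] or None,
                                            1 if end == 1 else -1))
                    nxt = side_next(conv(key, 3 - end), None)
                else:
                    sid = node[1]
                    visited_specials.add(sid)
                    sp = self.specials[sid]
                    genes = sp.genes if stub == 0 else \
                        tuple(g.flipped() for g in reversed(sp.genes))
                    tokens.extend(genes)
                    nxt = side_next(node, 1 - stub)
                if nxt is None:
                    break
                nnode, nstub = nxt
                if nnode[0] == "c":
                    if nnode[1] in visited_genes:
                        break
                    node, stub = nnode, None
                else:
                    if nnode[1] in visited_specials:
                        break
                    node, stub = nnode, nstub
            return Chromosome(tuple(tokens), circular)

        # linear chromosomes start at free attachment points
        for (key, end) in sorted(self.conv_slots):
            if self.conv_slots[(key, end)][color] is None \
                    and key not in visited_genes:
                chroms.append(walk(conv(key, end), None, circular=False))
        for sid in sorted(self.specials):
            sp = self.specials[sid]
            if sp.source != color or sp.loop or sid in visited_specials:
                continue
            for stub in (0, 1):
                if self.spec_slots[sid][stub] is None:
                    chroms.append(walk(("s", sid), stub, circular=False))
                    break
        # circular chromosomes: whatever of this colour remains unvisited
        for key in sorted({k for (k, _e) in self.conv_slots}):
            if key not in visited_genes:
                chroms.append(walk(conv(key, 1), None, circular=True))
        for sid in sorted(self.specials):
            sp = self.specials[sid]
            if sp.source == color and sid not in visited_specials:
                chroms.append(walk(("s", sid), 0, circular=True))
        return ChromosomeStructure(tuple(chroms), name).canonical()

    def to_dot(self) -> str:
        """Debug export of the current graph in DOT format."""
        lines = ["graph common {"]
        def nid(ref):
            if ref[0] == "c":
                return f"\"{ref[1][0]}.{ref[1][1]}:{ref[2]}\""
            sp = self.specials[ref[1]]
            genes = " ".join(str(g) for g in sp.genes)
            return f"\"{sp.source}[{genes}]#{ref[1]}\""
        for e in sorted(self.edges.values(), key=lambda e: e.id):
            style = "dashed" if e.kind != "conv" else "solid"
            lines.append(f"  {nid(e.u)} -- {nid(e.v)} "
                         f"[label=\"{e.color}\", style={style}];")
        for ref in self.conv_slots:
            if self.degree(conv(*ref)) == 0:
                lines.append(f"  {nid(conv(*ref))};")
        lines.append("}")
        return "\n".join(lines)


class Component:
    """One connected piece of the common graph, with its classification."""

    def __init__(self, g: CommonGraph, nodes: Set[tuple], edges: List[Edge]):
        self.g = g
        self.nodes = nodes
        self.edges = edges
        self.shape, self.order = self._shape()

    def _shape(self):
        if len(self.nodes) == 1 and not self.edges:
            return "isolated", [next(iter(self.nodes))]
        if any(e.loop for e in self.edges):
            return "sloop", [next(iter(self.nodes))]
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        ends = sorted((n for n, d in deg.items() if d == 1),
                      key=self.g.node_key)
        if not ends:
            return "circle", self._order_from(min(self.nodes, key=self.g.node_key))
        return "path", self._order_from(ends[0])

    def _order_from(self, start):
        order = [start]
        used: Set[int] = set()
        cur = start
        while True:
            nxt = None
            for e in self.g.incident(cur):
                if e.id not in used and e in self.edges:
                    used.add(e.id)
                    nxt = e.other(cur)
                    order.append(e)
                    order.append(nxt)
                    break
            if nxt is None:
                break
            if nxt == start:
                order.pop()               # do not repeat the start node
                break
            cur = nxt
        return order

    @property
    def path_nodes(self):
        return self.order[0::2]

    @property
    def path_edges(self):
        return self.order[1::2]

    @property
    def sort_key(self):
        return tuple(sorted(self.g.node_key(n) for n in self.nodes))

    def signature(self) -> tuple:
        """Canonical shape descriptor (invariant under traversal direction)."""
        def node_desc(n):
            if n[0] == "c":
                return "c"
            sp = self.g.specials[n[1]]
            return ("s", sp.source, sp.loop)

        def edge_desc(e):
            return (e.color, e.kind)

        seq = tuple(node_desc(x) if i % 2 == 0 else edge_desc(x)
                    for i, x in enumerate(self.order))
        if self.shape == "circle":
            # for circles the traversal already includes the closing edge
            nodes = [node_desc(n) for n in self.path_nodes]
            edges = [edge_desc(e) for e in self.path_edges]
            k = len(nodes)
            best = None
            for direction in (1, -1):
                if direction == 1:
                    ns, es = nodes, edges
                else:
                    ns = [nodes[0]] + nodes[:0:-1]
                    es = edges[::-1]
                for i in range(k):
                    rot = tuple(x for j in range(k)
                                for x in (ns[(i + j) % k], es[(i + j) % k]))
                    if best is None or repr(rot) < repr(best):
                        best = rot
            return ("circle", best)
        return (self.shape, min(seq, tuple(reversed(seq)), key=repr))

    # -- measurements ----------------------------------------------------

    def specials_in(self):
        return [n for n in self.path_nodes if n[0] == "s"]

    def has_color_node(self, color) -> bool:
        return any(self.g.specials[n[1]].source == color
                   for n in self.nodes if n[0] == "s")

    @property
    def length(self) -> int:
        conv_edges = sum(1 for e in self.edges if e.kind == "conv")
        if self.shape == "circle":
            internal = sum(1 for n in self.nodes if n[0] == "s")
        else:
            ends = {self.order[0], self.order[-1]} if self.shape == "path" else set()
            internal = sum(1 for n in self.nodes if n[0] == "s" and n not in ends)
        return conv_edges + internal

    def hanging_edges(self) -> List[Edge]:
        """Marginal edges whose outer endpoint is a special node."""
        if self.shape != "path" or not self.edges:
            return []
        out = []
        if self.order[0][0] == "s":
            out.append(self.order[1])
        if self.order[-1][0] == "s" and self.order[-2] is not (out[0] if out else None):
            out.append(self.order[-2])
        return out

    def classify(self) -> str:
        g = self.g
        if self.shape == "isolated":
            n = self.order[0]
            if n[0] == "c":
                return "isolated_conv"
            return "2a'" if g.specials[n[1]].source == "b" else "2b'"
        if self.shape == "sloop":
            n = self.order[0]
            return "loop" if g.specials[n[1]].source == "b" else "a-loop"
        if self.shape == "circle":
            has_a = self.has_color_node("a")
            has_b = self.has_color_node("b")
            if not has_a and not has_b:
                if len(self.edges) == 2 and len({e.color for e in self.edges}) == 2 \
                        and len(self.nodes) == 2:
                    return "final"
                return "conv-circle"
            if has_a and has_b:
                return "circle"
            return "a-circle" if has_a else "b-circle"
        # paths
        ends = (self.order[0], self.order[-1])
        hang = self.hanging_edges()
        n_hang = len(hang)
        length = self.length
        has_b = self.has_color_node("b")
        has_a = self.has_color_node("a")
        if length % 2 == 1:
            side = self._extreme_nonhanging_color()
            if side == "a":
                if n_hang == 1:
                    return "1a"
                if n_hang == 2:
                    return "2a"
                return "3a" if has_b else "3a'"
            if side == "b":
                if n_hang == 1:
                    return "1b"
                if n_hang == 2:
                    return "2b"
                return "3b" if has_a else "3b'"
            return "odd-unclassified"
        # even paths
        if len(self.nodes) == 2 and len(self.edges) == 1 and n_hang == 1:
            # one conventional node, one special node
            sp = next(n for n in self.nodes if n[0] == "s")
            return "1'" if g.specials[sp[1]].source == "a" else "1''"
        if n_hang == 1:
            end_sp = ends[0] if ends[0][0] == "s" else ends[1]
            if has_b:
                return "1_a" if g.specials[end_sp[1]].source == "a" else "1_b"
            return "even-unclassified"
        if n_hang == 2:
            if len(self.edges) == 2:
                return "2'"
            return "2"
        return "3"

    def _extreme_nonhanging_color(self) -> Optional[str]:
        """Colour of the outermost non-hanging edges of an odd path."""
        edges = self.path_edges
        if not edges:
            return None
        if self.order[0][0] == "s":
            first = edges[1] if len(edges) > 1 else None
        else:
            first = edges[0]
        if self.order[-1][0] == "s":
            last = edges[-2] if len(edges) > 1 else None
        else:
            last = edges[-1]
        colors = {e.color for e in (first, last) if e is not None}
        return colors.pop() if len(colors) == 1 else None
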