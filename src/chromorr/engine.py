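"""Five-step transformation of the common graph into its final form.

Step 1 deletes private-region loops of the source.  Step 2 extracts a final
2-circle for every conventional edge.  Step 3 combines paths so that cheap
standard operations absorb region nodes that would otherwise each cost a
deletion.  Step 4 funnels the remaining target-region ("b") nodes together so
that at most a couple of expensive insertions survive.  Step 5 clears what is
left.  Graph operations touching a-coloured elements mirror forward operations
on the source structure; operations touching b-coloured elements are inverses
of operations placed near the end of the forward sequence, so the emitted
scenario is the a-coloured part followed by the reversed b-coloured part.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Tuple

from .model import (ChromosomeStructure, OperationRecord, OpKind, WeightScheme,
                    validate_weights)
from .graph import CommonGraph, Component, Edge, conv


@dataclass
class GraphOp:
    """One graph-level operation with its forward-scenario interpretation."""

    gkind: str                 # 'double'|'sesqui'|'cut'|'join'|'node_del'|'loop_del'
    color: str                 # 'a' | 'b'
    weight: Fraction
    payload: tuple = ()
    snapshot: Optional[ChromosomeStructure] = None

    @property
    def record_kind(self) -> OpKind:
        if self.gkind == "double":
            return OpKind.DOUBLE
        if self.gkind == "sesqui":
            return OpKind.SESQUI
        if self.gkind in ("cut", "join"):
            return OpKind.CUTJOIN
        return (OpKind.DELETE_REGION if self.color == "a"
                else OpKind.INSERT_REGION)


class Engine:
    """Runs the five steps on one structure pair and logs every operation."""

    def __init__(self, a: ChromosomeStructure, b: ChromosomeStructure,
                 w: WeightScheme, record_scenario: bool = True):
        bad = validate_weights(w)
        if bad:
            raise ValueError("invalid weight scheme: " + "; ".join(bad))
        self.w = w
        self.g = CommonGraph(a, b)
        self.record_scenario = record_scenario
        self.log: List[GraphOp] = []
        self.step_marks: Dict[str, int] = {}
        self.counts = {"b_dels": 0, "closures": 0}
        self.n_small: Optional[int] = None
        self.post_step2_components: Optional[List] = None
        self.limbos: List["Engine.Limbo"] = []

    # ---- op emission ----------------------------------------------------

    def _weight(self, gkind: str, color: str) -> Fraction:
        w = self.w
        if gkind == "double":
            return w.double
        if gkind == "sesqui":
            return w.sesqui
        if gkind == "cut":
            return w.cut if color == "a" else w.join
        if gkind == "join":
            return w.join if color == "a" else w.cut
        return w.delete if color == "a" else w.insert

    def _emit(self, gkind: str, color: str, mutate: Callable[[], tuple],
              payload: tuple = ()):
        pre = self.g.extract("b") if (self.record_scenario and color == "b") \
            else None
        extra = mutate()
        snap = None
        if self.record_scenario:
            snap = self.g.extract("a") if color == "a" else pre
        op = GraphOp(gkind, color, self._weight(gkind, color),
                     payload + (extra or ()), snap)
        if op.record_kind is OpKind.INSERT_REGION:
            self.counts["b_dels"] += 1
        self.log.append(op)
        return op

    # primitive wrappers --------------------------------------------------

    def op_cut(self, e: Edge):
        return self._emit("cut", e.color, lambda: (self.g.remove_edge(e), )[1:])

    def op_join(self, u, v, color, u_stub=None, v_stub=None):
        def mut():
            self.g.add_edge(u, v, color, u_stub, v_stub)
            return ()
        return self._emit("join", color, mut)

    def op_sesqui(self, cut_edge: Edge, u, v, u_stub=None, v_stub=None):
        color = cut_edge.color

        def mut():
            self.g.remove_edge(cut_edge)
            self.g.add_edge(u, v, color, u_stub, v_stub)
            return ()
        return self._emit("sesqui", color, mut)

    def op_double(self, e1: Edge, e2: Edge, pairs):
        """Cut e1 and e2, reconnect the four ends as given in pairs.

        If a reconnection merges two region nodes, later pairs referring to
        either of them are redirected to the merged node.
        """
        color = e1.color
        assert e2.color == color

        def mut():
            self.g.remove_edge(e1)
            self.g.remove_edge(e2)
            mapping: dict = {}
            for (u, us), (v, vs) in pairs:
                if u in mapping:
                    u, us = mapping[u], None
                if v in mapping:
                    v, vs = mapping[v], None
                res = self.g.add_edge(u, v, color, us, vs)
                if res is not None and not isinstance(res, Edge):
                    mapping[u] = mapping[v] = res.ref
            return ()
        return self._emit("double", color, mut)

    def op_delete_special(self, sid: int):
        node = self.g.specials[sid]
        color = node.source
        genes = node.genes

        def mut():
            self.g.delete_special(sid)
            return ()
        kind = "loop_del" if node.loop else "node_del"
        return self._emit(kind, color, mut, payload=(genes,))

    # ---- helpers on component geometry ---------------------------------

    @staticmethod
    def _end_info(comp: Component):
        """For each path end: (node, marginal_edge|None)."""
        if comp.shape != "path":
            return []
        order = comp.order
        out = [(order[0], order[1] if len(order) > 1 else None)]
        if len(order) > 1:
            out.append((order[-1], order[-2]))
        return out

    def _free_special_ends(self, comp: Component):
        """Path-end special nodes (they have a free stub), with colour."""
        out = []
        if comp.shape == "isolated":
            n = comp.order[0]
            if n[0] == "s":
                out.append((n, self.g.specials[n[1]].source))
            return out
        for node, _e in self._end_info(comp):
            if node[0] == "s":
                out.append((node, self.g.specials[node[1]].source))
        return out

    def _conv_ends(self, comp: Component):
        """Path-end conventional nodes with the colour of their free slot."""
        out = []
        for node, edge in self._end_info(comp):
            if node[0] == "c" and edge is not None:
                free = "a" if edge.color == "b" else "b"
                out.append((node, free))
            elif node[0] == "c" and edge is None:
                out.append((node, None))
        return out

    def _marginal_special(self, comp: Component, which: int):
        """The special node adjacent to a conventional path end (external edge)."""
        node, edge = self._end_info(comp)[which]
        if node[0] != "c" or edge is None:
            return None
        other = edge.other(node)
        return other if other[0] == "s" else None

    # ---- step 1 ---------------------------------------------------------

    def step1(self):
        self.step_marks["step1"] = len(self.log)
        for sid in sorted(self.g.specials):
            node = self.g.specials[sid]
            if node.loop and node.source == "a":
                self.op_delete_special(sid)

    # ---- step 2 ---------------------------------------------------------

    def _closure_kind(self, e: Edge) -> Tuple[str, list]:
        """How edge e would be closed: by the other colour's occupancy."""
        other = "a" if e.color == "b" else "b"
        occupied = []
        for node in (e.u, e.v):
            oe = self.g.conv_slots[node[1:]][other]
            if oe is not None:
                occupied.append((node, oe))
        kind = {2: "double", 1: "sesqui", 0: "join"}[len(occupied)]
        return kind, occupied

    def _close(self, e: Edge, count: bool = False):
        other = "a" if e.color == "b" else "b"
        kind, occupied = self._closure_kind(e)
        if count:
            self.counts["closures"] += 1
        if kind == "join":
            self.op_join(e.u, e.v, other)
        elif kind == "sesqui":
            node, oe = occupied[0]
            tgt = e.other(node)
            self.op_sesqui(oe, node, tgt)
        else:
            (n1, oe1), (n2, oe2) = occupied
            p, ps = ((oe1.v, oe1.v_stub) if oe1.other(n1) == oe1.v
                     else (oe1.u, oe1.u_stub))
            q, qs = ((oe2.v, oe2.v_stub) if oe2.other(n2) == oe2.v
                     else (oe2.u, oe2.u_stub))
            self.op_double(oe1, oe2,
                           [((n1, None), (n2, None)), ((p, ps), (q, qs))])

    def step2(self):
        self.step_marks["step2"] = len(self.log)
        prefer = "double" if self.w.double <= self.w.sesqui else "sesqui"
        fallback = "sesqui" if prefer == "double" else "double"
        while True:
            cands = [e for e in self.g.conv_edge_list()
                     if not self.g.in_two_circle(e)]
            if not cands:
                break
            by_kind: Dict[str, list] = {"double": [], "sesqui": [], "join": []}
            for e in cands:
                by_kind[self._closure_kind(e)[0]].append(e)
            for kind in (prefer, fallback, "join"):
                if by_kind[kind]:
                    self._close(min(by_kind[kind], key=self.g.edge_key),
                                count=True)
                    break

    # ---- generic rule actions -------------------------------------------

    def _retrace(self, node):
        """Fresh Component containing `node` (after mutations)."""
        if node[0] == "s" and node[1] not in self.g.specials:
            return None
        return self.g._trace(node)

    def _surviving_node(self, *comps):
        for c in comps:
            for n in sorted(c.nodes, key=self.g.node_key):
                if n[0] == "c" and n[1:] in self.g.conv_slots:
                    return n
                if n[0] == "s" and n[1] in self.g.specials:
                    return n
        return None

    def act_join(self, P: Component, Q: Component):
        """Join same-coloured free special ends of two paths (they merge)."""
        for np_, cp in self._free_special_ends(P):
            for nq, cq in self._free_special_ends(Q):
                if cp == cq and np_ != nq:
                    self.op_join(np_, nq, cp)
                    return True
        return False

    def _transfer_candidates(self, comp: Component):
        """(edge, freed_special, colour) for each external edge at a conv end."""
        out = []
        for node, edge in self._end_info(comp):
            if node[0] == "c" and edge is not None:
                sp = edge.other(node)
                if sp[0] == "s":
                    out.append((edge, sp, self.g.specials[sp[1]].source))
        return out

    def act_transfer(self, cut_comp: Component, join_comp: Component):
        """Cut an external edge of one path; the freed region node merges into
        the other path's end region node (a single sesqui)."""
        targets = self._free_special_ends(join_comp)
        for edge, sp, col in self._transfer_candidates(cut_comp):
            for nq, cq in targets:
                if cq == col and nq != sp:
                    stub = edge.u_stub if edge.u == sp else edge.v_stub
                    self.op_sesqui(edge, sp, nq, stub, None)
                    return True
        return False

    def act_transfer_to_conv(self, cut_comp: Component, join_comp: Component):
        """Cut an external edge; join the freed region node to the other
        path's conventional end (no merge)."""
        for edge, sp, col in self._transfer_candidates(cut_comp):
            for nq, cq in self._conv_ends(join_comp):
                if cq == col:
                    stub = edge.u_stub if edge.u == sp else edge.v_stub
                    self.op_sesqui(edge, sp, nq, stub, None)
                    return True
        return False

    def act_merge(self, P: Component, Q: Component, order=("transfer01",)):
        """Apply the first applicable merge template from `order` plus
        fallbacks, so aggregated subtypes (isolated nodes, two-node paths)
        are handled by the geometrically possible variant."""
        chain = list(order) + ["transfer01", "transfer10", "join", "convclose"]
        seen = set()
        for tag in chain:
            if tag in seen:
                continue
            seen.add(tag)
            ok = {
                "join": lambda: self.act_join(P, Q),
                "transfer01": lambda: self.act_transfer(P, Q),
                "transfer10": lambda: self.act_transfer(Q, P),
                "convclose": lambda: self.act_conv_close(P, Q),
            }[tag]()
            if ok:
                return True
        return False

    def act_conv_close(self, P: Component, Q: Component):
        """Connect two conventional path ends by a conventional edge and
        immediately cut it out (a join and a closure)."""
        for np_, cp in self._conv_ends(P):
            if cp is None:
                continue
            for nq, cq in self._conv_ends(Q):
                if cq == cp:
                    self.op_join(np_, nq, cp)
                    e = self.g.conv_slots[np_[1:]][cp]
                    self._close(e)
                    return True
        return False

    def act_detach(self, donor: Component, acceptor: Component):
        """Cut out the pair (extreme a-node, neighbouring conventional node)
        of the donor; the freed b-region node merges into the acceptor's
        extreme b-node.  Leaves a two-node remainder path."""
        for node, edge in self._end_info(donor):
            if node[0] == "s" and self.g.specials[node[1]].source == "a" \
                    and edge is not None:
                u = edge.other(node)
                if u[0] != "c":
                    continue
                inward = self.g.conv_slots[u[1:]]["b" if edge.color == "a" else "a"]
                if inward is None or inward.kind != "spec":
                    continue
                s1 = inward.other(u)
                if s1[0] != "s":
                    continue
                for nq, cq in self._free_special_ends(acceptor):
                    if cq == self.g.specials[s1[1]].source and nq != s1:
                        stub = inward.u_stub if inward.u == s1 else inward.v_stub
                        self.op_sesqui(inward, s1, nq, stub, None)
                        return True
        return False

    def act_loop_absorb(self, loop_comp: Component, t: Component):
        """Merge a special loop's region into a b-node of t (4.1)."""
        L = loop_comp.order[0]
        loop_edge = next(e for e in self.g.incident(L) if e.loop)
        if t.shape == "isolated":
            B = t.order[0]
            self.op_sesqui(loop_edge, L, B, 0, None)
            return True
        if t.shape == "sloop":
            T = t.order[0]
            t_loop = next(e for e in self.g.incident(T) if e.loop)
            self.op_double(loop_edge, t_loop,
                           [((L, 0), (T, 0)), ((L, 1), (T, 1))])
            return True
        for B in sorted((n for n in t.nodes if n[0] == "s"
                         and self.g.specials[n[1]].source == "b"),
                        key=self.g.node_key):
            edges = [e for e in self.g.incident(B) if not e.loop]
            if not edges:
                continue
            e2 = min(edges, key=self.g.edge_key)
            x = e2.other(B)
            bstub = e2.u_stub if e2.u == B else e2.v_stub
            self.op_double(loop_edge, e2,
                           [((L, 0), (B, bstub)), ((L, 1), (x, None))])
            return True
        return False

    def act_circle_absorb(self, circ: Component, t: Component):
        """Insert a special circle next to a b-node of t (4.2): one double
        merging the two b-nodes, then a closure of the bridging edge."""
        bc = sorted((n for n in circ.nodes if n[0] == "s"
                     and self.g.specials[n[1]].source == "b"),
                    key=self.g.node_key)
        bt = sorted((n for n in t.nodes if n[0] == "s"
                     and self.g.specials[n[1]].source == "b"),
                    key=self.g.node_key)
        for Bc in bc:
            ec = [e for e in self.g.incident(Bc) if not e.loop]
            if not ec:
                continue
            e1 = min(ec, key=self.g.edge_key)
            uc = e1.other(Bc)
            for Bt in bt:
                et = [e for e in self.g.incident(Bt) if not e.loop]
                if not et:
                    continue
                e2 = min(et, key=self.g.edge_key)
                ut = e2.other(Bt)
                s1 = e1.u_stub if e1.u == Bc else e1.v_stub
                s2 = e2.u_stub if e2.u == Bt else e2.v_stub
                self.op_double(e1, e2,
                               [((Bc, s1), (Bt, s2)), ((uc, None), (ut, None))])
                bridge = self.g.conv_slots[uc[1:]]["b"]
                if bridge is not None and not self.g.in_two_circle(bridge):
                    self._close(bridge)
                return True
        return False

    # ---- deferred-choice (1_c) components -------------------------------

    class Limbo:
        """A deferred choice between two merge variants (type 1_c).

        The two constituent paths stay physically untouched in the graph;
        the limbo stands for their eventual merge, resolved to a 1_a- or
        1_b-shaped path at steps 4.15-4.24.
        """

        def __init__(self, engine, P: Component, Q: Component, variants):
            self.engine = engine
            self.P, self.Q = P, Q
            self.variants = variants          # {'a': fn, 'b': fn}
            self.nodes = set(P.nodes) | set(Q.nodes)
            self.resolved = None

        def resolve(self, c: str) -> Component:
            assert self.resolved is None
            self.variants[c]()
            self.resolved = c
            node = self.engine._surviving_node(self.P, self.Q)
            return self.engine._retrace(node)

    def _defer_31(self, P: Component, Q: Component):
        """1a + 1b: the cut may go in either path (result 1_b or 1_a)."""
        self.limbos.append(self.Limbo(
            self, P, Q,
            {"b": lambda: self.act_transfer(P, Q),
             "a": lambda: self.act_transfer(Q, P)}))

    def _defer_33(self, two: Component, three: Component):
        """2 + 3: either external edge of the 3-path may be cut."""
        def cut(color):
            def go():
                targets = [(n, c) for (n, c)
                           in self._free_special_ends(two) if c == color]
                for edge, sp, col in self._transfer_candidates(three):
                    if col != color:
                        continue
                    for nq, _cq in targets:
                        stub = edge.u_stub if edge.u == sp else edge.v_stub
                        self.op_sesqui(edge, sp, nq, stub, None)
                        return
                raise RuntimeError("deferred 2+3 variant not applicable")
            return go
        # cutting the b-side external edge leaves the a-node end hanging (1_a)
        self.limbos.append(self.Limbo(
            self, two, three, {"a": cut("b"), "b": cut("a")}))

    # ---- rule tables ----------------------------------------------------

    AGG = {"2a": ("2a", "2a'"), "3b": ("3b", "3b'"),
           "1_b": ("1_b", "1''"), "2": ("2", "2'")}

    STEP3_RULES = [
        ("3.1", [("1a", "1b")], "defer31"),
        ("3.2", [("2a", "3b"), ("2b", "3a"), ("2b'", "3a"), ("2b", "3a'"),
                 ("2b'", "3a'")], ("transfer", 1, 0)),
        ("3.3", [("2", "3")], "defer33"),
        ("3.4", [("1b", "2a", "3"), ("1a", "2b", "3"), ("1a", "2b'", "3")],
         ("seq", ("transfer", 0, 1), ("defer33", "r", 2))),
        ("3.5", [("1a", "3b", "2"), ("1b", "3a", "2"), ("1b", "3a'", "2")],
         ("seq", ("transfer", 1, 0), ("defer33", 2, "r"))),
        ("3.6", [("1a", "2"), ("1b", "2")], ("transfer", 0, 1)),
        ("3.7", [("1a", "3"), ("1b", "3")], ("transfer", 1, 0)),
        ("3.8", [("1a", "1a", "2b", "3b"), ("1a", "1a", "2b'", "3b"),
                 ("1b", "1b", "2a", "3a"), ("1b", "1b", "2a", "3a'")],
         ("seq", ("transfer", 0, 2), ("transfer", 3, 1), ("defer33", "r0", "r1"))),
        ("3.9", [("1a", "1a", "2b"), ("1a", "1a", "2b'"), ("1b", "1b", "2a")],
         ("seq", ("join", 0, 1), ("transfer", "r", 2))),
        ("3.10", [("1a", "1a", "3b"), ("1b", "1b", "3a"), ("1b", "1b", "3a'")],
         ("seq", ("transfer", 2, 0), ("transfer", "r", 1))),
        ("3.11", [("1a", "1a"), ("1b", "1b")], ("join", 0, 1)),
        ("3.12", [("1a", "2b"), ("1a", "2b'"), ("1b", "2a")], ("transfer", 0, 1)),
        ("3.13", [("1a", "3b"), ("1b", "3a"), ("1b", "3a'")], ("transfer", 1, 0)),
        ("3.14", [("2a", "2b", "3", "3"), ("2a", "2b'", "3", "3")],
         ("seq", ("transfer", 2, 1), ("transfer", "r", 0), ("defer33", "r", 3))),
        ("3.15", [("3a", "3b", "2", "2"), ("3a'", "3b", "2", "2")],
         ("seq", ("transfer", 1, 2), ("transfer", 0, "r"), ("defer33", 3, "r"))),
        ("3.16", [("2a", "3", "3"), ("2b", "3", "3"), ("2b'", "3", "3")],
         ("seq", ("transfer", 1, 0), ("transfer", 2, "r"))),
        ("3.17", [("3b", "2", "2"), ("3a", "2", "2"), ("3a'", "2", "2")],
         ("seq", ("transfer", 0, 1), ("transfer", "r", 2))),
        ("3.18", [("2a", "2b", "3"), ("2a", "2b'", "3")],
         ("seq", ("transfer", 2, 1), ("transfer", "r", 0))),
        ("3.19", [("3a", "3b", "2"), ("3a'", "3b", "2")],
         ("seq", ("transfer", 1, 2), ("transfer", 0, "r"))),
    ]

    STEP4_UNPRIMED = [
        ("4.1", "loop_rule", None),
        ("4.2", "circle_rule", None),
        ("4.3", [("2a", "2b")], ("detach", 1, 0)),
        ("4.4", [("3a", "3b")], ("transfer_conv", 0, 1)),
        ("4.5", [("2a", "3"), ("2b", "3")], ("transfer", 1, 0)),
        ("4.6", [("3a", "2"), ("3b", "2")], ("transfer", 0, 1)),
        ("4.7", [("2a'", "2a"), ("2a'", "2a'")], ("join", 0, 1)),
        ("4.8", [("3a", "3a"), ("3b", "3b")], ("convclose", 0, 1)),
        ("4.9", [("1a", "2a"), ("1b", "2b")], ("join", 0, 1)),
        ("4.10", [("1a", "3a"), ("1b", "3b")], ("convclose", 0, 1)),
        ("4.11", [("2a", "2"), ("2b", "2")], ("join", 0, 1)),
        ("4.12", [("3a", "3"), ("3b", "3")], ("convclose", 0, 1)),
        ("4.13", [("2", "2")], ("detach", 0, 1)),
        ("4.14", [("3", "3")], ("transfer_conv", 0, 1)),
        ("4.15", [("1_a", "1_a"), ("1_b", "1_b"), ("1_b", "1_c")],
         ("transfer", 0, 1)),
        ("4.16", [("1a", "1_b"), ("1b", "1_a"), ("1a", "1_c")],
         ("transfer", 1, 0)),
        ("4.17", [("1a", "1_a"), ("1b", "1_b"), ("1b", "1_c")],
         ("transfer", 0, 1)),
        ("4.18", [("2a", "1_b"), ("2b", "1_a"), ("2a", "1_c")],
         ("transfer", 1, 0)),
        ("4.19", [("3a", "1_a"), ("3b", "1_b"), ("3b", "1_c")],
         ("transfer", 0, 1)),
        ("4.20", [("2", "1_a"), ("2", "1_b"), ("2", "1_c")], ("transfer", 1, 0)),
        ("4.21", [("3", "1_a"), ("3", "1_b"), ("3", "1_c")], ("transfer", 0, 1)),
        ("4.22", [("1_a", "1_c"), ("1b", "1_c"), ("1a", "1_c"),
                  ("2b", "1_c"), ("3a", "1_c")], "resolve_a_merge"),
        ("4.23", "leftover_1c", None),
    ]

    # In the regime where double-cut-and-paste is not more expensive than
    # sesqui, the action list differs only where variants are spelt out; the
    # explicitly primed input types are all covered by the type-aggregation
    # convention, and the genuine differences are the null actions replacing
    # 4.14, 4.22 and 4.23 (leftover deferred choices resolve at the closing
    # step instead).
    STEP4_PRIMED = [rule for rule in STEP4_UNPRIMED
                    if rule[0] not in ("4.14", "4.22", "4.23")]

    # ---- rule matching and execution -------------------------------------

    def _live_components(self):
        limbo_nodes = set()
        for lm in self.limbos:
            if lm.resolved is None:
                limbo_nodes |= lm.nodes
        comps = []
        for c in self.g.components():
            t = c.classify()
            if t in ("final", "isolated_conv"):
                continue
            if c.nodes & limbo_nodes:
                continue
            comps.append((t, c))
        return comps

    def _match_types(self, pattern, comps, agg: bool):
        """First combination of distinct live components matching `pattern`.

        '1_c' slots match unresolved limbos.  Returns a list of Component /
        Limbo in pattern order, or None.
        """
        def expand(sym):
            if agg and sym in self.AGG:
                return self.AGG[sym]
            return (sym,)

        pool = {}
        for t, c in comps:
            pool.setdefault(t, []).append(c)
        limbos = [lm for lm in self.limbos if lm.resolved is None]

        def backtrack(i, used, used_limbo, acc):
            if i == len(pattern):
                return acc
            sym = pattern[i]
            if sym == "1_c":
                for lm in limbos:
                    if id(lm) in used_limbo:
                        continue
                    r = backtrack(i + 1, used, used_limbo | {id(lm)},
                                  acc + [lm])
                    if r:
                        return r
                return None
            for t in expand(sym):
                for c in pool.get(t, ()):
                    if id(c) in used:
                        continue
                    r = backtrack(i + 1, used | {id(c)}, used_limbo, acc + [c])
                    if r:
                        return r
            return None

        return backtrack(0, frozenset(), frozenset(), [])

    def _exec_action(self, action, matched):
        """Run one rule action; returns True on success."""
        def get(i, result):
            if isinstance(i, str) and i.startswith("r"):
                idx = int(i[1:]) if len(i) > 1 else -1
                return result[idx]
            m = matched[i]
            if isinstance(m, Engine.Limbo):
                m = m.resolve("b")
            return m

        if action == "defer31":
            self._defer_31(matched[0], matched[1])
            return True
        if action == "defer33":
            self._defer_33(matched[0], matched[1])
            return True
        if action == "resolve_a_merge":
            partner, limbo = matched
            comp = limbo.resolve("a")
            return self.act_merge(partner, comp)
        kind = action[0]
        if kind == "seq":
            results = []
            for sub in action[1:]:
                tag = sub[0]
                x = get(sub[1], results)
                y = get(sub[2], results)
                if tag == "transfer":
                    ok = self.act_merge(x, y, order=("transfer01",))
                elif tag == "join":
                    ok = self.act_merge(x, y, order=("join",))
                elif tag == "defer33":
                    self._defer_33(x, y)
                    ok = True
                else:
                    raise AssertionError(tag)
                if not ok:
                    raise RuntimeError(f"compound sub-action failed: {sub}")
                if tag != "defer33":
                    node = self._surviving_node(x, y)
                    results.append(self._retrace(node))
                else:
                    results.append(None)
            return True
        x = get(action[1], None)
        y = get(action[2], None)
        order = {"transfer": ("transfer01",), "join": ("join",),
                 "convclose": ("convclose",)}.get(kind)
        if kind == "detach":
            return self.act_detach(x, y)
        if kind == "transfer_conv":
            if self.act_transfer_to_conv(x, y):
                return True
            return self.act_transfer_to_conv(y, x)
        return self.act_merge(x, y, order=order)

    # ---- step 3 ----------------------------------------------------------

    def step3(self):
        self.step_marks["step3"] = len(self.log)
        guard = 0
        while True:
            guard += 1
            if guard > 40 * (len(self.g.specials) + 8):
                raise RuntimeError("step 3 failed to terminate")
            comps = self._live_components()
            fired = False
            for name, patterns, action in self.STEP3_RULES:
                for pattern in patterns:
                    matched = self._match_types(pattern, comps, agg=True)
                    if matched:
                        if self._exec_action(action, matched):
                            fired = True
                            break
                if fired:
                    break
            if not fired:
                return

    # ---- step 4 ----------------------------------------------------------

    def _loop_rule(self, comps):
        loops = [c for t, c in comps if t == "loop"]
        if not loops:
            return False
        for t, c in comps:
            if c is loops[0] or t in ("b-circle", "a-circle"):
                continue
            if c.has_color_node("b"):
                if self.act_loop_absorb(loops[0], c):
                    return True
        return False

    def _circle_rule(self, comps):
        circles = [c for t, c in comps if t == "circle"]
        if not circles:
            return False
        for t, c in comps:
            if c is circles[0] or t in ("b-circle", "a-circle", "loop", "a-loop"):
                continue
            if c.has_color_node("b") and c.has_color_node("a"):
                if self.act_circle_absorb(circles[0], c):
                    return True
        return False

    def step4(self):
        self.step_marks["step4"] = len(self.log)
        primed = self.w.double <= self.w.sesqui
        rules = self.STEP4_PRIMED if primed else self.STEP4_UNPRIMED
        agg = True
        guard = 0
        while True:
            guard += 1
            if guard > 40 * (len(self.g.specials) + 8):
                raise RuntimeError("step 4 failed to terminate")
            comps = self._live_components()
            fired = False
            for name, patterns, action in rules:
                if patterns == "loop_rule":
                    fired = self._loop_rule(comps)
                elif patterns == "circle_rule":
                    fired = self._circle_rule(comps)
                elif patterns == "leftover_1c":
                    fired = self._resolve_leftover_1c()
                else:
                    for pattern in patterns:
                        matched = self._match_types(pattern, comps, agg=agg)
                        if matched:
                            if self._exec_action(action, matched):
                                fired = True
                                break
                if fired:
                    break
            if not fired:
                break
        self._step4_close()
        # record the step-4 end state for the weight-formula bookkeeping;
        # only circles that were b-only from the start are excluded
        comps = self._live_components()
        with_b = sum(1 for t, c in comps
                     if c.has_color_node("b") or t == "loop")
        b_circ = sum(1 for t, c in comps if t == "b-circle")
        self.n_small = with_b - min(b_circ, getattr(self, "_b_prime0", b_circ))

    def _resolve_leftover_1c(self):
        pending = [lm for lm in self.limbos if lm.resolved is None]
        if not pending:
            return False
        comps = [lm.resolve("b") for lm in pending]
        while len(comps) >= 2:
            P, Q = comps.pop(), comps.pop()
            self.act_merge(P, Q, order=("transfer01",))
            node = self._surviving_node(P, Q)
            comps.append(self._retrace(node))
        return True

    def _step4_close(self):
        """4.24: close remaining paths into circles; re-run 4.2 afterwards."""
        guard = 0
        while True:
            guard += 1
            if guard > 10 * (len(self.g.specials) + 8):
                raise RuntimeError("closing loop failed to terminate")
            comps = self._live_components()
            target = None
            for t, c in comps:
                if c.shape != "path":
                    continue
                if t in ("1'", "1''", "2'"):
                    continue              # no non-hanging edge to close with
                if t in ("3a'", "3b'"):
                    continue              # closing would circularise a region
                target = (t, c)
                break
            # unresolved limbos count as closable 1_c paths
            if target is None:
                pending = [lm for lm in self.limbos if lm.resolved is None]
                if pending:
                    comp = pending[0].resolve("b")
                    target = (comp.classify(), comp)
            if target is None:
                break
            self._close_path(*target)
        # re-run 4.2 until no circle can be inserted anywhere
        guard = 0
        while True:
            guard += 1
            if guard > 10 * (len(self.g.specials) + 8):
                raise RuntimeError("4.2 re-run failed to terminate")
            if not self._circle_rule(self._live_components()):
                break

    def _close_path(self, t: str, comp: Component):
        g = self.g
        ends = self._end_info(comp)
        sp_ends = self._free_special_ends(comp)
        if len(sp_ends) == 2 and sp_ends[0][1] == sp_ends[1][1]:
            # 2a, 2b, 3a?, odd two-hanging paths: join the two end nodes
            self.op_join(sp_ends[0][0], sp_ends[1][0], sp_ends[0][1])
            return
        if len(sp_ends) == 2:
            # type 2: ends of different colours; merge the two b-nodes and
            # delete the a-node from the split-off two-node path
            a_end = next(n for n, c in sp_ends if c == "a")
            b_end = next(n for n, c in sp_ends if c == "b")
            a_edge = next(e for e in g.incident(a_end))
            u = a_edge.other(a_end)
            inward = g.conv_slots[u[1:]]["b" if a_edge.color == "a" else "a"]
            s1 = inward.other(u)
            stub = inward.u_stub if inward.u == s1 else inward.v_stub
            self.op_sesqui(inward, s1, b_end, stub, None)
            self.op_delete_special(a_end[1])
            return
        if len(sp_ends) == 1:
            sp, col = sp_ends[0]
            conv_end = next(n for n, _e in ends if n[0] == "c")
            # marginal special adjacent to the conventional end
            medge = next(e for n, e in ends if n[0] == "c")
            msp = medge.other(conv_end)
            if msp[0] == "s" and g.specials[msp[1]].source == col:
                # 1_a / 1_b: cut at the conventional end, merge the regions
                stub = medge.u_stub if medge.u == msp else medge.v_stub
                self.op_sesqui(medge, msp, sp, stub, None)
            else:
                # 1a / 1b: the end region node has a free flank of the same
                # colour as the conventional end's free slot; joining them
                # closes the circle with the region inside it
                self.op_join(sp, conv_end, col)
            return
        # both ends conventional
        (n1, e1), (n2, e2) = ends
        conv_ends = self._conv_ends(comp)
        if conv_ends[0][1] == conv_ends[1][1] and conv_ends[0][1] is not None:
            # 3a / 3b: join the ends by a conventional edge, then cut it out
            # (the closure merges the two marginal region nodes)
            self.op_join(n1, n2, conv_ends[0][1])
            e = self.g.conv_slots[n1[1:]][conv_ends[0][1]]
            if e is not None and not self.g.in_two_circle(e):
                self._close(e)
            return
        # type 3: ends of different free colours; a single sesqui closes it
        s_first = e1.other(n1)
        stub = e1.u_stub if e1.u == s_first else e1.v_stub
        self.op_sesqui(e1, s_first, n2, stub, None)

    # ---- step 5 ----------------------------------------------------------

    def step5(self):
        self.step_marks["step5"] = len(self.log)
        g = self.g
        # isolated special nodes and loops, and specials on leftover paths
        for t, c in list(self._live_components()):
            if c.shape in ("isolated", "sloop"):
                n = c.order[0]
                if n[0] == "s":
                    self.op_delete_special(n[1])
            elif c.shape == "path":
                for n in sorted(c.specials_in(), key=g.node_key):
                    if n[1] in g.specials:
                        self.op_delete_special(n[1])
        # chop circles longer than 2 so that b-nodes merge pairwise
        guard = 0
        while True:
            guard += 1
            if guard > 10 * (len(g.specials) + 8):
                raise RuntimeError("step 5 circle loop failed to terminate")
            circ = None
            for t, c in self._live_components():
                if c.shape == "circle" and c.length > 2 \
                        and sum(1 for n in c.nodes if n[0] == "s") >= 2:
                    circ = c
                    break
            if circ is None:
                break
            self._chop_circle(circ)
        # delete specials from the remaining 2-circles (and stray circles)
        for t, c in list(self._live_components()):
            if c.shape == "circle":
                for n in sorted((n for n in c.nodes if n[0] == "s"),
                                key=g.node_key):
                    if n[1] in g.specials:
                        self.op_delete_special(n[1])
        # close any conventional edges left outside final 2-circles
        guard = 0
        while True:
            guard += 1
            if guard > 4 * (len(g.edges) + 8):
                raise RuntimeError("step 5 closure loop failed to terminate")
            cands = [e for e in g.conv_edge_list() if not g.in_two_circle(e)]
            if not cands:
                break
            self._close(min(cands, key=g.edge_key))

    def _chop_circle(self, comp: Component):
        """Cut a 2-circle out of a longer circle so that two b-nodes merge."""
        g = self.g
        order = comp.order            # n0 e0 n1 e1 ... (cycle)
        nodes = comp.path_nodes
        k = len(nodes)
        # find pattern B1 - u - A - u' - B2 around the circle
        for i, n in enumerate(nodes):
            if n[0] == "s" and g.specials[n[1]].source == "b":
                a_node = nodes[(i + 2) % k]
                b2 = nodes[(i + 4) % k]
                if a_node[0] == "s" and g.specials[a_node[1]].source == "a" \
                        and b2[0] == "s" and g.specials[b2[1]].source == "b" \
                        and b2 != n:
                    u = nodes[(i + 1) % k]
                    u2 = nodes[(i + 3) % k]
                    e1 = g.conv_slots[u[1:]]["b"]
                    e2 = g.conv_slots[u2[1:]]["b"]
                    s1 = e1.u_stub if e1.u == n else e1.v_stub
                    s2 = e2.u_stub if e2.u == b2 else e2.v_stub
                    self.op_double(e1, e2,
                                   [((n, s1), (b2, s2)), ((u, None), (u2, None))])
                    return
        # circle with a single b-node (or none): fall back to deleting specials
        for n in sorted((n for n in comp.nodes if n[0] == "s"), key=g.node_key):
            if n[1] in g.specials:
                self.op_delete_special(n[1])
                return

    # ---- driver ----------------------------------------------------------

    def run(self, stop_after: Optional[str] = None,
            capture_components: bool = False):
        self._b_prime0 = sum(
            1 for c in self.g.components()
            if c.shape == "circle" and c.has_color_node("b")
            and not c.has_color_node("a"))
        self.step1()
        self.step2()
        if capture_components:
            self.post_step2_components = [
                (t, c.signature(), sum(1 for n in c.nodes if n[0] == "s"),
                 component_to_pair(self.g, c))
                for t, c in self._live_components()]
        if stop_after == "step2":
            return self
        self.step3()
        if stop_after == "step3":
            return self
        self.step4()
        if stop_after == "step4":
            return self
        self.step5()
        assert self.g.is_final(), "graph did not reach final form"
        return self

    @property
    def total_weight(self) -> Fraction:
        return sum((op.weight for op in self.log), Fraction(0))

    def scenario_records(self) -> List[OperationRecord]:
        """Forward scenario: a-coloured ops, then reversed b-coloured ops."""
        recs = []
        for op in self.log:
            if op.color == "a":
                recs.append(OperationRecord(op.record_kind, op.payload,
                                            op.weight, op.snapshot))
        for op in reversed(self.log):
            if op.color == "b":
                recs.append(OperationRecord(op.record_kind, op.payload,
                                            op.weight, op.snapshot))
        return recs


def component_to_pair(g: CommonGraph, comp: Component):
    """Re-express one component as a standalone structure pair.

    Each conventional node becomes extremity 1 of a fresh gene (the other
    extremity is free on both sides, which leaves the component's dynamics
    unchanged); each region node becomes a single fresh private gene.  The
    pair's optimal transformation cost therefore measures the component's
    individual contribution.
    """
    from . import ops as _o

    conv_name: Dict[tuple, tuple] = {}
    for i, n in enumerate(sorted((n for n in comp.nodes if n[0] == "c"),
                                 key=g.node_key)):
        conv_name[n] = (f"n{i}", 0)
    sp_name: Dict[int, tuple] = {}
    for j, n in enumerate(sorted((n for n in comp.nodes if n[0] == "s"),
                                 key=g.node_key)):
        sp_name[n[1]] = ((f"sa{j}", 0) if g.specials[n[1]].source == "a"
                         else (f"sb{j}", 0))

    def build(color):
        genes = set(conv_name.values())
        adjs = set()
        for sid, key in sp_name.items():
            if g.specials[sid].source == color:
                genes.add(key)
        for e in comp.edges:
            if e.color != color:
                continue
            if e.loop:
                key = sp_name[e.u[1]]
                adjs.add(frozenset(((key, 1), (key, 2))))
                continue
            ends = []
            for node, stub in ((e.u, e.u_stub), (e.v, e.v_stub)):
                if node[0] == "c":
                    ends.append((conv_name[node], 1))
                else:
                    ends.append((sp_name[node[1]], (stub or 0) + 1))
            adjs.add(frozenset(ends))
        return _o.to_structure(_o.AdjacencyState(frozenset(genes),
                                                 frozenset(adjs)))

    return build("a"), build("b")
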