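"""Paralog assignment by integer linear programming.

When gene families carry several copies, the distance between two structures
is the minimum over bijections between the copies of each family.  For
circular structures under equal standard-operation weights the distance
equals B + S1 - S2 (blocks, half-lengths of conventional-edge regions,
conventional-edge circles of the common graph), and each summand is encoded
with a dedicated variable family:

* ``z[k,i,j]``  -- copy i of family k in `a` corresponds to copy j in `b`;
* ``x[a|b][s]`` -- adjacent pair s lies at a block border (0.5 * sum = B);
* ``y[a|b][s]`` -- alternation markers along conventional-edge regions
  (sum = S1, a minimum vertex cover of the region chains);
* ``u[s], p[s]`` -- u is constant along each circle of conventional edges
  and bounded by a distinct cap m_s; p flags the one edge whose cap is
  attained (sum = S2).

One auxiliary 0/1 variable per chromosome covers the corner the printed sums
miss: a chromosome whose genes are all unmatched forms a region with no block
border yet still costs its deletion.

Linear chromosomes are handled by closing them into circles first; the result
overestimates the true distance by at most twice the number of closed paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import (Chromosome, ChromosomeStructure, GeneToken, WeightScheme,
                    case2_weights)
from . import ops as _ops

__all__ = [
    "Bijections", "MatchingILP", "SimilarityTable",
    "build_matching_ilp", "solve_paralog_matching", "relabel_matched",
    "close_paths", "distance_with_paths", "breakpoint_matching",
]

SimilarityTable = Dict[Tuple[str, int, int], float]   # (family, i, j) -> [0,1]


@dataclass
class Bijections:
    """Per-family partial one-to-one maps between paralog copies."""

    maps: Dict[str, Dict[int, int]] = field(default_factory=dict)

    def matched_pairs(self):
        for fam in sorted(self.maps):
            for i, j in sorted(self.maps[fam].items()):
                yield fam, i, j


def _paralog_sets(s: ChromosomeStructure) -> Dict[str, List[int]]:
    out: Dict[str, List[int]] = {}
    for c in s.chromosomes:
        for g in c.genes:
            out.setdefault(g.family, []).append(g.paralog or 0)
    for fam in out:
        out[fam] = sorted(out[fam])
    return out


@dataclass
class MatchingILP:
    """Assembled instance: objective, bounds, integrality and constraints."""

    n_vars: int
    objective: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    integrality: np.ndarray
    rows: List[tuple]                 # (coeff dict col->val, lb, ub)
    z_index: Dict[Tuple[str, int, int], int]
    aux_index: Dict[int, int]
    core_cols: List[int]              # columns of 0.5x + y - p (+aux)
    core_coeffs: List[float]
    counts: Dict[str, int]
    adjacency_info: dict

    def constraint_matrix(self):
        data, ri, ci = [], [], []
        lbs, ubs = [], []
        for r, (coeffs, lb, ub) in enumerate(self.rows):
            for c, v in coeffs.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
            lbs.append(lb)
            ubs.append(ub)
        A = sparse.csr_matrix((data, (ri, ci)),
                              shape=(len(self.rows), self.n_vars))
        return A, np.array(lbs), np.array(ubs)


def build_matching_ilp(a: ChromosomeStructure, b: ChromosomeStructure,
                       sim: Optional[SimilarityTable] = None) -> MatchingILP:
    """Variable and constraint families for the paralog-matching programme.

    Requires all chromosomes circular (close linear ones first, see
    :func:`distance_with_paths`); intended for equal standard-operation
    weights, where the optimum of F is the distance B + S1 - S2.
    """
    for s, nm in ((a, "a"), (b, "b")):
        if any(not c.circular for c in s.chromosomes):
            raise ValueError(
                f"structure {nm} has linear chromosomes; use distance_with_paths")

    pa, pb = _paralog_sets(a), _paralog_sets(b)
    shared = sorted(set(pa) & set(pb))

    cols: List[Tuple[str, tuple]] = []

    def new_col(tag, key):
        cols.append((tag, key))
        return len(cols) - 1

    z_index: Dict[Tuple[str, int, int], int] = {}
    for fam in shared:
        for i in pa[fam]:
            for j in pb[fam]:
                if sim is not None and sim.get((fam, i, j), 1.0) == 0.0:
                    continue
                z_index[(fam, i, j)] = new_col("z", (fam, i, j))

    st_a, st_b = _ops.to_adjacencies(a), _ops.to_adjacencies(b)
    adj_a = sorted(st_a.adjacencies, key=sorted)
    adj_b = sorted(st_b.adjacencies, key=sorted)

    x_index = {("a", s): new_col("x", ("a", s)) for s in range(len(adj_a))}
    x_index.update({("b", s): new_col("x", ("b", s))
                    for s in range(len(adj_b))})
    y_index = {("a", s): new_col("y", ("a", s)) for s in range(len(adj_a))}
    y_index.update({("b", s): new_col("y", ("b", s))
                    for s in range(len(adj_b))})
    u_index = {("a", s): new_col("u", ("a", s)) for s in range(len(adj_a))}
    u_index.update({("b", s): new_col("u", ("b", s))
                    for s in range(len(adj_b))})
    p_index = {("a", s): new_col("p", ("a", s)) for s in range(len(adj_a))}
    p_index.update({("b", s): new_col("p", ("b", s))
                    for s in range(len(adj_b))})
    # distinct caps 1..M make exactly one p per conventional circle reachable
    m_of: Dict[tuple, int] = {}
    cap = 0
    for side, adjs in (("a", adj_a), ("b", adj_b)):
        for s in range(len(adjs)):
            cap += 1
            m_of[(side, s)] = cap

    aux_index: Dict[int, int] = {}
    chrom_slots: List[List[tuple]] = []
    for ci, chrom in enumerate(list(a.chromosomes) + list(b.chromosomes)):
        aux_index[ci] = new_col("v", (ci,))

    n = len(cols)
    rows: List[tuple] = []

    def row(coeffs, lb, ub):
        rows.append((dict(coeffs), lb, ub))

    counts = {k: 0 for k in ("z_constraints", "x_constraints", "y_constraints",
                             "u_p_constraints", "aux_constraints")}

    # z: sums over the third index bounded by 1 for every copy slot
    for fam in shared:
        for i in pa[fam]:
            cs = {z_index[(fam, i, j)]: 1.0 for j in pb[fam]
                  if (fam, i, j) in z_index}
            if cs:
                row(cs, -np.inf, 1.0)
                counts["z_constraints"] += 1
        for j in pb[fam]:
            cs = {z_index[(fam, i, j)]: 1.0 for i in pa[fam]
                  if (fam, i, j) in z_index}
            if cs:
                row(cs, -np.inf, 1.0)
                counts["z_constraints"] += 1

    def matched_sum(side, ext):
        """Columns of sum_j z over the partners of one extremity's copy."""
        (fam, idx), _end = ext
        out = {}
        if fam not in shared:
            return out
        if side == "a":
            for j in pb[fam]:
                c = z_index.get((fam, idx, j))
                if c is not None:
                    out[c] = 1.0
        else:
            for i in pa[fam]:
                c = z_index.get((fam, i, idx))
                if c is not None:
                    out[c] = 1.0
        return out

    def add(dst, src, scale=1.0):
        for c, v in src.items():
            dst[c] = dst.get(c, 0.0) + scale * v

    # x: a border is an adjacency whose two slots differ in matchedness
    for side, adjs in (("a", adj_a), ("b", adj_b)):
        for s, adjacency in enumerate(adjs):
            exts = sorted(adjacency)
            if len(exts) == 1:
                exts = exts * 2
            xs = x_index[(side, s)]
            for e1, e2 in ((exts[0], exts[1]), (exts[1], exts[0])):
                cs = {xs: -1.0}
                add(cs, matched_sum(side, e1))
                add(cs, matched_sum(side, e2), -1.0)
                row(cs, -np.inf, 0.0)          # sum1 - sum2 - x <= 0
                counts["x_constraints"] += 1

    # potential neighbours: slots of the same family and extremity end
    ext_pos_b: Dict[tuple, List[tuple]] = {}
    for s, adjacency in enumerate(adj_b):
        exts = sorted(adjacency)
        if len(exts) == 1:
            exts = exts * 2
        for pos, ext in enumerate(exts):
            ext_pos_b.setdefault((ext[0][0], ext[1]), []).append(
                (s, ext, exts[1 - pos]))

    pairs = []                          # (sa, ext_a, other_a, sb, ext_b, other_b)
    for sa, adjacency in enumerate(adj_a):
        exts = sorted(adjacency)
        if len(exts) == 1:
            exts = exts * 2
        for pos, ext in enumerate(exts):
            (fam, i), end = ext
            if fam not in shared:
                continue
            for (sb, ext_b, other_b) in ext_pos_b.get((fam, end), ()):
                pairs.append((sa, ext, exts[1 - pos], sb, ext_b, other_b))

    # y: alternation along regions of conventional edges
    for sa, ext_a, other_a, sb, ext_b, other_b in pairs:
        zc = z_index.get((ext_a[0][0], ext_a[0][1], ext_b[0][1]))
        if zc is None:
            continue
        ya, yb = y_index[("a", sa)], y_index[("b", sb)]
        base = {zc: 1.0}
        add(base, matched_sum("a", other_a))
        add(base, matched_sum("b", other_b))
        up = dict(base)
        add(up, {ya: 1.0, yb: 1.0})
        row(up, -np.inf, 4.0)              # y_a + y_b <= 4 - (...)
        # y_b >= (...) - 2 - y_a  <=>  (...) - y_a - y_b <= 2
        lo = dict(base)
        add(lo, {ya: 1.0, yb: 1.0}, -1.0)
        row(lo, -np.inf, 2.0)
        counts["y_constraints"] += 2

    # u/p: circles of conventional edges
    M_total = cap
    for side, adjs in (("a", adj_a), ("b", adj_b)):
        for s, adjacency in enumerate(adjs):
            us, ps = u_index[(side, s)], p_index[(side, s)]
            ms = m_of[(side, s)]
            row({ps: ms, us: -1.0}, -np.inf, 0.0)     # p*m <= u
            counts["u_p_constraints"] += 1
            exts = sorted(adjacency)
            if len(exts) == 1:
                exts = exts * 2
            for ext in exts:
                cs = {us: 1.0}
                add(cs, matched_sum(side, ext), -float(ms))
                row(cs, -np.inf, 0.0)                 # u <= m * sum_j z
                counts["u_p_constraints"] += 1
    for sa, ext_a, _oa, sb, ext_b, _ob in pairs:
        zc = z_index.get((ext_a[0][0], ext_a[0][1], ext_b[0][1]))
        if zc is None:
            continue
        ua, ub = u_index[("a", sa)], u_index[("b", sb)]
        ma, mb = m_of[("a", sa)], m_of[("b", sb)]
        row({ua: 1.0, ub: -1.0, zc: float(ma)}, -np.inf, float(ma))
        row({ub: 1.0, ua: -1.0, zc: float(mb)}, -np.inf, float(mb))
        counts["u_p_constraints"] += 2

    # auxiliary per-chromosome variables: 1 when no gene of it is matched
    offset = 0
    for ci, chrom in enumerate(list(a.chromosomes) + list(b.chromosomes)):
        side = "a" if ci < len(a.chromosomes) else "b"
        cs = {aux_index[ci]: 1.0}
        for g in chrom.genes:
            add(cs, matched_sum(side, ((g.family, g.paralog or 0), 1)))
        row(cs, 1.0, np.inf)               # v + sum(matched) >= 1
        counts["aux_constraints"] += 1

    # similarity extension: coverage constraints for positive-similarity pairs
    if sim is not None:
        for (fam, i, j), val in sorted(sim.items()):
            if val > 0 and fam in shared and i in pa[fam] and j in pb[fam]:
                cs = {}
                for jj in pb[fam]:
                    c = z_index.get((fam, i, jj))
                    if c is not None:
                        cs[c] = 1.0
                for ii in pa[fam]:
                    c = z_index.get((fam, ii, j))
                    if c is not None:
                        cs[c] = cs.get(c, 0.0) + 1.0
                if cs:
                    row(cs, 1.0, np.inf)
                    counts["aux_constraints"] += 1

    objective = np.zeros(n)
    lower = np.zeros(n)
    upper = np.ones(n)
    integrality = np.ones(n)
    core_cols, core_coeffs = [], []
    for col, (tag, key) in enumerate(cols):
        if tag == "x":
            objective[col] = 0.5
            core_cols.append(col)
            core_coeffs.append(0.5)
        elif tag == "y":
            objective[col] = 1.0
            core_cols.append(col)
            core_coeffs.append(1.0)
        elif tag == "p":
            objective[col] = -1.0
            core_cols.append(col)
            core_coeffs.append(-1.0)
        elif tag == "v":
            objective[col] = 1.0
            core_cols.append(col)
            core_coeffs.append(1.0)
        elif tag == "u":
            side_s = key
            upper[col] = m_of[side_s]
        elif tag == "z" and sim is not None:
            fam, i, j = key
            objective[col] = 1.0 - float(sim.get((fam, i, j), 1.0))

    counts.update({
        "z_vars": sum(1 for t, _ in cols if t == "z"),
        "x_vars_a": len(adj_a),
        "x_vars_b": len(adj_b),
        "y_vars": len(adj_a) + len(adj_b),
        "u_vars": len(adj_a) + len(adj_b),
        "p_vars": len(adj_a) + len(adj_b),
        "aux_vars": len(aux_index),
        "family_vars": sum(1 for t, _ in cols if t != "v"),
        "total_vars": n,
        "family_constraints": sum(counts[k] for k in
                                  ("z_constraints", "x_constraints",
                                   "y_constraints", "u_p_constraints")),
    })
    counts["total_constraints"] = len(rows)

    return MatchingILP(
        n_vars=n, objective=objective, lower=lower, upper=upper,
        integrality=integrality, rows=rows, z_index=z_index,
        aux_index=aux_index, core_cols=core_cols, core_coeffs=core_coeffs,
        counts=counts,
        adjacency_info={"pairs": len(pairs), "adj_a": len(adj_a),
                        "adj_b": len(adj_b)})


def solve_paralog_matching(a: ChromosomeStructure, b: ChromosomeStructure,
                           sim: Optional[SimilarityTable] = None
                           ) -> Tuple[Bijections, int]:
    """Optimal paralog bijections and the distance B + S1 - S2.

    The distance part excludes the similarity penalty when a similarity
    table is supplied.
    """
    prob = build_matching_ilp(a, b, sim)
    if prob.n_vars == 0:
        return Bijections(), 0
    A, lbs, ubs = prob.constraint_matrix()
    res = milp(c=prob.objective,
               constraints=LinearConstraint(A, lbs, ubs),
               integrality=prob.integrality,
               bounds=Bounds(prob.lower, prob.upper))
    if res.status != 0:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    xs = np.round(res.x).astype(int)
    bij = Bijections()
    for (fam, i, j), col in sorted(prob.z_index.items()):
        if xs[col] == 1:
            bij.maps.setdefault(fam, {})[i] = j
    core = sum(c * xs[col] for col, c in zip(prob.core_cols, prob.core_coeffs))
    return bij, int(round(core))


def relabel_matched(a: ChromosomeStructure, b: ChromosomeStructure,
                    bij: Bijections
                    ) -> Tuple[ChromosomeStructure, ChromosomeStructure]:
    """Renumber paralogs so corresponding copies share an index and all
    unmatched copies get fresh distinct indices."""
    pa, pb = _paralog_sets(a), _paralog_sets(b)
    map_a: Dict[Tuple[str, int], int] = {}
    map_b: Dict[Tuple[str, int], int] = {}
    for fam in sorted(set(pa) | set(pb)):
        nxt = 1
        fam_map = bij.maps.get(fam, {})
        for i, j in sorted(fam_map.items()):
            map_a[(fam, i)] = nxt
            map_b[(fam, j)] = nxt
            nxt += 1
        for i in pa.get(fam, []):
            if (fam, i) not in map_a:
                map_a[(fam, i)] = nxt
                nxt += 1
        for j in pb.get(fam, []):
            if (fam, j) not in map_b:
                map_b[(fam, j)] = nxt
                nxt += 1

    def apply(s, mapping):
        chroms = []
        for c in s.chromosomes:
            genes = tuple(GeneToken(g.family,
                                    mapping[(g.family, g.paralog or 0)],
                                    g.orient)
                          for g in c.genes)
            chroms.append(Chromosome(genes, c.circular))
        return ChromosomeStructure(tuple(chroms), s.name).canonical()

    return apply(a, map_a), apply(b, map_b)


def close_paths(s: ChromosomeStructure) -> Tuple[ChromosomeStructure, int]:
    """Close every linear chromosome into a circle; count how many."""
    chroms = []
    n_paths = 0
    for c in s.chromosomes:
        if c.circular:
            chroms.append(c)
        else:
            n_paths += 1
            chroms.append(Chromosome(c.genes, circular=True))
    return ChromosomeStructure(tuple(chroms), s.name).canonical(), n_paths


def distance_with_paths(a: ChromosomeStructure, b: ChromosomeStructure,
                        sim: Optional[SimilarityTable] = None
                        ) -> Tuple[int, int]:
    """Distance via path closure: ILP distance of the closures plus the
    number of closed paths; the error bound is 2(n1 + n2)."""
    a2, n1 = close_paths(a)
    b2, n2 = close_paths(b)
    _bij, d = solve_paralog_matching(a2, b2, sim)
    return d + n1 + n2, 2 * (n1 + n2)


def breakpoint_matching(a: ChromosomeStructure, b: ChromosomeStructure
                        ) -> Tuple[Bijections, int]:
    """Bijections minimising the breakpoint distance, by 0/1 programming.

    An adjacency of `a` is conserved when both its slots map onto the slots
    of one adjacency of `b` with matching extremity ends; the distance is
    the number of non-conserved adjacencies on both sides plus the number of
    unmatched gene copies on both sides.
    """
    pa, pb = _paralog_sets(a), _paralog_sets(b)
    shared = sorted(set(pa) & set(pb))
    st_a, st_b = _ops.to_adjacencies(a), _ops.to_adjacencies(b)
    adj_a = sorted(st_a.adjacencies, key=sorted)
    adj_b = sorted(st_b.adjacencies, key=sorted)

    cols = []

    def new_col(tag, key):
        cols.append((tag, key))
        return len(cols) - 1

    z_index = {}
    for fam in shared:
        for i in pa[fam]:
            for j in pb[fam]:
                z_index[(fam, i, j)] = new_col("z", (fam, i, j))

    def slot_pairs(sa, sb):
        """z columns required for adjacency sa to map onto sb, or None."""
        ea = sorted(adj_a[sa])
        eb = sorted(adj_b[sb])
        if len(ea) == 1:
            ea = ea * 2
        if len(eb) == 1:
            eb = eb * 2
        for perm in ((0, 1), (1, 0)):
            need = []
            ok = True
            for idx in range(2):
                (fa, ia), ea_end = ea[idx]
                (fb, jb), eb_end = eb[perm[idx]]
                if fa != fb or ea_end != eb_end:
                    ok = False
                    break
                c = z_index.get((fa, ia, jb))
                if c is None:
                    ok = False
                    break
                need.append(c)
            if ok:
                yield tuple(sorted(set(need)))

    w_index = {}
    w_req = {}
    for sa in range(len(adj_a)):
        for sb in range(len(adj_b)):
            for need in slot_pairs(sa, sb):
                key = (sa, sb, need)
                if key not in w_index:
                    w_index[key] = new_col("w", key)
                    w_req[key] = need

    n = len(cols)
    rows = []
    for fam in shared:
        for i in pa[fam]:
            rows.append(({z_index[(fam, i, j)]: 1.0 for j in pb[fam]},
                         -np.inf, 1.0))
        for j in pb[fam]:
            rows.append(({z_index[(fam, i, j)]: 1.0 for i in pa[fam]},
                         -np.inf, 1.0))
    # each a-adjacency conserved at most once; same for b
    for sa in range(len(adj_a)):
        cs = {w_index[k]: 1.0 for k in w_index if k[0] == sa}
        if cs:
            rows.append((cs, -np.inf, 1.0))
    for sb in range(len(adj_b)):
        cs = {w_index[k]: 1.0 for k in w_index if k[1] == sb}
        if cs:
            rows.append((cs, -np.inf, 1.0))
    for key, need in w_req.items():
        for c in need:
            rows.append(({w_index[key]: 1.0, c: -1.0}, -np.inf, 0.0))

    # minimise: |adj_a| + |adj_b| - 2*conserved + genes_a + genes_b - 2*matched
    objective = np.zeros(n)
    for key, col in w_index.items():
        objective[col] = -2.0
    for zc in z_index.values():
        objective[zc] += -2.0
    const = len(adj_a) + len(adj_b) + a.n_genes + b.n_genes

    if n == 0:
        return Bijections(), const
    data, ri, ci, lbs, ubs = [], [], [], [], []
    for r, (coeffs, lb, ub) in enumerate(rows):
        for c, v in coeffs.items():
            ri.append(r)
            ci.append(c)
            data.append(v)
        lbs.append(lb)
        ubs.append(ub)
    A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), n))
    res = milp(c=objective,
               constraints=LinearConstraint(A, np.array(lbs), np.array(ubs)),
               integrality=np.ones(n), bounds=Bounds(np.zeros(n), np.ones(n)))
    if res.status != 0:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    xs = np.round(res.x).astype(int)
    bij = Bijections()
    for (fam, i, j), col in sorted(z_index.items()):
        if xs[col] == 1:
            bij.maps.setdefault(fam, {})[i] = j
    return bij, int(round(const + objective @ xs))
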