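# Methods

## The model

A chromosome structure is a finite set of paths (linear chromosomes) and
circles (circular chromosomes) whose directed edges are genes; a gene is a
family name with an optional paralog index and a strand.  The model
deliberately ignores gene and intergenic lengths and sequence content: two
structures are equal when their chromosomes coincide up to rotation of
circles and reversal-with-strand-flip of any chromosome.  Internally every
structure is an (unordered) gene set plus a partial matching on gene
extremities — the adjacency view — which makes equality testing canonical
and cheap.

Six operations act on structures.  Four are standard rearrangements:
double-cut-and-paste (cut two adjacencies, rejoin the four extremities the
other way), sesqui-cut-and-paste (cut one adjacency, join one freed
extremity to a free extremity), and the cut and join of a single adjacency.
Two accessory operations change gene content: deletion of a maximal region
of genes private to the source, and insertion of a region of genes private
to the target.  Three "unnatural" variants are excluded because they never
shorten a sequence: cutting inside a private region, inserting target genes
into a source-private region, and closing a cut private region into a fresh
circle.

Each operation carries a positive rational weight.  Weights are stored as
exact fractions throughout; no rule decision or tie ever depends on
floating-point rounding.  Two *descent patterns* order the weights:

* circular pattern: insertion ≥ sesqui ≥ join ≥ double ≥ deletion,
* linear pattern: insertion ≥ double ≥ sesqui ≥ cut ≥ deletion,

with default values 1.5, 1.2, 1.1, 1, 0.9 down the listed order and 0.8 for
the operation a pattern leaves unconstrained.  The defaults are the scheme
used for the organellar analyses this model was built for (circular for
plastids, linear for mitochondria).  A third regime sets the five standard
weights to a common value d and the insertion weight to c with d ≤ c ≤ 2d.

## The transformation algorithm

The distance computation builds the *common graph* of the two structures:
nodes are the extremities of shared genes plus one node per maximal region
of private genes; edges are adjacencies coloured `a` or `b` by the source
structure; a region forming a whole circular chromosome carries a special
loop.  Every extremity holds at most one incidence per colour, so components
are paths and circles.  The *final form* — isolated extremities and
2-circles made of one a- and one b-edge — corresponds to the two sides
agreeing, and graph operations that reach it mirror structure operations:
operations on a-coloured elements are forward operations on the source,
operations on b-coloured elements are inverses of operations placed near the
end of the forward sequence (deletions can always be moved before
insertions, so a deletion of a b-region node *is* the eventual insertion).
The emitted scenario is therefore the a-coloured operations in order,
followed by the b-coloured ones reversed, and replaying it takes the source
to the target exactly; the replay property is asserted in the tests with an
independent adjacency-level move generator.

The algorithm runs in five steps.  Step 1 deletes source-private loops.
Step 2 closes every conventional edge outside a 2-circle into a final
2-circle, using a double (both counter-colour slots occupied), a sesqui (one
occupied) or a join; when double-cut-and-paste is not more expensive than
sesqui all double closures run first, otherwise the sesqui closures do.
Step 3 applies the nineteen path-combination rules in priority order,
restarting the scan after every application; each rule transfers or joins
end region nodes so that one standard operation absorbs a region node that
would otherwise cost a deletion.  Two rules leave a *deferred choice* (the
1_c mechanism): the pair of paths is frozen and both resolutions are kept
until a later rule or the closing step picks one.  Step 4 runs the pairing
rules that funnel target-region nodes together (loops and circles are
inserted next to another component's b-node by doubles; paths merge by
joins, transfers, or detachments), then closes every path that still has a
non-hanging edge into a circle and re-runs the circle-insertion rule.  When
double-cut-and-paste is cheaper than or equal to sesqui, the action list
drops the three rules whose primed versions are null (3+3 merging and the
deferred-choice resolutions, which then happen at closing).  Step 5 deletes
what remains: isolated region nodes and loops, regions on leftover two- and
three-node paths, and circles — long circles are chopped into 2-circles by
doubles that merge two b-nodes, each surviving region node is deleted, and
any conventional edge left outside a final 2-circle is closed.

Two deliberate deviations from a literal reading of the published rule list,
both validated against the exhaustive solver: the closing of an odd path
with a hanging end (types 1a/1b) joins the end region node's free flank into
the circle rather than stranding it, which preserves the insertion economy;
and in the cheap-double regime the explicitly listed primed rule variants
are treated as instances of the aggregated base rules rather than
replacements, since dropping the base rules loses required merges (isolated
b-node pairs, 3b+3b) and breaks the additive-d guarantee.

### Exactness and the weight formula

The algorithm is exact in two regimes.  With equal gene content and a
circular or linear pattern it returns the minimum weight among
minimal-length sequences (the oracle comparison orders costs
lexicographically by operation count, then weight).  With uniform standard
weight d and d ≤ c ≤ 2d it is within an additive d of the optimum.  With all
six weights arbitrary in [0.8, 1.5] it is heuristic; across every sampled
instance the output stayed within 1.5 times the optimum (the acceptance
script reports the worst observed ratio).

For uniform-weight schemes the emitted total satisfies

    C = d · (B + S + D − P) + (c − d) · (B′ + n)

where B is the number of region nodes, S the closure count implied by the
maximal conventional-edge regions (half-length integer parts, plus odd
boundary regions, minus all-conventional circles), D the per-component extra
operations when components are processed individually, P the operations the
combination steps save, B′ the number of circles carrying b-nodes only, and
n ∈ {0, 1, 2,...} the components still holding b-nodes when step 4 ends
(excluding circles that were b-only from the start).  `compute_invariants`
reads B, S and B′ off the initial graph, derives D per component from the
exhaustive solver on the component re-expressed as a standalone pair
(memoised by a canonical component signature), and measures P and n by
simulating the combination steps; the identity against the emitted total is
a standing test.  For non-uniform patterns the decomposition is reported as
counts but no closed-form total is claimed — the formula's ε-term prices
only the insertion surcharge, so it presumes uniform standard weights.

## The exhaustive reference solver

The oracle is a bidirectional uniform-cost search over canonical structure
states.  From the source it applies the standard operations plus deletions
of maximal source-private regions; from the target the same with mirrored
weights (its deletions are forward insertions, its cuts forward joins and
vice versa), unrestricted because the excluded variants concern genes absent
on that side.  The frontiers can only meet on states whose gene content is
exactly the shared genes, and the search stops once the two frontier minima
cannot beat the best meeting found.  Admissible pruning discards states
whose remaining private regions already exceed the weight budget (each
maximal region costs at least one operation).  Correctness of the
"deletions before insertions" split is checked on tiny instances by a
forward-only search that enumerates insertion contents explicitly, and by
the operation-reversibility property.  Weights are rescaled to integers for
the inner loop; the minimal-length mode uses (count, weight) cost pairs.

## Paralog matching

With several copies per family the distance minimises over partial
bijections between copies — partial, so a copy may be "lost" on one side and
"emerged" on the other; this can genuinely beat matching everything when a
copy sits badly.  For circular chromosomes under equal standard weights the
matched distance is B + S1 − S2 of the induced common graph, and the
programme encodes each summand: z-variables choose the bijections (row and
column sums over the third index at most 1); x-variables mark block borders
(adjacencies whose two slots differ in matchedness; half their sum is B);
y-variables alternate 0/1 along regions of conventional edges (their minimal
feasible sum is a vertex cover of the region chains, i.e. S1); an integer u
per adjacency, constant along each circle of conventional edges and bounded
by a per-adjacency cap, together with an indicator p of the cap being
attained, counts the all-conventional circles (S2).  The caps are a distinct
enumeration 1..(total adjacencies): with equal caps every edge of a circle
would attain the maximum and S2 would count edges, not circles.  One
auxiliary 0/1 variable per chromosome, forced up when none of its genes is
matched, restores the deletion cost of fully-private chromosomes that the
border sum cannot see.  The optional similarity table adds the penalty
Σ z·(1−s), removes pairs with zero similarity, and requires some pairing
wherever similarity is positive.  HiGHS (via `scipy.optimize.milp`) solves
the instances; the optimum is asserted equal to the exhaustive-bijection
minimum on every sampled small instance.

Linear chromosomes are closed into circles before matching; the reported
distance adds the number of closed paths and carries the error bound
2(n1+n2).  The breakpoint analogue minimises the breakpoint distance over
bijections with a small 0/1 programme of this package's own construction
(conserved-adjacency indicators dominated by their z-variables), checked
against enumeration.

On the canonical counting instance (families 1..200, five copies each, one
circular chromosome per side) the construction produces exactly 5000
z-variables with 2000 constraints, 1000 border variables per side, 2000
alternation variables and 13000 variables over the five printed families.
The coupling-constraint families however scale with the number of potential
neighbours per extremity slot — five with five copies per family — so the
full constraint count is about 52000, not the printed 20000, which is
consistent only with one potential neighbour per adjacency.  The honest
count is reported; pruning couplings to reach the printed figure would make
the optimum wrong, which the oracle-equality test would expose.

## Reconstruction

The reconstruction problem — a binary tree over given structures plus
internal arrangements minimising the summed edge distances — reduces to the
minimum Steiner tree in the metric space of structures, with the direct edge
the shortest path by the triangle inequality.  The first algorithm spans the
terminals with Prim's minimum spanning tree over the pairwise distance
matrix and converts it to a binary rooted leaf-labelled tree (internal
terminals get leaf copies, non-terminal leaves are pruned, non-binary nodes
expand left-deep in label order, duplicated nodes carry the same structure),
giving weight within twice the optimum.  The second follows the
triple-contraction scheme: for every terminal triplet a median structure and
its star cost are computed, the triplet with the largest spanning-tree
saving is contracted greedily, and the final spanning tree over terminals
plus accepted medians is transformed as above (ratio 11/6 for the breakpoint
metric).  Breakpoint medians are exact — by exhaustive enumeration of all
structures over the united gene set when it is small, otherwise by a 0/1
programme selecting a matching on extremities that maximises adjacency
support under majority gene content.  Biological medians use the
scenario-walk heuristic: every intermediate structure of the three pairwise
transformations is scored against the third structure and the best
candidate kept.

Greedy descent refines an arrangement: for every internal node all
single-operation neighbours are enumerated (standard operations, single-gene
deletions, and insertions of single genes present elsewhere in the tree,
in all placements) and the globally best strictly-decreasing replacement is
applied until a local minimum of the total biological tree distance G.
Termination is guaranteed because G is bounded below and strictly decreases.
Insertion candidates are single genes rather than multi-gene regions — a
practical restriction; region-level moves would enlarge the neighbourhood
exponentially.  Rooting scans every node and minimises the total one-way
distance from the root outwards.

Distance-based trees come from a plain UPGMA (average linkage, deterministic
tie-break by label order) with neighbour joining as an alternative; the
published method only commits to "a UPGMA variant".

## Synthetic data

The generator arranges a gene alphabet (default six families, two
chromosomes, half circular) uniformly at random with random strands; the
simulator applies a configured number of random operations per tree edge
(default two; relative rates 0.45 double, 0.15 sesqui, 0.2 cut/join, 0.1
deletion, 0.1 insertion) and records the true arrangement at every node.
These defaults emulate organellar-scale gene orders and modest per-branch
divergence.  What they do not emulate: realistic rate heterogeneity,
hotspots, duplication mechanisms that produce tandem paralog arrays, or any
sequence-level signal — so passing tests demonstrate algorithmic
correctness on the model's own terms, not fidelity to any particular
genome's evolution.

## Problem sizes and numerical choices

The test suite and the acceptance script run exhaustively where the state
space allows (all equal-content pairs over one- and two-gene alphabets;
every rule path is also exercised by seeded sweeps over three- to six-gene
universes: several hundred pairs per regime in the suite, and thousands
in the development fuzz runs) and by seeded sampling above that:
reconstruction ratios use 4-terminal instances over 3-gene universes against
the exhaustive Steiner optimum (50 in the acceptance script), the heuristic
weight bound uses 300 sampled pairs over 2-5-gene universes, and the descent
check uses simulated 4-leaf trees with exact optima from a dynamic programme
over the full candidate space on 2-gene alphabets.  Ties everywhere break by
canonical (lexicographic) order of the objects involved, so repeated runs
are byte-identical.  The MILP path relies on HiGHS determinism for
reproducibility rather than enforcing a lexicographically minimal optimum.

## Known limitations

* The transformation algorithm's heuristic regime carries no proven bound;
  the 1.5x figure is an empirical worst case over the sampled distributions.
* The paralog programme assumes circular chromosomes and equal standard
  weights; the path-closure wrapper inherits the 2(n1+n2) slack.
* Biological medians and the descent neighbourhood are heuristic; only the
  breakpoint median is exact.
* Component-level D values are derived from the exhaustive solver and
  memoised by shape signature; the signature is conservative but a hash
  collision between genuinely different shapes would surface as a failure of
  the weight-formula test, not silently.
* The reconstruction of deep trees recomputes many pairwise distances; no
  caching is attempted beyond the metric closure inside single calls, so
  very large instances are out of scope.
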