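# Methods and design notes

## Tree model

A tree is a flat `id -> node` table with explicit parent/child links; each
node carries a label, an optional non-negative branch length (the length of
its *subtending* branch), a set of category tags, a free-form payload map,
and two display flags. Conventions that the rest of the package relies on:

* **Branches are identified with their child node.** Every non-root node has
  exactly one subtending branch; the root has none and is never selectable.
* **Child order is first-class.** It does not affect the topology (the clade
  set), but it determines leaf order in layouts and hence tanglegram
  crossings. All I/O preserves input order; only `ladderize` and the
  crossing minimizer reorder children, and the minimizer does so through a
  separate orientation overlay without touching the trees.
* **Absent branch length is not zero.** Writers omit absent lengths so that
  parse∘write round-trips exactly.
* **`hidden` and `collapsed` are independent.** A hidden subtree is removed
  from traversal and layout entirely; a collapsed subtree stays in the model
  but is drawn as a single leaf slot plus a boundary glyph. Collapse may
  nest; layouts honor only the outermost collapsed node.

`traverse_and_compute` snapshots the parent/child structure before visiting
and verifies it after each visit (and once at the end), so a visitor that
mutates topology fails fast with `traversal-mutation`. Visitors communicate
through `node.payload`.

## Newick dialect grammar

The `{TAG}` annotation grammar is a documented choice (the dialect exists in
the wild in several ad hoc variants): a tag block is accepted immediately
after a node's label and/or after its `:length` group and attaches to that
node's subtending branch; the writer emits it after the length. One tag per
branch on output; multi-category assignments must be resolved by an explicit
priority order before serialization (`ambiguous-tag` otherwise). BEAST-style
`[&key=value,...]` blocks are preserved as opaque string pairs in
`payload["beast"]`, never interpreted. Under the plain dialect, `{...}` and
`[...]` content is an error unless `strip_unknown_comments` is set, in which
case it is discarded; stripping and tag-parsing yield identical topologies
(tested). Quoted labels follow standard single-quote doubling; underscores
in unquoted labels are kept verbatim (no space substitution); lengths accept
exponent notation; parse errors report the character offset.

PhyloXML and NeXML support is deliberately minimal and read-only: clade
nesting / node-edge lists, names, and branch lengths (attribute or element
form). NeXML edge lists that are cyclic, disconnected or multiply rooted
fail with `not-a-tree`. Writing these formats is out of scope.

## Selection semantics

Selection modes resolve to branch sets as follows: `branch` is the anchor's
subtending branch; `clade` is every branch in the anchor's subtree *plus the
anchor's own subtending branch* (this matches the use case of tagging whole
test clades for hypothesis testing); `path_to_root` walks anchor→root;
`all_external` / `all_internal` partition leaf and internal non-root
branches; `near_point` formalizes "nearby on the screen" as Euclidean
distance from a query point to branch midpoints in layout coordinates (the
middle of the horizontal run of a rectangular elbow, or of the radial
segment in polar mode). Every `apply` fires all registered callbacks exactly
once, in registration order, with the post-update state.

## Layout conventions

Fixed conventions, chosen once and tested: `y` grows downward; angles grow
counter-clockwise from the positive x-axis; the root sits at `x = 0` (or
radius 0). Visible leaf slots — true leaves plus outermost collapsed nodes —
are placed at `y = 0, s, 2s, ...` (angles `2πk/n`) in depth-first child
order, and every internal node at the arithmetic mean of its children's
ordinate (not the midpoint of the extremes; the two differ for
multifurcations). Phylogram scaling maps cumulative root distance onto the
requested width/radius; a missing length counts as zero with a warning
rather than an error, so partially annotated trees still draw. Cladogram
scaling places internal nodes by node depth and pins every slot to full
width/radius.

**Collapsed boundaries.** The glyph for a collapsed clade interpolates the
positions its leaves *would* occupy: a phantom layout of the subtree is
anchored at the collapsed node's position (cumulative lengths in phylogram
mode, node depths otherwise), the convex hull of attachment point plus
phantom leaf positions is taken as the control polygon (densified with edge
midpoints so the interpolant hugs corners), and a closed centripetal
Catmull-Rom curve through it is sampled `samples` points per segment. The
returned polygon is the convex closure of curve samples and control points.
That last step is a deliberate guarantee: an interpolating spline alone can
cut inside the hull, whereas the closure provably contains every phantom
leaf position — the property the tests assert — at the cost of slightly
duller curvature. Degenerate (collinear) point sets are padded to a sliver
triangle perpendicular to their axis.

## Tanglegram crossing minimization

Links are rank pairs under the current orientations; `(a,b)` and `(c,d)`
cross iff `(a−c)(b−d) < 0`, so links sharing an endpoint never cross, and
many-to-many matchings need no special casing. The one-sided minimizer is a
bottom-up dynamic program: at each free internal node, for each candidate
child order, the inter-block cost is the number of link pairs in different
child blocks whose fixed-side ranks are inverted; because those ranks are
fixed, the cost depends only on block membership, per-node choices are
independent, and summing per-node minima is globally optimal over the whole
orientation space. Binary nodes compare two orders; multifurcations up to
degree 8 are permuted exhaustively within the node (pairwise costs remain
additive); beyond that the node fails with `degree-cap`. Ties are broken
toward the input orientation, so minimization is stable and idempotent.

The two-sided problem does not decompose this way. `free_side="both"` runs
alternating one-sided passes to a fixed point; because ties are kept, the
alternation can stall in a local optimum, so instances whose full
orientation space has at most 2^12 assignments are finished by exhaustive
enumeration. For larger instances the two-sided result is a documented
heuristic: never worse than the input, not guaranteed optimal. The
brute-force enumerator (capped at 16 free nodes / 2^20 assignments) is the
correctness authority for the one-sided DP in the test suite.

## Rendering

SVG output is deterministic by construction — no timestamps, no generated
ids, fixed attribute order, coordinates formatted to 4 decimals — so
identical inputs give byte-identical documents. Element counts are exact
functions of the input: one `<path class="branch">` per visible non-root
branch, one `<polygon class="clade">` per outermost collapsed clade, one
`<line class="link">` per matching pair. Styling is attached as explicit
attributes plus stable class names (selected branches also get a
`data-category` attribute), never external CSS, so both tests and consumers
can parse the drawing. The viewBox is the layout extents plus a fixed
10-unit margin. Tanglegrams draw the left tree left-to-right and the right
tree mirrored, both as cladograms, which makes geometric link crossings
coincide with rank-pair inversions (tested by segment intersection on the
emitted coordinates).

## Random-instance generation

`generate_yule_tree` grows a pure-birth tree: from two lineages, a uniform
extant lineage splits at each event, inter-event times are exponential with
rate `rate × n_extant` (default rate 1.0) and accrue onto all extant pendant
branches, so every branch length is strictly positive; leaves are labelled
`L1..Ln` in depth-first order, and a given seed always reproduces the same
tree. `generate_tangled_pair` copies a Yule tree, applies a configurable
number of leaf-label swaps plus random child-order flips, and matches leaves
by label. These generators emulate exactly what the layout and crossing
machinery cares about — plausible binary topologies with positive lengths
and controllable discordance — and nothing else: no rate heterogeneity, no
extinction, no non-identity matchings of real cophylogenies. Passing tests
therefore certify the algorithms' contracts, not any biological realism of
the corpora.

Test and acceptance corpora use trees of 4–64 leaves (4–8 for instances that
must also be solved by exhaustive enumeration, keeping the oracle's search
space at ≤ 2^7 assignments) and ~200 instances per property; these sizes
exercise every code path while keeping the whole suite near-instant.

## Known limitations

* Rerooting and other tree-editing operations are not implemented.
* PhyloXML/NeXML are read-only and ignore everything beyond topology, names
  and lengths; Nexus is unsupported.
* The two-sided crossing minimum is heuristic above 2^12 orientation
  assignments.
* Labels are rendered without collision avoidance or font metrics; output is
  SVG 1.1 only.
* `near_point` selection uses branch midpoints, not distance to the full
  drawn path.
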