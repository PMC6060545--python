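# phylodraw

A small Python toolkit for manipulating, annotating and drawing rooted
phylogenetic trees, aimed at people building analysis pipelines that need a
tree as *middleware* rather than as a final picture: select sets of branches,
hand the annotated tree to a downstream method, lay the tree out, compare two
trees side by side.

What it does:

* **Newick I/O in several dialects** — plain Newick, HyPhy-style `{TAG}`
  branch annotations, and BEAST-style `[&key=value]` comments — plus minimal
  read-only PhyloXML and NeXML support, with strict round-trip fidelity.
* **Traversal and manipulation** — a `traverse_and_compute` visitor
  abstraction (pre/post-order, with per-node payloads), ladderization,
  hiding and collapsing of subtrees.
* **Multi-category branch selection** — clades, paths to the root, individual
  branches, all external/internal branches, or branches near a point in
  layout space; callback notification on every update; serialization of the
  selection to annotated Newick (e.g. a `{test}` / `{reference}` branch
  partition for selection-relaxation tests such as RELAX).
* **Layouts and SVG** — rectangular and radial phylograms/cladograms,
  collapsed-clade boundary polygons, and deterministic SVG rendering.
* **Tanglegrams** — two trees with leaf-to-leaf links. Since child order at
  each internal node is free (it never changes the topology), the number of
  link crossings can be minimized over all 2^k child-order flips; the
  one-sided case is solved exactly by a bottom-up dynamic program.

## The crossing-minimization model

Put the left tree's `nL` leaves at ranks `1..nL` (depth-first under the
current child orders) and likewise on the right. A link is a rank pair
`(a, b)`; two links `(a, b)`, `(c, d)` cross iff `(a − c)(b − d) < 0`.
With one side fixed, the crossings between links attached to *different*
child blocks of a free node depend only on block membership and on the
fixed-side ranks — not on decisions made deeper in either block. Inter-block
costs are therefore additive over nodes, and choosing each free node's child
order independently (bottom-up, cheapest order per node) attains the global
minimum over the whole flip space. An exhaustive enumerator over all
orientation assignments serves as the independent oracle in the test suite.

## Worked example

Tag the clade `(A,B)` of `((A,B),C);` as the test set and serialize:

```bash
$ phylodraw select demo.nwk --mode clade --anchor-contains A,B --category test
((A{test},B{test}){test},C);
```

All three branches of the clade — `A`, `B`, and the clade's own subtending
branch — carry the `{test}` tag; parsing this string with the `hyphy_tags`
dialect recovers the exact branch-to-category assignment.

Untangle two discordant 3-leaf trees:

```python
from phylodraw import (Tanglegram, parse_newick, match_by_label,
                       count_crossings, minimize_crossings)

left = parse_newick("((A,B),C);")
right = parse_newick("((A,C),B);")
tg = Tanglegram(left=left, right=right, matching=match_by_label(left, right))
print("initial crossings:", count_crossings(tg))
print("one-sided minimum:", minimize_crossings(tg, "right")[1])
print("two-sided minimum:", minimize_crossings(tg, "both")[1])
```

prints

```
initial crossings: 1
one-sided minimum: 1
two-sided minimum: 0
```

With the left tree fixed, no flip of the right tree resolves the single
crossing (the minimum stays 1); freeing both sides finds the common leaf
order `B, A, C` and removes it entirely.

Other CLI subcommands: `stats`, `ladderize`, `render` (SVG), `tanglegram`
(reads two trees and an optional two-column leaf matching, minimizes
crossings, writes the SVG), `convert` (PhyloXML/NeXML to Newick). Run
`phylodraw --help` for flags.

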