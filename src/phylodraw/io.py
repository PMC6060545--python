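"""Tree readers and writers.

Newick is the primary interchange format, in three dialects:

``plain``
    Standard Newick.  ``{...}`` or ``[...]`` blocks are rejected unless
    ``strip_unknown_comments`` is set, in which case they are discarded.
``hyphy_tags``
    Accepts a ``{TAG}`` block immediately after a node's label and/or
    ``:length`` group; the tag names a branch-selection category and is
    stored in that node's ``tags`` set.  This is the dialect used to hand a
    test/reference branch partition to selection-analysis tools.
``beast_comments``
    Accepts ``[&key=value,...]`` comment blocks after labels or lengths and
    stores the key/value pairs, uninterpreted, under ``node.payload["beast"]``.

Grammar notes: unquoted labels keep underscores verbatim; quoted labels use
standard single-quote doubling (``'it''s'``); branch lengths are decimal reals
with optional exponent.  Parse errors carry the character offset.

PhyloXML and NeXML support is read-only and minimal: clade nesting / node-edge
lists, names and branch lengths.  Anything else in the documents is ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from xml.etree import ElementTree as ET

from .tree import Tree, TreeError

__all__ = [
    "NewickDialect", "PLAIN", "HYPHY_TAGS", "BEAST_COMMENTS", "NewickError",
    "parse_newick", "write_newick", "parse_phyloxml", "parse_nexml", "read_tree",
]


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass(frozen=True)
class NewickDialect:
    name: str = "plain"                    # plain | hyphy_tags | beast_comments
    strip_unknown_comments: bool = False

    def __post_init__(self):
        if self.name not in ("plain", "hyphy_tags", "beast_comments"):
            raise ValueError(f"unknown dialect {self.name!r}")


PLAIN = NewickDialect("plain")
PLAIN_STRIP = NewickDialect("plain", strip_unknown_comments=True)
HYPHY_TAGS = NewickDialect("hyphy_tags")
BEAST_COMMENTS = NewickDialect("beast_comments")

_UNQUOTED_END = set("(),:;[]{}' \t\n\r")
_NEEDS_QUOTE = re.compile(r"[(),:;\[\]{}'\s]")
_NUMBER = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?")


class _Parser:
    def __init__(self, text: str, dialect: NewickDialect):
        self.text = text
        self.pos = 0
        self.dialect = dialect
        self.tree = Tree()

    def error(self, message: str) -> NewickError:
        return NewickError(message, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\n\r":
            self.pos += 1

    def parse(self) -> Tree:
        self.skip_ws()
        self._node(parent=None)
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' terminating the tree")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing content after ';'")
        self.tree.validate()
        return self.tree

    def _node(self, parent):
        node = self.tree.add_node(parent=parent)
        self.skip_ws()
        if self.peek() == "(":
            self.pos += 1
            while True:
                self._node(parent=node.id)
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                elif ch == ")":
                    self.pos += 1
                    break
                elif ch == "":
                    raise self.error("unbalanced parentheses: unexpected end of input")
                else:
                    raise self.error(f"expected ',' or ')', found {ch!r}")
        self._annotations(node)           # comments may precede the label
        node.label = self._label()
        self._annotations(node)
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            node.length = self._length()
            self._annotations(node)
        self.skip_ws()
        if self.peek() == ")" and parent is None:
            raise self.error("unbalanced parentheses: unmatched ')'")
        return node

    def _label(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            return self._quoted_label()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in _UNQUOTED_END:
            self.pos += 1
        return self.text[start:self.pos]

    def _quoted_label(self) -> str:
        self.pos += 1  # opening quote
        out = []
        while True:
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted label")
            ch = self.text[self.pos]
            if ch == "'":
                if self.text[self.pos + 1:self.pos + 2] == "'":
                    out.append("'")
                    self.pos += 2
                else:
                    self.pos += 1
                    return "".join(out)
            else:
                out.append(ch)
                self.pos += 1

    def _length(self) -> float:
        self.skip_ws()
        m = _NUMBER.match(self.text, self.pos)
        if not m:
            raise self.error("malformed branch length")
        self.pos = m.end()
        return float(m.group(0))

    def _annotations(self, node) -> None:
        """Consume any run of ``{...}`` / ``[...]`` blocks at the cursor."""
        while True:
            self.skip_ws()
            ch = self.peek()
            if ch == "{":
                self._brace_block(node)
            elif ch == "[":
                self._bracket_block(node)
            else:
                return

    def _block_body(self, open_ch: str, close_ch: str) -> str:
        start = self.pos
        self.pos += 1
        end = self.text.find(close_ch, self.pos)
        if end == -1:
            self.pos = start
            raise self.error(f"unterminated {open_ch!r} block")
        body = self.text[self.pos:end]
        self.pos = end + 1
        return body

    def _brace_block(self, node) -> None:
        start = self.pos
        body = self._block_body("{", "}")
        if self.dialect.name == "hyphy_tags":
            if not body:
                self.pos = start
                raise self.error("empty {} tag")
            node.tags.add(body)
        elif not self.dialect.strip_unknown_comments:
            self.pos = start
            raise self.error(f"unexpected '{{{body}}}' under {self.dialect.name} dialect")

    def _bracket_block(self, node) -> None:
        start = self.pos
        body = self._block_body("[", "]")
        if self.dialect.name == "beast_comments" and body.startswith("&"):
            meta = node.payload.setdefault("beast", {})
            for item in body[1:].split(","):
                if not item:
                    continue
                key, _, value = item.partition("=")
                meta[key.strip()] = value.strip()
        elif not self.dialect.strip_unknown_comments:
            self.pos = start
            raise self.error(f"unexpected '[{body}]' under {self.dialect.name} dialect")


def parse_newick(text: str, dialect: NewickDialect = PLAIN) -> Tree:
    """Parse a single ``;``-terminated Newick statement into a :class:`Tree`."""
    return _Parser(text, dialect).parse()


def _format_label(label: str) -> str:
    if label and _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(length: float, precision: int) -> str:
    text = f"{length:.{precision}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text or "0"


def write_newick(tree: Tree, dialect: NewickDialect = PLAIN,
                 precision: int = 6) -> str:
    """Serialize a tree to Newick, emitting per-branch ``{tag}`` markers under
    the ``hyphy_tags`` dialect and ``[&...]`` payload under ``beast_comments``.

    Child order is written exactly as stored.  Absent branch lengths are
    omitted (absent is not zero).  Labels containing metacharacters are
    single-quoted.  A branch must carry at most one tag here; resolving
    multi-category assignments is the selection module's job.
    """

    def annotation(node) -> str:
        if dialect.name == "hyphy_tags" and node.tags:
            if len(node.tags) > 1:
                raise TreeError(
                    f"node {node.id} carries {len(node.tags)} tags; "
                    "serialize selections with a category priority")
            tag = next(iter(node.tags))
            if "}" in tag or "{" in tag:
                raise TreeError("untaggable")
            return "{" + tag + "}"
        if dialect.name == "beast_comments" and node.payload.get("beast"):
            items = ",".join(f"{k}={v}" for k, v in node.payload["beast"].items())
            return "[&" + items + "]"
        return ""

    def emit(node_id: int) -> str:
        node = tree[node_id]
        inner = ""
        if node.children:
            inner = "(" + ",".join(emit(c) for c in node.children) + ")"
        text = inner + _format_label(node.label)
        if node.length is not None:
            text += ":" + _format_length(node.length, precision)
        return text + annotation(node)

    tree.validate()
    return emit(tree.root) + ";"


# ---------------------------------------------------------------------------
# XML formats (read-only, minimal)
# ---------------------------------------------------------------------------

def _localname(element) -> str:
    return element.tag.rsplit("}", 1)[-1]


def _children_by_name(element, name):
    return [c for c in element if _localname(c) == name]


def parse_phyloxml(text: str) -> Tree:
    """Read the first ``phylogeny`` of a PhyloXML document.

    Supports nested ``clade`` elements, ``name`` children and branch lengths
    in either the ``branch_length`` attribute or child-element form.
    """
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise TreeError(f"invalid PhyloXML: {exc}") from exc
    phylogenies = ([root] if _localname(root) == "phylogeny"
                   else [e for e in root.iter() if _localname(e) == "phylogeny"])
    if not phylogenies:
        raise TreeError("no phylogeny element in document")
    top_clades = _children_by_name(phylogenies[0], "clade")
    if not top_clades:
        raise TreeError("phylogeny has no clade")
    tree = Tree(name=next((e.text or "" for e in phylogenies[0]
                           if _localname(e) == "name"), ""))

    def build(clade, parent):
        node = tree.add_node(parent=parent)
        length = clade.get("branch_length")
        for child in clade:
            tag = _localname(child)
            if tag == "name" and child.text:
                node.label = child.text.strip()
            elif tag == "branch_length" and child.text:
                length = child.text
        if length is not None:
            node.length = float(length)
        for sub in _children_by_name(clade, "clade"):
            build(sub, node.id)

    build(top_clades[0], None)
    tree.validate()
    return tree


def parse_nexml(text: str) -> Tree:
    """Reconstruct the first tree of a NeXML document from its node/edge lists.

    Edges run parent (``source``) to child (``target``); edge ``length``
    becomes the child's branch length; ``otu`` references supply leaf labels
    when the node has no label of its own.  Raises ``not-a-tree`` if the edge
    list is cyclic, disconnected or multiply rooted.
    """
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise TreeError(f"invalid NeXML: {exc}") from exc
    trees = [e for e in root.iter() if _localname(e) == "tree"]
    if not trees:
        raise TreeError("no tree element in document")
    tree_el = trees[0]

    otu_labels = {e.get("id"): e.get("label", "")
                  for e in root.iter() if _localname(e) == "otu"}
    node_els = _children_by_name(tree_el, "node")
    edge_els = _children_by_name(tree_el, "edge") + _children_by_name(tree_el, "rootedge")
    if not node_els:
        raise TreeError("tree element has no nodes")

    labels, lengths, parents, children = {}, {}, {}, {}
    for el in node_els:
        nid = el.get("id")
        labels[nid] = el.get("label") or otu_labels.get(el.get("otu"), "") or ""
        children[nid] = []
    for el in edge_els:
        source, target = el.get("source"), el.get("target")
        if source is None and _localname(el) == "rootedge":
            continue
        if source not in children or target not in children:
            raise TreeError("not-a-tree")
        if target in parents:
            raise TreeError("not-a-tree")
        parents[target] = source
        children[source].append(target)
        if el.get("length") is not None:
            lengths[target] = float(el.get("length"))

    roots = [nid for nid in children if nid not in parents]
    if len(roots) != 1:
        raise TreeError("not-a-tree")

    tree = Tree(name=tree_el.get("label") or tree_el.get("id") or "")
    id_map = {}
    stack = [(roots[0], None)]
    while stack:
        xml_id, parent = stack.pop()
        node = tree.add_node(label=labels[xml_id], length=lengths.get(xml_id),
                             parent=parent)
        id_map[xml_id] = node.id
        stack.extend((c, node.id) for c in reversed(children[xml_id]))
    if len(id_map) != len(node_els):
        raise TreeError("not-a-tree")
    tree.validate()
    return tree


def read_tree(text: str, dialect: NewickDialect = PLAIN) -> Tree:
    """Auto-detecting reader: XML documents are dispatched on their root
    element (``phyloxml``/``nexml``); anything else is parsed as Newick."""
    stripped = text.lstrip()
    if stripped.startswith("<"):
        head = stripped[:2048].lower()
        if "<nexml" in head or "nex:" in head:
            return parse_nexml(text)
        return parse_phyloxml(text)
    return parse_newick(text, dialect)
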