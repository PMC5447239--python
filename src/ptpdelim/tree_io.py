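"""Newick parsing, validation, rooting, and serialization.

Trees are binary and rooted for delimitation.  An input newick whose
top-level node is a trifurcation is accepted but flagged unrooted; it must
be rooted (on the longest terminal branch, or with an outgroup) before any
model computation.  Branch lengths are mandatory on every non-root edge:
the Poisson-tree-process likelihood is a function of branch lengths, so a
silent default would corrupt inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class NewickError(ValueError):
    """Malformed newick input; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class TreeError(ValueError):
    """Structural problem with a tree or a rooting request."""


@dataclass(eq=False)
class TreeNode:
    """A node of a rooted phylogeny.

    ``parent_edge_length`` is the length of the edge connecting the node to
    its parent, in expected substitutions per site; ``None`` for the root.
    """

    id: int = -1
    label: str | None = None
    parent_edge_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "inner"
        return f"<TreeNode {self.id} {kind} {self.label or ''}>"


class Tree:
    """A rooted phylogeny with stable post-order node indexing.

    ``nodes`` lists every node in post-order (children before parents, root
    last) and ``node.id`` is the index into that list, so node ids are stable
    and post-order by construction.  ``unrooted`` marks a tree whose top node
    is a trifurcation; such a tree must be rooted before delimitation.
    """

    def __init__(self, root: TreeNode, unrooted: bool = False):
        self.root = root
        self.unrooted = unrooted
        self.nodes: list[TreeNode] = []
        self._index()
        self._validate()

    def _index(self) -> None:
        self.nodes = []
        # iterative post-order; recursion depth is unbounded on caterpillars
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                node.id = len(self.nodes)
                self.nodes.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    child.parent = node
                    stack.append((child, False))
        self.root.parent = None

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.nodes:
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip without a label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label: {node.label!r}")
                seen.add(node.label)
            elif node is self.root:
                if len(node.children) not in (2, 3):
                    raise TreeError(
                        f"root has {len(node.children)} children; expected 2 "
                        "(rooted) or 3 (unrooted)"
                    )
            elif len(node.children) != 2:
                raise TreeError(
                    f"inner node with {len(node.children)} children; "
                    "only binary trees are supported"
                )
            if node is not self.root:
                if node.parent_edge_length is None:
                    raise TreeError(
                        f"missing branch length on the edge above "
                        f"{node.label or f'node {node.id}'}"
                    )
                if node.parent_edge_length < 0:
                    raise TreeError(
                        f"negative branch length {node.parent_edge_length} "
                        f"above {node.label or f'node {node.id}'}"
                    )

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes if n.is_tip)

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    def postorder(self) -> Iterator[TreeNode]:
        return iter(self.nodes)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.nodes if n.is_tip]  # type: ignore[misc]

    def total_length(self) -> float:
        return sum(n.parent_edge_length for n in self.nodes if n.parent is not None)

    def subtree_tip_labels(self, node: TreeNode) -> frozenset[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.label)  # type: ignore[arg-type]
            stack.extend(n.children)
        return frozenset(out)

    def require_rooted(self) -> None:
        if self.unrooted:
            raise TreeError(
                "tree is unrooted (top-level trifurcation); root it first "
                "(longest terminal branch or outgroup)"
            )

    def copy(self) -> "Tree":
        return parse_newick(write_newick(self))


# ---------------------------------------------------------------------------
# parsing


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    """Yield (kind, value, offset) tokens from a newick string."""
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "(),:;":
            yield c, c, i
            i += 1
        elif c == "'":
            j = i + 1
            parts: list[str] = []
            while True:
                if j >= n:
                    raise NewickError("unterminated quoted label", i)
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":  # escaped quote
                        parts.append("'")
                        j += 2
                        continue
                    break
                parts.append(text[j])
                j += 1
            yield "LABEL", "".join(parts), i
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),:;" and not text[j].isspace():
                j += 1
            yield "LABEL", text[i:j], i
            i = j


def parse_newick(text: str) -> Tree:
    """Parse a single newick statement into a :class:`Tree`.

    A top-level trifurcation is preserved and the tree flagged ``unrooted``.
    Missing branch lengths, negative lengths, duplicate tip labels and
    malformed syntax are all hard errors.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise NewickError("empty newick input", 0)
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> tuple[str, str, int]:
        nonlocal pos
        if pos >= len(tokens):
            raise NewickError("unexpected end of input", len(text))
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_clade() -> TreeNode:
        node = TreeNode()
        tok = peek()
        if tok is None:
            raise NewickError("unexpected end of input", len(text))
        if tok[0] == "(":
            take()
            while True:
                node.children.append(parse_clade())
                kind, _, off = take()
                if kind == ")":
                    break
                if kind != ",":
                    raise NewickError(f"expected ',' or ')', got {kind!r}", off)
            tok = peek()
            if tok is not None and tok[0] == "LABEL":  # inner label, kept
                node.label = take()[1]
        elif tok[0] == "LABEL":
            node.label = take()[1]
        else:
            raise NewickError(f"unexpected token {tok[1]!r}", tok[2])
        tok = peek()
        if tok is not None and tok[0] == ":":
            take()
            kind, value, off = take()
            if kind != "LABEL":
                raise NewickError("expected a branch length after ':'", off)
            try:
                node.parent_edge_length = float(value)
            except ValueError:
                raise NewickError(f"invalid branch length {value!r}", off) from None
        return node

    root = parse_clade()
    kind, _, off = take()
    if kind != ";":
        raise NewickError(f"expected ';' terminator, got {kind!r}", off)
    if pos < len(tokens):
        raise NewickError("trailing content after ';'", tokens[pos][2])

    if len(root.children) > 3 or len(root.children) == 1:
        raise NewickError(
            f"top-level node has {len(root.children)} children; expected 2 "
            "(rooted) or 3 (unrooted)"
        )
    return Tree(root, unrooted=len(root.children) == 3)


# ---------------------------------------------------------------------------
# serialization


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;'\" \t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, node_annotations: dict[int, float] | None = None) -> str:
    """Serialize a tree to newick; 10 significant digits on lengths.

    ``node_annotations`` maps node id to a real value rendered as the inner
    node's label (used for MCMC support values); it overrides any stored
    inner label.
    """
    ann = node_annotations or {}

    def render(node: TreeNode) -> str:
        if node.is_tip:
            s = _quote_label(node.label or "")
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.id in ann:
                s += _format_length(ann[node.id])
            elif node.label:
                s += _quote_label(node.label)
        if node.parent_edge_length is not None:
            s += ":" + _format_length(node.parent_edge_length)
        return s

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# rooting


def _unrooted_copy(tree: Tree) -> Tree:
    """Return a top-trifurcation copy (suppress a binary root if present)."""
    t = tree.copy()
    if not t.unrooted:
        left, right = t.root.children
        # merge the two root edges into one: hang the shallower-side child
        # under the other, summing lengths; total length is preserved
        if left.is_tip and right.is_tip:
            raise TreeError("cannot unroot a 2-tip tree")
        keep, move = (left, right) if not left.is_tip else (right, left)
        move.parent_edge_length += keep.parent_edge_length  # type: ignore[operator]
        keep.children.append(move)
        keep.parent_edge_length = None
        t = Tree(keep, unrooted=True)
    return t


def _reroot_on_edge(tree: Tree, child: TreeNode, dist_below_parent: float) -> Tree:
    """Insert a root on the edge above ``child`` of an unrooted-topology tree.

    The edge of length L is split into ``dist_below_parent`` (toward the old
    parent side) and ``L - dist_below_parent`` (toward ``child``); edges on the
    path from the old top node down to ``child`` are reversed.
    """
    length = child.parent_edge_length
    assert length is not None
    new_root = TreeNode()
    # reverse the path from child's parent up to the old top node
    path: list[TreeNode] = []
    node = child.parent
    while node is not None:
        path.append(node)
        node = node.parent
    prev = new_root
    prev_edge = dist_below_parent
    for node in path:
        # detach the node we are descending from
        if prev is new_root:
            node.children.remove(child)
        else:
            node.children.remove(prev)
        edge_up = node.parent_edge_length
        prev.children.append(node)
        node.parent_edge_length = prev_edge
        prev_edge = edge_up
        prev = node
    # old top node may now have a single child: splice it out
    top = path[-1] if path else None
    if top is not None and len(top.children) == 1:
        parent = new_root if len(path) == 1 else path[-2]
        only = top.children[0]
        only.parent_edge_length += top.parent_edge_length  # type: ignore[operator]
        idx = parent.children.index(top)
        parent.children[idx] = only
    child.parent_edge_length = length - dist_below_parent
    new_root.children.insert(0, child)
    return Tree(new_root, unrooted=False)


def root_longest_tip_edge(tree: Tree) -> Tree:
    """Root an unrooted tree at the midpoint of its longest terminal branch.

    Already-rooted trees are returned unchanged.  Ties in terminal branch
    length are broken by input (post-order) order, for determinism.
    """
    if tree.n_tips < 3:
        raise TreeError("need at least 3 tips to root on a terminal branch")
    if not tree.unrooted:
        return tree
    t = tree.copy()
    best = None
    for node in t.postorder():
        if node.is_tip and node.parent is not None:
            if best is None or node.parent_edge_length > best.parent_edge_length:  # type: ignore[operator]
                best = node
    assert best is not None
    return _reroot_on_edge(t, best, best.parent_edge_length / 2.0)  # type: ignore[operator]


def root_with_outgroup(tree: Tree, outgroup_labels: list[str]) -> Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The outgroup label set must form one side of an edge of the unrooted
    topology (i.e. be a clade once the root is discounted); the separating
    edge is split at its midpoint.
    """
    if not outgroup_labels:
        raise TreeError("empty outgroup")
    all_labels = set(tree.tip_labels())
    unknown = [x for x in outgroup_labels if x not in all_labels]
    if unknown:
        raise TreeError(f"unknown outgroup taxa: {', '.join(sorted(unknown))}")
    og = frozenset(outgroup_labels)
    if og == all_labels:
        raise TreeError("outgroup cannot contain every taxon")
    t = _unrooted_copy(tree)
    complement = frozenset(all_labels - og)
    for node in t.postorder():
        if node is t.root:
            continue
        clade = t.subtree_tip_labels(node)
        if clade == og or clade == complement:
            return _reroot_on_edge(t, node, node.parent_edge_length / 2.0)  # type: ignore[operator]
    raise TreeError(
        "outgroup is not monophyletic: "
        f"{{{', '.join(sorted(og))}}} is not one side of any edge"
    )
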