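"""Rooted phylogenetic trees: Newick I/O, random generation, branch lengths.

Trees are rooted node structures that allow multifurcations.  Branch
lengths are expected substitutions per site; the root carries no branch
length.  All traversals are iterative so that deep caterpillar trees do
not hit the interpreter recursion limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Node",
    "Tree",
    "BranchLengthDistribution",
    "parse_newick",
    "write_newick",
    "yule_harding_tree",
    "birth_death_tree",
    "assign_branch_lengths",
    "scale_branches",
    "tree_stats",
]

_NEWICK_DELIMS = set("(),:;")


class Node:
    """A tree node with an optional name and branch length to its parent."""

    __slots__ = ("name", "length", "children", "parent", "id")

    def __init__(self, name: str | None = None,
                 length: float | None = None) -> None:
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.id: int | None = None  # assigned by Tree.index_nodes()

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "tip" if self.is_tip else f"internal[{len(self.children)}]"
        return f"Node({self.name!r}, {kind}, length={self.length})"


class Tree:
    """A rooted tree; supports multifurcations and trifurcating roots."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal (iterative) -----------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def index_nodes(self) -> int:
        """Assign stable preorder ids; returns the node count."""
        count = 0
        for node in self.preorder():
            node.id = count
            count += 1
        return count

    def validate(self) -> None:
        names = [t.name for t in self.tips()]
        if any(n is None for n in names):
            raise ValueError("every tip must be named")
        if len(set(names)) != len(names):
            raise ValueError("tip names must be unique")
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is not None and (node.length < 0 or
                                            not np.isfinite(node.length)):
                raise ValueError("branch lengths must be finite and >= 0")

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder()
                   if n is not self.root)

    def copy(self) -> "Tree":
        mapping = {self.root: Node(self.root.name, self.root.length)}
        for node in self.preorder():
            for child in node.children:
                mapping[child] = mapping[node].add_child(
                    Node(child.name, child.length))
        return Tree(mapping[self.root])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Tree(n_tips={len(self.tips())})"


# ----------------------------------------------------------------------
def parse_newick(text: str) -> Tree:
    """Parse a Newick string (multifurcations allowed, lengths optional).

    Raises on unbalanced parentheses, duplicate tip names and negative
    branch lengths.  A length attached to the root is dropped.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty Newick string")
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")

    root = Node()
    cur = root
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            cur = cur.add_child(Node())
            i += 1
        elif ch == ",":
            if cur.parent is None:
                raise ValueError("unbalanced parentheses (stray ',')")
            cur = cur.parent.add_child(Node())
            i += 1
        elif ch == ")":
            if cur.parent is None:
                raise ValueError("unbalanced parentheses (extra ')')")
            cur = cur.parent
            i += 1
        elif ch == ";":
            if i != n - 1:
                raise ValueError("text after terminating ';'")
            break
        elif ch == ":":
            j = i + 1
            while j < n and text[j] not in _NEWICK_DELIMS:
                j += 1
            try:
                value = float(text[i + 1:j])
            except ValueError:
                raise ValueError(f"bad branch length {text[i + 1:j]!r}") from None
            if value < 0:
                raise ValueError(f"negative branch length {value}")
            cur.length = value
            i = j
        else:
            j = i
            while j < n and text[j] not in _NEWICK_DELIMS:
                j += 1
            cur.name = text[i:j].strip()
            i = j
    if cur is not root:
        raise ValueError("unbalanced parentheses (missing ')')")

    # A single outer group "(...)" produced a root with one synthetic child;
    # promote that child so the file's outermost clade is the root.
    if len(root.children) == 1 and root.name is None:
        root = root.children[0]
        root.parent = None
    root.length = None  # the root has no branch
    tree = Tree(root)
    tree.validate()
    return tree


def _fmt_length(value: float) -> str:
    return format(value, ".10g")


def write_newick(tree: Tree) -> str:
    """Serialize to Newick with 10-significant-digit branch lengths."""
    parts: list[str] = []
    stack: list[object] = [tree.root]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            parts.append(item)
            continue
        node = item
        suffix = ""
        if node.name:
            suffix += node.name
        if node.length is not None and node.parent is not None:
            suffix += ":" + _fmt_length(node.length)
        if node.is_tip:
            parts.append(suffix)
            continue
        parts.append("(")
        stack.append(")" + suffix)
        for child in reversed(node.children[1:]):
            stack.append(child)
            stack.append(",")
        stack.append(node.children[0])
    return "".join(parts) + ";"


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BranchLengthDistribution:
    """Either exponential(mean) or a uniform choice from a user list."""

    kind: str  # "exponential" | "user_list"
    mean: float | None = None
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "exponential":
            if self.mean is None or self.mean <= 0:
                raise ValueError("exponential mean must be > 0")
        elif self.kind == "user_list":
            if not self.values:
                raise ValueError("user list of branch lengths must be non-empty")
            if any(v < 0 for v in self.values):
                raise ValueError("user branch lengths must be >= 0")
        else:
            raise ValueError(f"unknown branch-length distribution {self.kind!r}")

    @classmethod
    def exponential(cls, mean: float = 0.1) -> "BranchLengthDistribution":
        return cls(kind="exponential", mean=mean)

    @classmethod
    def user_list(cls, values: Sequence[float]) -> "BranchLengthDistribution":
        return cls(kind="user_list", values=tuple(values))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "exponential":
            return rng.exponential(self.mean, size=size)
        vals = np.asarray(self.values, dtype=float)
        idx = rng.integers(len(vals), size=size)
        return vals[idx]


# ----------------------------------------------------------------------
def _label_tips(tips: list[Node], rng: np.random.Generator) -> None:
    order = rng.permutation(len(tips))
    for tip, k in zip(tips, order):
        tip.name = f"T{int(k) + 1}"


def yule_harding_tree(n_tips: int, rng: np.random.Generator) -> Tree:
    """Random bifurcating topology by uniform splitting of extant lineages.

    Starts from a two-tip cherry and repeatedly splits a uniformly chosen
    extant tip until ``n_tips`` tips exist.  Tips are labeled T1..Tn in a
    random order.  Branch lengths are not assigned.
    """
    n_tips = int(n_tips)
    if n_tips < 2:
        raise ValueError("need at least two tips")
    root = Node()
    tips = [root.add_child(Node()), root.add_child(Node())]
    while len(tips) < n_tips:
        i = int(rng.integers(len(tips)))
        node = tips[i]
        left = node.add_child(Node())
        right = node.add_child(Node())
        tips[i] = left
        tips.append(right)
    _label_tips(tips, rng)
    return Tree(root)


def birth_death_tree(n_tips: int, birth_rate: float, death_rate: float,
                     rng: np.random.Generator,
                     max_restarts: int = 100_000) -> Tree:
    """Forward-time birth-death topology conditioned on ``n_tips`` survivors.

    Simulation restarts whenever the process goes extinct before reaching
    the requested tip count; extinct lineages are pruned as they die and
    the resulting unifurcations suppressed.  Requires ``birth > death >= 0``.
    """
    n_tips = int(n_tips)
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if not (birth_rate > death_rate >= 0):
        raise ValueError("birth rate must exceed death rate (>= 0)")
    p_birth = birth_rate / (birth_rate + death_rate)

    for _ in range(max_restarts):
        root = Node()
        active = [root]
        while active and len(active) < n_tips:
            i = int(rng.integers(len(active)))
            if death_rate == 0 or rng.random() < p_birth:
                node = active[i]
                left = node.add_child(Node())
                right = node.add_child(Node())
                active[i] = left
                active.append(right)
            else:
                dead = active.pop(i)
                parent = dead.parent
                if parent is None:  # the root lineage itself died out
                    active = []
                    break
                parent.children.remove(dead)
                survivor = parent.children[0]
                grand = parent.parent
                if grand is None:
                    survivor.parent = None
                    root = survivor
                else:
                    grand.children[grand.children.index(parent)] = survivor
                    survivor.parent = grand
        if len(active) == n_tips:
            _label_tips(active, rng)
            return Tree(root)
    raise RuntimeError("birth-death simulation failed to reach the requested "
                       "tip count within the restart budget")


def assign_branch_lengths(tree: Tree, dist: BranchLengthDistribution,
                          rng: np.random.Generator) -> Tree:
    """Assign an i.i.d. draw from ``dist`` to every non-root branch (in place)."""
    for node in tree.preorder():
        if node is not tree.root:
            node.length = float(dist.sample(rng))
    return tree


def scale_branches(tree: Tree, factor: float) -> Tree:
    """Multiply every branch length by ``factor`` (in place)."""
    if not (factor > 0):
        raise ValueError("scale factor must be > 0")
    for node in tree.preorder():
        if node is not tree.root and node.length is not None:
            node.length *= factor
    return tree


def tree_stats(tree: Tree) -> dict:
    """Structural counts: tips, internal nodes, node depth, unrooted internal
    branches.

    ``max_depth_in_nodes`` counts nodes along the longest root-to-tip path.
    The unrooted internal-branch count merges the two root edges of a
    bifurcating root into a single branch.
    """
    n_tips = 0
    n_internal = 0
    max_depth = 0
    depth = {tree.root: 1}
    internal_child_edges = 0
    for node in tree.preorder():
        if node is not tree.root:
            depth[node] = depth[node.parent] + 1
        max_depth = max(max_depth, depth[node])
        if node.is_tip:
            n_tips += 1
        else:
            n_internal += 1
            if node is not tree.root:
                internal_child_edges += 1

    n_unrooted = internal_child_edges
    if len(tree.root.children) == 2:
        c1, c2 = tree.root.children
        # the two root edges collapse into one; it is internal iff both ends are
        n_unrooted -= int(not c1.is_tip) + int(not c2.is_tip)
        n_unrooted += int(not c1.is_tip and not c2.is_tip)
    return {
        "n_tips": n_tips,
        "n_internal_nodes": n_internal,
        "max_depth_in_nodes": max_depth,
        "n_internal_branches_unrooted": n_unrooted,
    }
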