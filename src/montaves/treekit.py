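"""Time-calibrated tree data model and Newick/NEXUS I/O.

Trees are rooted, with branch lengths in millions of years (Ma).  Node ages
are measured from the present: tips of an ultrametric tree sit at age 0 and
ages increase rootward.  All downstream stages (ancestral range
reconstruction, source-node tracing, Brownian-motion null models) consume
this structure.

Parsing is delegated to :mod:`dendropy` (Newick and NEXUS TREES blocks,
including translate tables); the in-memory model here is a flat arrays-based
structure convenient for likelihood computations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "TreeError",
    "TreeParseError",
    "parse_tree",
    "prune_to",
    "graft",
    "divergence_age",
]

#: relative tolerance used when checking that all root-to-tip path lengths
#: of a tree flagged ultrametric agree
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class TreeParseError(TreeError):
    """Malformed Newick/NEXUS input."""


@dataclass
class TimeTree:
    """Rooted tree stored as parallel per-node arrays.

    Nodes are indexed ``0 .. n_nodes-1``; ``parent[i] == -1`` marks the
    root.  ``labels[i]`` is the tip label for leaves (unique, non-empty) and
    an optional internal-node label otherwise.  ``brlen[i]`` is the length
    of the branch subtending node ``i`` (0 for the root).
    """

    parent: np.ndarray
    children: list[list[int]]
    brlen: np.ndarray
    labels: list[str | None]
    root: int = field(default=0)

    # -- construction / validation -------------------------------------

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.brlen = np.asarray(self.brlen, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.parent)
        if not (len(self.children) == len(self.brlen) == len(self.labels) == n):
            raise TreeError("node array lengths differ")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        if roots[0] != self.root:
            raise TreeError("root index inconsistent with parent array")
        if np.any(self.brlen < 0):
            bad = int(np.flatnonzero(self.brlen < 0)[0])
            raise TreeError(f"negative branch length at node {bad}")
        seen: set[str] = set()
        for i in self.tips():
            lab = self.labels[i]
            if not lab:
                raise TreeError(f"tip {i} has an empty label")
            if lab in seen:
                raise TreeError(f"duplicate tip label {lab!r}")
            seen.add(lab)

    # -- basic structure -----------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips()]  # type: ignore[misc]

    def tip_index(self, label: str) -> int:
        for i in self.tips():
            if self.labels[i] == label:
                return i
        raise TreeError(f"unknown tip label {label!r}")

    def postorder(self) -> list[int]:
        """Node indices, children always before their parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def is_bifurcating(self) -> bool:
        return all(len(self.children[i]) in (0, 2) for i in range(self.n_nodes))

    # -- depths and ages -----------------------------------------------

    def depths(self) -> np.ndarray:
        """Path length from the root to each node."""
        d = np.zeros(self.n_nodes)
        for i in self.preorder():
            if i != self.root:
                d[i] = d[self.parent[i]] + self.brlen[i]
        return d

    def node_ages(self) -> np.ndarray:
        """Age above the present for each node (deepest tip is at age 0)."""
        d = self.depths()
        tip_idx = self.tips()
        return d[tip_idx].max() - d

    @property
    def root_age(self) -> float:
        return float(self.node_ages()[self.root])

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()[self.tips()]
        span = d.max()
        if span == 0:
            return True
        return bool(np.ptp(d) <= rtol * span)

    def require_ultrametric(self) -> None:
        if not self.is_ultrametric():
            raise TreeError("operation requires an ultrametric tree")

    def require_bifurcating(self) -> None:
        if not self.is_bifurcating():
            raise TreeError(
                "operation requires a strictly bifurcating tree; "
                "resolve polytomies first"
            )

    def copy(self) -> "TimeTree":
        return TimeTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            brlen=self.brlen.copy(),
            labels=list(self.labels),
            root=self.root,
        )

    # -- serialisation --------------------------------------------------

    def _newick_node(self, i: int, with_internal_labels: bool) -> str:
        if self.is_tip(i):
            core = _quote_label(self.labels[i])
        else:
            inner = ",".join(
                self._newick_node(c, with_internal_labels) for c in self.children[i]
            )
            lab = self.labels[i] if with_internal_labels and self.labels[i] else ""
            core = f"({inner}){_quote_label(lab) if lab else ''}"
        if i == self.root:
            return core
        return f"{core}:{self.brlen[i]:.10g}"

    def to_newick(self, with_internal_labels: bool = False) -> str:
        return self._newick_node(self.root, with_internal_labels) + ";"

    def to_nexus(self, tree_name: str = "tree1") -> str:
        labels = self.tip_labels
        translate = ",\n".join(
            f"        {k + 1} {_quote_label(lab)}" for k, lab in enumerate(labels)
        )
        index = {lab: str(k + 1) for k, lab in enumerate(labels)}
        renamed = self.copy()
        for i in renamed.tips():
            renamed.labels[i] = index[renamed.labels[i]]
        return (
            "#NEXUS\nBEGIN TREES;\n    TRANSLATE\n"
            f"{translate};\n    TREE {tree_name} = {renamed.to_newick()}\nEND;\n"
        )

    def ascii_art(self) -> str:
        """Plain-text rendering for debugging."""
        lines: list[str] = []

        def walk(i: int, prefix: str) -> None:
            lab = self.labels[i] or f"node{i}"
            bl = "" if i == self.root else f":{self.brlen[i]:.3g}"
            lines.append(f"{prefix}{lab}{bl}")
            for c in self.children[i]:
                walk(c, prefix + "  ")

        walk(self.root, "")
        return "\n".join(lines)


def _quote_label(label: str | None) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in " ,():;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- parsing -----------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    children: list[list[int]] = [[] for _ in nodes]
    brlen = np.zeros(len(nodes))
    labels: list[str | None] = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is not None:
                if nd.edge.length < 0:
                    raise TreeParseError(
                        f"negative branch length {nd.edge.length} on edge to "
                        f"{nd.taxon.label if nd.taxon else 'an internal node'}"
                    )
                brlen[i] = nd.edge.length
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    try:
        return TimeTree(parent, children, brlen, labels, root=0)
    except TreeError as exc:  # surface invariant violations as parse errors
        raise TreeParseError(str(exc)) from exc


def parse_tree(text: str) -> TimeTree:
    """Parse a Newick or NEXUS tree string into a :class:`TimeTree`.

    NEXUS input is recognised by its ``#NEXUS`` header; only the TREES
    block (with optional translate table) is consumed.  The first tree in a
    multi-tree file is returned.
    """
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeParseError(f"could not parse {schema} input: {exc}") from exc
    return _from_dendropy(dtree)


def load_tree(path: str) -> TimeTree:
    with open(path) as fh:
        return parse_tree(fh.read())


# -- operations --------------------------------------------------------


def prune_to(tree: TimeTree, keep: set[str]) -> TimeTree:
    """Induced subtree on ``keep``.

    Unary internal nodes left by the pruning are suppressed, summing their
    branch lengths, so pairwise divergence ages among the kept tips are
    preserved.  The returned tree is rooted at the MRCA of the kept tips.
    """
    keep = set(keep)
    if not keep:
        raise TreeError("keep set is empty")
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise TreeError(f"unknown tip label(s): {sorted(unknown)}")

    retained = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.tips():
        if tree.labels[i] in keep:
            retained[i] = True
    for i in tree.postorder():
        if tree.children[i] and any(retained[c] for c in tree.children[i]):
            retained[i] = True

    # new root: deepest retained node with >=2 retained children, or the
    # single kept tip in the degenerate one-tip case
    kept_children = {
        i: [c for c in tree.children[i] if retained[c]]
        for i in range(tree.n_nodes)
        if retained[i]
    }
    new_root = tree.root
    while len(kept_children[new_root]) == 1:
        new_root = kept_children[new_root][0]

    old_new: dict[int, int] = {}
    parent: list[int] = []
    children: list[list[int]] = []
    brlen: list[float] = []
    labels: list[str | None] = []

    def add(old: int, new_parent: int, length: float) -> int:
        j = len(parent)
        old_new[old] = j
        parent.append(new_parent)
        children.append([])
        brlen.append(length)
        labels.append(tree.labels[old])
        if new_parent >= 0:
            children[new_parent].append(j)
        return j

    add(new_root, -1, 0.0)
    stack = [(c, old_new[new_root], float(tree.brlen[c])) for c in kept_children[new_root]]
    while stack:
        old, par, acc = stack.pop()
        chs = kept_children[old]
        if len(chs) == 1:  # suppress unary node, accumulate its branch
            stack.append((chs[0], par, acc + float(tree.brlen[chs[0]])))
            continue
        j = add(old, par, acc)
        for c in chs:
            stack.append((c, j, float(tree.brlen[c])))

    return TimeTree(np.array(parent), children, np.array(brlen), labels, root=0)


def graft(backbone: TimeTree, attach_tip: str, subtree: TimeTree) -> TimeTree:
    """Replace a backbone tip by a clade, keeping the result ultrametric.

    The connecting branch is chosen so the subtree's tips sit at age 0:
    its length is the age of ``attach_tip``'s parent minus the subtree's
    root age.  Both trees must be ultrametric.
    """
    backbone.require_ultrametric()
    subtree.require_ultrametric()
    tip = backbone.tip_index(attach_tip)
    if backbone.parent[tip] < 0:
        raise TreeError("cannot graft onto a single-node backbone")
    parent_age = float(backbone.node_ages()[backbone.parent[tip]])
    sub_age = subtree.root_age
    if sub_age >= parent_age:
        raise TreeError(
            f"incompatible ages: subtree root age {sub_age:.6g} Ma is not "
            f"younger than the attachment point at {parent_age:.6g} Ma"
        )
    connecting = parent_age - sub_age

    out = backbone.copy()
    offset = out.n_nodes
    # append subtree nodes, re-indexed
    out.parent = np.concatenate([out.parent, subtree.parent + offset])
    out.parent[offset + subtree.root] = out.parent[tip]
    out.children = out.children + [
        [c + offset for c in ch] for ch in subtree.children
    ]
    out.brlen = np.concatenate([out.brlen, subtree.brlen])
    out.brlen[offset + subtree.root] = connecting
    out.labels = out.labels + list(subtree.labels)
    # splice: parent of the replaced tip now points at the subtree root
    p = int(out.parent[tip])
    out.children[p] = [
        offset + subtree.root if c == tip else c for c in out.children[p]
    ]
    # detach the replaced tip and drop it by re-extraction
    out.parent[tip] = -2  # orphan marker, removed below
    return _compact(out, drop={tip})


def _compact(tree: TimeTree, drop: set[int]) -> TimeTree:
    """Rebuild node arrays, dropping the given (detached) nodes."""
    keep = [i for i in range(tree.n_nodes) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    parent = np.array(
        [remap[tree.parent[i]] if tree.parent[i] >= 0 else -1 for i in keep]
    )
    children = [[remap[c] for c in tree.children[i] if c not in drop] for i in keep]
    brlen = tree.brlen[keep]
    labels = [tree.labels[i] for i in keep]
    root = [j for j, i in enumerate(keep) if tree.parent[i] < 0]
    return TimeTree(parent, children, brlen, labels, root=root[0])


def divergence_age(tree: TimeTree, tip: str) -> float:
    """Age of the tip's parent node: time to divergence from its sister
    species or clade."""
    if len(tree.tips()) < 2:
        raise TreeError("divergence age needs a tree with at least 2 tips")
    i = tree.tip_index(tip)
    return float(tree.node_ages()[tree.parent[i]])
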