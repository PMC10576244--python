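"""Tree data model, Newick I/O, and tree-preparation utilities.

The central object is :class:`PhyloTree`, a rooted tree with nonnegative
branch lengths in time units. It is the substrate for every likelihood in the
package: the discrete ordered-Markov machinery walks its postorder, and the
Brownian-motion machinery reads its phylogenetic variance-covariance matrix
(:func:`vcv`).

Preparation utilities mirror the steps a comparative study applies before
analysis: checking/enforcing ultrametricity (:func:`is_ultrametric`,
:func:`make_ultrametric`, a mean-path-length node dating) and pruning a tree
with multiple specimens per species down to one representative tip per species
(:func:`prune_to_representatives`).

Newick parsing is delegated to dendropy; writing is done here so that per-node
annotations (for example ancestral-state posterior probabilities) can travel
inside bracketed ``[&key=value]`` comments and survive a round trip.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "VcvMatrix",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "is_ultrametric",
    "make_ultrametric",
    "prune_to_representatives",
    "vcv",
]


class NewickParseError(ValueError):
    """Raised when a Newick string is malformed or violates tree invariants."""


@dataclass
class Node:
    """A single node: tips carry labels, internal nodes may carry support labels."""

    id: int
    label: str | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    branch_length: float = 0.0
    comment: str | None = None  # raw bracketed-comment payload, sans "[&" and "]"

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted phylogeny with branch lengths.

    Invariants (checked by :meth:`validate`): exactly one root; every non-root
    node has one parent; branch lengths nonnegative; tip labels unique and
    non-empty; no unary (single-child) internal nodes. Multifurcations are
    allowed.
    """

    def __init__(self, nodes: list[Node], root: int):
        self.nodes = nodes
        self.root = root
        self.validate()

    # -- construction helpers -------------------------------------------------

    def validate(self) -> None:
        roots = [n.id for n in self.nodes if n.parent is None]
        if roots != [self.root]:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        labels = [n.label for n in self.nodes if n.is_tip]
        if any(not lab for lab in labels):
            raise ValueError("every tip must carry a non-empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip label(s): {sorted(dupes)}")
        for n in self.nodes:
            if n.branch_length < 0:
                raise ValueError(
                    f"negative branch length {n.branch_length} on node {n.id}"
                )
            if len(n.children) == 1:
                raise ValueError(f"unary node {n.id}; collapse before constructing")
            for c in n.children:
                if self.nodes[c].parent != n.id:
                    raise ValueError("parent/child pointers inconsistent")

    # -- basic queries --------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.nodes if n.is_tip]

    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    def tip_by_label(self, label: str) -> Node:
        for n in self.nodes:
            if n.is_tip and n.label == label:
                return n
        raise KeyError(label)

    def n_tips(self) -> int:
        return sum(1 for n in self.nodes if n.is_tip)

    def postorder(self) -> list[int]:
        """Node ids, children always before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.nodes[v].children)
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root branch excluded)."""
        d = np.zeros(len(self.nodes))
        for v in self.preorder():
            node = self.nodes[v]
            if node.parent is not None:
                d[v] = d[node.parent] + node.branch_length
        return d

    def tree_height(self) -> float:
        d = self.depths()
        return float(max(d[n.id] for n in self.tips()))

    def mrca(self, i: int, j: int) -> int:
        anc = set()
        v: int | None = i
        while v is not None:
            anc.add(v)
            v = self.nodes[v].parent
        v = j
        while v not in anc:
            v = self.nodes[v].parent  # type: ignore[assignment]
        return v  # type: ignore[return-value]

    def patristic_distance(self, i: int, j: int) -> float:
        d = self.depths()
        return float(d[i] + d[j] - 2.0 * d[self.mrca(i, j)])

    def copy(self) -> "PhyloTree":
        nodes = [
            Node(n.id, n.label, n.parent, list(n.children), n.branch_length, n.comment)
            for n in self.nodes
        ]
        return PhyloTree(nodes, self.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips()} tips, {len(self.nodes)} nodes>"


@dataclass
class VcvMatrix:
    """Brownian-motion phylogenetic covariance: shared root-to-MRCA path lengths.

    ``C[i, j]`` is the length of the root-to-MRCA path for tips ``labels[i]``
    and ``labels[j]``; the diagonal holds root-to-tip distances.
    """

    labels: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.labels), len(self.labels)):
            raise ValueError("C shape does not match labels")
        self.C = C


# -- Newick I/O ---------------------------------------------------------------


def _comment_payload(comments: list[str]) -> str | None:
    """Extract our 'key=value' payload from dendropy's comment list."""
    for c in comments:
        c = c.strip()
        if c.startswith("&"):
            return c[1:]
    return comments[0].strip() if comments else None


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Missing branch lengths become 0 (with a warning); internal-node labels
    (support values) are preserved; bracketed ``[&...]`` comments are stored on
    nodes; unary nodes are collapsed with branch lengths summed.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None

    nodes: list[Node] = []
    mapping: dict[dendropy.Node, int] = {}
    missing_bl = 0
    for dnode in dtree.preorder_node_iter():
        nid = len(nodes)
        mapping[dnode] = nid
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            label = dnode.label
        bl = dnode.edge.length
        if bl is None:
            if dnode.parent_node is not None:
                missing_bl += 1
            bl = 0.0
        if bl < 0:
            raise NewickParseError(f"negative branch length {bl} on node {label!r}")
        parent = mapping[dnode.parent_node] if dnode.parent_node is not None else None
        node = Node(nid, label, parent, [], float(bl),
                    _comment_payload(list(dnode.comments)))
        nodes.append(node)
        if parent is not None:
            nodes[parent].children.append(nid)
    if missing_bl:
        warnings.warn(
            f"{missing_bl} branch length(s) missing in Newick input; set to 0",
            stacklevel=2,
        )

    nodes, root = _collapse_unary(nodes, 0)
    return PhyloTree(nodes, root)


def _collapse_unary(nodes: list[Node], root: int) -> tuple[list[Node], int]:
    """Remove single-child internal nodes, summing branch lengths; reindex."""
    # repeatedly splice out unary nodes (a unary root is replaced by its child)
    changed = True
    alive = {n.id for n in nodes}
    while changed:
        changed = False
        for nid in list(alive):
            n = nodes[nid]
            if len(n.children) != 1:
                continue
            (child,) = n.children
            if n.parent is None:
                nodes[child].parent = None
                nodes[child].branch_length = 0.0
                root = child
            else:
                p = nodes[n.parent]
                p.children[p.children.index(nid)] = child
                nodes[child].parent = n.parent
                nodes[child].branch_length += n.branch_length
            alive.discard(nid)
            changed = True
    # reindex densely preserving preorder
    old_ids = [nid for nid in range(len(nodes)) if nid in alive]
    remap = {old: new for new, old in enumerate(old_ids)}
    out: list[Node] = []
    for old in old_ids:
        n = nodes[old]
        out.append(
            Node(
                remap[old],
                n.label,
                remap[n.parent] if n.parent is not None else None,
                [remap[c] for c in n.children],
                n.branch_length,
                n.comment,
            )
        )
    return out, remap[root]


def _escape_label(label: str) -> str:
    if any(ch in label for ch in " ,():;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(
    tree: PhyloTree,
    node_annotations: Mapping[int, str] | None = None,
    include_branch_lengths: bool = True,
) -> str:
    """Serialize to Newick; annotations become ``[&payload]`` node comments."""
    ann = dict(node_annotations or {})
    for nid in ann:
        if not 0 <= nid < len(tree.nodes):
            raise KeyError(f"annotation for unknown node id {nid}")
    # carry pre-existing comments unless overridden
    for n in tree.nodes:
        if n.comment is not None and n.id not in ann:
            ann[n.id] = n.comment

    buf = io.StringIO()

    def emit(nid: int) -> None:
        node = tree.nodes[nid]
        if node.children:
            buf.write("(")
            for i, c in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(c)
            buf.write(")")
            if node.label:
                buf.write(_escape_label(node.label))
        else:
            buf.write(_escape_label(node.label or ""))
        if nid in ann:
            buf.write(f"[&{ann[nid]}]")
        if include_branch_lengths and node.parent is not None:
            buf.write(f":{node.branch_length:.12g}")

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()


# -- ultrametricity -----------------------------------------------------------


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-9) -> bool:
    """True iff all root-to-tip distances agree within ``rel_tol`` of their mean."""
    d = tree.depths()
    tip_d = np.array([d[n.id] for n in tree.tips()])
    mean = tip_d.mean()
    scale = mean if mean > 0 else 1.0
    return bool(np.max(np.abs(tip_d - mean)) <= rel_tol * scale)


def make_ultrametric(tree: PhyloTree) -> PhyloTree:
    """Mean-path-length node dating.

    Each internal node's age is set to the mean path length from that node to
    its descendant tips, clamped so a child is never older than its parent;
    tips sit at age 0. Topology is preserved, already-ultrametric trees are
    fixed points, and relative node ordering survives the transform.
    """
    if all(n.branch_length == 0 for n in tree.nodes):
        raise ValueError("cannot date a tree whose branch lengths are all zero")
    out = tree.copy()
    # mean path length to descendant tips, bottom-up
    n_desc = np.zeros(len(out.nodes))
    sum_path = np.zeros(len(out.nodes))
    for v in out.postorder():
        node = out.nodes[v]
        if node.is_tip:
            n_desc[v] = 1
            sum_path[v] = 0.0
        else:
            for c in node.children:
                n_desc[v] += n_desc[c]
                sum_path[v] += sum_path[c] + n_desc[c] * out.nodes[c].branch_length
    age = np.zeros(len(out.nodes))
    for v in out.preorder():
        node = out.nodes[v]
        if node.is_tip:
            age[v] = 0.0
            continue
        mpl = sum_path[v] / n_desc[v]
        if node.parent is None:
            age[v] = mpl
        else:
            age[v] = min(mpl, age[node.parent])
    for v in out.preorder():
        node = out.nodes[v]
        if node.parent is not None:
            node.branch_length = float(age[node.parent] - age[v])
    return out


# -- representative pruning ---------------------------------------------------


def prune_to_representatives(
    tree: PhyloTree, species_of: Mapping[str, str]
) -> PhyloTree:
    """Retain one tip per species, keeping the most phylogenetically distant tips.

    Among a species' tips, the one maximizing the summed patristic distance to
    the other species' candidate tips is retained (nested duplicates — likely
    hybrids or misidentifications — are dropped). Species are resolved greedily
    in alphabetical order; ties break on lexicographic tip label. The retained
    tip is renamed to its species name when the species has several tips.
    """
    tips = tree.tips()
    for t in tips:
        if t.label not in species_of:
            raise KeyError(f"tip {t.label!r} missing from species map")
    by_species: dict[str, list[Node]] = {}
    for t in tips:
        by_species.setdefault(species_of[t.label], []).append(t)
    for sp, members in by_species.items():
        if not members:
            raise ValueError(f"species {sp!r} has zero tips")

    d = tree.depths()

    def pdist(i: int, j: int) -> float:
        return float(d[i] + d[j] - 2.0 * d[tree.mrca(i, j)])

    candidates: dict[str, list[Node]] = {
        sp: sorted(members, key=lambda n: n.label or "")
        for sp, members in by_species.items()
    }
    for sp in sorted(candidates):
        others = [
            n.id
            for sp2, members in candidates.items()
            if sp2 != sp
            for n in members
        ]
        best = max(
            candidates[sp],
            key=lambda n: (sum(pdist(n.id, o) for o in others), n.label or ""),
        )
        candidates[sp] = [best]

    keep_ids = {members[0].id for members in candidates.values()}
    nodes = [
        Node(n.id, n.label, n.parent, list(n.children), n.branch_length, n.comment)
        for n in tree.nodes
    ]
    # drop unkept tips, then prune now-childless internals, bottom-up
    for v in tree.postorder():
        n = nodes[v]
        keep = v in keep_ids if n.is_tip else bool(n.children)
        if not keep and n.parent is not None:
            nodes[n.parent].children.remove(v)
            n.parent = None
    live = set()
    stack = [tree.root]
    while stack:
        v = stack.pop()
        live.add(v)
        stack.extend(nodes[v].children)
    kept_nodes = [nodes[v] for v in sorted(live)]
    # reuse unary collapse (handles reindexing)
    dense: list[Node] = []
    remap = {n.id: i for i, n in enumerate(kept_nodes)}
    for n in kept_nodes:
        dense.append(
            Node(
                remap[n.id],
                n.label,
                remap[n.parent] if n.parent is not None else None,
                [remap[c] for c in n.children],
                n.branch_length,
                n.comment,
            )
        )
    dense, root = _collapse_unary(dense, remap[tree.root])
    out = PhyloTree(dense, root)
    # rename multi-specimen species tips to the species name
    rename = {
        members[0].label: sp
        for sp, members in candidates.items()
        if len(by_species[sp]) > 1
    }
    for n in out.nodes:
        if n.is_tip and n.label in rename:
            n.label = rename[n.label]
    out.validate()
    return out


# -- covariance ---------------------------------------------------------------


def vcv(tree: PhyloTree, tip_order: Iterable[str] | None = None) -> VcvMatrix:
    """Phylogenetic variance-covariance matrix under Brownian motion.

    ``C[i, j]`` equals the root-to-MRCA distance of tips i and j — the shared
    evolutionary time along which their trait values covary.
    """
    tips = tree.tips()
    labels = [t.label for t in tips]  # type: ignore[misc]
    if tip_order is not None:
        order = list(tip_order)
        if sorted(order) != sorted(labels):
            raise ValueError("tip_order does not match the tree's tips")
        labels = order
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = tree.depths()
    C = np.zeros((n, n))
    # tips below each node, assembled postorder; cross-child pairs share d[node]
    below: dict[int, list[int]] = {}
    for v in tree.postorder():
        node = tree.nodes[v]
        if node.is_tip:
            ti = idx[node.label]  # type: ignore[index]
            C[ti, ti] = d[v]
            below[v] = [ti]
            continue
        merged: list[int] = []
        for c in node.children:
            for a in merged:
                for b in below[c]:
                    C[a, b] = C[b, a] = d[v]
            merged.extend(below.pop(c))
        below[v] = merged
    return VcvMatrix(labels, C)
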