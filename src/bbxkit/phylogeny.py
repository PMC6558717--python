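"""Distance-based phylogeny and domain-architecture trajectory inference.

The tree machinery is deliberately classical: Poisson-corrected protein
distances, Saitou–Nei neighbor joining with deterministic tie-breaking,
column-resampling bootstrap, and two-pass Fitch parsimony over three binary
domain characters (duplicated B-BOX1, presence of B-BOX2, presence of CCT).
State flips along branches are then labeled as named evolutionary events —
B-BOX duplication, CCT gain, B-BOX2 deletion, B-BOX1 duplication — which
together describe the family's domain-architecture trajectory: an ancestral
single-B-BOX protein gains a second B-BOX by duplication, then the CCT
domain; later lineages lose B-BOX2 or duplicate B-BOX1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import SeqRecord
from .domains import Architecture

__all__ = [
    "TreeNode",
    "TrajectoryEvent",
    "distance_matrix",
    "nj_tree",
    "bootstrap",
    "bipartitions",
    "to_newick",
    "from_newick",
    "root_with_outgroup",
    "fitch_reconstruct",
    "label_events",
    "architecture_characters",
    "CHARACTER_NAMES",
]

CHARACTER_NAMES = ("has_B1_duplicated", "has_B2", "has_CCT")

# clade -> (has_B1_duplicated, has_B2, has_CCT); the clade-V architecture
# (single B-BOX, no CCT) is the assumed ancestral state.
CLADE_STATES = {
    "I": (1, 1, 1),
    "II": (0, 1, 1),
    "III": (0, 0, 1),
    "IV": (0, 1, 0),
    "V": (0, 0, 0),
}
ANCESTRAL_STATE = CLADE_STATES["V"]

EVENT_NAMES = {
    ("has_B2", 0, 1): "BBOX_duplication",
    ("has_B2", 1, 0): "BBOX2_deletion",
    ("has_CCT", 0, 1): "CCT_gain",
    ("has_CCT", 1, 0): "CCT_loss",
    ("has_B1_duplicated", 0, 1): "BBOX1_duplication",
    ("has_B1_duplicated", 1, 0): "BBOX1_loss",
}


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent, substitutions/site
    support: float | None = None  # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(leaf.name for leaf in self.leaves())

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self


def to_newick(node: TreeNode, with_support: bool = True) -> str:
    def fmt(n: TreeNode) -> str:
        if n.is_leaf:
            return f"{n.name}:{n.length:.6g}"
        inner = ",".join(fmt(c) for c in n.children)
        label = ""
        if with_support and n.support is not None:
            label = f"{n.support:g}"
        elif n.name:
            label = n.name
        return f"({inner}){label}:{n.length:.6g}"

    inner = ",".join(fmt(c) for c in node.children)
    label = f"{node.support:g}" if (with_support and node.support is not None) else (node.name or "")
    return f"({inner}){label};" if node.children else f"{node.name};"


def from_newick(text: str) -> TreeNode:
    """Parse a Newick string (internal labels read as bootstrap supports)."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else dnode.label
        node = TreeNode(
            name=name if dnode.is_leaf() else None,
            length=dnode.edge.length or 0.0,
        )
        if not dnode.is_leaf() and name:
            try:
                node.support = float(name)
            except ValueError:
                node.name = name
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(tree.seed_node)


# --- distances -------------------------------------------------------------


def distance_matrix(
    records: list[SeqRecord], model: str = "poisson"
) -> tuple[list[str], np.ndarray]:
    """Pairwise distances over shared non-gap columns of aligned sequences.

    ``poisson`` applies d = -ln(1 - p) to the mismatch fraction p; ``p``
    returns the raw proportion.  Sequences must be equal length (gapped).
    """
    n = len(records)
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError("sequences must be aligned to equal length")
    names = [r.id for r in records]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].seq, records[j].seq
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                raise ValueError(f"no shared columns between {names[i]} and {names[j]}")
            p = sum(1 for x, y in shared if x != y) / len(shared)
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("mismatch proportion of 1 cannot be Poisson-corrected")
                d = -math.log(1.0 - p)
            elif model == "p":
                d = p
            else:
                raise ValueError(f"unknown distance model {model!r}")
            mat[i, j] = mat[j, i] = d
    return names, mat


# --- neighbor joining ------------------------------------------------------


def nj_tree(names: list[str], matrix: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining; deterministic (lexicographically smallest
    taxon-name pair wins Q-score ties).  Returns an unrooted tree whose root
    is the final trifurcation (or the 2-taxon join)."""
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if matrix.shape != (n, n):
        raise ValueError("distance matrix does not match taxon count")
    nodes = [TreeNode(name=nm) for nm in names]
    # sort keys carry the smallest leaf name under each working node
    labels = list(names)
    D = matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                q = (m - 2) * sub[ii, jj] - totals[ii] - totals[jj]
                key = tuple(sorted((labels[active[ii]], labels[active[jj]])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, ii, jj)
        _, _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = D[i, j]
        li = 0.5 * dij + (totals[ii] - totals[jj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = new_row
        D[active, k] = new_row
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [a for a in active if a not in (i, j)] + [k]

    if len(active) == 3:
        i, j, k = active
        dij, dik, djk = D[i, j], D[i, k], D[j, k]
        root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
        nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
        nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
        nodes[k].length = max(0.5 * (dik + djk - dij), 0.0)
    else:  # exactly 2 working nodes left (n == 2 never reaches here)
        i, j = active
        root = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = nodes[j].length = 0.5 * D[i, j]
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits, each keyed by the side not containing the
    alphabetically first leaf (a canonical form for unrooted comparison)."""
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    splits = set()
    for node in tree.preorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def bootstrap(
    records: list[SeqRecord],
    n: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Supports are the percentage of replicates containing each bipartition of
    the full-data tree; ``n=0`` returns the tree without supports.
    """
    names, mat = distance_matrix(records, model)
    tree = nj_tree(names, mat)
    if n <= 0:
        return tree
    length = len(records[0].seq)
    if length < 2:
        raise ValueError("bootstrap needs an alignment with >= 2 columns")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    seqs = [r.seq for r in records]
    for _ in range(n):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SeqRecord(r.id, "".join(s[c] for c in cols), r.alphabet)
            for r, s in zip(records, seqs)
        ]
        try:
            rep_names, rep_mat = distance_matrix(resampled, model)
        except ValueError:  # saturated replicate; contributes no support
            continue
        for split in bipartitions(nj_tree(rep_names, rep_mat)):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    for node in tree.preorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = 100.0 * counts.get(side, 0) / n
    return tree


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root an unrooted NJ tree on the branch leading to ``outgroup``.

    Works on a copy; the input tree is left untouched.
    """
    import copy

    tree = copy.deepcopy(tree)
    parent_of: dict[int, TreeNode | None] = {id(tree): None}
    target = None
    for node in tree.preorder():
        for child in node.children:
            parent_of[id(child)] = node
        if node.is_leaf and node.name == outgroup:
            target = node
    if target is None:
        raise ValueError(f"outgroup {outgroup!r} not found in tree")

    # walk up from the outgroup, reversing parent links
    path = [target]
    while parent_of[id(path[-1])] is not None:
        path.append(parent_of[id(path[-1])])
    half = 0.5 * target.length
    new_root = TreeNode(children=[])
    # re-hang: outgroup on one side, the rest of the tree re-rooted on the other
    def detach(parent: TreeNode, child: TreeNode) -> None:
        parent.children = [c for c in parent.children if c is not child]

    old_parent = parent_of[id(target)]
    detach(old_parent, target)
    target.length = half
    new_root.children.append(target)

    # reverse the chain from old_parent back to the original root
    chain = []
    node = old_parent
    while node is not None:
        chain.append(node)
        node = parent_of[id(node)]
    lengths = [n.length for n in chain]
    for idx, node in enumerate(chain):
        if idx + 1 < len(chain):
            detach(chain[idx + 1], node)
            node.children.append(chain[idx + 1])
            chain[idx + 1].length = lengths[idx]
    old_parent.length = half
    new_root.children.append(old_parent)
    _suppress_unifurcations(new_root)
    return new_root


def _suppress_unifurcations(node: TreeNode) -> None:
    for child in list(node.children):
        _suppress_unifurcations(child)
    if len(node.children) == 1 and node.children:
        only = node.children[0]
        node.children = only.children
        node.name = node.name or only.name
        node.length += only.length
        if only.support is not None:
            node.support = only.support


# --- Fitch parsimony and event labeling ------------------------------------


@dataclass
class TrajectoryEvent:
    parent: str
    child: str
    character: str
    event: str
    direction: tuple[int, int]


def fitch_reconstruct(
    tree: TreeNode,
    leaf_states: dict[str, tuple[int, ...]],
    ancestral: tuple[int, ...] = ANCESTRAL_STATE,
) -> tuple[dict[int, tuple[int, ...]], int]:
    """Two-pass Fitch parsimony over independent binary characters.

    Returns ``(states, score)`` where ``states`` maps ``id(node)`` to its
    reconstructed state vector and ``score`` is the minimal total number of
    changes.  Ambiguities resolve toward the ancestral (single-B-BOX)
    state at the root and toward the parent state below it.
    """
    n_chars = len(ancestral)
    for leaf in tree.leaves():
        if leaf.name not in leaf_states:
            raise ValueError(f"no character states for leaf {leaf.name!r}")

    candidate: dict[int, list[set]] = {}
    score = 0
    for node in tree.postorder():
        if node.is_leaf:
            candidate[id(node)] = [{s} for s in leaf_states[node.name]]
            continue
        sets = []
        for c in range(n_chars):
            inter = set.intersection(*(candidate[id(ch)][c] for ch in node.children))
            if inter:
                sets.append(inter)
            else:
                union = set.union(*(candidate[id(ch)][c] for ch in node.children))
                sets.append(union)
                score += 1
        candidate[id(node)] = sets

    parents: dict[int, TreeNode] = {}
    for node in tree.preorder():
        for child in node.children:
            parents[id(child)] = node

    states: dict[int, tuple[int, ...]] = {}
    for node in tree.preorder():
        cand = candidate[id(node)]
        if node is tree:
            chosen = tuple(
                ancestral[c] if ancestral[c] in cand[c] else min(cand[c])
                for c in range(n_chars)
            )
        else:
            parent_state = states[id(parents[id(node)])]
            chosen = tuple(
                parent_state[c] if parent_state[c] in cand[c] else min(cand[c])
                for c in range(n_chars)
            )
        states[id(node)] = chosen
    return states, score


def label_events(
    tree: TreeNode,
    states: dict[int, tuple[int, ...]],
    char_names: tuple[str, ...] = CHARACTER_NAMES,
) -> list[TrajectoryEvent]:
    """Name every parent->child state flip, in preorder traversal order.

    Multiple characters flipping on one edge yield multiple events on that
    edge (legal, just unusual enough to be worth noticing in the output).
    """
    events: list[TrajectoryEvent] = []
    counter = [0]

    def node_label(node: TreeNode) -> str:
        if node.name:
            return node.name
        counter[0] += 1
        node.name = f"node{counter[0]}"
        return node.name

    def walk(node: TreeNode) -> None:
        for child in node.children:
            ps, cs = states[id(node)], states[id(child)]
            for c, char in enumerate(char_names):
                if ps[c] != cs[c]:
                    events.append(
                        TrajectoryEvent(
                            parent=node_label(node),
                            child=node_label(child) if not child.is_leaf else child.name,
                            character=char,
                            event=EVENT_NAMES.get((char, ps[c], cs[c]), f"{char}:{ps[c]}->{cs[c]}"),
                            direction=(ps[c], cs[c]),
                        )
                    )
            walk(child)

    if not tree.name:
        node_label(tree)
    walk(tree)
    return events


def architecture_characters(arch: Architecture) -> tuple[int, int, int]:
    """Encode an architecture as (has_B1_duplicated, has_B2, has_CCT)."""
    if arch.clade in CLADE_STATES:
        return CLADE_STATES[arch.clade]
    if arch.clade == "I/II":
        return CLADE_STATES["II"]
    n_bbox = sum(1 for label in arch.code if label in {"B1", "B2"})
    return (
        1 if n_bbox > 2 else 0,
        1 if n_bbox >= 2 else 0,
        1 if "CCT" in arch.code else 0,
    )
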