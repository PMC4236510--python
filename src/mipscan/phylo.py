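"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap support,
majority-rule collapse and reference-guided clade labeling.

Trees are unrooted; internally they are stored rooted at the final
trifurcation produced by neighbor joining. Branch support is a percentage in
[0, 100] attached to internal edges (the edge above each non-root internal
node of the rooted representation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from mipscan.io_core import ProteinSequence

GAP = ord("-")


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: List[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise PhyloError("distance matrix has non-finite entries")
        if np.any(self.d < -1e-12):
            raise PhyloError("distance matrix has negative entries")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise PhyloError("distance matrix diagonal is not zero")


def p_distance_matrix(seqs: Sequence[ProteinSequence], **align_kwargs) -> DistanceMatrix:
    """d[i][j] = 1 - identity(i, j) from pairwise global alignments."""
    from mipscan.anchor_align import global_align

    if len(seqs) < 3:
        raise PhyloError("p_distance_matrix requires at least 3 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], **align_kwargs)
            d[i, j] = d[j, i] = 1.0 - aln.identity
    return DistanceMatrix(labels=[s.id for s in seqs], d=d)


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0  # branch length to parent
    support: Optional[float] = None  # bootstrap % for the edge to parent
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> FrozenSet[str]:
        if self.is_leaf:
            return frozenset([self.name])
        out: set = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.add(node.name)
            else:
                stack.extend(node.children)
        return frozenset(out)


@dataclass
class Tree:
    """Unrooted tree held at an arbitrary (trifurcating) root."""

    root: TreeNode

    def leaves(self) -> List[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> List[TreeNode]:
        """Non-root internal nodes; each defines one internal edge/bipartition."""
        out = []
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def bipartitions(self) -> Dict[FrozenSet[str], Optional[float]]:
        """Map each non-trivial bipartition (side away from root) to its support."""
        all_names = frozenset(self.leaf_names())
        out: Dict[FrozenSet[str], Optional[float]] = {}
        for node in self.internal_edges():
            side = node.leaf_names()
            if 1 < len(side) < len(all_names):
                out[side] = node.support
        return out

    # -- newick -----------------------------------------------------------
    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.4g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @staticmethod
    def from_newick(text: str) -> "Tree":
        text = text.strip()
        if not text.endswith(";"):
            raise PhyloError("newick string must end with ';'")
        pos = 0

        def parse_node() -> TreeNode:
            nonlocal pos
            node = TreeNode()
            if text[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse_node())
                    if text[pos] == ",":
                        pos += 1
                        continue
                    if text[pos] == ")":
                        pos += 1
                        break
                label = _read_token()
                if label:
                    node.support = float(label)
            else:
                node.name = _read_token()
            if pos < len(text) and text[pos] == ":":
                pos += 1
                node.length = float(_read_token())
            return node

        def _read_token() -> str:
            nonlocal pos
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            return text[start:pos]

        root = parse_node()
        if text[pos] != ";":
            raise PhyloError(f"unexpected character at {pos}: {text[pos]!r}")
        return Tree(root=root)

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(
                name=node.name,
                length=node.length,
                support=node.support,
                children=[clone(c) for c in node.children],
            )

        return Tree(root=clone(self.root))

    def path_length_matrix(self) -> Tuple[List[str], np.ndarray]:
        """Pairwise leaf-to-leaf path lengths (for additivity checks)."""
        leaf_list = self.leaf_names()
        idx = {name: i for i, name in enumerate(leaf_list)}
        n = len(leaf_list)
        mat = np.zeros((n, n))

        def collect(node: TreeNode) -> Dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            maps = []
            for child in node.children:
                cmap = collect(child)
                maps.append({k: v + child.length for k, v in cmap.items()})
            for i in range(len(maps)):
                for j in range(i + 1, len(maps)):
                    for a, da in maps[i].items():
                        for b, db in maps[j].items():
                            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = da + db
            merged = {}
            for m in maps:
                merged.update(m)
            return merged

        collect(self.root)
        return leaf_list, mat


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break to the lowest (i, j) index pair; negative
    branch lengths are clamped to zero with a warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbor_joining requires at least 3 labels")
    d = dm.d.copy()
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0.0:
            if x < -1e-9:
                warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major -> lowest (i, j) on ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the remaining ones
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        new_index = d.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    root = TreeNode()
    nodes[i].length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root.children = [nodes[i], nodes[j], nodes[k]]
    return Tree(root=root)


# ---------------------------------------------------------------------------
# pseudo-alignment utilities

@dataclass
class PseudoAlignment:
    """Anchor-projected alignment: one row per sequence, fixed column count."""

    labels: List[str]
    matrix: np.ndarray  # uint8, GAP for gaps

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @staticmethod
    def from_strings(labels: Sequence[str], rows: Sequence[str]) -> "PseudoAlignment":
        if len({len(r) for r in rows}) > 1:
            raise PhyloError("pseudo-alignment rows must have equal length")
        mat = np.array([[ord(c) for c in row] for row in rows], dtype=np.uint8)
        return PseudoAlignment(labels=list(labels), matrix=mat)

    def p_distances(self, columns: Optional[np.ndarray] = None) -> DistanceMatrix:
        mat = self.matrix if columns is None else self.matrix[:, columns]
        nongap = mat != GAP
        valid = nongap[:, None, :] & nongap[None, :, :]
        diff = (mat[:, None, :] != mat[None, :, :]) & valid
        nvalid = valid.sum(axis=2)
        ndiff = diff.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(nvalid > 0, ndiff / np.maximum(nvalid, 1), 1.0)
        np.fill_diagonal(d, 0.0)
        d = 0.5 * (d + d.T)
        return DistanceMatrix(labels=list(self.labels), d=d)


def project_to_anchor(seqs: Sequence[ProteinSequence], refs) -> PseudoAlignment:
    """Project each sequence onto its best anchor's coordinate frame.

    All anchors must share a common length; columns are anchor positions,
    query insertions are dropped, unmapped columns become gaps.
    """
    from mipscan.anchor_align import choose_reference, map_positions

    lengths = {len(r.sequence.residues) for r in refs}
    if len(lengths) != 1:
        raise PhyloError("anchor projection requires references of equal length")
    ncol = lengths.pop()
    rows = []
    for seq in seqs:
        ref, aln = choose_reference(seq, refs)
        mapped = map_positions(aln, list(range(ncol)))
        rows.append("".join(seq.residues[i] if i is not None else "-" for i in mapped))
    return PseudoAlignment.from_strings([s.id for s in seqs], rows)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    alignment: PseudoAlignment,
    n_reps: int = 1000,
    seed: int = 0,
) -> Tree:
    """NJ tree from the full alignment, with bootstrap supports on internal edges.

    Replicates resample columns with replacement; support is the percentage of
    replicates whose NJ tree contains each reference bipartition. Reproducible
    for a fixed seed.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    if len(alignment.labels) < 4:
        raise PhyloError("bootstrap_support requires at least 4 sequences")
    rng = np.random.default_rng(seed)
    ref_tree = neighbor_joining(alignment.p_distances())
    ref_bips = {b for b in ref_tree.bipartitions()}
    # normalize away root-side ambiguity: key each split by the side holding label[0]
    all_names = frozenset(alignment.labels)
    anchor_label = alignment.labels[0]

    def norm(b: FrozenSet[str]) -> FrozenSet[str]:
        return b if anchor_label in b else all_names - b

    counts = {norm(b): 0 for b in ref_bips}
    ncol = alignment.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = neighbor_joining(alignment.p_distances(columns=cols))
        rep_bips = {norm(b) for b in rep_tree.bipartitions()}
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
    for node in ref_tree.internal_edges():
        side = node.leaf_names()
        if 1 < len(side) < len(all_names):
            node.support = 100.0 * counts[norm(side)] / n_reps
    return ref_tree


# ---------------------------------------------------------------------------
# consensus / collapse

def majority_rule_collapse(tree: Tree, threshold: float = 50.0) -> Tree:
    """Contract internal edges with support below ``threshold`` into polytomies."""
    out = tree.copy()

    def walk(node: TreeNode) -> None:
        new_children: List[TreeNode] = []
        for child in node.children:
            walk(child)
            collapse = (
                not child.is_leaf
                and child.support is not None
                and child.support < threshold
            )
            if collapse:
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    walk(out.root)
    return out


# ---------------------------------------------------------------------------
# clade labeling

def assign_clades(
    tree: Tree,
    labeled_refs: Dict[str, str],
    support_threshold: float = 50.0,
) -> Dict[str, str]:
    """Label each unlabeled leaf from the smallest well-supported unanimous clade.

    Candidate clades for a leaf are the bipartition sides containing it (both
    sides of every internal edge, so clades straddling the arbitrary root are
    still usable; edges with support below ``support_threshold`` are ignored,
    edges without support are trusted). Among the smallest candidates holding
    at least one labeled reference, the labeled members must be unanimous and
    all such candidates must agree on one label; otherwise 'unclassified'.
    """
    leaf_names = tree.leaf_names()
    present_refs = {k: v for k, v in labeled_refs.items() if k in set(leaf_names)}
    if not present_refs:
        raise PhyloError("assign_clades requires at least one labeled reference leaf")
    all_names = frozenset(leaf_names)
    sides: List[FrozenSet[str]] = []
    for node in tree.internal_edges():
        if node.support is not None and node.support < support_threshold:
            continue
        s = node.leaf_names()
        if 1 < len(s) < len(all_names):
            sides.append(s)
            sides.append(all_names - s)
    out: Dict[str, str] = {}
    for leaf in leaf_names:
        if leaf in present_refs:
            out[leaf] = present_refs[leaf]
            continue
        candidates = [
            s for s in sides
            if leaf in s and any(r in present_refs for r in s)
        ]
        if not candidates:
            out[leaf] = "unclassified"
            continue
        min_size = min(len(s) for s in candidates)
        labels = set()
        for s in candidates:
            if len(s) == min_size:
                labels.update({present_refs[r] for r in s if r in present_refs})
        out[leaf] = labels.pop() if len(labels) == 1 else "unclassified"
    return out
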