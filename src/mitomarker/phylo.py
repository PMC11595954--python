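"""Distance matrices, neighbor joining, newick I/O and Robinson-Foulds comparison.

The tree machinery is implemented natively: Saitou-Nei neighbor joining
with deterministic tie-breaking, unrooted Robinson-Foulds distance via
bipartition sets, and a small newick reader/writer. Trees are compared
unrooted throughout; the p-distance (optionally Jukes-Cantor corrected)
is the distance model, appropriate at the within-genus divergences this
pipeline targets.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from mitomarker.align_variants import GAP, MultipleAlignment
from mitomarker.errors import AlignmentError, TreeError


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over ordered taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise TreeError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise TreeError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise TreeError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12) or not np.all(np.isfinite(self.values)):
            raise TreeError("distances must be finite and nonnegative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary internal root.

    Leaf labels are unique. Comparison and reporting treat the tree as
    unrooted: bipartitions are read off edges, and a degree-2 root
    (a rooted binary reading) is suppressed.
    """

    root: TreeNode

    def __post_init__(self):
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf labels")

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        n = len(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                side = all_leaves - below if anchor in below else below
                if 2 <= len(side) <= n - 2:
                    parts.add(side)
            return below

        walk(self.root)
        return parts

    def newick(self, precision: int = 6) -> str:
        return newick_write(self, precision)


def _quote_label(name: str) -> str:
    if re.search(r"[\s(),:;'\[\]]", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def newick_write(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize to newick; branch lengths rendered to ``precision`` decimals."""

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf():
            body = _quote_label(node.name or "")
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.name:
                body += _quote_label(node.name)
        if top:
            return body
        return f"{body}:{node.length:.{precision}f}"

    return fmt(tree.root, True) + ";"


class _NewickParser:
    def __init__(self, text: str):
        self.text = text.strip()
        self.pos = 0

    def error(self, msg: str):
        raise TreeError(f"newick parse error at position {self.pos}: {msg}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> TreeNode:
        node = self.parse_node()
        if self.peek() != ";":
            self.error("expected ';'")
        self.pos += 1
        if self.text[self.pos :].strip():
            self.error("trailing characters after ';'")
        return node

    def parse_node(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            node.children.append(self.parse_node())
            while self.peek() == ",":
                self.pos += 1
                node.children.append(self.parse_node())
            if self.peek() != ")":
                self.error("unbalanced parentheses")
            self.pos += 1
        name = self.parse_label()
        if name:
            node.name = name
        if self.peek() == ":":
            self.pos += 1
            node.length = self.parse_number()
        return node

    def parse_label(self) -> str:
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    self.error("unterminated quoted label")
                c = self.text[self.pos]
                if c == "'":
                    if self.text[self.pos : self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(c)
                self.pos += 1
            return "".join(out)
        m = re.match(r"[^\s(),:;\[\]]+", self.text[self.pos :])
        if not m:
            return ""
        self.pos += m.end()
        return m.group()

    def parse_number(self) -> float:
        m = re.match(r"[-+0-9.eE]+", self.text[self.pos :])
        if not m:
            self.error("expected branch length")
        self.pos += m.end()
        try:
            return float(m.group())
        except ValueError:
            self.error(f"bad branch length {m.group()!r}")


def newick_read(text: str) -> PhyloTree:
    """Parse a newick string into a PhyloTree."""
    if ";" not in text:
        raise TreeError("newick string must end with ';'")
    return PhyloTree(root=_NewickParser(text).parse())


def p_distance_matrix(
    alignment: MultipleAlignment,
    gap_mode: str = "pairwise_deletion",
    model: str = "p",
) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    p-distance = mismatching comparable columns / comparable columns, where
    a column is comparable for a pair when both rows carry an unambiguous
    base (complete_deletion instead drops every column containing any gap
    or N). model "jc" applies the Jukes-Cantor correction
    d = -(3/4) ln(1 - 4p/3).
    """
    if gap_mode not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    if model not in ("p", "jc"):
        raise ValueError(f"unknown model {model!r}")
    n = len(alignment.taxa)
    if n < 2:
        raise AlignmentError("need at least 2 taxa")
    arr = np.array([list(r) for r in alignment.rows])
    ok = (arr != GAP) & (arr != "N")
    if gap_mode == "complete_deletion":
        keep = ok.all(axis=0)
        arr, ok = arr[:, keep], ok[:, keep]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            total = int(comparable.sum())
            if total == 0:
                raise AlignmentError(
                    f"no comparable columns between {alignment.taxa[i]} and {alignment.taxa[j]}"
                )
            p = float(np.sum(arr[i, comparable] != arr[j, comparable])) / total
            if model == "jc":
                if p >= 0.75:
                    raise AlignmentError(
                        f"p-distance {p:.3f} saturates the Jukes-Cantor correction "
                        f"({alignment.taxa[i]} vs {alignment.taxa[j]})"
                    )
                p = -0.75 * math.log(1 - 4 * p / 3)
            D[i, j] = D[j, i] = p
    return DistanceMatrix(taxa=list(alignment.taxa), values=D)


def _zero_components(taxa: list[str], D: dict[tuple[str, str], float]) -> list[list[str]]:
    """Connected components of the zero-distance relation, label-sorted."""
    parent = {t: t for t in taxa}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            if D[(a, b)] < 1e-12:
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for t in taxa:
        comps.setdefault(find(t), []).append(t)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Zero-distance taxa (identical sequences) are coalesced first into a
    label-ordered caterpillar with zero-length branches, so their
    resolution never depends on the surrounding matrix -- different genes
    with the same identity pattern yield identical subtrees. The NJ loop
    then runs on the distinct clusters; on equal Q values the join with
    the lexicographically smallest (canonical-label) pair wins; negative
    branch-length estimates are clamped to zero. The final three nodes
    are resolved in closed form, leaving a degree-3 internal root (a
    properly unrooted tree).
    """
    n = len(dm.taxa)
    if n < 3:
        raise TreeError(f"neighbor joining needs >= 3 taxa, got {n}")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    # canonical label for tie-breaking: smallest leaf name under the node
    canon: dict[str, str] = {t: t for t in dm.taxa}
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dm.taxa):
        for j, b in enumerate(dm.taxa):
            if i < j:
                D[(a, b)] = D[(b, a)] = float(dm.values[i, j])
    active = list(dm.taxa)
    counter = 0
    # pre-coalesce identical taxa (kept as distinct zero-length leaves)
    components = _zero_components(active, D)
    for comp in components:
        if len(comp) == 1:
            continue
        rep = comp[0]
        joined = nodes[rep]
        for member in comp[1:]:
            nodes[member].length = 0.0
            joined.length = 0.0
            joined = TreeNode(children=[joined, nodes[member]])
        cluster_id = f"__zc{counter}"
        counter += 1
        nodes[cluster_id] = joined
        canon[cluster_id] = rep
        for other in active:
            if other not in comp:
                # members are equidistant to outsiders up to noise; the
                # representative's row keeps this deterministic
                D[(cluster_id, other)] = D[(other, cluster_id)] = D[(rep, other)]
        active = [t for t in active if t not in comp] + [cluster_id]
        active.sort(key=lambda t: canon[t])
    if len(active) == 1:
        return PhyloTree(root=nodes[active[0]])
    if len(active) == 2:
        a, b = sorted(active, key=lambda t: canon[t])
        d = D[(a, b)]
        nodes[a].length = nodes[b].length = max(d / 2, 0.0)
        return PhyloTree(root=TreeNode(children=[nodes[a], nodes[b]]))
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ia in range(r):
            for ib in range(ia + 1, r):
                a, b = active[ia], active[ib]
                q = (r - 2) * D[(a, b)] - totals[a] - totals[b]
                pair_key = tuple(sorted((canon[a], canon[b])))
                cand = (q, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        dab = D[(a, b)]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        nodes[a].length, nodes[b].length = la, lb
        new_id = f"__nj{counter}"
        counter += 1
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[new_id] = parent
        canon[new_id] = min(canon[a], canon[b])
        for c in active:
            if c in (a, b):
                continue
            D[(new_id, c)] = D[(c, new_id)] = 0.5 * (D[(a, c)] + D[(b, c)] - dab)
        active = [c for c in active if c not in (a, b)] + [new_id]
    x, y, z = sorted(active, key=lambda t: canon[t])
    dxy, dxz, dyz = D[(x, y)], D[(x, z)], D[(y, z)]
    nodes[x].length = max(0.5 * (dxy + dxz - dyz), 0.0)
    nodes[y].length = max(0.5 * (dxy + dyz - dxz), 0.0)
    nodes[z].length = max(0.5 * (dxz + dyz - dxy), 0.0)
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return PhyloTree(root=root)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalized form.

    The integer is the size of the symmetric difference of nontrivial
    bipartition sets; the normalized form divides by 2(n-3), the maximum
    for binary trees on n leaves (0.0 when n <= 3).
    """
    s1, s2 = set(t1.leaf_names()), set(t2.leaf_names())
    if s1 != s2:
        only1, only2 = sorted(s1 - s2), sorted(s2 - s1)
        raise TreeError(f"leaf sets differ: only in first {only1}, only in second {only2}")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    rf = len(b1 ^ b2)
    n = len(s1)
    norm = rf / (2 * (n - 3)) if n > 3 else 0.0
    return rf, norm


def concat_alignment(
    per_gene_msas: list[MultipleAlignment],
    block_names: list[str] | None = None,
) -> MultipleAlignment:
    """Column-wise concatenation of per-gene alignments over identical taxa.

    No silent gap-filling: a taxon missing from any block is an error.
    Per-block provenance is kept in ``blocks``.
    """
    if not per_gene_msas:
        raise AlignmentError("no alignments to concatenate")
    taxa = list(per_gene_msas[0].taxa)
    names = block_names or [f"block{i + 1}" for i in range(len(per_gene_msas))]
    if len(names) != len(per_gene_msas):
        raise AlignmentError("block_names length mismatch")
    rows = {t: [] for t in taxa}
    blocks = []
    for name, msa_block in zip(names, per_gene_msas):
        missing = set(taxa) ^ set(msa_block.taxa)
        if missing:
            raise AlignmentError(f"block {name}: taxon set mismatch: {sorted(missing)}")
        for t in taxa:
            rows[t].append(msa_block.row(t))
        blocks.append((name, msa_block.width))
    return MultipleAlignment(
        taxa=taxa, rows=["".join(rows[t]) for t in taxa], blocks=blocks
    )


def write_phylip_matrix(dm: DistanceMatrix) -> str:
    """PHYLIP-style square distance matrix text."""
    lines = [f"{len(dm.taxa)}"]
    for i, t in enumerate(dm.taxa):
        vals = " ".join(f"{v:.6f}" for v in dm.values[i])
        lines.append(f"{t}  {vals}")
    return "\n".join(lines) + "\n"
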