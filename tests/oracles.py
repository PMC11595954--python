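"""Independent reference implementations used only to check the package."""

from functools import lru_cache


def brute_force_align_score(a, b, match=1.0, mismatch=-2.0, gap_open=-2.0, gap_extend=-1.0):
    """Optimal global alignment score by top-down recursion over the three
    possible final columns, memoized on (i, j, previous-column state).

    Independent of the production implementation: no numpy, no vectorized
    sweep, affine gaps tracked through an explicit state argument. A gap
    run of length L costs gap_open + (L - 1) * gap_extend.
    """

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # best score aligning a[:i] with b[:j] with the LAST column of type
        # `state`: 0 = substitution column, 1 = a-over-gap, 2 = gap-over-b
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        if state == 0:
            if i == 0 or j == 0:
                return NEG
            s = match if a[i - 1] == b[j - 1] else mismatch
            return s + max(best(i - 1, j - 1, p) for p in (0, 1, 2))
        if state == 1:
            if i == 0:
                return NEG
            return max(
                best(i - 1, j, 1) + gap_extend,
                best(i - 1, j, 0) + gap_open,
                best(i - 1, j, 2) + gap_open,
            )
        if j == 0:
            return NEG
        return max(
            best(i, j - 1, 2) + gap_extend,
            best(i, j - 1, 0) + gap_open,
            best(i, j - 1, 1) + gap_open,
        )

    return max(best(len(a), len(b), s) for s in (0, 1, 2))


def enumerate_alignment_scores(a, b, match=1.0, mismatch=-2.0, gap_open=-2.0, gap_extend=-1.0):
    """Exhaustively enumerate every global alignment and yield its score.

    Pure path enumeration with run-aware scoring; exponential, for tiny
    inputs only. Used to validate the memoized oracle itself.
    """

    def walk(i, j, last):
        if i == len(a) and j == len(b):
            yield 0.0
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            for rest in walk(i + 1, j + 1, 0):
                yield s + rest
        if i < len(a):
            cost = gap_extend if last == 1 else gap_open
            for rest in walk(i + 1, j, 1):
                yield cost + rest
        if j < len(b):
            cost = gap_extend if last == 2 else gap_open
            for rest in walk(i, j + 1, 2):
                yield cost + rest

    return walk(0, 0, 0)


def tree_splits_by_connectivity(adjacency, leaves):
    """All nontrivial splits of an unrooted tree by brute-force subset testing.

    A leaf subset S is a split iff both S and its complement induce
    connected subgraphs after deleting a single edge -- equivalently, iff
    there is an edge whose removal separates exactly S from the rest. We
    test every subset directly: S is a split iff the minimal spanning
    subtree of S and that of its complement are node-disjoint.
    """
    from itertools import combinations

    leaves = sorted(leaves)
    n = len(leaves)
    anchor = leaves[0]

    def steiner_nodes(subset):
        # nodes on paths between members of subset
        subset = set(subset)
        nodes = set()
        start = next(iter(subset))
        for target in subset:
            path = _path(adjacency, start, target)
            nodes.update(path)
        # take union of pairwise paths for correctness on small trees
        for u, v in combinations(subset, 2):
            nodes.update(_path(adjacency, u, v))
        return nodes

    splits = set()
    for k in range(2, n - 1):
        for combo in combinations(leaves, k):
            s = set(combo)
            comp = set(leaves) - s
            if anchor in s:
                s, comp = comp, s
            if len(s) < 2 or len(comp) < 2:
                continue
            if steiner_nodes(s) & steiner_nodes(comp):
                continue
            splits.add(frozenset(s))
    return splits


def _path(adjacency, u, v):
    prev = {u: None}
    stack = [u]
    while stack:
        x = stack.pop()
        if x == v:
            break
        for y in adjacency[x]:
            if y not in prev:
                prev[y] = x
                stack.append(y)
    path = []
    x = v
    while x is not None:
        path.append(x)
        x = prev[x]
    return path


def enumerate_unrooted_topologies(labels):
    """Every unrooted binary topology on the labels, as adjacency dicts.

    Built by the classic edge-insertion recursion: the tree on 3 leaves is
    unique; each further leaf is attached to the middle of every existing
    edge in turn.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    base = {labels[0]: ["x0"], labels[1]: ["x0"], labels[2]: ["x0"],
            "x0": [labels[0], labels[1], labels[2]]}
    trees = [base]
    for idx, leaf in enumerate(labels[3:], start=1):
        new_trees = []
        for adj in trees:
            edges = {tuple(sorted((u, v))) for u in adj for v in adj[u]}
            for u, v in sorted(edges):
                new = {k: list(vs) for k, vs in adj.items()}
                mid = f"x{idx}_{u}_{v}"
                new[u] = [mid if w == v else w for w in new[u]]
                new[v] = [mid if w == u else w for w in new[v]]
                new[mid] = [u, v, leaf]
                new[leaf] = [mid]
                new_trees.append(new)
        trees = new_trees
    return trees


def adjacency_to_newick(adjacency, leaves):
    """Serialize an adjacency-dict tree rooted at an internal node."""
    leaves = set(leaves)
    root = next(n for n in sorted(adjacency) if n not in leaves)

    def render(node, parent):
        kids = [x for x in adjacency[node] if x != parent]
        if not kids:
            return node
        return "(" + ",".join(render(k, node) for k in kids) + ")"

    return render(root, None) + ";"
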