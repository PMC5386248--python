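"""Distance-based phylogenetics: Poisson-corrected amino-acid distances,
neighbor joining with bootstrap supports, clade-based group assignment,
and a minimal progressive aligner for synthetic sequence sets.

Distances are in substitutions per site. The p-distance between two gapped
rows is the fraction of differing compared columns; under the default
pairwise-deletion policy a column is compared only if neither row has a gap
there. The Poisson correction ``d = -ln(1 - p)`` accounts for multiple
substitutions at a site under a Poisson substitution process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import (
    GroupAssignmentError,
    NoComparableColumnsError,
    SaturationError,
    TreeError,
)
from .io_formats import GAP, Msa

GAP_POLICIES = ("pairwise_deletion", "complete_deletion")


@dataclass
class DistanceMatrix:
    """A symmetric matrix of pairwise distances with row/column labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise TreeError(
                f"distance matrix shape {self.d.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.d, self.d.T):
            raise TreeError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise TreeError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise TreeError("distances must be finite and non-negative")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites among pairwise-compared columns.

    Columns where either row carries a gap are skipped (pairwise deletion).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    compared = 0
    diffs = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a == GAP or b == GAP:
            continue
        compared += 1
        if a != b:
            diffs += 1
    if compared == 0:
        raise NoComparableColumnsError(
            "no comparable columns between the two rows"
        )
    return diffs / compared


def poisson_correct(p: float, epsilon: float = 1e-9) -> float:
    """Poisson-corrected distance ``d = -ln(1 - p)`` for a p-distance."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= 1.0 - epsilon:
        raise SaturationError(
            f"p-distance {p} is saturated (>= 1 - {epsilon}); the Poisson "
            "correction diverges"
        )
    return -math.log1p(-p)


def distance_matrix(
    msa: Msa, gap_policy: str = "pairwise_deletion", epsilon: float = 1e-9
) -> DistanceMatrix:
    """All-pairs Poisson-corrected distances for an alignment."""
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    enc = np.array([list(r) for r in msa.rows], dtype="U1")
    gaps = enc == GAP
    if gap_policy == "complete_deletion":
        keep = ~gaps.any(axis=0)
        if not keep.any():
            raise NoComparableColumnsError(
                "complete deletion removed every column"
            )
        enc = enc[:, keep]
        gaps = gaps[:, keep]
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            compared = int(ok.sum())
            if compared == 0:
                raise NoComparableColumnsError(
                    f"no comparable columns between rows "
                    f"{msa.sequence_ids[i]!r} and {msa.sequence_ids[j]!r}"
                )
            p = float((enc[i, ok] != enc[j, ok]).sum()) / compared
            d[i, j] = d[j, i] = poisson_correct(p, epsilon)
    return DistanceMatrix(list(msa.sequence_ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Returns an unrooted tree represented with a trifurcating seed node.
    Negative branch-length estimates are clamped to 0 (the deficit is not
    redistributed). Ties in the Q criterion are broken deterministically by
    the smallest (i, j) index pair after sorting labels alphabetically.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise TreeError("neighbor joining needs at least 3 labels")
    order = sorted(range(n0), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].copy()

    taxon_namespace = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(lab))
        nodes.append(node)
    active = list(range(n0))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: smallest Q, then smallest (i, j)
        best = np.unravel_index(np.argmin(q), q.shape)
        qmin = q[best]
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        ii, jj = min((min(a, b), max(a, b)) for a, b in ties)
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to the remaining ones
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d[i, active] = new_row
        d[active, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    seed = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=seed)
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial unrooted bipartitions as {side, complement} label sets."""
    all_leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )
    splits: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset({side, all_leaves - side}))
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted RF distance via symmetric difference of bipartition sets."""
    return len(tree_bipartitions(t1) ^ tree_bipartitions(t2))


def bootstrap_support(
    msa: Msa,
    n_replicates: int,
    seed: int,
    gap_policy: str = "pairwise_deletion",
) -> dendropy.Tree:
    """NJ tree of the alignment with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; the support of a
    bipartition is the fraction of replicate NJ trees containing it. Supports
    are stored both as internal-node labels and as ``node.support`` floats.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = neighbor_joining(distance_matrix(msa, gap_policy))
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    counts: dict[frozenset[frozenset[str]], int] = {}
    rows = np.array([list(r) for r in msa.rows], dtype="U1")
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row) for row in rows[:, cols]]
        rep_msa = Msa(list(msa.sequence_ids), rep_rows)
        try:
            rep_tree = neighbor_joining(distance_matrix(rep_msa, gap_policy))
        except NoComparableColumnsError:
            continue
        for split in tree_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (1 < len(side) < len(all_leaves) - 1):
            continue
        split = frozenset({side, all_leaves - side})
        support = counts.get(split, 0) / n_replicates
        node.support = support
        node.label = f"{support:g}"
    return tree


def supports_by_clade(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Map each supported internal node's leaf set to its bootstrap support."""
    out = {}
    for node in tree.preorder_node_iter():
        if getattr(node, "support", None) is not None:
            out[frozenset(lf.taxon.label for lf in node.leaf_iter())] = (
                node.support
            )
    return out


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------

def _undirected_adjacency(tree: dendropy.Tree):
    """node -> list of (neighbour, length, edge-of-the-rooted-tree)."""
    adj: dict[int, list] = {}
    nodes = {id(n): n for n in tree.preorder_node_iter()}
    for node in nodes.values():
        adj.setdefault(id(node), [])
    for node in nodes.values():
        p = node.parent_node
        if p is None:
            continue
        length = node.edge.length or 0.0
        adj[id(node)].append((p, length, node.edge))
        adj[id(p)].append((node, length, node.edge))
    return nodes, adj


def _farthest_leaf(tree, adj, start):
    """(leaf, distance, predecessor map) via Dijkstra-style traversal."""
    import heapq

    dist = {id(start): 0.0}
    pred: dict[int, tuple] = {}
    heap = [(0.0, 0, start)]
    counter = 1
    while heap:
        d, _, node = heapq.heappop(heap)
        if d > dist.get(id(node), math.inf):
            continue
        for nb, length, edge in adj[id(node)]:
            nd = d + length
            if nd < dist.get(id(nb), math.inf):
                dist[id(nb)] = nd
                pred[id(nb)] = (node, edge, length)
                heapq.heappush(heap, (nd, counter, nb))
                counter += 1
    leaves = [(dist[id(lf)], lf.taxon.label, lf)
              for lf in tree.leaf_node_iter() if id(lf) in dist]
    best = max(leaves, key=lambda t: (t[0], [-ord(c) for c in t[1]]))
    return best[2], best[0], pred


def _midpoint_reroot(tree: dendropy.Tree) -> None:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Unlike node-snapping midpoint implementations, the root is always
    placed ON an edge of the path (deterministically the edge reached from
    the farthest end), so the two halves of the longest path are proper
    clades even when the midpoint coincides with an internal node.
    """
    nodes, adj = _undirected_adjacency(tree)
    some_leaf = next(tree.leaf_node_iter())
    u, _, _ = _farthest_leaf(tree, adj, some_leaf)
    v, diameter, pred = _farthest_leaf(tree, adj, u)
    if diameter <= 0:
        return
    # path from v back to u via predecessors
    path = []  # (edge, length) walking from u towards v
    node = v
    while id(node) in pred:
        prev, edge, length = pred[id(node)]
        path.append((edge, length))
        node = prev
    path.reverse()  # now ordered u -> v
    target = diameter / 2.0
    cum = 0.0
    for edge, length in path:
        if cum + length >= target - 1e-12 and length > 0:
            # position within this edge measured from the u-side; only the
            # split matters downstream, the two part-lengths are cosmetic
            offset = min(max(target - cum, 0.0), length)
            tree.reroot_at_edge(
                edge,
                length1=length - offset,
                length2=offset,
                update_bipartitions=False,
            )
            return
        cum += length
    tree.reroot_at_midpoint(update_bipartitions=False)  # fallback

def assign_groups(
    tree: dendropy.Tree, seeds: Mapping[str, Iterable[str]]
) -> dict[str, str]:
    """Assign every leaf to a group via seed-anchored maximal clades.

    The tree is midpoint-rooted (on a clone); each group's clade is the
    largest clade containing all of that group's seed leaves and none of any
    other group's. Leaves outside every group clade map to ``"unassigned"``.
    """
    seeds = {g: list(v) for g, v in seeds.items()}
    seen: dict[str, str] = {}
    for g, leaves in seeds.items():
        if not leaves:
            raise GroupAssignmentError(f"group {g!r} has no seed leaves")
        for leaf in leaves:
            if leaf in seen:
                raise GroupAssignmentError(
                    f"leaf {leaf!r} is a seed of both {seen[leaf]!r} and {g!r}"
                )
            seen[leaf] = g
    work = tree.clone(depth=1)
    leaf_labels = {lf.taxon.label for lf in work.leaf_node_iter()}
    missing = set(seen) - leaf_labels
    if missing:
        raise GroupAssignmentError(f"seed leaves not in tree: {sorted(missing)}")
    if len(leaf_labels) > 2:
        _midpoint_reroot(work)

    def clade_leaves(node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    leaf_by_label = {
        lf.taxon.label: lf for lf in work.leaf_node_iter()
    }
    assignment = {label: "unassigned" for label in leaf_labels}
    for g, group_seeds in sorted(seeds.items()):
        foreign = {leaf for leaf, grp in seen.items() if grp != g}
        # MRCA by walking up from one seed until the clade covers them all
        # (robust to rerooting, no cached bipartitions involved)
        mrca = leaf_by_label[group_seeds[0]]
        want = set(group_seeds)
        while not want <= clade_leaves(mrca):
            mrca = mrca.parent_node
        if clade_leaves(mrca) & foreign:
            raise GroupAssignmentError(
                f"seeds of group {g!r} are intermixed with other groups' "
                "seeds; no clean clade exists"
            )
        node = mrca
        while (
            node.parent_node is not None
            and not (clade_leaves(node.parent_node) & foreign)
        ):
            node = node.parent_node
        for leaf in clade_leaves(node):
            assignment[leaf] = g
    return assignment


# ---------------------------------------------------------------------------
# Minimal progressive aligner (synthetic sets only)
# ---------------------------------------------------------------------------

MATCH, MISMATCH = 1.0, -1.0


def _nw_align(
    a: Sequence[str], b: Sequence[str], gap_open: float, gap_extend: float,
    score,
):
    """Global Needleman–Wunsch with affine gaps over arbitrary 'columns'.

    Returns the aligned index lists (None marks a gap).
    """
    la, lb = len(a), len(b)
    neg = -math.inf
    # three-state affine DP: M (match), X (gap in b), Y (gap in a),
    # with explicit backpointers (0=M, 1=X, 2=Y) for a deterministic traceback
    m = np.full((la + 1, lb + 1), neg)
    x = np.full((la + 1, lb + 1), neg)
    y = np.full((la + 1, lb + 1), neg)
    bm = np.zeros((la + 1, lb + 1), dtype=np.int8)
    bx = np.zeros((la + 1, lb + 1), dtype=np.int8)
    by = np.zeros((la + 1, lb + 1), dtype=np.int8)
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        x[i, 0] = gap_open + (i - 1) * gap_extend
        bx[i, 0] = 1
    for j in range(1, lb + 1):
        y[0, j] = gap_open + (j - 1) * gap_extend
        by[0, j] = 2
    bx[1, 0] = 0
    by[0, 1] = 0

    def _argmax3(t0, t1, t2):
        if t0 >= t1 and t0 >= t2:
            return t0, 0
        if t1 >= t2:
            return t1, 1
        return t2, 2

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score(a[i - 1], b[j - 1])
            m[i, j], bm[i, j] = _argmax3(
                m[i - 1, j - 1] + s, x[i - 1, j - 1] + s, y[i - 1, j - 1] + s
            )
            x[i, j], bx[i, j] = _argmax3(
                m[i - 1, j] + gap_open, x[i - 1, j] + gap_extend,
                y[i - 1, j] + gap_open,
            )
            y[i, j], by[i, j] = _argmax3(
                m[i, j - 1] + gap_open, x[i, j - 1] + gap_open,
                y[i, j - 1] + gap_extend,
            )
    out_a: list[int | None] = []
    out_b: list[int | None] = []
    i, j = la, lb
    _, state = _argmax3(m[i, j], x[i, j], y[i, j])
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(i - 1)
            out_b.append(j - 1)
            state = int(bm[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(i - 1)
            out_b.append(None)
            state = int(bx[i, j])
            i -= 1
        else:
            out_a.append(None)
            out_b.append(j - 1)
            state = int(by[i, j])
            j -= 1
    out_a.reverse()
    out_b.reverse()
    return out_a, out_b


def _char_score(a: str, b: str) -> float:
    return MATCH if a == b else MISMATCH


def pairwise_identity(seq_a: str, seq_b: str, gap_open: float = -2.0,
                      gap_extend: float = -2.0) -> float:
    """Fraction of identical residue pairs among aligned (non-gap) columns."""
    ia, ib = _nw_align(seq_a, seq_b, gap_open, gap_extend, _char_score)
    matches = aligned = 0
    for x, y in zip(ia, ib):
        if x is not None and y is not None:
            aligned += 1
            if seq_a[x] == seq_b[y]:
                matches += 1
    return matches / aligned if aligned else 0.0


def _profile_score(col_a: tuple[str, ...], col_b: tuple[str, ...]) -> float:
    total = 0.0
    pairs = 0
    for ca in col_a:
        for cb in col_b:
            if ca == GAP or cb == GAP:
                continue
            total += MATCH if ca == cb else MISMATCH
            pairs += 1
    return total / pairs if pairs else 0.0


def progressive_align(
    records: list[tuple[str, str]],
    gap_open: float = -2.0,
    gap_extend: float = -2.0,
) -> Msa:
    """Progressive MSA: UPGMA guide tree on NW identities, profile-profile
    Needleman–Wunsch merges. Deterministic; intended for synthetic sets.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    if not records:
        raise ValueError("no records to align")
    ids = [r[0] for r in records]
    seqs = [r[1].upper() for r in records]
    n = len(records)
    if n == 1:
        return Msa(ids, seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - pairwise_identity(
                seqs[i], seqs[j], gap_open, gap_extend
            )
    link = linkage(squareform(dist, checks=False), method="average")

    # profile: (member row-indices, list of columns); column = tuple of chars
    profiles: dict[int, tuple[list[int], list[tuple[str, ...]]]] = {
        i: ([i], [tuple(c) for c in seqs[i]]) for i in range(n)
    }
    for k, (a_id, b_id, *_rest) in enumerate(link):
        mem_a, cols_a = profiles.pop(int(a_id))
        mem_b, cols_b = profiles.pop(int(b_id))
        ia, ib = _nw_align(cols_a, cols_b, gap_open, gap_extend,
                           _profile_score)
        merged: list[tuple[str, ...]] = []
        gap_a = (GAP,) * len(mem_a)
        gap_b = (GAP,) * len(mem_b)
        for x, y in zip(ia, ib):
            left = cols_a[x] if x is not None else gap_a
            right = cols_b[y] if y is not None else gap_b
            merged.append(left + right)
        profiles[n + k] = (mem_a + mem_b, merged)
    (members, cols), = profiles.values()
    rows = ["" for _ in range(n)]
    for ridx, member in enumerate(members):
        rows[member] = "".join(col[ridx] for col in cols)
    return Msa(ids, rows)
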