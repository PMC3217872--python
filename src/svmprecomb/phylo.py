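"""Distance-based phylogenetics and domain-tree discordance.

Neighbor joining (Saitou-Nei Q-criterion) on p-distances, bootstrap support by
column resampling, domain-partitioned trees and an unweighted Robinson-Foulds
distance. The chimera flag is the domain-tree discordance signal: a sequence
whose catalytic-domain tree neighborhood belongs to a different SVMP class
than its disintegrin-domain neighborhood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import DomainBoundaries
from .msa import AA_GAP, NT_GAP, MultipleAlignment


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if (self.values < 0).any():
            raise ValueError("negative distances")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.support: float | None = None
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode | None" = None

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self


@dataclass
class Tree:
    """Unrooted tree stored with a trifurcating root; supports in [0, 100]."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def splits(self, with_support: bool = False):
        """Non-trivial bipartitions as canonical frozensets of leaf names.

        Each split is represented by the side *not* containing the
        lexicographically smallest leaf. With ``with_support`` returns a dict
        split -> support (None when unset).
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        n = len(all_leaves)
        result: dict[frozenset, float | None] = {}
        for node in self.root.postorder():
            if node is self.root or not node.children:
                continue
            clade = frozenset(leaf.name for leaf in node.leaves())
            if len(clade) < 2 or len(clade) > n - 2:
                continue
            side = clade if anchor not in clade else all_leaves - clade
            result[side] = node.support
        return result if with_support else set(result)

    def supported_clades(self, threshold: float):
        """Both sides of every internal edge with support >= threshold."""
        all_leaves = frozenset(self.leaf_names())
        n = len(all_leaves)
        clades: list[frozenset] = []
        for node in self.root.postorder():
            if node is self.root or not node.children:
                continue
            if node.support is None or node.support < threshold:
                continue
            clade = frozenset(leaf.name for leaf in node.leaves())
            if len(clade) < 2 or len(clade) > n - 2:
                continue
            clades.append(clade)
            clades.append(all_leaves - clade)
        return clades

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{int(round(node.support))}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


@dataclass
class DiscordanceReport:
    """Per-sequence domain-tree neighborhood classes and chimera flags."""

    neighbor_classes: dict[str, tuple[str | None, str | None]]
    concordant: dict[str, bool]
    rf_distance: int | None
    flagged: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def p_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    """Pairwise-deletion p-distances: 1 - identity/100 per pair."""
    if len(aln) < 2:
        raise ValueError("need >= 2 rows")
    gap = NT_GAP if aln.moltype == "nt" else AA_GAP
    e = aln.encoded
    nongap = e != gap
    n = len(aln)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counted = nongap[i] & nongap[j]
            c = int(counted.sum())
            if c == 0:
                raise ValueError(
                    f"no shared columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            mism = int((counted & (e[i] != e[j])).sum())
            values[i, j] = values[j, i] = mism / c
    return DistanceMatrix(list(aln.ids), values)


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) for a proportion p < 0.75."""
    if not (0 <= p < 0.75):
        raise ValueError(f"saturated or invalid proportion {p}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current working order. Negative branch lengths are clamped to zero
    with the deficit moved to the sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.ids]
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (Q[a, b], a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances from the new node
        new_row = 0.5 * (D[i, active] + D[j, active] - D[i, j])
        D[i, active] = new_row
        D[active, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # join the last three nodes at a trifurcating root
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _distances_from_columns(
    e: np.ndarray, nongap: np.ndarray, cols: np.ndarray
) -> np.ndarray | None:
    n = e.shape[0]
    sub = e[:, cols]
    ng = nongap[:, cols]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counted = ng[i] & ng[j]
            c = int(counted.sum())
            if c == 0:
                return None
            mism = int((counted & (sub[i] != sub[j])).sum())
            values[i, j] = values[j, i] = mism / c
    return values


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int,
    seed: int,
    region: tuple[int, int] | None = None,
) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    The point-estimate tree is built from all columns of ``region`` (default:
    whole alignment); each internal edge's support is the percentage of
    ``n_reps`` column-resampled NJ trees containing the same bipartition.
    Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    work = aln if region is None else aln.subalignment_columns(*region)
    point = nj_tree(p_distance_matrix(work))
    gap = NT_GAP if work.moltype == "nt" else AA_GAP
    e = work.encoded
    nongap = e != gap
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {split: 0 for split in point.splits()}
    effective = 0
    for _ in range(n_reps):
        cols = rng.integers(0, work.ncols, size=work.ncols)
        values = _distances_from_columns(e, nongap, cols)
        if values is None:
            continue  # replicate with an empty pair comparison: drop
        rep_tree = nj_tree(DistanceMatrix(list(work.ids), values))
        effective += 1
        for split in rep_tree.splits():
            if split in counts:
                counts[split] += 1
    denom = max(effective, 1)
    all_leaves = frozenset(point.leaf_names())
    anchor = min(all_leaves)
    nleaves = len(all_leaves)
    for node in point.root.postorder():
        if node is point.root or not node.children:
            continue
        clade = frozenset(leaf.name for leaf in node.leaves())
        if len(clade) < 2 or len(clade) > nleaves - 2:
            continue
        side = clade if anchor not in clade else all_leaves - clade
        node.support = 100.0 * counts[side] / denom
    return point


# ---------------------------------------------------------------------------
# Domain partitioning and tree comparison
# ---------------------------------------------------------------------------


def partition_domains(
    aa_aln: MultipleAlignment, boundaries: DomainBoundaries,
    min_coverage: float = 0.25,
) -> tuple[MultipleAlignment, MultipleAlignment]:
    """Split a protein alignment into catalytic and disintegrin partitions.

    Boundaries follow the column positions of the reference sequence's
    residues (e.g. 1-214 and 215-307). Rows whose non-gap residues cover
    less than ``min_coverage`` of a partition's columns (e.g. P-I sequences
    in the disintegrin partition, possibly with a few stray residues aligned
    into it) are dropped from that partition: distances estimated from a
    handful of sites are unreliable and can leave row pairs with no shared
    columns at all.
    """
    ref = boundaries.reference_id
    if ref is None:
        raise ValueError("boundaries must name a reference_id")
    c1, c2 = boundaries.catalytic_aa
    d1, d2 = boundaries.disintegrin_aa
    ref_len = len(aa_aln.degapped(ref))
    if ref_len < d2:
        raise ValueError(
            f"reference {ref!r} has {ref_len} residues, needs >= {d2}"
        )
    # Split at the columns housing the reference's boundary residues; leading
    # columns (reference gaps before residue 1) stay with the catalytic side.
    cat_cols = (1, aa_aln.pos_to_col(ref, c2))
    dis_cols = (aa_aln.pos_to_col(ref, d1), aa_aln.pos_to_col(ref, d2))

    def cut(cols: tuple[int, int]) -> MultipleAlignment:
        sub = aa_aln.subalignment_columns(*cols)
        n_cols = cols[1] - cols[0] + 1
        keep = [
            i for i in sub.ids
            if len(sub.degapped(i)) >= min_coverage * n_cols
        ]
        if not keep:
            raise ValueError("partition is empty")
        return MultipleAlignment(keep, [sub.row(i) for i in keep], sub.moltype)

    return cut(cat_cols), cut(dis_cols)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Unweighted Robinson-Foulds distance: bipartitions in exactly one tree."""
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(t1.splits() ^ t2.splits())


def _restricted_splits(tree: Tree, shared: frozenset) -> set[frozenset]:
    """Splits of ``tree`` restricted to a shared leaf subset (non-trivial only)."""
    n = len(shared)
    anchor = min(shared)
    out: set[frozenset] = set()
    for split in tree.splits():
        side = frozenset(split & shared)
        if anchor in side:
            side = frozenset(shared - side)
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _restricted_clades(
    tree: Tree, shared: frozenset, threshold: float
) -> list[frozenset]:
    """Supported clades induced on the shared leaf set.

    Leaves present in only one tree (e.g. P-I sequences, absent from the
    disintegrin partition) are removed from each supported clade before
    neighborhood comparison; a clade that becomes trivial (fewer than two
    shared leaves, or the whole shared set) carries no positional signal
    and is dropped.
    """
    n = len(shared)
    out = set()
    for clade in tree.supported_clades(threshold):
        induced = frozenset(clade & shared)
        if 2 <= len(induced) <= n - 1:
            out.add(induced)
    # deterministic order: smallest first, ties by sorted member names, so
    # the smallest-clade search below never depends on set iteration order
    return sorted(out, key=lambda c: (len(c), tuple(sorted(c))))


def _neighbor_class(
    clades: list[frozenset], leaf: str, class_labels: dict[str, str]
) -> str | None:
    """Majority class of the smallest supported clade containing ``leaf``."""
    best: frozenset | None = None
    for clade in clades:
        if leaf in clade:
            if best is None or len(clade) < len(best):
                best = clade
    if best is None:
        return None
    others = [class_labels[x] for x in best if x != leaf and x in class_labels]
    if not others:
        return None
    tally: dict[str, int] = {}
    for cls in others:
        tally[cls] = tally.get(cls, 0) + 1
    top = max(tally.values())
    leaders = sorted(c for c, n in tally.items() if n == top)
    if len(leaders) > 1:
        return None  # tied vote: no majority class exists
    return leaders[0]


def discordance_report(
    tree_cat: Tree,
    tree_dis: Tree,
    class_labels: dict[str, str],
    support_threshold: float = 70.0,
) -> DiscordanceReport:
    """Flag sequences whose catalytic and disintegrin tree neighborhoods disagree.

    The analysis is restricted to leaves present in both domain trees:
    supported clades are induced on the shared leaf set before comparison,
    so sequences that exist in only one partition (e.g. P-I, which has no
    disintegrin domain) cannot manufacture discordance. For each shared
    leaf, the neighbor class is the majority class of the smallest induced
    clade with bootstrap support >= threshold containing it and at least one
    other leaf. A leaf is flagged chimeric when the two neighbor classes are
    both defined and differ.
    """
    leaves_cat = set(tree_cat.leaf_names())
    leaves_dis = set(tree_dis.leaf_names())
    shared = leaves_cat & leaves_dis
    skipped = sorted((leaves_cat | leaves_dis) - shared)
    shared_frozen = frozenset(shared)
    clades_cat = _restricted_clades(tree_cat, shared_frozen, support_threshold)
    clades_dis = _restricted_clades(tree_dis, shared_frozen, support_threshold)

    neighbor: dict[str, tuple[str | None, str | None]] = {}
    concordant: dict[str, bool] = {}
    flagged: list[str] = []
    for leaf in sorted(shared):
        nc = _neighbor_class(clades_cat, leaf, class_labels)
        nd = _neighbor_class(clades_dis, leaf, class_labels)
        neighbor[leaf] = (nc, nd)
        is_discordant = nc is not None and nd is not None and nc != nd
        concordant[leaf] = not is_discordant
        if is_discordant:
            flagged.append(leaf)

    rf: int | None = None
    if len(shared) >= 4:
        frozen = frozenset(shared)
        rf = len(_restricted_splits(tree_cat, frozen) ^ _restricted_splits(tree_dis, frozen))
    return DiscordanceReport(neighbor, concordant, rf, flagged, skipped)


def write_discordance_tsv(report: DiscordanceReport, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("id\tcatalytic_neighbor_class\tdisintegrin_neighbor_class\tconcordant\tflagged\n")
        for leaf in sorted(report.neighbor_classes):
            nc, nd = report.neighbor_classes[leaf]
            handle.write(
                f"{leaf}\t{nc or '-'}\t{nd or '-'}\t"
                f"{report.concordant[leaf]}\t{leaf in report.flagged}\n"
            )
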