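"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

Distances are observed divergence (p-distance) over a selected column
slice with pairwise gap deletion, optionally transformed by the Kimura
protein correction d = -ln(1 - p - p^2/5). Trees are built with the
Saitou-Nei neighbor-joining algorithm using the standard Q-criterion;
tie-breaks are lexicographic on cluster labels so results are
deterministic, and negative intermediate branch lengths are clamped to
zero with the deficit shifted to the sister edge. Bootstrap support for an
internal edge is the fraction of column-resampled replicate trees
containing the same leaf bipartition.

Trees are ``dendropy.Tree`` objects; Newick is written by a small emitter
(branch lengths to 6 significant digits, supports as internal node labels)
and parsed through dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from Bio import SeqIO

GAP_CHARS = frozenset("-.")


@dataclass
class MultipleAlignment:
    """Ordered aligned rows (id, gapped sequence), all the same length."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def slice_columns(self, col_slice: tuple[int, int] | None) -> "MultipleAlignment":
        """Restrict to a 1-based closed column interval."""
        if col_slice is None:
            return self
        start, end = col_slice
        if not (1 <= start <= end <= self.n_cols):
            raise ValueError(f"column slice {col_slice} out of bounds for {self.n_cols} columns")
        return MultipleAlignment(self.ids, [s[start - 1:end] for s in self.seqs])

    def take_columns(self, indices: np.ndarray) -> "MultipleAlignment":
        rows = ["".join(s[i] for i in indices) for s in self.seqs]
        return MultipleAlignment(self.ids, rows)

    @classmethod
    def read_fasta(cls, path: str | Path) -> "MultipleAlignment":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(ids, seqs)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("distance matrix contains negative entries")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("distance matrix is not symmetric within 1e-12")
        if np.max(np.abs(np.diag(self.values))) > 0:
            raise ValueError("distance matrix diagonal is not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def kimura_correction(p: float, pair: tuple[str, str] | None = None) -> float:
    """Kimura's protein-distance correction d = -ln(1 - p - p^2/5)."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        who = f" for pair {pair[0]!r}/{pair[1]!r}" if pair else ""
        raise ValueError(f"distance saturation{who}: p={p:.4f} outside the Kimura correction domain")
    return -math.log(arg)


def p_distance_matrix(
    aln: MultipleAlignment,
    correction: str = "none",
    col_slice: tuple[int, int] | None = None,
) -> DistanceMatrix:
    """Pairwise observed divergence over the slice, pairwise gap deletion.

    p(i, j) = mismatches / compared sites, counting only columns where
    neither row has a gap. A pair with zero comparable columns is an error
    naming the pair, as is Kimura saturation.
    """
    if correction not in ("none", "kimura"):
        raise ValueError(f"unknown correction {correction!r}; use 'none' or 'kimura'")
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows for distances")
    sub = aln.slice_columns(col_slice)
    if sub.n_cols == 0:
        raise ValueError("empty column slice")
    arr = np.array([list(s) for s in sub.seqs])
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = sub.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~is_gap[i] & ~is_gap[j]
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns for pair {sub.ids[i]!r}/{sub.ids[j]!r}"
                )
            p = float((arr[i, comparable] != arr[j, comparable]).sum()) / total
            dij = kimura_correction(p, (sub.ids[i], sub.ids[j])) if correction == "kimura" else p
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(sub.ids), d)


# --- neighbor joining -------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining, deterministic under ties.

    Pair selection minimizes the Q-criterion with ties broken by the
    lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest leaf name). Negative branch lengths are
    clamped to 0 and the deficit moved to the sister edge. The returned
    tree is unrooted (central trifurcation for >= 3 taxa).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    labels = list(dm.ids)
    D = dm.values.copy()

    def join(i: int, j: int, li: float, lj: float) -> None:
        """Merge clusters i < j into a new internal node."""
        nonlocal D, nodes, labels
        if li < 0:
            li, lj = 0.0, D[i, j]
        elif lj < 0:
            li, lj = D[i, j], 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        m = D.shape[0]
        keep = [k for k in range(m) if k not in (i, j)]
        newrow = np.array([max(0.0, 0.5 * (D[i, k] + D[j, k] - D[i, j])) for k in keep])
        D = np.vstack([np.column_stack([D[np.ix_(keep, keep)], newrow]),
                       np.append(newrow, 0.0)])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        join(i, j, li, D[i, j] - li)

    if len(nodes) == 3:
        la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
        lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
        lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
        center = dendropy.Node()
        for node, ln in zip(nodes, (la, lb, lc)):
            center.add_child(node)
            node.edge.length = max(0.0, ln)
        tree.seed_node = center
    elif len(nodes) == 2:
        root = dendropy.Node()
        root.add_child(nodes[0])
        root.add_child(nodes[1])
        nodes[0].edge.length = D[0, 1]
        nodes[1].edge.length = 0.0
        tree.seed_node = root
    else:
        tree.seed_node = nodes[0]
    tree.is_rooted = False
    return tree


# --- bipartitions and support ----------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each normalized to the side that does
    not contain the alphabetically first leaf."""
    all_leaves = leaf_labels(tree)
    ref = all_leaves[0]
    universe = set(all_leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 2 <= len(below) <= len(universe) - 2:
            side = universe - below if ref in below else below
            parts.add(frozenset(side))
    return parts


def edge_length_map(tree: dendropy.Tree) -> dict[object, float]:
    """Edge lengths keyed by leaf name (pendant edges) or normalized
    bipartition (internal edges). Edges that map to the same bipartition
    (a seed-adjacent duplicate in rooted representations) are summed."""
    all_leaves = leaf_labels(tree)
    ref = all_leaves[0]
    universe = set(all_leaves)
    out: dict[object, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        if node.is_leaf():
            out[node.taxon.label] = out.get(node.taxon.label, 0.0) + length
        else:
            below = {leaf.taxon.label for leaf in node.leaf_iter()}
            if 2 <= len(below) <= len(universe) - 2:
                key = frozenset(universe - below if ref in below else below)
                out[key] = out.get(key, 0.0) + length
    return out


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    table: pd.DataFrame  # bipartition, support, high_confidence
    n_reps: int
    n_success: int
    n_failed: int
    supports: dict[frozenset[str], float] = field(default_factory=dict)


def bootstrap_support(
    aln: MultipleAlignment,
    correction: str = "none",
    n_reps: int = 100,
    seed: int = 0,
    col_slice: tuple[int, int] | None = None,
    flag_threshold: float = 0.70,
) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree built from ``aln``.

    The reference tree is built from the original slice. Each replicate
    resamples slice columns with replacement and rebuilds distances and the
    tree; support of an internal edge is the fraction of successful
    replicates containing the same bipartition (replicates failing distance
    computation, e.g. by saturation, are recorded and excluded from the
    denominator). Supports are attached to the reference tree as internal
    node labels, and bipartitions at or above ``flag_threshold`` are marked
    high-confidence.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sub = aln.slice_columns(col_slice)
    ref_tree = neighbor_joining(p_distance_matrix(sub, correction))
    ref_parts = tree_bipartitions(ref_tree)
    rng = np.random.default_rng(seed)
    counts = {part: 0 for part in ref_parts}
    n_success = n_failed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, sub.n_cols, size=sub.n_cols)
        try:
            rep_dm = p_distance_matrix(sub.take_columns(idx), correction)
        except ValueError:
            n_failed += 1
            continue
        rep_parts = tree_bipartitions(neighbor_joining(rep_dm))
        n_success += 1
        for part in ref_parts & rep_parts:
            counts[part] += 1
    supports = {
        part: (counts[part] / n_success if n_success else float("nan"))
        for part in ref_parts
    }

    universe = set(leaf_labels(ref_tree))
    ref = min(universe)
    for node in ref_tree.preorder_node_iter():
        if node is ref_tree.seed_node or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 2 <= len(below) <= len(universe) - 2:
            key = frozenset(universe - below if ref in below else below)
            node.label = repr(supports[key])

    rows = [
        {
            "bipartition": "+".join(sorted(part)),
            "support": supports[part],
            "high_confidence": supports[part] >= flag_threshold,
        }
        for part in sorted(ref_parts, key=lambda p: tuple(sorted(p)))
    ]
    table = pd.DataFrame(rows, columns=["bipartition", "support", "high_confidence"])
    return BootstrapResult(
        tree=ref_tree, table=table, n_reps=n_reps,
        n_success=n_success, n_failed=n_failed, supports=supports,
    )


# --- Newick I/O -------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Emit Newick with branch lengths to 12 significant digits (compact
    yet lossless at the 1e-9 round-trip tolerance) and internal node labels
    (bootstrap supports) passed through verbatim."""

    def fmt(node: dendropy.Node, top: bool) -> str:
        if node.is_leaf():
            s = node.taxon.label if node.taxon else (node.label or "")
        else:
            inner = ",".join(fmt(c, False) for c in node.child_nodes())
            s = f"({inner}){node.label or ''}"
        if not top and node.edge.length is not None:
            s += f":{node.edge.length:.12g}"
        return s

    return fmt(tree.seed_node, True) + ";"


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into an unrooted tree, reporting the failure
    position on malformed input."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        offset = getattr(exc, "col_num", None)
        where = f" at character {offset}" if offset is not None else ""
        raise ValueError(f"newick parse error{where}: {exc}") from exc
    tree.is_rooted = False
    return tree


def support_values(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Bootstrap supports read back from internal node labels."""
    universe = set(leaf_labels(tree))
    ref = min(universe)
    out: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or node.label is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 2 <= len(below) <= len(universe) - 2:
            key = frozenset(universe - below if ref in below else below)
            out[key] = float(node.label)
    return out


# --- additive-tree helpers (oracles for NJ consistency) ---------------------

def random_additive_tree(
    n_leaves: int,
    rng: np.random.Generator,
    length_range: tuple[float, float] = (0.1, 1.0),
) -> dendropy.Tree:
    """Random unrooted binary tree with positive branch lengths, built by
    repeatedly attaching a new leaf to a uniformly chosen edge."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    lo, hi = length_range
    labels = [f"t{i + 1}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    center = dendropy.Node()
    tree.seed_node = center
    for lab in labels[:3]:
        leaf = dendropy.Node(taxon=taxa.get_taxon(lab))
        center.add_child(leaf)
        leaf.edge.length = float(rng.uniform(lo, hi))
    for lab in labels[3:]:
        edges = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
        child = edges[int(rng.integers(0, len(edges)))]
        parent = child.parent_node
        frac = float(rng.uniform(0.2, 0.8))
        old_len = child.edge.length
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = old_len * frac
        mid.add_child(child)
        child.edge.length = old_len * (1.0 - frac)
        leaf = dendropy.Node(taxon=taxa.get_taxon(lab))
        mid.add_child(leaf)
        leaf.edge.length = float(rng.uniform(lo, hi))
    tree.is_rooted = False
    return tree


def additive_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaves of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    names = leaf_labels(tree)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(names, d)
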