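"""Neighbor-joining phylogenetics over amino-acid alignments.

Distances are uncorrected p or Poisson-corrected (−ln(1−p)) with pairwise or
complete gap deletion. Trees are built by the Saitou–Nei neighbor-joining
agglomeration with deterministic lexicographic tie-breaking, bootstrap
supports are attached to internal edges as leaf-bipartition percentages, and
an outgroup can root the tree at the midpoint of its pendant edge. Tree
containers and Newick serialisation use dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO

from .precursor import InputError

__all__ = [
    "MultipleAlignment", "DistanceMatrix", "UndefinedDistanceError",
    "pairwise_distance", "neighbor_joining", "bootstrap_support",
    "root_with_outgroup", "read_newick", "write_newick",
    "leaf_bipartitions", "attach_supports",
]

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


class UndefinedDistanceError(ValueError):
    """A pair has no comparable sites, or p = 1 (Poisson correction diverges)."""


@dataclass
class MultipleAlignment:
    """A gapped amino-acid alignment: parallel lists of taxa and rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise InputError("taxa/rows length mismatch")
        if len(self.taxa) < 3:
            raise InputError("alignment needs at least 3 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise InputError("rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa, rows)

    def resample_columns(self, columns: np.ndarray) -> "MultipleAlignment":
        """A new alignment made of the given column indices (with repeats)."""
        rows = ["".join(r[c] for c in columns) for r in self.rows]
        return MultipleAlignment(list(self.taxa), rows)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise InputError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise InputError("asymmetric distance matrix")
        if np.any(np.diag(self.matrix) != 0):
            raise InputError("nonzero diagonal")
        if np.any(self.matrix < 0):
            raise InputError("negative distances")


def pairwise_distance(
    aln: MultipleAlignment,
    model: str = "poisson",
    gap_mode: str = "pairwise",
) -> DistanceMatrix:
    """p-distance or Poisson-corrected distance (−ln(1−p)) per pair.

    ``gap_mode='pairwise'`` compares, per pair, only columns where both rows
    are ungapped; ``'complete'`` first drops every column containing any gap.
    """
    if model not in ("p", "poisson"):
        raise InputError(f"unknown model {model!r}")
    if gap_mode not in ("pairwise", "complete"):
        raise InputError(f"unknown gap_mode {gap_mode!r}")
    rows = aln.rows
    if gap_mode == "complete":
        keep = [c for c in range(aln.n_columns)
                if all(r[c] != GAP for r in rows)]
        rows = ["".join(r[c] for c in keep) for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [(a, b) for a, b in zip(rows[i], rows[j])
                     if a != GAP and b != GAP]
            if not pairs:
                raise UndefinedDistanceError(
                    f"no comparable sites for ({aln.taxa[i]}, {aln.taxa[j]})")
            p = sum(a != b for a, b in pairs) / len(pairs)
            if model == "p":
                dist = p
            else:
                if p >= 1.0:
                    raise UndefinedDistanceError(
                        f"p = 1 for ({aln.taxa[i]}, {aln.taxa[j]}): "
                        "Poisson correction undefined")
                dist = -np.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aln.taxa), d)


def _new_tree(labels: list[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    tns = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = {}
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        leaves[lab] = node
    return tree, leaves


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; unrooted tree with branch lengths.

    Ties in the Q criterion resolve to the lexicographically smallest pair of
    cluster representative labels (a cluster is represented by the smallest
    leaf label it contains). Negative branch-length estimates are clamped to
    zero with a warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    tree, leaf_nodes = _new_tree(dm.labels)
    nodes: list[dendropy.Node] = [leaf_nodes[lab] for lab in dm.labels]
    reps: list[str] = list(dm.labels)
    d = dm.matrix.copy()

    def clamp(x: float, pair: tuple[str, str]) -> float:
        if x < 0:
            warnings.warn(
                f"negative NJ branch length {x:.4g} for {pair} clamped to 0",
                stacklevel=2)
            return 0.0
        return x + 0.0  # normalises -0.0

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        pair = (reps[i], reps[j])
        li, lj = clamp(li, pair), clamp(lj, pair)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(pair)]

    # final three clusters join at the unrooted central node
    (a, b, c) = nodes
    la = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), (reps[0], reps[1]))
    lb = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), (reps[0], reps[1]))
    lc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), (reps[0], reps[2]))
    center = dendropy.Node()
    for node, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(node)
        node.edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalised to the side that
    excludes the lexicographically smallest leaf label."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        canon = frozenset(labels - side) if ref in side else side
        if 2 <= len(canon) <= len(labels) - 2:
            splits.add(canon)
    return splits


def attach_supports(tree: dendropy.Tree, supports: dict[frozenset[str], float]) -> None:
    """Write bipartition support percentages onto internal node labels."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        canon = frozenset(labels - side) if ref in side else side
        if canon in supports:
            node.label = str(int(round(supports[canon])))


def bootstrap_support(
    aln: MultipleAlignment,
    model: str = "poisson",
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise",
    max_redraw_factor: int = 100,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree from the full alignment plus bootstrap bipartition supports.

    Columns are resampled with replacement; replicate r draws from substream
    r of a single seeded generator. Replicates yielding undefined distances
    are redrawn and counted; exceeding ``max_redraw_factor * n_reps`` redraws
    raises, advising a different model or more data.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    main = neighbor_joining(pairwise_distance(aln, model, gap_mode))
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    counts: dict[frozenset[str], int] = {}
    redraws = 0
    cap = max_redraw_factor * n_reps
    for child in streams:
        rng = np.random.default_rng(child)
        while True:
            cols = rng.integers(0, aln.n_columns, aln.n_columns)
            try:
                rep = neighbor_joining(
                    pairwise_distance(aln.resample_columns(cols), model, gap_mode))
                break
            except UndefinedDistanceError:
                redraws += 1
                if redraws > cap:
                    raise UndefinedDistanceError(
                        "bootstrap redraw cap exceeded: distances repeatedly "
                        "undefined; consider model='p' or a longer alignment")
        for split in leaf_bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    attach_supports(main, supports)
    return main, supports


def _collect_support_labels(tree: dendropy.Tree) -> dict[frozenset[str], str]:
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(labels)
    found = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or not node.label:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        canon = frozenset(labels - side) if ref in side else side
        found[canon] = node.label
    return found


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root at the midpoint of the outgroup's pendant edge (on a clone).

    Internal-node support labels are re-mapped by leaf bipartition after
    re-orientation, so each support stays on the edge it belongs to.
    """
    support_labels = _collect_support_labels(tree)
    rooted = tree.clone(depth=1)
    node = None
    for leaf in rooted.leaf_node_iter():
        if leaf.taxon.label == outgroup_label:
            node = leaf
            break
    if node is None:
        raise InputError(f"outgroup {outgroup_label!r} not in tree")
    length = node.edge.length
    half = None if length is None else length / 2.0
    rooted.reroot_at_edge(node.edge, length1=half, length2=half,
                          update_bipartitions=False)
    rooted.is_rooted = True
    labels = {leaf.taxon.label for leaf in rooted.leaf_node_iter()}
    ref = min(labels)
    for n in rooted.preorder_node_iter():
        if n is rooted.seed_node or n.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in n.leaf_iter())
        canon = frozenset(labels - side) if ref in side else side
        n.label = support_labels.get(canon)
    return rooted


def read_newick(text_or_path: str | Path) -> dendropy.Tree:
    """Parse Newick text (or a file path) into a tree.

    Branch lengths absent in the text stay absent (None), never 0. Internal
    node labels (e.g. bootstrap percentages) are preserved.
    """
    text = str(text_or_path)
    if "\n" not in text and Path(text).exists() and not text.strip().startswith("("):
        text = Path(text).read_text()
    try:
        return dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"malformed Newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise with branch lengths and internal-node support labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
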