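"""Distance-based phylogenetics: protein distances, neighbor joining,
bootstrap supports and anchor-based clade assignment.

Neighbor joining follows Saitou & Nei with the usual Q criterion
Q(i,j) = (n-2) d(i,j) - r_i - r_j.  Tie-breaking is lexicographic on the
smallest leaf label of each cluster, so the tree is a deterministic function
of the distance matrix, independent of taxon order.  Negative branch lengths
(possible for non-additive inputs) are clamped to zero with the deficit
moved to the sister branch, preserving the joined pair's path length.

Trees are dendropy objects; clade assignment labels each gene by the clade
of its nearest anchor taxon, the convention used to sort gene-family members
into the ancient / intermediate / modern-WUS groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io_formats import SequenceRecord

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "tree_distance_matrix",
    "assign_clades",
    "clade_proportions",
]

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Alignment:
    """A protein multiple alignment; all records share one length."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"aligned records differ in length: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids in alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def labels(self) -> list[str]:
        return [r.id for r in self.records]

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns drawn with replacement."""
        idx = rng.integers(0, self.n_columns, size=self.n_columns)
        recs = [
            SequenceRecord(
                r.id, "".join(r.residues[i] for i in idx), alphabet="protein-aligned"
            )
            for r in self.records
        ]
        return Alignment(recs)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def pairwise_distance(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """p-distance or Poisson-corrected distance with pairwise gap deletion.

    For each pair only columns where neither sequence has a gap are compared;
    p = mismatches / compared columns and the Poisson correction is
    d = -ln(1 - p).  A pair with no comparable column, or p = 1 under the
    Poisson model, raises naming the pair.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = alignment.n_taxa
    if n < 2:
        raise ValueError("need at least two taxa")
    seqs = [np.frombuffer(r.residues.encode(), dtype="S1") for r in alignment.records]
    gap = GAP.encode()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"no comparable columns for pair "
                    f"({alignment.labels[i]!r}, {alignment.labels[j]!r})"
                )
            p = float((seqs[i][ok] != seqs[j][ok]).sum()) / n_ok
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair ({alignment.labels[i]!r}, "
                        f"{alignment.labels[j]!r}): p = 1 has no Poisson distance"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(alignment.labels, d)


def _clamped(b_i: float, b_j: float) -> tuple[float, float]:
    # negative length moves to the sister branch; the pair's sum is preserved
    if b_i < 0:
        return 0.0, b_i + b_j
    if b_j < 0:
        return b_i + b_j, 0.0
    return b_i, b_j


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree whose
    seed node trifurcates.  Deterministic: Q ties are resolved toward the
    lexicographically smallest pair of cluster labels."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes[label] = node  # dict key doubles as the cluster's min leaf label

    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.d[i, j])

    active = sorted(nodes)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and (a, b) < best):
                    best_q = q
                    best = (a, b)
        a, b = best
        dab = dist[frozenset((a, b))]
        b_a = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        b_b = dab - b_a
        b_a, b_b = _clamped(b_a, b_b)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = b_a
        nodes[b].edge.length = b_b
        key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = (dist[frozenset((a, c))] + dist[frozenset((b, c))] - dab) / 2.0
            dist[frozenset((key, c))] = duc
        active = sorted(c for c in active if c not in (a, b))
        nodes[key] = parent
        active.append(key)
        active.sort()

    a, b, c = active
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    la = max(0.0, (dab + dac - dbc) / 2.0)
    lb = max(0.0, (dab + dbc - dac) / 2.0)
    lc = max(0.0, (dac + dbc - dab) / 2.0)
    root = dendropy.Node()
    for key, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[key])
        nodes[key].edge.length = length
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions as canonical frozensets (the side not
    containing the lexicographically smallest taxon)."""
    all_leaves = _leafset(tree.seed_node)
    ref = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: Alignment,
    model: str = "p",
    n_reps: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with internal-edge bootstrap supports (percent of replicates
    containing the same leaf bipartition).  Replicates whose resampled
    columns leave a pair with no comparable site are dropped and logged."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    main = neighbor_joining(pairwise_distance(alignment, model))
    counts: dict[frozenset[str], int] = {}
    n_used = 0
    for _ in range(n_reps):
        rep = alignment.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep, model))
        except ValueError as exc:
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        n_used += 1
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = _leafset(main.seed_node)
    ref = min(all_leaves)
    for node in main.preorder_node_iter():
        if node is main.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2 and n_used > 0:
            support = 100.0 * counts.get(side, 0) / n_used
            node.label = f"{support:g}"
            node.support = support
    return main


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)


def assign_clades(dm: DistanceMatrix, anchors: dict[str, str]) -> pd.DataFrame:
    """Label each non-anchor gene by the clade of its nearest anchor.

    Returns a DataFrame indexed by gene id with columns clade,
    nearest_anchor and margin (second-best clade distance minus best); a
    zero margin yields the clade 'ambiguous'.
    """
    missing = [a for a in anchors if a not in dm.labels]
    if missing:
        raise ValueError(f"anchor ids missing from distance matrix: {missing}")
    clades = sorted(set(anchors.values()))
    if len(clades) < 2:
        raise ValueError("need anchors from at least two clades")
    df = dm.as_dataframe()
    rows = []
    for gene in dm.labels:
        if gene in anchors:
            continue
        per_clade = {}
        nearest = {}
        for clade in clades:
            members = [a for a, c in anchors.items() if c == clade]
            dists = df.loc[gene, members]
            per_clade[clade] = float(dists.min())
            nearest[clade] = dists.idxmin()
        order = sorted(per_clade, key=lambda c: (per_clade[c], c))
        best, second = order[0], order[1]
        margin = per_clade[second] - per_clade[best]
        rows.append(
            {
                "gene_id": gene,
                "clade": best if margin > 0 else "ambiguous",
                "nearest_anchor": nearest[best],
                "margin": margin,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def clade_proportions(sizes: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentage share of each clade, rounded half away from zero."""
    total = sum(sizes.values())
    if total == 0:
        raise ValueError("empty clade sizes")
    return {
        clade: _round_half_away(100.0 * n / total, decimals)
        for clade, n in sizes.items()
    }
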