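"""Relative-rate tests and distance-based protein trees.

A pseudogene evolves free of purifying selection and should accumulate
amino-acid substitutions faster than a functional ortholog. The
relative-rate test polarises substitutions with an outgroup: over
alignment columns complete in the two test lineages and the outgroup, a
substitution is *unique* to lineage A when A differs while B and the
outgroup agree. Under equal rates the unique counts n_A and n_B are
binomially balanced, and

    chi^2 = (n_A - n_B)^2 / (n_A + n_B),  df = 1

tests the equality (no continuity correction). Tree building uses
neighbor joining on p- or Poisson-corrected protein distances with
column-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import dendropy
import numpy as np
from scipy import stats

from .gene_models import read_fasta


@dataclass
class ProteinAlignment:
    """Gapped, equal-length protein rows keyed by sequence id."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinAlignment":
        records = read_fasta(path, alphabet="protein")
        return cls(rows={rec.id: rec.residues for rec in records})

    def column_subset(self, indices: np.ndarray) -> "ProteinAlignment":
        return ProteinAlignment(rows={
            rid: "".join(seq[i] for i in indices)
            for rid, seq in self.rows.items()
        })


@dataclass(frozen=True)
class RateTestResult:
    lineage_a: str
    lineage_b: str
    outgroup: str
    n_a: int
    n_b: int
    chi_square: float
    p_value: float
    df: int = 1
    n_uninformative: int = 0


def count_unique_substitutions(
    aln: ProteinAlignment, a: str, b: str, outgroup: str,
    return_uninformative: bool = False,
):
    """Counts of substitutions unique to lineages ``a`` and ``b``.

    Columns with a gap or X in any of the three sequences are excluded
    (complete-case deletion). A column where all three residues differ is
    informative for neither lineage; its count is available via
    ``return_uninformative``.
    """
    for key in (a, b, outgroup):
        if key not in aln.rows:
            raise KeyError(f"sequence {key!r} not in alignment")
    sa, sb, so = aln.rows[a], aln.rows[b], aln.rows[outgroup]
    n_a = n_b = n_unif = 0
    for ra, rb, ro in zip(sa, sb, so):
        if "-" in (ra, rb, ro) or "X" in (ra, rb, ro):
            continue
        if ra != rb:
            if rb == ro:
                n_a += 1
            elif ra == ro:
                n_b += 1
            else:
                n_unif += 1
    if return_uninformative:
        return n_a, n_b, n_unif
    return n_a, n_b


def tajima_chi2(
    n_a: int, n_b: int,
    lineage_a: str = "A", lineage_b: str = "B", outgroup: str = "outgroup",
    n_uninformative: int = 0,
) -> RateTestResult:
    """Chi-square relative-rate test from unique-substitution counts.

    chi² = (n_a − n_b)² / (n_a + n_b) with 1 df; (0, 0) gives chi² = 0 and
    p = 1. No continuity correction is applied.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("substitution counts must be non-negative")
    total = n_a + n_b
    chi2 = 0.0 if total == 0 else (n_a - n_b) ** 2 / total
    p = 1.0 if chi2 == 0.0 else float(stats.chi2.sf(chi2, df=1))
    return RateTestResult(lineage_a=lineage_a, lineage_b=lineage_b,
                          outgroup=outgroup, n_a=n_a, n_b=n_b,
                          chi_square=chi2, p_value=p,
                          n_uninformative=n_uninformative)


def relative_rate_test(
    aln: ProteinAlignment, a: str, b: str, outgroup: str
) -> RateTestResult:
    """Full relative-rate test of two lineages against an outgroup."""
    n_a, n_b, n_unif = count_unique_substitutions(
        aln, a, b, outgroup, return_uninformative=True)
    return tajima_chi2(n_a, n_b, lineage_a=a, lineage_b=b,
                       outgroup=outgroup, n_uninformative=n_unif)


# ---------------------------------------------------------------------------
# Distances

def _compared_columns(si: str, sj: str):
    for ri, rj in zip(si, sj):
        if ri in "-X" or rj in "-X":
            continue
        yield ri, rj


def p_distance(aln: ProteinAlignment, i: str, j: str) -> float:
    """Observed proportion of differing residues over pairwise-complete
    columns (gap/X in either row excluded)."""
    compared = mismatches = 0
    for ri, rj in _compared_columns(aln.rows[i], aln.rows[j]):
        compared += 1
        if ri != rj:
            mismatches += 1
    if compared == 0:
        raise ValueError(f"no comparable columns between {i!r} and {j!r}")
    return mismatches / compared


def poisson_distance(aln: ProteinAlignment, i: str, j: str) -> float:
    """Poisson-corrected protein distance, −ln(1 − p)."""
    p = p_distance(aln, i, j)
    if p >= 1.0:
        raise ValueError(f"saturated distance between {i!r} and {j!r} (p = 1)")
    return -float(np.log(1.0 - p))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    @classmethod
    def from_alignment(
        cls, aln: ProteinAlignment,
        distance_fn: Callable[[ProteinAlignment, str, str], float],
    ) -> "DistanceMatrix":
        labels = aln.ids
        n = len(labels)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = distance_fn(aln, labels[i], labels[j])
                values[i, j] = values[j, i] = d
        return cls(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising the rate-corrected criterion
    Q(i,j) = (n−2)d(i,j) − r_i − r_j is joined; ties break on the lowest
    (i, j) label-index pair. Negative branch lengths are clamped to zero.
    The returned tree is unrooted (trifurcating seed node for n ≥ 3).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    d = dm.values.astype(float).copy()
    active = list(range(n))
    order = {i: i for i in active}  # creation order for tie-breaking

    def finish(tree_root: dendropy.Node) -> dendropy.Tree:
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = tree_root
        tree.is_rooted = False
        return tree

    if n == 2:
        root = dendropy.Node()
        for idx, half in ((0, d[0, 1] / 2), (1, d[0, 1] / 2)):
            nodes[idx].edge.length = max(half, 0.0)
            root.add_child(nodes[idx])
        return finish(root)

    next_order = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, order[i], order[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        nodes[i].edge.length = max(vi, 0.0)
        nodes[j].edge.length = max(vj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes.append(parent)
        order[new_idx] = next_order
        next_order += 1
        active = [k for k in active if k not in (i, j)] + [new_idx]

    root = dendropy.Node()
    i, j, k = active
    vi = (d[i, j] + d[i, k] - d[j, k]) / 2
    vj = (d[i, j] + d[j, k] - d[i, k]) / 2
    vk = (d[i, k] + d[j, k] - d[i, j]) / 2
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        nodes[idx].edge.length = max(v, 0.0)
        root.add_child(nodes[idx])
    return finish(root)


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, rooting

def _tip_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(
        leaf.taxon.label if leaf.taxon else leaf.label
        for leaf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each canonicalised to the side
    not containing the lexicographically smallest tip label."""
    all_tips = _tip_labels(tree.seed_node)
    anchor = min(all_tips)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _tip_labels(node)
        if anchor in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            out.add(side)
    return out


def bootstrap_support(
    aln: ProteinAlignment,
    distance_fn: Callable[[ProteinAlignment, str, str], float],
    n_replicates: int = 100,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for the clades of the NJ tree
    built from the full alignment.

    All replicate column-index draws come from a single seeded generator,
    drawn up front in a documented order, so supports are exactly
    reproducible for a given seed. Support is the percentage of replicate
    trees containing each original bipartition.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if aln.n_columns < 2:
        raise ValueError("alignment too short to resample")
    # canonical row order so supports do not depend on input ordering
    # (NJ tie-breaks on row index)
    aln = ProteinAlignment(rows={k: aln.rows[k] for k in sorted(aln.rows)})
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, aln.n_columns, size=(n_replicates, aln.n_columns))
    original = bipartitions(nj(DistanceMatrix.from_alignment(aln,
                                                             distance_fn)))
    counts = {bp: 0 for bp in original}
    for rep in range(n_replicates):
        sub = aln.column_subset(idx[rep])
        rep_bps = bipartitions(nj(DistanceMatrix.from_alignment(sub,
                                                                distance_fn)))
        for bp in original:
            if bp in rep_bps:
                counts[bp] += 1
    return {bp: 100.0 * c / n_replicates for bp, c in counts.items()}


def root_tree(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge (at its midpoint)."""
    tree = tree.clone(depth=1)
    node = None
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        if label == outgroup_id:
            node = leaf
            break
    if node is None:
        raise KeyError(f"outgroup tip {outgroup_id!r} not in tree")
    root = tree.seed_node
    # Already rooted on this outgroup: re-rooting is a no-op.
    if (len(root.child_nodes()) == 2 and node in root.child_nodes()):
        return tree
    length = node.edge.length
    if length is None:
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    else:
        tree.reroot_at_edge(node.edge, length1=length / 2,
                            length2=length / 2, update_bipartitions=False)
    tree.is_rooted = True
    return tree
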