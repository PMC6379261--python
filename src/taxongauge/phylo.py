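"""Marker-gene alignment handling and distance phylogenetics.

Pre-aligned marker genes (16S; atpD/leuS/rplB/gyrB for MLSA) are
post-processed by complete gap elimination, concatenated in a fixed gene
order, converted to p- or Jukes-Cantor distances and turned into
neighbor-joining or UPGMA trees with bootstrap support.  Distance trees
stand in for likelihood trees here: clade membership at the genus and
species level is robust to the method, and the point of these trees in
the pipeline is clade assignment, not branch-length inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

_MISSING = set("-.NnXx")


@dataclass
class MarkerAlignment:
    """One aligned marker gene: strain id -> equal-length aligned sequence."""

    gene_name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"alignment {self.gene_name!r} needs >= 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment {self.gene_name!r} rows differ in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class ConcatenatedAlignment:
    gene_order: list[str]
    gene_lengths: dict[str, int]
    rows: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(self.gene_lengths.values())


@dataclass
class DistanceMatrixP:
    strain_order: list[str]
    values: np.ndarray
    model: str  # "p-distance" | "jc69"


def remove_gap_columns(aln: MarkerAlignment) -> MarkerAlignment:
    """Complete deletion: drop every column with a gap or missing symbol
    ('-', '.', 'N'/'X') in any row.  Idempotent; row order preserved."""
    ids = list(aln.rows)
    matrix = np.array([list(aln.rows[i]) for i in ids])
    missing = np.isin(matrix, list(_MISSING))
    keep = ~missing.any(axis=0)
    if not keep.any():
        raise ValueError(f"alignment {aln.gene_name!r}: no columns survive gap elimination")
    filtered = matrix[:, keep]
    return MarkerAlignment(aln.gene_name, {i: "".join(row) for i, row in zip(ids, filtered)})


def concatenate(alns: list[MarkerAlignment]) -> ConcatenatedAlignment:
    """Row-wise concatenation of gap-filtered marker alignments in order."""
    if not alns:
        raise ValueError("no alignments to concatenate")
    strain_sets = [set(a.rows) for a in alns]
    common = set.intersection(*strain_sets)
    offenders = {
        a.gene_name: sorted(set(a.rows) ^ strain_sets[0]) for a in alns if set(a.rows) != strain_sets[0]
    }
    if offenders:
        raise ValueError(f"strain sets differ between genes: {offenders}")
    rows = {sid: "".join(a.rows[sid] for a in alns) for sid in alns[0].rows}
    return ConcatenatedAlignment(
        gene_order=[a.gene_name for a in alns],
        gene_lengths={a.gene_name: a.length for a in alns},
        rows=rows,
    )


def percent_identity(a: str, b: str) -> float:
    """Pairwise percent identity over columns where both rows are
    unambiguous bases (pairwise deletion of gap/missing columns)."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    matches = comparable = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _MISSING or y in _MISSING:
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable columns between sequences")
    return 100.0 * matches / comparable


def _p_distance_matrix(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(rows)
    matrix = np.array([np.frombuffer(rows[i].upper().encode(), dtype=np.uint8) for i in ids])
    missing = np.isin(matrix, np.frombuffer("".join(_MISSING).upper().encode(), dtype=np.uint8))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~missing[i] & ~missing[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = float((matrix[i][ok] != matrix[j][ok]).sum()) / comparable
            d[i, j] = d[j, i] = p
    return ids, d


def distance_matrix(aln: MarkerAlignment | ConcatenatedAlignment, model: str = "p-distance") -> DistanceMatrixP:
    """p-distance or JC69 distances from an alignment.

    JC69: d = -(3/4) ln(1 - 4p/3), defined only for p < 0.75.
    """
    ids, p = _p_distance_matrix(aln.rows)
    if model == "p-distance":
        return DistanceMatrixP(ids, p, model)
    if model.lower() in {"jc69", "jc"}:
        if (p >= 0.75).any():
            i, j = np.argwhere(p >= 0.75)[0]
            raise ValueError(f"JC69 undefined for pair ({ids[i]}, {ids[j]}): p = {p[i, j]:.3f} >= 0.75")
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrixP(ids, d, "jc69")
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Tree building.  NJ and UPGMA are implemented here rather than delegated so
# that tie-breaking is deterministic (lexicographically smallest pair) and
# UPGMA node heights are available for threshold cutting; both are
# cross-checked against independent implementations in the test suite.

def _pair_key(names: list[str], i: int, j: int) -> tuple[str, str]:
    return tuple(sorted((names[i], names[j])))  # type: ignore[return-value]


def nj_tree(d: DistanceMatrixP) -> TreeNode:
    """Neighbor joining by the canonical Q-criterion.

    Ties in Q are broken by the lexicographically smallest pair of node
    labels; negative branch lengths are clamped to zero (logged).
    """
    n = len(d.strain_order)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    nodes = [TreeNode(name=name) for name in d.strain_order]
    labels = list(d.strain_order)
    dist = d.values.astype(float).copy()
    active = list(range(n))

    def clamp(value: float, where: str) -> float:
        if value < 0:
            logger.info("NJ: clamping negative branch length %.3g at %s", value, where)
            return 0.0
        return value

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - sums[i] - sums[j]
                key = (q, _pair_key(labels, i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        delta = (sums[i] - sums[j]) / (m - 2)
        li = clamp(0.5 * dist[i, j] + 0.5 * delta, labels[i])
        lj = clamp(0.5 * dist[i, j] - 0.5 * delta, labels[j])
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.extend([nodes[i], nodes[j]])
        new_d = {k: 0.5 * (dist[i, k] + dist[j, k] - dist[i, j]) for k in active if k not in (i, j)}
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        for k, value in new_d.items():
            dist[i, k] = dist[k, i] = max(value, 0.0)
        active.remove(j)
    # final trifurcation (the unrooted NJ convention)
    i, j, k = sorted(active, key=lambda x: labels[x])
    root = TreeNode()
    nodes[i].length = clamp(0.5 * (dist[i, j] + dist[i, k] - dist[j, k]), labels[i])
    nodes[j].length = clamp(0.5 * (dist[i, j] + dist[j, k] - dist[i, k]), labels[j])
    nodes[k].length = clamp(0.5 * (dist[i, k] + dist[j, k] - dist[i, j]), labels[k])
    root.extend([nodes[i], nodes[j], nodes[k]])
    return root


def upgma_tree(d: DistanceMatrixP) -> TreeNode:
    """UPGMA (average linkage) tree; output is ultrametric.

    Each internal node carries a ``height`` attribute: half the average
    linkage distance at which its children merged.
    """
    n = len(d.strain_order)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    nodes: dict[int, TreeNode] = {}
    heights: dict[int, float] = {}
    sizes: dict[int, int] = {}
    labels: dict[int, str] = {}
    for i, name in enumerate(d.strain_order):
        node = TreeNode(name=name)
        node.height = 0.0
        nodes[i], heights[i], sizes[i], labels[i] = node, 0.0, 1, name
    dist = {frozenset((i, j)): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (dist[frozenset((i, j))], tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (merge_dist, _), i, j = best
        height = merge_dist / 2.0
        parent = TreeNode()
        parent.height = height
        for child_id in (i, j):
            child = nodes[child_id]
            child.length = height - heights[child_id]
            parent.append(child)
        nodes[next_id] = parent
        heights[next_id] = height
        sizes[next_id] = sizes[i] + sizes[j]
        labels[next_id] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        del dist[frozenset((i, j))]
        active.remove(i)
        active.remove(j)
        active.append(next_id)
        next_id += 1
    return nodes[active[0]]


def midpoint_root(tree: TreeNode) -> TreeNode:
    return tree.root_at_midpoint()


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            parts.add(min(side, leaves - side, key=sorted))
    return parts


def bootstrap_support(
    aln: MarkerAlignment | ConcatenatedAlignment,
    tree_builder,
    model: str = "p-distance",
    n_replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Attach bootstrap support (%) to internal nodes of the full-data tree.

    Columns are resampled with replacement; support of a bipartition is
    the percentage of replicate trees containing it.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    ids = list(aln.rows)
    matrix = np.array([list(aln.rows[i]) for i in ids])
    n_cols = matrix.shape[1]
    tree = tree_builder(distance_matrix(_aln_from_matrix(ids, matrix), model))
    counts: dict[frozenset[str], int] = {part: 0 for part in _bipartitions(tree)}
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        replicate = tree_builder(distance_matrix(_aln_from_matrix(ids, matrix[:, cols]), model))
        for part in _bipartitions(replicate):
            if part in counts:
                counts[part] += 1
    leaves = frozenset(ids)
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            part = min(side, leaves - side, key=sorted)
            node.support = 100.0 * counts[part] / n_replicates
    return tree


def _aln_from_matrix(ids: list[str], matrix: np.ndarray) -> MarkerAlignment:
    return MarkerAlignment("replicate", {i: "".join(row) for i, row in zip(ids, matrix)})
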