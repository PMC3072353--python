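"""Differential signature selection and two-dimensional clustering.

The signature is derived in two sequential filters over a genes x samples
log10-ratio matrix with a binary RB1 phenotype:

1. variance filter — drop genes whose sample standard deviation (ddof=1)
   over all samples is below ``sd_min`` (default 0.1 log10 units), i.e.
   probes that barely move across the panel;
2. correlation filter — keep genes whose Pearson correlation with the 0/1
   phenotype (the point-biserial correlation) has a two-sided p-value at or
   below ``alpha`` (default 0.001).

The p-value uses the exact small-sample t transform
``t = r * sqrt((n - 2) / (1 - r**2))`` on ``n - 2`` degrees of freedom,
which for a binary regressor is identical to the pooled two-sample t-test.
No multiple-testing correction is applied by default, matching the raw
alpha cut the procedure is defined with; Benjamini-Hochberg q-values are
available as an optional extra column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateMetricError,
    DegeneratePhenotypeError,
    InsufficientDataError,
    ValidationError,
)
from .io import ExpressionMatrix, PhenotypeLabels

__all__ = [
    "GeneStats",
    "SignatureResult",
    "Dendrogram",
    "ClusterResult",
    "gene_sd",
    "pearson_with_phenotype",
    "pearson_permutation_p",
    "derive_signature",
    "cluster_2d",
]


@dataclass(frozen=True)
class GeneStats:
    """Per-gene filter statistics.

    ``degenerate`` marks a zero-variance gene, for which the correlation is
    undefined; such genes carry (r, p) = (0, 1) so a single flat probe can
    never enter the signature nor abort a run.
    """

    gene_id: str
    sd: float
    r: float
    p: float
    degenerate: bool = False
    q: float | None = None


@dataclass(frozen=True)
class SignatureResult:
    selected: tuple[GeneStats, ...]
    sd_min: float
    alpha: float
    n_input_genes: int
    all_stats: tuple[GeneStats, ...] = field(default_factory=tuple, repr=False)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.selected)

    def __len__(self) -> int:
        return len(self.selected)

    def to_frame(self, *, all_genes: bool = False) -> pd.DataFrame:
        rows = self.all_stats if all_genes else self.selected
        df = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in rows],
                "sd": [g.sd for g in rows],
                "r": [g.r for g in rows],
                "p": [g.p for g in rows],
            }
        )
        if rows and rows[0].q is not None:
            df["q"] = [g.q for g in rows]
        return df


def gene_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n - 1 denominator) of one gene's ratios."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("standard deviation needs at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite value in expression vector")
    return float(np.std(v, ddof=1))


def _check_labels_vector(y: np.ndarray) -> None:
    if y.size < 3:
        raise InsufficientDataError("correlation needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise DegeneratePhenotypeError("phenotype labels contain a single class")


def pearson_with_phenotype(
    values: Sequence[float], labels: np.ndarray
) -> tuple[float, float, bool]:
    """Pearson r of a gene against the 0/1 phenotype, with two-sided p.

    Returns ``(r, p, degenerate)``. A constant gene is flagged degenerate
    and reported as (0.0, 1.0, True); a perfectly correlated gene gets
    p = 0 exactly.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("expression vector and labels are not aligned")
    _check_labels_vector(y)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite value in expression vector")
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    if sx == 0.0:
        return 0.0, 1.0, True
    r = float(np.sum(xc * yc) / (sx * np.sqrt(np.sum(yc * yc))))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, False
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0), False


def pearson_permutation_p(
    values: Sequence[float],
    labels: np.ndarray,
    n_resamples: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Two-sided permutation p for |r| under label shuffling.

    Intended for very small panels where the t approximation may be doubted;
    uses the add-one (Davison-Hinkley) estimator so p is never exactly 0.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_labels_vector(y)
    rng = np.random.default_rng(rng)
    r_obs, _, degenerate = pearson_with_phenotype(x, y)
    if degenerate:
        return 1.0
    xc = x - x.mean()
    xs = xc / np.sqrt(np.sum(xc * xc))
    perms = np.empty(n_resamples)
    for i in range(n_resamples):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        perms[i] = np.dot(xs, yc) / np.sqrt(np.sum(yc * yc))
    hits = int(np.sum(np.abs(perms) >= abs(r_obs) - 1e-12))
    return (hits + 1) / (n_resamples + 1)


def derive_signature(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    sd_min: float = 0.1,
    alpha: float = 0.001,
    *,
    bh: bool = False,
) -> SignatureResult:
    """Apply the SD filter, then the phenotype-correlation filter.

    Genes failing ``sd >= sd_min`` are removed before the correlation
    filter. Survivors with ``p <= alpha`` are returned sorted by ascending
    p, ties broken by gene id. With ``bh=True`` a Benjamini-Hochberg
    q-value (computed over the SD-passing genes) is attached as an extra
    column; it plays no role in selection.
    """
    missing = [s for s in labels.sample_ids if s not in matrix.sample_ids]
    if missing:
        raise ValidationError(f"labeled samples not in matrix: {missing}")
    sub = matrix.subset_samples(labels.sample_ids)
    y = labels.vector(sub.sample_ids)
    _check_labels_vector(y)

    stats_all: list[GeneStats] = []
    survivors: list[GeneStats] = []
    for gid, row in zip(sub.gene_ids, sub.values):
        sd = gene_sd(row)
        if sd < sd_min:
            stats_all.append(GeneStats(gid, sd, float("nan"), float("nan")))
            continue
        r, p, degenerate = pearson_with_phenotype(row, y)
        gs = GeneStats(gid, sd, r, p, degenerate)
        stats_all.append(gs)
        survivors.append(gs)

    if bh and survivors:
        q = stats_bh([g.p for g in survivors])
        qmap = {g.gene_id: qi for g, qi in zip(survivors, q)}
        survivors = [
            GeneStats(g.gene_id, g.sd, g.r, g.p, g.degenerate, qmap[g.gene_id])
            for g in survivors
        ]
        stats_all = [
            GeneStats(g.gene_id, g.sd, g.r, g.p, g.degenerate, qmap.get(g.gene_id))
            for g in stats_all
        ]

    selected = [g for g in survivors if not g.degenerate and g.p <= alpha]
    selected.sort(key=lambda g: (g.p, g.gene_id))
    return SignatureResult(
        selected=tuple(selected),
        sd_min=sd_min,
        alpha=alpha,
        n_input_genes=len(sub.gene_ids),
        all_stats=tuple(stats_all),
    )


def stats_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


# ---------------------------------------------------------------------------
# hierarchical clustering, 1 - Pearson distance, average linkage

@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over named leaves.

    Nodes 0..n-1 are leaves (in ``ids`` order); merge k creates node n+k.
    ``merges`` lists (left, right, height) with UPGMA heights, which are
    non-decreasing along any root path (average linkage is monotone).
    """

    ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.ids) - 1:
            raise ValidationError("a binary merge tree needs n - 1 merges for n leaves")

    def _label(self, node: int) -> str:
        # lexicographically smallest leaf id under the node; used for the
        # deterministic left/right ordering of children
        n = len(self.ids)
        if node < n:
            return self.ids[node]
        left, right, _ = self.merges[node - n]
        return min(self._label(left), self._label(right))

    def leaf_order(self) -> tuple[str, ...]:
        n = len(self.ids)
        root = n + len(self.merges) - 1 if self.merges else 0

        def walk(node: int) -> list[str]:
            if node < n:
                return [self.ids[node]]
            left, right, _ = self.merges[node - n]
            if self._label(left) > self._label(right):
                left, right = right, left
            return walk(left) + walk(right)

        return tuple(walk(root))

    def height(self, node: int) -> float:
        n = len(self.ids)
        return 0.0 if node < n else self.merges[node - n][2]

    def to_newick(self) -> str:
        n = len(self.ids)
        root = n + len(self.merges) - 1 if self.merges else 0

        def walk(node: int, parent_height: float) -> str:
            branch = max(parent_height - self.height(node), 0.0)
            if node < n:
                name = self.ids[node].replace(" ", "_")
                return f"{name}:{branch:.6g}"
            left, right, h = self.merges[node - n]
            if self._label(left) > self._label(right):
                left, right = right, left
            return f"({walk(left, h)},{walk(right, h)}):{branch:.6g}"

        return walk(root, self.height(root)) + ";"

    def root_bipartition(self) -> tuple[frozenset[str], frozenset[str]]:
        """Leaf ids on either side of the last (root) merge."""
        n = len(self.ids)
        if not self.merges:
            raise ValidationError("tree has a single leaf")
        left, right, _ = self.merges[-1]

        def leaves(node: int) -> set[str]:
            if node < n:
                return {self.ids[node]}
            a, b, _ = self.merges[node - n]
            return leaves(a) | leaves(b)

        return frozenset(leaves(left)), frozenset(leaves(right))


@dataclass(frozen=True)
class ClusterResult:
    gene_tree: Dendrogram
    sample_tree: Dendrogram
    gene_order: tuple[str, ...]
    sample_order: tuple[str, ...]
    dropped_genes: tuple[str, ...] = ()
    dropped_samples: tuple[str, ...] = ()


def correlation_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson distances between the rows of ``vectors``."""
    v = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(v * v, axis=1))
    if np.any(norms == 0):
        raise DegenerateMetricError("zero-variance vector in correlation metric")
    corr = (v / norms[:, None]) @ (v / norms[:, None]).T
    corr = np.clip(corr, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(dist: np.ndarray, ids: Sequence[str]) -> Dendrogram:
    """Deterministic UPGMA on a full dissimilarity matrix.

    Cluster-to-cluster distance is the unweighted mean of the original
    pairwise distances (Lance-Williams update). Equal-distance ties merge
    the pair whose (smallest-leaf-id, smallest-leaf-id) labels sort first,
    so golden tests see one canonical tree.
    """
    ids = tuple(ids)
    n = len(ids)
    if n < 2:
        raise InsufficientDataError("clustering needs at least 2 items")
    d = np.asarray(dist, dtype=float).copy()
    active: dict[int, int] = {i: 1 for i in range(n)}  # node -> cluster size
    node_of = {i: i for i in range(n)}  # row index -> current node id
    labels = {i: ids[i] for i in range(n)}  # node -> smallest leaf id
    merges: list[tuple[int, int, float]] = []
    next_node = n
    rows = list(range(n))

    while len(rows) > 1:
        idx = np.array(rows)
        sub = d[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(len(idx), k=1)
        vals = sub[iu, ju]
        best = float(vals.min())
        ties = np.nonzero(vals <= best + 1e-15)[0]
        # lexicographic tie-break on sorted cluster labels
        def pair_key(t: int) -> tuple[str, str]:
            a, b = int(idx[iu[t]]), int(idx[ju[t]])
            return tuple(sorted((labels[node_of[a]], labels[node_of[b]])))

        t = min(ties, key=pair_key)
        i, j = int(idx[iu[t]]), int(idx[ju[t]])
        ni, nj = active[node_of[i]], active[node_of[j]]
        merges.append((node_of[i], node_of[j], float(d[i, j])))
        # Lance-Williams average update into row i
        for k in rows:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
        new_label = min(labels[node_of[i]], labels[node_of[j]])
        active[next_node] = ni + nj
        labels[next_node] = new_label
        node_of[i] = next_node
        next_node += 1
        rows.remove(j)

    return Dendrogram(ids, tuple(merges))


def cluster_2d(matrix: ExpressionMatrix) -> ClusterResult:
    """Cluster genes and samples independently (1 - Pearson, average linkage).

    Zero-variance rows/columns are undefined under the correlation metric
    and are dropped with a warning; an all-constant matrix raises
    :class:`DegenerateMetricError`.
    """
    values = matrix.values
    gene_var = np.var(values, axis=1)
    sample_var = np.var(values, axis=0)
    dropped_genes = tuple(g for g, v in zip(matrix.gene_ids, gene_var) if v == 0)
    dropped_samples = tuple(s for s, v in zip(matrix.sample_ids, sample_var) if v == 0)
    keep_g = [i for i, v in enumerate(gene_var) if v > 0]
    keep_s = [i for i, v in enumerate(sample_var) if v > 0]
    if len(keep_g) < 2 or len(keep_s) < 2:
        raise DegenerateMetricError(
            "correlation metric undefined: fewer than 2 varying genes or samples"
        )
    if dropped_genes:
        warnings.warn(f"dropping zero-variance genes: {dropped_genes}", stacklevel=2)
    if dropped_samples:
        warnings.warn(f"dropping zero-variance samples: {dropped_samples}", stacklevel=2)
    sub = values[np.ix_(keep_g, keep_s)]
    gene_ids = tuple(matrix.gene_ids[i] for i in keep_g)
    sample_ids = tuple(matrix.sample_ids[i] for i in keep_s)
    # dropping constant columns can make a surviving row constant (and vice
    # versa); recheck rather than silently divide by zero
    if np.any(np.var(sub, axis=1) == 0) or np.any(np.var(sub, axis=0) == 0):
        raise DegenerateMetricError("matrix degenerates after dropping constant vectors")
    gene_tree = average_linkage(correlation_distance_matrix(sub), gene_ids)
    sample_tree = average_linkage(correlation_distance_matrix(sub.T), sample_ids)
    return ClusterResult(
        gene_tree=gene_tree,
        sample_tree=sample_tree,
        gene_order=gene_tree.leaf_order(),
        sample_order=sample_tree.leaf_order(),
        dropped_genes=dropped_genes,
        dropped_samples=dropped_samples,
    )
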