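"""Mapping bulk clone profiles onto a labeled single-cell reference.

Each clone's mean log2(normalized + 1) expression profile is Pearson-
correlated with every cell of a developmental reference whose cells carry a
type label (SCP, bridge, chromaffin, sympathoblast) and a developmental-
order index.  Summaries follow: per-cell-type mean correlations, mutual-
exclusivity Fisher tests on zero/nonzero binarized expression, and
agglomerative hierarchical clustering (Manhattan distance, complete linkage
by default) of the cell x clone correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "OrthologReport",
    "map_orthologs",
    "CorrelationMap",
    "correlate_clones_to_cells",
    "mean_correlation_by_type",
    "binarize_expression",
    "fisher_exact_2x2",
    "ExclusivityResult",
    "exclusivity_test",
    "expression_vs_celltype_test",
    "ClusteringResult",
    "hierarchical_cluster",
]


@dataclass
class OrthologReport:
    n_mapped: int
    unmapped: list[str]
    dropped_many_to_one: list[str]


def map_orthologs(
    reference_matrix: pd.DataFrame, mapping: dict[str, str] | None = None
) -> tuple[pd.DataFrame, OrthologReport]:
    """Rename reference-species gene symbols to analysis-species symbols.

    Without an explicit map, falls back to case-normalized identity
    (mouse-style ``Yap1`` -> ``YAP1``).  Symbols absent from the map are
    dropped and reported; targets hit by more than one source symbol
    (many-to-one) are dropped entirely to keep the map one-to-one.
    """
    if mapping is None:
        mapping = {g: str(g).upper() for g in reference_matrix.index}
    renamed = {}
    unmapped = []
    for g in reference_matrix.index:
        if g in mapping:
            renamed[g] = mapping[g]
        else:
            unmapped.append(g)
    counts = pd.Series(list(renamed.values())).value_counts()
    collided = set(counts.index[counts > 1])
    keep = [g for g in reference_matrix.index if g in renamed and renamed[g] not in collided]
    dropped = sorted(g for g in renamed if renamed[g] in collided)
    out = reference_matrix.loc[keep].rename(index=renamed)
    return out, OrthologReport(
        n_mapped=len(keep), unmapped=unmapped, dropped_many_to_one=dropped
    )


@dataclass
class CorrelationMap:
    """Cell x clone Pearson correlations with cell annotations."""

    r: pd.DataFrame  # cells in rows, clones in columns
    annotations: pd.DataFrame  # indexed by cell id: cell_type, dev_order
    n_genes_used: int
    n_constant_dropped: int = 0
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = self.r.index.difference(self.annotations.index)
        if len(missing):
            raise ValueError(f"cells without annotation: {list(missing)[:10]}")


def correlate_clones_to_cells(
    clone_matrix: pd.DataFrame,
    cell_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    clone_groups: pd.Series | None = None,
    use_log: bool = True,
    min_shared_genes: int = 100,
) -> CorrelationMap:
    """Pearson correlation of each clone profile with each cell.

    Both matrices should already be normalized (median-of-ratios).  Values
    are log2(x+1)-transformed by default; a clone's profile is the mean of
    its replicate columns.  Genes constant across all clone profiles or
    across all cells carry no information for the correlation and are
    dropped with a count; pairs left with fewer than 2 non-constant genes
    are recorded as undefined (NaN).
    """
    shared = clone_matrix.index.intersection(cell_matrix.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes between clone and reference "
            f"matrices (need >= {min_shared_genes})"
        )
    clones = clone_matrix.loc[shared].astype(float)
    cells = cell_matrix.loc[shared].astype(float)
    if use_log:
        clones = np.log2(clones + 1.0)
        cells = np.log2(cells + 1.0)
    if clone_groups is not None:
        clones = clones.T.groupby(clone_groups.reindex(clones.columns)).mean().T

    const = pd.Series(False, index=clones.index)
    if cells.shape[1] > 1:
        const |= cells.std(axis=1, ddof=0) == 0
    if clones.shape[1] > 1:
        const |= clones.std(axis=1, ddof=0) == 0
    n_dropped = int(const.sum())
    clones = clones.loc[~const]
    cells = cells.loc[~const]

    undefined: list[tuple[str, str]] = []
    if len(clones) < 2:
        r = pd.DataFrame(
            np.nan, index=cell_matrix.columns, columns=clones.columns
        )
        undefined = [(c, k) for c in cell_matrix.columns for k in clones.columns]
        return CorrelationMap(r, annotations, 0, n_dropped, undefined)

    x = clones.to_numpy()  # genes x clones
    y = cells.to_numpy()  # genes x cells
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    yn = np.linalg.norm(yc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_mat = (yc.T @ xc) / np.outer(yn, xn)
    r = pd.DataFrame(r_mat, index=cells.columns, columns=clones.columns)
    for cell, clone in zip(*np.nonzero(~np.isfinite(r_mat))):
        undefined.append((str(cells.columns[cell]), str(clones.columns[clone])))
    return CorrelationMap(
        r=r,
        annotations=annotations,
        n_genes_used=len(clones),
        n_constant_dropped=n_dropped,
        undefined_pairs=undefined,
    )


def mean_correlation_by_type(cmap: CorrelationMap) -> pd.DataFrame:
    """Mean Pearson r per (cell type, clone), cell types in developmental order."""
    types = cmap.annotations.reindex(cmap.r.index)
    means = cmap.r.groupby(types["cell_type"]).mean()
    order = (
        types.drop_duplicates("cell_type")
        .sort_values("dev_order")["cell_type"]
        .tolist()
    )
    return means.reindex(order)


def binarize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Expressed (count > 0) / non-expressed (count = 0) boolean matrix.

    Median-of-ratios normalization preserves zero-sets, so raw and
    normalized inputs give identical output.
    """
    values = matrix.to_numpy()
    if values.size and values.min() < 0:
        raise ValueError("expression values must be non-negative")
    return matrix > 0


def fisher_exact_2x2(table) -> tuple[float, float, bool]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (odds_ratio, pvalue, zero_cell_flag).  The p-value is the
    conditional hypergeometric two-sided probability-mass rule (sum over
    tables with fixed margins whose probability does not exceed the
    observed).  The odds ratio is the sample OR a*d/(b*c), with Haldane 0.5
    continuity applied to the reported OR only when some cell is zero (never
    to the p-value).  A zero margin yields p = 1 and an undefined (NaN) OR.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(np.int64)
    (a, b), (c, d) = t
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan"), 1.0, True
    zero_cell = min(a, b, c, d) == 0
    if zero_cell:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    pvalue = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return float(odds), min(pvalue, 1.0), zero_cell


@dataclass
class ExclusivityResult:
    gene_a: str
    gene_b: str
    table: np.ndarray  # [[both on, A only], [B only, both off]]
    odds_ratio: float
    pvalue: float
    zero_cell: bool
    direction: str  # "exclusive" | "co-occurring" | "none"


def exclusivity_test(
    binary_matrix: pd.DataFrame, gene_a: str, gene_b: str
) -> ExclusivityResult:
    """Fisher test of mutual exclusivity between two genes across cells.

    The 2x2 table counts cells by on/off state of each gene; odds ratio < 1
    means the genes tend not to be expressed in the same cell (exclusive),
    > 1 co-occurring.
    """
    for g in (gene_a, gene_b):
        if g not in binary_matrix.index:
            raise ValueError(f"gene {g!r} absent from the matrix")
    on_a = binary_matrix.loc[gene_a].to_numpy(dtype=bool)
    on_b = binary_matrix.loc[gene_b].to_numpy(dtype=bool)
    table = np.array(
        [
            [int(np.sum(on_a & on_b)), int(np.sum(on_a & ~on_b))],
            [int(np.sum(~on_a & on_b)), int(np.sum(~on_a & ~on_b))],
        ]
    )
    odds, p, zero_cell = fisher_exact_2x2(table)
    if np.isnan(odds) or odds == 1.0:
        direction = "none"
    else:
        direction = "exclusive" if odds < 1.0 else "co-occurring"
    return ExclusivityResult(gene_a, gene_b, table, odds, p, zero_cell, direction)


def expression_vs_celltype_test(
    binary_matrix: pd.DataFrame,
    gene: str,
    annotations: pd.DataFrame,
    cell_type: str,
) -> ExclusivityResult:
    """Alternative contingency: gene on/off versus membership in one cell type."""
    if gene not in binary_matrix.index:
        raise ValueError(f"gene {gene!r} absent from the matrix")
    on = binary_matrix.loc[gene].to_numpy(dtype=bool)
    is_type = (
        annotations.reindex(binary_matrix.columns)["cell_type"] == cell_type
    ).to_numpy()
    table = np.array(
        [
            [int(np.sum(on & is_type)), int(np.sum(on & ~is_type))],
            [int(np.sum(~on & is_type)), int(np.sum(~on & ~is_type))],
        ]
    )
    odds, p, zero_cell = fisher_exact_2x2(table)
    if np.isnan(odds) or odds == 1.0:
        direction = "none"
    else:
        direction = "enriched" if odds > 1.0 else "depleted"
    return ExclusivityResult(gene, f"type:{cell_type}", table, odds, p, zero_cell, direction)


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str

    def cut(self, n_clusters: int) -> pd.Series:
        flat = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    method: str = "complete",
    metric: str = "cityblock",
) -> ClusteringResult:
    """Agglomerative clustering of correlation-matrix rows or columns.

    Manhattan (cityblock) distance with complete linkage by default,
    matching common heatmap-clustering practice; ``method`` accepts
    complete | average | single.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix if axis == "rows" else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need >= 2 items on the clustered axis")
    values = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = [
            (data.index[i], data.columns[j])
            for i, j in np.argwhere(~np.isfinite(values))[:10]
        ]
        raise ValueError(f"non-finite entries at {bad}")
    linkage = sch.linkage(pdist(values, metric=metric), method=method)
    labels = [str(x) for x in data.index]
    order = [labels[i] for i in sch.leaves_list(linkage)]
    return ClusteringResult(
        linkage=linkage,
        labels=labels,
        leaf_order=order,
        newick=_linkage_to_newick(linkage, labels),
    )


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = sch.to_tree(linkage)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
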