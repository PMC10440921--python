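"""Cross-comparison DEG integration: common DEGs, Fisher-combined p-values,
perturbation scores, optimal score threshold and gene/sample clustering.

The procedure mirrors a multi-contrast cohort analysis: genes regulated in
the same direction in every contrast (common DEGs) anchor an optimal
threshold on the perturbation score (-log10 of the BH-adjusted Fisher
combined p), and only genes scoring at or above that threshold are retained
for k-means clustering of standardized log2 counts; samples are ordered by
average-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from ._stats import bh_adjust, fisher_combine, fisher_combine_rows
from .diffexp import ComparisonSet

__all__ = [
    "PerturbationTable",
    "ClusterAssignment",
    "common_degs",
    "combine_pvalues",
    "perturbation_scores",
    "optimal_threshold",
    "cluster_genes",
    "linkage_to_newick",
]


@dataclass
class PerturbationTable:
    """Per-gene combined statistics over a shared comparison universe.

    Columns of ``table``: one ``p.<comparison>`` per contrast,
    ``combined_p``, ``combined_fdr``, ``score`` (-log10 combined FDR),
    ``is_common_deg`` and, after thresholding, ``predicted``.
    """

    table: pd.DataFrame
    comparisons: list[str]
    threshold: float | None = None
    youden_j: float | None = None

    def retained(self) -> pd.Index:
        if self.threshold is None:
            raise ValueError("optimal_threshold has not been applied")
        return self.table.index[self.table["predicted"]]


@dataclass
class ClusterAssignment:
    """K-means gene clusters plus the sample-side dendrogram."""

    gene_clusters: pd.Series          # gene -> cluster label in 1..k
    sample_linkage: np.ndarray        # scipy linkage matrix over columns
    sample_order: list[str]           # dendrogram leaf order
    standardized: pd.DataFrame        # the matrix that was clustered
    inertia: float
    restart_stability: float          # mean pairwise ARI over restarts
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def sample_groups(self, n_groups: int) -> pd.Series:
        """Flat cut of the sample dendrogram into ``n_groups`` clusters."""
        labels = hierarchy.fcluster(self.sample_linkage, n_groups, criterion="maxclust")
        return pd.Series(labels, index=self.standardized.columns, name="group")


def common_degs(comparisons: ComparisonSet) -> pd.Series:
    """True for genes that are DEGs in every comparison with one shared
    direction of regulation (all up or all down)."""
    if not comparisons:
        raise ValueError("empty comparison set")
    statuses = pd.DataFrame(
        {name: res.table["status"] for name, res in comparisons.items()}
    )
    if statuses.isna().any().any():
        raise ValueError("comparisons do not share a gene universe")
    all_up = (statuses == "up").all(axis=1)
    all_down = (statuses == "down").all(axis=1)
    return (all_up | all_down).rename("is_common_deg")


def combine_pvalues(p_vector) -> float:
    """Fisher's sum-of-logs combination (chi-square with 2k df)."""
    return fisher_combine(p_vector)


def perturbation_scores(comparisons: ComparisonSet) -> PerturbationTable:
    """Combined p / FDR and perturbation score per gene.

    The combined p is Fisher's statistic over each gene's per-comparison
    p-values; combined FDRs are BH-adjusted over the full tested universe;
    score = -log10(combined FDR).
    """
    names = list(comparisons)
    pmat = pd.DataFrame(
        {f"p.{n}": comparisons[n].table["p"] for n in names}
    )
    if pmat.isna().any().any():
        raise ValueError("comparisons do not share a gene universe")
    combined_p = fisher_combine_rows(pmat.to_numpy())
    combined_fdr = bh_adjust(combined_p)
    table = pmat.copy()
    table["combined_p"] = combined_p
    table["combined_fdr"] = combined_fdr
    with np.errstate(divide="ignore"):
        table["score"] = -np.log10(combined_fdr)
    table["is_common_deg"] = common_degs(comparisons)
    return PerturbationTable(table, names)


def optimal_threshold(scores, labels) -> tuple[float, float]:
    """Score cutpoint maximizing Youden's J (sensitivity + specificity - 1).

    Candidate cutpoints are the observed scores; a gene is predicted
    positive when its score is >= the cutpoint.  Ties in J break toward the
    lower (more inclusive) threshold: candidates are scanned in ascending
    order and a later cutpoint is kept only on a strict improvement.
    Returns (threshold, J).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be non-empty")
    best_j, best_t = -np.inf, None
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t), float(best_j)


def apply_threshold(pt: PerturbationTable) -> PerturbationTable:
    """Learn the optimal threshold from the common-DEG labels and flag
    predicted common DEGs (score >= threshold)."""
    threshold, j = optimal_threshold(
        pt.table["score"].to_numpy(), pt.table["is_common_deg"].to_numpy()
    )
    table = pt.table.copy()
    table["predicted"] = table["score"] >= threshold
    return PerturbationTable(table, pt.comparisons, threshold, j)


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization (mean 0, population sd 1); zero-variance
    rows are dropped."""
    arr = matrix.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    z = (arr[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def cluster_genes(
    log_counts: pd.DataFrame,
    k: int = 4,
    n_restarts: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """K-means clustering of standardized log2 counts plus a sample-side
    average-linkage dendrogram.

    ``log_counts`` holds the retained genes (rows) by samples (columns) on
    the log2 scale; rows are standardized internally.  K-means runs
    ``n_restarts`` k-means++ initializations, the best inertia is kept, and
    restart stability is summarized as the mean pairwise adjusted Rand
    index over all restarts.
    """
    z = standardize_rows(log_counts)
    if len(z) < k:
        raise ValueError(f"only {len(z)} usable genes for k={k}")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(max(1, n_restarts)):
        km = KMeans(
            n_clusters=k,
            n_init=1,
            init="k-means++",
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(z.to_numpy())
        runs.append((km.inertia_, km.labels_))
    best_inertia, best_labels = min(runs, key=lambda r: r[0])
    if len(runs) > 1:
        aris = [
            adjusted_rand_score(runs[i][1], runs[j][1])
            for i in range(len(runs))
            for j in range(i + 1, len(runs))
        ]
        stability = float(np.mean(aris))
    else:
        stability = 1.0
    gene_clusters = pd.Series(best_labels + 1, index=z.index, name="cluster")

    linkage = hierarchy.linkage(z.to_numpy().T, method="average", metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    sample_order = [z.columns[i] for i in order]
    return ClusterAssignment(
        gene_clusters, linkage, sample_order, z, float(best_inertia), stability, seed
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"
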