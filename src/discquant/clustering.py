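"""TF-signature selection and dual-metric hierarchical clustering.

Reproduces the transcriptome-comparison analysis in which tumor samples
cluster with early embryos: counts are normalised with median-of-ratios
size factors, variance-stabilised with a log2 transform, a signature of
differentially expressed TF genes is selected (simplified negative-binomial
Wald test, Benjamini-Hochberg at padj <= 0.01), rows are mean-centred, and
samples are clustered hierarchically with 1 - Pearson correlation distance
while genes use Euclidean distance (average linkage for both).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Dendrogram",
    "SignatureGeneSet",
    "size_factors",
    "vst",
    "simple_de",
    "select_signature",
    "center_rows",
    "hcluster_samples",
    "hcluster_genes",
    "co_cluster_purity",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over genes (expressed in every sample) of
    count / geometric-mean-across-samples. Errors if no gene is expressed
    in all samples.
    """
    mat = counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(mat[expressed])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Simplified variance-stabilising transform: log2(count/factor + 1)."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(factors, axis=1) + 1.0)


@dataclass
class DEResult:
    """Per-gene Wald differential-expression results (treatment vs reference)."""

    table: pd.DataFrame  # gene-indexed: log2fc, pvalue, padj, direction, significant
    reference: str
    treatment: str
    alpha: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def simple_de(
    counts: pd.DataFrame,
    sample_groups: Mapping[str, str] | pd.Series,
    reference: str,
    treatment: str,
    alpha: float = 0.01,
) -> DEResult:
    """Simplified NB Wald test between two sample groups.

    Per gene: group means of size-factor-normalised counts; dispersion by
    method of moments on the within-group (group-mean-centred) normalised
    counts, alpha_g = max(0, (s_res^2 - m) / m^2), floored at the
    across-genes median (a crude shrinkage toward the common dispersion);
    Wald z on the log2 fold change with a delta-method standard error from
    the NB variance m + alpha m^2; BH adjustment; a gene is called DE at
    padj <= alpha.
    """
    groups = pd.Series(sample_groups)
    ref_samples = [s for s in counts.columns if groups.get(s) == reference]
    trt_samples = [s for s in counts.columns if groups.get(s) == treatment]
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ValueError("each group needs at least two samples")
    sub = counts[ref_samples + trt_samples]
    norm = sub.div(size_factors(sub), axis=1).to_numpy(dtype=float)
    n_ref = len(ref_samples)
    a, b = norm[:, :n_ref], norm[:, n_ref:]

    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    pooled_m = norm.mean(axis=1)
    resid = np.concatenate([a - m_a[:, None], b - m_b[:, None]], axis=1)
    s2_within = (resid**2).sum(axis=1) / (norm.shape[1] - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(
            pooled_m > 0, np.maximum(0.0, (s2_within - pooled_m) / pooled_m**2), 0.0
        )
    disp = np.maximum(disp, np.median(disp))

    eps = 0.5  # symmetric pseudocount: identical groups give exactly lfc 0
    lfc = np.log2((m_b + eps) / (m_a + eps))
    var_a = (m_a + disp * m_a**2) / a.shape[1]
    var_b = (m_b + disp * m_b**2) / b.shape[1]
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((var_a / (m_a + eps) ** 2 + var_b / (m_b + eps) ** 2) / ln2sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    pvals = np.where(se > 0, pvals, 1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
            "significant": padj <= alpha,
        },
        index=sub.index,
    )
    return DEResult(table=table, reference=reference, treatment=treatment, alpha=alpha)


@dataclass
class SignatureGeneSet:
    """An ordered gene set with the provenance of its selection."""

    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def select_signature(de: DEResult, tf_annotation: Iterable[str]) -> SignatureGeneSet:
    """DE genes intersected with a TF annotation, order stable by gene id."""
    annotation = set(tf_annotation)
    if not annotation:
        raise ValueError("TF annotation set is empty")
    sig = sorted(set(de.significant_genes) & annotation)
    if not sig:
        raise ValueError(
            "no differentially expressed gene is in the TF annotation; "
            "clustering on an empty signature is impossible"
        )
    return SignatureGeneSet(
        genes=sig,
        provenance={
            "alpha": de.alpha,
            "reference": de.reference,
            "treatment": de.treatment,
            "n_de": len(de.significant_genes),
            "n_annotated": len(annotation),
        },
    )


def center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples (row means become 0)."""
    if matrix.shape[1] < 1:
        raise ValueError("need at least one column")
    return matrix.sub(matrix.mean(axis=1), axis=0)


@dataclass
class Dendrogram:
    """A rooted binary merge tree in scipy linkage form plus leaf labels."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.linkage_matrix.shape[0] != len(self.labels) - 1:
            raise ValueError("a dendrogram over n items must contain n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Flat clusters from cutting at the k-1 highest merges."""
        if not (1 <= k <= len(self.labels)):
            raise ValueError("k must lie in [1, number of leaves]")
        assign = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        root = to_tree(self.linkage_matrix)

        def recurse(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                length = node.dist - (0.0 if child.is_leaf() else child.dist)
                parts.append(f"{recurse(child)}:{length:.10g}")
            return f"({','.join(parts)})"

        return recurse(root) + ";"


def _check_items(n: int, what: str) -> None:
    if n < 2:
        raise ValueError(f"need at least two {what} to cluster")


def hcluster_samples(matrix: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Cluster samples (columns) with 1 - Pearson correlation distance.

    The matrix should already be restricted to the signature genes. Any
    sample whose profile has zero variance over those genes has no defined
    correlation and is reported by name.
    """
    _check_items(matrix.shape[1], "samples")
    x = matrix.to_numpy(dtype=float).T
    sds = x.std(axis=1)
    if (sds == 0).any():
        bad = [matrix.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance profile for sample(s): {bad}")
    d = pdist(x, metric="correlation")  # == 1 - Pearson r
    return Dendrogram(linkage(d, method=method), list(matrix.columns))


def hcluster_genes(matrix: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Cluster genes (rows) with Euclidean distance, same linkage."""
    _check_items(matrix.shape[0], "genes")
    d = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    return Dendrogram(linkage(d, method=method), list(matrix.index))


def co_cluster_purity(
    dend: Dendrogram,
    sample_groups: Mapping[str, str] | pd.Series,
    k: int,
    query_group: str,
    reference_group: str,
) -> float:
    """Fraction of query-group samples in the reference group's main cluster.

    The dendrogram is cut into k flat clusters; the reference cluster is the
    one holding the plurality of reference-group samples (a tie means the
    reference group has no majority cluster and raises). Returns the
    fraction of query-group samples assigned to that cluster.
    """
    groups = pd.Series(sample_groups)
    assign = dend.cut(k)
    ref = assign[[s for s in assign.index if groups.get(s) == reference_group]]
    query = assign[[s for s in assign.index if groups.get(s) == query_group]]
    if ref.empty or query.empty:
        raise ValueError("both query and reference groups must be present")
    counts = ref.value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        raise ValueError(
            f"reference group {reference_group!r} splits evenly across clusters "
            f"({dict(counts)}); no majority cluster"
        )
    ref_cluster = counts.index[0]
    return float((query == ref_cluster).mean())
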