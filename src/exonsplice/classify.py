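"""Hierarchical classification of samples by splicing signatures.

Samples are clustered agglomeratively on a feature x sample matrix
(gene-normalized intensities or FIRMA scores of selected probe-sets),
with correlation distance d(i, j) = 1 - Pearson(sample_i, sample_j) by
default (Euclidean available), and the tree cut at the root into two
groups.  Misclassification against known binary labels is counted as the
minimum over the two cluster-to-label assignments, so it never exceeds
floor(n_samples / 2).

The scientifically interesting use restricts the matrix to probe-sets whose
events were predicted to trigger nonsense-mediated decay
(:func:`classify_by_nmd`): a clean two-group cut on that signature is what
distinguishes disease or treatment states.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .consequence import NMD, ConsequenceCall


@dataclass
class ClusterResult:
    linkage: np.ndarray
    samples: list[str]
    assignments: pd.Series          # sample -> cluster id (1 or 2)
    misclassified: int
    order: list[str]                # leaf order of the dendrogram
    newick: str


def _misclassification(assign: np.ndarray, labels: np.ndarray) -> int:
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(
            f"misclassification needs exactly two label groups, got {list(groups)}")
    y = (labels == groups[0]).astype(int)
    c = (assign == 1).astype(int)
    direct = int((y != c).sum())
    return min(direct, len(y) - direct)


def _to_newick(Z: np.ndarray, ids: Sequence[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(ids))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def hcl(
    matrix: pd.DataFrame,
    labels: pd.Series,
    distance: str = "correlation",
    linkage: str = "average",
    center: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of samples with a two-group root cut.

    ``matrix``: feature x sample; ``labels``: true binary group per sample
    (used only for misclassification counting).  With ``center`` (default)
    each feature is mean-centered across samples first, so clustering acts
    on relative levels — the standard heatmap convention — and both sides
    of a two-group contrast carry a coherent (mirrored) signature.
    Correlation distance requires non-constant sample vectors and at least
    two features; with a single feature the distance falls back to
    Euclidean (with a warning), since correlation is undefined there.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    if matrix.shape[0] < 1:
        raise ValueError("clustering needs at least one feature")
    if center:
        matrix = matrix.sub(matrix.mean(axis=1), axis=0)
    X = matrix.T.to_numpy(dtype=float)
    samples = list(matrix.columns)
    if distance == "correlation":
        if matrix.shape[0] < 2:
            warnings.warn("single feature: correlation distance undefined, "
                          "falling back to euclidean")
            distance = "euclidean"
        else:
            const = np.isclose(X.std(axis=1), 0.0)
            if const.any():
                bad = [samples[i] for i in np.flatnonzero(const)]
                raise ValueError(
                    f"constant sample vector(s) {bad} under correlation "
                    "distance; use distance='euclidean'")
    d = pdist(X, metric=distance)
    Z = hierarchy.linkage(d, method=linkage)
    assign = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = labels.loc[samples]
    mis = _misclassification(assign, labels.to_numpy())
    order = [samples[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        linkage=Z,
        samples=samples,
        assignments=pd.Series(assign, index=samples, name="cluster"),
        misclassified=mis,
        order=order,
        newick=_to_newick(Z, samples),
    )


def classify_by_nmd(
    matrix: pd.DataFrame,
    calls: Iterable[ConsequenceCall],
    labels: pd.Series,
    distance: str = "correlation",
    linkage: str = "average",
    center: bool = True,
) -> ClusterResult:
    """Cluster samples on the probe-sets predicted to trigger NMD.

    ``matrix`` holds per-sample values (NI or expression) for all
    probe-sets; it is restricted to those whose consequence call includes
    NMD.  Raises if no NMD-predicted probe-set is available.
    """
    nmd_ps = sorted({c.probeset_id for c in calls if NMD in c.consequences})
    nmd_ps = [p for p in nmd_ps if p in matrix.index]
    if not nmd_ps:
        raise ValueError("no NMD-predicted probe-sets available for classification")
    return hcl(matrix.loc[nmd_ps], labels, distance=distance, linkage=linkage,
               center=center)


def plot_heatmap(matrix: pd.DataFrame, result: ClusterResult, path) -> None:
    """Optional heatmap of the clustered matrix (features x ordered samples)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix[result.order]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * data.shape[1]),
                                    max(3, 0.2 * data.shape[0])))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(result.order, rotation=90, fontsize=6)
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels(data.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="relative level (log2)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
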