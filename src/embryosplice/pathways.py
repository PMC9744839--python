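"""Pathway activity over developmental timepoints and embryonic labeling.

Activity is the median log2(TPM+1) of a pathway's genes per sample.  The
smoothing step runs a PCA with timepoints as observations and pathways as
variables and replaces each (pathway, timepoint) cell by the cosine
similarity between the pathway's loading vector and the timepoint's score
vector over the leading principal components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

log = logging.getLogger(__name__)

__all__ = [
    "score_pathway_activity",
    "SmoothedActivity",
    "smooth_activity_pca",
    "classify_embryonic_pathways",
]

DEFAULT_MIN_GENES = 3
DEFAULT_N_PCS = 5


def score_pathway_activity(
    expr: pd.DataFrame,
    pathways: dict[str, set[str]],
    min_genes: int = DEFAULT_MIN_GENES,
) -> pd.DataFrame:
    """Pathway x sample activity: median log2(TPM+1) of member genes.

    Pathways with fewer than ``min_genes`` genes present in ``expr`` are
    dropped with a warning.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be nonnegative (TPM-like)")
    logx = np.log2(expr + 1.0)
    rows = {}
    for name, genes in pathways.items():
        present = sorted(genes & set(expr.index))
        if len(present) < min_genes:
            log.warning("pathway %s: only %d genes matched, dropped", name, len(present))
            continue
        rows[name] = logx.loc[present].median(axis=0)
    if not rows:
        raise ValueError(f"no pathway retained >= {min_genes} matched genes")
    return pd.DataFrame(rows).T


@dataclass
class SmoothedActivity:
    values: pd.DataFrame        # pathway x timepoint, in [-1, 1]
    n_pcs: int                  # effective number of components used


def smooth_activity_pca(
    activity: pd.DataFrame,
    n_pcs: int = DEFAULT_N_PCS,
    scale_pathways: bool = True,
) -> SmoothedActivity:
    """Cosine-similarity smoothing of the activity matrix in PC space.

    Components with a negligible singular value (rank deficiency) are
    truncated so that arbitrary null-space directions cannot contaminate
    the cosine; either operand being the zero vector yields similarity 0.
    """
    if n_pcs > min(activity.shape) - 1:
        raise ValueError("n_pcs must be <= min(#pathways, #timepoints) - 1")
    mat = activity.to_numpy(dtype=float).T  # timepoints x pathways
    keep = np.ptp(mat, axis=0) > 0
    if not keep.all():
        dropped = activity.index[~keep].tolist()
        log.warning("dropping %d constant pathway rows: %s", len(dropped), dropped[:5])
        mat = mat[:, keep]
    names = activity.index[keep]
    if scale_pathways:
        mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
    else:
        mat = mat - mat.mean(axis=0)

    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-9)) if s.size and s[0] > 0 else 0
    k = min(n_pcs, rank)
    if k == 0:
        raise ValueError("activity matrix has no variance; need more timepoints")
    scores = u[:, :k] * s[:k]          # timepoint coordinates
    loadings = vt[:k].T                # pathway loading vectors

    ln = np.linalg.norm(loadings, axis=1)
    sn = np.linalg.norm(scores, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (loadings @ scores.T) / np.outer(ln, sn)
    cos[~np.isfinite(cos)] = 0.0
    values = pd.DataFrame(np.clip(cos, -1.0, 1.0), index=names, columns=activity.columns)
    return SmoothedActivity(values=values, n_pcs=k)


def classify_embryonic_pathways(
    smoothed: SmoothedActivity,
    prenatal_timepoints: list[str],
) -> dict[str, str]:
    """Split pathways into embryonic_positive / embryonic_negative.

    Ward/Euclidean hierarchical clustering of the smoothed rows, cut at
    k=2; the cluster with the higher mean smoothed activity over prenatal
    timepoints is embryonic_positive.  An exact tie labels the smaller
    cluster embryonic_positive (logged).
    """
    values = smoothed.values
    missing = set(prenatal_timepoints) - set(values.columns)
    if missing:
        raise ValueError(f"prenatal timepoints absent from matrix: {sorted(missing)[:5]}")
    if len(prenatal_timepoints) == 0 or len(prenatal_timepoints) == values.shape[1]:
        raise ValueError("both prenatal and postnatal timepoints must be present")
    mat = values.to_numpy()
    if np.allclose(mat, mat[0]):
        raise ValueError(
            "all pathway rows are identical; cannot split into two classes "
            "(more timepoints or less smoothing needed)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on tied distances
        z = linkage(mat, method="ward", metric="euclidean")
    cluster = fcluster(z, t=2, criterion="maxclust")
    pre = values[prenatal_timepoints].to_numpy()
    m1 = pre[cluster == 1].mean()
    m2 = pre[cluster == 2].mean()
    if m1 == m2:
        log.warning("prenatal-mean tie; labeling the smaller cluster embryonic_positive")
        pos_cluster = 1 if (cluster == 1).sum() <= (cluster == 2).sum() else 2
    else:
        pos_cluster = 1 if m1 > m2 else 2
    return {
        name: ("embryonic_positive" if cl == pos_cluster else "embryonic_negative")
        for name, cl in zip(values.index, cluster)
    }
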