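"""Graph clustering on PCA scores and marker-panel cluster annotation.

Cells are clustered by Leiden modularity optimisation on a shared-nearest-
neighbour (SNN) graph built from principal-component scores. Clusters are
then annotated by marker-panel detection fractions; clusters that fail the
myeloid panel (Itgam, Aif1, Cx3cr1, Csf1r) are labelled by their best
contaminant panel and removed, leaving the myeloid object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .simulate import CountMatrix


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-cell integer cluster id, 0-based
    n_clusters: int
    params: dict = field(default_factory=dict)
    annotations: dict[int, str] = field(default_factory=dict)

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def snn_graph(scores: np.ndarray, k: int = 20, prune: float = 1 / 15) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbour graph of the score rows.

    Edge weight between i and j is |N(i) ∩ N(j)| / |N(i) ∪ N(j)| over the
    k-nearest-neighbour sets (self included); weights below ``prune`` are
    dropped.
    """
    n = scores.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    _, idx = nn.kneighbors(scores)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k, dtype=np.float32), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T
    shared = shared.tocoo()
    jacc = shared.data / (2 * k - shared.data)
    keep = (jacc >= prune) & (shared.row != shared.col)
    return sp.csr_matrix(
        (jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def cluster_cells(
    scores: np.ndarray,
    resolution: float = 0.8,
    seed: int = 0,
    snn_k: int = 20,
) -> ClusterAssignment:
    """Leiden community detection on the SNN graph; deterministic given seed."""
    graph = snn_graph(scores, k=snn_k)
    graph = graph.maximum(graph.T).tocoo()
    mask = graph.row < graph.col
    g = ig.Graph(
        n=scores.shape[0],
        edges=list(zip(graph.row[mask].tolist(), graph.col[mask].tolist())),
        edge_attrs={"weight": graph.data[mask].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # Renumber by descending cluster size for stable, reportable ids.
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[x] for x in labels])
    return ClusterAssignment(
        labels=labels,
        n_clusters=len(ids),
        params={"resolution": resolution, "seed": seed, "snn_k": snn_k},
    )


def panel_detection_fractions(
    matrix: CountMatrix, labels: np.ndarray, panels: dict[str, list[str]]
) -> dict[int, dict[str, float]]:
    """Per cluster, the mean detection fraction of each panel's genes."""
    gene_idx = {g: i for i, g in enumerate(matrix.gene_meta["gene_id"])}
    detected = (matrix.counts > 0).tocsr()
    out: dict[int, dict[str, float]] = {}
    for cid in np.unique(labels):
        cols = np.flatnonzero(labels == cid)
        scores = {}
        for name, genes in panels.items():
            rows = [gene_idx[g] for g in genes if g in gene_idx]
            if not rows:
                scores[name] = 0.0
                continue
            frac = np.asarray(detected[rows][:, cols].mean(axis=1)).ravel()
            scores[name] = float(frac.mean())
        out[int(cid)] = scores
    return out


def annotate_and_strip(
    matrix: CountMatrix,
    assignment: ClusterAssignment,
    marker_panels: dict[str, list[str]],
    myeloid_key: str = "myeloid",
    myeloid_threshold: float = 0.25,
) -> tuple[CountMatrix, ClusterAssignment]:
    """Label clusters by marker panels and drop non-myeloid ones.

    A cluster whose myeloid-panel detection score falls below
    ``myeloid_threshold`` is annotated with its highest-scoring contaminant
    panel and removed. Surviving clusters are renumbered contiguously in
    their original order.
    """
    if myeloid_key not in marker_panels:
        raise ValueError(f"marker_panels must include {myeloid_key!r}")
    contaminant_keys = [k for k in marker_panels if k != myeloid_key]
    scores = panel_detection_fractions(matrix, assignment.labels, marker_panels)

    annotations: dict[int, str] = {}
    keep_clusters = []
    for cid, s in scores.items():
        if s[myeloid_key] >= myeloid_threshold:
            annotations[cid] = "myeloid"
            keep_clusters.append(cid)
        else:
            best = max(contaminant_keys, key=lambda k: s[k]) if contaminant_keys else None
            annotations[cid] = best if best and s[best] > 0 else "unknown"
    if not keep_clusters:
        raise ValueError("all clusters flagged as contaminants")

    keep_mask = np.isin(assignment.labels, keep_clusters)
    stripped = matrix.subset_cells(keep_mask)
    remap = {old: new for new, old in enumerate(sorted(keep_clusters))}
    new_labels = np.array([remap[x] for x in assignment.labels[keep_mask]])
    new_assignment = ClusterAssignment(
        labels=new_labels,
        n_clusters=len(keep_clusters),
        params=dict(assignment.params),
        annotations={remap[c]: "myeloid" for c in keep_clusters},
    )
    new_assignment.params["removed_clusters"] = {
        int(c): annotations[c] for c in scores if c not in keep_clusters
    }
    new_assignment.params["panel_scores"] = scores
    return stripped, new_assignment
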