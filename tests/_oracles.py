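"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: clustering is done by
explicit neighborhood graphs, IOU by shapely polygon arithmetic, medians by
the statistics module, and matching by exhaustive bipartite search.
"""

from __future__ import annotations

import statistics
from collections import Counter

import numpy as np
from shapely.geometry import box as shapely_box


def dbscan_oracle(points: np.ndarray, eps: float, min_size: int):
    """Textbook DBSCAN: core points, BFS expansion in index order.

    Returns (clusters, noise) where clusters is a list of sorted index
    lists (ordered by seed index) and noise a sorted index list.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return [], []
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [np.nonzero(d[i] <= eps)[0].tolist() for i in range(n)]
    core = [len(nb) >= min_size for nb in neighbors]
    labels = [-1] * n
    cluster_id = 0
    for seed in range(n):
        if labels[seed] != -1 or not core[seed]:
            continue
        labels[seed] = cluster_id
        queue = list(neighbors[seed])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cluster_id
                if core[j]:
                    queue.extend(neighbors[j])
        cluster_id += 1
    clusters = [sorted(i for i in range(n) if labels[i] == c) for c in range(cluster_id)]
    noise = sorted(i for i in range(n) if labels[i] == -1)
    return clusters, noise


def median_box_oracle(boxes):
    """Coordinate-wise median via the statistics module."""
    return tuple(
        statistics.median(getattr(b, attr) for b in boxes) for attr in ("x", "y", "w", "h")
    )


def mode_oracle(labels):
    """(consensus or None, tally) by exhaustive counting; None on ties."""
    tally = Counter(labels)
    top = max(tally.values())
    winners = [c for c, k in tally.items() if k == top]
    return (winners[0] if len(winners) == 1 else None), dict(tally)


def iou_oracle(a, b) -> float:
    """IOU via shapely polygon intersection/union."""
    pa = shapely_box(a.x, a.y, a.x2, a.y2)
    pb = shapely_box(b.x, b.y, b.x2, b.y2)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union > 0 else 0.0


def max_matching_oracle(iou_matrix: np.ndarray, threshold: float) -> int:
    """Maximum-cardinality bipartite matching above an IOU threshold."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    adj = csr_matrix((iou_matrix >= threshold).astype(int))
    match = maximum_bipartite_matching(adj, perm_type="column")
    return int((match >= 0).sum())
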