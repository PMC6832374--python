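"""DBSCAN over the embedded component map, with k-dist Eps selection.

A core point has at least ``k`` points (itself included) within radius
``eps``; clusters are maximal density-connected sets and everything else
is the explicit noise group (label -1).  The radius is chosen from the
sorted k-dist curve: each point's distance to its k-th nearest neighbor,
sorted descending, whose "knee" (maximum distance to the endpoint chord)
marks the transition from cluster interiors to sparse noise.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import DBSCAN as _SkDBSCAN
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterAssignment, ClusterParams, FloatArray

#: Default MinPts, suited to component maps of a few hundred to a few
#: thousand points.
DEFAULT_K = 20
#: Default radius in the embedded space (map units); override or use
#: select_eps for other geometries.
DEFAULT_EPS = 7.0


def kdist_curve(Y: FloatArray, k: int = DEFAULT_K) -> FloatArray:
    """Distance of every point to its k-th nearest neighbor, sorted descending."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Y)
    dist, _ = nn.kneighbors(Y)
    return np.sort(dist[:, k])[::-1]


def select_eps(curve: FloatArray) -> tuple[float, int]:
    """Knee of the sorted k-dist curve by maximum distance to the chord.

    Returns (eps, index) so the choice can be audited on the curve.  A flat
    curve has no knee; its median is returned with a warning.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    if n < 10:
        raise ValueError("curve too short for knee detection")
    if np.ptp(curve) < 1e-12 * max(abs(curve[0]), 1.0):
        warnings.warn("flat k-dist curve; returning the median distance")
        return float(np.median(curve)), n // 2
    x = np.arange(n, dtype=float)
    p0 = np.array([x[0], curve[0]])
    p1 = np.array([x[-1], curve[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([x, curve]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    idx = int(np.argmax(dist))
    return float(curve[idx]), idx


def dbscan(Y: FloatArray, params: ClusterParams) -> ClusterAssignment:
    """Classical DBSCAN; deterministic given input order.

    Neighborhood counts include the point itself, and border points reached
    by several clusters go to the first-discovered core's cluster.
    """
    Y = np.asarray(Y, dtype=float)
    params.validate(Y.shape[1])
    model = _SkDBSCAN(eps=params.eps, min_samples=params.k).fit(Y)
    return ClusterAssignment(labels=model.labels_.astype(int))


def cluster_map(Y: FloatArray, k: int = DEFAULT_K, eps: float | None = None,
                ) -> tuple[ClusterAssignment, ClusterParams]:
    """Convenience wrapper: pick eps from the k-dist knee unless given."""
    if eps is None:
        curve = kdist_curve(Y, k=k)
        if curve.size >= 10:
            eps, _ = select_eps(curve)
        else:  # too few points for a knee; median k-dist is a safe radius
            eps = float(np.median(curve))
    params = ClusterParams(eps=eps, k=k)
    return dbscan(Y, params), params
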