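"""Bridge between density fields and point patterns.

Cluster centres are extracted from a density snapshot as the density-weighted
centroids of connected super-threshold components (periodic 8-connectivity by
default, so clusters straddling the domain boundary stay whole).  Centroids
use a circular mean per axis, which is the correct average for a periodic
coordinate.  The inverse direction — preparing observed column coordinates as
an initial condition — is a pure similarity rescale bringing the mean
nearest-neighbour distance to the model's interaction length (0.61 sensing
radii by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .points import PointSet
from .solver import Grid

__all__ = [
    "extract_cluster_centers",
    "cluster_components",
    "rescale_to_mean_nn",
    "is_disrupted",
    "DisruptionCheck",
]


def _periodic_label(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Connected-component labels on a torus."""
    structure = np.ones((3, 3), dtype=bool) if connectivity == 8 else None
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels, 0
    # merge labels that touch across the periodic boundary
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    N0, N1 = mask.shape
    shifts = [0] if connectivity == 4 else [-1, 0, 1]
    for s in shifts:
        a, b = labels[0, :], np.roll(labels[-1, :], -s)
        for x, y in zip(a, b):
            if x and y:
                union(int(x), int(y))
        a, b = labels[:, 0], np.roll(labels[:, -1], -s)
        for x, y in zip(a, b):
            if x and y:
                union(int(x), int(y))
    remap = np.zeros(n + 1, dtype=labels.dtype)
    roots = sorted({find(a) for a in range(1, n + 1)})
    for new, root in enumerate(roots, start=1):
        remap[[a for a in range(1, n + 1) if find(a) == root]] = new
    return remap[labels], len(roots)


def cluster_components(
    field: np.ndarray,
    grid: Grid,
    threshold: float = 0.01,
    connectivity: int = 8,
):
    """Labelled super-threshold components and their cell counts."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(field) >= threshold
    labels, n = _periodic_label(mask, connectivity)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    return labels, n, np.asarray(sizes, dtype=int)


def extract_cluster_centers(
    field: np.ndarray,
    grid: Grid,
    threshold: float = 0.01,
    connectivity: int = 8,
) -> PointSet | None:
    """Density-weighted centroids of clusters where ``field >= threshold``.

    Each periodic connected component yields one point; the centroid of a
    component is computed with the circular mean per axis so clusters wrapped
    around the boundary land in the right place.  Returns ``None`` when no
    cell reaches the threshold (an empty pattern, not an error).
    """
    field = np.asarray(field, dtype=float)
    labels, n, _ = cluster_components(field, grid, threshold, connectivity)
    if n == 0:
        return None
    box = 2.0 * grid.L
    ax = grid.axis() + grid.L  # cell centres in [0, box)
    phase = 2.0 * np.pi * ax / box
    X_ang, Y_ang = np.meshgrid(phase, phase, indexing="xy")
    w = np.where(labels > 0, field, 0.0)
    centers = np.empty((n, 2))
    for comp in range(1, n + 1):
        m = labels == comp
        wm = w[m]
        for axis, ang in ((0, X_ang), (1, Y_ang)):
            c = (wm * np.cos(ang[m])).sum()
            s = (wm * np.sin(ang[m])).sum()
            centers[comp - 1, axis] = np.mod(np.arctan2(s, c), 2 * np.pi) * box / (2 * np.pi)
    return PointSet(np.mod(centers, box), box=(box, box))


@dataclass(frozen=True)
class DisruptionCheck:
    """Outcome of the columnar-integrity check for one steady state."""

    disrupted: bool
    n_clusters: int
    n_initial: int
    max_area_fraction: float


def is_disrupted(
    field: np.ndarray,
    grid: Grid,
    n_initial: int,
    threshold: float = 0.01,
    count_tol: float = 0.2,
    area_fraction: float = 0.1,
    connectivity: int = 8,
) -> DisruptionCheck:
    """Flag a steady state whose columnar pattern broke down.

    Disrupted when the cluster count deviates from the initial column count
    by more than ``count_tol`` (relative), or when any single component
    covers more than ``area_fraction`` of the domain (clusters merged into
    stripes/blobs).
    """
    _, n, sizes = cluster_components(field, grid, threshold, connectivity)
    domain_cells = grid.N * grid.N
    max_frac = float(sizes.max() / domain_cells) if n else 0.0
    bad_count = n_initial > 0 and abs(n - n_initial) > count_tol * n_initial
    return DisruptionCheck(
        disrupted=bool(bad_count or max_frac > area_fraction or n == 0),
        n_clusters=int(n),
        n_initial=int(n_initial),
        max_area_fraction=max_frac,
    )


def rescale_to_mean_nn(points: PointSet, target: float = 0.61) -> PointSet:
    """Similarity-rescale so the mean nearest-neighbour distance is ``target``.

    The set is also recentred about the origin (finite sets), ready to be
    placed in the solver's domain.  Angles, and hence all symmetry indices,
    are unchanged.
    """
    if target <= 0:
        raise ValueError("target distance must be positive")
    if points.n < 2:
        raise ValueError("need at least two points to define spacing")
    from .symmetry import nearest_neighbor_distances

    mean_nn = float(nearest_neighbor_distances(points).mean())
    if mean_nn == 0:
        raise ValueError("degenerate point set: zero nearest-neighbour distance")
    scale = target / mean_nn
    if points.box is not None:
        bx, by = points.box
        return PointSet(points.coords * scale, (bx * scale, by * scale))
    centred = points.coords - points.coords.mean(axis=0)
    return PointSet(centred * scale, None)
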