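"""NBH-1/2/3 angle statistics and the perturbed-lattice symmetry-index fit.

For each "home" particle of a point set the neighbourhood rules collect a
set of neighbour directions, and the angles recorded are the gaps between
azimuthally consecutive directions (they sum to 360 degrees at every home):

    NBH-1: the 4 nearest neighbours,
    NBH-2: the 6 nearest neighbours,
    NBH-3: all particles within d_ave * sqrt(2) * alpha1 of the home, where
           d_ave is the mean distance to the home's 4 nearest neighbours
           (alpha1 = 1.1).

On a slightly perturbed triangular lattice these concentrate at
{60, 120, 180} / {60} / {60} degrees respectively, and on a square lattice
at {90} / {45, 90} / {45} — so the pooled angle distribution separates
hexagonal from tetragonal order.

Edge exclusion: particles with fewer than 6 others within
d_med * sqrt(2) * alpha2 (d_med the median nearest-neighbour distance,
alpha2 = 1.2) are edge particles and contribute no angles.  Point sets on a
torus have no edges and every particle is a home.

The index fit compares the pooled empirical angle CDF against a library of
reference CDFs F_k(theta; h, p) from the perturbed regular-lattice family
and minimises the L2(0, pi) distance over 0.5 <= h <= 1, 0 <= p <= pmax.
The minimising h is Index-k: 1/2 tetragonal, sqrt(3)/2 hexagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .points import PointSet, min_image

__all__ = [
    "ALPHA1",
    "ALPHA2",
    "THETA_GRID",
    "NeighborStats",
    "AngleECDF",
    "SymmetryFit",
    "neighbor_stats",
    "nearest_neighbor_distances",
    "interior_indices",
    "interior_particles",
    "angles_nbh1",
    "angles_nbh2",
    "angles_nbh3",
    "pooled_angles",
    "angle_ecdf",
    "l2_error",
    "fit_index",
    "compute_indices",
]

log = logging.getLogger(__name__)

ALPHA1 = 1.1  # NBH-3 radius factor: d_ave * sqrt(2) * alpha1
ALPHA2 = 1.2  # edge rule radius factor: d_med * sqrt(2) * alpha2

# Common evaluation grid for the L2(0, pi) norm of CDF differences.
THETA_GRID = np.linspace(0.0, np.pi, 2048)


def _tree(points: PointSet) -> cKDTree:
    if points.is_periodic:
        return cKDTree(points.coords, boxsize=points.box)
    return cKDTree(points.coords)


def _knn(points: PointSet, m: int):
    """Index-tie-broken m nearest neighbours of every particle.

    Returns (dist, idx), each (n, m), sorted by distance with exact ties
    resolved by ascending point index (deterministic on perfect lattices).
    """
    n = points.n
    if n - 1 < m:
        raise ValueError(f"need at least {m} other particles, have {n - 1}")
    kq = min(n, m + 9)  # a few extra candidates so ties can be re-ordered
    dist, idx = _tree(points).query(points.coords, k=kq)
    # drop self (distance 0 in the first column)
    dist, idx = dist[:, 1:], idx[:, 1:]
    # re-order candidate columns by index first, then stable-sort by distance,
    # so exact distance ties come out in ascending point index
    perm = np.argsort(idx, axis=1)
    r = np.arange(n)[:, None]
    dist, idx = dist[r, perm], idx[r, perm]
    order = np.argsort(dist, axis=1, kind="stable")
    dist, idx = dist[r, order], idx[r, order]
    return dist[:, :m], idx[:, :m]


def nearest_neighbor_distances(points: PointSet) -> np.ndarray:
    """Distance from each particle to its nearest other particle."""
    if points.n < 2:
        raise ValueError("need at least two points")
    return _tree(points).query(points.coords, k=2)[0][:, 1]


@dataclass(frozen=True)
class NeighborStats:
    """Per-particle neighbour distances used by the edge and NBH-3 rules."""

    d_i: np.ndarray      # nearest-neighbour distance per particle
    d_med: float         # median of d_i
    d_ave: np.ndarray    # per-particle mean distance to the 4 nearest
    alpha1: float = ALPHA1
    alpha2: float = ALPHA2

    @property
    def edge_radius(self) -> float:
        return self.d_med * np.sqrt(2.0) * self.alpha2

    def nbh3_radius(self, i: int | np.ndarray) -> np.ndarray:
        return self.d_ave[i] * np.sqrt(2.0) * self.alpha1


def neighbor_stats(points: PointSet, alpha1: float = ALPHA1,
                   alpha2: float = ALPHA2) -> NeighborStats:
    dist4, _ = _knn(points, 4)
    d_i = dist4[:, 0]
    return NeighborStats(
        d_i=d_i,
        d_med=float(np.median(d_i)),
        d_ave=dist4.mean(axis=1),
        alpha1=alpha1,
        alpha2=alpha2,
    )


def interior_indices(points: PointSet, alpha2: float = ALPHA2) -> np.ndarray:
    """Indices of home (non-edge) particles.

    A particle is a home if at least 6 others lie within
    d_med * sqrt(2) * alpha2.  Torus point sets have no edges: all kept.
    """
    if points.n < 7:
        raise ValueError("fewer than 7 points: no interior particles possible")
    if points.is_periodic:
        return np.arange(points.n)
    stats = neighbor_stats(points, alpha2=alpha2)
    counts = _tree(points).query_ball_point(
        points.coords, stats.edge_radius, return_length=True
    )
    return np.nonzero(np.asarray(counts) - 1 >= 6)[0]  # subtract self


def interior_particles(points: PointSet, alpha2: float = ALPHA2) -> PointSet | None:
    """The home-particle subset (None when every particle is an edge)."""
    keep = interior_indices(points, alpha2)
    if keep.size == 0:
        return None
    return points.subset(keep)


def _gaps(az: np.ndarray) -> np.ndarray:
    """Gaps between azimuthally consecutive directions; sum to 2*pi."""
    a = np.sort(az)
    return np.diff(a, append=a[0] + 2.0 * np.pi)


def _azimuths(points: PointSet, home: int, nb: np.ndarray) -> np.ndarray:
    d = points.coords[nb] - points.coords[home]
    if points.is_periodic:
        d = min_image(d, points.box)
    return np.arctan2(d[:, 1], d[:, 0])


def angles_nbh1(points: PointSet, home: int) -> np.ndarray:
    """The 4 consecutive-direction gaps over the home's 4 nearest neighbours."""
    _, idx = _knn(points, 4)
    return _gaps(_azimuths(points, home, idx[home]))


def angles_nbh2(points: PointSet, home: int) -> np.ndarray:
    """The 6 consecutive-direction gaps over the home's 6 nearest neighbours."""
    _, idx = _knn(points, 6)
    return _gaps(_azimuths(points, home, idx[home]))


def angles_nbh3(points: PointSet, home: int, alpha1: float = ALPHA1) -> np.ndarray:
    """Gaps over all particles within d_ave * sqrt(2) * alpha1 of the home.

    Returns an empty array (and logs) when fewer than 2 particles fall in
    the region.
    """
    stats = neighbor_stats(points, alpha1=alpha1)
    nb = _tree(points).query_ball_point(
        points.coords[home], float(stats.nbh3_radius(home))
    )
    nb = np.array([j for j in nb if j != home], dtype=int)
    if nb.size < 2:
        log.info("home %d has %d NBH-3 neighbours; contributes no angles",
                 home, nb.size)
        return np.empty(0)
    return _gaps(_azimuths(points, home, nb))


def pooled_angles(points: PointSet, k: int, alpha1: float = ALPHA1,
                  alpha2: float = ALPHA2) -> np.ndarray:
    """All interior particles' NBH-k gap angles, pooled (radians)."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    homes = interior_indices(points, alpha2)
    if homes.size == 0:
        raise ValueError("no interior particles: cannot pool angles")
    coords = points.coords
    box = points.box

    def az_of(home_rep, nb_flat):
        d = coords[nb_flat] - coords[home_rep]
        if box is not None:
            d = min_image(d, box)
        return np.arctan2(d[:, 1], d[:, 0])

    if k in (1, 2):
        m = 4 if k == 1 else 6
        _, idx = _knn(points, m)
        nb = idx[homes]                      # (H, m)
        az = az_of(np.repeat(homes, m), nb.ravel()).reshape(-1, m)
        az = np.sort(az, axis=1)
        gaps = np.diff(az, axis=1)
        wrap = 2.0 * np.pi - (az[:, -1] - az[:, 0])
        return np.concatenate([gaps.ravel(), wrap])

    stats = neighbor_stats(points, alpha1=alpha1)
    tree = _tree(points)
    radii = stats.nbh3_radius(homes)
    groups = tree.query_ball_point(coords[homes], radii)
    out = []
    dropped = 0
    for home, nb in zip(homes, groups):
        nb = [j for j in nb if j != home]
        if len(nb) < 2:
            dropped += 1
            continue
        out.append(_gaps(az_of(home, np.asarray(nb))))
    if dropped:
        log.info("%d of %d homes had <2 NBH-3 neighbours and were skipped",
                 dropped, homes.size)
    if not out:
        raise ValueError("no home particle produced NBH-3 angles")
    return np.concatenate(out)


@dataclass(frozen=True)
class AngleECDF:
    """Empirical CDF of a pooled angle sample.

    ``sample`` is sorted ascending; ``n`` is the total pooled count,
    including angles beyond pi (kept in the denominator, so F(pi) may fall
    short of 1 — both data and reference CDFs treat them identically and the
    deficit cancels in the L2 error over (0, pi)).
    """

    sample: np.ndarray
    n: int

    @classmethod
    def from_angles(cls, angles: np.ndarray) -> "AngleECDF":
        a = np.sort(np.asarray(angles, dtype=float).ravel())
        if a.size == 0:
            raise ValueError("empty angle sample")
        return cls(a, a.size)

    def evaluate(self, theta=None) -> np.ndarray:
        """F(theta) = (number of angles <= theta) / n."""
        if theta is None or theta is THETA_GRID:
            cached = getattr(self, "_grid_eval", None)
            if cached is None:
                cached = np.searchsorted(self.sample, THETA_GRID,
                                         side="right") / self.n
                object.__setattr__(self, "_grid_eval", cached)
            return cached
        return np.searchsorted(self.sample, theta, side="right") / self.n


def angle_ecdf(points: PointSet, k: int, alpha1: float = ALPHA1,
               alpha2: float = ALPHA2) -> AngleECDF:
    """Pooled NBH-k angle ECDF of a point set (interior particles only)."""
    return AngleECDF.from_angles(pooled_angles(points, k, alpha1, alpha2))


def l2_error(f_data: AngleECDF, f_ref: AngleECDF,
             grid: np.ndarray = THETA_GRID) -> float:
    """Discrete L2(0, pi) norm of F_data - F_ref (trapezoidal quadrature)."""
    diff = f_data.evaluate(grid) - f_ref.evaluate(grid)
    return float(np.sqrt(np.trapezoid(diff * diff, grid)))


@dataclass(frozen=True)
class SymmetryFit:
    """Result of the perturbed-lattice fit: Index-k = h_star."""

    k: int
    h_star: float
    p_star: float
    E: float
    pmax: float
    n_interior: int = 0
    n_angles: int = 0


def fit_index(f_data: AngleECDF, k: int, library, pmax: float = 40.0,
              n_interior: int = 0) -> SymmetryFit:
    """Exhaustive argmin of E_k(h, p) over the reference library grid.

    Only nodes with p <= pmax are considered; exact ties are broken by
    smaller p, then smaller h.
    """
    f_grid = f_data.evaluate(THETA_GRID)
    best = None
    for h, p, ref in library:
        if p > pmax + 1e-12:
            continue
        diff = f_grid - ref.evaluate()
        e = float(np.sqrt(np.trapezoid(diff * diff, THETA_GRID)))
        key = (e, p, h)
        if best is None or key < best[0]:
            best = (key, h, p, e)
    if best is None:
        raise ValueError("reference library has no nodes with p <= pmax")
    _, h_star, p_star, e = best
    return SymmetryFit(k=k, h_star=float(h_star), p_star=float(p_star), E=e,
                       pmax=pmax, n_interior=n_interior,
                       n_angles=int(f_data.n))


def compute_indices(points: PointSet, pmax: float = 40.0, libraries=None,
                    alpha1: float = ALPHA1, alpha2: float = ALPHA2,
                    **library_kwargs) -> dict[int, SymmetryFit]:
    """Index-1/2/3 of a point set (Index-3 is the headline index).

    ``libraries`` maps k -> ReferenceLibrary; missing entries are built on
    the default grids (h step 0.005, p step 1), which is slow — sweep-scale
    callers should pass prebuilt libraries.
    """
    libraries = dict(libraries or {})
    ks = sorted(libraries) or [1, 2, 3]
    out = {}
    for kk in ks:
        if kk not in libraries:
            from .lattice import ReferenceLibrary

            libraries[kk] = ReferenceLibrary.build(kk, pmax=pmax,
                                                   **library_kwargs)
        n_int = len(interior_indices(points, alpha2))
        ecdf = angle_ecdf(points, kk, alpha1, alpha2)
        out[kk] = fit_index(ecdf, kk, libraries[kk], pmax, n_interior=n_int)
    return out
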