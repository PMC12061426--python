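"""2D point sets (column centres / cluster centres) with optional periodic box."""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = ["PointSet", "read_points_csv", "write_points_csv", "min_image"]


@dataclass(frozen=True)
class PointSet:
    """Coordinates of columns or cluster centres.

    ``box = (bx, by)`` marks the set as living on a torus of those side
    lengths (coordinates interpreted modulo the box); ``box = None`` is a
    plain finite set with edges.
    """

    coords: np.ndarray
    box: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if coords.shape[0] < 1:
            raise ValueError("a PointSet needs at least one point")
        if self.box is not None:
            bx, by = self.box
            if bx <= 0 or by <= 0:
                raise ValueError("box side lengths must be positive")
            coords = np.mod(coords, (bx, by))
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("coincident points are not allowed")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def is_periodic(self) -> bool:
        return self.box is not None

    def displacements_from(self, i: int) -> np.ndarray:
        """Vectors from point i to every point (minimum image if periodic)."""
        d = self.coords - self.coords[i]
        if self.box is not None:
            d = min_image(d, self.box)
        return d

    def subset(self, indices) -> "PointSet":
        return PointSet(self.coords[np.asarray(indices)], self.box)

    def transformed(self, scale: float = 1.0, rotation: float = 0.0,
                    shift=(0.0, 0.0), reflect: bool = False) -> "PointSet":
        """Similarity transform (finite sets only; a box does not rotate)."""
        c, s = np.cos(rotation), np.sin(rotation)
        R = np.array([[c, -s], [s, c]])
        xy = self.coords.copy()
        if reflect:
            xy[:, 0] = -xy[:, 0]
        xy = scale * xy @ R.T + np.asarray(shift, dtype=float)
        return PointSet(xy, None)


def min_image(d: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    b = np.asarray(box, dtype=float)
    return d - b * np.round(d / b)


def write_points_csv(points: PointSet, path_or_buf) -> None:
    """Two-column x,y CSV; the periodic box (if any) goes in a comment header."""
    header = "x,y"
    if points.box is not None:
        header = f"# box {points.box[0]:.17g} {points.box[1]:.17g}\n" + header
    lines = [header] + [f"{x:.17g},{y:.17g}" for x, y in points.coords]
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_points_csv(path_or_buf) -> PointSet:
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    box = None
    body = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "box":
                box = (float(parts[1]), float(parts[2]))
            continue
        if line.lower().startswith("x,"):
            continue
        body.append(line)
    coords = np.loadtxt(io.StringIO("\n".join(body)), delimiter=",")
    return PointSet(coords, box)
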