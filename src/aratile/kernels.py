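"""Piecewise-constant interaction kernels and their potentials.

The ARA (adhesion-repulsion-attraction) kernel assigns a signed radial force
to each distance ``r`` from a cell, measured in units of the sensing radius
(normalised to 1):

    omega(r) = F0  on [0, R0)    short-range adhesion  (F0 > 0)
               Fr  on [R0, R1)   medium-range repulsion (Fr <= 0)
               0   on [R1, R2)   the "terrace"
               Fa  on [R2, 1)    long-range attraction  (Fa >= 0)
               0   on [1, inf)

All intervals are half-open: a radius sitting exactly on a breakpoint takes
the right-hand band's value.  The induced potential ``U`` is the continuous
piecewise-linear antiderivative of omega with U(0) = 0; its flat stretch over
[R1, R2) (the terrace) is what tilts steady patterns from triangular towards
square arrangements.

Pure-adhesion kernels (used for every species pair except R7-R7) are the same
shape with the repulsion and attraction bands collapsed: Fr = Fa = 0 and
R1 = R2 = R0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "InteractionMatrix",
    "KernelValidationError",
    "evaluate_kernel",
    "potential",
    "pure_adhesion",
    "build_interaction_matrix",
    "TABLE2_DEFAULTS",
]

SPECIES = ("R7", "R8", "Mi1")


class KernelValidationError(ValueError):
    """Raised when kernel parameters violate the model's constraints."""


@dataclass(frozen=True)
class KernelParams:
    """Parameters of one piecewise-constant ARA kernel.

    F0 : adhesion strength, > 0
    Fr : repulsion strength, <= 0 (0 for pure-adhesion kernels)
    Fa : attraction strength, >= 0 (0 for pure-adhesion kernels)
    R0, R1, R2 : band breakpoints in sensing-radius units,
        0 < R0 <= R1 <= R2 <= 1
    """

    F0: float
    Fr: float
    Fa: float
    R0: float
    R1: float
    R2: float

    def __post_init__(self) -> None:
        if not self.F0 > 0:
            raise KernelValidationError(f"F0 must be > 0, got F0={self.F0}")
        if not self.Fr <= 0:
            raise KernelValidationError(f"Fr must be <= 0, got Fr={self.Fr}")
        if not self.Fa >= 0:
            raise KernelValidationError(f"Fa must be >= 0, got Fa={self.Fa}")
        if not 0 < self.R0:
            raise KernelValidationError(f"R0 must be > 0, got R0={self.R0}")
        if not self.R0 <= self.R1 <= self.R2 <= 1:
            raise KernelValidationError(
                "breakpoints must satisfy 0 < R0 <= R1 <= R2 <= 1, got "
                f"R0={self.R0}, R1={self.R1}, R2={self.R2}"
            )
        if self.R2 == 1 and self.Fa != 0:
            warnings.warn(
                "R2 = 1 leaves no attraction band; Fa has no effect",
                stacklevel=3,
            )

    @property
    def is_pure_adhesion(self) -> bool:
        return self.Fr == 0 and self.Fa == 0

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def pure_adhesion(F0: float, R0: float) -> KernelParams:
    """Adhesion-only kernel: F0 on [0, R0), zero beyond."""
    return KernelParams(F0=F0, Fr=0.0, Fa=0.0, R0=R0, R1=R0, R2=R0)


def evaluate_kernel(r, params: KernelParams):
    """Evaluate omega(r); scalar or ndarray ``r`` >= 0.

    Bands are half-open [a, b): a radius exactly at a breakpoint takes the
    right-hand band's constant.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    out = np.zeros_like(r)
    out[r < params.R0] = params.F0
    out[(r >= params.R0) & (r < params.R1)] = params.Fr
    out[(r >= params.R2) & (r < 1.0)] = params.Fa
    return out if out.ndim else float(out)


def potential(r, params: KernelParams):
    """Piecewise-linear potential U(r) with U' = omega and U(0) = 0.

    Continuous; constant on the terrace [R1, R2) and for r >= 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    F0, Fr, Fa = params.F0, params.Fr, params.Fa
    R0, R1, R2 = params.R0, params.R1, params.R2
    # cumulative values at the left edge of each band
    u_R0 = F0 * R0
    u_R1 = u_R0 + Fr * (R1 - R0)
    u_R2 = u_R1  # terrace
    u_1 = u_R2 + Fa * (1.0 - R2)
    out = np.empty_like(r)
    b0 = r < R0
    b1 = (r >= R0) & (r < R1)
    b2 = (r >= R1) & (r < R2)
    b3 = (r >= R2) & (r < 1.0)
    b4 = r >= 1.0
    out[b0] = F0 * r[b0]
    out[b1] = u_R0 + Fr * (r[b1] - R0)
    out[b2] = u_R1
    out[b3] = u_R2 + Fa * (r[b3] - R2)
    out[b4] = u_1
    return out if out.ndim else float(out)


# Default three-species parameters: species 1 = R7, 2 = R8, 3 = Mi1.
# Only the R7-R7 interaction carries the full ARA shape; all other pairs are
# pure adhesion, ordered F0_11 > F0_12 > F0_22 > F0_23 > F0_33 so that the
# most cohesive population (R7) sits at the column core.
TABLE2_DEFAULTS: dict[tuple[int, int], dict[str, float]] = {
    (1, 1): dict(F0=2000.0, Fr=-2000.0, Fa=300.0, R0=0.14, R1=0.55, R2=0.64),
    (1, 2): dict(F0=50.0, R0=0.3),
    (1, 3): dict(F0=20.0, R0=0.14),
    (2, 2): dict(F0=25.0, R0=0.14),
    (2, 3): dict(F0=15.0, R0=0.14),
    (3, 3): dict(F0=10.0, R0=0.14),
}


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric 3x3 table of kernels for the three-species model.

    Entry (1,1) (R7-R7) is the full ARA kernel; every other pair is pure
    adhesion.  Symmetry (kernels[i][j] == kernels[j][i]) encodes the
    action-reaction law.
    """

    kernels: tuple[tuple[KernelParams, ...], ...]

    def __getitem__(self, pair: tuple[int, int]) -> KernelParams:
        i, j = pair
        return self.kernels[i - 1][j - 1]

    def row(self, i: int) -> tuple[KernelParams, ...]:
        """Kernels felt by species ``i`` (1-based) from species 1..3."""
        return self.kernels[i - 1]

    def to_config(self) -> dict[str, dict[str, float]]:
        """Serialise as a ``{"kernel.ij": {F0, Fr, Fa, R0, R1, R2}}`` mapping."""
        out = {}
        for i in range(1, 4):
            for j in range(i, 4):
                out[f"kernel.{i}{j}"] = self[i, j].to_dict()
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_config(), indent=2, sort_keys=True)


def _parse_pair(key: str) -> tuple[int, int]:
    digits = key.removeprefix("kernel.")
    if len(digits) != 2 or not digits.isdigit():
        raise KernelValidationError(f"malformed kernel section name {key!r}")
    i, j = int(digits[0]), int(digits[1])
    if not (1 <= i <= 3 and 1 <= j <= 3):
        raise KernelValidationError(f"species indices out of range in {key!r}")
    return i, j


def build_interaction_matrix(config: dict | None = None) -> InteractionMatrix:
    """Populate the 3x3 kernel matrix from defaults plus overrides.

    ``config`` maps either ``"kernel.ij"`` sections or bare parameter names
    suffixed with the pair (``"Fa_11"``, ``"R2_11"``) to values.  Unspecified
    entries take the defaults above.  Supplying both orientations of an
    off-diagonal pair with different values is rejected (action-reaction law).
    """
    overrides: dict[tuple[int, int], dict[str, float]] = {}

    def put(i: int, j: int, name: str, value: float) -> None:
        pair = (min(i, j), max(i, j))
        entry = overrides.setdefault(pair, {})
        if name in entry and entry[name] != value:
            raise KernelValidationError(
                f"asymmetric input for {name}_{i}{j}: {entry[name]} vs {value} "
                "violates the action-reaction law"
            )
        entry[name] = value

    for key, val in (config or {}).items():
        if key.startswith("kernel."):
            i, j = _parse_pair(key)
            for name, x in val.items():
                put(i, j, name, float(x))
        elif "_" in key:
            name, pair = key.rsplit("_", 1)
            if len(pair) != 2 or not pair.isdigit():
                raise KernelValidationError(f"malformed parameter name {key!r}")
            put(int(pair[0]), int(pair[1]), name, float(val))
        else:
            raise KernelValidationError(f"unrecognised config key {key!r}")

    table: dict[tuple[int, int], KernelParams] = {}
    for (i, j), defaults in TABLE2_DEFAULTS.items():
        params = dict(defaults)
        params.update(overrides.get((i, j), {}))
        if (i, j) == (1, 1):
            table[i, j] = KernelParams(**params)
        else:
            # pure adhesion: Fr/Fa must vanish and R1/R2 collapse onto R0
            r0 = params["R0"]
            bad = [k for k in ("Fr", "Fa") if params.get(k)]
            bad += [k for k in ("R1", "R2")
                    if k in params and params[k] != r0]
            if bad:
                raise KernelValidationError(
                    f"pair ({i},{j}) is pure adhesion; only F0 and R0 may "
                    f"vary (got {sorted(bad)})"
                )
            params = {"F0": params["F0"], "R0": r0}
            table[i, j] = pure_adhesion(params["F0"], params["R0"])
    rows = tuple(
        tuple(table[min(i, j), max(i, j)] for j in range(1, 4)) for i in range(1, 4)
    )
    return InteractionMatrix(kernels=rows)


def matrix_from_json(text: str) -> InteractionMatrix:
    return build_interaction_matrix(json.loads(text))
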