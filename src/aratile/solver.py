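"""Explicit upwind finite-volume solver for the nonlocal ARA population model.

Single-species model on a periodic square (-L, L)^2:

    du/dt = div(u grad u) - div(u (1 - u) K(u)),
    K(u)(x) = integral over |y| <= 1 of u(x + y) omega(|y|) y/|y| dy,

and its three-species extension for the R7/R8/Mi1 densities u, v, w with
total density sigma = u + v + w:

    du_i/dt = div(u_i grad sigma) - div(u_i (1 - sigma) K_i),
    K_i = sum_j (omega_ij convolved against u_j, as above).

The nonlinear-diffusion term models population pressure (cells flow down the
total-density gradient); the nonlocal drift K_i aggregates the pairwise
adhesion/repulsion/attraction forces within the unit sensing radius; the
(1 - sigma) factor saturates motion in packed regions.

Discretisation: cell-centred finite volumes, donor-cell (upwind) face fluxes
with a two-point central gradient, explicit Euler in time with an adaptive
CFL-limited step.  The nonlocal integral is a fixed Cartesian stencil
w(y) = omega(|y|) y/|y| dx^2 sampled at cell-centre offsets inside the unit
disk, applied either by FFT (default) or by direct shift-and-accumulate
summation over the same stencil nodes (the two agree to round-off and
cross-validate each other).

Both models share one code path: a single species is the three-species system
with S = 1, where sigma = u.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .kernels import InteractionMatrix, KernelParams, evaluate_kernel

__all__ = [
    "Grid",
    "SpeciesState",
    "ConfigurationError",
    "CFLError",
    "vector_stencil",
    "nonlocal_term",
    "disk_initial",
    "initial_from_points",
    "Simulation",
    "SteadyResult",
]


class ConfigurationError(ValueError):
    pass


class CFLError(RuntimeError):
    """Requested time step violates the explicit stability restriction."""

    def __init__(self, dt: float, admissible: float):
        self.admissible = admissible
        super().__init__(
            f"dt={dt:g} violates the CFL restriction; admissible dt={admissible:g}"
        )


@dataclass(frozen=True)
class Grid:
    """Uniform periodic N x N grid on the square (-L, L)^2."""

    N: int
    L: float = 2.8

    def __post_init__(self) -> None:
        if self.N % 2 or self.N <= 0:
            raise ConfigurationError(f"N must be a positive even integer, got {self.N}")
        if self.L < 1.0:
            raise ConfigurationError(
                f"half-width L={self.L} cannot contain the unit sensing radius"
            )

    @property
    def dx(self) -> float:
        return 2.0 * self.L / self.N

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx

    def axis(self) -> np.ndarray:
        """Cell-centre coordinates along one axis."""
        return -self.L + (np.arange(self.N) + 0.5) * self.dx

    def offsets(self) -> np.ndarray:
        """Signed cell-centre offsets in FFT (wrapped) order, one axis."""
        k = np.arange(self.N)
        return np.where(k <= self.N // 2, k, k - self.N) * self.dx


def vector_stencil(params: KernelParams, grid: Grid) -> np.ndarray:
    """Discrete vector weight w(y) = omega(|y|) y/|y| dx^2 on wrapped offsets.

    Returns shape (2, N, N): components (x, y) indexed [comp, iy, ix].  Cells
    whose centre lies exactly on a band breakpoint take the right-hand band's
    constant (half-open convention of the kernel).
    """
    o = grid.offsets()
    X, Y = np.meshgrid(o, o, indexing="xy")  # X varies along ix, Y along iy
    r = np.hypot(X, Y)
    w = evaluate_kernel(r, params) * grid.cell_area
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, X / r, 0.0)
        uy = np.where(r > 0, Y / r, 0.0)
    return np.stack([w * ux, w * uy])


def _flip(a: np.ndarray) -> np.ndarray:
    """a(-y) on the wrapped grid: index map i -> (-i) mod N on both axes."""
    return np.roll(a[..., ::-1, ::-1], shift=(1, 1), axis=(-2, -1))


def nonlocal_term(
    fields: np.ndarray,
    kernels: KernelParams | list[KernelParams] | tuple[KernelParams, ...],
    grid: Grid,
    method: str = "fft",
) -> np.ndarray:
    """Nonlocal drift K (or K_i) for one species.

    ``fields``: (N, N) single density or (S, N, N) stack; ``kernels`` one
    KernelParams per field (the matrix row of the species of interest).
    Returns (2, N, N): the x and y components of K at every cell.

    ``method="fft"`` applies the stencil by periodic convolution;
    ``method="direct"`` evaluates the same sum by explicit shift-and-accumulate
    over stencil nodes (slow; used for cross-validation).
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim == 2:
        fields = fields[None]
    if isinstance(kernels, KernelParams):
        kernels = [kernels]
    if len(kernels) != fields.shape[0]:
        raise ValueError("need one kernel per density field")

    K = np.zeros((2, grid.N, grid.N))
    if method == "fft":
        for u, params in zip(fields, kernels):
            u_hat = np.fft.rfft2(u)
            g = _flip(vector_stencil(params, grid))  # w(-y) for convolution
            for c in range(2):
                K[c] += np.fft.irfft2(u_hat * np.fft.rfft2(g[c]), s=u.shape)
    elif method == "direct":
        for u, params in zip(fields, kernels):
            w = vector_stencil(params, grid)
            iy, ix = np.nonzero(w[0] ** 2 + w[1] ** 2)
            for oy, ox in zip(iy, ix):
                shifted = np.roll(u, shift=(-oy, -ox), axis=(0, 1))
                K[0] += w[0, oy, ox] * shifted
                K[1] += w[1, oy, ox] * shifted
    else:
        raise ValueError(f"unknown method {method!r}")
    return K


def disk_initial(grid: Grid, level: float = 0.1, radius: float = 0.2) -> np.ndarray:
    """Density = ``level`` in the disk of given radius about the origin, else 0."""
    if radius >= grid.L:
        raise ConfigurationError("disk radius must be smaller than the half-width")
    x = grid.axis()
    X, Y = np.meshgrid(x, x, indexing="xy")
    return np.where(X * X + Y * Y < radius * radius, float(level), 0.0)


def initial_from_points(
    points,
    grid: Grid,
    r_core: float = 0.04,
    r_shell: float = 0.12,
    levels: tuple[float, float, float] = (0.2, 0.1, 0.04),
) -> np.ndarray:
    """Three-species initial condition from column-centre coordinates.

    With d = periodic distance from a cell centre to the nearest column
    centre: u = levels[0] where d < r_core, v = levels[1] where
    r_core <= d < r_shell, w = levels[2] where d >= r_shell.  The point set
    should already be rescaled so the mean nearest-neighbour distance matches
    the kernels' length scale (0.61 by default elsewhere).
    """
    coords = np.asarray(getattr(points, "coords", points), dtype=float)
    if coords.size == 0:
        raise ValueError("empty point set")
    box = 2.0 * grid.L
    tree = cKDTree(np.mod(coords + grid.L, box), boxsize=box)
    x = grid.axis()
    X, Y = np.meshgrid(x, x, indexing="xy")
    cells = np.column_stack([(X + grid.L).ravel(), (Y + grid.L).ravel()])
    d = tree.query(cells)[0].reshape(grid.N, grid.N)
    u = np.where(d < r_core, levels[0], 0.0)
    v = np.where((d >= r_core) & (d < r_shell), levels[1], 0.0)
    w = np.where(d >= r_shell, levels[2], 0.0)
    return np.stack([u, v, w])


@dataclass
class SpeciesState:
    """Density fields (S, N, N) at time t; S = 1 or 3 species."""

    fields: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.ndim == 2:
            self.fields = self.fields[None]
        if np.any(self.fields < 0):
            raise ValueError("density fields must be nonnegative")

    @property
    def sigma(self) -> np.ndarray:
        return self.fields.sum(axis=0)

    def mass(self, grid: Grid) -> np.ndarray:
        """Per-species total mass."""
        return self.fields.sum(axis=(1, 2)) * grid.cell_area

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.fields.copy(), self.t)


@dataclass
class SteadyResult:
    state: SpeciesState
    converged: bool
    residuals: list[tuple[float, float]] = field(default_factory=list)
    initial_mass: np.ndarray | None = None  # per-species, if the caller recorded it


class Simulation:
    """Time integrator for the one- or three-species ARA model.

    ``kernels`` is a single KernelParams (one species) or an
    InteractionMatrix (three species).  The finest adhesion band must span at
    least three cells (dx <= R0/3) so the force profile is resolved.
    """

    CFL_SAFETY = 0.9

    def __init__(
        self,
        grid: Grid,
        kernels: KernelParams | InteractionMatrix,
        check_resolution: bool = True,
    ):
        self.grid = grid
        if isinstance(kernels, KernelParams):
            rows = [[kernels]]
        else:
            rows = [list(kernels.row(i)) for i in (1, 2, 3)]
        self.kernel_rows = rows
        self.n_species = len(rows)
        if check_resolution:
            r0_min = min(p.R0 for row in rows for p in row)
            if grid.dx > r0_min / 3 + 1e-12:
                raise ConfigurationError(
                    f"dx={grid.dx:g} under-resolves the adhesion band "
                    f"(need dx <= R0/3 = {r0_min / 3:g}); increase N"
                )
        # Fourier transforms of the flipped stencils, one per species pair.
        self._g_hat = [
            [
                np.stack(
                    [np.fft.rfft2(c) for c in _flip(vector_stencil(p, grid))]
                )
                for p in row
            ]
            for row in rows
        ]

    # -- spatial operators ------------------------------------------------

    def nonlocal_all(self, fields: np.ndarray) -> np.ndarray:
        """K_i for every species; shape (S, 2, N, N)."""
        N = self.grid.N
        u_hat = [np.fft.rfft2(f) for f in fields]
        K = np.empty((self.n_species, 2, N, N))
        for i in range(self.n_species):
            for c in range(2):
                acc = np.zeros_like(u_hat[0])
                for j in range(self.n_species):
                    acc += u_hat[j] * self._g_hat[i][j][c]
                K[i, c] = np.fft.irfft2(acc, s=(N, N))
        return K

    def _face_velocities(self, fields: np.ndarray, K: np.ndarray):
        """Upwind face velocities for both axes; each (S, N, N).

        Vx[s, iy, ix] lives on the face between cells ix and ix+1 (periodic);
        Vy on the face between iy and iy+1.
        """
        sigma = fields.sum(axis=0)
        out = []
        for axis, comp in ((2, 0), (1, 1)):  # x-faces then y-faces
            ax = axis - 1  # axis within an (N, N) slice
            s_nb = np.roll(sigma, -1, axis=ax)
            grad = (s_nb - sigma) / self.grid.dx
            sat = np.maximum(1.0 - 0.5 * (sigma + s_nb), 0.0)
            Kf = 0.5 * (K[:, comp] + np.roll(K[:, comp], -1, axis=ax + 1))
            out.append(-grad[None] + sat[None] * Kf)
        return out  # [Vx, Vy]

    def admissible_dt(self, state: SpeciesState) -> float:
        K = self.nonlocal_all(state.fields)
        Vx, Vy = self._face_velocities(state.fields, K)
        return self._dt_from(state.fields, Vx, Vy)

    def _dt_from(self, fields, Vx, Vy) -> float:
        dx = self.grid.dx
        smax = max(fields.sum(axis=0).max(), 1e-300)
        vmax = np.abs(Vx).max() + np.abs(Vy).max()
        dt_diff = dx * dx / (4.0 * smax)
        dt_adv = dx / (2.0 * vmax) if vmax > 0 else np.inf
        return self.CFL_SAFETY * min(dt_diff, dt_adv)

    # -- time stepping ----------------------------------------------------

    def step(self, state: SpeciesState, dt: float | None = None) -> SpeciesState:
        """One explicit donor-cell update.  Conserves each species' mass.

        If ``dt`` exceeds the admissible CFL step, raises :class:`CFLError`
        carrying the admissible value.
        """
        fields = state.fields
        K = self.nonlocal_all(fields)
        Vx, Vy = self._face_velocities(fields, K)
        dt_adm = self._dt_from(fields, Vx, Vy)
        if dt is None:
            dt = dt_adm
        elif dt > dt_adm * (1 + 1e-12):
            raise CFLError(dt, dt_adm)
        dx = self.grid.dx
        new = fields.copy()
        for ax, V in ((1, Vx), (0, Vy)):  # ax within (N, N) slices: y=0, x=1
            a = ax + 1  # axis within (S, N, N)
            donor = np.where(V > 0, fields, np.roll(fields, -1, axis=a))
            F = donor * V
            new -= (dt / dx) * (F - np.roll(F, 1, axis=a))
        return SpeciesState(new, state.t + dt)

    def advance_to(self, state: SpeciesState, t_end: float) -> SpeciesState:
        while state.t < t_end - 1e-12:
            fields = state.fields
            K = self.nonlocal_all(fields)
            Vx, Vy = self._face_velocities(fields, K)
            dt = min(self._dt_from(fields, Vx, Vy), t_end - state.t)
            new = fields.copy()
            dx = self.grid.dx
            for ax, V in ((1, Vx), (0, Vy)):
                a = ax + 1
                donor = np.where(V > 0, fields, np.roll(fields, -1, axis=a))
                F = donor * V
                new -= (dt / dx) * (F - np.roll(F, 1, axis=a))
            state = SpeciesState(new, state.t + dt)
        return state

    def run_to_steady(
        self,
        state: SpeciesState,
        tol: float = 1e-5,
        t_max: float = 2000.0,
        check_interval: float = 1.0,
        callback=None,
    ) -> SteadyResult:
        """Integrate until the l2 distance between states one time unit apart
        falls below ``tol`` (or ``t_max`` is reached, flagged non-converged).
        """
        if tol <= 0:
            raise ValueError("tol must be positive")
        residuals: list[tuple[float, float]] = []
        prev = state.copy()
        while state.t < t_max - 1e-9:
            target = min(state.t + check_interval, t_max)
            state = self.advance_to(state, target)
            diff = state.fields - prev.fields
            res = float(np.sqrt((diff * diff).sum() * self.grid.cell_area))
            residuals.append((state.t, res))
            if callback is not None:
                callback(state.t, res)
            if res < tol:
                return SteadyResult(state, True, residuals)
            prev = state.copy()
        return SteadyResult(state, False, residuals)
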