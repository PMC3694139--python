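"""Interstitial fluid pressure from Darcy flow with Starling sources.

The tissue is a porous medium: v = -K grad(P_i), with fluid entering
from the capillaries at rate (per unit volume)

    Phi_B = A L_p (S/V) [ (P_b - P_i) - sigma (pi_B - pi_i) ]

wherever the source indicator A marks a perfused cell (lymphatic drainage
is neglected).  Steady continuity gives -div(K grad P_i) = Phi_B, a
linear reaction-diffusion equation discretized on a cell-centered
5-point stencil with harmonic face averaging of K at the tumor/normal
interface.  The left edge (parent vessel side) carries a Dirichlet value;
the other three edges are no-flux.  The solver is red-black SOR with the
source's P_i-dependence folded into the diagonal; a direct sparse solve
of the identical system is available as an alternative backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import DomainConfig, SolverConfig, TissueConfig


class InterstitialSolverError(RuntimeError):
    pass


@dataclass
class TissueDomain:
    """2-D tissue grid with a tumor mask and per-cell transport fields."""

    config: DomainConfig
    tissue: TissueConfig
    tumor_mask: np.ndarray = None  # (n, n) bool, index [i, j] = [x, y]

    def __post_init__(self):
        if self.tumor_mask is None:
            self.tumor_mask = disc_tumor_mask(self.config)
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        n = self.config.n
        if self.tumor_mask.shape != (n, n):
            raise ValueError("tumor mask shape does not match the grid")

    @property
    def n(self) -> int:
        return self.config.n

    @property
    def h(self) -> float:
        return self.config.h

    def cell_k(self) -> np.ndarray:
        """Hydraulic conductivity K per cell (SI)."""
        k = np.where(self.tumor_mask, self.tissue.tumor.k,
                     self.tissue.normal.k)
        return k

    def cell_property(self, attr: str) -> np.ndarray:
        t = getattr(self.tissue.tumor, attr)
        n = getattr(self.tissue.normal, attr)
        return np.where(self.tumor_mask, t, n)


def disc_tumor_mask(config: DomainConfig) -> np.ndarray:
    """Disc of the configured radius centered on the right edge midpoint."""
    n, length = config.n, config.length
    h = config.h
    centers = (np.arange(n) + 0.5) * h
    x, y = np.meshgrid(centers, centers, indexing="ij")
    return (x - length) ** 2 + (y - 0.5 * length) ** 2 <= config.tumor_radius ** 2


@dataclass
class InterstitialField:
    pressure: np.ndarray                 # P_i, Pa, shape (n, n)
    source: np.ndarray                   # Phi_B at convergence, 1/s
    iterations: int = 0
    residual: float = np.nan             # relative max-norm residual
    history: list = field(default_factory=list)

    @property
    def max_pressure(self) -> float:
        return float(self.pressure.max())

    @property
    def argmax(self) -> tuple[int, int]:
        i, j = np.unravel_index(np.argmax(self.pressure),
                                self.pressure.shape)
        return int(i), int(j)


def source_term(pi_cell: np.ndarray, pb_cell: np.ndarray,
                domain: TissueDomain, indicator: np.ndarray) -> np.ndarray:
    """Starling source rate Phi_B per cell (1/s)."""
    lp_sv = domain.cell_property("lp") * domain.cell_property("sv")
    osm = domain.cell_property("sigma") * (domain.cell_property("pi_b")
                                           - domain.cell_property("pi_i"))
    a = np.asarray(indicator, dtype=float)
    return a * lp_sv * ((pb_cell - pi_cell) - osm)


def source_coefficients(domain: TissueDomain, indicator: np.ndarray,
                        pb_cell: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Split Phi_B = alpha - beta * P_i into constant and linear parts."""
    lp_sv = domain.cell_property("lp") * domain.cell_property("sv")
    osm = domain.cell_property("sigma") * (domain.cell_property("pi_b")
                                           - domain.cell_property("pi_i"))
    a = np.asarray(indicator, dtype=float)
    pb = np.where(np.isfinite(pb_cell), pb_cell, 0.0)
    alpha = a * lp_sv * (pb - osm)
    beta = a * lp_sv
    return alpha, beta


def _face_conductivities(domain: TissueDomain):
    k = domain.cell_k()
    # harmonic mean on interior faces
    kx = 2.0 * k[1:, :] * k[:-1, :] / (k[1:, :] + k[:-1, :])
    ky = 2.0 * k[:, 1:] * k[:, :-1] / (k[:, 1:] + k[:, :-1])
    return k, kx, ky


def solve_interstitial_pressure(domain: TissueDomain,
                                indicator: np.ndarray,
                                pb_cell: np.ndarray,
                                solver: SolverConfig | None = None,
                                p0: np.ndarray | None = None,
                                compute_residual: bool = False
                                ) -> InterstitialField:
    """Solve -div(K grad P_i) = Phi_B(P_i) on the tissue grid.

    ``indicator`` is the binary blood-source map A; ``pb_cell`` the
    per-cell intravascular pressure (may contain NaN where A = 0).
    ``p0`` warm-starts the SOR iteration.
    """
    solver = solver or SolverConfig()
    n, h = domain.n, domain.h
    alpha, beta = source_coefficients(domain, indicator, pb_cell)
    k, kx, ky = _face_conductivities(domain)

    if solver.grid_method == "direct":
        p = _solve_direct(domain, alpha, beta, k, kx, ky)
        iters = 1
    else:
        p, iters = _solve_sor(domain, alpha, beta, k, kx, ky, solver, p0)
    resid = (residual_norm(domain, indicator, pb_cell, p)
             if compute_residual else np.nan)
    phi = source_term(p, np.where(np.isfinite(pb_cell), pb_cell, 0.0),
                      domain, indicator)
    return InterstitialField(pressure=p, source=phi, iterations=iters,
                             residual=resid)


def _build_system(domain: TissueDomain, alpha, beta, k, kx, ky):
    """Sparse 5-point system A p = b (row-major cell index i*n + j)."""
    n, h = domain.n, domain.h
    h2 = h * h
    p_left = domain.config.left_pressure
    idx = np.arange(n * n).reshape(n, n)
    rows, cols, vals = [], [], []
    b = np.zeros(n * n)
    diag = np.zeros(n * n)

    def add_face(me, you, kf):
        rows.append(me); cols.append(you); vals.append(-kf / h2)

    for i in range(n):
        for j in range(n):
            me = idx[i, j]
            d = beta[i, j]
            if i > 0:
                kf = kx[i - 1, j]; d += kf / h2; add_face(me, idx[i - 1, j], kf)
            else:
                # Dirichlet boundary half-cell away
                kf = k[i, j]
                d += 2.0 * kf / h2
                b[me] += 2.0 * kf / h2 * p_left
            if i < n - 1:
                kf = kx[i, j]; d += kf / h2; add_face(me, idx[i + 1, j], kf)
            if j > 0:
                kf = ky[i, j - 1]; d += kf / h2; add_face(me, idx[i, j - 1], kf)
            if j < n - 1:
                kf = ky[i, j]; d += kf / h2; add_face(me, idx[i, j + 1], kf)
            diag[me] = d
            b[me] += alpha[i, j]
    rows.extend(range(n * n)); cols.extend(range(n * n)); vals.extend(diag)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n * n, n * n)), b


_LU_CACHE: dict = {}


def _solve_direct(domain, alpha, beta, k, kx, ky):
    """Direct sparse solve; LU factors cached per (domain, beta) operator.

    The 5-point operator depends only on the conductivity field and the
    source's linear coefficient, both of which stay fixed across outer
    coupling iterations, so repeated solves reuse the factorization.
    """
    n = domain.n
    key = (id(domain), n, beta.tobytes())
    hit = _LU_CACHE.get(key)
    if hit is None:
        a_mat, _ = _build_system(domain, np.zeros_like(alpha), beta,
                                 k, kx, ky)
        hit = spla.splu(a_mat.tocsc())
        _LU_CACHE.clear()  # keep at most one factorization around
        _LU_CACHE[key] = hit
    b = _rhs_only(domain, alpha, k)
    p = hit.solve(b)
    return p.reshape(n, n)


def _rhs_only(domain, alpha, k):
    """Right-hand side of the 5-point system for a given source constant."""
    n, h = domain.n, domain.h
    b = alpha.copy().reshape(n, n)
    b = b.astype(float).copy()
    b[0, :] += 2.0 * k[0, :] / (h * h) * domain.config.left_pressure
    return b.ravel()


def _solve_sor(domain, alpha, beta, k, kx, ky, solver: SolverConfig,
               p0: np.ndarray | None):
    """Vectorized red-black SOR on the 5-point stencil."""
    n, h = domain.n, domain.h
    h2 = h * h
    p_left = domain.config.left_pressure
    omega = solver.omega_grid

    # neighbor conductivities padded to (n, n); zero where no face (no-flux)
    kw = np.zeros((n, n)); kw[1:, :] = kx            # west face (i-1)
    ke = np.zeros((n, n)); ke[:-1, :] = kx           # east face (i+1)
    ks_ = np.zeros((n, n)); ks_[:, 1:] = ky          # south face (j-1)
    kn_ = np.zeros((n, n)); kn_[:, :-1] = ky         # north face (j+1)
    bc = np.zeros((n, n))
    kw_dir = np.zeros((n, n))
    kw_dir[0, :] = 2.0 * k[0, :]
    bc[0, :] = kw_dir[0, :] / h2 * p_left

    diag = (kw + ke + ks_ + kn_ + kw_dir) / h2 + beta
    rhs0 = alpha + bc

    p = np.full((n, n), p_left, dtype=float) if p0 is None else p0.astype(float).copy()

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    red = (ii + jj) % 2 == 0
    black = ~red
    scale_src = np.max(np.abs(rhs0)) + 1e-300

    def sweep_color(mask):
        nb = np.zeros((n, n))
        nb[1:, :] += kw[1:, :] * p[:-1, :]
        nb[:-1, :] += ke[:-1, :] * p[1:, :]
        nb[:, 1:] += ks_[:, 1:] * p[:, :-1]
        nb[:, :-1] += kn_[:, :-1] * p[:, 1:]
        gs = (rhs0 + nb / h2) / diag
        p[mask] += omega * (gs[mask] - p[mask])

    p_scale = 1.0
    for it in range(1, solver.max_iter + 1):
        p_old = p.copy()
        sweep_color(red)
        sweep_color(black)
        p_scale = max(np.max(np.abs(p)), abs(p_left), 1.0)
        change = np.max(np.abs(p - p_old)) / p_scale
        if change < solver.tol:
            return p, it
    raise InterstitialSolverError(
        f"interstitial SOR did not converge in {solver.max_iter} sweeps "
        f"(last relative change {change:.3e})")


def residual_norm(domain: TissueDomain, indicator, pb_cell,
                  p: np.ndarray) -> float:
    """Relative max-norm residual of the discrete equation."""
    alpha, beta = source_coefficients(domain, indicator, pb_cell)
    k, kx, ky = _face_conductivities(domain)
    a_mat, b = _build_system(domain, alpha, beta, k, kx, ky)
    r = a_mat @ p.ravel() - b
    return float(np.max(np.abs(r)) / (np.max(np.abs(b)) + 1e-300))


def darcy_velocity(domain: TissueDomain, p: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Face-centered Darcy velocities v = -K grad P_i.

    Returns (vx, vy): vx on interior x-faces, shape (n-1, n); vy on
    interior y-faces, shape (n, n-1).  Harmonic face conductivities keep
    the flux continuous across the tumor boundary.
    """
    h = domain.h
    _, kx, ky = _face_conductivities(domain)
    vx = -kx * (p[1:, :] - p[:-1, :]) / h
    vy = -ky * (p[:, 1:] - p[:, :-1]) / h
    return vx, vy


def speed_field(domain: TissueDomain, p: np.ndarray) -> np.ndarray:
    """Cell-centered |v| interpolated from face velocities."""
    n = domain.n
    vx, vy = darcy_velocity(domain, p)
    vxc = np.zeros((n, n))
    vxc[1:-1, :] = 0.5 * (vx[1:, :] + vx[:-1, :])
    vxc[0, :] = vx[0, :]
    vxc[-1, :] = vx[-1, :]
    vyc = np.zeros((n, n))
    vyc[:, 1:-1] = 0.5 * (vy[:, 1:] + vy[:, :-1])
    vyc[:, 0] = vy[:, 0]
    vyc[:, -1] = vy[:, -1]
    return np.hypot(vxc, vyc)
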