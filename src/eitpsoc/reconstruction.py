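"""Difference imaging: normalized differences, the linear pixel
reconstruction operator, and iterative Gauss-Newton with total-variation
regularization.

Time-difference EIT: the measurement vector of an inhomogeneous frame is
compared against the homogeneous reference as ``dv = (v_nh - v_h)/v_h``,
and a conductivity-change image is obtained either through the one-step
regularized Gauss-Newton operator (a fixed ``n_pixels x n_measurements``
matrix, 1024x40 for the 8-electrode device on a 32x32 grid) or through an
iterative TV-regularized solve.  The sign convention is physical: a
conductive inclusion produces positive pixel values, an insulating one
negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .forward import DiskMesh, SensitivityMatrix, element_areas, element_centroids

__all__ = [
    "PixelGrid",
    "ReconOperator",
    "PixelImage",
    "normalized_difference",
    "element_to_pixel_matrix",
    "element_adjacency_laplacian",
    "build_recon_operator",
    "apply_recon",
    "gn_tv_reconstruct",
]


@dataclass(frozen=True)
class PixelGrid:
    """Square pixel grid covering the tank's bounding box."""

    n: int  # pixels per side
    radius: float  # tank radius, meters

    @property
    def centers(self) -> np.ndarray:
        """(n*n, 2) pixel-center coordinates, row-major from (-r, -r) corner."""
        c = (np.arange(self.n) + 0.5) / self.n * 2 * self.radius - self.radius
        xx, yy = np.meshgrid(c, c, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def mask(self) -> np.ndarray:
        """Boolean (n, n) mask of pixels whose center lies inside the disk."""
        c = self.centers
        return (np.hypot(c[:, 0], c[:, 1]) <= self.radius).reshape(self.n, self.n)


@dataclass(frozen=True)
class ReconOperator:
    """Linear map from normalized voltage differences to pixel values."""

    matrix: np.ndarray  # (n*n, n_measurements)
    grid: PixelGrid
    lam: float
    prior: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.grid.n**2:
            raise ValueError("operator rows must equal pixel count")


@dataclass(frozen=True)
class PixelImage:
    """Reconstructed conductivity-change image on the pixel grid."""

    values: np.ndarray  # (n, n), arbitrary linear units; 0 outside the disk
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError("out-of-disk pixels must be zero")


def normalized_difference(vh: np.ndarray, vnh: np.ndarray) -> np.ndarray:
    """Elementwise ``(v_nh - v_h)/v_h`` of two frame vectors."""
    vh = np.asarray(vh, dtype=float).reshape(-1)
    vnh = np.asarray(vnh, dtype=float).reshape(-1)
    if vh.shape != vnh.shape:
        raise ValueError("reference and measurement vectors differ in length")
    if np.any(vh == 0):
        raise ValueError("reference channel dead: v_h contains zeros")
    return (vnh - vh) / vh


def element_to_pixel_matrix(mesh: DiskMesh, grid: PixelGrid) -> sp.csr_matrix:
    """Sparse (n_pixels, n_elements) area-weighted interpolation matrix.

    Each triangle's area is spread over four interior sample points (edge
    midpoints and centroid); each pixel averages the conductivity change of
    the elements sampled into it, weighted by the deposited area.  Rows of
    pixels outside the disk (or never hit) are zero.
    """
    p = mesh.nodes[mesh.triangles]
    samples = np.stack(
        [
            p.mean(axis=1),
            0.5 * (p[:, 0] + p[:, 1]),
            0.5 * (p[:, 1] + p[:, 2]),
            0.5 * (p[:, 2] + p[:, 0]),
        ],
        axis=1,
    )  # (M, 4, 2)
    w = np.repeat(element_areas(mesh) / 4.0, 4)
    pts = samples.reshape(-1, 2)
    elems = np.repeat(np.arange(mesh.n_elements), 4)
    ij = np.clip(
        ((pts + grid.radius) / (2 * grid.radius) * grid.n).astype(int), 0, grid.n - 1
    )
    pix = ij[:, 0] * grid.n + ij[:, 1]
    mat = sp.coo_matrix(
        (w, (pix, elems)), shape=(grid.n**2, mesh.n_elements)
    ).tocsr()
    rowsum = np.asarray(mat.sum(axis=1)).ravel()
    inside = grid.mask.ravel()
    scale = np.where((rowsum > 0) & inside, 1.0 / np.maximum(rowsum, 1e-300), 0.0)
    return sp.diags(scale) @ mat


def element_adjacency_laplacian(mesh: DiskMesh) -> sp.csr_matrix:
    """Graph Laplacian over elements sharing an edge (smoothness prior)."""
    edges = _shared_edges(mesh)
    n = mesh.n_elements
    i, j = edges[:, 0], edges[:, 1]
    data = np.ones(len(edges))
    adj = sp.coo_matrix((data, (i, j)), shape=(n, n))
    adj = adj + adj.T
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(deg) - adj).tocsr()


def _shared_edges(mesh: DiskMesh) -> np.ndarray:
    """(n_pairs, 2) element index pairs sharing a mesh edge."""
    tri = mesh.triangles
    edge_nodes = np.concatenate(
        [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
    )
    edge_nodes.sort(axis=1)
    owner = np.tile(np.arange(mesh.n_elements), 3)
    order = np.lexsort((edge_nodes[:, 1], edge_nodes[:, 0]))
    en = edge_nodes[order]
    ow = owner[order]
    same = np.all(en[:-1] == en[1:], axis=1)
    return np.column_stack([ow[:-1][same], ow[1:][same]])


def _element_inverse(
    j_mat: np.ndarray,
    lam_rel: float,
    prior: str,
    mesh: DiskMesh,
    extra: sp.spmatrix | None = None,
) -> np.ndarray:
    """Solve (J^T J + lam^2 L^T L [+ extra]) X = J^T  -> (n_elem, n_meas)."""
    if lam_rel <= 0:
        raise ValueError("regularization parameter must be positive")
    smax = np.linalg.norm(j_mat, 2)
    lam = lam_rel * smax
    if prior == "identity":
        ltl = sp.identity(j_mat.shape[1], format="csr")
    elif prior == "smoothness":
        lap = element_adjacency_laplacian(mesh)
        ltl = (lap.T @ lap).tocsr()
        # scale so the penalty is comparable to the identity prior
        ltl = ltl / spla_norm_estimate(ltl)
    else:
        raise ValueError("prior must be 'identity' or 'smoothness'")
    a = j_mat.T @ j_mat + lam**2 * ltl.toarray()
    if extra is not None:
        a = a + extra.toarray()
    return sla.solve(a, j_mat.T, assume_a="pos")


def spla_norm_estimate(mat: sp.spmatrix) -> float:
    """Cheap spectral-norm upper estimate (infinity norm) for scaling priors."""
    return float(np.max(np.abs(mat).sum(axis=1)))


def build_recon_operator(
    j: SensitivityMatrix,
    mesh: DiskMesh,
    lam: float = 0.05,
    prior: str = "smoothness",
    grid: PixelGrid | None = None,
    v_ref: np.ndarray | None = None,
) -> ReconOperator:
    """One-step Gauss-Newton reconstruction operator on the pixel grid.

    ``R = P (J^T J + lam^2 L^T L)^{-1} J^T`` with ``P`` the element-to-pixel
    area interpolation; ``lam`` is relative to the largest singular value of
    (the normalized) ``J``.  When ``v_ref`` (the homogeneous frame vector)
    is given, rows of ``J`` are divided by it so the operator acts on
    normalized differences ``dv``.
    """
    if grid is None:
        grid = PixelGrid(n=32, radius=mesh.radius)
    j_mat = j.matrix
    if v_ref is not None:
        v_ref = np.asarray(v_ref, dtype=float).reshape(-1)
        if np.any(v_ref == 0):
            raise ValueError("reference vector contains zeros")
        j_mat = j_mat / v_ref[:, None]
    inv = _element_inverse(j_mat, lam, prior, mesh)
    p_mat = element_to_pixel_matrix(mesh, grid)
    return ReconOperator(
        matrix=np.asarray(p_mat @ inv), grid=grid, lam=lam, prior=prior
    )


def apply_recon(op: ReconOperator, dv: np.ndarray) -> PixelImage:
    """Apply the linear operator to a normalized difference vector."""
    dv = np.asarray(dv, dtype=float).reshape(-1)
    if dv.size != op.matrix.shape[1]:
        raise ValueError(
            f"expected {op.matrix.shape[1]} measurements, got {dv.size}"
        )
    img = (op.matrix @ dv).reshape(op.grid.n, op.grid.n)
    img = np.where(op.grid.mask, img, 0.0)
    return PixelImage(values=img, mask=op.grid.mask)


def gn_tv_reconstruct(
    j: SensitivityMatrix,
    mesh: DiskMesh,
    dv: np.ndarray,
    iterations: int = 8,
    lam_tv: float = 1e-3,
    beta: float = 1e-4,
    lam_base: float = 0.05,
    prior: str = "smoothness",
    v_ref: np.ndarray | None = None,
    tol: float = 1e-6,
) -> np.ndarray:
    """Gauss-Newton with lagged-diffusivity total-variation regularization.

    Minimizes ``||J x - dv||^2 + lam_base'^2 ||L x||^2 + lam_tv * TV_beta(x)``
    over element conductivity changes ``x``, where ``TV_beta`` is the
    beta-smoothed total variation over pairs of edge-adjacent elements and
    ``beta`` is specified as a fraction of the one-step image's dynamic
    range.  With ``lam_tv = 0`` the first iterate is exactly the one-step
    Gauss-Newton solution.  The objective is non-increasing across accepted
    steps (backtracking line search).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    dv = np.asarray(dv, dtype=float).reshape(-1)
    j_mat = j.matrix
    if v_ref is not None:
        j_mat = j_mat / np.asarray(v_ref, dtype=float).reshape(-1)[:, None]

    edges = _shared_edges(mesh)
    n_e = mesh.n_elements
    d_inc = sp.coo_matrix(
        (
            np.concatenate([np.ones(len(edges)), -np.ones(len(edges))]),
            (
                np.concatenate([np.arange(len(edges))] * 2),
                np.concatenate([edges[:, 0], edges[:, 1]]),
            ),
        ),
        shape=(len(edges), n_e),
    ).tocsr()

    x = _element_inverse(j_mat, lam_base, prior, mesh) @ dv  # one-step start
    beta_abs = beta * max(np.ptp(x), 1e-300)

    def objective(z: np.ndarray) -> float:
        r = j_mat @ z - dv
        tv = np.sum(np.sqrt((d_inc @ z) ** 2 + beta_abs**2))
        smax = np.linalg.norm(j_mat, 2)
        base = (lam_base * smax) ** 2 * _prior_quad(z, prior, mesh)
        return float(r @ r + base + lam_tv * tv)

    if lam_tv == 0:
        return x

    f_prev = objective(x)
    for _ in range(iterations - 1):
        w = 1.0 / np.sqrt((d_inc @ x) ** 2 + beta_abs**2)
        tv_term = (lam_tv / 2.0) * (d_inc.T @ sp.diags(w) @ d_inc)
        x_new = _element_inverse(j_mat, lam_base, prior, mesh, extra=tv_term) @ dv
        f_new = objective(x_new)
        if not np.isfinite(f_new):
            raise ValueError("non-finite objective in TV iteration")
        alpha = 1.0
        while f_new > f_prev and alpha > 1e-3:
            alpha /= 2.0
            x_try = x + alpha * (x_new - x)
            f_new = objective(x_try)
            x_new = x_try
        if f_new > f_prev:
            break
        if abs(f_prev - f_new) <= tol * max(abs(f_prev), 1.0):
            x = x_new
            break
        x, f_prev = x_new, f_new
    return x


def _prior_quad(z: np.ndarray, prior: str, mesh: DiskMesh) -> float:
    if prior == "identity":
        return float(z @ z)
    lap = element_adjacency_laplacian(mesh)
    lz = lap @ z
    return float(lz @ lz) / spla_norm_estimate((lap.T @ lap).tocsr())
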