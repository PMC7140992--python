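"""Thin-plate-spline deformation grids between mean shapes.

The interpolating 2D thin-plate spline with kernel ``U(r) = r^2 log r^2``
(``U(0) = 0``) maps every reference landmark exactly onto its target.  The
warp splits into an affine part and a non-affine part whose weights carry the
bending energy — zero exactly when the target is an affine transform of the
reference.  Deformation grids visualise how the space around a reference
mean shape must bend to reach a target mean shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TpsWarp", "fit_tps", "warp_points", "warp_grid", "plot_warp"]


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with the removable singularity at r = 0 set to 0."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = r2[pos] * np.log(r2[pos])
    return out


@dataclass
class TpsWarp:
    reference: np.ndarray          # (k, 2)
    target: np.ndarray             # (k, 2)
    affine: np.ndarray             # (3, 2): rows constant, x, y
    weights: np.ndarray            # (k, 2) non-affine kernel weights
    bending_energy: float


def fit_tps(reference, target) -> TpsWarp:
    """Fit the interpolating thin-plate spline taking reference to target.

    Solves the standard bordered system ``[[K, P], [P^T, 0]]`` where
    ``K_ij = U(|p_i - p_j|)`` and ``P = [1, x, y]``; the bending energy is the
    quadratic form ``sum_d w_d^T K w_d`` of the non-affine weights (clipped at
    zero against roundoff).  Collinear references make the system singular.
    """
    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    if reference.ndim != 2 or reference.shape[1] != 2:
        raise ValueError(f"reference must be (k, 2), got {reference.shape}")
    if reference.shape != target.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {target.shape}")
    k = reference.shape[0]
    if k < 3:
        raise ValueError("need at least 3 landmarks")
    p_mat = np.column_stack([np.ones(k), reference])
    if np.linalg.matrix_rank(p_mat, tol=1e-10 * max(1.0, np.abs(reference).max())) < 3:
        raise np.linalg.LinAlgError("reference landmarks are collinear; TPS system is singular")

    diff = reference[:, None, :] - reference[None, :, :]
    kmat = _kernel((diff**2).sum(axis=2))
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p_mat
    lmat[k:, :k] = p_mat.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    sol = np.linalg.solve(lmat, rhs)
    weights, affine = sol[:k], sol[k:]
    be = float(np.einsum("id,ij,jd->", weights, kmat, weights))
    return TpsWarp(reference=reference, target=target, affine=affine,
                   weights=weights, bending_energy=max(be, 0.0))


def warp_points(warp: TpsWarp, points) -> np.ndarray:
    """Evaluate the warp at arbitrary 2D points."""
    pts = np.asarray(points, float)
    squeeze = pts.ndim == 1
    if squeeze:
        pts = pts[None]
    diff = pts[:, None, :] - warp.reference[None, :, :]
    u = _kernel((diff**2).sum(axis=2))
    out = np.column_stack([np.ones(len(pts)), pts]) @ warp.affine + u @ warp.weights
    return out[0] if squeeze else out


def warp_grid(warp: TpsWarp, rows: int = 24, cols: int = 24,
              margin: float = 0.1) -> np.ndarray:
    """Deform a rows x cols grid spanning the reference bounding box.

    The box is expanded by ``margin`` (fraction of its span) on every side;
    returns the warped node positions as a ``(rows, cols, 2)`` array.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid needs at least 2 rows and 2 columns")
    lo = warp.reference.min(axis=0)
    hi = warp.reference.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    hi = hi + margin * span
    xs = np.linspace(lo[0], hi[0], cols)
    ys = np.linspace(lo[1], hi[1], rows)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    return warp_points(warp, nodes).reshape(rows, cols, 2)


def plot_warp(warp: TpsWarp, rows: int = 24, cols: int = 24, margin: float = 0.1,
              ax=None):
    """Render the deformation grid plus reference/target landmarks."""
    import matplotlib.pyplot as plt

    grid = warp_grid(warp, rows=rows, cols=cols, margin=margin)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for r in range(grid.shape[0]):
        ax.plot(grid[r, :, 0], grid[r, :, 1], color="0.6", lw=0.6)
    for c in range(grid.shape[1]):
        ax.plot(grid[:, c, 0], grid[:, c, 1], color="0.6", lw=0.6)
    ax.scatter(*warp.reference.T, s=14, color="0.3", label="reference")
    ax.scatter(*warp.target.T, s=14, color="crimson", label="target")
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    return ax
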