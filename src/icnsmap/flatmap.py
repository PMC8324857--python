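"""PCA flatmap projection and 2D packing-density estimation.

The neuron cloud of a mapped heart lies on a gently curved sheet, so its two
leading principal axes give a faithful 2D "flatmap" of the distribution.
Packing density — neurons per µm² in the flatmap plane — is estimated with a
Gaussian kernel summed over neurons (so the density field integrates to the
neuron count), with Scott's rule per axis as the default bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FlatmapProjection", "pca_flatmap", "packing_density", "flatmap_with_density"]


@dataclass
class FlatmapProjection:
    """Scores of the neuron cloud on its two leading principal axes."""

    coords2d: np.ndarray  # (n, 2), µm, centered
    axis_loadings: np.ndarray  # (2, 3) rows are unit principal axes
    variance_explained: tuple[float, float]
    centroid: np.ndarray  # (3,) of the original cloud
    degenerate: bool = False  # second axis ill-defined (collinear data)
    density: np.ndarray | None = None  # per-point, neurons/µm²
    bandwidth: tuple[float, float] | None = None
    grid_density: dict | None = None  # {"x", "y", "values"} raster


def pca_flatmap(points: np.ndarray) -> FlatmapProjection:
    """Project a 3D neuron cloud onto its two leading principal axes.

    The reflection ambiguity of each axis is fixed by making the
    largest-magnitude loading positive, so the superior–inferior orientation
    of the flatmap is reproducible across runs and subjects.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = len(points)
    if n < 3:
        raise ValueError("need at least 3 points for a flatmap")
    centroid = points.mean(axis=0)
    xc = points - centroid
    # principal axes via SVD of the centered cloud
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    var = svals**2 / n
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    axes = vt[:2].copy()
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    scores = xc @ axes.T
    rel_rank_tol = svals[0] * max(points.shape) * np.finfo(float).eps
    degenerate = bool(svals[1] <= max(rel_rank_tol, 1e-12))
    return FlatmapProjection(
        coords2d=scores,
        axis_loadings=axes,
        variance_explained=(float(frac[0]), float(frac[1])),
        centroid=centroid,
        degenerate=degenerate,
    )


def _scott_bandwidth(coords2d: np.ndarray) -> tuple[float, float]:
    n = len(coords2d)
    sd = coords2d.std(axis=0, ddof=1)
    factor = n ** (-1.0 / 6.0)  # Scott's rule, d = 2
    return float(sd[0] * factor), float(sd[1] * factor)


def packing_density(
    coords2d: np.ndarray,
    bandwidth: float | tuple[float, float] | str = "auto",
    *,
    grid_size: int = 128,
    grid_pad: float = 3.0,
) -> tuple[np.ndarray, dict, tuple[float, float]]:
    """Gaussian-kernel packing density of a 2D neuron layout.

    The density at x is ``sum_i K_h(x - x_i)`` (kernels are *summed*, not
    averaged, so the field has units neurons/µm² and integrates to n).

    Parameters
    ----------
    coords2d:
        (n, 2) flatmap coordinates, µm.
    bandwidth:
        Scalar or per-axis (hx, hy) in µm, or ``"auto"`` for Scott's rule
        per axis.
    grid_size, grid_pad:
        Raster resolution and padding (in bandwidths) around the data.

    Returns
    -------
    density, raster, (hx, hy):
        Per-point density, a raster dict with keys ``x``, ``y``, ``values``,
        and the bandwidths used.
    """
    coords2d = np.asarray(coords2d, dtype=float)
    if coords2d.ndim != 2 or coords2d.shape[1] != 2:
        raise ValueError("coords2d must be (n, 2)")
    n = len(coords2d)
    if n < 2:
        raise ValueError("need at least 2 points")
    if isinstance(bandwidth, str):
        if bandwidth != "auto":
            raise ValueError("bandwidth must be positive numbers or 'auto'")
        hx, hy = _scott_bandwidth(coords2d)
    else:
        hx, hy = (
            (float(bandwidth), float(bandwidth))
            if np.isscalar(bandwidth)
            else (float(bandwidth[0]), float(bandwidth[1]))
        )
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive")

    norm = 1.0 / (2.0 * np.pi * hx * hy)

    def kde_at(q: np.ndarray) -> np.ndarray:
        dx = (q[:, None, 0] - coords2d[None, :, 0]) / hx
        dy = (q[:, None, 1] - coords2d[None, :, 1]) / hy
        return norm * np.exp(-0.5 * (dx**2 + dy**2)).sum(axis=1)

    density = kde_at(coords2d)

    lo = coords2d.min(axis=0) - grid_pad * np.array([hx, hy])
    hi = coords2d.max(axis=0) + grid_pad * np.array([hx, hy])
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    q = np.column_stack([xx.ravel(), yy.ravel()])
    values = np.empty(len(q))
    step = 200 * 128  # evaluate the raster in chunks to bound memory
    chunk = max(1, step // max(1, n))
    for s in range(0, len(q), chunk):
        values[s : s + chunk] = kde_at(q[s : s + chunk])
    raster = {"x": gx, "y": gy, "values": values.reshape(grid_size, grid_size)}
    return density, raster, (hx, hy)


def flatmap_with_density(
    points: np.ndarray,
    bandwidth: float | tuple[float, float] | str = "auto",
    **kde_kwargs,
) -> FlatmapProjection:
    """Convenience: PCA flatmap with packing density filled in."""
    proj = pca_flatmap(points)
    density, raster, h = packing_density(proj.coords2d, bandwidth, **kde_kwargs)
    proj.density = density
    proj.bandwidth = h
    proj.grid_density = raster
    return proj
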