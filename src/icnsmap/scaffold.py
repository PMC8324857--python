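"""Material-coordinate scaffold: a structured bilinear quad-element surface
that can be fitted to per-subject contour data and used to transfer neuron
positions into a common coordinate frame.

A *scaffold* is a (nu+1)×(nv+1) node grid forming nu×nv bilinear quad
elements. A point on the scaffold is addressed by a *material coordinate*
(element id, ξ ∈ [0,1]²) which is invariant under deformation of the nodes:
the same material address evaluates to different world positions on the
generic and on a subject-fitted scaffold. Registration proceeds by

1. aligning the generic scaffold to the subject's contour data with a
   similarity transform estimated from per-structure centroids (closest-point
   fitting alone cannot observe in-plane motion, so this anatomical
   pre-alignment is what anchors the material frame),
2. fitting the aligned scaffold to the contour points by alternating
   per-structure nearest-element projection with a linear least-squares
   update of the node coordinates (plus a membrane penalty on node
   displacements),
3. embedding each neuron as the material coordinate of its projection onto
   the fitted surface, and
4. evaluating those material coordinates on the generic scaffold, which
   places every subject's neurons in one common frame where per-bin density
   overlap between subjects can be quantified.

Element nodes are ordered counterclockwise from ξ=(0,0); the bilinear map is
``S(ξ) = Σ_j φ_j(ξ) p_j`` with the usual tensor-product hat functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_io import NeuronMarker, SubjectMap
from .synthetic import TemplateHeart, slice_contours

__all__ = [
    "Scaffold",
    "MaterialCoordinate",
    "EmbeddedPoint",
    "OverlapMap",
    "FitResult",
    "make_generic_scaffold",
    "structure_element_map",
    "evaluate",
    "project_point",
    "project_points",
    "fit_scaffold",
    "estimate_similarity",
    "align_scaffold",
    "reference_structure_centroids",
    "register_subject",
    "RegistrationResult",
    "embed_markers",
    "transfer_to_generic",
    "overlap_map",
]


@dataclass
class Scaffold:
    """Structured surface mesh of bilinear quad elements.

    ``nodes`` has shape (nu+1, nv+1, 3) in micrometres. Element ``e`` covers
    grid cell ``(i, j) = divmod(e, nv)``; its corner nodes, counterclockwise
    from ξ=(0,0), are (i,j), (i+1,j), (i+1,j+1), (i,j+1). Element ids are
    stable under deformation of the nodes.
    """

    nodes: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 3 or self.nodes.shape[2] != 3:
            raise ValueError("nodes must have shape (nu+1, nv+1, 3)")
        if self.nodes.shape[0] < 2 or self.nodes.shape[1] < 2:
            raise ValueError("need at least a 1x1 element grid")

    @property
    def shape(self) -> tuple[int, int]:
        """(nu, nv) element-grid shape."""
        return self.nodes.shape[0] - 1, self.nodes.shape[1] - 1

    @property
    def n_elements(self) -> int:
        nu, nv = self.shape
        return nu * nv

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0] * self.nodes.shape[1]

    def element_corners(self, element_id: int | np.ndarray) -> np.ndarray:
        """Corner coordinates of element(s), shape (..., 4, 3), CCW from
        ξ=(0,0)."""
        nu, nv = self.shape
        e = np.asarray(element_id)
        if np.any(e < 0) or np.any(e >= nu * nv):
            raise ValueError("invalid element id")
        i, j = np.divmod(e, nv)
        return np.stack(
            [
                self.nodes[i, j],
                self.nodes[i + 1, j],
                self.nodes[i + 1, j + 1],
                self.nodes[i, j + 1],
            ],
            axis=-2,
        )

    def copy(self) -> "Scaffold":
        return Scaffold(self.nodes.copy())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"nodes": self.nodes.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "Scaffold":
        with open(path) as fh:
            return cls(np.asarray(json.load(fh)["nodes"]))


@dataclass(frozen=True)
class MaterialCoordinate:
    """(element id, ξ) address of a point on a scaffold; ξ ∈ [0,1]²."""

    element_id: int
    xi: tuple[float, float]

    def __post_init__(self) -> None:
        x1, x2 = self.xi
        if not (0 <= x1 <= 1 and 0 <= x2 <= 1):
            raise ValueError("xi must lie in [0,1]^2")


@dataclass(frozen=True)
class EmbeddedPoint:
    """A marker stored as a material coordinate on a fitted scaffold."""

    marker_id: str
    material: MaterialCoordinate
    projection_distance: float

    def __post_init__(self) -> None:
        if self.projection_distance < 0:
            raise ValueError("projection_distance must be >= 0")


def make_generic_scaffold(
    template: TemplateHeart, grid: tuple[int, int] = (16, 16)
) -> Scaffold:
    """Sample the template heart surface into a generic scaffold.

    Deterministic; the scaffold geometry belongs to the same surface family
    the synthetic subjects are generated from, so synthetic contour data are
    in-model up to the bilinear discretization.
    """
    nu, nv = grid
    if nu < 2 or nv < 2:
        raise ValueError("grid must be at least (2, 2)")
    u = np.linspace(0.0, 1.0, nu + 1)
    v = np.linspace(0.0, 1.0, nv + 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    return Scaffold(template.surface_point(np.stack([uu, vv], axis=-1)))


# ---------------------------------------------------------------------------
# Evaluation and projection


def _shape_functions(xi: np.ndarray) -> np.ndarray:
    """Bilinear shape functions φ_j(ξ), CCW corner order; xi (..., 2) ->
    (..., 4)."""
    x1, x2 = xi[..., 0], xi[..., 1]
    return np.stack(
        [(1 - x1) * (1 - x2), x1 * (1 - x2), x1 * x2, (1 - x1) * x2], axis=-1
    )


def evaluate(scaffold: Scaffold, material: MaterialCoordinate) -> np.ndarray:
    """World position of a material coordinate (bilinear interpolation of
    the element's corner nodes)."""
    corners = scaffold.element_corners(material.element_id)
    phi = _shape_functions(np.asarray(material.xi, dtype=float))
    return phi @ corners


def evaluate_many(
    scaffold: Scaffold, element_ids: np.ndarray, xis: np.ndarray
) -> np.ndarray:
    corners = scaffold.element_corners(np.asarray(element_ids))
    phi = _shape_functions(np.asarray(xis, dtype=float))
    return np.einsum("nj,njd->nd", phi, corners)


_GN_STARTS = np.array(
    [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.5, 0.5]]
)


def _gauss_newton_element(
    corners: np.ndarray, points: np.ndarray, xi0: np.ndarray, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Clamped minimization of ‖S(ξ) − x‖ on one bilinear element for a
    batch of points, by Gauss–Newton-style alternating *exact* coordinate
    minimization: with one ξ coordinate held fixed the surface is linear in
    the other, so each 1D sub-problem has a closed-form clamped solution.
    This makes constrained (element-edge) minima exact, where a projected
    2x2 Newton step can stall. corners (4,3); points (n,3); xi0 (n,2).
    Returns (xi, squared distances)."""
    p00, p10, p11, p01 = corners
    xi = xi0.copy()
    for _ in range(n_iter):
        old = xi.copy()
        # exact ξ1 given ξ2: S = a + ξ1 b with a, b linear in ξ2
        x2 = xi[:, 1:2]
        a = (1 - x2) * p00 + x2 * p01
        b = (1 - x2) * (p10 - p00) + x2 * (p11 - p01)
        denom = np.einsum("nd,nd->n", b, b)
        num = np.einsum("nd,nd->n", points - a, b)
        xi[:, 0] = np.clip(
            np.where(denom > 1e-18, num / np.maximum(denom, 1e-18), xi[:, 0]),
            0.0,
            1.0,
        )
        # exact ξ2 given ξ1
        x1 = xi[:, 0:1]
        a = (1 - x1) * p00 + x1 * p10
        b = (1 - x1) * (p01 - p00) + x1 * (p11 - p10)
        denom = np.einsum("nd,nd->n", b, b)
        num = np.einsum("nd,nd->n", points - a, b)
        xi[:, 1] = np.clip(
            np.where(denom > 1e-18, num / np.maximum(denom, 1e-18), xi[:, 1]),
            0.0,
            1.0,
        )
        if np.abs(xi - old).max() < 1e-14:
            break
    x1 = xi[:, 0:1]
    x2 = xi[:, 1:2]
    s = (
        (1 - x1) * (1 - x2) * p00
        + x1 * (1 - x2) * p10
        + x1 * x2 * p11
        + (1 - x1) * x2 * p01
    )
    d2 = np.einsum("nd,nd->n", s - points, s - points)
    return xi, d2


def project_points(
    scaffold: Scaffold,
    points: np.ndarray,
    *,
    mode: str = "full",
    candidates: int = 4,
    element_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project points onto the scaffold surface.

    ``mode="full"`` runs multi-start (4 corners + center) Gauss–Newton on
    every element and takes the global best — robust, used for API-level
    projection. ``mode="fast"`` seeds from a coarse per-element ξ-grid and
    refines only the few closest candidate elements per point — used inside
    the fitting loop where tens of thousands of projections are needed.

    ``element_subset`` restricts the search to the given element ids (used
    to project anatomical contour data onto the scaffold elements of their
    corresponding structure).

    Returns (element_ids, xis, distances); ties between elements resolve to
    the lower element id.
    """
    points = np.asarray(points, dtype=float)
    single = points.ndim == 1
    pts = np.atleast_2d(points)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    nu, nv = scaffold.shape
    if element_subset is None:
        els = np.arange(nu * nv)
    else:
        els = np.unique(np.asarray(element_subset, dtype=int))
        if len(els) == 0:
            raise ValueError("element_subset must be non-empty")
    n = len(pts)
    best_d2 = np.full(n, np.inf)
    best_xi = np.zeros((n, 2))
    best_el = np.zeros(n, dtype=int)

    if mode == "full":
        for e in els:
            corners = scaffold.element_corners(int(e))
            for xi0 in _GN_STARTS:
                xi, d2 = _gauss_newton_element(
                    corners, pts, np.tile(xi0, (n, 1))
                )
                better = d2 < best_d2 - 1e-12
                best_d2[better] = d2[better]
                best_xi[better] = xi[better]
                best_el[better] = int(e)
    elif mode == "fast":
        # coarse 5x5 ξ-grid per element proposes candidate elements; at
        # least 4 candidates so the elements sharing a nearest corner node
        # (exact coarse-distance ties) are all refined
        n_cand = min(candidates, len(els))
        g = np.linspace(0.0, 1.0, 5)
        gxi = np.array([[a, b] for a in g for b in g])  # (25, 2)
        corners_all = scaffold.element_corners(els)  # (E,4,3)
        phi = _shape_functions(gxi)  # (25, 4)
        coarse = np.einsum("gj,ejd->egd", phi, corners_all)  # (E,25,3)
        flat = coarse.reshape(-1, 3)
        # distances point -> all coarse samples, chunked
        cand_el = np.empty((n, n_cand), dtype=int)
        cand_xi0 = np.empty((n, n_cand, 2))
        chunk = max(1, int(4e6) // max(1, len(flat)))
        for s in range(0, n, chunk):
            d2 = (
                (pts[s : s + chunk, None, :] - flat[None]) ** 2
            ).sum(-1).reshape(-1, len(els), len(gxi))
            d2min = d2.min(axis=2)
            order = np.argsort(d2min, axis=1)[:, :n_cand]
            cand_el[s : s + chunk] = order  # positions within els
            gi = np.take_along_axis(d2.argmin(axis=2), order, axis=1)
            cand_xi0[s : s + chunk] = gxi[gi]
        for epos in np.unique(cand_el):
            mask = (cand_el == epos).any(axis=1)
            idx = np.flatnonzero(mask)
            # seed: coarse best ξ for this element, fall back to center
            seed = np.tile([0.5, 0.5], (len(idx), 1))
            has = cand_el[idx] == epos
            rows, cols = np.nonzero(has)
            seed[rows] = cand_xi0[idx[rows], cols]
            xi, d2 = _gauss_newton_element(
                scaffold.element_corners(int(els[epos])), pts[idx], seed
            )
            better = d2 < best_d2[idx] - 1e-12
            upd = idx[better]
            best_d2[upd] = d2[better]
            best_xi[upd] = xi[better]
            best_el[upd] = int(els[epos])
    else:
        raise ValueError("mode must be 'full' or 'fast'")

    dist = np.sqrt(best_d2)
    if single:
        return best_el[:1], best_xi[:1], dist[:1]
    return best_el, best_xi, dist


def project_point(
    scaffold: Scaffold, point: np.ndarray
) -> tuple[MaterialCoordinate, float]:
    """Globally nearest material coordinate of a single point (multi-start
    Gauss–Newton over every element; ties to the lower element id)."""
    el, xi, d = project_points(scaffold, np.asarray(point, dtype=float))
    return (
        MaterialCoordinate(int(el[0]), (float(xi[0, 0]), float(xi[0, 1]))),
        float(d[0]),
    )


# ---------------------------------------------------------------------------
# Fitting


class FitSingularError(np.linalg.LinAlgError):
    """Raised when the unpenalized normal equations are singular."""


@dataclass
class FitResult:
    """Fitted scaffold plus per-iteration diagnostics."""

    scaffold: Scaffold
    rms_history: list[float]
    n_data: int
    lambda_smooth: float
    converged: bool

    @property
    def rms(self) -> float:
        return self.rms_history[-1]


def _edge_pairs(nu: int, nv: int) -> np.ndarray:
    """Adjacent node index pairs (flattened ids) of the structured grid."""
    ids = np.arange((nu + 1) * (nv + 1)).reshape(nu + 1, nv + 1)
    horiz = np.column_stack([ids[:-1].ravel(), ids[1:].ravel()])
    vert = np.column_stack([ids[:, :-1].ravel(), ids[:, 1:].ravel()])
    return np.vstack([horiz, vert])


def structure_element_map(
    template: TemplateHeart, grid: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Element ids of a ``grid``-shaped generic scaffold overlapping each
    structure's (u, v) patch on the template (used to restrict contour
    correspondences to the anatomically corresponding scaffold region)."""
    nu, nv = grid
    out: dict[str, np.ndarray] = {}
    for name, (umin, vmin, umax, vmax) in template.structure_regions.items():
        ids = []
        for i in range(nu):
            if (i + 1) / nu <= umin or i / nu >= umax:
                continue
            for j in range(nv):
                if (j + 1) / nv <= vmin or j / nv >= vmax:
                    continue
                ids.append(i * nv + j)
        out[name] = np.array(ids, dtype=int)
    return out


def fit_scaffold(
    generic: Scaffold,
    data: np.ndarray,
    weights: np.ndarray | None = None,
    lambda_smooth: float = 0.01,
    max_iters: int = 10,
    tol: float = 0.5,
    *,
    correspondences: tuple[np.ndarray, np.ndarray] | None = None,
    groups: np.ndarray | None = None,
    group_elements: dict | None = None,
) -> FitResult:
    """Fit the scaffold node coordinates to contour data points.

    Alternates (1) *correspondence*: project every datum onto the current
    surface, and (2) a linear least-squares node update minimizing

    ``Σ_i w_i ‖x_i − Σ_j φ_j(ξ_i) p_j‖² + λ Σ_(j,j') ‖(p_j − g_j) − (p_j' − g_j')‖²``

    where the second sum runs over adjacent node pairs and ``g`` is the
    generic configuration — a membrane penalty on node *displacements*, which
    regularizes toward the generic geometry without shrinking the mesh.
    Iteration stops when the RMS data distance changes by less than ``tol``
    (µm) or after ``max_iters`` rounds; given fixed correspondences each
    solve minimizes the objective exactly, so the RMS is non-increasing
    within a round.

    Parameters
    ----------
    correspondences:
        Optional fixed (element_ids, xis); when given, projection is skipped
        and a single solve is performed (used when the material addresses of
        the data are known, e.g. for calibration).
    groups, group_elements:
        Optional anatomical correspondence constraint: ``groups`` labels each
        datum (e.g. with its contour's structure name) and ``group_elements``
        maps labels to scaffold element ids; each datum is then projected
        only onto its own structure's elements, which anchors the material
        coordinates against tangential sliding that pure closest-point
        correspondence cannot detect. Labels absent from the map fall back
        to a global search.

    Raises
    ------
    FitSingularError
        If ``lambda_smooth == 0`` and the data do not constrain every node;
        the message instructs to use λ > 0.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError("data must be (n, 3)")
    n = len(data)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0):
        raise ValueError("weights must be (n,) non-negative")
    if lambda_smooth < 0:
        raise ValueError("lambda_smooth must be >= 0")

    nu, nv = generic.shape
    n_nodes = (nu + 1) * (nv + 1)
    g_flat = generic.nodes.reshape(n_nodes, 3)
    edges = _edge_pairs(nu, nv)
    lap = np.zeros((n_nodes, n_nodes))
    np.add.at(lap, (edges[:, 0], edges[:, 0]), 1.0)
    np.add.at(lap, (edges[:, 1], edges[:, 1]), 1.0)
    np.add.at(lap, (edges[:, 0], edges[:, 1]), -1.0)
    np.add.at(lap, (edges[:, 1], edges[:, 0]), -1.0)

    def node_ids(el: np.ndarray) -> np.ndarray:
        i, j = np.divmod(el, nv)
        base = i * (nv + 1) + j
        return np.stack(
            [base, base + (nv + 1), base + (nv + 1) + 1, base + 1], axis=-1
        )

    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape != (n,):
            raise ValueError("groups must label every datum")
        group_elements = group_elements or {}

    def correspond(surface: Scaffold) -> tuple[np.ndarray, np.ndarray]:
        if groups is None:
            el, xi, _ = project_points(surface, data, mode="fast")
            return el, xi
        el = np.empty(n, dtype=int)
        xi = np.empty((n, 2))
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            subset = group_elements.get(g)
            el[idx], xi[idx], _ = project_points(
                surface, data[idx], mode="fast", element_subset=subset
            )
        return el, xi

    fitted = generic.copy()
    rms_history: list[float] = []
    fixed = correspondences is not None
    rounds = 1 if fixed else max_iters
    converged = False
    for it in range(rounds):
        if fixed:
            el, xi = correspondences
            el = np.asarray(el, dtype=int)
            xi = np.asarray(xi, dtype=float)
        else:
            el, xi = correspond(fitted)
        phi = _shape_functions(xi)  # (n, 4)
        nid = node_ids(el)  # (n, 4)

        # normal equations: (AᵀWA + λL) P = AᵀW X + λ L G
        ata = np.zeros((n_nodes, n_nodes))
        wphi = phi * w[:, None]
        for a in range(4):
            for bcol in range(4):
                np.add.at(
                    ata, (nid[:, a], nid[:, bcol]), wphi[:, a] * phi[:, bcol]
                )
        atx = np.zeros((n_nodes, 3))
        for a in range(4):
            np.add.at(atx, nid[:, a], wphi[:, a, None] * data)

        lhs = ata + lambda_smooth * lap
        rhs = atx + lambda_smooth * lap @ g_flat
        if lambda_smooth == 0:
            try:
                sol = np.linalg.solve(lhs, rhs)
                if not np.all(np.isfinite(sol)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError as exc:
                raise FitSingularError(
                    "normal equations are singular: the data do not "
                    "constrain every node; refit with lambda_smooth > 0"
                ) from exc
        else:
            sol = np.linalg.solve(lhs, rhs)
        fitted = Scaffold(sol.reshape(nu + 1, nv + 1, 3))

        resid = data - np.einsum("nj,njd->nd", phi, sol[nid])
        rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
        rms_history.append(rms)
        if not fixed and it > 0 and abs(rms_history[-2] - rms) < tol:
            converged = True
            break
    if not fixed and not converged:
        # final RMS against re-projected correspondences for reporting
        el, xi = correspond(fitted)
        resid = data - evaluate_many(fitted, el, xi)
        rms_history.append(float(np.sqrt((resid**2).sum(axis=1).mean())))
    return FitResult(
        scaffold=fitted,
        rms_history=rms_history,
        n_data=n,
        lambda_smooth=lambda_smooth,
        converged=converged or fixed,
    )


# ---------------------------------------------------------------------------
# Alignment and end-to-end registration


def estimate_similarity(
    src: np.ndarray, dst: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform (scale s, rotation R, translation
    t) mapping src points onto dst points (Umeyama's closed form):
    ``dst ≈ s · R · src + t``."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or len(src) < 3:
        raise ValueError("need matching (n>=3, d) point sets")
    ms, md = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - ms, dst - md
    cov = dc.T @ sc / len(src)
    u, svals, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    dd = np.ones(src.shape[1])
    dd[-1] = d
    rot = u @ np.diag(dd) @ vt
    var = (sc**2).sum() / len(src)
    scale = float((svals * dd).sum() / var)
    trans = md - scale * rot @ ms
    return scale, rot, trans


def reference_structure_centroids(
    template: TemplateHeart,
    section_thickness: float = 5.0,
    resolution: int = 129,
) -> dict[str, np.ndarray]:
    """Per-structure centroid of the *template* contour data, sliced exactly
    the way subjects are sectioned so the sampling bias (iso-z lines are
    denser where the sheet is steep) matches the subject data."""
    contours = slice_contours(
        template.sample_grid(resolution), template.structure_regions, section_thickness
    )
    out: dict[str, np.ndarray] = {}
    for name in template.structure_regions:
        pts = [c.points for c in contours if c.structure_name == name]
        if pts:
            out[name] = np.vstack(pts).mean(axis=0)
    return out


def align_scaffold(
    generic: Scaffold,
    data: np.ndarray,
    groups: np.ndarray,
    reference_centroids: dict[str, np.ndarray],
) -> tuple[Scaffold, dict]:
    """Similarity-align the generic scaffold to contour data using matched
    per-structure centroids as landmarks. Returns the transformed scaffold
    (identical topology and material semantics) and the transform."""
    groups = np.asarray(groups)
    src, dst = [], []
    for name, ref in reference_centroids.items():
        mask = groups == name
        if mask.any():
            src.append(ref)
            dst.append(np.asarray(data)[mask].mean(axis=0))
    if len(src) < 3:
        raise ValueError("need at least 3 structures with data to align")
    scale, rot, trans = estimate_similarity(np.array(src), np.array(dst))
    nodes = scale * generic.nodes.reshape(-1, 3) @ rot.T + trans
    return (
        Scaffold(nodes.reshape(generic.nodes.shape)),
        {"scale": scale, "rotation": rot.tolist(), "translation": trans.tolist()},
    )


@dataclass
class RegistrationResult:
    """Everything produced by registering one subject onto the scaffold."""

    fitted: Scaffold
    fit: "FitResult"
    transform: dict
    embedded: list["EmbeddedPoint"]
    transferred: np.ndarray  # (n, 3) marker positions on the generic scaffold


def register_subject(
    subject: SubjectMap,
    template: TemplateHeart,
    generic: Scaffold,
    *,
    lambda_smooth: float = 1.0,
    max_iters: int = 10,
    tol: float = 0.5,
    max_data_points: int = 2000,
    reference_centroids: dict[str, np.ndarray] | None = None,
) -> RegistrationResult:
    """Register a subject's markers onto the generic scaffold.

    Pipeline: collect contour points with their structure labels, subsample
    to ``max_data_points``, similarity-align the generic scaffold to the
    per-structure centroids, fit it to the contours with structure-restricted
    correspondences, embed the markers in the fitted scaffold, and evaluate
    their material coordinates on the generic scaffold.
    """
    if not subject.contours:
        raise ValueError("subject has no contours to register against")
    pts = np.vstack([c.points for c in subject.contours])
    names = np.concatenate(
        [np.full(len(c.points), c.structure_name) for c in subject.contours]
    )
    stride = max(1, len(pts) // max_data_points)
    pts, names = pts[::stride], names[::stride]

    if reference_centroids is None:
        reference_centroids = reference_structure_centroids(
            template, subject.section_thickness
        )
    aligned, transform = align_scaffold(generic, pts, names, reference_centroids)
    gmap = structure_element_map(template, generic.shape)
    fit = fit_scaffold(
        aligned,
        pts,
        lambda_smooth=lambda_smooth,
        max_iters=max_iters,
        tol=tol,
        groups=names,
        group_elements=gmap,
    )
    embedded = embed_markers(fit.scaffold, subject.markers)
    transferred = transfer_to_generic(embedded, generic)
    return RegistrationResult(
        fitted=fit.scaffold,
        fit=fit,
        transform=transform,
        embedded=embedded,
        transferred=transferred,
    )


# ---------------------------------------------------------------------------
# Embedding, transfer, overlap


def embed_markers(
    fitted: Scaffold, markers: list[NeuronMarker], *, mode: str = "fast"
) -> list[EmbeddedPoint]:
    """Project every marker onto the fitted surface and store its material
    coordinate (one embedded point per marker, in order)."""
    if not markers:
        return []
    pts = np.array([m.position for m in markers])
    el, xi, d = project_points(fitted, pts, mode=mode)
    return [
        EmbeddedPoint(
            marker_id=m.id,
            material=MaterialCoordinate(
                int(el[i]), (float(xi[i, 0]), float(xi[i, 1]))
            ),
            projection_distance=float(d[i]),
        )
        for i, m in enumerate(markers)
    ]


def transfer_to_generic(
    embedded: list[EmbeddedPoint], generic: Scaffold
) -> np.ndarray:
    """Evaluate embedded material coordinates on the generic scaffold.

    The material addresses are preserved exactly; only the world positions
    change. The generic scaffold must have the same element-grid topology as
    the scaffold the points were embedded against.
    """
    if not embedded:
        return np.empty((0, 3))
    el = np.array([e.material.element_id for e in embedded])
    if el.max(initial=0) >= generic.n_elements:
        raise ValueError("topology mismatch: element id outside generic scaffold")
    xi = np.array([e.material.xi for e in embedded])
    return evaluate_many(generic, el, xi)


@dataclass
class OverlapMap:
    """Per-bin density overlap of two subjects on the generic scaffold.

    Bins are ξ-subcells of the generic elements. ``density_a``/``density_b``
    are per-bin fractions (each sums to 1); ``global_overlap`` is the
    histogram intersection Σ min(d_a, d_b) ∈ [0, 1]; ``jaccard_occupied``
    compares the sets of occupied bins. All quantities are symmetric in the
    two subjects.
    """

    subgrid: int
    counts_a: np.ndarray
    counts_b: np.ndarray
    density_a: np.ndarray = field(init=False)
    density_b: np.ndarray = field(init=False)
    overlap_per_bin: np.ndarray = field(init=False)
    global_overlap: float = field(init=False)
    jaccard_occupied: float = field(init=False)

    def __post_init__(self) -> None:
        ca, cb = self.counts_a, self.counts_b
        na, nb = int(ca.sum()), int(cb.sum())
        self.density_a = ca / na
        self.density_b = cb / nb
        # integer-exact histogram intersection: min(ca/na, cb/nb) summed
        self.global_overlap = float(
            np.minimum(ca * nb, cb * na).sum() / (na * nb)
        )
        occ_a, occ_b = ca > 0, cb > 0
        either = occ_a | occ_b
        both = occ_a & occ_b
        self.jaccard_occupied = float(both.sum() / either.sum()) if either.any() else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.minimum(self.density_a, self.density_b) / np.maximum(
                self.density_a, self.density_b
            )
        self.overlap_per_bin = np.where(either, ratio, np.nan)


def _bin_indices(
    materials: list[MaterialCoordinate] | np.ndarray,
    generic: Scaffold,
    subgrid: int,
) -> np.ndarray:
    if isinstance(materials, np.ndarray):
        el, xi, _ = project_points(generic, materials, mode="fast")
    else:
        el = np.array([m.element_id for m in materials])
        xi = np.array([m.xi for m in materials])
    sub = np.minimum((xi * subgrid).astype(int), subgrid - 1)
    return el * subgrid * subgrid + sub[:, 0] * subgrid + sub[:, 1]


def overlap_map(
    a: list | np.ndarray,
    b: list | np.ndarray,
    generic: Scaffold,
    subgrid: int = 2,
) -> OverlapMap:
    """Bin two transferred point sets on the generic scaffold and measure
    their density overlap.

    ``a`` and ``b`` may be lists of :class:`EmbeddedPoint`/
    :class:`MaterialCoordinate` (binned by their material address) or (n, 3)
    world points (projected onto the generic scaffold first).
    """
    if subgrid < 1:
        raise ValueError("subgrid must be >= 1")

    def as_materials(x):
        if isinstance(x, np.ndarray):
            if len(x) == 0:
                raise ValueError("point sets must be non-empty")
            return x
        if len(x) == 0:
            raise ValueError("point sets must be non-empty")
        if isinstance(x[0], EmbeddedPoint):
            return [e.material for e in x]
        return x

    n_bins = generic.n_elements * subgrid * subgrid
    ia = _bin_indices(as_materials(a), generic, subgrid)
    ib = _bin_indices(as_materials(b), generic, subgrid)
    counts_a = np.bincount(ia, minlength=n_bins)
    counts_b = np.bincount(ib, minlength=n_bins)
    return OverlapMap(subgrid=subgrid, counts_a=counts_a, counts_b=counts_b)
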