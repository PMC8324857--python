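"""Synthetic heart-like subjects for end-to-end testing of the mapping
pipeline.

Real inputs to this package are whole-heart annotation files: thousands of
neuron somata mapped as 3D points on the epicardial surface of the atrial
base, plus per-section contour traces of chambers and vessels. This module
emulates those data so every downstream stage (filtering, clustering,
flatmaps, ROI association, scaffold registration) can be exercised and
validated against a known ground truth without any download.

The template geometry is a single-sheet parametric surface over
(u, v) ∈ [0, 1]²: a tilted plane carrying a broad dome (the atrial base)
and a gentler ridge (the hilum where the great vessels enter), at a
physiological ~8 mm extent. Named anatomical structures are rectangular
(u, v) patches of this sheet, and five regions of interest (the four
vessel/sulcus ROIs plus the posterior left atrium) are anchor points on it.
Neurons are planted as ROI-anchored Gaussian clusters with sex-specific
totals (male ≈ 2845, female ≈ 1581 neurons per heart, females at lower
packing density), per-subject smooth deformations stand in for individual
anatomical variability, and contours are obtained by slicing the deformed
surface at the 5 µm section spacing of the serial-sectioning microscope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import measure

from .core_io import ContourTrace, NeuronMarker, SubjectMap

__all__ = [
    "CORE_ROIS",
    "ALL_ROIS",
    "SurfaceGrid",
    "TemplateHeart",
    "SexProfile",
    "GroundTruth",
    "make_template_heart",
    "male_profile",
    "female_profile",
    "validation_profile",
    "sample_icns",
    "deform_subject",
    "slice_contours",
    "make_subject",
    "expand_section_span",
    "dedup_section_intervals",
]

logger = logging.getLogger(__name__)

#: The four vessel/sulcus regions of interest where neuron clusters
#: consistently localize, plus the posterior left atrium band.
CORE_ROIS = (
    "pv_hilum",
    "svc_ra_root",
    "left_av_sulcus",
    "anterior_interatrial_sulcus",
)
ALL_ROIS = CORE_ROIS + ("posterior_left_atrium",)

_ANCHORS = {
    "pv_hilum": (0.50, 0.80),
    "svc_ra_root": (0.20, 0.65),
    "left_av_sulcus": (0.75, 0.30),
    "anterior_interatrial_sulcus": (0.42, 0.55),
    "posterior_left_atrium": (0.62, 0.50),
}

# (umin, vmin, umax, vmax) patches of the sheet per contoured structure.
_REGIONS = {
    "left_atrium": (0.44, 0.22, 0.88, 0.72),
    "right_atrium": (0.06, 0.30, 0.40, 0.78),
    "pulmonary_vein_left": (0.56, 0.74, 0.66, 0.92),
    "pulmonary_vein_middle": (0.45, 0.74, 0.55, 0.92),
    "pulmonary_vein_right": (0.34, 0.74, 0.44, 0.92),
    "superior_vena_cava": (0.10, 0.62, 0.24, 0.88),
    "inferior_vena_cava": (0.08, 0.10, 0.22, 0.30),
    "coronary_sinus": (0.62, 0.18, 0.90, 0.34),
    "left_auricle": (0.84, 0.40, 0.96, 0.62),
    "right_auricle": (0.04, 0.40, 0.16, 0.60),
    "aorta": (0.30, 0.56, 0.42, 0.72),
    "pulmonary_trunk": (0.58, 0.60, 0.72, 0.74),
}


@dataclass
class SurfaceGrid:
    """A surface sampled on a regular (u, v) grid; ``X[i, j]`` is the world
    x-coordinate at ``(u[i], v[j])`` (micrometres)."""

    u: np.ndarray
    v: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.stack([self.X, self.Y, self.Z], axis=-1)


@dataclass(frozen=True)
class TemplateHeart:
    """Analytic template of the atrial-base sheet.

    ``nodes`` samples the surface on the requested quad grid; the analytic
    evaluators below are exact at any (u, v).
    """

    extent: float
    grid: tuple[int, int]
    nodes: np.ndarray  # ((nu+1), (nv+1), 3)
    roi_anchors: dict[str, tuple[float, float]]
    structure_regions: dict[str, tuple[float, float, float, float]]

    def _params(self):
        E = self.extent
        return dict(
            z0=0.10 * E,
            tilt=0.18,
            dome_amp=0.225 * E,
            dome_sig=0.25 * E,
            dome_c=(0.5 * E, 0.45 * E),
            ridge_amp=0.0625 * E,
            ridge_sig=(0.175 * E, 0.13 * E),
            ridge_c=(0.5 * E, 0.85 * E),
        )

    def surface_point(self, uv: np.ndarray) -> np.ndarray:
        """Evaluate the surface at (u, v) pairs; returns (..., 3) in µm."""
        uv = np.asarray(uv, dtype=float)
        p = self._params()
        x = uv[..., 0] * self.extent
        y = uv[..., 1] * self.extent
        gd = np.exp(
            -((x - p["dome_c"][0]) ** 2 + (y - p["dome_c"][1]) ** 2)
            / (2 * p["dome_sig"] ** 2)
        )
        gt = np.exp(
            -((x - p["ridge_c"][0]) ** 2) / (2 * p["ridge_sig"][0] ** 2)
            - ((y - p["ridge_c"][1]) ** 2) / (2 * p["ridge_sig"][1] ** 2)
        )
        z = p["z0"] + p["tilt"] * x + p["dome_amp"] * gd + p["ridge_amp"] * gt
        return np.stack([x, y, z], axis=-1)

    def surface_normal(self, uv: np.ndarray) -> np.ndarray:
        """Unit upward normal of the height field at (u, v)."""
        uv = np.asarray(uv, dtype=float)
        p = self._params()
        x = uv[..., 0] * self.extent
        y = uv[..., 1] * self.extent
        gd = np.exp(
            -((x - p["dome_c"][0]) ** 2 + (y - p["dome_c"][1]) ** 2)
            / (2 * p["dome_sig"] ** 2)
        )
        gt = np.exp(
            -((x - p["ridge_c"][0]) ** 2) / (2 * p["ridge_sig"][0] ** 2)
            - ((y - p["ridge_c"][1]) ** 2) / (2 * p["ridge_sig"][1] ** 2)
        )
        zx = (
            p["tilt"]
            - (x - p["dome_c"][0]) / p["dome_sig"] ** 2 * p["dome_amp"] * gd
            - (x - p["ridge_c"][0]) / p["ridge_sig"][0] ** 2 * p["ridge_amp"] * gt
        )
        zy = (
            -(y - p["dome_c"][1]) / p["dome_sig"] ** 2 * p["dome_amp"] * gd
            - (y - p["ridge_c"][1]) / p["ridge_sig"][1] ** 2 * p["ridge_amp"] * gt
        )
        n = np.stack([-zx, -zy, np.ones_like(zx)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    def sample_grid(self, resolution: int = 129) -> SurfaceGrid:
        """Sample the surface on a fine uniform grid for slicing/warping."""
        u = np.linspace(0.0, 1.0, resolution)
        v = np.linspace(0.0, 1.0, resolution)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        pts = self.surface_point(np.stack([uu, vv], axis=-1))
        return SurfaceGrid(u=u, v=v, X=pts[..., 0], Y=pts[..., 1], Z=pts[..., 2])


def make_template_heart(
    extent: float = 8000.0, grid: tuple[int, int] = (8, 8)
) -> TemplateHeart:
    """Build the deterministic template heart surface.

    Parameters
    ----------
    extent:
        Lateral extent of the sheet in micrometres (~8 mm for a young rat
        atrial base).
    grid:
        (nu, nv) quad resolution of the stored node grid; the surface itself
        is analytic and can be evaluated anywhere.
    """
    nu, nv = grid
    if nu < 2 or nv < 2:
        raise ValueError("grid must be at least (2, 2)")
    if not extent > 0:
        raise ValueError("extent must be positive")
    tpl = TemplateHeart(
        extent=float(extent),
        grid=(nu, nv),
        nodes=np.empty((nu + 1, nv + 1, 3)),
        roi_anchors=dict(_ANCHORS),
        structure_regions=dict(_REGIONS),
    )
    u = np.linspace(0.0, 1.0, nu + 1)
    v = np.linspace(0.0, 1.0, nv + 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    nodes = tpl.surface_point(np.stack([uu, vv], axis=-1))
    object.__setattr__(tpl, "nodes", nodes)
    return tpl


# ---------------------------------------------------------------------------
# Sex profiles and neuron sampling


@dataclass(frozen=True)
class SexProfile:
    """Generation parameters for one sex.

    Defaults reproduce the study conditions: males average 2845 neurons per
    heart in 8–12 clusters, females 1581 neurons in fewer, less densely
    packed clusters. ``density_scale`` rescales cluster spread as
    ``spread / sqrt(density_scale)`` so a smaller value yields the lower
    female packing density at fixed cluster count.
    """

    label: str
    total_neurons_mean: float
    total_neurons_cv: float
    n_clusters_range: tuple[int, int]
    cluster_spread: float  # µm, tangent-plane Gaussian sd
    background_fraction: float
    density_scale: float
    normal_sd: float = 25.0  # µm, off-surface jitter

    def __post_init__(self) -> None:
        if not self.total_neurons_mean > 0:
            raise ValueError("total_neurons_mean must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        lo, hi = self.n_clusters_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid n_clusters_range")

    @property
    def effective_spread(self) -> float:
        return self.cluster_spread / np.sqrt(self.density_scale)


def male_profile(**overrides) -> SexProfile:
    kw = dict(
        label="male",
        total_neurons_mean=2845.0,
        total_neurons_cv=0.05,
        n_clusters_range=(8, 12),
        cluster_spread=300.0,
        background_fraction=0.05,
        density_scale=1.0,
    )
    kw.update(overrides)
    return SexProfile(**kw)


def female_profile(**overrides) -> SexProfile:
    kw = dict(
        label="female",
        total_neurons_mean=1581.0,
        total_neurons_cv=0.07,
        n_clusters_range=(4, 8),
        cluster_spread=300.0,
        background_fraction=0.05,
        density_scale=0.7,
    )
    kw.update(overrides)
    return SexProfile(**kw)


def validation_profile(total_neurons_mean: float = 240.0, **overrides) -> SexProfile:
    """A deliberately small 4-cluster profile (one cluster per vessel/sulcus
    ROI) used for ground-truth recovery simulations, where hundreds of
    repeated clustering and registration runs are required."""
    kw = dict(
        label="male",
        total_neurons_mean=total_neurons_mean,
        total_neurons_cv=0.08,
        n_clusters_range=(4, 4),
        cluster_spread=300.0,
        background_fraction=0.03,
        density_scale=1.0,
    )
    kw.update(overrides)
    return SexProfile(**kw)


@dataclass
class GroundTruth:
    """Per-marker truth and per-subject warp bookkeeping."""

    true_cluster: dict[str, int] = field(default_factory=dict)
    roi_of_cluster: dict[int, str] = field(default_factory=dict)
    cluster_centers_uv: np.ndarray | None = None
    warp: dict = field(default_factory=dict)
    seed: int | None = None

    def roi_of_marker(self, marker_id: str) -> str | None:
        c = self.true_cluster.get(marker_id, -1)
        return self.roi_of_cluster.get(c)


def _place_cluster_centers(
    template: TemplateHeart,
    profile: SexProfile,
    n_clusters: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Anchor each cluster at an ROI and jitter it, enforcing a pairwise
    3D separation of at least 4x the effective cluster spread (a lower
    bound on the geodesic separation) so planted clusters are recoverable."""
    min_sep = 4.0 * profile.effective_spread
    E = template.extent
    names: list[str] = []
    centers: list[np.ndarray] = []
    pts3d: list[np.ndarray] = []
    for ci in range(n_clusters):
        if ci < len(CORE_ROIS):
            name, jitter_sd = CORE_ROIS[ci], 120.0
        else:
            name, jitter_sd = rng.choice(ALL_ROIS), 800.0
        anchor = np.array(template.roi_anchors[name])
        for attempt in range(2000):
            # widen the jitter progressively so placement succeeds even when
            # an anchor's neighbourhood is already crowded
            sd = jitter_sd * (1.0 + 0.01 * attempt)
            uv = np.clip(anchor + rng.normal(0, sd / E, 2), 0.03, 0.97)
            p = template.surface_point(uv)
            if all(np.linalg.norm(p - q) >= min_sep for q in pts3d):
                break
        else:
            raise RuntimeError(
                "could not place cluster centers at the requested separation; "
                "reduce n_clusters or cluster_spread"
            )
        names.append(str(name))
        centers.append(uv)
        pts3d.append(p)
    return np.array(centers), names


def sample_icns(
    template: TemplateHeart,
    profile: SexProfile,
    seed: int,
    *,
    section_thickness: float = 5.0,
) -> tuple[list[NeuronMarker], GroundTruth]:
    """Draw a synthetic ICNS point cloud on the template surface.

    Cluster count is uniform over the profile's range with every one of the
    four vessel/sulcus ROIs receiving at least one cluster; the total neuron
    count is Gaussian around the profile mean; cluster sizes are multinomial;
    marker positions are the cluster-center surface point plus a
    tangent-plane Gaussian of sd ``effective_spread`` and a small off-surface
    offset. A ``background_fraction`` of markers is spread uniformly over the
    sheet. Soma axes are lognormal with medians (16, 28) µm so that roughly
    97% of somata pass the 13 µm × 23 µm inclusion rule.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    rng = np.random.default_rng(seed)
    lo, hi = profile.n_clusters_range
    n_clusters = int(rng.integers(lo, hi + 1))
    centers_uv, anchor_names = _place_cluster_centers(
        template, profile, n_clusters, rng
    )

    total = max(
        n_clusters,
        int(round(rng.normal(profile.total_neurons_mean,
                             profile.total_neurons_cv * profile.total_neurons_mean))),
    )
    n_bg = int(round(profile.background_fraction * total))
    sizes = rng.multinomial(total - n_bg, np.full(n_clusters, 1.0 / n_clusters))

    E = template.extent
    spread_uv = profile.effective_spread / E
    uv_list = []
    true_ids = []
    for ci, m in enumerate(sizes):
        uv = centers_uv[ci] + rng.normal(0, spread_uv, (m, 2))
        uv_list.append(np.clip(uv, 0.005, 0.995))
        true_ids.extend([ci] * m)
    if n_bg:
        uv_list.append(rng.uniform(0.02, 0.98, (n_bg, 2)))
        true_ids.extend([-1] * n_bg)
    uv = np.vstack(uv_list)
    pos = template.surface_point(uv)
    pos += template.surface_normal(uv) * rng.normal(
        0, profile.normal_sd, (len(uv), 1)
    )

    short = np.exp(rng.normal(np.log(16.0), 0.09, len(uv)))
    ratio = np.exp(rng.normal(np.log(28.0 / 16.0), 0.04, len(uv)))
    long_ = short * ratio

    markers = [
        NeuronMarker(
            id=f"n{i:05d}",
            position=pos[i],
            section_index=max(0, int(np.floor(pos[i, 2] / section_thickness))),
            soma_short_axis=float(short[i]),
            soma_long_axis=float(long_[i]),
        )
        for i in range(len(uv))
    ]
    gt = GroundTruth(
        true_cluster={m.id: c for m, c in zip(markers, true_ids)},
        roi_of_cluster={ci: anchor_names[ci] for ci in range(n_clusters)},
        cluster_centers_uv=centers_uv,
        seed=int(seed),
    )
    return markers, gt


# ---------------------------------------------------------------------------
# Per-subject deformation


@dataclass
class _Warp:
    """Affine (scale + small z-rotation about the sheet centroid) plus a
    low-frequency sinusoidal displacement field, applied identically to the
    surface and the markers."""

    center: np.ndarray
    scale: float
    angle: float
    amplitudes: np.ndarray  # (3,) per-axis sinusoid amplitude, µm
    wave_dirs: np.ndarray  # (3, 3) unit direction per axis
    wave_freqs: np.ndarray  # (3,) cycles per µm
    phases: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        if self.scale == 1.0 and self.angle == 0.0 and not self.amplitudes.any():
            return p.copy()  # amplitude 0 is exactly the identity
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        q = self.center + self.scale * (p - self.center) @ rot.T
        phase = 2 * np.pi * self.wave_freqs * (p @ self.wave_dirs.T) + self.phases
        q = q + self.amplitudes * np.sin(phase)
        return q

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale,
            "angle": self.angle,
            "amplitudes": self.amplitudes.tolist(),
            "wave_dirs": self.wave_dirs.tolist(),
            "wave_freqs": self.wave_freqs.tolist(),
            "phases": self.phases.tolist(),
        }


_REFERENCE_AMPLITUDE = 300.0  # µm; affine deviation scales with a/300


def _draw_warp(
    template: TemplateHeart, warp_amplitude: float, rng: np.random.Generator
) -> _Warp:
    rel = warp_amplitude / _REFERENCE_AMPLITUDE
    scale = 1.0 + rel * rng.uniform(-0.1, 0.1)
    angle = rel * rng.uniform(-0.08, 0.08)
    dirs = rng.normal(size=(3, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    freqs = rng.uniform(0.5, 1.2, 3) / template.extent
    phases = rng.uniform(0, 2 * np.pi, 3)
    amp = np.full(3, warp_amplitude / np.sqrt(3.0))
    center = template.nodes.reshape(-1, 3).mean(axis=0)
    return _Warp(center, scale, angle, amp, dirs, freqs, phases)


def deform_subject(
    template: TemplateHeart,
    markers: list[NeuronMarker],
    warp_amplitude: float = 300.0,
    seed: int = 0,
    *,
    subject_id: str = "synthetic",
    sex: str = "unknown",
    section_thickness: float = 5.0,
    surface_resolution: int = 129,
    with_contours: bool = True,
    ground_truth: GroundTruth | None = None,
) -> SubjectMap:
    """Warp the template and its markers into an individual subject.

    The deformation is a subject-specific affine (scale and small rotation,
    both proportional to ``warp_amplitude / 300``) plus a low-frequency
    sinusoidal displacement whose per-axis amplitude is
    ``warp_amplitude / sqrt(3)``, so the total sinusoidal displacement never
    exceeds ``warp_amplitude``. Amplitude 0 is exactly the identity. The
    warped surface is sectioned into contour traces at the given thickness.
    """
    if warp_amplitude < 0:
        raise ValueError("warp_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    warp = _draw_warp(template, warp_amplitude, rng)
    if ground_truth is not None:
        ground_truth.warp = warp.to_dict()

    new_markers = []
    for m in markers:
        p = warp.apply(m.position[None])[0]
        new_markers.append(
            NeuronMarker(
                id=m.id,
                position=p,
                section_index=max(0, int(np.floor(p[2] / section_thickness))),
                soma_short_axis=m.soma_short_axis,
                soma_long_axis=m.soma_long_axis,
                cluster_label=m.cluster_label,
                roi_labels=set(m.roi_labels),
                flags=set(m.flags),
            )
        )

    contours: list[ContourTrace] = []
    if with_contours:
        grid = template.sample_grid(surface_resolution)
        pts = warp.apply(grid.points.reshape(-1, 3)).reshape(grid.points.shape)
        warped = SurfaceGrid(
            u=grid.u, v=grid.v, X=pts[..., 0], Y=pts[..., 1], Z=pts[..., 2]
        )
        contours = slice_contours(
            warped, template.structure_regions, section_thickness
        )

    return SubjectMap(
        subject_id=subject_id,
        sex=sex,
        section_thickness=section_thickness,
        markers=new_markers,
        contours=contours,
        provenance=f"synthetic subject, warp_amplitude={warp_amplitude}, seed={seed}",
    )


# ---------------------------------------------------------------------------
# Contour slicing


def slice_contours(
    surface: SurfaceGrid,
    structure_regions: dict[str, tuple[float, float, float, float]],
    thickness: float = 5.0,
) -> list[ContourTrace]:
    """Section the surface at planes ``z = k * thickness`` and clip the
    resulting iso-z polylines to each structure's (u, v) patch.

    Every emitted contour has all points at one z (the section plane) and at
    least two points; structures whose patch never meets a plane are simply
    skipped. Curves fully contained in a patch and closed on the grid are
    emitted as closed contours.
    """
    if not thickness > 0:
        raise ValueError("thickness must be positive")
    Z = surface.Z
    kmin = int(np.ceil(Z.min() / thickness))
    kmax = int(np.floor(Z.max() / thickness))
    du = surface.u[1] - surface.u[0]
    dv = surface.v[1] - surface.v[0]
    out: list[ContourTrace] = []
    for k in range(kmin, kmax + 1):
        level = k * thickness
        for curve in measure.find_contours(Z, level):
            is_closed = bool(np.allclose(curve[0], curve[-1]))
            if is_closed:
                curve = curve[:-1]
            if len(curve) < 2:
                continue
            u = surface.u[0] + curve[:, 0] * du
            v = surface.v[0] + curve[:, 1] * dv
            x = map_coordinates(surface.X, curve.T, order=1)
            y = map_coordinates(surface.Y, curve.T, order=1)
            for name, (umin, vmin, umax, vmax) in structure_regions.items():
                inside = (u >= umin) & (u <= umax) & (v >= vmin) & (v <= vmax)
                if not inside.any():
                    continue
                if inside.all():
                    pts = np.column_stack([x, y, np.full(len(u), level)])
                    if is_closed and len(pts) >= 3:
                        out.append(ContourTrace(name, pts, k, closed=True))
                    elif len(pts) >= 2:
                        out.append(ContourTrace(name, pts, k, closed=False))
                    continue
                # rotate a closed curve so runs do not wrap around the ends
                idx = np.arange(len(u))
                if is_closed:
                    first_out = int(np.argmin(inside))
                    idx = np.roll(idx, -first_out)
                ins = inside[idx]
                starts = np.flatnonzero(np.diff(np.r_[0, ins.view(np.int8)]) == 1)
                ends = np.flatnonzero(np.diff(np.r_[ins.view(np.int8), 0]) == -1)
                for s, e in zip(starts, ends):
                    sel = idx[s : e + 1]
                    if len(sel) < 2:
                        continue
                    pts = np.column_stack(
                        [x[sel], y[sel], np.full(len(sel), level)]
                    )
                    out.append(ContourTrace(name, pts, k, closed=False))
    if not out:
        logger.debug("no contour/plane intersections at thickness %g", thickness)
    return out


# ---------------------------------------------------------------------------
# Four-section counting-rule emulation


def expand_section_span(
    markers: list[NeuronMarker],
    seed: int,
    section_thickness: float = 5.0,
    span_range: tuple[int, int] = (3, 5),
) -> list[NeuronMarker]:
    """Emulate a soma appearing on every section it spans: each marker is
    duplicated over 3–5 consecutive sections at the same lateral position
    (the substrate for the interval counting rule)."""
    rng = np.random.default_rng(seed)
    out: list[NeuronMarker] = []
    for m in markers:
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        start = m.section_index
        for j in range(span):
            sec = start + j
            pos = m.position.copy()
            pos[2] = sec * section_thickness
            out.append(
                NeuronMarker(
                    id=f"{m.id}_s{j}",
                    position=pos,
                    section_index=sec,
                    soma_short_axis=m.soma_short_axis,
                    soma_long_axis=m.soma_long_axis,
                )
            )
    return out


def dedup_section_intervals(
    markers: list[NeuronMarker],
    window: int = 4,
    xy_decimals: int = 6,
) -> list[NeuronMarker]:
    """Collapse per-section duplicates of one soma into a single marker.

    Markers sharing a lateral position are grouped; within a group, runs of
    sections closer than ``window`` apart are treated as one soma (somata
    span ~3–5 sections at 5 µm, hence the four-section counting interval)
    and represented by the run's middle marker.
    """
    groups: dict[tuple, list[NeuronMarker]] = {}
    for m in markers:
        key = (round(m.position[0], xy_decimals), round(m.position[1], xy_decimals))
        groups.setdefault(key, []).append(m)
    out: list[NeuronMarker] = []
    for group in groups.values():
        group.sort(key=lambda m: m.section_index)
        run = [group[0]]
        for m in group[1:]:
            if m.section_index - run[-1].section_index < window:
                run.append(m)
            else:
                out.append(run[len(run) // 2])
                run = [m]
        out.append(run[len(run) // 2])
    out.sort(key=lambda m: m.id)
    return out


# ---------------------------------------------------------------------------
# Convenience


def make_subject(
    template: TemplateHeart,
    profile: SexProfile,
    seed: int,
    warp_amplitude: float = 300.0,
    *,
    subject_id: str | None = None,
    section_thickness: float = 5.0,
    surface_resolution: int = 129,
    with_contours: bool = True,
) -> tuple[SubjectMap, GroundTruth]:
    """Sample an ICNS and deform it into a complete synthetic subject."""
    markers, gt = sample_icns(
        template, profile, seed, section_thickness=section_thickness
    )
    subject = deform_subject(
        template,
        markers,
        warp_amplitude,
        # decorrelate the warp from the sampling draw
        seed=seed + 104729,
        subject_id=subject_id or f"{profile.label}-{seed}",
        sex=profile.label,
        section_thickness=section_thickness,
        surface_resolution=surface_resolution,
        with_contours=with_contours,
        ground_truth=gt,
    )
    return subject, gt
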