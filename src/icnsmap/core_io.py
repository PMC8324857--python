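"""Domain types and file I/O for single-neuron mapping data.

A *subject* is one mapped heart: a set of neuron markers (soma positions in
micrometres, one record per accepted neuron) plus anatomical contour traces
(per-section polylines outlining chambers and vessels). Subjects are stored
in a small XML dialect documented in ``docs/xml_format.md``:

.. code-block:: xml

    <subject id="M1" sex="male" section_thickness="5">
      <provenance>free text</provenance>
      <markers>
        <marker id="m0" section="12" soma_short="15.2" soma_long="28.4" cluster="3">
          <point x="100.0" y="200.0" z="62.5"/>
          <roi name="pv_hilum"/>
        </marker>
      </markers>
      <contours>
        <contour name="left_atrium" section="12" closed="false">
          <point x="0" y="0" z="60"/>
          ...
        </contour>
      </contours>
    </subject>

All coordinates are micrometres. Section indices are 0-based and relate to z
through ``z = section_index * section_thickness`` at the section mid-plane;
when a marker carries no explicit ``section`` attribute the index is derived
as ``floor(z / thickness)``. Unknown elements and attributes are ignored so
that richer files (e.g. full Tissue Mapper exports) still load; unknown
contour structure names are preserved verbatim but flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "STRUCTURE_VOCABULARY",
    "NeuronMarker",
    "ContourTrace",
    "SubjectMap",
    "SubjectValidationError",
    "MarkerRecordError",
    "read_subject",
    "write_subject",
    "apply_inclusion_filter",
    "markers_to_dataframe",
    "export_markers_csv",
]

#: Controlled vocabulary of anatomical structures that may be contoured.
STRUCTURE_VOCABULARY = frozenset(
    {
        "left_atrium",
        "right_atrium",
        "left_auricle",
        "right_auricle",
        "ventricles",
        "aorta",
        "pulmonary_trunk",
        "pulmonary_artery_left",
        "pulmonary_artery_right",
        "pulmonary_vein_left",
        "pulmonary_vein_middle",
        "pulmonary_vein_right",
        "superior_vena_cava",
        "inferior_vena_cava",
        "coronary_sinus",
        "coronary_artery",
    }
)


class SubjectValidationError(ValueError):
    """A subject or one of its records violates an invariant."""


class MarkerRecordError(SubjectValidationError):
    """One or more marker records are malformed (e.g. missing a position)."""


@dataclass
class NeuronMarker:
    """One mapped neuron soma.

    Parameters
    ----------
    id:
        Identifier, unique within a subject.
    position:
        3-vector (x, y, z) in micrometres.
    section_index:
        0-based index of the histological section the soma was mapped on.
    soma_short_axis, soma_long_axis:
        Measured soma axes in micrometres, or ``None`` when the source file
        records already-accepted neurons without size attributes.
    cluster_label:
        Cluster id assigned by downstream clustering, if any.
    roi_labels:
        Names of anatomical regions of interest the neuron is proximal to.
    flags:
        Free-form quality flags (e.g. ``size_unverified``).
    """

    id: str
    position: np.ndarray
    section_index: int
    soma_short_axis: float | None = None
    soma_long_axis: float | None = None
    cluster_label: int | None = None
    roi_labels: set[str] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise SubjectValidationError(
                f"marker {self.id!r}: position must be a 3-vector"
            )
        if not np.all(np.isfinite(self.position)):
            raise SubjectValidationError(f"marker {self.id!r}: non-finite position")
        if self.section_index < 0:
            raise SubjectValidationError(
                f"marker {self.id!r}: negative section index"
            )
        if (
            self.soma_short_axis is not None
            and self.soma_long_axis is not None
            and self.soma_long_axis < self.soma_short_axis
        ):
            raise SubjectValidationError(
                f"marker {self.id!r}: long axis < short axis"
            )

    def validate_section(self, thickness: float) -> None:
        """Check z vs. section-index consistency within half a thickness."""
        z_mid = self.section_index * thickness
        if abs(self.position[2] - z_mid) > 0.5 * thickness + 1e-9:
            raise SubjectValidationError(
                f"marker {self.id!r}: z={self.position[2]:g} inconsistent with "
                f"section {self.section_index} at thickness {thickness:g}"
            )


@dataclass
class ContourTrace:
    """A named anatomical structure polyline on one section."""

    structure_name: str
    points: np.ndarray
    section_index: int
    closed: bool = False
    recognized: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise SubjectValidationError(
                f"contour {self.structure_name!r}: points must be (n, 3)"
            )
        n_min = 3 if self.closed else 2
        if len(self.points) < n_min:
            raise SubjectValidationError(
                f"contour {self.structure_name!r}: needs >= {n_min} points"
            )
        z = self.points[:, 2]
        if np.ptp(z) > 1e-6 * max(1.0, abs(float(z[0]))) + 1e-6:
            raise SubjectValidationError(
                f"contour {self.structure_name!r}: points span multiple z values"
            )
        self.recognized = self.structure_name in STRUCTURE_VOCABULARY or self.recognized


@dataclass
class SubjectMap:
    """One subject: all markers and contours of a mapped heart."""

    subject_id: str
    sex: str = "unknown"
    section_thickness: float = 5.0
    markers: list[NeuronMarker] = field(default_factory=list)
    contours: list[ContourTrace] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise SubjectValidationError(f"unknown sex {self.sex!r}")
        if not self.section_thickness > 0:
            raise SubjectValidationError("section_thickness must be > 0")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SubjectValidationError(f"duplicate marker ids: {dup}")

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of marker positions in micrometres."""
        if not self.markers:
            return np.empty((0, 3))
        return np.array([m.position for m in self.markers])

    def contours_for(self, structure_name: str) -> list[ContourTrace]:
        return [c for c in self.contours if c.structure_name == structure_name]

    @property
    def structure_names(self) -> set[str]:
        return {c.structure_name for c in self.contours}


# ---------------------------------------------------------------------------
# XML reading / writing


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _parse_point(el: etree._Element, context: str) -> np.ndarray:
    try:
        return np.array(
            [float(el.get("x")), float(el.get("y")), float(el.get("z"))]
        )
    except (TypeError, ValueError) as exc:
        raise SubjectValidationError(
            f"{context}: point element missing x/y/z (line {el.sourceline})"
        ) from exc


def read_subject(
    path,
    section_thickness: float | None = None,
    contour_z_mode: str = "um",
) -> SubjectMap:
    """Read a subject from the mapping-XML dialect.

    Parameters
    ----------
    path:
        File path of the XML document.
    section_thickness:
        Section thickness in micrometres. Overrides the value stored in the
        file; defaults to the file's value (or 5 µm if absent).
    contour_z_mode:
        ``"um"`` if contour z coordinates are already micrometres (default),
        ``"section"`` if they are section indices to be multiplied by the
        thickness. Deposited files are ambiguous on this point, hence the flag.

    Raises
    ------
    lxml.etree.XMLSyntaxError
        Malformed markup (the error names the offending line).
    MarkerRecordError
        A marker record lacks a position; lists the marker ids.
    SubjectValidationError
        Duplicate marker ids or other invariant violations.
    """
    if contour_z_mode not in ("um", "section"):
        raise ValueError("contour_z_mode must be 'um' or 'section'")
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "subject":
        raise SubjectValidationError(
            f"root element is <{root.tag}>, expected <subject>"
        )
    thickness = section_thickness
    if thickness is None:
        thickness = float(root.get("section_thickness", 5.0))

    prov_el = root.find("provenance")
    provenance = prov_el.text or "" if prov_el is not None else ""

    markers: list[NeuronMarker] = []
    bad_ids: list[str] = []
    for mel in root.iterfind("markers/marker"):
        mid = mel.get("id", f"line{mel.sourceline}")
        pel = mel.find("point")
        if pel is None:
            bad_ids.append(mid)
            continue
        pos = _parse_point(pel, f"marker {mid!r}")
        sec = mel.get("section")
        section_index = (
            int(sec) if sec is not None else int(math.floor(pos[2] / thickness))
        )
        cluster = mel.get("cluster")
        rois = {rel.get("name") for rel in mel.iterfind("roi") if rel.get("name")}
        flags = {fel.get("name") for fel in mel.iterfind("flag") if fel.get("name")}
        short = mel.get("soma_short")
        long_ = mel.get("soma_long")
        markers.append(
            NeuronMarker(
                id=mid,
                position=pos,
                section_index=section_index,
                soma_short_axis=float(short) if short is not None else None,
                soma_long_axis=float(long_) if long_ is not None else None,
                cluster_label=int(cluster) if cluster is not None else None,
                roi_labels=rois,
                flags=flags,
            )
        )
    if bad_ids:
        raise MarkerRecordError(f"markers missing <point>: {bad_ids}")

    contours: list[ContourTrace] = []
    for cel in root.iterfind("contours/contour"):
        name = cel.get("name", "")
        pts = np.array(
            [_parse_point(p, f"contour {name!r}") for p in cel.iterfind("point")]
        )
        if pts.size and contour_z_mode == "section":
            pts = pts.copy()
            pts[:, 2] *= thickness
        sec = cel.get("section")
        section_index = (
            int(sec)
            if sec is not None
            else int(math.floor(pts[0, 2] / thickness))
        )
        recognized = name in STRUCTURE_VOCABULARY
        if not recognized:
            warnings.warn(
                f"unknown structure name {name!r} preserved verbatim",
                stacklevel=2,
            )
        contours.append(
            ContourTrace(
                structure_name=name,
                points=pts,
                section_index=section_index,
                closed=cel.get("closed", "false").lower() == "true",
                recognized=recognized,
            )
        )

    return SubjectMap(
        subject_id=root.get("id", ""),
        sex=root.get("sex", "unknown"),
        section_thickness=thickness,
        markers=markers,
        contours=contours,
        provenance=provenance,
    )


def write_subject(subject: SubjectMap, path) -> None:
    """Write a subject to the mapping-XML dialect (round-trips through
    :func:`read_subject` with 6-significant-digit float fidelity)."""
    root = etree.Element(
        "subject",
        id=subject.subject_id,
        sex=subject.sex,
        section_thickness=_fmt(subject.section_thickness),
    )
    if subject.provenance:
        etree.SubElement(root, "provenance").text = subject.provenance
    mroot = etree.SubElement(root, "markers")
    for m in subject.markers:
        attrs = {"id": m.id, "section": str(m.section_index)}
        if m.soma_short_axis is not None:
            attrs["soma_short"] = _fmt(m.soma_short_axis)
        if m.soma_long_axis is not None:
            attrs["soma_long"] = _fmt(m.soma_long_axis)
        if m.cluster_label is not None:
            attrs["cluster"] = str(m.cluster_label)
        mel = etree.SubElement(mroot, "marker", **attrs)
        etree.SubElement(
            mel,
            "point",
            x=_fmt(m.position[0]),
            y=_fmt(m.position[1]),
            z=_fmt(m.position[2]),
        )
        for name in sorted(m.roi_labels):
            etree.SubElement(mel, "roi", name=name)
        for name in sorted(m.flags):
            etree.SubElement(mel, "flag", name=name)
    croot = etree.SubElement(root, "contours")
    for c in subject.contours:
        cel = etree.SubElement(
            croot,
            "contour",
            name=c.structure_name,
            section=str(c.section_index),
            closed="true" if c.closed else "false",
        )
        for p in c.points:
            etree.SubElement(cel, "point", x=_fmt(p[0]), y=_fmt(p[1]), z=_fmt(p[2]))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# Inclusion filter and tabular export


def apply_inclusion_filter(
    markers: list[NeuronMarker],
    min_short: float = 13.0,
    min_long: float = 23.0,
) -> list[NeuronMarker]:
    """Apply the soma-size inclusion rule (boundary-inclusive).

    A marker is retained iff ``soma_short_axis >= min_short`` **and**
    ``soma_long_axis >= min_long``. Markers lacking axis measurements are
    retained with a ``size_unverified`` flag: deposited marker files record
    neurons that already passed the size criterion at annotation time.

    The operation is idempotent and order-preserving.
    """
    if min_short < 0 or min_long < 0:
        raise ValueError("thresholds must be non-negative")
    if min_short > min_long:
        raise ValueError("min_short must be <= min_long")
    kept: list[NeuronMarker] = []
    for m in markers:
        if m.soma_short_axis is None or m.soma_long_axis is None:
            m.flags.add("size_unverified")
            kept.append(m)
        elif m.soma_short_axis >= min_short and m.soma_long_axis >= min_long:
            kept.append(m)
    return kept


def markers_to_dataframe(subject: SubjectMap) -> pd.DataFrame:
    """Tabulate markers as a DataFrame (id, x, y, z, section, cluster, rois)."""
    rows = [
        {
            "id": m.id,
            "x": m.position[0],
            "y": m.position[1],
            "z": m.position[2],
            "section": m.section_index,
            "cluster": m.cluster_label if m.cluster_label is not None else -1,
            "rois": ";".join(sorted(m.roi_labels)),
        }
        for m in subject.markers
    ]
    return pd.DataFrame(
        rows, columns=["id", "x", "y", "z", "section", "cluster", "rois"]
    )


def export_markers_csv(subject: SubjectMap, path) -> None:
    markers_to_dataframe(subject).to_csv(path, index=False)
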