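# Subject mapping-XML dialect

One file per subject (one mapped heart). The dialect is a minimal, forward-
compatible subset of the kind of XML produced by neuroanatomical annotation
tools: readers ignore unknown elements and attributes, so richer exports
still load.

```xml
<?xml version="1.0" encoding="UTF-8"?>
<subject id="M0" sex="male" section_thickness="5">
  <provenance>free-text metadata</provenance>
  <markers>
    <marker id="n00001" section="12" soma_short="15.2" soma_long="28.4" cluster="3">
      <point x="1250.5" y="980.2" z="62.5"/>
      <roi name="pv_hilum"/>
      <flag name="size_unverified"/>
    </marker>
  </markers>
  <contours>
    <contour name="left_atrium" section="12" closed="false">
      <point x="1000.0" y="500.0" z="60.0"/>
      <point x="1030.0" y="520.0" z="60.0"/>
    </contour>
  </contours>
</subject>
```

## Conventions

- **Units**: all coordinates in micrometres (µm).
- **Sections**: 0-based indices; `z = section * section_thickness` at the
  section mid-plane. A marker without a `section` attribute gets
  `floor(z / thickness)`. A marker's z must be consistent with its section
  index within ±½ thickness.
- **Markers**: `id` unique within the subject (duplicate ids are a
  validation error); a `<point>` child is mandatory (its absence is a record
  error listing the offending ids); `soma_short`/`soma_long` (µm) are
  optional — markers without them pass the soma-size inclusion filter with a
  `size_unverified` flag; `cluster` is an optional integer label; `<roi>`
  children record proximity assignments.
- **Contours**: `name` should come from the controlled structure vocabulary
  (`left_atrium`, `right_atrium`, `left_auricle`, `right_auricle`,
  `ventricles`, `aorta`, `pulmonary_trunk`, `pulmonary_artery_left/right`,
  `pulmonary_vein_left/middle/right`, `superior_vena_cava`,
  `inferior_vena_cava`, `coronary_sinus`, `coronary_artery`); unknown names
  are preserved verbatim with a warning and `recognized=False`. All points
  of a contour share one z. Closed contours need ≥ 3 points, open ones ≥ 2.
  Whether deposited contour z values are µm or section indices is
  ambiguous in the wild, so `read_subject(..., contour_z_mode="section")`
  converts indices to µm on load.
- **Floats** are written with 10 significant digits; write → read
  round-trips are exact for strings/integers and to at least 6 significant
  digits for coordinates.

A flat CSV export of markers (`id, x, y, z, section, cluster, rois`) is
available through `icnsmap.core_io.export_markers_csv`.
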