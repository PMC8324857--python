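"""End-to-end orchestration: synthesize or load subjects, filter, cluster,
flatmap, ROI association, scaffold registration, and reporting.

Every random draw derives from one master seed through stage-named child
seeds, so a report is reproducible from its config alone. All artifacts are
plain JSON/CSV/PNG under the run's output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, core_io, flatmap, roi, scaffold, synthetic

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_sexes", "child_seed"]


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by hashing the
    master seed with the stage name (avoids correlated streams across
    stages without manual bookkeeping)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``inputs`` (paths of subject XML files) or synthetic subject
    counts (``n_male``/``n_female``) drive the run.
    """

    outdir: str = "icns_run"
    seed: int = 0
    inputs: list[str] = field(default_factory=list)
    n_male: int = 2
    n_female: int = 1
    total_neurons_male: float = 2845.0
    total_neurons_female: float = 1581.0
    warp_amplitude: float = 300.0
    section_thickness: float = 5.0
    min_soma_short: float = 13.0
    min_soma_long: float = 23.0
    k_min: int = 2
    k_max: int = 16
    n_null: int = 10
    cluster_subsample: int = 800
    roi_radius: float = 500.0
    scaffold_grid: tuple[int, int] = (16, 16)
    lambda_smooth: float = 1.0
    fit_data_points: int = 2000
    overlap_subgrid: int = 2
    write_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        missing = [p for p in self.inputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input files not found: {missing}")
        if not self.inputs and self.n_male + self.n_female < 1:
            raise ValueError("need at least one subject (inputs or synthetic)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scaffold_grid"] = list(self.scaffold_grid)
        return d


@dataclass
class RunReport:
    """All quantities computed by one run, reproducible from config + seed."""

    config: dict
    subjects: list[dict]  # per-subject counts, chosen k, silhouettes, density
    roi_counts: dict  # counts/fractions tables as dicts
    registration: dict  # fit RMS per subject, overlap scores
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "subjects": self.subjects,
                    "roi_counts": self.roi_counts,
                    "registration": self.registration,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _synthesize(config: RunConfig, outdir: Path) -> list[core_io.SubjectMap]:
    template = synthetic.make_template_heart()
    subjects = []
    specs = [("male", i) for i in range(config.n_male)] + [
        ("female", i) for i in range(config.n_female)
    ]
    for sex, i in specs:
        profile = (
            synthetic.male_profile(total_neurons_mean=config.total_neurons_male)
            if sex == "male"
            else synthetic.female_profile(
                total_neurons_mean=config.total_neurons_female
            )
        )
        seed = child_seed(config.seed, f"synth:{sex}:{i}")
        subject, gt = synthetic.make_subject(
            template,
            profile,
            seed,
            warp_amplitude=config.warp_amplitude,
            subject_id=f"{sex[0].upper()}{i}",
            section_thickness=config.section_thickness,
        )
        subjects.append(subject)
        with open(outdir / f"{subject.subject_id}_truth.json", "w") as fh:
            json.dump(
                {
                    "true_cluster": gt.true_cluster,
                    "roi_of_cluster": gt.roi_of_cluster,
                    "warp": gt.warp,
                    "seed": gt.seed,
                },
                fh,
            )
    return subjects


def _cluster_subject(
    subject: core_io.SubjectMap, config: RunConfig
) -> dict:
    pts = subject.positions
    seed = child_seed(config.seed, f"cluster:{subject.subject_id}")
    rng = np.random.default_rng(seed)
    if len(pts) > config.cluster_subsample:
        idx = np.sort(
            rng.choice(len(pts), config.cluster_subsample, replace=False)
        )
        sub = pts[idx]
    else:
        sub = pts
    k_max = min(config.k_max, len(sub) - 1)
    report = clustering.select_k(
        sub, config.k_min, k_max, n_null=config.n_null, seed=seed
    )
    final = clustering.pam(pts, report.chosen_k)
    for m, lab in zip(subject.markers, final.labels):
        m.cluster_label = int(lab)
    return {
        "chosen_k": report.chosen_k,
        "mean_silhouette": final.mean_silhouette,
        "selection": report.to_dict(),
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write artifacts under ``config.outdir``.

    Stage order: synthesize/load → soma-size filter → PAM + k selection →
    flatmap + packing density → ROI tabulation → scaffold registration and
    cross-subject overlap (first two subjects of the most numerous sex).
    Identical config and seed give an identical report.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    template = synthetic.make_template_heart()
    if config.inputs:
        subjects = [
            core_io.read_subject(p, section_thickness=config.section_thickness)
            for p in config.inputs
        ]
    else:
        subjects = _synthesize(config, outdir)

    subject_rows = []
    flatmaps = {}
    for subject in subjects:
        raw_n = len(subject.markers)
        subject.markers = core_io.apply_inclusion_filter(
            subject.markers, config.min_soma_short, config.min_soma_long
        )
        cluster_info = _cluster_subject(subject, config)
        proj = flatmap.flatmap_with_density(subject.positions)
        flatmaps[subject.subject_id] = proj
        subject_rows.append(
            {
                "subject_id": subject.subject_id,
                "sex": subject.sex,
                "n_markers_raw": raw_n,
                "n_markers": len(subject.markers),
                "chosen_k": cluster_info["chosen_k"],
                "mean_silhouette": cluster_info["mean_silhouette"],
                "selection": cluster_info["selection"],
                "mean_packing_density": float(np.mean(proj.density)),
                "kde_bandwidth": list(proj.bandwidth),
                "variance_explained": list(proj.variance_explained),
            }
        )
        core_io.write_subject(subject, outdir / f"{subject.subject_id}.xml")
        df = core_io.markers_to_dataframe(subject)
        df["flatmap_x"] = proj.coords2d[:, 0]
        df["flatmap_y"] = proj.coords2d[:, 1]
        df["density"] = proj.density
        df.to_csv(outdir / f"{subject.subject_id}_markers.csv", index=False)
        if config.write_plots:
            _plot_flatmap(subject, proj, outdir / f"{subject.subject_id}_flatmap.png")

    rois = roi.default_roi_definitions(config.roi_radius)
    table = roi.roi_counts(subjects, rois)
    table.counts.to_csv(outdir / "roi_counts.csv")
    table.fractions.to_csv(outdir / "roi_fractions.csv")

    registration = _register_pair(subjects, template, config, outdir)

    report = RunReport(
        config=config.to_dict(),
        subjects=subject_rows,
        roi_counts={
            "counts": table.counts.to_dict(),
            "fractions": table.fractions.to_dict(),
            "cluster_majority": table.cluster_majority,
        },
        registration=registration,
    )
    report.to_json(outdir / "report.json")
    return report


def _register_pair(
    subjects, template, config: RunConfig, outdir: Path
) -> dict:
    by_sex: dict[str, list] = {}
    for s in subjects:
        if s.contours:
            by_sex.setdefault(s.sex, []).append(s)
    pair = next((v[:2] for v in by_sex.values() if len(v) >= 2), None)
    generic = scaffold.make_generic_scaffold(template, config.scaffold_grid)
    out: dict = {"fit_rms_um": {}, "pair": None}
    if pair is None:
        return out
    refc = scaffold.reference_structure_centroids(
        template, config.section_thickness
    )
    regs = []
    for s in pair:
        reg = scaffold.register_subject(
            s,
            template,
            generic,
            lambda_smooth=config.lambda_smooth,
            max_data_points=config.fit_data_points,
            reference_centroids=refc,
        )
        out["fit_rms_um"][s.subject_id] = reg.fit.rms
        regs.append(reg)
    om = scaffold.overlap_map(
        regs[0].embedded, regs[1].embedded, generic, config.overlap_subgrid
    )
    out["pair"] = [s.subject_id for s in pair]
    out["global_overlap"] = om.global_overlap
    out["jaccard_occupied"] = om.jaccard_occupied
    with open(outdir / "overlap.json", "w") as fh:
        json.dump(
            {
                "pair": out["pair"],
                "subgrid": om.subgrid,
                "global_overlap": om.global_overlap,
                "jaccard_occupied": om.jaccard_occupied,
            },
            fh,
            indent=2,
        )
    return out


def _plot_flatmap(subject, proj, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharex=True, sharey=True)
    labels = np.array(
        [m.cluster_label if m.cluster_label is not None else -1 for m in subject.markers]
    )
    sc0 = axes[0].scatter(
        proj.coords2d[:, 0], proj.coords2d[:, 1], c=labels, s=4, cmap="tab20"
    )
    axes[0].set_title(f"{subject.subject_id}: PAM clusters")
    sc1 = axes[1].scatter(
        proj.coords2d[:, 0], proj.coords2d[:, 1], c=proj.density, s=4, cmap="viridis"
    )
    axes[1].set_title("packing density (neurons/µm²)")
    fig.colorbar(sc1, ax=axes[1])
    for ax in axes:
        ax.set_xlabel("PC1 (µm)")
        ax.set_aspect("equal")
    axes[0].set_ylabel("PC2 (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def compare_sexes(reports: list[RunReport]) -> pd.DataFrame:
    """Per-sex summary over one or more run reports: mean/sd of neuron
    counts and packing densities, mean chosen k, and the fraction of
    subjects with neurons present in each of the four vessel/sulcus ROIs."""
    rows = []
    for rep in reports:
        frac = pd.DataFrame(rep.roi_counts["fractions"])
        for s in rep.subjects:
            row = {
                "sex": s["sex"],
                "n_markers": s["n_markers"],
                "chosen_k": s["chosen_k"],
                "mean_packing_density": s["mean_packing_density"],
            }
            for r in synthetic.CORE_ROIS:
                row[f"present_{r}"] = float(
                    frac.loc[s["subject_id"], r] > 0 if r in frac.columns else 0.0
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    sexes = df["sex"].unique()
    if len(sexes) < 1 or df.groupby("sex").size().min() < 1:
        raise ValueError("need at least one report per sex")
    agg = df.groupby("sex").agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg
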