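"""End-to-end runs: phantoms or scans → per-object tables → statistics.

One config drives phantom synthesis (or volume loading), segmentation,
per-object morphometry, subject summaries, size-class analysis, group
comparisons and — when a reader-count table is supplied — the
expert-vs-automated agreement analysis.  Identical config + seed yields
byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .defaults import ALPHA, VISIBILITY_THRESHOLD_MM3, VOXEL_SIZE_MM
from .io import CountTable, VoxelVolume, read_count_table, read_volume, write_volume
from .morphometry import export_mesh, measure_all, mesh_object
from .phantom import CohortSpec, PhantomGroundTruth, make_cohort
from .segment import (
    LabeledMask,
    SegmentationConfig,
    apply_exclusions,
    global_threshold,
    label_objects,
    local_adaptive_threshold,
)
from .stats import (
    PARAMETER_COLUMNS,
    bland_altman,
    classify_by_size,
    compare_groups,
    count_ratio,
    mean_sd,
    paired_count_test,
    summarize_subject,
)

__all__ = ["PipelineConfig", "run_pipeline", "segment_volume", "validate_tables"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    ``mode`` is "synthesize" (render a phantom cohort from ``cohort``) or
    "volumes" (read TIFF stacks from ``input_dir``; subject group is taken
    from a leading "benign"/"malignant" in the file or directory name).
    """

    mode: str = "synthesize"
    voxel_size_mm: float = VOXEL_SIZE_MM
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    visibility_threshold_mm3: float = VISIBILITY_THRESHOLD_MM3
    alpha: float = ALPHA
    cohort: CohortSpec | None = None
    input_dir: str | None = None
    count_table: str | None = None
    output_dir: str = "runs/run"
    seed: int = 0
    export_meshes: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthesize", "volumes"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.visibility_threshold_mm3 > 0 and self.alpha > 0):
            raise ValueError("thresholds must be positive")
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationConfig(**self.segmentation)
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def segment_volume(vol: VoxelVolume, cfg: SegmentationConfig) -> LabeledMask:
    """Threshold (per ``cfg.method``) and label one volume."""
    if cfg.method == "global-otsu":
        mask = global_threshold(vol)
    else:
        mask = local_adaptive_threshold(vol, cfg)
    return label_objects(mask, connectivity=cfg.connectivity)


def _load_subjects(config: PipelineConfig):
    """Yield (name, group, VoxelVolume, ground truth | None)."""
    if config.mode == "synthesize":
        if config.cohort is None:
            config.cohort = CohortSpec(voxel_size=config.voxel_size_mm)
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        for vol, truth, group in make_cohort(spec):
            yield vol.name, group, vol, truth
        return
    root = Path(config.input_dir or ".")

    def _is_slice_dir(p: Path) -> bool:
        return p.is_dir() and any(
            q.suffix.lower() in (".tif", ".tiff") for q in p.iterdir()
        )

    entries = sorted(
        p for p in root.iterdir()
        if _is_slice_dir(p) or p.suffix.lower() in (".tif", ".tiff")
    ) if root.is_dir() else []
    if not entries:
        raise FileNotFoundError(f"no input volumes under {root}")
    for p in entries:
        name = p.stem if p.is_file() else p.name
        group = next(
            (g for g in ("benign", "malignant") if name.lower().startswith(g)),
            "unknown",
        )
        yield name, group, read_volume(p, config.voxel_size_mm, name=name), None


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Writes objects.csv, subjects.csv, size_classes.csv, exclusions.csv,
    comparisons.json, ground-truth tables (synthesize mode), Bland–Altman
    and count-test outputs (when a count table is configured), optional
    PLY meshes, and a manifest recording config, seed, package version and
    config hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_cfg = config.segmentation

    object_rows: list[dict] = []
    subject_rows: list[dict] = []
    exclusion_rows: list[dict] = []
    stage = "setup"
    try:
        for name, group, vol, truth in _load_subjects(config):
            stage = f"segmentation[{name}]"
            labels = segment_volume(vol, seg_cfg)
            labels, report = apply_exclusions(labels, seg_cfg)
            report.insert(0, "subject", name)
            exclusion_rows.append(report)

            stage = f"morphometry[{name}]"
            measured = measure_all(labels, min_voxels=seg_cfg.min_object_voxels)
            for m in measured:
                object_rows.append(
                    {
                        "subject": name,
                        "group": group,
                        "object_id": m.object_id,
                        "voxels": m.voxel_count,
                        "obj_v_mm3": m.volume_mm3,
                        "obj_s_mm2": m.surface_mm2,
                        "sv_per_mm": m.sv_ratio_per_mm,
                        "st_th_mm": m.thickness_mm,
                        "smi": m.smi,
                        "feret_mm": m.feret_mm,
                        "centroid_z_mm": m.centroid_mm[0],
                        "centroid_y_mm": m.centroid_mm[1],
                        "centroid_x_mm": m.centroid_mm[2],
                    }
                )
            summ = summarize_subject(measured, labels.n_objects, name, group)
            subject_rows.append(dataclasses.asdict(summ))
            if truth is not None:
                truth.table.to_csv(out / f"ground_truth_{name}.csv", index=False)
            if config.export_meshes:
                mesh_dir = out / "meshes"
                for m in measured:
                    export_mesh(
                        mesh_object(labels, m.object_id),
                        mesh_dir / f"{name}_obj{m.object_id:04d}.ply",
                    )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    objects = pd.DataFrame(object_rows)
    subjects = pd.DataFrame(subject_rows)
    objects.to_csv(out / "objects.csv", index=False)
    subjects.to_csv(out / "subjects.csv", index=False)
    pd.concat(exclusion_rows, ignore_index=True).to_csv(
        out / "exclusions.csv", index=False
    ) if exclusion_rows else None

    # size classes over pooled objects
    if len(objects):
        classified = classify_by_size(
            objects, visibility_threshold_mm3=config.visibility_threshold_mm3,
            min_voxels=seg_cfg.min_object_voxels,
        )
        classified.to_csv(out / "size_classes.csv", index=False)

    comparisons = _group_comparisons(subjects, config.alpha)
    agreement = {}
    if config.count_table:
        agreement = _count_agreement(read_count_table(config.count_table), out, config.alpha)
    with open(out / "comparisons.json", "w") as fh:
        json.dump({"group_comparisons": comparisons, "count_agreement": agreement,
                   "note": "no multiple-testing correction; each parameter "
                           f"tested independently at alpha={config.alpha}"},
                  fh, indent=2)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "calcimorph_version": __version__,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def _group_comparisons(subjects: pd.DataFrame, alpha: float) -> list[dict]:
    results = []
    if subjects.empty:
        return results
    ben = subjects[subjects["group"] == "benign"]
    mal = subjects[subjects["group"] == "malignant"]
    for col in PARAMETER_COLUMNS + ["obj_n"]:
        a = ben[col].dropna().to_numpy()
        b = mal[col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = compare_groups(a, b, parameter=col, alpha=alpha)
        results.append(
            {"parameter": col, "test": res.test, "statistic": res.statistic,
             "p": res.p_value, "n": list(res.n), "significant": res.significant}
        )
    return results


def _count_agreement(table: CountTable, out: Path, alpha: float) -> dict:
    ba = bland_altman(table)
    ba["points"].to_csv(out / "bland_altman.csv", index=False)
    agreement: dict = {
        "bland_altman": {"mean_difference": ba["mean_difference"],
                         "sd": ba["sd"], "limits": list(ba["limits"])},
        "ratio_estimators": {},
        "wilcoxon": {},
    }
    for est in ("through-origin-slope", "ols-slope", "ratio-of-totals"):
        val, ci = count_ratio(table, estimator=est)
        agreement["ratio_estimators"][est] = {"estimate": val, "ci95": list(ci)}
    for grp in ("benign", "malignant"):
        sub = table.group(grp)
        if len(sub) >= 5:
            res = paired_count_test(sub, alpha=alpha)
            agreement["wilcoxon"][grp] = {"statistic": res.statistic,
                                          "p": res.p_value, "n": res.n[0]}
    return agreement


def validate_tables(run_dir: str | Path, rel_tol: float = 1e-6) -> pd.DataFrame:
    """Internal-consistency checks on a completed run.

    Verifies, per objects.csv row, that S/V equals S ÷ V; per subject,
    that Obj.N >= the measurable count; that size classes partition the
    measured objects; and that exclusion bookkeeping adds up (retained +
    sub-resolution rows = objects kept in the mask).  Returns a report
    frame with one row per check; failures name the offending row.
    """
    run_dir = Path(run_dir)
    objects = pd.read_csv(run_dir / "objects.csv")
    subjects = pd.read_csv(run_dir / "subjects.csv")
    checks = []

    bad = objects.index[
        ~np.isclose(objects["sv_per_mm"],
                    objects["obj_s_mm2"] / objects["obj_v_mm3"], rtol=rel_tol)
    ].tolist() if len(objects) else []
    checks.append({"check": "sv_ratio_consistent", "passed": not bad,
                   "detail": f"rows {bad[:5]}" if bad else ""})

    bad = subjects.index[subjects["obj_n"] < subjects["obj_n_measurable"]].tolist()
    checks.append({"check": "objn_vs_measurable", "passed": not bad,
                   "detail": f"rows {bad[:5]}" if bad else ""})

    sc_path = run_dir / "size_classes.csv"
    if sc_path.exists() and len(objects):
        sc = pd.read_csv(sc_path)
        ok = len(sc) == len(objects) and set(sc["size_class"]) <= {
            "sub-resolution", "small", "large"}
        checks.append({"check": "size_classes_partition", "passed": bool(ok),
                       "detail": "" if ok else "class rows do not match objects"})

    ex_path = run_dir / "exclusions.csv"
    if ex_path.exists():
        ex = pd.read_csv(ex_path)
        kept = ex[ex["status"] != "macrocalcification"].groupby("subject").size()
        objn = subjects.set_index("subject")["obj_n"]
        mismatch = [s for s in objn.index
                    if int(kept.get(s, 0)) != int(objn[s])]
        checks.append({"check": "exclusion_bookkeeping", "passed": not mismatch,
                       "detail": f"subjects {mismatch[:5]}" if mismatch else ""})
    return pd.DataFrame(checks)
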