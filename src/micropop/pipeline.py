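"""End-to-end pipeline orchestration.

Stage sequence: prepared sections → (externally produced anchoring files,
validated here rather than regenerated, since the interactive registration
tools are upstream of this package) → segmentation post-processing →
voxelization → curation → hemisphere split/mirror → analytics. The run
manifest records pixel/voxel conservation at every stage so losses are
visible and auditable; outputs are deterministic for fixed inputs, and a
completed run is skipped on re-execution unless ``force`` is set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import analytics, segmentation, voxelization
from .anchoring import build_warp, read_nonlinear_anchoring
from .reference_space import load_reference_space
from .segmentation import CleaningParams


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    segmentation_dir: str
    anchoring_json: str
    annotation_path: str
    template_path: str
    hierarchy_path: str
    out_dir: str
    experiment_id: str = "exp1"
    flatmap_json: str | None = None
    min_object_px: int = 12
    radius_factor: float = 1.5
    nucleus_acronym: str = "VPM"
    area_acronym: str | None = None
    denominator: str = "targeted"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        return cls(**doc)

    def validate(self) -> None:
        for name in (
            "segmentation_dir",
            "anchoring_json",
            "annotation_path",
            "template_path",
            "hierarchy_path",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config path {name} does not exist: {p}")
        if self.min_object_px < 1:
            raise PipelineError("min_object_px must be >= 1")
        if self.radius_factor <= 0:
            raise PipelineError("radius_factor must be positive")
        if self.denominator not in {"targeted", "area"}:
            raise PipelineError(f"unknown denominator mode {self.denominator!r}")


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the full pipeline and return the run manifest.

    Aborts with the stage name and the offending section stem on any
    per-section error. Re-running a completed configuration returns the
    cached manifest unless ``force`` is given.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        with open(manifest_path) as fh:
            return json.load(fh)

    space = load_reference_space(
        config.annotation_path, config.template_path, config.hierarchy_path
    )
    hier = space.hierarchy
    anchoring = read_nonlinear_anchoring(config.anchoring_json)

    # --- pause-point validation: every segmented section must have anchoring
    seg_paths = sorted(Path(config.segmentation_dir).glob("*.png"))
    if not seg_paths:
        raise PipelineError(f"no segmentation images in {config.segmentation_dir}")
    stems = [p.stem for p in seg_paths]
    missing = [s for s in stems if s not in anchoring]
    if missing:
        raise PipelineError(f"stage anchoring: no anchoring for section(s) {missing}")

    params = CleaningParams(min_object_px=config.min_object_px)
    ledger: dict = {"sections": {}, "totals": {}}
    increments = []
    cleaning_reports = []
    for path, stem in zip(seg_paths, stems):
        try:
            seg = segmentation.read_label_image(path, stem=stem)
            raw_px = int(np.count_nonzero(seg.labels))
            cleaned, report = segmentation.clean_small_objects(seg, params)
            cleaning_reports.append(report)
            anchor, markers = anchoring[stem]
            warp = build_warp(markers, (anchor.width_px, anchor.height_px))
            src, tgt, vox_report = voxelization.voxelize_section(cleaned, anchor, warp, space)
            increments.append((src, tgt))
            ledger["sections"][stem] = {
                "raw_label_px": raw_px,
                "removed_px": sum(report["pixels_removed"].values()),
                "clamped": vox_report["clamped"],
                "out_of_space": vox_report["out_of_space"],
                "voxelized_px": src.total + tgt.total,
            }
            entry = ledger["sections"][stem]
            if entry["raw_label_px"] != (
                entry["removed_px"] + entry["voxelized_px"] + entry["out_of_space"]
            ):
                raise PipelineError(f"stage voxelize: conservation broken at {stem}")
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 — abort names stage + stem
            raise PipelineError(f"stage voxelize: section {stem}: {exc}") from exc

    record = voxelization.assemble_experiment(
        increments, config.experiment_id, color=(228, 26, 28)
    )
    pre_total = record.total
    record = voxelization.curate_injection_volume(record, space, hier, config.nucleus_acronym)
    if record.total != pre_total:
        raise PipelineError("stage curate: count conservation broken")
    left, right = voxelization.split_and_mirror(record, space)
    if left.total + right.total != record.total:
        raise PipelineError("stage split: count conservation broken")

    voxelization.write_record(out / "record.json", record)
    voxelization.write_record(out / "record_left.json", left)
    voxelization.write_record(out / "record_right_mirrored.json", right)
    segmentation.write_cleaning_report(out / "cleaning.json", cleaning_reports)

    ledger["totals"] = {
        "raw_label_px": sum(s["raw_label_px"] for s in ledger["sections"].values()),
        "removed_px": sum(s["removed_px"] for s in ledger["sections"].values()),
        "out_of_space": sum(s["out_of_space"] for s in ledger["sections"].values()),
        "clamped": sum(s["clamped"] for s in ledger["sections"].values()),
        "voxel_count_total": record.total,
        "source_total": record.source.total,
        "target_total": record.target.total,
    }

    results: dict = {}
    if config.flatmap_json is not None:
        lookup = analytics.flatmap_from_json(config.flatmap_json)
        merged = left.target.merged_with(right.target)
        flat = analytics.flatmap_project(merged, lookup)
        results["cortical_coverage"] = analytics.cortical_coverage(flat, lookup)
        results["flatmap_skipped_counts"] = flat.skipped_count
    if config.area_acronym is not None:
        results["layer_distribution"] = analytics.layer_distribution(
            record, space, hier, config.area_acronym
        )

    manifest = {
        "experiment_id": config.experiment_id,
        "seed": config.seed,
        "ledger": ledger,
        "results": results,
        "outputs": sorted(p.name for p in out.glob("*.json") if p.name != "manifest.json"),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
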