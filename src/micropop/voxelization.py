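"""Voxelization of registered segmented sections into sparse voxel clouds.

Every segmented pixel is pushed through the section's registration (warp
then anchor), binned into the 10 µm voxel containing it, and counted: a
voxel of value 100 holds 100 segmented pixels. Each tracing experiment
yields a *source* cloud (soma / injection volume, gray value 129) and a
*target* cloud (axonal segments, gray value 255).

Curation relabels source voxels found outside the expected nucleus as
axons (false negatives of neurite pixels). Hemispheres are split at the
mid left-right plane and right-hemisphere voxels may be mirrored onto the
left, exploiting the left-right symmetry of the reference template.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .anchoring import SectionAnchor, WarpField, section_pixel_to_reference
from .reference_space import ReferenceSpace, RegionHierarchy
from .segmentation import AXON, SOMA, SegmentedSection

Coord = tuple[int, int, int]


class VoxelizationError(ValueError):
    pass


@dataclass
class VoxelCloud:
    """Sparse voxel→pixel-count map over a declared grid."""

    space_dims: tuple[int, int, int]
    entries: dict[Coord, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nx, ny, nz = self.space_dims
        for (x, y, z), c in self.entries.items():
            if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
                raise VoxelizationError(f"voxel {(x, y, z)} outside dims {self.space_dims}")
            if c < 1:
                raise VoxelizationError(f"non-positive count {c} at {(x, y, z)}")

    def add(self, coord: Coord, count: int = 1) -> None:
        self.entries[coord] = self.entries.get(coord, 0) + count

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    @property
    def support(self) -> set[Coord]:
        return set(self.entries)

    def get(self, coord: Coord) -> int:
        return self.entries.get(tuple(int(c) for c in coord), 0)

    def coords_counts(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.entries:
            return np.empty((0, 3), dtype=int), np.empty((0,), dtype=int)
        items = sorted(self.entries.items())
        coords = np.array([c for c, _ in items], dtype=int)
        counts = np.array([n for _, n in items], dtype=int)
        return coords, counts

    def merged_with(self, other: "VoxelCloud") -> "VoxelCloud":
        if other.space_dims != self.space_dims:
            raise VoxelizationError(
                f"mixed space dims: {self.space_dims} vs {other.space_dims}"
            )
        out = dict(self.entries)
        for c, n in other.entries.items():
            out[c] = out.get(c, 0) + n
        return VoxelCloud(space_dims=self.space_dims, entries=out)

    def to_dense(self) -> np.ndarray:
        vol = np.zeros(self.space_dims, dtype=np.int64)
        coords, counts = self.coords_counts()
        if len(counts):
            vol[coords[:, 0], coords[:, 1], coords[:, 2]] = counts
        return vol


@dataclass
class PopulationRecord:
    """One registered tracing experiment: soma source + axon target clouds."""

    experiment_id: str
    source: VoxelCloud
    target: VoxelCloud
    color: tuple[int, int, int] = (255, 0, 0)

    def __post_init__(self) -> None:
        if self.source.space_dims != self.target.space_dims:
            raise VoxelizationError("source and target clouds disagree on space dims")

    @property
    def space_dims(self) -> tuple[int, int, int]:
        return self.source.space_dims

    @property
    def total(self) -> int:
        return self.source.total + self.target.total


def voxelize_section(
    seg: SegmentedSection,
    anchor: SectionAnchor,
    warp: WarpField | None,
    space: ReferenceSpace,
) -> tuple[VoxelCloud, VoxelCloud, dict]:
    """Map one cleaned segmented section into source/target cloud increments.

    Pixel centers are pushed through the registration and floor-binned into
    voxels. Returns (source_increment, target_increment, report); the report
    counts pixels whose warped position was clamped to the image rectangle
    and pixels that landed outside the reference grid (dropped).
    """
    if seg.geometry != (anchor.width_px, anchor.height_px):
        raise VoxelizationError(
            f"section {seg.stem!r}: segmentation geometry {seg.geometry} does not match "
            f"anchor geometry {(anchor.width_px, anchor.height_px)}"
        )
    dims = space.dims
    report = {"stem": seg.stem, "clamped": 0, "out_of_space": 0}
    clouds = {SOMA: VoxelCloud(space_dims=dims), AXON: VoxelCloud(space_dims=dims)}
    for value, cloud in clouds.items():
        rows, cols = np.nonzero(seg.labels == value)
        if rows.size == 0:
            continue
        pix = np.column_stack([cols + 0.5, rows + 0.5])
        ref, n_clamped = section_pixel_to_reference(anchor, warp, pix)
        report["clamped"] += n_clamped
        vox = np.floor(ref).astype(int)
        inb = np.all((vox >= 0) & (vox < np.asarray(dims)), axis=1)
        report["out_of_space"] += int(np.count_nonzero(~inb))
        for x, y, z in vox[inb]:
            cloud.add((int(x), int(y), int(z)))
    return clouds[SOMA], clouds[AXON], report


def assemble_experiment(
    increments: Sequence[tuple[VoxelCloud, VoxelCloud]],
    experiment_id: str,
    color: tuple[int, int, int] = (255, 0, 0),
) -> PopulationRecord:
    """Sum per-section cloud increments into one population record."""
    if not increments:
        raise VoxelizationError("no section increments to assemble")
    dims = increments[0][0].space_dims
    source = VoxelCloud(space_dims=dims)
    target = VoxelCloud(space_dims=dims)
    for src, tgt in increments:
        source = source.merged_with(src)
        target = target.merged_with(tgt)
    return PopulationRecord(experiment_id=experiment_id, source=source, target=target, color=color)


def curate_injection_volume(
    record: PopulationRecord,
    space: ReferenceSpace,
    hier: RegionHierarchy,
    nucleus_acronym: str,
) -> PopulationRecord:
    """Move source voxels lying outside the expected nucleus to the target
    cloud (their counts added): soma labels outside the injection nucleus
    are treated as false negatives of neurite pixels."""
    nucleus_ids = hier.descendant_ids(nucleus_acronym)  # raises on unknown acronym
    kept: dict[Coord, int] = {}
    moved: dict[Coord, int] = {}
    for coord, n in record.source.entries.items():
        if space.region_at(coord) in nucleus_ids:
            kept[coord] = n
        else:
            moved[coord] = n
    target = record.target.merged_with(VoxelCloud(space_dims=record.space_dims, entries=moved))
    return PopulationRecord(
        experiment_id=record.experiment_id,
        source=VoxelCloud(space_dims=record.space_dims, entries=kept),
        target=target,
        color=record.color,
    )


def split_and_mirror(
    record: PopulationRecord, space: ReferenceSpace
) -> tuple[PopulationRecord, PopulationRecord]:
    """Partition a record by hemisphere; right-hemisphere voxels are mirrored
    about the mid left-right plane so both parts live on the left."""

    def split_cloud(cloud: VoxelCloud) -> tuple[VoxelCloud, VoxelCloud]:
        left = VoxelCloud(space_dims=cloud.space_dims)
        right = VoxelCloud(space_dims=cloud.space_dims)
        for coord, n in cloud.entries.items():
            if space.is_left(coord):
                left.add(coord, n)
            else:
                right.add(space.mirror_to_left(coord), n)
        return left, right

    src_l, src_r = split_cloud(record.source)
    tgt_l, tgt_r = split_cloud(record.target)
    mk = lambda s, t: PopulationRecord(
        experiment_id=record.experiment_id, source=s, target=t, color=record.color
    )
    return mk(src_l, tgt_l), mk(src_r, tgt_r)


def dominant_population(
    records: Sequence[PopulationRecord], coordinate: Coord
) -> str | None:
    """Experiment id with the highest axon-pixel count at a coordinate.

    Ties break lexicographically on experiment id; returns None when no
    population has signal there.
    """
    best: tuple[int, str] | None = None
    for rec in records:
        n = rec.target.get(coordinate)
        if n <= 0:
            continue
        if best is None or n > best[0] or (n == best[0] and rec.experiment_id < best[1]):
            best = (n, rec.experiment_id)
    return None if best is None else best[1]


def assign_colors(experiment_ids: Sequence[str]) -> dict[str, tuple[int, int, int]]:
    """Maximally hue-spaced RGB palette, one unique color per experiment."""
    ids = sorted(set(experiment_ids))
    out = {}
    for i, eid in enumerate(ids):
        r, g, b = colorsys.hsv_to_rgb(i / max(len(ids), 1), 0.9, 0.95)
        out[eid] = (int(r * 255), int(g * 255), int(b * 255))
    return out


# ---------------------------------------------------------------------------
# serialization


def cloud_to_json_obj(cloud: VoxelCloud) -> dict:
    coords, counts = cloud.coords_counts()
    return {
        "space_dims": list(cloud.space_dims),
        "entries": [[int(x), int(y), int(z), int(c)] for (x, y, z), c in zip(coords, counts)],
    }


def cloud_from_json_obj(obj: Mapping) -> VoxelCloud:
    return VoxelCloud(
        space_dims=tuple(obj["space_dims"]),
        entries={(int(x), int(y), int(z)): int(c) for x, y, z, c in obj["entries"]},
    )


def write_record(path: str | Path, record: PopulationRecord) -> None:
    doc = {
        "experiment_id": record.experiment_id,
        "color": list(record.color),
        "source": cloud_to_json_obj(record.source),
        "target": cloud_to_json_obj(record.target),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_record(path: str | Path) -> PopulationRecord:
    with open(path) as fh:
        doc = json.load(fh)
    return PopulationRecord(
        experiment_id=doc["experiment_id"],
        source=cloud_from_json_obj(doc["source"]),
        target=cloud_from_json_obj(doc["target"]),
        color=tuple(doc.get("color", (255, 0, 0))),
    )


def cloud_to_nifti(path: str | Path, cloud: VoxelCloud, resolution_um: float = 10.0) -> None:
    """Export a cloud as a dense NIfTI count volume (interoperability)."""
    import nibabel as nib

    affine = np.diag([resolution_um / 1000.0] * 3 + [1.0])
    nib.save(nib.Nifti1Image(cloud.to_dense().astype(np.int32), affine), str(path))
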