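"""Quantification and visualization of registered populations.

Covers the dorsal cortical flatmap projection (voxel counts summed over
depth), per-layer axon distributions within a cortical area, the fraction
of the cortical surface covered by a population, maximum-projection views
of subcortical structures, and SVG overlays of segmented sections on atlas
template sections.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .anchoring import SectionAnchor, WarpField, linear_pixel_to_ccf
from .reference_space import LAYER_TAGS, ReferenceSpace, RegionHierarchy
from .segmentation import SegmentedSection
from .voxelization import Coord, PopulationRecord, VoxelCloud

AXES = {"coronal": 0, "horizontal": 1, "sagittal": 2}


class AnalyticsError(ValueError):
    pass


@dataclass
class FlatmapLookup:
    """Voxel→flatmap-pixel lookup for cortical voxels.

    ``entries`` maps a voxel triple to a flat pixel (row, col); voxels
    without an entry are non-cortical. ``area_labels`` carries the region id
    seen at each flat pixel and ``cortex_mask`` flags the pixels belonging
    to the unfolded cortical surface.
    """

    flat_dims: tuple[int, int]
    entries: dict[Coord, tuple[int, int]]
    area_labels: np.ndarray | None = None
    cortex_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        h, w = self.flat_dims
        for vox, (r, c) in self.entries.items():
            if not (0 <= r < h and 0 <= c < w):
                raise AnalyticsError(f"flat pixel {(r, c)} outside flat dims {self.flat_dims}")
        if self.cortex_mask is None:
            mask = np.zeros(self.flat_dims, dtype=bool)
            for r, c in self.entries.values():
                mask[r, c] = True
            self.cortex_mask = mask


@dataclass
class FlatIntensity:
    """Per-flatmap-pixel signal intensity for one population."""

    intensity: np.ndarray
    skipped_count: int = 0

    @property
    def total(self) -> float:
        return float(self.intensity.sum())


def flatmap_project(cloud: VoxelCloud, lookup: FlatmapLookup) -> FlatIntensity:
    """Sum each voxel's pixel count into its flatmap pixel.

    Voxels without a flat assignment are skipped and counted in
    ``skipped_count`` (their counts do not appear in the map).
    """
    out = np.zeros(lookup.flat_dims, dtype=np.int64)
    skipped = 0
    for coord, n in cloud.entries.items():
        px = lookup.entries.get(coord)
        if px is None:
            skipped += n
            continue
        out[px] += n
    return FlatIntensity(intensity=out, skipped_count=skipped)


def layer_distribution(
    record: PopulationRecord,
    space: ReferenceSpace,
    hier: RegionHierarchy,
    area_acronym: str,
) -> dict[str, float]:
    """Percentage of a population's axonal segments per cortical layer
    within one area, normalized to 100 across layers.

    Returns 0 for every layer when the area holds no axon signal (with a
    zero-total sentinel rather than a division error).
    """
    area_ids = hier.descendant_ids(area_acronym)
    counts = {tag: 0 for tag in LAYER_TAGS}
    for coord, n in record.target.entries.items():
        region = space.region_at(coord)
        if region == 0 or region not in area_ids:
            continue
        tag = hier.layer_tag(region)
        if tag in counts:
            counts[tag] += n
    total = sum(counts.values())
    if total == 0:
        import warnings

        warnings.warn(f"no axonal signal inside {area_acronym!r}; empty layer profile")
        return {tag: 0.0 for tag in LAYER_TAGS}
    return {tag: 100.0 * c / total for tag, c in counts.items()}


def cortical_coverage(flat: FlatIntensity, lookup: FlatmapLookup, threshold: float = 0.0) -> float:
    """Fraction of cortex-mask flatmap pixels carrying signal above the
    threshold (default: any signal at all)."""
    mask = lookup.cortex_mask
    denom = int(np.count_nonzero(mask))
    if denom == 0:
        raise AnalyticsError("empty cortex mask")
    hit = int(np.count_nonzero(flat.intensity[mask] > threshold))
    return hit / denom


@dataclass
class MaxProjection:
    """Three overlaid layers of a maximum-projection view."""

    background: np.ndarray  # template intensity, per-pixel max along axis
    contours: np.ndarray  # bool, boundaries between projected region labels
    soma_overlay: np.ndarray  # per-pixel max of source counts along axis
    axis: str


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels whose 4-neighborhood holds a differing label."""
    out = np.zeros(labels.shape, dtype=bool)
    out[:-1, :] |= labels[:-1, :] != labels[1:, :]
    out[1:, :] |= labels[1:, :] != labels[:-1, :]
    out[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    out[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    return out


def max_projection(
    record: PopulationRecord,
    space: ReferenceSpace,
    hier: RegionHierarchy,
    axis: str,
    nucleus_acronym: str,
) -> MaxProjection:
    """Maximum-projection view of a subcortical nucleus along a plane axis.

    Background is the per-pixel maximum of the template along the axis;
    contours delineate the boundaries between projected nucleus sub-region
    labels (projection rule: first nonzero label along the axis); the soma
    overlay is the per-pixel maximum of source voxel counts.
    """
    if axis not in AXES:
        raise AnalyticsError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    ax = AXES[axis]
    background = space.template.max(axis=ax)
    nucleus_ids = hier.descendant_ids(nucleus_acronym)
    sub = np.where(np.isin(space.annotation, sorted(nucleus_ids)), space.annotation, 0)
    nonzero = sub != 0
    first = np.argmax(nonzero, axis=ax)
    projected = np.take_along_axis(sub, np.expand_dims(first, ax), axis=ax).squeeze(ax)
    projected[~nonzero.any(axis=ax)] = 0
    contours = _boundary_mask(projected)
    soma = np.zeros(background.shape, dtype=np.int64)
    for (x, y, z), n in record.source.entries.items():
        pix = tuple(v for i, v in enumerate((x, y, z)) if i != ax)
        soma[pix] = max(soma[pix], n)
    return MaxProjection(background=background, contours=contours, soma_overlay=soma, axis=axis)


# ---------------------------------------------------------------------------
# SVG overlay of a segmented section on its atlas template section


def _region_color(region_id: int) -> str:
    # deterministic pseudo-color per region id
    rng = np.random.default_rng(region_id)
    r, g, b = (int(v) for v in rng.integers(60, 230, size=3))
    return f"#{r:02x}{g:02x}{b:02x}"


def sample_section_annotation(
    anchor: SectionAnchor, space: ReferenceSpace, stride: int = 1
) -> np.ndarray:
    """Region-id image of the template section seen through an anchor."""
    w, h = anchor.width_px, anchor.height_px
    cols = np.arange(0, w, stride) + 0.5
    rows = np.arange(0, h, stride) + 0.5
    cc, rr = np.meshgrid(cols, rows)
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    ref = linear_pixel_to_ccf(anchor, pts)
    vox = np.floor(ref).astype(int)
    dims = np.asarray(space.dims)
    inb = np.all((vox >= 0) & (vox < dims), axis=1)
    out = np.zeros(len(pts), dtype=space.annotation.dtype)
    out[inb] = space.annotation[vox[inb, 0], vox[inb, 1], vox[inb, 2]]
    return out.reshape(rr.shape)


def atlas_overlay_svg(
    seg: SegmentedSection,
    anchor: SectionAnchor,
    warp: WarpField | None,
    space: ReferenceSpace,
    hier: RegionHierarchy,
    stride: int = 1,
    max_marks: int = 20000,
) -> str:
    """SVG overlay: region-colored template section, black region
    boundaries, and the segmented pixels drawn in black on top.

    Selecting an alternative parcellation is done by passing the space and
    hierarchy of that parcellation (see
    :meth:`ReferenceSpace.with_parcellation`).
    """
    from skimage import measure

    w, h = anchor.width_px, anchor.height_px
    ann = sample_section_annotation(anchor, space, stride=stride)
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": str(w),
            "height": str(h),
            "viewBox": f"0 0 {w} {h}",
            "version": "1.1",
        },
    )
    regions = ET.SubElement(svg, "g", {"id": "regions"})
    for region_id in sorted(set(np.unique(ann).tolist()) - {0}):
        mask = ann == region_id
        acronym = hier.record(int(region_id)).acronym if int(region_id) in hier else str(region_id)
        g = ET.SubElement(
            regions,
            "g",
            {
                "id": f"region-{region_id}",
                "data-acronym": acronym,
                "fill": _region_color(int(region_id)),
                "stroke": "black",
                "stroke-width": "1",
            },
        )
        padded = np.pad(mask.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            pts = (contour - 1.0) * stride  # rows, cols → y, x
            d = "M " + " L ".join(f"{c:.1f},{r:.1f}" for r, c in pts) + " Z"
            ET.SubElement(g, "path", {"d": d})
    marks = ET.SubElement(svg, "g", {"id": "segments", "fill": "black"})
    rows, cols = np.nonzero(seg.labels)
    if rows.size > max_marks:
        step = int(np.ceil(rows.size / max_marks))
        rows, cols = rows[::step], cols[::step]
    for r, c in zip(rows.tolist(), cols.tolist()):
        ET.SubElement(
            marks, "rect", {"x": str(c), "y": str(r), "width": "1", "height": "1"}
        )
    return ET.tostring(svg, encoding="unicode")


# ---------------------------------------------------------------------------
# flatmap lookup I/O and tabular export


def flatmap_from_json(path: str | Path) -> FlatmapLookup:
    with open(path) as fh:
        doc = json.load(fh)
    entries = {
        (int(x), int(y), int(z)): (int(r), int(c)) for x, y, z, r, c in doc["entries"]
    }
    area = None
    if "area_labels" in doc and doc["area_labels"] is not None:
        area = np.asarray(doc["area_labels"], dtype=int)
    return FlatmapLookup(flat_dims=tuple(doc["flat_dims"]), entries=entries, area_labels=area)


def flatmap_to_json(path: str | Path, lookup: FlatmapLookup) -> None:
    doc = {
        "flat_dims": list(lookup.flat_dims),
        "entries": [
            [x, y, z, r, c] for (x, y, z), (r, c) in sorted(lookup.entries.items())
        ],
        "area_labels": None if lookup.area_labels is None else lookup.area_labels.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def layer_table(profiles: Mapping[str, Mapping[str, float]]):
    """Layer-distribution table (rows: experiments, cols: layers) as a
    pandas DataFrame, ready for CSV export."""
    import pandas as pd

    return pd.DataFrame.from_dict(profiles, orient="index")[list(LAYER_TAGS)]


def rasterize_flatmap(path: str | Path, flat: FlatIntensity, color=(255, 0, 0)) -> None:
    """Write a PNG where the chosen color scales with signal intensity."""
    import imageio.v3 as iio

    inten = flat.intensity.astype(float)
    peak = inten.max() if inten.max() > 0 else 1.0
    scale = (inten / peak)[..., None]
    rgb = (scale * np.asarray(color, dtype=float)).astype(np.uint8)
    iio.imwrite(str(path), rgb)
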