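"""Post-processing of pixel-classifier output for labeled sections.

The upstream pixel classifier emits integer labels 1 (axon), 2 (background)
and 3 (soma / injection volume). These are recoded to the gray-value
convention 255 / 0 / 129 for visual distinction, then small false-positive
objects are removed: pixels labeled soma or axon are grouped into objects
using a squared-Euclidean neighbor distance of at most 3 (in 2D this admits
the 8-neighborhood: diagonal steps have squared distance 2, two orthogonal
steps have 4), and every object of fewer than 12 pixels is relabeled as
background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label

AXON = 255
SOMA = 129
BACKGROUND = 0

_RAW_TO_GRAY = {1: AXON, 2: BACKGROUND, 3: SOMA}


class SegmentationError(ValueError):
    pass


@dataclass
class CleaningParams:
    """Small-object removal parameters.

    ``max_sq_distance`` is the squared Euclidean distance up to which two
    member pixels count as neighbors of the same object (3 → 8-connectivity
    in 2D). Objects with fewer than ``min_object_px`` pixels are removed.
    """

    min_object_px: int = 12
    max_sq_distance: int = 3

    def __post_init__(self) -> None:
        if self.min_object_px < 1:
            raise SegmentationError("min_object_px must be >= 1")

    @property
    def connectivity(self) -> int:
        # squared distance >= 2 admits diagonal neighbors
        return 2 if self.max_sq_distance >= 2 else 1


@dataclass
class SegmentedSection:
    """Recoded 3-class label image (values in {0, 129, 255})."""

    labels: np.ndarray
    stem: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SegmentationError("labels must be a 2D image")
        bad = set(np.unique(self.labels).tolist()) - {BACKGROUND, SOMA, AXON}
        if bad:
            raise SegmentationError(f"invalid label values: {sorted(bad)}")

    @property
    def geometry(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.labels.shape[1], self.labels.shape[0])


def recode_labels(raw: np.ndarray, stem: str = "") -> SegmentedSection:
    """Recode classifier labels 1/2/3 to gray values 255/0/129.

    Tolerant of already-recoded input (values in {0, 129, 255} pass through
    unchanged), which makes the operation idempotent.
    """
    raw = np.asarray(raw)
    values = set(np.unique(raw).tolist())
    if values <= {BACKGROUND, SOMA, AXON}:
        return SegmentedSection(labels=raw.astype(np.uint8), stem=stem)
    bad = values - {1, 2, 3}
    if bad:
        counts = {int(v): int((raw == v).sum()) for v in sorted(bad)}
        raise SegmentationError(f"unexpected raw label values (value: count): {counts}")
    out = np.zeros(raw.shape, dtype=np.uint8)
    for src, dst in _RAW_TO_GRAY.items():
        out[raw == src] = dst
    return SegmentedSection(labels=out, stem=stem)


def clean_small_objects(
    seg: SegmentedSection, params: CleaningParams | None = None
) -> tuple[SegmentedSection, dict]:
    """Remove objects below the size threshold.

    Objects are connected components over the union of soma and axon pixels
    (one joint rule, labels restored afterwards). Returns the cleaned
    section and a report with component and removed-pixel counts.
    """
    params = params or CleaningParams()
    mask = seg.labels != BACKGROUND
    comp = cc_label(mask, connectivity=params.connectivity)
    n_comp = int(comp.max())
    sizes = np.bincount(comp.ravel())
    small = sizes < params.min_object_px
    small[0] = False
    remove = small[comp]
    out = seg.labels.copy()
    removed_axon = int(np.count_nonzero(remove & (seg.labels == AXON)))
    removed_soma = int(np.count_nonzero(remove & (seg.labels == SOMA)))
    out[remove] = BACKGROUND
    report = {
        "stem": seg.stem,
        "components_found": n_comp,
        "components_removed": int(np.count_nonzero(small)),
        "pixels_removed": {"axon": removed_axon, "soma": removed_soma},
    }
    return SegmentedSection(labels=out, stem=seg.stem), report


def read_label_image(path: str | Path, stem: str | None = None) -> SegmentedSection:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:  # RGB(A) label image: use first channel
        arr = arr[..., 0]
    return recode_labels(arr, stem=stem or Path(path).stem)


def write_label_image(path: str | Path, seg: SegmentedSection) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), seg.labels.astype(np.uint8))


def write_cleaning_report(path: str | Path, reports: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True)
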