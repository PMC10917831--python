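"""Section-image preparation: ordering, downsampling and orientation fixes.

Histological section images must be numbered anterior→posterior (the suffix
``s001``, ``s002``, … is appended to the filename stem), downsampled so that
every image of a series stays under the 16-megapixel input bound of the
registration tools, and optionally rotated/mirrored where the user has
flagged a mounting problem. The downsampling factor is shared by the whole
series so all sections keep the same resolution.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Target pixel budget after downsampling; guarantees < 16 megapixels.
PIXEL_BUDGET = 15_000_000

#: Recognized orientation tokens. Rotations are counter-clockwise.
ORIENTATION_OPS = ("rotate90", "rotate180", "rotate270", "mirror_horizontal", "mirror_vertical")

_STEM_RE = re.compile(r"s(\d{3})$")


class SectionPrepError(ValueError):
    pass


@dataclass
class DownsampleSpec:
    """Uniform keep-every-``n``-th-pixel subsampling for one series."""

    n: int = 1
    pixel_budget: int = PIXEL_BUDGET

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SectionPrepError(f"downsample factor must be >= 1, got {self.n}")


@dataclass
class SectionImage:
    pixels: np.ndarray
    section_ordinal: int
    filename_stem: str
    orientation_ops: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = _STEM_RE.search(self.filename_stem)
        if not m or int(m.group(1)) != self.section_ordinal:
            raise SectionPrepError(
                f"stem {self.filename_stem!r} does not encode ordinal {self.section_ordinal}"
            )
        bad = [op for op in self.orientation_ops if op not in ORIENTATION_OPS]
        if bad:
            raise SectionPrepError(f"unknown orientation ops: {bad}")


def ordinal_from_stem(stem: str) -> int:
    m = _STEM_RE.search(stem)
    if not m:
        raise SectionPrepError(f"stem {stem!r} does not end in a section number sNNN")
    return int(m.group(1))


def assign_ordinals(filenames: Sequence[str]) -> list[str]:
    """Assign ``s001``, ``s002``, … stems to filenames already ordered
    anterior→posterior. Returns one stem per input, in order."""
    if not filenames:
        raise SectionPrepError("empty section series")
    if len(set(filenames)) != len(filenames):
        dups = sorted({f for f in filenames if list(filenames).count(f) > 1})
        raise SectionPrepError(f"duplicate filenames: {dups}")
    stems = []
    for i, name in enumerate(filenames, start=1):
        stem = Path(name).stem
        stems.append(f"{stem}s{i:03d}")
    return stems


def downsample_factor(series_dims: Sequence[tuple[int, int]], pixel_budget: int = PIXEL_BUDGET) -> int:
    """Series-wide subsampling factor: the largest per-image
    ``ceil(sqrt(h*w / budget))``, floored at 1.

    Every image subsampled at 1-out-of-``n`` per axis then holds at most
    ``pixel_budget`` pixels.
    """
    if not series_dims:
        raise SectionPrepError("empty section series")
    n = 1
    for h, w in series_dims:
        if h <= 0 or w <= 0:
            raise SectionPrepError(f"non-positive image dims ({h}, {w})")
        n = max(n, math.ceil(math.sqrt(h * w / pixel_budget)))
    return n


def apply_orientation(pixels: np.ndarray, ops: Sequence[str]) -> np.ndarray:
    out = pixels
    for op in ops:
        if op == "rotate90":
            out = np.rot90(out, 1)
        elif op == "rotate180":
            out = np.rot90(out, 2)
        elif op == "rotate270":
            out = np.rot90(out, 3)
        elif op == "mirror_horizontal":
            out = np.fliplr(out)
        elif op == "mirror_vertical":
            out = np.flipud(out)
        else:
            raise SectionPrepError(f"unknown orientation op {op!r}")
    return out


def preprocess(image: SectionImage, spec: DownsampleSpec) -> SectionImage:
    """Subsample by keeping every ``n``-th pixel per axis (phase 0), then
    apply the image's orientation fixes in order."""
    pixels = image.pixels[:: spec.n, :: spec.n]
    pixels = apply_orientation(pixels, image.orientation_ops)
    return SectionImage(
        pixels=pixels,
        section_ordinal=image.section_ordinal,
        filename_stem=image.filename_stem,
        orientation_ops=[],
    )


def prepare_series(
    images: Sequence[SectionImage],
    pixel_budget: int = PIXEL_BUDGET,
) -> tuple[list[SectionImage], DownsampleSpec]:
    """Compute the shared factor for a series and preprocess every section."""
    spec = DownsampleSpec(
        n=downsample_factor([im.pixels.shape[:2] for im in images], pixel_budget),
        pixel_budget=pixel_budget,
    )
    return [preprocess(im, spec) for im in images], spec


def write_manifest(path: str | Path, stems: Sequence[str], spec: DownsampleSpec,
                   orientation_ops: dict[str, list[str]] | None = None) -> None:
    doc = {
        "n": spec.n,
        "pixel_budget": spec.pixel_budget,
        "sections": [
            {"stem": s, "orientation_ops": (orientation_ops or {}).get(s, [])} for s in stems
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
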