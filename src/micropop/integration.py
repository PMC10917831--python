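"""Cross-modality integration of populations with single-neuron
morphologies and bulk tract-tracing experiments.

A population's soma cloud is summarized by its medoid — the occupied voxel
minimizing the (count-weighted) sum of Euclidean distances to all occupied
voxels, which unlike a centroid is guaranteed to be a labeled voxel. A
membership radius of 1.5 × the maximum medoid-to-soma distance (the factor
compensating incomplete tracer sampling) defines the anatomical volume a
population may occupy: any reconstructed long-range projecting neuron
(LRPN) whose soma falls inside the closed ball is classified as a putative
member and its axonal terminal points are pooled with the population.

Overlap between two modalities is assessed pixel-wise on the cortical
flatmap with three mutually exclusive states: both present (overlap),
population only, other modality only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .analytics import FlatIntensity
from .voxelization import Coord, PopulationRecord, VoxelCloud


class IntegrationError(ValueError):
    pass


@dataclass
class Morphology:
    """Single-neuron reconstruction reduced to soma + axon terminal points
    (reference-space voxel units)."""

    neuron_id: str
    soma: np.ndarray
    axon_terminal_points: np.ndarray

    def __post_init__(self) -> None:
        self.soma = np.asarray(self.soma, dtype=float)
        self.axon_terminal_points = np.asarray(self.axon_terminal_points, dtype=float).reshape(-1, 3)


@dataclass
class MembershipParams:
    radius_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_factor <= 0:
            raise IntegrationError("radius factor must be positive")


class OverlapState(IntEnum):
    NEITHER = 0
    POPULATION_ONLY = 1
    OTHER_ONLY = 2
    OVERLAP = 3


def population_medoid(source: VoxelCloud, weighted: bool = True) -> Coord:
    """Medoid of the soma cloud (k-medoids with k = 1): the occupied voxel
    minimizing the sum of Euclidean distances to all occupied voxels,
    weighted by pixel count unless ``weighted=False``."""
    coords, counts = source.coords_counts()
    if len(coords) == 0:
        raise IntegrationError("cannot take the medoid of an empty soma cloud")
    w = counts.astype(float) if weighted else np.ones(len(coords))
    d = cdist(coords, coords)
    cost = d @ w
    best = int(np.argmin(cost))  # coords are lexicographically sorted: ties → smallest
    return tuple(int(v) for v in coords[best])


def membership_radius(
    source: VoxelCloud, medoid: Coord, params: MembershipParams | None = None
) -> float:
    """1.5 × the maximum distance from the medoid to any occupied soma voxel."""
    params = params or MembershipParams()
    coords, _ = source.coords_counts()
    if len(coords) == 0:
        raise IntegrationError("empty soma cloud")
    d = np.linalg.norm(coords - np.asarray(medoid, dtype=float), axis=1)
    return params.radius_factor * float(d.max())


def classify_members(
    morphologies: Sequence[Morphology],
    medoid: Coord,
    radius: float,
    space_dims: tuple[int, int, int],
) -> tuple[list[Morphology], VoxelCloud]:
    """Select morphologies whose soma lies within the closed membership ball
    and pool their terminal points into a voxel cloud (floor-binned, one
    count each; out-of-grid terminals dropped)."""
    m = np.asarray(medoid, dtype=float)
    members = [mo for mo in morphologies if np.linalg.norm(mo.soma - m) <= radius]
    pooled = VoxelCloud(space_dims=space_dims)
    dims = np.asarray(space_dims)
    for mo in members:
        if mo.axon_terminal_points.size == 0:
            continue
        vox = np.floor(mo.axon_terminal_points).astype(int)
        inb = np.all((vox >= 0) & (vox < dims), axis=1)
        for x, y, z in vox[inb]:
            pooled.add((int(x), int(y), int(z)))
    return members, pooled


def nearest_bulk_experiment(
    record: PopulationRecord,
    catalogue: Sequence[tuple[str, Sequence[float]]],
    medoid: Coord | None = None,
) -> str:
    """Bulk-tracing experiment whose injection centroid is closest to the
    population medoid (ties break lexicographically on experiment id)."""
    if not catalogue:
        raise IntegrationError("empty bulk-experiment catalogue")
    if medoid is None:
        medoid = population_medoid(record.source)
    m = np.asarray(medoid, dtype=float)
    best: tuple[float, str] | None = None
    for eid, centroid in catalogue:
        d = float(np.linalg.norm(np.asarray(centroid, dtype=float) - m))
        if best is None or d < best[0] or (d == best[0] and eid < best[1]):
            best = (d, eid)
    return best[1]


def overlap_states(pop_flat: FlatIntensity, other_flat: FlatIntensity) -> np.ndarray:
    """Pixel-wise three-state overlap map (values from :class:`OverlapState`)."""
    a = pop_flat.intensity
    b = other_flat.intensity
    if a.shape != b.shape:
        raise IntegrationError(f"flatmap dims differ: {a.shape} vs {b.shape}")
    pop = a > 0
    other = b > 0
    out = np.full(a.shape, OverlapState.NEITHER, dtype=np.int8)
    out[pop & ~other] = OverlapState.POPULATION_ONLY
    out[~pop & other] = OverlapState.OTHER_ONLY
    out[pop & other] = OverlapState.OVERLAP
    return out


def overlap_fractions(
    states: np.ndarray,
    area_mask: np.ndarray,
    denominator: str = "targeted",
) -> dict[str, float]:
    """Per-state fractions inside an area of interest.

    ``denominator="targeted"`` (default) divides by the targeted pixels in
    the area (states then sum to 1); ``denominator="area"`` divides by all
    pixels of the area.
    """
    if area_mask.shape != states.shape:
        raise IntegrationError("area mask dims differ from state map dims")
    s = states[area_mask]
    n_overlap = int(np.count_nonzero(s == OverlapState.OVERLAP))
    n_pop = int(np.count_nonzero(s == OverlapState.POPULATION_ONLY))
    n_other = int(np.count_nonzero(s == OverlapState.OTHER_ONLY))
    targeted = n_overlap + n_pop + n_other
    if targeted == 0:
        import warnings

        warnings.warn("no targeted pixels inside the area mask")
        return {}
    if denominator == "targeted":
        denom = targeted
    elif denominator == "area":
        denom = int(np.count_nonzero(area_mask))
    else:
        raise IntegrationError(f"unknown denominator mode {denominator!r}")
    return {
        "overlap": n_overlap / denom,
        "population_only": n_pop / denom,
        "other_only": n_other / denom,
    }


# ---------------------------------------------------------------------------
# morphology and catalogue readers


def read_swc(path: str | Path, neuron_id: str | None = None) -> Morphology:
    """Read an SWC reconstruction; terminal points are the leaf nodes of the
    axon-typed (SWC type 2) subtrees, the soma the first type-1 node."""
    ids: dict[int, tuple[int, np.ndarray, int]] = {}
    children: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            nid, ntype = int(parts[0]), int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            parent = int(parts[6])
            ids[nid] = (ntype, xyz, parent)
            children[parent] = children.get(parent, 0) + 1
    soma = None
    terminals = []
    for nid, (ntype, xyz, parent) in ids.items():
        if ntype == 1 and soma is None:
            soma = xyz
        if ntype == 2 and children.get(nid, 0) == 0:
            terminals.append(xyz)
    if soma is None:
        raise IntegrationError(f"{path}: no soma (type 1) node")
    return Morphology(
        neuron_id=neuron_id or Path(path).stem,
        soma=soma,
        axon_terminal_points=np.asarray(terminals).reshape(-1, 3),
    )


def read_morphology_json(path: str | Path) -> Morphology:
    """Point-list JSON dialect: {neuron_id, soma: [x,y,z], terminals: [[…]]}."""
    with open(path) as fh:
        doc = json.load(fh)
    return Morphology(
        neuron_id=doc["neuron_id"],
        soma=np.asarray(doc["soma"], dtype=float),
        axon_terminal_points=np.asarray(doc.get("terminals", []), dtype=float).reshape(-1, 3),
    )


def read_bulk_catalogue(path: str | Path) -> list[tuple[str, tuple[float, float, float]]]:
    """Bulk-experiment catalogue: CSV with columns
    experiment_id, centroid_x, centroid_y, centroid_z (or a JSON list)."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        return [
            (str(e["experiment_id"]), (float(e["centroid_x"]), float(e["centroid_y"]), float(e["centroid_z"])))
            for e in doc
        ]
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                (
                    str(row["experiment_id"]),
                    (float(row["centroid_x"]), float(row["centroid_y"]), float(row["centroid_z"])),
                )
            )
    return out
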