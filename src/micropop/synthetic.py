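"""Synthetic fixture study generator with known ground truth.

Builds a miniature reference space (same axis semantics as the full-scale
10 µm grid, ~1/10 linear scale), tracing experiments whose section images,
anchoring files and nonlinear warps are emitted in the same formats the
pipeline consumes, plus single-neuron morphologies and a flatmap lookup.
Every stage of the pipeline can therefore be exercised against planted
ground truth without any external data.

The synthetic brain layout: a cortical shell (six layer bands stacked
superior→inferior) subdivided into areas along the left-right axis and
mirrored across the midline, a thalamic "VPM"-role nucleus with a "PO"
neighbor per hemisphere, and a generic remainder region. Tracing
experiments plant a soma blob inside the nucleus and axon blobs inside
chosen cortical layer regions, on coronal section planes; small decoy
objects (1–11 px) straddle the object-cleaning threshold.

When a nonzero warp magnitude is requested, the generator defines a smooth
analytic displacement field, samples marker pairs from it, and renders
section pixels by numerically inverting the forward field; the pipeline
recovers the geometry through its own piecewise-affine fit of the markers,
so recovery error measures genuine interpolation and rounding error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .anchoring import MarkerSet, SectionAnchor, write_linear_anchoring, write_nonlinear_anchoring
from .analytics import FlatmapLookup
from .integration import Morphology, membership_radius, population_medoid
from .reference_space import LAYER_TAGS, ReferenceSpace, RegionHierarchy
from .voxelization import Coord, VoxelCloud

_AREA_NAMES = ("SSp-bfd", "SSp-n", "SSp-m", "SSs", "MOp", "VISp", "AUDp", "RSPv")

ROOT_ID = 997
ISOCORTEX_ID = 315
TH_ID = 549
VPM_ID = 733
PO_ID = 734
OTHER_ID = 8


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reference space


def make_reference_space(
    dims: tuple[int, int, int] = (132, 80, 114),
    n_areas: int = 4,
    layered_cortex: bool = True,
    symmetric: bool = True,
    seed: int = 0,
) -> tuple[ReferenceSpace, RegionHierarchy]:
    """Build a miniature annotated reference space plus its hierarchy."""
    nx, ny, nz = dims
    if min(dims) < 20:
        raise SyntheticError(f"dims too small for a synthetic brain: {dims}")
    if not (1 <= n_areas <= len(_AREA_NAMES)):
        raise SyntheticError(f"n_areas must be in 1..{len(_AREA_NAMES)}")
    m = max(2, min(dims) // 16)
    records: list[dict] = [
        {"id": ROOT_ID, "acronym": "root", "parent_id": None, "layer": None},
        {"id": ISOCORTEX_ID, "acronym": "Isocortex", "parent_id": ROOT_ID, "layer": None},
        {"id": TH_ID, "acronym": "TH", "parent_id": ROOT_ID, "layer": None},
        {"id": VPM_ID, "acronym": "VPM", "parent_id": TH_ID, "layer": None},
        {"id": PO_ID, "acronym": "PO", "parent_id": TH_ID, "layer": None},
        {"id": OTHER_ID, "acronym": "OTH", "parent_id": ROOT_ID, "layer": None},
    ]
    ann = np.zeros(dims, dtype=np.int32)
    # brain interior
    ann[m : nx - m, m : ny - m, m : nz - m] = OTHER_ID

    # cortex: top band of y, areas as z-bands on the left mirrored right
    t = max(1, (ny - 2 * m) // 12)  # layer thickness
    half = nz // 2
    area_edges = np.linspace(m, half, n_areas + 1).astype(int)
    for i in range(n_areas):
        area_id = 100 + i
        acr = _AREA_NAMES[i]
        records.append({"id": area_id, "acronym": acr, "parent_id": ISOCORTEX_ID, "layer": None})
        z0, z1 = int(area_edges[i]), int(area_edges[i + 1])
        zs_left = (z0, z1)
        zs_right = (nz - z1, nz - z0)
        n_layers = 6 if layered_cortex else 1
        for j in range(n_layers):
            tag = LAYER_TAGS[j] if layered_cortex else None
            leaf_id = area_id * 10 + j
            leaf_acr = f"{acr}{tag}" if layered_cortex else f"{acr}-u"
            records.append(
                {"id": leaf_id, "acronym": leaf_acr, "parent_id": area_id, "layer": tag}
            )
            y0 = m + j * t
            y1 = m + (j + 1) * t if j < n_layers - 1 else m + 6 * t
            ann[m : nx - m, y0:y1, zs_left[0] : zs_left[1]] = leaf_id
            ann[m : nx - m, y0:y1, zs_right[0] : zs_right[1]] = leaf_id

    # thalamic nuclei: boxes below the cortex, per hemisphere
    ty0 = m + 6 * t + 2
    ty1 = min(ny - m, ty0 + max(4, (ny - 2 * m) // 5))
    tx0 = m + (nx - 2 * m) // 3
    tx1 = m + 2 * (nx - 2 * m) // 3
    zw = max(4, (half - m) // 4)
    vz0, vz1 = m + 2, m + 2 + zw
    pz0, pz1 = vz1 + 1, min(half - 1, vz1 + 1 + zw)
    for z0, z1, rid in (
        (vz0, vz1, VPM_ID),
        (pz0, pz1, PO_ID),
        (nz - vz1, nz - vz0, VPM_ID),
        (nz - pz1, nz - pz0, PO_ID),
    ):
        ann[tx0:tx1, ty0:ty1, z0:z1] = rid

    if not symmetric:
        # nudge one area boundary on the right hemisphere only
        z0r = nz - int(area_edges[1])
        ann[m : nx - m, m : m + 6 * t, z0r] = ann[m : nx - m, m : m + 6 * t, z0r - 1]

    hier = RegionHierarchy(records)

    # smooth template with per-region offsets so boundaries show up
    xx, yy, zz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r2 = ((xx - cx) / nx) ** 2 + ((yy - cy) / ny) ** 2 + ((zz - cz) / nz) ** 2
    template = np.where(ann > 0, 40.0 + 120.0 * np.exp(-8.0 * r2) + (ann % 7) * 6.0, 0.0)
    space = ReferenceSpace(annotation=ann, template=template, hierarchy=hier)
    return space, hier


def make_flatmap_lookup(space: ReferenceSpace, hier: RegionHierarchy) -> FlatmapLookup:
    """Dorsal flatmap for the synthetic cortex: cortical voxel (x, y, z)
    maps to flat pixel (row=x, col=z); the area label of a pixel is the
    area-level region of its column."""
    cortex_ids = hier.descendant_ids("Isocortex")
    nx, ny, nz = space.dims
    entries: dict[Coord, tuple[int, int]] = {}
    area_labels = np.zeros((nx, nz), dtype=int)
    area_level = {c for c in cortex_ids if hier.record(c).parent_id == ISOCORTEX_ID}
    for x, y, z in zip(*np.nonzero(np.isin(space.annotation, sorted(cortex_ids)))):
        entries[(int(x), int(y), int(z))] = (int(x), int(z))
        region = int(space.annotation[x, y, z])
        for anc in hier.ancestors(region):
            if anc in area_level:
                area_labels[x, z] = anc
                break
    return FlatmapLookup(flat_dims=(nx, nz), entries=entries, area_labels=area_labels)


def area_mask(lookup: FlatmapLookup, hier: RegionHierarchy, acronym: str) -> np.ndarray:
    """Boolean flatmap mask of one cortical area (by area label)."""
    ids = sorted(hier.descendant_ids(acronym))
    return np.isin(lookup.area_labels, ids)


# ---------------------------------------------------------------------------
# experiments


@dataclass
class BlobSpec:
    """One planted rectangular blob per section inside a named region."""

    region: str
    size_yz: tuple[int, int] = (3, 4)
    hemisphere: str = "left"  # left | right


@dataclass
class SyntheticSection:
    stem: str
    raw_labels: np.ndarray  # values 1 (axon), 2 (background), 3 (soma)
    anchor: SectionAnchor
    markers: MarkerSet
    decoy_px: int


@dataclass
class SyntheticStudy:
    experiment_id: str
    space: ReferenceSpace
    hier: RegionHierarchy
    sections: list[SyntheticSection]
    truth_source: VoxelCloud  # planted soma voxels with drawn pixel counts
    truth_target: VoxelCloud  # planted axon voxels with drawn pixel counts
    seed: int
    px_per_vox: int

    @property
    def total_label_px(self) -> int:
        """All nonzero (non-background) pixels, decoys included."""
        return sum(
            int(np.count_nonzero(s.raw_labels != 2)) for s in self.sections
        )


class _DisplacementField:
    """Smooth analytic 2D displacement field with a fixed peak magnitude,
    vanishing at the image border so pinned corners stay consistent."""

    def __init__(self, width: float, height: float, magnitude: float, rng: np.random.Generator):
        self.mag = magnitude
        k = 2
        self.centers = np.column_stack(
            [
                rng.uniform(0.25 * width, 0.75 * width, k),
                rng.uniform(0.25 * height, 0.75 * height, k),
            ]
        )
        ang = rng.uniform(0, 2 * np.pi, k)
        self.dirs = np.column_stack([np.cos(ang), np.sin(ang)])
        self.sigma = 0.22 * min(width, height)
        # calibrate so the realized peak magnitude equals `magnitude`
        gw = np.linspace(0, width, 41)
        gh = np.linspace(0, height, 41)
        grid = np.array([[a, b] for a in gw for b in gh])
        self.scale = 1.0
        peak = np.linalg.norm(self._raw(grid), axis=1).max()
        self.scale = self.mag / max(peak, 1e-12)

    def _raw(self, p: np.ndarray) -> np.ndarray:
        disp = np.zeros_like(p, dtype=float)
        for c, d in zip(self.centers, self.dirs):
            w = np.exp(-np.sum((p - c) ** 2, axis=1) / (2 * self.sigma**2))
            disp += w[:, None] * d
        return disp

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return self._raw(np.atleast_2d(p)) * self.scale

    def forward(self, q: np.ndarray) -> np.ndarray:
        """Section pixel → template pixel."""
        q = np.atleast_2d(q)
        return q + self(q)

    def invert(self, p: np.ndarray, iters: int = 10) -> np.ndarray:
        """Fixed-point inverse of forward (template pixel → section pixel)."""
        p = np.atleast_2d(p)
        q = p.copy()
        for _ in range(iters):
            q = p - self(q)
        return q


def _fit_positions(mask2d: np.ndarray, dy: int, dz: int) -> list[tuple[int, int]]:
    """Top-left (y, z) positions where a dy×dz rectangle fits inside the mask."""
    from scipy.ndimage import minimum_filter

    ok = minimum_filter(mask2d.astype(np.uint8), size=(dy, dz), mode="constant") > 0
    ys, zs = np.nonzero(ok)
    # minimum_filter is centered: convert to top-left corner positions
    out = []
    for y, z in zip(ys, zs):
        y0, z0 = y - (dy - 1) // 2, z - (dz - 1) // 2
        if y0 >= 0 and z0 >= 0 and mask2d[y0 : y0 + dy, z0 : z0 + dz].all():
            out.append((int(y0), int(z0)))
    return sorted(set(out))


def make_experiment(
    space: ReferenceSpace,
    hier: RegionHierarchy,
    n_sections: int = 10,
    soma_blob_spec: BlobSpec | None = None,
    axon_blob_specs: Sequence[BlobSpec] | None = None,
    warp_magnitude_px: float = 0.0,
    seed: int = 0,
    experiment_id: str = "exp1",
    px_per_vox: int = 4,
    n_decoys: int = 6,
) -> SyntheticStudy:
    """Generate one tracing experiment with planted ground truth.

    Coronal section planes are placed inside the x-extent of the soma
    nucleus; each section receives the planted blobs (one rectangle per blob
    spec per section), decoy objects below the cleaning threshold, a linear
    anchor and — when ``warp_magnitude_px > 0`` — a marker set sampled from
    a smooth displacement field of that peak magnitude.
    """
    rng = np.random.default_rng(seed)
    soma_blob_spec = soma_blob_spec or BlobSpec(region="VPM", size_yz=(3, 4))
    axon_blob_specs = list(
        axon_blob_specs
        if axon_blob_specs is not None
        else [BlobSpec(region=f"{_AREA_NAMES[0]}4", size_yz=(3, 4))]
    )
    nx, ny, nz = space.dims
    W, H = px_per_vox * nz, px_per_vox * ny

    # candidate coronal planes: x-extent of the soma nucleus
    soma_ids = sorted(hier.descendant_ids(soma_blob_spec.region))
    xs_all = np.nonzero(np.isin(space.annotation, soma_ids).any(axis=(1, 2)))[0]
    if len(xs_all) < n_sections:
        raise SyntheticError(
            f"nucleus {soma_blob_spec.region!r} spans only {len(xs_all)} planes, "
            f"need {n_sections}"
        )
    picks = np.sort(rng.choice(xs_all, size=n_sections, replace=False))

    truth_source = VoxelCloud(space_dims=space.dims)
    truth_target = VoxelCloud(space_dims=space.dims)
    sections: list[SyntheticSection] = []
    half = nz / 2

    for i, x0 in enumerate(picks, start=1):
        x0 = int(x0)
        stem = f"{experiment_id}_s{i:03d}"
        anchor = SectionAnchor(
            o=np.array([x0 + 0.5, 0.0, 0.0]),
            u=np.array([0.0, 0.0, float(nz)]),
            v=np.array([0.0, float(ny), 0.0]),
            width_px=W,
            height_px=H,
        )
        dfield = (
            _DisplacementField(W, H, warp_magnitude_px, rng)
            if warp_magnitude_px > 0
            else None
        )
        if dfield is not None:
            gy = np.linspace(0.12 * H, 0.88 * H, 5)
            gz = np.linspace(0.12 * W, 0.88 * W, 7)
            qq = np.array([[z, y] for y in gy for z in gz])
            markers = MarkerSet(template_points=dfield.forward(qq), section_points=qq)
        else:
            markers = MarkerSet.empty()

        raw = np.full((H, W), 2, dtype=np.uint8)
        plane = space.annotation[x0]

        def plant(spec: BlobSpec, label: int, cloud: VoxelCloud) -> None:
            ids = sorted(hier.descendant_ids(spec.region))
            mask = np.isin(plane, ids)
            hemi = (
                (np.arange(nz) < half) if spec.hemisphere == "left" else (np.arange(nz) >= half)
            )
            mask = mask & hemi[None, :]
            dy, dz = spec.size_yz
            positions = _fit_positions(mask, dy, dz)
            if not positions:
                raise SyntheticError(
                    f"blob {spec.region!r} ({dy}x{dz}) does not fit at plane x={x0}"
                )
            y0, z0 = positions[int(rng.integers(len(positions)))]
            for y in range(y0, y0 + dy):
                for z in range(z0, z0 + dz):
                    n_drawn = 0
                    for a in range(px_per_vox):
                        for b in range(px_per_vox):
                            pt = np.array(
                                [z * px_per_vox + a + 0.5, y * px_per_vox + b + 0.5]
                            )
                            q = dfield.invert(pt)[0] if dfield is not None else pt
                            c, r = int(np.floor(q[0])), int(np.floor(q[1]))
                            if 0 <= r < H and 0 <= c < W and raw[r, c] == 2:
                                raw[r, c] = label
                                n_drawn += 1
                    if n_drawn:
                        cloud.add((x0, y, z), n_drawn)

        plant(soma_blob_spec, 3, truth_source)
        for spec in axon_blob_specs:
            plant(spec, 1, truth_target)

        # decoy objects (1–11 px): placed clear of real signal so cleaning
        # removes exactly them
        decoy_px = 0
        occupied = raw != 2
        for d in range(n_decoys):
            size = int(rng.integers(1, 12))
            for _attempt in range(50):
                r = int(rng.integers(2, H - 2))
                c = int(rng.integers(2, W - size - 2))
                window = occupied[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + size + 3]
                if not window.any():
                    raw[r, c : c + size] = 1 if d % 2 == 0 else 3
                    occupied[r, c : c + size] = True
                    decoy_px += size
                    break
        sections.append(
            SyntheticSection(
                stem=stem, raw_labels=raw, anchor=anchor, markers=markers, decoy_px=decoy_px
            )
        )

    return SyntheticStudy(
        experiment_id=experiment_id,
        space=space,
        hier=hier,
        sections=sections,
        truth_source=truth_source,
        truth_target=truth_target,
        seed=seed,
        px_per_vox=px_per_vox,
    )


# ---------------------------------------------------------------------------
# morphologies and bulk catalogue


def make_morphologies(
    space: ReferenceSpace,
    population_source: VoxelCloud,
    population_target: VoxelCloud,
    n_members: int = 5,
    n_nonmembers: int = 5,
    seed: int = 0,
) -> tuple[list[Morphology], list[str], list[tuple[str, tuple[float, float, float]]]]:
    """Generate single-neuron morphologies around a population.

    Member somata fall safely inside the population's 1.5× membership ball
    (≤ 0.9 × radius), non-member somata safely outside (≥ 1.2 × radius).
    Member terminals scatter near the population's axon target voxels,
    non-member terminals elsewhere. Returns (morphologies, member_ids,
    bulk_catalogue) where the catalogue's nearest entry to the medoid is
    the one named ``bulk_near``.
    """
    if not population_source.entries:
        raise SyntheticError("population source cloud is empty")
    rng = np.random.default_rng(seed)
    medoid = np.asarray(population_medoid(population_source), dtype=float)
    radius = membership_radius(population_source, tuple(int(v) for v in medoid))
    radius = max(radius, 2.0)  # single-voxel clouds still get a usable ball
    dims = np.asarray(space.dims, dtype=float)
    tgt_coords, _ = population_target.coords_counts()

    def clip(p: np.ndarray) -> np.ndarray:
        return np.clip(p, 0.0, dims - 1.001)

    morphologies: list[Morphology] = []
    member_ids: list[str] = []
    for i in range(n_members):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        soma = clip(medoid + direction * rng.uniform(0, 0.9 * radius))
        if np.linalg.norm(soma - medoid) > radius:  # clipping can only shrink
            soma = medoid.copy()
        base = tgt_coords[rng.integers(len(tgt_coords))] if len(tgt_coords) else medoid
        terminals = clip(
            np.asarray(base, dtype=float) + 0.5 + rng.uniform(-1.5, 1.5, size=(6, 3))
        )
        nid = f"member{i:02d}"
        morphologies.append(Morphology(neuron_id=nid, soma=soma, axon_terminal_points=terminals))
        member_ids.append(nid)
    for i in range(n_nonmembers):
        for _attempt in range(200):
            soma = rng.uniform(0, 1, size=3) * (dims - 1)
            if np.linalg.norm(soma - medoid) >= 1.2 * radius:
                break
        else:
            raise SyntheticError("could not place a non-member soma outside the ball")
        terminals = clip(soma + rng.uniform(-3, 3, size=(4, 3)))
        morphologies.append(
            Morphology(
                neuron_id=f"nonmember{i:02d}", soma=soma, axon_terminal_points=terminals
            )
        )

    near = medoid + rng.uniform(-1.5, 1.5, size=3)
    catalogue = [("bulk_near", tuple(float(v) for v in near))]
    for j in range(3):
        for _attempt in range(200):
            far = rng.uniform(0, 1, size=3) * (dims - 1)
            if np.linalg.norm(far - medoid) > np.linalg.norm(near - medoid) + 2:
                break
        catalogue.append((f"bulk_far{j}", tuple(float(v) for v in far)))
    return morphologies, member_ids, catalogue


def write_swc(path: str | Path, morph: Morphology) -> None:
    """Write a morphology as SWC: type-1 soma, type-2 axon tree whose leaf
    nodes are exactly the terminal points."""
    lines = ["# synthetic morphology (fixture) — voxel units"]
    x, y, z = morph.soma
    lines.append(f"1 1 {x:.4f} {y:.4f} {z:.4f} 1.0 -1")
    hub_id = 2
    lines.append(f"{hub_id} 2 {x:.4f} {y:.4f} {z:.4f} 0.5 1")
    nid = hub_id
    for tx, ty, tz in morph.axon_terminal_points:
        nid += 1
        lines.append(f"{nid} 2 {tx:.4f} {ty:.4f} {tz:.4f} 0.3 {hub_id}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# on-disk study emission (same formats the pipeline consumes)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict:
    """Write a study to disk: raw segmentation PNGs, section-image PNGs,
    anchoring XML + JSON, atlas volumes (.npy), hierarchy JSON, flatmap
    JSON, and a ground-truth manifest. Returns the manifest."""
    import imageio.v3 as iio

    from .analytics import flatmap_to_json
    from .voxelization import cloud_to_json_obj

    out = Path(out_dir)
    (out / "sections").mkdir(parents=True, exist_ok=True)
    (out / "segmentation").mkdir(exist_ok=True)
    (out / "atlas").mkdir(exist_ok=True)

    anchors = {}
    nonlinear = {}
    for s in study.sections:
        iio.imwrite(out / "segmentation" / f"{s.stem}.png", s.raw_labels)
        visual = (255 - s.raw_labels.astype(np.uint16) * 60).clip(0, 255).astype(np.uint8)
        iio.imwrite(out / "sections" / f"{s.stem}.png", visual)
        anchors[s.stem] = s.anchor
        nonlinear[s.stem] = (s.anchor, s.markers)
    write_linear_anchoring(out / "anchoring.xml", anchors)
    write_nonlinear_anchoring(out / "anchoring.json", nonlinear)

    np.save(out / "atlas" / "annotation.npy", study.space.annotation)
    np.save(out / "atlas" / "template.npy", study.space.template)
    with open(out / "atlas" / "hierarchy.json", "w") as fh:
        json.dump(study.hier.to_records(), fh, indent=1)
    flatmap_to_json(out / "atlas" / "flatmap.json", make_flatmap_lookup(study.space, study.hier))

    manifest = {
        "experiment_id": study.experiment_id,
        "seed": study.seed,
        "px_per_vox": study.px_per_vox,
        "space_dims": list(study.space.dims),
        "n_sections": len(study.sections),
        "decoy_px": {s.stem: s.decoy_px for s in study.sections},
        "total_label_px": study.total_label_px,
        "truth_source": cloud_to_json_obj(study.truth_source),
        "truth_target": cloud_to_json_obj(study.truth_target),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
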