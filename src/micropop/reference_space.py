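"""Common 3D reference space: annotation/template volumes and region hierarchy.

The reference space follows the conventions of the 10 µm Allen Common
Coordinate Framework (CCF): the x-axis runs anterior→posterior, the y-axis
superior→inferior, the z-axis left→right, and the coordinate origin sits at
the anterior-superior-left corner. At full scale the grid measures
1320 × 800 × 1140 voxels. Synthetic (desk-scale) instances use the same axis
semantics on a smaller grid.

Voxel indices are 0-based; a voxel with index ``i`` covers the half-open
interval ``[i, i+1)`` along each axis in voxel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Grid size of the full-scale 10 µm reference volume (AP, SI, LR).
FULL_SCALE_DIMS = (1320, 800, 1140)

#: Recognized cortical layer tags.
LAYER_TAGS = ("1", "2/3", "4", "5", "6a", "6b")


class ReferenceSpaceError(ValueError):
    """Raised on invalid reference-space data (dimension or id mismatches)."""


@dataclass(frozen=True)
class RegionRecord:
    region_id: int
    acronym: str
    parent_id: int | None
    layer_tag: str | None = None


class RegionHierarchy:
    """Tree of brain regions identified by opaque integer ids.

    Parameters
    ----------
    records:
        Iterable of :class:`RegionRecord` (or mappings with keys
        ``id``/``acronym``/``parent_id``/``layer``). Exactly one record must
        be the root (``parent_id is None``); acronyms must be unique and
        parent links acyclic.
    """

    def __init__(self, records: Iterable[RegionRecord | Mapping]) -> None:
        recs = []
        for r in records:
            if isinstance(r, RegionRecord):
                recs.append(r)
            else:
                recs.append(
                    RegionRecord(
                        region_id=int(r["id"]),
                        acronym=str(r["acronym"]),
                        parent_id=None if r.get("parent_id") is None else int(r["parent_id"]),
                        layer_tag=r.get("layer"),
                    )
                )
        self._by_id = {r.region_id: r for r in recs}
        if len(self._by_id) != len(recs):
            raise ReferenceSpaceError("duplicate region ids in hierarchy")
        self._by_acronym = {r.acronym: r for r in recs}
        if len(self._by_acronym) != len(recs):
            seen: set[str] = set()
            dups = {r.acronym for r in recs if r.acronym in seen or seen.add(r.acronym)}
            raise ReferenceSpaceError(f"duplicate acronyms in hierarchy: {sorted(dups)}")
        roots = [r for r in recs if r.parent_id is None]
        if len(roots) != 1:
            raise ReferenceSpaceError(f"hierarchy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        # validate acyclicity / parent existence by walking every chain
        for r in recs:
            self.ancestors(r.region_id)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def ids(self) -> set[int]:
        return set(self._by_id)

    def record(self, region_id: int) -> RegionRecord:
        try:
            return self._by_id[region_id]
        except KeyError:
            raise ReferenceSpaceError(f"unknown region id {region_id}") from None

    def by_acronym(self, acronym: str) -> RegionRecord:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise ReferenceSpaceError(f"unknown acronym {acronym!r}") from None

    def ancestors(self, region_id: int) -> list[int]:
        """Ancestor chain from ``region_id`` (inclusive) up to the root."""
        chain = []
        seen = set()
        cur: int | None = region_id
        while cur is not None:
            if cur in seen:
                raise ReferenceSpaceError(f"cycle in hierarchy at region {cur}")
            if cur not in self._by_id:
                raise ReferenceSpaceError(f"parent id {cur} missing from hierarchy")
            seen.add(cur)
            chain.append(cur)
            cur = self._by_id[cur].parent_id
        return chain

    def is_within(self, region_id: int, ancestor_acronym: str) -> bool:
        """True iff the ancestor chain of ``region_id`` (self included)
        contains the region named ``ancestor_acronym``."""
        anc = self.by_acronym(ancestor_acronym).region_id
        return anc in self.ancestors(region_id)

    def descendant_ids(self, acronym: str) -> set[int]:
        """All ids whose ancestor chain passes through ``acronym`` (self included)."""
        top = self.by_acronym(acronym).region_id
        return {i for i in self._by_id if top in self.ancestors(i)}

    def layer_tag(self, region_id: int) -> str | None:
        """Layer tag of a region: the explicit tag if set, otherwise parsed
        from an ARA-style acronym suffix (e.g. ``SSp-bfd2/3`` → ``2/3``)."""
        rec = self.record(region_id)
        if rec.layer_tag is not None:
            return rec.layer_tag
        return parse_layer_suffix(rec.acronym)

    def to_records(self) -> list[dict]:
        return [
            {"id": r.region_id, "acronym": r.acronym, "parent_id": r.parent_id, "layer": r.layer_tag}
            for r in sorted(self._by_id.values(), key=lambda r: r.region_id)
        ]


def parse_layer_suffix(acronym: str) -> str | None:
    """Parse a cortical layer tag from an ARA-style acronym suffix.

    A fallback only: names whose stem itself ends in a digit (e.g. the
    hippocampal ``CA1``) are indistinguishable from layer suffixes, so
    hierarchies should carry explicit layer tags wherever possible.
    """
    for tag in ("2/3", "6a", "6b", "1", "4", "5"):
        if acronym.endswith(tag):
            stem = acronym[: -len(tag)]
            if stem and (stem[-1].isalpha() or stem[-1] in "-_ "):
                return tag
    return None


@dataclass
class ReferenceSpace:
    """Annotation + template volume pair on a shared voxel grid.

    ``annotation`` holds one integer region id per voxel (0 = outside brain);
    ``template`` holds gray-matter intensity on the same grid.
    """

    annotation: np.ndarray
    template: np.ndarray
    hierarchy: RegionHierarchy
    resolution_um: float = 10.0

    def __post_init__(self) -> None:
        self.annotation = np.asarray(self.annotation)
        self.template = np.asarray(self.template)
        if self.annotation.ndim != 3 or self.template.ndim != 3:
            raise ReferenceSpaceError("annotation and template must be 3D volumes")
        if self.annotation.shape != self.template.shape:
            raise ReferenceSpaceError(
                "annotation and template dims differ: "
                f"{self.annotation.shape} vs {self.template.shape}"
            )
        present = set(np.unique(self.annotation).tolist()) - {0}
        missing = present - self.hierarchy.ids
        if missing:
            raise ReferenceSpaceError(
                f"annotation ids absent from hierarchy: {sorted(missing)}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.annotation.shape  # type: ignore[return-value]

    def _check_bounds(self, voxel: Sequence[int]) -> tuple[int, int, int]:
        x, y, z = (int(v) for v in voxel)
        nx, ny, nz = self.dims
        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            raise IndexError(f"voxel {(x, y, z)} outside dims {self.dims}")
        return x, y, z

    def region_at(self, voxel: Sequence[int]) -> int:
        """Region id at a voxel; 0 means outside the brain."""
        x, y, z = self._check_bounds(voxel)
        return int(self.annotation[x, y, z])

    def mirror_to_left(self, voxel: Sequence[int]) -> tuple[int, int, int]:
        """Reflect a voxel about the grid's mid left-right plane:
        ``(x, y, z) → (x, y, nz−1−z)``. An involution."""
        x, y, z = self._check_bounds(voxel)
        return (x, y, self.dims[2] - 1 - z)

    def is_left(self, voxel: Sequence[int]) -> bool:
        """Left-hemisphere test: the origin is the Left corner, so low z is left."""
        _, _, z = self._check_bounds(voxel)
        return z < self.dims[2] / 2

    def with_parcellation(
        self, annotation: np.ndarray, hierarchy: RegionHierarchy
    ) -> "ReferenceSpace":
        """Swap in an alternative parcellation (e.g. EUAL-style for
        ARA-style) on the identical grid and template."""
        return ReferenceSpace(
            annotation=annotation,
            template=self.template,
            hierarchy=hierarchy,
            resolution_um=self.resolution_um,
        )


def _load_volume(path: str | Path) -> np.ndarray:
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".npy"):
        return np.load(path)
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).dataobj)
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # SimpleITK returns (z, y, x); restore file-order (x, y, z) indexing
        return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    raise ReferenceSpaceError(f"unsupported volume format: {path}")


def load_hierarchy(path: str | Path) -> RegionHierarchy:
    """Load a hierarchy from JSON: either the flat record dialect
    (``[{id, acronym, parent_id, layer}, …]``) or an Allen structure-graph
    document, which is converted on the fly."""
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict) and "msg" in doc:
        return hierarchy_from_allen_structure_graph(doc)
    return RegionHierarchy(doc)


def hierarchy_from_allen_structure_graph(doc: Mapping) -> RegionHierarchy:
    """Convert the Allen structure-graph JSON dialect (possibly nested via
    ``children``) into a flat :class:`RegionHierarchy`."""
    records: list[dict] = []

    def walk(node: Mapping, parent_id: int | None) -> None:
        records.append(
            {
                "id": node["id"],
                "acronym": node["acronym"],
                "parent_id": node.get("parent_structure_id", parent_id),
                "layer": None,
            }
        )
        for child in node.get("children", []):
            walk(child, node["id"])

    for top in doc["msg"]:
        walk(top, None)
    return RegionHierarchy(records)


def load_reference_space(
    annotation_path: str | Path,
    template_path: str | Path,
    hierarchy_path: str | Path,
    resolution_um: float = 10.0,
) -> ReferenceSpace:
    """Load annotation/template volumes (NRRD, NIfTI or .npy) plus a region
    hierarchy and validate their mutual consistency."""
    annotation = _load_volume(annotation_path)
    template = _load_volume(template_path)
    hierarchy = load_hierarchy(hierarchy_path)
    return ReferenceSpace(
        annotation=annotation,
        template=template,
        hierarchy=hierarchy,
        resolution_um=resolution_um,
    )
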