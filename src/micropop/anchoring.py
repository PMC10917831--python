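"""Section anchoring: linear anchor vectors and nonlinear marker warps.

A section image is placed in the reference volume by an anchor triple
``(o, u, v)`` of 3-vectors in voxel units: ``o`` is the position of the
image's top-left pixel, ``u`` spans the full image width and ``v`` the full
image height. A pixel ``p = (px, py)`` (x rightward, y downward, measured
from the top-left corner) maps to

    o + (px / width) · u + (py / height) · v .

Nonlinear refinement is given as marker pairs between the section image and
its anchored template plane, both expressed in the section's pixel frame.
The deformation is evaluated here in the section→template direction, so a
segmented section image can be pushed directly into the reference volume
("reverse registration"): the field is a continuous piecewise-affine
interpolant over a Delaunay triangulation of the section-side marker points
augmented with the four image corners, which are pinned to themselves.

Two file dialects are supported: a QuickNII-style XML file holding the nine
anchoring scalars per slice, and a VisuAlign-style JSON file holding the
same anchoring plus the marker pairs.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "AnchoringError",
    "SectionAnchor",
    "MarkerSet",
    "WarpField",
    "read_linear_anchoring",
    "write_linear_anchoring",
    "read_nonlinear_anchoring",
    "write_nonlinear_anchoring",
    "linear_pixel_to_ccf",
    "build_warp",
    "section_pixel_to_reference",
]

_SCALARS = ("ox", "oy", "oz", "ux", "uy", "uz", "vx", "vy", "vz")


class AnchoringError(ValueError):
    pass


@dataclass
class SectionAnchor:
    """Linear placement of one section image in the reference volume."""

    o: np.ndarray
    u: np.ndarray
    v: np.ndarray
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name, vec in (("o", self.o), ("u", self.u), ("v", self.v)):
            if vec.shape != (3,):
                raise AnchoringError(f"anchor vector {name} must be a 3-vector, got {vec.shape}")
        if np.allclose(np.cross(self.u, self.v), 0.0):
            raise AnchoringError("anchor vectors u and v are parallel")
        if self.width_px <= 0 or self.height_px <= 0:
            raise AnchoringError(
                f"anchor image dims must be positive, got {self.width_px}x{self.height_px}"
            )

    def corners(self) -> np.ndarray:
        """Reference-space positions of the image corners (o, o+u, o+v, o+u+v)."""
        return np.stack([self.o, self.o + self.u, self.o + self.v, self.o + self.u + self.v])

    def scalars(self) -> dict[str, float]:
        return dict(zip(_SCALARS, [*self.o, *self.u, *self.v]))


@dataclass
class MarkerSet:
    """Corresponding points between a section and its template plane,
    both in the section's pixel frame."""

    template_points: np.ndarray  # (n, 2)
    section_points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.template_points = np.atleast_2d(np.asarray(self.template_points, dtype=float))
        self.section_points = np.atleast_2d(np.asarray(self.section_points, dtype=float))
        if self.template_points.size == 0:
            self.template_points = np.empty((0, 2))
            self.section_points = np.empty((0, 2))
        if self.template_points.shape != self.section_points.shape or (
            self.template_points.size and self.template_points.shape[1] != 2
        ):
            raise AnchoringError("marker arrays must both be (n, 2)")
        if len(self) > 1:
            uniq = {tuple(p) for p in self.template_points.tolist()}
            if len(uniq) != len(self):
                raise AnchoringError("duplicated template points in marker set")

    def __len__(self) -> int:
        return self.template_points.shape[0]

    @classmethod
    def empty(cls) -> "MarkerSet":
        return cls(np.empty((0, 2)), np.empty((0, 2)))


class WarpField:
    """Continuous piecewise-affine map section pixel → template pixel.

    Exact at every marker; identity when built from zero markers; the four
    image corners are pinned to themselves so the field covers the whole
    image rectangle.
    """

    def __init__(self, markers: MarkerSet, image_dims: tuple[int, int]) -> None:
        w, h = image_dims
        if w <= 0 or h <= 0:
            raise AnchoringError(f"image dims must be positive, got {image_dims}")
        self.image_dims = (float(w), float(h))
        self.markers = markers
        if len(markers) == 0:
            self._tri = None
            return
        sec = markers.section_points
        tpl = markers.template_points
        # contradictory constraints: same section point, different targets
        order = np.lexsort(sec.T)
        ss, tt = sec[order], tpl[order]
        same = np.all(np.isclose(ss[1:], ss[:-1]), axis=1)
        for i in np.nonzero(same)[0]:
            if not np.allclose(tt[i + 1], tt[i]):
                raise AnchoringError(
                    f"contradictory markers at section point {tuple(ss[i])}"
                )
        corners = np.array([[0.0, 0.0], [w, 0.0], [0.0, h], [w, h]])
        keep = [
            c for c in corners if not np.any(np.all(np.isclose(sec, c), axis=1))
        ]
        if keep:
            pts = np.vstack([sec, np.asarray(keep)])
            vals = np.vstack([tpl, np.asarray(keep)])
        else:
            pts, vals = sec.copy(), tpl.copy()
        self._points = pts
        self._values = vals
        self._tri = Delaunay(pts)

    @property
    def is_identity(self) -> bool:
        return self._tri is None

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Evaluate section→template at ``points`` (shape (n, 2) or (2,))."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self._tri is None:
            out = p.copy()
        else:
            simplex = self._tri.find_simplex(p)
            out = np.empty_like(p)
            # outside the triangulated rectangle: leave unwarped
            outside = simplex < 0
            out[outside] = p[outside]
            inside = ~outside
            if np.any(inside):
                s = simplex[inside]
                trans = self._tri.transform[s]
                bary2 = np.einsum(
                    "nij,nj->ni", trans[:, :2, :], p[inside] - trans[:, 2, :]
                )
                bary = np.concatenate(
                    [bary2, 1.0 - bary2.sum(axis=1, keepdims=True)], axis=1
                )
                verts = self._tri.simplices[s]
                out[inside] = np.einsum("ni,nij->nj", bary, self._values[verts])
        if np.asarray(points).ndim == 1:
            return out[0]
        return out


def build_warp(markers: MarkerSet | None, image_dims: tuple[int, int]) -> WarpField:
    """Build the piecewise-affine section→template deformation field."""
    return WarpField(markers if markers is not None else MarkerSet.empty(), image_dims)


def linear_pixel_to_ccf(
    anchor: SectionAnchor,
    p: np.ndarray,
    image_dims: tuple[int, int] | None = None,
) -> np.ndarray:
    """Affine pixel→reference map ``o + (px/width)·u + (py/height)·v``.

    ``p`` may be one point ``(2,)`` or a batch ``(n, 2)``.
    """
    w, h = image_dims if image_dims is not None else (anchor.width_px, anchor.height_px)
    if w <= 0 or h <= 0:
        raise AnchoringError(f"zero-sized image: {w}x{h}")
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    out = (
        anchor.o[None, :]
        + (pts[:, 0:1] / w) * anchor.u[None, :]
        + (pts[:, 1:2] / h) * anchor.v[None, :]
    )
    if np.asarray(p).ndim == 1:
        return out[0]
    return out


def section_pixel_to_reference(
    anchor: SectionAnchor,
    warp: WarpField | None,
    p: np.ndarray,
    image_dims: tuple[int, int] | None = None,
) -> tuple[np.ndarray, int]:
    """Full section-pixel→reference map: nonlinear warp then linear anchor.

    Warped points that leave the image rectangle are clamped to it; the
    second return value counts the clamped points.
    """
    w, h = image_dims if image_dims is not None else (anchor.width_px, anchor.height_px)
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    warped = warp.forward(pts) if warp is not None else pts.astype(float)
    clamped = np.clip(warped, [0.0, 0.0], [float(w), float(h)])
    n_clamped = int(np.any(clamped != warped, axis=1).sum())
    ref = linear_pixel_to_ccf(anchor, clamped, (w, h))
    if np.asarray(p).ndim == 1:
        return ref[0], n_clamped
    return ref, n_clamped


# ---------------------------------------------------------------------------
# file dialects

#: Field names used by the XML/JSON dialects; edit to absorb version drift.
DIALECT = {
    "xml_root": "series",
    "xml_slice": "slice",
    "filename": "filename",
    "width": "width",
    "height": "height",
    "json_slices": "slices",
    "json_anchoring": "anchoring",
    "json_markers": "markers",
}


def _stem_of(filename: str) -> str:
    return Path(filename).stem


def read_linear_anchoring(path: str | Path) -> dict[str, SectionAnchor]:
    """Read a QuickNII-dialect XML anchoring file into stem→anchor."""
    tree = ET.parse(str(path))
    out: dict[str, SectionAnchor] = {}
    for el in tree.getroot().iter(DIALECT["xml_slice"]):
        fname = el.get(DIALECT["filename"])
        if fname is None:
            raise AnchoringError(f"slice element without {DIALECT['filename']!r} in {path}")
        try:
            vals = [float(el.attrib[s]) for s in _SCALARS]
            w = int(el.attrib[DIALECT["width"]])
            h = int(el.attrib[DIALECT["height"]])
        except KeyError as exc:
            raise AnchoringError(f"slice {fname!r}: missing scalar {exc.args[0]!r}") from None
        except ValueError as exc:
            raise AnchoringError(f"slice {fname!r}: unparseable number ({exc})") from None
        stem = _stem_of(fname)
        if stem in out:
            raise AnchoringError(f"duplicate slice stem {stem!r} in {path}")
        out[stem] = SectionAnchor(o=vals[0:3], u=vals[3:6], v=vals[6:9], width_px=w, height_px=h)
    if not out:
        raise AnchoringError(f"no slice elements found in {path}")
    return out


def write_linear_anchoring(path: str | Path, anchors: Mapping[str, SectionAnchor]) -> None:
    root = ET.Element(DIALECT["xml_root"])
    for stem in sorted(anchors):
        a = anchors[stem]
        attrs = {
            DIALECT["filename"]: f"{stem}.png",
            DIALECT["width"]: str(a.width_px),
            DIALECT["height"]: str(a.height_px),
        }
        attrs.update({k: repr(float(v)) for k, v in a.scalars().items()})
        ET.SubElement(root, DIALECT["xml_slice"], attrs)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=False)


def read_nonlinear_anchoring(path: str | Path) -> dict[str, tuple[SectionAnchor, MarkerSet]]:
    """Read a VisuAlign-dialect JSON file into stem→(anchor, markers).

    Marker entries are ``[section_x, section_y, template_x, template_y]`` in
    the section's pixel frame.
    """
    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, tuple[SectionAnchor, MarkerSet]] = {}
    for sl in doc[DIALECT["json_slices"]]:
        fname = sl.get(DIALECT["filename"])
        if fname is None:
            raise AnchoringError(f"slice without filename in {path}")
        anch = sl.get(DIALECT["json_anchoring"])
        if anch is None or len(anch) != 9:
            raise AnchoringError(f"slice {fname!r}: anchoring must hold 9 scalars")
        try:
            vals = [float(x) for x in anch]
            w = int(sl[DIALECT["width"]])
            h = int(sl[DIALECT["height"]])
        except (KeyError, ValueError) as exc:
            raise AnchoringError(f"slice {fname!r}: bad anchoring ({exc})") from None
        markers_raw = sl.get(DIALECT["json_markers"], [])
        if markers_raw:
            arr = np.asarray(markers_raw, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 4:
                raise AnchoringError(f"slice {fname!r}: markers must be n x 4")
            markers = MarkerSet(template_points=arr[:, 2:4], section_points=arr[:, 0:2])
        else:
            markers = MarkerSet.empty()
        stem = _stem_of(fname)
        if stem in out:
            raise AnchoringError(f"duplicate slice stem {stem!r} in {path}")
        out[stem] = (
            SectionAnchor(o=vals[0:3], u=vals[3:6], v=vals[6:9], width_px=w, height_px=h),
            markers,
        )
    if not out:
        raise AnchoringError(f"no slices found in {path}")
    return out


def write_nonlinear_anchoring(
    path: str | Path, data: Mapping[str, tuple[SectionAnchor, MarkerSet]]
) -> None:
    slices = []
    for stem in sorted(data):
        a, m = data[stem]
        slices.append(
            {
                DIALECT["filename"]: f"{stem}.png",
                DIALECT["width"]: a.width_px,
                DIALECT["height"]: a.height_px,
                DIALECT["json_anchoring"]: [*a.o, *a.u, *a.v],
                DIALECT["json_markers"]: np.hstack(
                    [m.section_points, m.template_points]
                ).tolist(),
            }
        )
    with open(path, "w") as fh:
        json.dump({DIALECT["json_slices"]: slices}, fh, indent=1)
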