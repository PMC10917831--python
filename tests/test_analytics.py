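import warnings
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from micropop.analytics import (
    AnalyticsError,
    FlatIntensity,
    FlatmapLookup,
    atlas_overlay_svg,
    cortical_coverage,
    flatmap_from_json,
    flatmap_project,
    flatmap_to_json,
    layer_distribution,
    max_projection,
)
from micropop.reference_space import LAYER_TAGS, RegionHierarchy
from micropop.segmentation import AXON, SegmentedSection
from micropop.voxelization import PopulationRecord, VoxelCloud

DIMS = (132, 80, 114)


def simple_lookup(n=1000):
    """n voxels mapped 1:1 onto n flat pixels on one row block."""
    entries = {}
    w = 50
    for i in range(n):
        entries[(i % 100, 0, i // 100)] = (i // w, i % w)
    return FlatmapLookup(flat_dims=((n + w - 1) // w, w), entries=entries)


class TestFlatmapProject:
    def test_empty_cloud_zero_map(self):
        lk = simple_lookup()
        flat = flatmap_project(VoxelCloud(DIMS), lk)
        assert flat.total == 0

    def test_single_voxel_lands_on_its_pixel(self):
        lk = FlatmapLookup(flat_dims=(10, 10), entries={(1, 2, 3): (3, 4)})
        flat = flatmap_project(VoxelCloud(DIMS, {(1, 2, 3): 7}), lk)
        assert flat.intensity[3, 4] == 7
        assert flat.total == 7

    def test_conserves_mapped_counts(self, space, flatmap):
        rng = np.random.default_rng(2)
        cloud = VoxelCloud(space.dims)
        mapped = 0
        for _ in range(200):
            c = tuple(int(rng.integers(0, d)) for d in space.dims)
            k = int(rng.integers(1, 6))
            cloud.add(c, k)
        flat = flatmap_project(cloud, flatmap)
        assert flat.total + flat.skipped_count == cloud.total

    def test_out_of_dims_pixel_rejected(self):
        with pytest.raises(AnalyticsError, match="outside"):
            FlatmapLookup(flat_dims=(2, 2), entries={(0, 0, 0): (5, 5)})


class TestLayerDistribution:
    def layer_voxel(self, space, hier, area, tag):
        leaf = next(
            r for r in hier.to_records()
            if r["layer"] == tag and hier.is_within(r["id"], area)
        )
        vox = np.argwhere(space.annotation == leaf["id"])[0]
        return tuple(int(v) for v in vox)

    def test_single_layer_gets_100_percent(self, space, hier):
        v4 = self.layer_voxel(space, hier, "SSp-bfd", "4")
        rec = PopulationRecord(
            "e", VoxelCloud(space.dims), VoxelCloud(space.dims, {v4: 13})
        )
        out = layer_distribution(rec, space, hier, "SSp-bfd")
        assert out["4"] == 100.0
        assert all(out[t] == 0.0 for t in LAYER_TAGS if t != "4")

    def test_uniform_across_six_layers(self, space, hier):
        tgt = VoxelCloud(space.dims)
        for tag in LAYER_TAGS:
            tgt.add(self.layer_voxel(space, hier, "SSp-n", tag), 5)
        rec = PopulationRecord("e", VoxelCloud(space.dims), tgt)
        out = layer_distribution(rec, space, hier, "SSp-n")
        for tag in LAYER_TAGS:
            assert out[tag] == pytest.approx(100 / 6)

    def test_planted_profile_recovered_exactly(self, space, hier):
        plant = {"2/3": 40, "4": 30, "5": 20, "6a": 10}
        tgt = VoxelCloud(space.dims)
        for tag, count in plant.items():
            tgt.add(self.layer_voxel(space, hier, "SSp-bfd", tag), count)
        rec = PopulationRecord("e", VoxelCloud(space.dims), tgt)
        out = layer_distribution(rec, space, hier, "SSp-bfd")
        assert out == {
            "1": 0.0, "2/3": 40.0, "4": 30.0, "5": 20.0, "6a": 10.0, "6b": 0.0
        }

    def test_counts_outside_area_ignored(self, space, hier):
        v_other = self.layer_voxel(space, hier, "SSs", "4")
        v_in = self.layer_voxel(space, hier, "SSp-bfd", "5")
        rec = PopulationRecord(
            "e", VoxelCloud(space.dims),
            VoxelCloud(space.dims, {v_other: 99, v_in: 1}),
        )
        out = layer_distribution(rec, space, hier, "SSp-bfd")
        assert out["5"] == 100.0

    def test_zero_signal_warns_not_raises(self, space, hier):
        rec = PopulationRecord("e", VoxelCloud(space.dims), VoxelCloud(space.dims))
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = layer_distribution(rec, space, hier, "SSp-bfd")
        assert any("no axonal signal" in str(x.message) for x in w)
        assert all(v == 0.0 for v in out.values())

    def test_percentages_sum_to_100(self, space, hier):
        rng = np.random.default_rng(3)
        tgt = VoxelCloud(space.dims)
        for tag in LAYER_TAGS:
            tgt.add(self.layer_voxel(space, hier, "SSp-m", tag), int(rng.integers(1, 50)))
        rec = PopulationRecord("e", VoxelCloud(space.dims), tgt)
        out = layer_distribution(rec, space, hier, "SSp-m")
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)


class TestCoverage:
    def test_zero_map(self):
        lk = simple_lookup(1000)
        assert cortical_coverage(FlatIntensity(np.zeros(lk.flat_dims)), lk) == 0.0

    def test_full_map(self):
        lk = simple_lookup(1000)
        assert cortical_coverage(FlatIntensity(np.ones(lk.flat_dims)), lk) == 1.0

    def test_37_of_1000(self):
        lk = simple_lookup(1000)
        inten = np.zeros(lk.flat_dims)
        hit = 0
        for (r, c) in sorted(set(lk.entries.values())):
            if hit == 37:
                break
            inten[r, c] = 1 + hit
            hit += 1
        assert cortical_coverage(FlatIntensity(inten), lk) == 0.037

    def test_monotone_under_added_voxels(self):
        lk = simple_lookup(200)
        inten = np.zeros(lk.flat_dims)
        prev = 0.0
        for (r, c) in list(lk.entries.values())[:50]:
            inten[r, c] += 1
            cov = cortical_coverage(FlatIntensity(inten), lk)
            assert cov >= prev
            prev = cov

    def test_empty_mask_rejected(self):
        lk = FlatmapLookup(flat_dims=(5, 5), entries={})
        with pytest.raises(AnalyticsError, match="mask"):
            cortical_coverage(FlatIntensity(np.zeros((5, 5))), lk)


class TestMaxProjection:
    def test_uniform_template_flat_background(self, hier):
        from micropop.reference_space import ReferenceSpace

        ann = np.zeros((30, 30, 30), dtype=int)
        sp_uniform = ReferenceSpace(
            annotation=ann, template=np.full((30, 30, 30), 7.0),
            hierarchy=RegionHierarchy([{"id": 1, "acronym": "root", "parent_id": None, "layer": None}]),
        )
        rec = PopulationRecord("e", VoxelCloud((30, 30, 30)), VoxelCloud((30, 30, 30)))
        mp = max_projection(rec, sp_uniform, sp_uniform.hierarchy, "coronal", "root")
        assert (mp.background == 7.0).all()

    def test_single_soma_voxel_single_overlay_pixel(self, space, hier):
        rec = PopulationRecord(
            "e", VoxelCloud(space.dims, {(60, 40, 20): 9}), VoxelCloud(space.dims)
        )
        mp = max_projection(rec, space, hier, "coronal", "TH")
        assert mp.soma_overlay[40, 20] == 9
        assert np.count_nonzero(mp.soma_overlay) == 1

    def test_contours_match_neighbor_comparison_oracle(self, space, hier):
        rec = PopulationRecord("e", VoxelCloud(space.dims), VoxelCloud(space.dims))
        mp = max_projection(rec, space, hier, "coronal", "TH")
        # independent oracle: recompute projected labels, then mark a pixel
        # iff some 4-neighbor carries a different label
        sub = np.where(
            np.isin(space.annotation, sorted(hier.descendant_ids("TH"))),
            space.annotation, 0,
        )
        nonzero = sub != 0
        first = np.argmax(nonzero, axis=0)
        proj = np.take_along_axis(sub, first[None, ...], axis=0)[0]
        proj[~nonzero.any(axis=0)] = 0
        h, w = proj.shape
        oracle = np.zeros((h, w), dtype=bool)
        for r in range(h):
            for c in range(w):
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and proj[rr, cc] != proj[r, c]:
                        oracle[r, c] = True
        np.testing.assert_array_equal(mp.contours, oracle)

    def test_invalid_axis_rejected(self, space, hier):
        rec = PopulationRecord("e", VoxelCloud(space.dims), VoxelCloud(space.dims))
        with pytest.raises(AnalyticsError, match="axis"):
            max_projection(rec, space, hier, "oblique", "TH")


class TestSvgOverlay:
    def coronal_anchor(self, space, x0=60, ppv=2):
        from micropop.anchoring import SectionAnchor

        _, ny, nz = space.dims
        return SectionAnchor(
            o=np.array([x0 + 0.5, 0.0, 0.0]),
            u=np.array([0.0, 0.0, float(nz)]),
            v=np.array([0.0, float(ny), 0.0]),
            width_px=ppv * nz,
            height_px=ppv * ny,
        )

    def test_empty_segmentation_pure_atlas_svg(self, space, hier):
        anchor = self.coronal_anchor(space)
        seg = SegmentedSection(
            labels=np.zeros((anchor.height_px, anchor.width_px), dtype=np.uint8), stem="s"
        )
        svg = atlas_overlay_svg(seg, anchor, None, space, hier, stride=2)
        root = ET.fromstring(svg)
        ns = "{http://www.w3.org/2000/svg}"
        regions = root.find(f"{ns}g[@id='regions']")
        assert len(list(regions)) > 3  # several region groups drawn
        marks = root.find(f"{ns}g[@id='segments']")
        assert len(list(marks)) == 0

    def test_segment_pixel_marked_in_black(self, space, hier):
        anchor = self.coronal_anchor(space)
        labels = np.zeros((anchor.height_px, anchor.width_px), dtype=np.uint8)
        labels[20, 30] = AXON
        seg = SegmentedSection(labels=labels, stem="s")
        svg = atlas_overlay_svg(seg, anchor, None, space, hier, stride=2)
        root = ET.fromstring(svg)
        ns = "{http://www.w3.org/2000/svg}"
        marks = root.find(f"{ns}g[@id='segments']")
        rects = list(marks)
        assert len(rects) == 1
        assert rects[0].get("x") == "30" and rects[0].get("y") == "20"

    def test_parcellation_swap_same_geometry_different_regions(self, space, hier):
        anchor = self.coronal_anchor(space)
        seg = SegmentedSection(
            labels=np.zeros((anchor.height_px, anchor.width_px), dtype=np.uint8), stem="s"
        )
        alt_ann = np.where(space.annotation > 0, 5, 0)
        alt_hier = RegionHierarchy(
            [
                {"id": 1, "acronym": "root", "parent_id": None, "layer": None},
                {"id": 5, "acronym": "brain", "parent_id": 1, "layer": None},
            ]
        )
        alt_space = space.with_parcellation(alt_ann, alt_hier)
        svg_a = atlas_overlay_svg(seg, anchor, None, space, hier, stride=2)
        svg_b = atlas_overlay_svg(seg, anchor, None, alt_space, alt_hier, stride=2)
        ra, rb = ET.fromstring(svg_a), ET.fromstring(svg_b)
        assert ra.get("viewBox") == rb.get("viewBox")
        ns = "{http://www.w3.org/2000/svg}"
        ids_a = {g.get("id") for g in ra.find(f"{ns}g[@id='regions']")}
        ids_b = {g.get("id") for g in rb.find(f"{ns}g[@id='regions']")}
        assert ids_a != ids_b


def test_flatmap_json_roundtrip(tmp_path, flatmap):
    path = tmp_path / "fm.json"
    flatmap_to_json(path, flatmap)
    back = flatmap_from_json(path)
    assert back.flat_dims == flatmap.flat_dims
    assert back.entries == flatmap.entries
    np.testing.assert_array_equal(back.area_labels, flatmap.area_labels)
    np.testing.assert_array_equal(back.cortex_mask, flatmap.cortex_mask)
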