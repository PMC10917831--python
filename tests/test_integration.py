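import numpy as np
import pytest

from micropop.analytics import FlatIntensity
from micropop.integration import (
    IntegrationError,
    MembershipParams,
    Morphology,
    OverlapState,
    classify_members,
    membership_radius,
    nearest_bulk_experiment,
    overlap_fractions,
    overlap_states,
    population_medoid,
    read_bulk_catalogue,
    read_swc,
)
from micropop.voxelization import PopulationRecord, VoxelCloud

DIMS = (132, 80, 114)


def cloud(coords, counts=None):
    counts = counts or [1] * len(coords)
    return VoxelCloud(DIMS, dict(zip([tuple(c) for c in coords], counts)))


def medoid_oracle(coords, counts):
    """Exhaustive weighted argmin of summed distances."""
    best, best_cost = None, np.inf
    for cand in coords:
        cost = sum(
            w * np.linalg.norm(np.asarray(cand) - np.asarray(c))
            for c, w in zip(coords, counts)
        )
        if cost < best_cost - 1e-12:
            best, best_cost = tuple(cand), cost
    return best


class TestMedoid:
    def test_single_voxel_is_its_own_medoid(self):
        assert population_medoid(cloud([(3, 4, 5)])) == (3, 4, 5)

    def test_three_collinear_points(self):
        assert population_medoid(cloud([(0, 0, 0), (2, 0, 0), (10, 0, 0)])) == (2, 0, 0)

    def test_matches_exhaustive_oracle_on_random_clouds(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            n = int(rng.integers(20, 200))
            coords = [tuple(int(rng.integers(0, d)) for d in DIMS) for _ in range(n)]
            coords = list(dict.fromkeys(coords))
            counts = [int(rng.integers(1, 10)) for _ in coords]
            got = population_medoid(cloud(coords, counts))
            want = medoid_oracle(sorted(coords), [c for _, c in sorted(zip(coords, counts))])
            # compare costs, not coordinates: distinct voxels can tie
            d_got = sum(
                w * np.linalg.norm(np.asarray(got) - np.asarray(c))
                for c, w in zip(coords, counts)
            )
            d_want = sum(
                w * np.linalg.norm(np.asarray(want) - np.asarray(c))
                for c, w in zip(coords, counts)
            )
            assert d_got == pytest.approx(d_want, abs=1e-9)

    def test_medoid_is_occupied_voxel(self):
        rng = np.random.default_rng(22)
        coords = [tuple(int(rng.integers(0, d)) for d in DIMS) for _ in range(50)]
        c = cloud(list(dict.fromkeys(coords)))
        assert population_medoid(c) in c.support

    def test_empty_cloud_rejected(self):
        with pytest.raises(IntegrationError, match="empty"):
            population_medoid(VoxelCloud(DIMS))


class TestMembershipRadius:
    def test_single_voxel_radius_zero(self):
        c = cloud([(3, 3, 3)])
        assert membership_radius(c, (3, 3, 3)) == 0.0

    def test_max_distance_8_gives_radius_12(self):
        c = cloud([(0, 0, 0), (8, 0, 0)])
        assert membership_radius(c, (0, 0, 0)) == pytest.approx(12.0)

    def test_ratio_is_15_on_random_clouds(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            coords = [tuple(int(rng.integers(0, 60)) for _ in range(3)) for _ in range(30)]
            c = cloud(list(dict.fromkeys(coords)))
            m = population_medoid(c)
            r = membership_radius(c, m)
            maxd = max(np.linalg.norm(np.asarray(p) - np.asarray(m)) for p in c.support)
            if maxd > 0:
                assert r / maxd == pytest.approx(1.5)

    def test_factor_must_be_positive(self):
        with pytest.raises(IntegrationError):
            MembershipParams(radius_factor=0)


class TestClassifyMembers:
    def morph(self, nid, soma, terminals=((50.0, 10.0, 10.0),)):
        return Morphology(neuron_id=nid, soma=np.asarray(soma, float),
                          axon_terminal_points=np.asarray(terminals, float))

    def test_soma_exactly_at_radius_is_member(self):
        medoid, radius = (10, 10, 10), 5.0
        m = self.morph("a", (15.0, 10.0, 10.0))
        members, pooled = classify_members([m], medoid, radius, DIMS)
        assert [x.neuron_id for x in members] == ["a"]
        assert pooled.total == 1

    def test_soma_just_outside_excluded(self):
        medoid, radius = (10, 10, 10), 5.0
        m = self.morph("a", (10.0 + 5.05, 10.0, 10.0))
        members, pooled = classify_members([m], medoid, radius, DIMS)
        assert members == [] and pooled.total == 0

    def test_no_morphologies(self):
        members, pooled = classify_members([], (1, 1, 1), 3.0, DIMS)
        assert members == [] and pooled.total == 0

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(24)
        morphs = [
            self.morph(f"m{i}", rng.uniform(0, 60, 3)) for i in range(30)
        ]
        medoid = (30, 30, 30)
        prev: set[str] = set()
        for radius in (0.0, 5.0, 10.0, 20.0, 40.0, 80.0):
            members, _ = classify_members(morphs, medoid, radius, DIMS)
            ids = {m.neuron_id for m in members}
            assert prev <= ids
            prev = ids

    def test_terminals_floor_binned_unit_counts(self):
        m = self.morph("a", (10.0, 10.0, 10.0), [(5.7, 6.2, 7.9), (5.1, 6.8, 7.2)])
        _, pooled = classify_members([m], (10, 10, 10), 1.0, DIMS)
        assert pooled.entries == {(5, 6, 7): 2}


class TestNearestBulk:
    def record_with_medoid(self, medoid):
        return PopulationRecord("e", cloud([medoid]), VoxelCloud(DIMS))

    def test_single_entry(self):
        rec = self.record_with_medoid((10, 10, 10))
        assert nearest_bulk_experiment(rec, [("only", (0, 0, 0))]) == "only"

    def test_argmin_of_distances(self):
        rec = self.record_with_medoid((0, 0, 0))
        cat = [("d5", (5, 0, 0)), ("d3", (3, 0, 0)), ("d9", (9, 0, 0))]
        assert nearest_bulk_experiment(rec, cat) == "d3"

    def test_empty_catalogue_rejected(self):
        with pytest.raises(IntegrationError, match="catalogue"):
            nearest_bulk_experiment(self.record_with_medoid((0, 0, 0)), [])

    def test_matches_exhaustive_scan_on_random_catalogues(self):
        rng = np.random.default_rng(25)
        for _ in range(100):
            medoid = tuple(int(rng.integers(0, d)) for d in DIMS)
            rec = self.record_with_medoid(medoid)
            cat = [
                (f"e{i}", tuple(float(rng.uniform(0, d)) for d in DIMS))
                for i in range(int(rng.integers(1, 10)))
            ]
            got = nearest_bulk_experiment(rec, cat)
            dists = {eid: np.linalg.norm(np.asarray(c) - np.asarray(medoid)) for eid, c in cat}
            want = min(sorted(dists), key=lambda k: dists[k])
            assert got == want


class TestOverlap:
    def test_identical_masks_all_overlap(self):
        a = FlatIntensity(np.array([[1, 0], [2, 0]]))
        states = overlap_states(a, a)
        assert (states[a.intensity > 0] == OverlapState.OVERLAP).all()
        assert (states[a.intensity == 0] == OverlapState.NEITHER).all()

    def test_disjoint_masks_no_overlap(self):
        a = FlatIntensity(np.array([[1, 0]]))
        b = FlatIntensity(np.array([[0, 1]]))
        states = overlap_states(a, b)
        assert np.count_nonzero(states == OverlapState.OVERLAP) == 0

    def test_constructed_state_counts(self):
        # 10×10 map: 20 overlap, 30 population-only, 10 other-only
        pop = np.zeros((10, 10))
        oth = np.zeros((10, 10))
        flat_idx = np.arange(100).reshape(10, 10)
        pop[(flat_idx >= 0) & (flat_idx < 50)] = 1  # 0..49
        oth[(flat_idx >= 30) & (flat_idx < 60)] = 1  # 30..59 → 20 shared
        states = overlap_states(FlatIntensity(pop), FlatIntensity(oth))
        assert np.count_nonzero(states == OverlapState.OVERLAP) == 20
        assert np.count_nonzero(states == OverlapState.POPULATION_ONLY) == 30
        assert np.count_nonzero(states == OverlapState.OTHER_ONLY) == 10
        assert np.count_nonzero(states == OverlapState.NEITHER) == 40

    def test_states_partition_every_pixel(self):
        rng = np.random.default_rng(26)
        a = FlatIntensity(rng.integers(0, 3, (20, 20)))
        b = FlatIntensity(rng.integers(0, 3, (20, 20)))
        states = overlap_states(a, b)
        assert set(np.unique(states)) <= {0, 1, 2, 3}

    def test_dim_mismatch_rejected(self):
        with pytest.raises(IntegrationError, match="dims"):
            overlap_states(FlatIntensity(np.zeros((2, 2))), FlatIntensity(np.zeros((3, 3))))


class TestOverlapFractions:
    def test_all_overlap(self):
        states = np.full((5, 5), int(OverlapState.OVERLAP), dtype=np.int8)
        out = overlap_fractions(states, np.ones((5, 5), dtype=bool))
        assert out == {"overlap": 1.0, "population_only": 0.0, "other_only": 0.0}

    def test_equal_thirds(self):
        states = np.array([[1, 2, 3]] * 3, dtype=np.int8)
        out = overlap_fractions(states, np.ones((3, 3), dtype=bool))
        assert out["overlap"] == pytest.approx(1 / 3)
        assert out["population_only"] == pytest.approx(1 / 3)
        assert out["other_only"] == pytest.approx(1 / 3)

    def test_planted_45_35_20_split(self):
        states = np.zeros(100, dtype=np.int8)
        states[:45] = OverlapState.OVERLAP
        states[45:80] = OverlapState.POPULATION_ONLY
        states[80:] = OverlapState.OTHER_ONLY
        out = overlap_fractions(states.reshape(10, 10), np.ones((10, 10), dtype=bool))
        assert out == {"overlap": 0.45, "population_only": 0.35, "other_only": 0.20}

    def test_fractions_sum_to_one_over_targeted(self):
        rng = np.random.default_rng(27)
        states = rng.integers(0, 4, (15, 15)).astype(np.int8)
        mask = rng.uniform(size=(15, 15)) < 0.6
        out = overlap_fractions(states, mask)
        if out:
            assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_area_denominator_mode(self):
        states = np.zeros((10, 10), dtype=np.int8)
        states[0, :5] = OverlapState.OVERLAP  # 5 targeted of 100 area pixels
        out = overlap_fractions(states, np.ones((10, 10), dtype=bool), denominator="area")
        assert out["overlap"] == 0.05

    def test_no_targeted_pixels_warns_empty(self):
        import warnings

        states = np.zeros((4, 4), dtype=np.int8)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = overlap_fractions(states, np.ones((4, 4), dtype=bool))
        assert out == {}
        assert any("targeted" in str(x.message) for x in w)


class TestReaders:
    def test_swc_roundtrip(self, tmp_path):
        from micropop.synthetic import write_swc

        m = Morphology(
            neuron_id="n1",
            soma=np.array([10.25, 20.5, 30.75]),
            axon_terminal_points=np.array([[1.0, 2.0, 3.0], [4.5, 5.5, 6.5]]),
        )
        write_swc(tmp_path / "n1.swc", m)
        back = read_swc(tmp_path / "n1.swc")
        np.testing.assert_allclose(back.soma, m.soma, atol=1e-4)
        np.testing.assert_allclose(
            np.sort(back.axon_terminal_points, axis=0),
            np.sort(m.axon_terminal_points, axis=0),
            atol=1e-4,
        )

    def test_bulk_catalogue_csv(self, tmp_path):
        path = tmp_path / "cat.csv"
        path.write_text(
            "experiment_id,centroid_x,centroid_y,centroid_z\n"
            "268206050,10.5,20.5,30.5\n478581080,1,2,3\n"
        )
        cat = read_bulk_catalogue(path)
        assert cat[0] == ("268206050", (10.5, 20.5, 30.5))
        assert len(cat) == 2
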