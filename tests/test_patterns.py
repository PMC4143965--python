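import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import synapstat as ss
from synapstat.patterns import pooled_intensity
from synapstat.reference import sample_table


class TestBox:
    def test_volume_conversion(self, cube):
        assert cube.volume_nm3 == 1e9
        assert cube.volume_um3 == 1.0

    def test_membership_is_half_open(self, cube):
        inside = cube.contains([[0.0, 0.0, 0.0], [999.999, 0.0, 0.0]])
        outside = cube.contains([[1000.0, 0.0, 0.0], [0.0, -1e-9, 0.0]])
        assert inside.all() and not outside.any()

    def test_rejects_nonpositive_sides(self):
        with pytest.raises(ValueError):
            ss.Box3D([0.0, 10.0, 10.0])

    @given(st.floats(1.0, 1e5), st.floats(1.0, 1e5), st.floats(1.0, 1e5))
    def test_volume_is_product_of_sides(self, a, b, c):
        assert ss.Box3D([a, b, c]).volume_nm3 == pytest.approx(a * b * c)


class TestPattern:
    def test_point_outside_box_rejected(self, cube):
        with pytest.raises(ValueError):
            ss.PointPattern3D(box=cube, coords=[[500, 500, 1000.0]])

    def test_nonpositive_feret_rejected(self, cube):
        with pytest.raises(ValueError):
            ss.PointPattern3D(box=cube, coords=[[1, 2, 3]], feret=[0.0])

    def test_missing_ferets_allowed(self, cube):
        p = ss.PointPattern3D(
            box=cube, coords=[[1, 2, 3], [4, 5, 6]], feret=[np.nan, 40.0]
        )
        pts = p.points
        assert pts[0].feret_diameter is None
        assert pts[1].feret_diameter == 40.0

    def test_duplicate_sample_ids_rejected(self, cube):
        p1 = ss.PointPattern3D(box=cube, coords=[[1, 1, 1]], layer="I", sample_id="1")
        p2 = ss.PointPattern3D(box=cube, coords=[[2, 2, 2]], layer="I", sample_id="1")
        with pytest.raises(ValueError):
            ss.StudyCollection([p1, p2])


class TestIO:
    def test_empty_pattern_roundtrip(self, cube, tmp_path):
        p = ss.PointPattern3D(box=cube, coords=np.empty((0, 3)), sample_id="e")
        path = ss.write_pattern(p, tmp_path / "empty.csv")
        q = ss.read_pattern(path)
        assert q.n_points == 0 and q.sample_id == "e"

    def test_single_point_roundtrip(self, cube, tmp_path):
        p = ss.PointPattern3D(
            box=cube, coords=[[500, 500, 500]], feret=[400.0], sample_id="s"
        )
        q = ss.read_pattern(ss.write_pattern(p, tmp_path / "one.csv"))
        assert q.n_points == 1
        assert q.feret[0] == 400.0

    def test_large_roundtrip_bit_exact(self, rng, tmp_path):
        box = ss.Box3D([2000.0, 1500.0, 1000.0], origin=[10.0, -5.0, 0.0])
        coords = box.origin + rng.random((420, 3)) * box.side_lengths
        feret = rng.lognormal(5.9, 0.4, 420)
        p = ss.PointPattern3D(
            box=box, coords=coords, feret=feret, layer="III", animal="w33",
            sample_id="7",
        )
        q = ss.read_pattern(ss.write_pattern(p, tmp_path / "big.csv"))
        np.testing.assert_array_equal(q.coords, p.coords)
        np.testing.assert_array_equal(q.feret, p.feret)
        np.testing.assert_array_equal(q.box.side_lengths, box.side_lengths)
        np.testing.assert_array_equal(q.box.origin, box.origin)
        assert (q.layer, q.animal, q.sample_id) == ("III", "w33", "7")

    def test_missing_sidecar_raises(self, cube, tmp_path):
        p = ss.PointPattern3D(box=cube, coords=[[1, 1, 1]])
        path = ss.write_pattern(p, tmp_path / "x.csv")
        path.with_suffix(".json").unlink()
        with pytest.raises(FileNotFoundError):
            ss.read_pattern(path)

    def test_study_manifest_roundtrip(self, tmp_path, default_study):
        manifest = ss.write_study(default_study, tmp_path / "study")
        back = ss.read_study(manifest)
        assert len(back) == len(default_study)
        for a, b in zip(default_study, back):
            np.testing.assert_array_equal(a.coords, b.coords)
            assert (a.layer, a.animal, a.sample_id) == (b.layer, b.animal, b.sample_id)


class TestIntensity:
    @pytest.mark.parametrize(
        "row", list(sample_table().itertuples()), ids=lambda r: f"{r.layer}-{r.sample}"
    )
    def test_published_per_sample_densities(self, row, rng):
        """count/volume reproduces every published per-sample density."""
        side = (row.volume_um3 * 1e9) ** (1 / 3)
        box = ss.Box3D([side, side, side])
        p = ss.PointPattern3D(
            box=box, coords=rng.random((row.n_synapses, 3)) * box.side_lengths
        )
        assert round(ss.estimate_intensity(p), 3) == row.density

    def test_empty_pattern_zero_intensity(self, cube):
        p = ss.PointPattern3D(box=cube, coords=np.empty((0, 3)))
        assert ss.estimate_intensity(p) == 0.0

    def test_pooled_intensity_is_count_over_volume(self, table_study):
        layer_I = table_study.by_layer("I")
        assert pooled_intensity(layer_I) == pytest.approx(308 / 387.81)


class TestShrinkage:
    def test_identity_at_factor_one(self, cube, rng):
        p = ss.PointPattern3D(box=cube, coords=rng.random((5, 3)) * 1000)
        q = ss.shrinkage_correct(p, 1.0)
        np.testing.assert_array_equal(q.coords, p.coords)

    def test_linear_and_volume_scaling(self):
        box = ss.Box3D([900.0, 900.0, 900.0])
        p = ss.PointPattern3D(box=box, coords=[[450, 450, 450]], feret=[90.0])
        q = ss.shrinkage_correct(p, 0.90)
        np.testing.assert_allclose(q.box.side_lengths, 1000.0)
        # cube of volume 0.729 um^3 -> 1.0 um^3 (factor 0.9^3 = 0.729)
        assert q.box.volume_um3 == pytest.approx(0.729 / 0.9**3)
        assert q.feret[0] == pytest.approx(100.0)

    def test_invalid_factor(self, cube):
        p = ss.PointPattern3D(box=cube, coords=[[1, 1, 1]])
        with pytest.raises(ValueError):
            ss.shrinkage_correct(p, 0.0)


class TestNearestNeighbor:
    def test_two_points_symmetric(self, cube):
        p = ss.PointPattern3D(box=cube, coords=[[0, 0, 0], [5, 0, 0]])
        np.testing.assert_allclose(ss.nearest_neighbor_distances(p), [5.0, 5.0])

    def test_collinear_points(self, cube):
        p = ss.PointPattern3D(box=cube, coords=[[0, 0, 0], [3, 0, 0], [10, 0, 0]])
        np.testing.assert_allclose(ss.nearest_neighbor_distances(p), [3.0, 3.0, 7.0])

    def test_matches_bruteforce_scan(self, rng, cube):
        coords = rng.random((200, 3)) * 1000
        p = ss.PointPattern3D(box=cube, coords=coords)
        # O(N^2) oracle
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        expected = np.sqrt(d2.min(axis=1))
        np.testing.assert_allclose(ss.nearest_neighbor_distances(p), expected)

    def test_needs_two_points(self, cube):
        p = ss.PointPattern3D(box=cube, coords=[[1, 1, 1]])
        with pytest.raises(ValueError):
            ss.nearest_neighbor_distances(p)
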