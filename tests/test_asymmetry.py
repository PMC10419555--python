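"""Asymmetry scoring: layers, facial region, pointwise statistic, metrics."""

import numpy as np
import pytest
import trimesh

from craniosym.asymmetry import (
    PairwiseAsymmetry,
    facial_region,
    head_metrics,
    layer_landmarks,
    pointwise_asymmetry,
    summarize,
    export_heatmap,
)
from craniosym.errors import MeshError
from craniosym.io import HeadMesh, read_mesh
from craniosym.model import AsymmetryModel
from craniosym.template import build_template, closest_point_map


class TestLayerLandmarks:
    def test_cylinder_gives_constant_radius(self, class1_male_subject):
        R = 75.0
        m = trimesh.creation.cylinder(radius=R, height=400.0, sections=128)
        v = np.asarray(m.vertices)[:, [0, 2, 1]]
        mesh = HeadMesh(v, np.asarray(m.faces))
        lms = layer_landmarks(mesh, class1_male_subject.landmarks)
        pts = np.array(
            [lms[f"Layer{k}-{j}"] for k in range(1, 5) for j in range(10)]
        )
        radii = np.linalg.norm(pts[:, [0, 2]], axis=1)
        np.testing.assert_allclose(radii, R, atol=R * 1e-2)

    def test_count_and_labels(self, mesh_subject):
        lms = layer_landmarks(mesh_subject.mesh, mesh_subject.landmarks)
        layer = [lb for lb in lms.labels() if lb.startswith("Layer")]
        assert len(layer) == 40
        assert len(lms) == 77

    def test_heights_strictly_between_obs_and_vertex(self, mesh_subject):
        lms = layer_landmarks(mesh_subject.mesh, mesh_subject.landmarks)
        y_obs = 0.5 * (lms["OBs-r"][1] + lms["OBs-l"][1])
        y_v = lms["V"][1]
        for k in range(1, 5):
            for j in range(10):
                y = lms[f"Layer{k}-{j}"][1]
                assert y_obs < y < y_v

    def test_mirror_consistency_on_symmetric_mesh(self, symmetric_mesh_subject):
        """On a symmetric head, the point at azimuth theta mirrors the
        point at -theta."""
        s = symmetric_mesh_subject
        lms = layer_landmarks(s.mesh, s.landmarks)
        for k in range(1, 5):
            for j in range(1, 5):
                a = lms[f"Layer{k}-{j}"]
                b = lms[f"Layer{k}-{10 - j}"]
                np.testing.assert_allclose(a * [-1, 1, 1], b, atol=1e-6)

    def test_ray_miss_error_names_layer(self, class1_male_subject):
        tiny = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        mesh = HeadMesh(np.asarray(tiny.vertices), np.asarray(tiny.faces))
        with pytest.raises(MeshError, match="Layer"):
            layer_landmarks(mesh, class1_male_subject.landmarks)


class TestFacialRegion:
    def test_prn_in_face_gn_out(self):
        prn = np.array([0.0, 50.0, 80.0])
        gn = np.array([0.0, -60.0, 60.0])
        mask = facial_region(np.array([prn, gn]), prn, gn)
        assert mask.in_face[0] and not mask.in_face[1]

    def test_boundary_is_perpendicular_bisector(self):
        """Membership agrees with the half-space test against the
        perpendicular-bisector plane of the PRn-Gn segment."""
        rng = np.random.default_rng(0)
        prn = np.array([0.0, 40.0, 70.0])
        gn = np.array([0.0, -50.0, 55.0])
        pts = rng.uniform(-120, 120, (500, 3))
        mask = facial_region(pts, prn, gn)
        mid = 0.5 * (prn + gn)
        n = gn - prn
        halfspace = (pts - mid) @ n <= 0
        np.testing.assert_array_equal(mask.in_face, halfspace)

    def test_mask_partition(self, default_template):
        t = default_template
        prn = t.mesh.vertices[t.anchors["PRn"]]
        gn = t.mesh.vertices[t.anchors["Gn"]]
        mask = facial_region(t, prn, gn)
        assert mask.in_face.sum() + mask.in_skull.sum() == len(t.mesh.vertices)

    def test_mask_mirror_consistent_on_template(self, default_template):
        t = default_template
        prn = t.mesh.vertices[t.anchors["PRn"]]
        gn = t.mesh.vertices[t.anchors["Gn"]]
        mask = facial_region(t, prn, gn)
        np.testing.assert_array_equal(mask.in_face[t.mirror], mask.in_face)


class TestPointwiseAsymmetry:
    def test_null_for_symmetric_subject(self, default_template):
        """Self-correspondence of the symmetric template: all pair values 0."""
        t = default_template
        corr = closest_point_map(t.mesh.vertices, t.mesh)
        pa = pointwise_asymmetry(corr, t, origin=(0.0, 0.0, 0.0))
        assert np.abs(pa.values).max() < 1e-9

    @pytest.mark.parametrize("delta", [0.5, 2.0])
    def test_radial_inflation_recovered(self, default_template, delta):
        """Left-hemisphere radial inflation by delta about the origin is
        recovered by the correspondence statistic within 10%."""
        t = default_template
        fine = build_template(64, 44)
        v = fine.mesh.vertices.copy()
        r = v / np.linalg.norm(v, axis=1, keepdims=True)
        left = v[:, 0] > 1e-9
        v[left] += delta * r[left]
        subject = HeadMesh(v, fine.mesh.faces)
        corr = closest_point_map(t.mesh.vertices, subject)
        pa = pointwise_asymmetry(corr, t, origin=(0.0, 0.0, 0.0))
        assert pa.values.mean() == pytest.approx(delta, rel=0.10)

    def test_label_swap_invariance(self, default_template):
        """|d_L - d_R| is unchanged when left/right are exchanged."""
        t = default_template
        fine = build_template(64, 44)
        rng = np.random.default_rng(1)
        v = fine.mesh.vertices * rng.uniform(0.99, 1.01, (len(fine.mesh.vertices), 1))
        subject = HeadMesh(v, fine.mesh.faces)
        mirrored = HeadMesh(v * [-1, 1, 1], fine.mesh.faces[:, ::-1])
        pa = pointwise_asymmetry(
            closest_point_map(t.mesh.vertices, subject), t, (0, 0, 0)
        )
        pam = pointwise_asymmetry(
            closest_point_map(t.mesh.vertices, mirrored), t, (0, 0, 0)
        )
        assert pa.values.mean() == pytest.approx(pam.values.mean(), abs=1e-6)

    def test_midline_excluded(self, default_template):
        t = default_template
        corr = closest_point_map(t.mesh.vertices, t.mesh)
        pa = pointwise_asymmetry(corr, t, (0, 0, 0))
        assert np.all(t.mesh.vertices[pa.rep, 0] > 0)
        assert len(pa.values) * 2 + np.sum(
            t.mirror == np.arange(len(t.mirror))
        ) == len(t.mirror)


class TestSummaries:
    def test_constant_values(self, default_template):
        t = default_template
        reps = t.left_pairs()
        pa = PairwiseAsymmetry(reps, t.mirror[reps], np.full(len(reps), 1.7))
        mask = facial_region(
            t, t.mesh.vertices[t.anchors["PRn"]], t.mesh.vertices[t.anchors["Gn"]]
        )
        AH, AF = summarize(pa, mask)
        assert AH == pytest.approx(1.7) and AF == pytest.approx(1.7)

    def test_hand_computed_mean(self, default_template):
        t = default_template
        reps = t.left_pairs()[:5]
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        pa = PairwiseAsymmetry(reps, t.mirror[reps], vals)
        mask = facial_region(t, t.mesh.vertices[reps[0]], np.array([0, -500, 0.0]))
        AH, _ = summarize(pa, mask)
        assert AH == pytest.approx(0.3)


class TestHeadMetrics:
    def test_unit_cube(self, class1_male_subject):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        mesh = HeadMesh(np.asarray(box.vertices), np.asarray(box.faces))
        m = head_metrics(mesh, class1_male_subject.landmarks)
        assert m.L == pytest.approx(1.0) and m.W == pytest.approx(1.0)
        assert m.V == pytest.approx(0.001)
        lms = class1_male_subject.landmarks
        assert m.H == pytest.approx(lms["V"][1] - lms["Gn"][1])

    def test_sphere_volume(self, class1_male_subject):
        m = trimesh.creation.icosphere(subdivisions=4, radius=100.0)
        mesh = HeadMesh(np.asarray(m.vertices), np.asarray(m.faces))
        got = head_metrics(mesh, class1_male_subject.landmarks)
        assert got.V == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=0.01)

    def test_open_mesh_volume_error(self, class1_male_subject):
        tri = HeadMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]), np.array([[0, 1, 2]])
        )
        with pytest.raises(MeshError):
            head_metrics(tri, class1_male_subject.landmarks)


class TestHeatmap:
    def test_export_and_reload(self, tmp_path, default_template):
        t = default_template
        reps = t.left_pairs()
        rng = np.random.default_rng(2)
        pa = PairwiseAsymmetry(reps, t.mirror[reps], rng.uniform(0, 4, len(reps)))
        path = export_heatmap(t, pa, tmp_path / "heat.ply")
        back = read_mesh(path)
        assert back.scalar is not None
        expected = np.zeros(len(t.mesh.vertices))
        expected[pa.rep] = pa.values
        expected[pa.partner] = pa.values
        np.testing.assert_allclose(back.scalar, expected, atol=1e-6)

    def test_symmetric_subject_uniform_zero(self, tmp_path, default_template):
        t = default_template
        corr = closest_point_map(t.mesh.vertices, t.mesh)
        pa = pointwise_asymmetry(corr, t, (0, 0, 0))
        path = export_heatmap(t, pa, tmp_path / "null.ply")
        back = read_mesh(path)
        assert np.abs(back.scalar).max() < 1e-6

    def test_localized_bump_concentrates_heat(self, symmetric_mesh_subject):
        """A left-buccal bump shows up as maximal heat inside the bump's
        bounding box."""
        s = symmetric_mesh_subject
        v = s.mesh.vertices.copy()
        center = np.array([v[:, 0].max() * 0.9, 0.0, 20.0])
        d = np.linalg.norm(v - center, axis=1)
        bump = np.exp(-0.5 * (d / 25.0) ** 2)
        r = v / np.linalg.norm(v, axis=1, keepdims=True)
        v[v[:, 0] > 1e-9] += (4.0 * bump[v[:, 0] > 1e-9])[:, None] * r[v[:, 0] > 1e-9]
        res = AsymmetryModel(HeadMesh(v, s.mesh.faces), s.landmarks).fit()
        vv = res.result.vertex_values
        tpl_v = res.model.template.mesh.vertices
        hot = tpl_v[np.argmax(vv)]
        assert hot[0] > 0 and np.linalg.norm(hot - center) < 60.0
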