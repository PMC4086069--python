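import numpy as np
import pytest

from icnma import affine_domains as ad
from icnma import fixtures as fx
from icnma import nma_core as nc

from oracles import affine_normal_equations


class TestFitAffine:
    def test_exact_affine_field_recovered(self, rng):
        coords = rng.normal(scale=5.0, size=(12, 3))
        B = rng.normal(size=(3, 3))
        c = rng.normal(size=3)
        model = ad.fit_affine(coords, coords @ B.T + c)
        assert np.allclose(model.A, B, atol=1e-10)
        assert np.allclose(model.t, c, atol=1e-10)
        assert model.fit_error < 1e-10

    def test_pure_translation(self, rng):
        coords = rng.normal(size=(8, 3))
        t = np.array([1.0, -2.0, 0.5])
        model = ad.fit_affine(coords, np.tile(t, (8, 1)))
        assert np.allclose(model.A, 0.0, atol=1e-10)
        assert np.allclose(model.t, t)

    def test_matches_normal_equations_oracle(self, rng):
        coords = rng.normal(scale=3.0, size=(10, 3))
        disp = rng.normal(size=(10, 3))
        model = ad.fit_affine(coords, disp)
        A_ref, t_ref = affine_normal_equations(coords, disp)
        assert np.allclose(model.A, A_ref, atol=1e-10)
        assert np.allclose(model.t, t_ref, atol=1e-10)

    def test_degenerate_set_flagged(self, rng):
        coords = np.zeros((5, 3))
        coords[:, 0] = np.arange(5)  # collinear
        model = ad.fit_affine(coords, rng.normal(size=(5, 3)))
        assert model.degenerate


class TestClusterMode:
    def test_global_rotation_single_domain(self, helix10):
        omega = np.array([0.0, 0.0, 0.04])
        field = np.cross(omega, helix10.coords - helix10.coords.mean(0))
        part = ad.cluster_mode(helix10, field, 1)
        assert part.n_domains == 1
        assert part.models[0].fit_error < 1e-8
        assert np.all(part.labels == 0)

    def test_two_rigid_bodies_exact_recovery(self, rigid_field):
        s, field, labels = rigid_field
        part = ad.cluster_mode(s, field, 2)
        agree = max(np.mean(part.labels == labels), np.mean(part.labels != labels))
        assert agree == 1.0
        assert all(m.fit_error < 1e-8 for m in part.models)

    def test_three_rigid_bodies_exact_recovery(self, rng):
        s = fx.make_helix(24)
        ridx = s.residue_index()
        labels = np.minimum(ridx // 8, 2)
        field = np.zeros_like(s.coords)
        for lab in range(3):
            atoms = np.nonzero(labels == lab)[0]
            omega = rng.normal(size=3) * 0.05
            t = rng.normal(size=3) * 0.4
            field[atoms] = np.cross(omega, s.coords[atoms] - s.coords[atoms].mean(0)) + t
        part = ad.cluster_mode(s, field, 3)
        # relabel-invariant comparison
        mapping = {}
        for lab in range(3):
            atoms = labels == lab
            mapping[lab] = np.bincount(part.labels[atoms]).argmax()
        assert len(set(mapping.values())) == 3
        relabeled = np.array([mapping[l] for l in labels])
        assert np.array_equal(relabeled, part.labels)
        assert all(m.fit_error < 1e-8 for m in part.models)

    def test_merge_cost_monotone_and_scale_invariant(self, rigid_field, hinge12_nma):
        s, _, _, system, modes = hinge12_nma
        field = modes.cartesian_vectors[:, 0].reshape(-1, 3)
        part1 = ad.cluster_mode(s, field, 2)
        deltas = [c for *_, c in part1.merge_history]
        assert all(d >= -1e-12 for d in deltas)
        # non-decreasing merge cost (Ward-style agglomeration)
        assert all(deltas[i + 1] >= deltas[i] - 1e-9 for i in range(len(deltas) - 1))
        part2 = ad.cluster_mode(s, 7.5 * field, 2)
        assert np.array_equal(part1.labels, part2.labels)

    def test_too_many_clusters_rejected(self, helix10):
        with pytest.raises(ValueError):
            ad.cluster_mode(helix10, np.zeros_like(helix10.coords), 99)


class TestArrows:
    def test_z_axis_rotation(self):
        model = ad.AffineModel(
            A=np.array([[0.0, -0.1, 0.0], [0.1, 0.0, 0.0], [0.0, 0.0, 0.0]]),
            t=np.zeros(3), fit_error=0.0,
        )
        arrow = ad.arrow_from_affine(model, centroid=np.array([5.0, 0.0, 3.0]))
        assert arrow.kind == "screw"
        assert np.allclose(np.abs(arrow.axis_direction), [0, 0, 1])
        assert arrow.rotation_angle == pytest.approx(0.1)
        assert abs(arrow.translation_along_axis) < 1e-12
        assert np.allclose(arrow.axis_point[:2], 0.0, atol=1e-10)

    def test_pure_translation_arrow(self):
        model = ad.AffineModel(A=np.zeros((3, 3)),
                               t=np.array([0.0, 2.0, 0.0]), fit_error=0.0)
        arrow = ad.arrow_from_affine(model, centroid=np.zeros(3))
        assert arrow.kind == "translation"
        assert np.allclose(arrow.axis_direction, [0, 1, 0])
        assert arrow.rotation_angle == 0.0

    def test_helical_field_pitch_recovered(self):
        omega = 0.2
        pitch_translation = 0.37  # per radian-equivalent unit
        A = np.array([[0.0, -omega, 0.0], [omega, 0.0, 0.0], [0.0, 0.0, 0.0]])
        t = np.array([0.0, 0.0, omega * pitch_translation])
        model = ad.AffineModel(A=A, t=t, fit_error=0.0)
        arrow = ad.arrow_from_affine(model, centroid=np.array([1.0, 2.0, 0.0]))
        assert arrow.kind == "screw"
        pitch = arrow.translation_along_axis / arrow.rotation_angle
        assert pitch == pytest.approx(pitch_translation, abs=1e-6)


def test_partition_export_roundtrip(rigid_field, tmp_path):
    s, field, _ = rigid_field
    part = ad.cluster_mode(s, field, 2)
    arrows = ad.arrows_for_partition(s, part)
    ad.write_partition(s, part, tmp_path / "domains.tsv")
    ad.write_arrows(arrows, tmp_path / "arrows.json")
    import json

    records = json.loads((tmp_path / "arrows.json").read_text())
    assert len(records) == 2
    assert {r["domain_id"] for r in records} == {0, 1}
    lines = (tmp_path / "domains.tsv").read_text().splitlines()
    assert len(lines) == 1 + s.n_residues
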