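import numpy as np
import pytest

from vasodose import masses
from vasodose.geometry import ConvexPoly, box, cylinder, icosahedron, regular_hex_prism
from vasodose.lobule import (
    LabeledMeshSet,
    LobuleSpec,
    build_hexagonal_lobule,
    classify_tiled,
    place_kupffer_cells,
    region_mass_report,
    tile_and_crop_prism,
)


class TestGeometryPrimitives:
    def test_box_volume(self):
        assert box((0, 0, 0), (2, 3, 4)).volume == pytest.approx(24.0)

    def test_cylinder_area_preserving(self):
        c = cylinder((0, 0, 0), (0, 0, 5), 2.0, n_sides=24)
        assert c.volume == pytest.approx(np.pi * 4 * 5, rel=1e-9)

    def test_hex_prism_volume(self):
        # (3 sqrt 3 / 2) a^2 h for side a
        p = regular_hex_prism(2.0, 3.0)
        assert p.volume == pytest.approx(1.5 * np.sqrt(3) * 4 * 3, rel=1e-12)

    def test_icosahedron_volume(self):
        R = 2.0
        ico = icosahedron((1, 1, 1), R)
        edge = R / np.sin(2 * np.pi / 5)
        expected = 5 / 12 * (3 + np.sqrt(5)) * edge**3
        assert ico.volume == pytest.approx(expected, rel=1e-9)

    def test_halfspace_clip_volume(self):
        b = box((0, 0, 0), (1, 1, 1))
        half = b.clip_halfspace([1, 0, 0], 0.5)
        assert half.volume == pytest.approx(0.5, rel=1e-12)
        assert b.clip_halfspace([1, 0, 0], -0.1) is None

    def test_contains(self):
        c = cylinder((0, 0, 0), (0, 0, 2), 1.0)
        inside = c.contains(np.array([[0, 0, 1.0], [0, 0, 3.0], [2, 0, 1.0]]))
        np.testing.assert_array_equal(inside, [True, False, False])


class TestBuildLobule:
    def test_all_targets_within_5_percent(self, small_lobule, small_lobule_spec):
        V = small_lobule_spec.prism_volume()
        fv = small_lobule_spec.target_volume_fractions()
        vols = small_lobule.component_volumes()
        for name, target in fv.items():
            got = vols[name] / V
            assert got == pytest.approx(target, rel=0.05), name

    def test_sinusoid_mass_fraction_matches_reference(self, small_lobule, small_lobule_spec):
        report = region_mass_report(small_lobule, small_lobule_spec.densities)
        assert report["sinusoids"]["mass_fraction"] == pytest.approx(0.1538, rel=0.05)

    def test_hex_prism_volume_formula(self, small_lobule, small_lobule_spec):
        s, h = small_lobule_spec.side_um, small_lobule_spec.height_um
        assert small_lobule.domain.volume == pytest.approx(1.5 * np.sqrt(3) * s**2 * h, rel=1e-9)

    def test_zero_kupffer_target_omits_component(self):
        lf = masses.reference_lobule_fractions()
        fr = dict(lf.fractions)
        fr["hepatocytes"] += fr["kupffer_cells"]
        fr["kupffer_cells"] = 0.0
        targets = masses.LobuleMassFractions(fractions=fr, total_mass=lf.total_mass)
        spec = LobuleSpec(side_um=150, height_um=150, canaliculus_radius_um=4.5, targets=targets, seed=1)
        lob = build_hexagonal_lobule(spec)
        assert "kupffer_cells" not in lob.components

    def test_infeasible_blood_target_errors(self):
        lf = masses.reference_lobule_fractions()
        fr = {k: v * 0.2 for k, v in lf.fractions.items()}
        fr["sinusoids"] = 1.0 - sum(v for k, v in fr.items() if k != "sinusoids")
        targets = masses.LobuleMassFractions(fractions=fr, total_mass=lf.total_mass)
        spec = LobuleSpec(side_um=150, height_um=150, targets=targets)
        with pytest.raises(ValueError, match="infeasible"):
            build_hexagonal_lobule(spec)

    def test_components_disjoint(self, small_lobule, rng):
        # random points classify to at most one component by construction;
        # verify explicit parts never co-claim a point
        lo, hi = small_lobule.domain.bounds()
        pts = lo + (hi - lo) * rng.random((4000, 3))
        claims = np.zeros(len(pts), int)
        for name, parts in small_lobule.components.items():
            hit = np.zeros(len(pts), bool)
            for p in parts:
                plo, phi = p.bounds()
                cand = ((pts >= plo - 1e-9) & (pts <= phi + 1e-9)).all(axis=1)
                if cand.any():
                    idx = np.flatnonzero(cand)
                    hit[idx[p.contains(pts[idx], tol=-1e-9)]] = True
            claims += hit
        assert claims.max() <= 1

    def test_components_inside_prism(self, small_lobule):
        for name, parts in small_lobule.components.items():
            for p in parts:
                assert small_lobule.domain.contains(p.vertices, tol=1e-6).all(), name

    def test_deterministic(self, small_lobule_spec, small_lobule):
        again = build_hexagonal_lobule(small_lobule_spec)
        v1 = small_lobule.component_volumes()
        v2 = again.component_volumes()
        for k in v1:
            assert v1[k] == pytest.approx(v2[k], rel=1e-12)


class TestKupffer:
    def test_target_zero_empty(self, small_lobule):
        assert place_kupffer_cells(small_lobule.components["sinusoids"], 0.0, 6.0, seed=1) == []

    def test_cells_inside_lumen_and_volume(self, small_lobule):
        lumen = small_lobule.components["sinusoids"]
        target = 4000.0  # um^3
        cells = place_kupffer_cells(lumen, target, 5.0, seed=7)
        total = sum(c.volume for c in cells)
        assert abs(total - target) <= 0.02 * target + max(c.volume for c in cells)
        for c in cells:
            centers = c.vertices
            inside_any = np.zeros(len(centers), bool)
            for part in lumen:
                inside_any |= part.contains(centers, tol=1e-6)
            assert inside_any.all()

    def test_deterministic(self, small_lobule):
        lumen = small_lobule.components["sinusoids"]
        a = place_kupffer_cells(lumen, 2000.0, 5.0, seed=3)
        b = place_kupffer_cells(lumen, 2000.0, 5.0, seed=3)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            np.testing.assert_allclose(ca.vertices, cb.vertices)

    def test_unreachable_target_errors(self, small_lobule):
        lumen = small_lobule.components["sinusoids"]
        total = sum(p.volume for p in lumen)
        with pytest.raises(ValueError):
            place_kupffer_cells(lumen, total * 2, 5.0, seed=1)


@pytest.fixture(scope="module")
def cropped(small_lobule):
    return tile_and_crop_prism(small_lobule)


class TestTileAndCrop:
    def test_bounding_box_is_rectangular_cell(self, cropped, small_lobule_spec):
        lo, hi = cropped.domain.bounds()
        s, a = small_lobule_spec.side_um, small_lobule_spec.apothem_um
        np.testing.assert_allclose(hi - lo, [1.5 * s, 2 * a, small_lobule_spec.height_um], rtol=1e-12)

    def test_fractions_preserved_within_1_percent(self, cropped, small_lobule):
        before = small_lobule.component_volumes()
        after = cropped.component_volumes()
        vb = small_lobule.domain.volume
        va = cropped.domain.volume
        for name in before:
            fb = before[name] / vb
            fa = after[name] / va
            assert fa == pytest.approx(fb, rel=0.01), name

    def test_total_volume_closes(self, cropped):
        vols = cropped.component_volumes()
        assert sum(vols.values()) == pytest.approx(cropped.domain.volume, rel=0.005)

    def test_mirror_symmetric_boundary(self, cropped, small_lobule, rng):
        # reflecting near-face points across each box face maps labels onto
        # themselves in the infinite tiling (Kupffer sites are random and
        # excluded)
        lo, hi = cropped.domain.bounds()
        n = 400
        for axis in range(3):
            for face in (lo[axis], hi[axis]):
                pts = lo + (hi - lo) * rng.random((n, 3))
                pts[:, axis] = face + rng.uniform(1.0, 6.0, n) * (1 if face == lo[axis] else -1)
                mirrored = pts.copy()
                mirrored[:, axis] = 2 * face - pts[:, axis]
                a = classify_tiled(pts, small_lobule)
                b = classify_tiled(mirrored, small_lobule)
                keep = (a != "kupffer_cells") & (b != "kupffer_cells")
                agree = (a[keep] == b[keep]).mean()
                assert agree > 0.97, (axis, face, agree)


class TestRegionMassReport:
    def test_two_cubes(self):
        comps = {
            "a": [box((0, 0, 0), (1, 1, 1))],
            "b": [box((2, 0, 0), (3, 1, 1))],
        }
        ms = LabeledMeshSet(comps, box((0, 0, 0), (3, 1, 1)), fill=None)
        rep = region_mass_report(ms, {"a": 1.0, "b": 1.06})
        assert rep["a"]["mass_fraction"] == pytest.approx(0.4854, abs=1e-4)
        assert rep["b"]["mass_fraction"] == pytest.approx(0.5146, abs=1e-4)

    def test_single_component_fraction_one(self):
        ms = LabeledMeshSet({"only": [box((0, 0, 0), (1, 1, 1))]}, box((0, 0, 0), (1, 1, 1)), fill=None)
        rep = region_mass_report(ms, {"only": 2.0})
        assert rep["only"]["mass_fraction"] == pytest.approx(1.0)

    def test_reference_lobule_fractions_within_5_percent(self, small_lobule, small_lobule_spec):
        rep = region_mass_report(small_lobule, small_lobule_spec.densities)
        for name, target in small_lobule_spec.targets.fractions.items():
            assert rep[name]["mass_fraction"] == pytest.approx(target, rel=0.06), name

    def test_open_mesh_errors(self, small_lobule, small_lobule_spec):
        broken = LabeledMeshSet(dict(small_lobule.components), small_lobule.domain, fill="hepatocytes", spec=small_lobule_spec)
        sin = broken.components["sinusoids"][0]
        bad = ConvexPoly(sin.vertices.copy())

        class OpenPoly(ConvexPoly):
            @property
            def faces(self):
                return super().faces[:-1]

        broken.components["sinusoids"] = [OpenPoly(sin.vertices)] + broken.components["sinusoids"][1:]
        with pytest.raises(ValueError, match="watertight"):
            region_mass_report(broken, small_lobule_spec.densities)


class TestMeshes:
    def test_component_meshes_closed(self, small_lobule):
        meshes = small_lobule.meshes()
        for name, mesh in meshes.items():
            assert mesh.is_watertight(), name

    def test_mesh_volumes_match_poly_volumes(self, small_lobule):
        meshes = small_lobule.meshes()
        vols = small_lobule.component_volumes()
        for name, parts in small_lobule.components.items():
            assert meshes[name].volume() == pytest.approx(vols[name], rel=1e-9), name
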