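"""Scaffold geometry, projection, fitting, material transfer, and overlap."""

import numpy as np
import pytest

from icnsmap.scaffold import (
    EmbeddedPoint,
    FitSingularError,
    MaterialCoordinate,
    Scaffold,
    _shape_functions,
    align_scaffold,
    embed_markers,
    estimate_similarity,
    evaluate,
    evaluate_many,
    fit_scaffold,
    make_generic_scaffold,
    overlap_map,
    project_point,
    project_points,
    reference_structure_centroids,
    register_subject,
    structure_element_map,
    transfer_to_generic,
)
from icnsmap.core_io import NeuronMarker


@pytest.fixture(scope="module")
def generic(template):
    return make_generic_scaffold(template, (8, 8))


def _flat_scaffold(n=2, size=1.0):
    u = np.linspace(0, size * n, n + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    return Scaffold(np.stack([uu, vv, np.zeros_like(uu)], axis=-1))


class TestGeometry:
    def test_counts(self, generic):
        assert generic.n_elements == 64
        assert generic.n_nodes == 81

    def test_repeated_calls_identical(self, template):
        a = make_generic_scaffold(template, (8, 8))
        b = make_generic_scaffold(template, (8, 8))
        np.testing.assert_array_equal(a.nodes, b.nodes)

    def test_corner_evaluation_matches_nodes(self, generic):
        nu, nv = generic.shape
        for e in (0, 5, nu * nv - 1):
            i, j = divmod(e, nv)
            np.testing.assert_allclose(
                evaluate(generic, MaterialCoordinate(e, (0.0, 0.0))),
                generic.nodes[i, j],
            )
            np.testing.assert_allclose(
                evaluate(generic, MaterialCoordinate(e, (1.0, 1.0))),
                generic.nodes[i + 1, j + 1],
            )

    def test_unit_square_center(self):
        sc = _flat_scaffold(n=1)
        np.testing.assert_allclose(
            evaluate(sc, MaterialCoordinate(0, (0.5, 0.5))), [0.5, 0.5, 0.0]
        )

    def test_shape_function_summation_oracle(self, generic, rng):
        """Bilinear evaluation equals the explicit Σ φ_j(ξ) p_j sum."""
        for _ in range(20):
            e = int(rng.integers(0, generic.n_elements))
            xi = rng.uniform(0, 1, 2)
            corners = generic.element_corners(e)
            x1, x2 = xi
            phi = [
                (1 - x1) * (1 - x2),
                x1 * (1 - x2),
                x1 * x2,
                (1 - x1) * x2,
            ]
            expected = sum(p * c for p, c in zip(phi, corners))
            np.testing.assert_allclose(
                evaluate(generic, MaterialCoordinate(e, tuple(xi))), expected
            )

    def test_shape_functions_partition_of_unity(self, rng):
        xi = rng.uniform(0, 1, (50, 2))
        np.testing.assert_allclose(_shape_functions(xi).sum(axis=1), 1.0)

    def test_invalid_element(self, generic):
        with pytest.raises(ValueError):
            evaluate(generic, MaterialCoordinate(10**6, (0.5, 0.5)))
        with pytest.raises(ValueError):
            MaterialCoordinate(0, (1.5, 0.0))

    def test_json_round_trip(self, generic, tmp_path):
        p = tmp_path / "scaffold.json"
        generic.to_json(p)
        np.testing.assert_array_equal(Scaffold.from_json(p).nodes, generic.nodes)


class TestProjection:
    def test_surface_point_is_fixed_point(self, generic):
        # a point evaluated on the scaffold projects back to itself
        mc = MaterialCoordinate(27, (0.3, 0.7))
        p = evaluate(generic, mc)
        m, d = project_point(generic, p)
        assert d == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(evaluate(generic, m), p, atol=1e-6)

    def test_point_above_flat_element(self):
        sc = _flat_scaffold(n=1)
        m, d = project_point(sc, np.array([0.5, 0.5, 1.0]))
        assert d == pytest.approx(1.0)
        assert m.xi == pytest.approx((0.5, 0.5))

    def test_matches_dense_grid_brute_force(self, generic, rng):
        g = np.linspace(0, 1, 101)
        gg = np.stack(np.meshgrid(g, g, indexing="ij"), -1).reshape(-1, 2)
        phi = _shape_functions(gg)
        corners = generic.element_corners(np.arange(generic.n_elements))
        dense = np.einsum("gj,ejd->egd", phi, corners).reshape(-1, 3)
        res = max(np.linalg.norm(c[0] - c[2], axis=-1).max() for c in corners) / 100
        for _ in range(15):
            pt = rng.uniform([0, 0, 0], [8000, 8000, 4000])
            _, d = project_point(generic, pt)
            brute = np.linalg.norm(dense - pt, axis=1).min()
            assert d <= brute + 1e-9
            assert abs(d - brute) <= res

    def test_fast_matches_full(self, generic, rng):
        pts = rng.uniform([0, 0, 0], [8000, 8000, 4500], (300, 3))
        _, _, d_full = project_points(generic, pts, mode="full")
        _, _, d_fast = project_points(generic, pts, mode="fast")
        np.testing.assert_allclose(d_fast, d_full, atol=1e-6)

    def test_element_subset_restricts(self, generic):
        p = evaluate(generic, MaterialCoordinate(0, (0.5, 0.5)))
        el, _, _ = project_points(generic, p[None], element_subset=np.array([63]))
        assert el[0] == 63

    def test_non_finite_rejected(self, generic):
        with pytest.raises(ValueError):
            project_point(generic, np.array([np.nan, 0, 0]))


class TestFit:
    def test_generic_data_is_fixed_point(self, generic):
        data = generic.nodes.reshape(-1, 3)
        res = fit_scaffold(generic, data, lambda_smooth=0.0)
        assert res.rms == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.scaffold.nodes, generic.nodes, atol=1e-6)

    def test_translation_recovered_exactly(self, generic):
        """With known (node-corner) correspondences and λ=0 the solve is a
        consistent linear system: translated data give translated nodes."""
        nu, nv = generic.shape
        els, xis = [], []
        for i in range(nu + 1):
            for j in range(nv + 1):
                els.append(min(i, nu - 1) * nv + min(j, nv - 1))
                xis.append((1.0 if i == nu else 0.0, 1.0 if j == nv else 0.0))
        t = np.array([300.0, -200.0, 150.0])
        data = generic.nodes.reshape(-1, 3) + t
        res = fit_scaffold(
            generic,
            data,
            lambda_smooth=0.0,
            correspondences=(np.array(els), np.array(xis)),
        )
        np.testing.assert_allclose(
            res.scaffold.nodes, generic.nodes + t, atol=1e-8
        )

    def test_rms_non_increasing_with_fixed_correspondences(self, generic, rng):
        """Given any fixed correspondences the node solve minimizes the
        objective exactly, so the resulting data RMS cannot exceed the RMS
        of the starting configuration."""
        mc_el = rng.integers(0, generic.n_elements, 300)
        mc_xi = rng.uniform(0, 1, (300, 2))
        data = evaluate_many(generic, mc_el, mc_xi) + rng.normal(0, 40, (300, 3))
        start_rms = np.sqrt(
            ((data - evaluate_many(generic, mc_el, mc_xi)) ** 2).sum(axis=1).mean()
        )
        res = fit_scaffold(
            generic, data, lambda_smooth=0.1, correspondences=(mc_el, mc_xi)
        )
        assert res.rms <= start_rms + 1e-9

    def test_singular_without_smoothing(self, generic):
        # 3 data points cannot constrain 81 nodes
        data = generic.nodes.reshape(-1, 3)[:3]
        with pytest.raises(FitSingularError, match="lambda_smooth"):
            fit_scaffold(generic, data, lambda_smooth=0.0)

    def test_warp_recovery(self, template, small_subject):
        """Fitting to a 300 µm-warped subject's contours brings the RMS
        contour distance down to the few-µm scale."""
        subject, _ = small_subject
        generic = make_generic_scaffold(template, (16, 16))
        reg = register_subject(subject, template, generic)
        assert reg.fit.rms < 25.0

    def test_weights_validation(self, generic):
        data = generic.nodes.reshape(-1, 3)
        with pytest.raises(ValueError):
            fit_scaffold(generic, data, weights=np.ones(3))


class TestSimilarity:
    def test_known_transform_recovered(self, rng):
        src = rng.normal(size=(20, 3)) * 100
        angle = 0.3
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        dst = 1.07 * src @ rot.T + [50.0, -20.0, 10.0]
        scale, r, t = estimate_similarity(src, dst)
        assert scale == pytest.approx(1.07, rel=1e-9)
        np.testing.assert_allclose(r, rot, atol=1e-9)
        np.testing.assert_allclose(t, [50.0, -20.0, 10.0], atol=1e-6)

    def test_align_scaffold_uses_structure_centroids(
        self, template, generic, small_subject
    ):
        subject, _ = small_subject
        pts = np.vstack([c.points for c in subject.contours])
        names = np.concatenate(
            [np.full(len(c.points), c.structure_name) for c in subject.contours]
        )
        refc = reference_structure_centroids(template)
        aligned, transform = align_scaffold(generic, pts, names, refc)
        assert aligned.nodes.shape == generic.nodes.shape
        assert 0.8 < transform["scale"] < 1.25


class TestEmbedTransfer:
    def test_embedding_round_trip(self, generic, rng):
        mc_el = rng.integers(0, generic.n_elements, 20)
        mc_xi = rng.uniform(0.05, 0.95, (20, 2))
        pts = evaluate_many(generic, mc_el, mc_xi)
        markers = [NeuronMarker(f"m{i}", p, 0) for i, p in enumerate(pts)]
        embedded = embed_markers(generic, markers)
        assert len(embedded) == 20  # count preservation
        for e, p in zip(embedded, pts):
            assert e.projection_distance == pytest.approx(0.0, abs=1e-6)
            foot = evaluate(generic, e.material)
            np.testing.assert_allclose(foot, p, rtol=1e-6, atol=1e-6)

    def test_transfer_identity_when_fitted_is_generic(self, generic, rng):
        pts = generic.nodes.reshape(-1, 3)[:10] + rng.normal(0, 30, (10, 3))
        markers = [NeuronMarker(f"m{i}", p, 0) for i, p in enumerate(pts)]
        embedded = embed_markers(generic, markers)
        transferred = transfer_to_generic(embedded, generic)
        feet = np.array([evaluate(generic, e.material) for e in embedded])
        np.testing.assert_allclose(transferred, feet, atol=1e-9)

    def test_material_preserved_exactly(self, generic):
        e = EmbeddedPoint("m", MaterialCoordinate(5, (0.25, 0.75)), 1.0)
        transfer_to_generic([e], generic)
        assert e.material.element_id == 5 and e.material.xi == (0.25, 0.75)

    def test_topology_mismatch(self, template):
        small = make_generic_scaffold(template, (2, 2))
        e = EmbeddedPoint("m", MaterialCoordinate(50, (0.5, 0.5)), 0.0)
        with pytest.raises(ValueError, match="topology"):
            transfer_to_generic([e], small)


class TestOverlap:
    def test_identical_sets_overlap_one(self, generic, rng):
        mats = [
            MaterialCoordinate(int(e), (float(a), float(b)))
            for e, a, b in zip(
                rng.integers(0, generic.n_elements, 40),
                rng.uniform(0, 1, 40),
                rng.uniform(0, 1, 40),
            )
        ]
        om = overlap_map(mats, list(mats), generic, subgrid=2)
        assert om.global_overlap == 1.0
        assert om.jaccard_occupied == 1.0

    def test_disjoint_occupancy_overlap_zero(self, generic):
        a = [MaterialCoordinate(0, (0.1, 0.1))] * 5
        b = [MaterialCoordinate(3, (0.9, 0.9))] * 7
        om = overlap_map(a, b, generic, subgrid=2)
        assert om.global_overlap == 0.0
        assert om.jaccard_occupied == 0.0

    def test_matches_histogram_intersection_oracle(self, generic, rng):
        els_a = rng.integers(0, generic.n_elements, 200)
        xi_a = rng.uniform(0, 1, (200, 2))
        els_b = rng.integers(0, generic.n_elements, 150)
        xi_b = rng.uniform(0, 1, (150, 2))
        a = [MaterialCoordinate(int(e), tuple(x)) for e, x in zip(els_a, xi_a)]
        b = [MaterialCoordinate(int(e), tuple(x)) for e, x in zip(els_b, xi_b)]
        s = 3
        om = overlap_map(a, b, generic, subgrid=s)
        # independent oracle: dictionary histogram intersection
        def hist(els, xis):
            h = {}
            for e, (x1, x2) in zip(els, xis):
                key = (int(e), min(int(x1 * s), s - 1), min(int(x2 * s), s - 1))
                h[key] = h.get(key, 0) + 1
            return h
        ha, hb = hist(els_a, xi_a), hist(els_b, xi_b)
        expected = sum(
            min(ha.get(k, 0) / 200, hb.get(k, 0) / 150)
            for k in set(ha) | set(hb)
        )
        assert om.global_overlap == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self, generic, rng):
        a = [MaterialCoordinate(int(e), (0.5, 0.5)) for e in rng.integers(0, 64, 30)]
        b = [MaterialCoordinate(int(e), (0.5, 0.5)) for e in rng.integers(0, 64, 50)]
        ab = overlap_map(a, b, generic)
        ba = overlap_map(b, a, generic)
        assert ab.global_overlap == ba.global_overlap
        assert ab.jaccard_occupied == ba.jaccard_occupied

    def test_empty_rejected(self, generic):
        with pytest.raises(ValueError):
            overlap_map([], [MaterialCoordinate(0, (0.5, 0.5))], generic)


def test_structure_element_map_covers_regions(template):
    gmap = structure_element_map(template, (16, 16))
    for name, (umin, vmin, umax, vmax) in template.structure_regions.items():
        assert len(gmap[name]) > 0
        # the element containing the region center is always included
        cu = min(int((umin + umax) / 2 * 16), 15)
        cv = min(int((vmin + vmax) / 2 * 16), 15)
        assert cu * 16 + cv in gmap[name]
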