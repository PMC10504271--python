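"""Feature-alignment decoder: nearest codes, position encoding, decoding."""

import numpy as np
import pytest

from faseg import fa_decoder as fa
from faseg.encoder import FeatureMap, FeaturePyramid


def brute_force_nearest(coords, x_q):
    """Exhaustive argmin of Euclidean distance, ties to smaller (row, col)."""
    h, w, _ = coords.shape
    best = None
    for r in range(h):
        for c in range(w):
            d = np.sum((coords[r, c] - x_q) ** 2)
            if best is None or d < best[0] - 1e-15:
                best = (d, r, c)
    return best[1], best[2]


def random_grids(rng, latent_width=6, sides=(16, 8, 4, 2, 1)):
    return [
        fa.LatentGrid(codes=rng.normal(0, 1, (latent_width, s, s)),
                      coords=fa.level_coords(s, s), level=i + 1)
        for i, s in enumerate(sides)
    ]


def random_mlp(rng, in_w, hidden=(13,), out=2):
    widths = [in_w, *hidden, out]
    return fa.DecoderMLP(
        weights=[(rng.normal(0, 0.5, (a, b)), rng.normal(0, 0.1, b))
                 for a, b in zip(widths[:-1], widths[1:])],
        num_classes=out,
    )


class TestCoords:
    def test_pixel_centres_h2(self):
        coords = fa.level_coords(2, 2)
        np.testing.assert_allclose(coords[:, :, 0],
                                   [[0.25, 0.25], [0.75, 0.75]])
        np.testing.assert_allclose(coords[:, :, 1],
                                   [[0.25, 0.75], [0.25, 0.75]])

    def test_side8_has_64_interior_coords(self):
        coords = fa.level_coords(8, 8).reshape(-1, 2)
        assert coords.shape == (64, 2)
        assert (coords > 0).all() and (coords < 1).all()


class TestNearestLatent:
    def test_query_at_code_coordinate(self, rng):
        grid = random_grids(rng)[0]
        near = fa.nearest_latent(grid, grid.coords[5, 9])
        assert near.index == (5, 9)
        np.testing.assert_array_equal(near.delta, 0.0)
        np.testing.assert_array_equal(near.z_star, grid.codes[:, 5, 9])

    def test_tie_centre_of_four_codes_goes_top_left(self, rng):
        grid = random_grids(rng, sides=(4, 8, 4, 2, 1))[0]
        x_q = np.array([2 / 4, 3 / 4])  # equidistant from rows 1,2 / cols 2,3
        near = fa.nearest_latent(grid, x_q)
        assert near.index == (1, 2)

    @pytest.mark.parametrize("h,w", [(1, 1), (2, 3), (5, 5), (16, 16)])
    def test_matches_brute_force_on_small_grids(self, rng, h, w):
        grid = fa.LatentGrid(codes=rng.normal(0, 1, (3, h, w)),
                             coords=fa.level_coords(h, w), level=1)
        for x_q in rng.uniform(0, 1, (200, 2)):
            near = fa.nearest_latent(grid, x_q)
            assert near.index == brute_force_nearest(grid.coords, x_q)

    def test_thousand_random_queries_match_brute_force(self, rng):
        grid = fa.LatentGrid(codes=rng.normal(0, 1, (2, 9, 13)),
                             coords=fa.level_coords(9, 13), level=1)
        pts = rng.uniform(0, 1, (1000, 2))
        rows, cols = fa.nearest_indices(pts, 9, 13)
        for k in range(1000):
            assert (rows[k], cols[k]) == brute_force_nearest(grid.coords, pts[k])

    def test_delta_bound(self, rng):
        for s in (2, 8, 16):
            grid = fa.LatentGrid(codes=rng.normal(0, 1, (2, s, s)),
                                 coords=fa.level_coords(s, s), level=1)
            for x_q in rng.uniform(0, 1, (100, 2)):
                near = fa.nearest_latent(grid, x_q)
                assert np.all(np.abs(near.delta) <= 0.5 / s + 1e-12)


class TestPositionEncoding:
    def test_zero_offset_gives_sin0_cos1_pattern(self):
        spec = fa.PositionEncodingSpec(L=3)
        enc = fa.position_encode(np.zeros(2), spec)
        np.testing.assert_array_equal(enc[0::2], 0.0)
        np.testing.assert_array_equal(enc[1::2], 1.0)

    def test_quarter_period_first_pair(self):
        spec = fa.PositionEncodingSpec(L=2)
        u = np.pi / (2 * spec.omega[0])
        enc = fa.position_encode(np.array([u, 0.0]), spec)
        assert enc[0] == pytest.approx(1.0, abs=1e-12)  # sin(w1 u) = 1
        assert enc[1] == pytest.approx(0.0, abs=1e-12)  # cos(w1 u) = 0

    def test_matches_independent_formula(self, rng):
        spec = fa.PositionEncodingSpec(L=8)
        delta = rng.uniform(-0.5, 0.5, 2)
        got = fa.position_encode(delta, spec)
        expect = []
        for comp in delta:
            for l in range(1, 9):
                w = 2.0 * np.exp(l)
                expect.extend([np.sin(w * comp), np.cos(w * comp)])
        np.testing.assert_allclose(got, np.array(expect), atol=1e-12)

    def test_output_bounded(self, rng):
        spec = fa.PositionEncodingSpec(L=6)
        enc = fa.position_encode(rng.uniform(-5, 5, (300, 2)), spec)
        assert enc.shape == (300, 24)
        assert np.all(np.abs(enc) <= 1.0)

    def test_frequencies_strictly_increasing(self):
        omega = fa.PositionEncodingSpec(L=5).omega
        assert np.all(np.diff(omega) > 0)


class TestDecode:
    def test_input_width_arithmetic(self):
        spec = fa.PositionEncodingSpec(L=8)
        assert fa.decoder_input_width(64, spec) == 5 * (64 + 32 + 2) == 490

    def test_decode_point_alignment_identity_single_level(self, rng):
        """At a code's own coordinate, an identity read-out returns the code."""
        grids = random_grids(rng, latent_width=4, sides=(6, 8, 4, 2, 1))
        spec = fa.PositionEncodingSpec(L=2)
        d = fa.decoder_input_width(4, spec)
        w = np.zeros((d, 4))
        w[0:4, :] = np.eye(4)  # pick level 1's z slice
        mlp = fa.DecoderMLP(weights=[(w, np.zeros(4))], num_classes=4)
        out = fa.decode_point(grids[0].coords[3, 2], grids, spec, mlp)
        np.testing.assert_array_equal(out, grids[0].codes[:, 3, 2])

    def test_level_order_sensitivity(self, rng):
        grids = random_grids(rng, latent_width=4, sides=(8, 6, 4, 2, 1))
        spec = fa.PositionEncodingSpec(L=2)
        mlp = random_mlp(rng, fa.decoder_input_width(4, spec))
        x_q = np.array([0.4, 0.7])
        base = fa.decode_point(x_q, grids, spec, mlp)
        swapped = [grids[1], grids[0], *grids[2:]]
        out = fa.decode_point(x_q, swapped, spec, mlp)
        assert not np.allclose(base, out)

    def test_decode_grid_equals_pointwise_loop(self, rng):
        grids = random_grids(rng, latent_width=5, sides=(8, 4, 2, 2, 1))
        spec = fa.PositionEncodingSpec(L=3)
        mlp = random_mlp(rng, fa.decoder_input_width(5, spec))
        got = fa.decode_grid(grids, spec, mlp, (9, 7))
        pts = fa.QueryGrid.full_grid((9, 7)).points
        loop = np.array([fa.decode_point(p, grids, spec, mlp) for p in pts])
        np.testing.assert_allclose(got.reshape(-1, 2), loop, atol=1e-5)

    def test_any_resolution_from_same_grids(self, rng):
        grids = random_grids(rng, latent_width=3, sides=(16, 8, 4, 2, 1))
        spec = fa.PositionEncodingSpec(L=2)
        mlp = random_mlp(rng, fa.decoder_input_width(3, spec))
        for shape in ((8, 8), (32, 32), (64, 64)):
            assert fa.decode_grid(grids, spec, mlp, shape).shape == (*shape, 2)

    def test_decoder_is_pure_function_of_query(self, rng):
        """Same coordinates give bitwise-identical outputs regardless of the
        batch they are evaluated in (resolution-consistency of the field)."""
        grids = random_grids(rng, latent_width=3, sides=(8, 4, 2, 2, 1))
        spec = fa.PositionEncodingSpec(L=3)
        mlp = random_mlp(rng, fa.decoder_input_width(3, spec))
        pts = fa.QueryGrid.full_grid((16, 16)).points
        alone = fa.decode_points(pts, grids, spec, mlp)
        again = fa.decode_points(pts.copy(), grids, spec, mlp)
        np.testing.assert_array_equal(alone, again)  # repeatable bitwise
        padded = np.concatenate([rng.uniform(0, 1, (37, 2)), pts])
        together = fa.decode_points(padded, grids, spec, mlp)[37:]
        # batch shape changes BLAS summation order by <= 1 ulp
        np.testing.assert_allclose(together, alone, atol=1e-12)

    def test_mlp_width_mismatch_raises(self, rng):
        grids = random_grids(rng, latent_width=3)
        spec = fa.PositionEncodingSpec(L=2)
        mlp = random_mlp(rng, 99)
        with pytest.raises(ValueError):
            fa.decode_point(np.array([0.5, 0.5]), grids, spec, mlp)


class TestAlignmentIdentityAllLevels:
    def test_codes_reproduced_exactly_at_own_coordinates(self, rng):
        """Decoding at each level's code coordinates with an identity
        read-out reproduces that level's codes with zero interpolation."""
        c = 3
        grids = random_grids(rng, latent_width=c, sides=(16, 8, 4, 2, 1))
        spec = fa.PositionEncodingSpec(L=2)
        block = c + 4 * spec.L + 2
        for i, grid in enumerate(grids):
            w = np.zeros((5 * block, c))
            w[i * block: i * block + c, :] = np.eye(c)
            mlp = fa.DecoderMLP(weights=[(w, np.zeros(c))], num_classes=c)
            pts = grid.coords.reshape(-1, 2)
            out = fa.decode_points(pts, grids, spec, mlp)
            h, wd = grid.codes.shape[1:]
            expect = grid.codes.reshape(c, h * wd).T
            np.testing.assert_array_equal(out, expect)


class TestPredictMask:
    def test_all_background(self):
        logits = np.stack([np.ones((4, 4)), np.zeros((4, 4))], axis=-1)
        assert not fa.predict_mask(logits).pixels.any()

    def test_tie_goes_to_class_zero(self):
        logits = np.zeros((3, 3, 2))
        assert not fa.predict_mask(logits).pixels.any()

    def test_matches_elementwise_argmax(self, rng):
        logits = rng.normal(0, 1, (6, 5, 2))
        got = fa.predict_mask(logits).pixels
        expect = (logits[..., 1] > logits[..., 0]).astype(np.uint8)
        np.testing.assert_array_equal(got, expect)


class TestProjection:
    def _pyramid(self, rng, side=32):
        maps = []
        for i, s in enumerate((2, 4, 8, 16, 32)):
            maps.append(FeatureMap(values=rng.normal(0, 1, (4, side // s, side // s)),
                                   level=i + 1, stride=s))
        return FeaturePyramid(maps)

    def test_identity_projection_preserves_features(self, rng):
        pyr = self._pyramid(rng)
        grids = fa.project_to_latents(pyr, fa.identity_projections(pyr))
        for g, f in zip(grids, pyr.levels):
            np.testing.assert_allclose(g.codes, f.values, atol=1e-12)

    def test_coordinates_are_pixel_centres(self, rng):
        pyr = self._pyramid(rng)
        grids = fa.project_to_latents(pyr, fa.identity_projections(pyr))
        g = grids[-1]  # side 1 grid: single centred code
        np.testing.assert_allclose(g.coords[0, 0], [0.5, 0.5])
        g0 = grids[0]
        np.testing.assert_allclose(g0.coords[0, 0],
                                   [0.5 / 16, 0.5 / 16])
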