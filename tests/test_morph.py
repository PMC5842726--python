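"""Unit and property tests for the morphological primitives, each against a
brute-force oracle or an independent library implementation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from hemoseg.morph import (
    ConstantImageError,
    euclidean_distance_transform,
    fill_holes,
    h_minima,
    impose_minima,
    label_components,
    otsu_threshold,
    reconstruct_by_erosion,
    regional_maxima,
    regional_minima,
    sobel_gradient,
    watershed,
)


# ---------------------------------------------------------------- oracles
def otsu_sweep_oracle(img: np.ndarray) -> int:
    """Exhaustive 256-threshold between-class variance sweep."""
    v = np.round(np.asarray(img, dtype=float)).ravel()
    best_t, best_s = None, -1.0
    for t in range(256):
        lo, hi = v[v <= t], v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / v.size, hi.size / v.size
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s + 1e-12:
            best_s, best_t = s, t
    return best_t


def edt_brute_force(mask: np.ndarray) -> np.ndarray:
    """O(N^2) nearest-background search."""
    m = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~m)
    out = np.zeros(m.shape)
    for y, x in np.argwhere(m):
        out[y, x] = np.sqrt(((bg - (y, x)) ** 2).sum(axis=1).min())
    return out


def regional_maxima_brute(img: np.ndarray) -> np.ndarray:
    """Plateau flood: a plateau is a maximum iff no neighbour is higher."""
    a = np.asarray(img, dtype=float)
    out = np.zeros(a.shape, dtype=bool)
    H, W = a.shape
    seen = np.zeros(a.shape, dtype=bool)
    for y0, x0 in np.ndindex(H, W):
        if seen[y0, x0]:
            continue
        stack, plateau, is_max = [(y0, x0)], [], True
        seen[y0, x0] = True
        while stack:
            y, x = stack.pop()
            plateau.append((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (dy or dx) and 0 <= ny < H and 0 <= nx < W:
                        if a[ny, nx] > a[y0, x0]:
                            is_max = False
                        elif a[ny, nx] == a[y0, x0] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
        if is_max:
            for p in plateau:
                out[p] = True
    return out


# ------------------------------------------------------------------ otsu
class TestOtsu:
    def test_constant_image_has_no_threshold(self):
        with pytest.raises(ConstantImageError):
            otsu_threshold(np.full((4, 4), 7))

    def test_smallest_threshold_tie_break(self):
        # any t in 2..7 separates {1,1,2} from {8,9,9}; smallest wins
        img = np.array([[1, 1, 2], [8, 9, 9]])
        assert otsu_threshold(img) == 2
        assert otsu_sweep_oracle(img) == 2

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_sweep(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16))
        assert otsu_threshold(img) == otsu_sweep_oracle(img)


# ----------------------------------------------------------------- sobel
class TestSobel:
    def test_constant_image_is_flat(self):
        assert np.all(sobel_gradient(np.full((5, 7), 42.0)) == 0)

    def test_vertical_step_peaks_on_step(self):
        img = np.zeros((9, 10))
        img[:, 5:] = 255.0
        g = sobel_gradient(img)
        assert np.argmax(g[4]) in (4, 5)
        assert g[4, 0] == 0 and g[4, -1] == 0

    def test_nonnegative_and_matches_scipy(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (12, 15))
        g = sobel_gradient(img)
        assert (g >= 0).all()
        ref = np.hypot(
            ndimage.sobel(img, axis=1, mode="nearest"),
            ndimage.sobel(img, axis=0, mode="nearest"),
        )
        np.testing.assert_allclose(g, ref, rtol=1e-12)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            sobel_gradient(np.zeros((2, 5)))


# ------------------------------------------------------------------- edt
class TestEDT:
    def test_all_background_is_zero(self):
        assert np.all(euclidean_distance_transform(np.zeros((4, 6), bool)) == 0)

    def test_row_profile(self):
        mask = np.array([[0, 1, 1, 1, 0]], dtype=bool)
        np.testing.assert_allclose(
            euclidean_distance_transform(mask), [[0, 1, 2, 1, 0]]
        )

    def test_all_foreground_raises(self):
        with pytest.raises(ValueError):
            euclidean_distance_transform(np.ones((3, 3), bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((20, 20)) < 0.7
        d = euclidean_distance_transform(mask)
        np.testing.assert_allclose(d, edt_brute_force(mask), atol=1e-9)
        np.testing.assert_allclose(d, ndimage.distance_transform_edt(mask), atol=1e-9)


# ------------------------------------------------------------ fill_holes
class TestFillHoles:
    def test_solid_disc_unchanged(self):
        yy, xx = np.mgrid[:15, :15]
        disc = (yy - 7) ** 2 + (xx - 7) ** 2 <= 25
        assert np.array_equal(fill_holes(disc), disc)

    def test_annulus_becomes_disc(self):
        yy, xx = np.mgrid[:15, :15]
        r2 = (yy - 7) ** 2 + (xx - 7) ** 2
        ring = (r2 <= 36) & (r2 >= 9)
        filled = fill_holes(ring)
        assert np.array_equal(filled, r2 <= 36)
        assert np.array_equal(filled, ndimage.binary_fill_holes(ring))

    def test_border_open_cavity_preserved(self):
        # U-shape: cavity opens to the top border, must stay background
        m = np.ones((5, 5), bool)
        m[:4, 2] = False
        out = fill_holes(m)
        assert not out[:4, 2].any()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = rng.random((20, 20)) < 0.5
        once = fill_holes(m)
        assert np.array_equal(fill_holes(once), once)


# ------------------------------------------------------- regional extrema
class TestRegionalExtrema:
    @pytest.mark.parametrize(
        "row, expect",
        [
            ([1, 3, 2], [False, True, False]),
            ([1, 3, 3, 1], [False, True, True, False]),
        ],
    )
    def test_1d_profiles(self, row, expect):
        out = regional_maxima(np.array([row], dtype=float))
        assert out.tolist() == [expect]

    def test_constant_image_is_one_maximum(self):
        assert regional_maxima(np.full((4, 5), 2.0)).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_plateau_flood_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 6, (12, 12)).astype(float)
        assert np.array_equal(regional_maxima(img), regional_maxima_brute(img))

    def test_minima_are_maxima_of_negation(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 9, (10, 10)).astype(float)
        assert np.array_equal(regional_minima(img), regional_maxima(-img))


# --------------------------------------------------------- reconstruction
FIXTURE_1D = np.array([[9.0, 4.0, 9.0, 8.0, 9.0]])


class TestReconstructionByErosion:
    def test_hand_computed_fixture(self):
        out = reconstruct_by_erosion(FIXTURE_1D + 3, FIXTURE_1D)
        np.testing.assert_allclose(out, [[9, 7, 9, 9, 9]])

    def test_marker_equal_mask_is_fixpoint(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 10, (8, 8))
        np.testing.assert_allclose(reconstruct_by_erosion(f, f), f)

    def test_bounds_and_idempotence(self):
        rng = np.random.default_rng(5)
        mask = rng.uniform(0, 10, (10, 10))
        marker = mask + rng.uniform(0, 5, (10, 10))
        out = reconstruct_by_erosion(marker, mask)
        assert np.all(out >= mask - 1e-12) and np.all(out <= marker + 1e-12)
        np.testing.assert_allclose(reconstruct_by_erosion(out, out), out)

    def test_invalid_marker_raises(self):
        with pytest.raises(ValueError):
            reconstruct_by_erosion(FIXTURE_1D - 1, FIXTURE_1D)

    def test_matches_skimage(self):
        from skimage.morphology import reconstruction

        rng = np.random.default_rng(9)
        mask = rng.uniform(0, 10, (15, 15))
        marker = mask + rng.uniform(0, 4, (15, 15))
        ours = reconstruct_by_erosion(marker, mask)
        ref = reconstruction(marker, mask, method="erosion")
        np.testing.assert_allclose(ours, ref)


# ---------------------------------------------------------------- h-minima
class TestHMinima:
    def test_hand_fixture_depth_filter(self):
        # the depth-1 basin at 8 is filled; the depth-5 basin at 4 survives
        np.testing.assert_allclose(h_minima(FIXTURE_1D, 3.0), [[9, 7, 9, 9, 9]])

    def test_monotone_ramp_keeps_shape(self):
        ramp = np.arange(10.0)[None, :]
        out = h_minima(ramp, 2.0)
        # single border basin is raised; differences elsewhere preserved
        assert np.all(np.diff(out[0]) >= 0)

    def test_nonpositive_t_rejected(self):
        with pytest.raises(ValueError):
            h_minima(FIXTURE_1D, 0.0)

    @given(
        hnp.arrays(
            np.float64,
            (8, 8),
            elements=st.integers(0, 20).map(float),
        ),
        st.sampled_from([1.0, 2.5, 4.0]),
    )
    @settings(max_examples=25, deadline=None)
    def test_bounds_property(self, img, t):
        out = h_minima(img, t)
        assert np.all(out >= img - 1e-12)
        assert np.all(out - img <= t + 1e-12)

    def test_composition_law(self):
        # applying twice with depth t equals applying once with 2t: the
        # transform is *not* idempotent (surviving basins keep depth h - t)
        rng = np.random.default_rng(2)
        img = rng.integers(0, 30, (15, 15)).astype(float)
        np.testing.assert_allclose(
            h_minima(h_minima(img, 3.0), 3.0), h_minima(img, 6.0)
        )

    def test_strictly_deep_minima_survive(self):
        from hemoseg.segment import basin_depth

        rng = np.random.default_rng(11)
        img = rng.integers(0, 30, (15, 15)).astype(float)
        t = 3.0
        out_minima = regional_minima(h_minima(img, t))
        lab, n = label_components(regional_minima(img))
        checked = 0
        for k in range(1, n + 1):
            comp = lab == k
            if basin_depth(img, comp) > t:
                assert out_minima[comp].all()
                checked += 1
        assert checked > 0


# ----------------------------------------------------------- imposition
class TestImposeMinima:
    def test_whole_image_marker_is_constant(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 9, (6, 6))
        out = impose_minima(img, np.ones((6, 6), bool))
        assert np.unique(out).size == 1

    def test_1d_erases_unmarked_minimum(self):
        img = np.array([[5.0, 1.0, 5.0, 1.0, 5.0]])
        markers = np.zeros((1, 5), bool)
        markers[0, 1] = True
        out = impose_minima(img, markers)
        assert np.array_equal(regional_minima(out), markers)

    def test_empty_markers_rejected(self):
        with pytest.raises(ValueError):
            impose_minima(np.zeros((3, 3)), np.zeros((3, 3), bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_minima_components_biject_with_markers(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 50, (20, 20)).astype(float)
        markers = rng.random((20, 20)) < 0.05
        if not markers.any():
            markers[3, 3] = True
        out = impose_minima(img, markers)
        rmin = regional_minima(out)
        _, n_min = label_components(rmin)
        _, n_mark = label_components(markers)
        assert n_min == n_mark
        # every marker component contains a minimum and vice versa
        assert np.array_equal(rmin & markers, markers & rmin)
        assert (rmin == markers).all()


# ------------------------------------------------------------- watershed
class TestWatershed:
    def test_single_marker_floods_everything(self):
        rng = np.random.default_rng(0)
        topo = rng.uniform(0, 9, (8, 8))
        markers = np.zeros((8, 8), int)
        markers[4, 4] = 1
        labels, ridge = watershed(topo, markers)
        assert (labels == 1).all() and not ridge.any()

    def test_1d_two_seeds_meet_at_barrier(self):
        topo = np.array([[0.0, 9.0, 0.0]])
        markers = np.array([[1, 0, 2]])
        labels, ridge = watershed(topo, markers)
        assert labels[0, 0] == 1 and labels[0, 2] == 2
        assert ridge[0, 1] and labels[0, 1] == 0

    def test_no_markers_rejected(self):
        with pytest.raises(ValueError):
            watershed(np.zeros((3, 3)), np.zeros((3, 3), int))

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_connectivity_and_label_count(self, seed):
        rng = np.random.default_rng(seed)
        topo = rng.integers(0, 40, (24, 24)).astype(float)
        markers = np.zeros((24, 24), int)
        pts = rng.integers(0, 24, size=(4, 2))
        for i, (y, x) in enumerate(np.unique(pts, axis=0), start=1):
            markers[y, x] = i
        n_seeds = markers.max()
        labels, ridge = watershed(topo, markers)
        # non-ridge pixels all labelled; seed count preserved
        assert np.array_equal(labels > 0, ~ridge)
        assert set(np.unique(labels[labels > 0])) == set(range(1, n_seeds + 1))
        for k in range(1, n_seeds + 1):
            _, n_comp = label_components(labels == k)
            assert n_comp == 1
            assert (labels[markers == k] == k).all()

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        topo = rng.uniform(0, 10, (20, 20))
        markers = np.zeros((20, 20), int)
        markers[2, 2], markers[17, 15] = 1, 2
        l1, r1 = watershed(topo, markers)
        l2, r2 = watershed(topo, markers)
        assert np.array_equal(l1, l2) and np.array_equal(r1, r2)
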