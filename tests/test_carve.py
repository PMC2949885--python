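import numpy as np
import pytest

from cellcarve.attention import EllipseWindow, rasterize_ellipses
from cellcarve.carve import (
    Seam,
    auto_target_size,
    build_cost_matrix,
    find_min_seam,
    forward_costs,
    gradient_energy,
    local_energy,
    remove_seam,
    replay_seams,
    resize,
)
from cellcarve.exceptions import InvalidInputError, NoAttentionWindowsError


# ---------------------------------------------------------------- oracles

def p_oracle(e):
    """Independent L1 central-difference gradient (one-sided at borders)."""
    e = np.asarray(e, float)
    h, w = e.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            if 0 < j < w - 1:
                gx = (e[i, j + 1] - e[i, j - 1]) / 2
            elif j == 0:
                gx = e[i, 1] - e[i, 0] if w > 1 else 0.0
            else:
                gx = e[i, -1] - e[i, -2]
            if 0 < i < h - 1:
                gy = (e[i + 1, j] - e[i - 1, j]) / 2
            elif i == 0:
                gy = e[1, j] - e[0, j] if h > 1 else 0.0
            else:
                gy = e[-1, j] - e[-2, j]
            out[i, j] = abs(gx) + abs(gy)
    return out


def step_cost_oracle(e, i, j, j_prev):
    h, w = e.shape
    cu = abs(e[i, j + 1] - e[i, j - 1]) if 0 < j < w - 1 else 0.0
    if j_prev == j - 1:
        return cu + (abs(e[i - 1, j] - e[i, j - 1]) if j > 0 else 0.0)
    if j_prev == j + 1:
        return cu + (abs(e[i - 1, j] - e[i, j + 1]) if j < w - 1 else 0.0)
    return cu


def brute_force_min_path(e):
    """Exhaustive enumeration of all monotone 8-connected column paths."""
    e = np.asarray(e, float)
    h, w = e.shape
    p = p_oracle(e)
    best_cost, best_path = np.inf, None
    for start in range(w):
        stack = [(0, start, p[0, start], (start,))]
        while stack:
            i, j, cost, path = stack.pop()
            if cost >= best_cost:
                continue
            if i == h - 1:
                if cost < best_cost:
                    best_cost, best_path = cost, path
                continue
            for nj in (j - 1, j, j + 1):
                if 0 <= nj < w:
                    c2 = cost + p[i + 1, nj] + step_cost_oracle(e, i + 1,
                                                                nj, j)
                    stack.append((i + 1, nj, c2, path + (nj,)))
    return best_cost, best_path


def seam_cost(e, path):
    p = p_oracle(e)
    total = p[0, path[0]]
    for i in range(1, len(path)):
        total += p[i, path[i]] + step_cost_oracle(e, i, path[i], path[i - 1])
    return total


# ---------------------------------------------------------------- tests

class TestForwardCosts:
    def test_constant_is_zero(self):
        e = np.full((5, 5), 7.0)
        sc = forward_costs(e, 2, 2)
        assert (sc.cL, sc.cU, sc.cR) == (0.0, 0.0, 0.0)

    def test_hand_case(self):
        e = np.zeros((3, 3))
        e[1, 2], e[1, 0], e[0, 1] = 10.0, 4.0, 7.0
        sc = forward_costs(e, 1, 1)
        assert sc.cU == pytest.approx(6.0)
        assert sc.cL == pytest.approx(6.0 + abs(7.0 - 4.0))
        assert sc.cR == pytest.approx(6.0 + abs(7.0 - 10.0))

    def test_left_border_policy(self, rng):
        e = rng.uniform(size=(4, 5))
        sc = forward_costs(e, 2, 0)
        # both cU's difference and cL's extra term reference j-1 -> 0
        assert sc.cU == 0.0 and sc.cL == 0.0
        assert sc.cR == pytest.approx(abs(e[1, 0] - e[2, 1]))

    def test_out_of_range_pixel_rejected(self):
        with pytest.raises(InvalidInputError):
            forward_costs(np.zeros((3, 3)), 3, 0)


class TestCostMatrix:
    def test_single_row_equals_local_term(self, rng):
        e = rng.uniform(size=(1, 7))
        m = build_cost_matrix(e)
        assert np.allclose(m.values, p_oracle(e))

    def test_constant_is_zero(self):
        m = build_cost_matrix(np.full((6, 6), 3.0))
        assert np.allclose(m.values, 0.0)

    def test_numba_and_numpy_paths_agree(self, rng):
        for _ in range(10):
            e = rng.uniform(0, 255, size=rng.integers(2, 12, size=2))
            fast = build_cost_matrix(e, use_numba=True)
            slow = build_cost_matrix(e, use_numba=False)
            assert np.allclose(fast.values, slow.values)
            assert np.array_equal(fast.backpointers, slow.backpointers)

    @pytest.mark.parametrize("shape", [(4, 4), (6, 6), (5, 3)])
    def test_dp_matches_bruteforce(self, shape, rng):
        for _ in range(5):
            e = rng.uniform(0, 10, size=shape)
            m = build_cost_matrix(e)
            expected, _ = brute_force_min_path(e)
            assert m.values[-1].min() == pytest.approx(expected)

    def test_recurrence_row0(self, rng):
        e = rng.uniform(size=(5, 6))
        m = build_cost_matrix(e)
        assert np.allclose(m.values[0], local_energy(e)[0])


class TestFindMinSeam:
    def test_zero_valley_column(self):
        # V-shaped field: zero-cost corridor down column 3, costly borders
        e = np.tile(100.0 * np.abs(np.arange(7) - 3), (8, 1))
        seam = find_min_seam(build_cost_matrix(e))
        assert np.all(seam.path == 3)
        expected_cost, expected_path = brute_force_min_path(e)
        assert expected_path == (3,) * 8
        assert expected_cost == pytest.approx(0.0)

    def test_tie_leftmost(self):
        seam = find_min_seam(build_cost_matrix(np.zeros((5, 5))))
        assert np.all(seam.path == 0)

    def test_single_column(self):
        seam = find_min_seam(build_cost_matrix(np.ones((6, 1))))
        assert np.all(seam.path == 0)

    def test_seam_cost_matches_oracle(self, rng):
        for _ in range(10):
            e = rng.uniform(0, 50, size=(6, 6))
            m = build_cost_matrix(e)
            seam = find_min_seam(m)
            assert seam_cost(e, seam.path) == pytest.approx(
                m.values[-1].min())

    def test_monotone_invariant(self, rng):
        e = rng.uniform(size=(30, 20))
        seam = find_min_seam(build_cost_matrix(e))
        assert np.abs(np.diff(seam.path)).max() <= 1


class TestRemoveSeam:
    def test_middle_column(self):
        img = np.arange(27).reshape(3, 3, 3)
        seam = Seam("vertical", np.array([1, 1, 1]))
        out = remove_seam(img, seam)
        assert np.array_equal(out, img[:, [0, 2]])

    def test_carve_to_single_column(self, rng):
        img = rng.integers(0, 255, (6, 5, 3), dtype=np.uint8)
        for _ in range(4):
            seam = find_min_seam(build_cost_matrix(
                gradient_energy(img)))
            img = remove_seam(img, seam)
        assert img.shape == (6, 1, 3)

    def test_pixel_conservation(self, rng):
        img = rng.integers(0, 255, (10, 12, 3), dtype=np.uint8)
        seam = find_min_seam(build_cost_matrix(gradient_energy(img)))
        out = remove_seam(img, seam)
        assert out.size == img.size - 10 * 3

    def test_horizontal_seam(self, rng):
        img = rng.integers(0, 255, (8, 10, 3), dtype=np.uint8)
        seam = Seam("horizontal", np.full(10, 2))
        out = remove_seam(img, seam)
        assert out.shape == (7, 10, 3)
        assert np.array_equal(out[:2], img[:2])
        assert np.array_equal(out[2:], img[3:])

    def test_bad_seam_rejected(self):
        with pytest.raises(InvalidInputError):
            remove_seam(np.zeros((4, 4, 3)),
                        Seam("vertical", np.array([0, 0])))

    def test_nonconnected_path_rejected(self):
        with pytest.raises(InvalidInputError):
            Seam("vertical", np.array([0, 2, 0]))


class TestGradientEnergy:
    def test_constant_zero(self):
        assert np.allclose(gradient_energy(np.full((8, 8, 3), 50,
                                                   np.uint8)), 0.0)

    def test_linear_ramp_interior_one(self):
        ramp = np.tile(np.arange(10, dtype=float), (8, 1))
        e = local_energy(ramp)
        assert np.allclose(e, 1.0)

    def test_vertical_step_edge_maxima(self):
        chan = np.zeros((6, 10))
        chan[:, 5:] = 8.0
        e = local_energy(chan)
        cols = e.mean(axis=0)
        assert set(np.argsort(cols)[-2:]) == {4, 5}


class TestAutoTarget:
    def test_single_eaw_span(self):
        e = EllipseWindow(cx=200, cy=300, rx=100, ry=50)
        h_t, w_t = auto_target_size([e], (600, 800), margin=10)
        assert w_t == 220
        assert h_t == 120

    def test_full_width_clamps(self):
        e = EllipseWindow(cx=400, cy=300, rx=400, ry=300)
        h_t, w_t = auto_target_size([e], (600, 800), margin=10)
        assert (h_t, w_t) == (600, 800)

    def test_two_eaws_union_vs_projection(self):
        eaws = [EllipseWindow(cx=100, cy=100, rx=50, ry=50),
                EllipseWindow(cx=650, cy=100, rx=50, ry=50)]
        _, w_union = auto_target_size(eaws, (600, 800), margin=10,
                                      policy="union-span")
        _, w_proj = auto_target_size(eaws, (600, 800), margin=10,
                                     policy="projection")
        assert w_union == 650 + 20  # bounding span of columns 50..700
        assert w_proj == 200 + 20   # only EAW-covered columns

    def test_no_eaws_raises(self):
        with pytest.raises(NoAttentionWindowsError):
            auto_target_size([], (100, 100))


class TestResize:
    def test_identity_target(self, rng):
        img = rng.integers(0, 255, (20, 30, 3), dtype=np.uint8)
        out, seams = resize(img, (20, 30), energy="gradient")
        assert np.array_equal(out, img) and seams == []

    def test_constant_image_any_target(self):
        img = np.full((24, 30, 3), 77, dtype=np.uint8)
        out, seams = resize(img, (15, 18), energy="gradient")
        assert out.shape == (15, 18, 3)
        assert np.all(out == 77)
        assert len(seams) == (24 - 15) + (30 - 18)

    def test_enlargement_unsupported(self):
        with pytest.raises(InvalidInputError):
            resize(np.zeros((10, 10, 3)), (12, 10), energy="gradient")

    def test_ssm_requires_map(self):
        with pytest.raises(InvalidInputError):
            resize(np.zeros((10, 10, 3)), (8, 8), energy="ssm")

    def test_each_removal_changes_one_dim(self, rng):
        img = rng.integers(0, 255, (16, 20, 3), dtype=np.uint8)
        out, seams = resize(img, (12, 14), energy="gradient")
        n_v = sum(s.orientation == "vertical" for s in seams)
        n_h = sum(s.orientation == "horizontal" for s in seams)
        assert (n_v, n_h) == (6, 4)
        assert out.shape == (12, 14, 3)

    def test_seam_avoidance_of_plateau(self):
        h, w = 40, 60
        e = np.zeros((h, w))
        ell = EllipseWindow(cx=30, cy=20, rx=12, ry=15)
        plateau = rasterize_ellipses([ell], (h, w))
        e[plateau] = 1000.0
        img = np.zeros((h, w, 3), dtype=np.uint8)
        img[plateau] = 200
        out, seams = resize(img, (h, w - 10), energy="ssm", energy_map=e)
        survived, _, _ = replay_seams((h, w), seams)
        assert np.all(survived[plateau])

    def test_shape_idempotence(self, rng):
        img = rng.integers(0, 255, (18, 22, 3), dtype=np.uint8)
        once, _ = resize(img, (14, 16), energy="gradient")
        twice, seams = resize(once, (14, 16), energy="gradient")
        assert np.array_equal(once, twice) and seams == []

    def test_non_seam_values_preserved(self, rng):
        img = rng.integers(0, 255, (15, 17, 3), dtype=np.uint8)
        out, seams = resize(img, (11, 12), energy="gradient")
        survived, rows, cols = replay_seams((15, 17), seams)
        assert np.array_equal(out, img[rows, cols])
        assert survived.sum() == 11 * 12


class TestReplay:
    def test_roundtrip_with_dict_log(self, rng):
        img = rng.integers(0, 255, (12, 14, 3), dtype=np.uint8)
        out, seams = resize(img, (10, 11), energy="gradient")
        log = [s.to_dict() for s in seams]
        survived, rows, cols = replay_seams((12, 14), log)
        assert rows.shape == (10, 11)
        assert np.array_equal(out, img[rows, cols])
        assert survived.sum() == 10 * 11
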