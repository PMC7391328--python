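"""Second-order estimators against brute-force oracles and CSR theory."""

import numpy as np
import pytest

from quadpat import (
    PointPattern,
    RGrid,
    Window,
    estimate_intensity,
    estimate_K,
    estimate_pcf,
    gen_matern2,
    make_rgrid,
    simulate_csr,
    stoyan_bandwidth,
)
from quadpat.ppcore import InsufficientPointsError


# --- independent naive oracles -------------------------------------------

def naive_K(p, rgrid):
    """O(n^2) loop re-implementation of the translation-corrected K."""
    out = np.zeros(len(rgrid))
    W = p.window
    for k, r in enumerate(rgrid.values):
        acc = 0.0
        for i in range(p.n):
            for j in range(p.n):
                if i == j:
                    continue
                dx = p.points[i, 0] - p.points[j, 0]
                dy = p.points[i, 1] - p.points[j, 1]
                if np.hypot(dx, dy) <= r:
                    acc += 1.0 / ((W.width - abs(dx)) * (W.height - abs(dy)))
        out[k] = acc * W.area**2 / (p.n * (p.n - 1))
    return out


def naive_pcf(p, rgrid, bw):
    """O(n^2) loop re-implementation of the divisor-d kernel pcf."""
    out = np.zeros(len(rgrid))
    W = p.window
    for k, r in enumerate(rgrid.values):
        acc = 0.0
        for i in range(p.n):
            for j in range(p.n):
                if i == j:
                    continue
                dx = p.points[i, 0] - p.points[j, 0]
                dy = p.points[i, 1] - p.points[j, 1]
                d = np.hypot(dx, dy)
                u = (r - d) / bw
                if abs(u) < 1 and d > 1e-12:
                    kern = 0.75 / bw * (1 - u * u)
                    area = (W.width - abs(dx)) * (W.height - abs(dy))
                    acc += kern / (2 * np.pi * d * area)
        out[k] = acc * W.area**2 / (p.n * (p.n - 1))
    return out


def test_estimators_match_naive_oracle(small_pattern):
    r = make_rgrid(0.5, 0.05)
    np.testing.assert_allclose(
        estimate_K(small_pattern, r).values, naive_K(small_pattern, r),
        rtol=0, atol=1e-12,
    )
    np.testing.assert_allclose(
        estimate_pcf(small_pattern, r).values, naive_pcf(small_pattern, r, 0.05),
        rtol=0, atol=1e-12,
    )


def test_K_zero_below_first_interpoint_distance(unit_window):
    p = PointPattern([[0.4, 0.5], [0.6, 0.5]], unit_window)  # 0.2 m apart
    r = RGrid(np.array([0.05, 0.1]), 0.05)
    assert np.all(estimate_K(p, r).values == 0.0)


def test_K_requires_two_points(unit_window):
    p = PointPattern([[0.5, 0.5]], unit_window)
    with pytest.raises(InsufficientPointsError):
        estimate_K(p, make_rgrid(0.5, 0.05))
    with pytest.raises(InsufficientPointsError):
        estimate_pcf(p, make_rgrid(0.5, 0.05))


def test_K_nondecreasing_and_pcf_nonnegative(csr100):
    r = make_rgrid(0.5, 0.05)
    k = estimate_K(csr100, r).values
    assert np.all(np.diff(k) >= 0)
    assert np.all(estimate_pcf(csr100, r).values >= 0)


def test_csr_means_small(unit_window):
    """Mean K(0.1) ~ pi r^2 and mean g ~ 1 over 150 CSR simulations."""
    r = RGrid(np.array([0.05, 0.1, 0.15, 0.2]), 0.05)
    ks, gs = [], []
    for i in range(150):
        p = simulate_csr(unit_window, 100, np.random.default_rng([11, i]))
        ks.append(estimate_K(p, r).values[1])
        gs.append(estimate_pcf(p, r).values)
    ks, gs = np.array(ks), np.array(gs)
    assert abs(ks.mean() - np.pi * 0.01) <= 3 * ks.std() / np.sqrt(len(ks))
    dev = np.abs(gs.mean(0) - 1.0)
    assert np.all(dev <= 3 * gs.std(0) / np.sqrt(len(gs)))


def test_hardcore_pcf_vanishes_below_inhibition_distance(plot_window):
    h, bw = 0.1, 0.02
    p = gen_matern2(plot_window, 20.0, h, np.random.default_rng(3))
    r = RGrid(np.arange(1, 5) * 0.02, 0.02)  # bins up to 0.08 = h - bw
    g = estimate_pcf(p, r, bw=bw).values
    assert np.all(g[r.values <= h - bw] == 0.0)


def test_pcf_is_derivative_of_K(unit_window):
    """(2 pi r)^-1 dK/dr, by centred differences, tracks g-hat within 10%."""
    p = simulate_csr(unit_window, 500, np.random.default_rng(5))
    fine = make_rgrid(0.3, 0.01)
    k = estimate_K(p, fine).values
    g = estimate_pcf(p, fine, bw=0.02).values
    r = fine.values
    dk = np.gradient(k, r)
    g_from_k = dk / (2 * np.pi * r)
    sel = (r >= 0.05) & (r <= 0.25)
    assert np.all(np.abs(g_from_k[sel] - g[sel]) <= 0.10 * np.abs(g[sel]))


def test_permutation_and_translation_invariance(csr100):
    r = make_rgrid(0.4, 0.05)
    k0, g0 = estimate_K(csr100, r).values, estimate_pcf(csr100, r).values
    perm = np.random.default_rng(0).permutation(csr100.n)
    p2 = PointPattern(csr100.points[perm], csr100.window)
    np.testing.assert_allclose(estimate_K(p2, r).values, k0, atol=1e-12)
    np.testing.assert_allclose(estimate_pcf(p2, r).values, g0, atol=1e-12)
    w = csr100.window
    shifted = Window(w.x_min + 3, w.y_min - 2, w.x_max + 3, w.y_max - 2)
    p3 = PointPattern(csr100.points + [3, -2], shifted)
    np.testing.assert_allclose(estimate_K(p3, r).values, k0, atol=1e-12)
    np.testing.assert_allclose(estimate_pcf(p3, r).values, g0, atol=1e-12)


def test_scale_equivariance(csr100):
    """Scaling everything by c leaves g unchanged and scales K by c^2."""
    c = 3.0
    r = make_rgrid(0.4, 0.05)
    rc = RGrid(r.values * c, r.dr * c)
    w = csr100.window
    pc = PointPattern(
        csr100.points * c, Window(w.x_min * c, w.y_min * c, w.x_max * c, w.y_max * c)
    )
    np.testing.assert_allclose(
        estimate_K(pc, rc).values, c**2 * estimate_K(csr100, r).values, rtol=1e-10
    )
    np.testing.assert_allclose(
        estimate_pcf(pc, rc, bw=c * r.dr).values,
        estimate_pcf(csr100, r).values,
        rtol=1e-10,
    )


# --- intensity surface -----------------------------------------------------

def test_intensity_integrates_to_n(csr100):
    s = estimate_intensity(csr100, bandwidth=0.3)
    assert abs(s.integral - csr100.n) <= 1e-3 * csr100.n


def test_intensity_single_point_peak_and_support(unit_window):
    p = PointPattern([[0.5, 0.5]], unit_window)
    s = estimate_intensity(p, bandwidth=0.2, cell=0.02)
    xs, ys = s.cell_centres()
    iy, ix = np.unravel_index(np.argmax(s.values), s.values.shape)
    assert abs(xs[ix] - 0.5) <= 0.02 and abs(ys[iy] - 0.5) <= 0.02
    gx, gy = np.meshgrid(xs, ys)
    outside = np.hypot(gx - 0.5, gy - 0.5) > 0.2
    assert np.all(s.values[outside] == 0.0)


def test_intensity_recovers_linear_gradient(plot_window):
    """Kernel estimate correlates > 0.9 with a true lambda = 40x/4 surface."""
    from quadpat import gen_gradient_ipp

    corrs = []
    for seed in range(20):
        p = gen_gradient_ipp(plot_window, 0.0, 4.0, np.random.default_rng([21, seed]))
        s = estimate_intensity(p, bandwidth=1.0)
        xs, _ = s.cell_centres()
        true = np.broadcast_to(4.0 * xs, s.values.shape)
        corrs.append(np.corrcoef(true.ravel(), s.values.ravel())[0, 1])
    assert np.mean(corrs) > 0.9


def test_intensity_rejects_empty_pattern(unit_window):
    with pytest.raises(InsufficientPointsError):
        estimate_intensity(PointPattern(np.empty((0, 2)), unit_window))


def test_stoyan_bandwidth(csr100):
    assert stoyan_bandwidth(csr100) == pytest.approx(0.2 / np.sqrt(100))


def test_rgrid_validation():
    with pytest.raises(ValueError):
        RGrid(np.array([0.1, 0.2, 0.4]), 0.1)  # non-uniform
    with pytest.raises(ValueError):
        RGrid(np.array([-0.1, 0.0]), 0.1)  # non-positive
    with pytest.raises(ValueError):
        make_rgrid(2.5, 0.3)  # not an integer number of bins


def test_pattern_rejects_outside_points(unit_window):
    with pytest.raises(ValueError):
        PointPattern([[1.5, 0.5]], unit_window)
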