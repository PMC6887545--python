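"""The four filter metrics, with independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from specfilt import (
    Chromaticity,
    GridMismatchError,
    SigmoidFilterParams,
    compute_filter_metrics,
    gamut_hull_area,
    nd_filter,
    notch_filter,
    sigmoid_filter,
    tristimulus10,
    uv_prime,
    weighted_transmittance,
)
from specfilt.metrics import _check_shared_grid
from specfilt.spectra import SpectralSamples


def brute_force_hull_area(points: np.ndarray) -> float:
    """Independent hull-area oracle for small point sets.

    A point is a hull vertex iff it is not strictly inside the triangle of
    any three other points; vertices are then ordered by angle around the
    centroid and the area taken by the shoelace formula.
    """
    pts = np.asarray(points, float)
    if len(pts) < 3:
        return 0.0

    def in_triangle(p, a, b, c):
        def cross(o, u, v):
            return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])
        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        neg = (d1 < -1e-12) or (d2 < -1e-12) or (d3 < -1e-12)
        pos = (d1 > 1e-12) or (d2 > 1e-12) or (d3 > 1e-12)
        return not (neg and pos)

    hull_pts = []
    for i, p in enumerate(pts):
        others = [pts[j] for j in range(len(pts)) if j != i]
        interior = any(
            in_triangle(p, a, b, c)
            and not any(np.allclose(p, q) for q in (a, b, c))
            for a, b, c in itertools.combinations(others, 3)
        )
        if not interior:
            hull_pts.append(p)
    hull_pts = np.unique(np.array(hull_pts), axis=0)
    if len(hull_pts) < 3:
        return 0.0
    centroid = hull_pts.mean(axis=0)
    order = np.argsort(np.arctan2(hull_pts[:, 1] - centroid[1], hull_pts[:, 0] - centroid[0]))
    h = hull_pts[order]
    x, y = h[:, 0], h[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestWeightedTransmittance:
    def test_constant_filter_passes_its_constant(self, bundle):
        half = nd_filter(0.5, bundle.grid)
        t = weighted_transmittance(half, bundle.d65, bundle.observer.v10)
        assert t == pytest.approx(0.5, abs=1e-12)

    def test_identity_filter_passes_everything(self, bundle):
        one = nd_filter(1.0, bundle.grid)
        for sens in (bundle.observer.v10, bundle.melanopic.s_mel):
            assert weighted_transmittance(one, bundle.d65, sens) == pytest.approx(1.0, abs=1e-12)

    def test_grid_mismatch_raises(self, bundle):
        from specfilt import GridSpec
        coarse = nd_filter(0.5, GridSpec(380, 780, 5))
        with pytest.raises(GridMismatchError):
            weighted_transmittance(coarse, bundle.d65, bundle.observer.v10)

    def test_zero_weighting_raises(self, bundle):
        zero_sens = bundle.d65.with_values(np.zeros(len(bundle.d65)), kind="sensitivity")
        with pytest.raises(ValueError, match="degenerate"):
            weighted_transmittance(nd_filter(0.5, bundle.grid), bundle.d65, zero_sens)

    def test_agrees_with_fine_grid_brute_force(self, bundle):
        """Rectangle-rule value at 1 nm vs an independent 0.1 nm summation with
        linear resampling of the weighting functions."""
        p = SigmoidFilterParams(550.0, 0.9, 0.5)
        filt = sigmoid_filter(p, bundle.grid)
        coarse = weighted_transmittance(filt, bundle.d65, bundle.observer.v10)

        w1 = bundle.grid.wavelengths()
        wf = np.arange(380.0, 780.0001, 0.1)
        d65 = np.interp(wf, w1, bundle.d65.values)
        v10 = np.interp(wf, w1, bundle.observer.v10.values)
        t = p.upper_asymptote / (1.0 + np.exp(-p.slope * (wf - p.lambda0_nm)))
        fine = np.sum(t * d65 * v10) / np.sum(d65 * v10)
        assert coarse == pytest.approx(fine, abs=1e-3)


class TestColorimetry:
    def test_zero_spd_gives_zero_tristimulus(self, bundle):
        zero = bundle.d65.with_values(np.zeros(len(bundle.d65)), kind="power")
        assert tristimulus10(zero, bundle.observer) == (0.0, 0.0, 0.0)

    def test_tristimulus_linear_in_spd(self, bundle):
        X, Y, Z = tristimulus10(bundle.d65, bundle.observer)
        doubled = bundle.d65.with_values(bundle.d65.values * 2.0)
        X2, Y2, Z2 = tristimulus10(doubled, bundle.observer)
        assert (X2, Y2, Z2) == pytest.approx((2 * X, 2 * Y, 2 * Z), rel=1e-12)

    def test_uv_prime_equal_energy_closed_form(self):
        c = uv_prime(1.0, 1.0, 1.0)
        assert c.u_prime == pytest.approx(4.0 / 19.0, abs=1e-15)
        assert c.v_prime == pytest.approx(9.0 / 19.0, abs=1e-15)

    def test_uv_prime_zero_luminance_closed_form(self):
        # X = 1, Z = 1: denominator 4, so u' = 1 and v' = 0 exactly
        c = uv_prime(1.0, 0.0, 1.0)
        assert (c.u_prime, c.v_prime) == (1.0, 0.0)

    def test_uv_prime_projectively_invariant(self):
        a = uv_prime(0.3, 0.5, 0.2)
        b = uv_prime(0.3 * 7.7, 0.5 * 7.7, 0.2 * 7.7)
        assert (a.u_prime, a.v_prime) == pytest.approx((b.u_prime, b.v_prime), rel=1e-12)

    def test_uv_prime_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            uv_prime(0.0, 0.0, 0.0)


class TestHullArea:
    def test_unit_square(self):
        pts = [Chromaticity(0, 0), Chromaticity(1, 0), Chromaticity(1, 1), Chromaticity(0, 1)]
        assert gamut_hull_area(pts) == pytest.approx(1.0, abs=1e-15)

    def test_degenerate_sets_give_zero(self):
        same = [Chromaticity(0.2, 0.3)] * 5
        assert gamut_hull_area(same) == 0.0
        line = [Chromaticity(x, 2 * x) for x in np.linspace(0, 1, 6)]
        assert gamut_hull_area(line) == 0.0
        assert gamut_hull_area([Chromaticity(0.1, 0.1), Chromaticity(0.2, 0.4)]) == 0.0

    @pytest.mark.parametrize("n,seed", [(5, 1), (8, 2), (12, 3), (50, 4)])
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, size=(n, 2))
        expected = brute_force_hull_area(pts)
        got = gamut_hull_area([Chromaticity(*p) for p in pts])
        assert got == pytest.approx(expected, abs=1e-12)


class TestFilterMetrics:
    def test_neutral_density_reference_case(self, bundle):
        """A spectrally flat filter attenuates every mechanism equally and
        leaves all chromaticities untouched."""
        m = compute_filter_metrics(nd_filter(0.1, bundle.grid), bundle)
        assert m.luminous_transmittance == pytest.approx(0.1, abs=1e-12)
        assert m.melanopsin_transmittance == pytest.approx(0.1, abs=1e-12)
        assert abs(m.colour_shift) < 1e-12
        assert m.gamut_ratio == pytest.approx(1.0, abs=1e-12)

    def test_cutoff_attenuates_melanopsin_more_than_luminance(self, bundle):
        for lam0 in (450.0, 500.0, 550.0, 600.0):
            filt = sigmoid_filter(SigmoidFilterParams(lam0, 0.9, 0.5), bundle.grid)
            m = compute_filter_metrics(filt, bundle)
            assert m.melanopsin_transmittance <= m.luminous_transmittance + 1e-9

    def test_narrow_bandpass_collapses_gamut(self, bundle):
        """A 10 nm band-pass at 590 nm drives the white point to the spectral
        locus: huge colour shift, gamut below 1%."""
        w = bundle.grid.wavelengths()
        t = np.where(np.abs(w - 590.0) <= 5.0, 1.0, 0.0)
        bandpass = SpectralSamples(w, t, kind="transmittance", cleaned=True)
        m = compute_filter_metrics(bandpass, bundle)
        assert m.gamut_ratio < 0.01
        assert m.colour_shift > 0.05

    def test_fully_opaque_filter_degenerate_but_finite(self, bundle):
        w = bundle.grid.wavelengths()
        opaque = SpectralSamples(w, np.zeros_like(w), kind="transmittance", cleaned=True)
        m = compute_filter_metrics(opaque, bundle)
        assert m.luminous_transmittance == 0.0
        assert m.degenerate_gamut and m.gamut_ratio == 0.0

    def test_grid_mismatch_rejected(self, bundle):
        from specfilt import GridSpec
        filt = nd_filter(0.5, GridSpec(400, 700, 1))
        with pytest.raises(GridMismatchError):
            compute_filter_metrics(filt, bundle)

    def test_flat_composition_multiplies_transmittances(self, bundle):
        """Composing with a flat filter scales both transmittances exactly;
        composing two non-flat filters does not factorize."""
        sig = sigmoid_filter(SigmoidFilterParams(520.0, 0.9, 0.3), bundle.grid)
        m_sig = compute_filter_metrics(sig, bundle)
        combined = sig.with_values(sig.values * 0.5)
        m_comb = compute_filter_metrics(combined, bundle)
        assert m_comb.luminous_transmittance == pytest.approx(
            0.5 * m_sig.luminous_transmittance, rel=1e-12)
        assert m_comb.melanopsin_transmittance == pytest.approx(
            0.5 * m_sig.melanopsin_transmittance, rel=1e-12)

        notch = notch_filter(480.0, 40.0, 1.0, bundle.grid)
        m_notch = compute_filter_metrics(notch, bundle)
        both = sig.with_values(sig.values * notch.values)
        m_both = compute_filter_metrics(both, bundle)
        assert m_both.melanopsin_transmittance != pytest.approx(
            m_sig.melanopsin_transmittance * m_notch.melanopsin_transmittance, rel=1e-3)

    def test_colour_shift_anticorrelates_with_gamut_across_cutoff_family(self, bundle):
        """Pushing the white point toward the spectral locus shrinks the gamut."""
        shifts, gamuts = [], []
        for lam0 in np.arange(450.0, 601.0, 25.0):
            m = compute_filter_metrics(
                sigmoid_filter(SigmoidFilterParams(lam0, 0.9, 0.5), bundle.grid), bundle)
            shifts.append(m.colour_shift)
            gamuts.append(m.gamut_ratio)
        r = np.corrcoef(shifts, gamuts)[0, 1]
        assert r < 0.0
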