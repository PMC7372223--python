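"""Division-symmetry, ring-position, rCV, gating and rank-test statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu

from sulfodiv import (
    DELTA_CDVB2,
    MW001,
    GateFailure,
    daughter_ratio,
    gate_1n,
    mann_whitney_u,
    measure_ring_images,
    rcv,
    ring_position,
    simulate_cytometry,
    simulate_ring_images,
)


class TestDaughterRatio:
    @pytest.mark.parametrize(
        "a, b, expected", [(100, 100, 1.0), (50, 100, 0.5), (100, 50, 0.5)]
    )
    def test_examples(self, a, b, expected):
        assert daughter_ratio(a, b) == expected

    def test_positive_areas_required(self):
        with pytest.raises(ValueError):
            daughter_ratio(0, 10)

    @given(a=st.floats(0.1, 1e6), b=st.floats(0.1, 1e6),
           c=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant_and_symmetric(self, a, b, c):
        r = daughter_ratio(a, b)
        assert daughter_ratio(b, a) == r
        assert daughter_ratio(c * a, c * b) == pytest.approx(r, rel=1e-9)
        assert 0 < r <= 1


class TestRingPosition:
    def test_centre_scores_one(self):
        assert ring_position(5.0, 0.0, 10.0) == 1.0

    def test_pole_scores_zero(self):
        assert ring_position(0.0, 0.0, 10.0) == 0.0

    def test_quarter_scores_one_third(self):
        assert ring_position(2.5, 0.0, 10.0) == pytest.approx(1.0 / 3.0)

    def test_outside_poles_rejected(self):
        with pytest.raises(ValueError):
            ring_position(11.0, 0.0, 10.0)

    @given(p=st.floats(0.01, 0.99), scale=st.floats(0.1, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, p, scale):
        r1 = ring_position(p, 0.0, 1.0)
        r2 = ring_position(p * scale, 0.0, scale)
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestRcv:
    def test_constant_sample(self):
        assert rcv([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed(self):
        # sd({2,4,6}) = 2, median = 4
        assert rcv([2.0, 4.0, 6.0]) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            rcv([1.0])
        with pytest.raises(ValueError):
            rcv([-1.0, 0.0, 1.0])

    @given(c=st.floats(0.01, 100))
    @settings(max_examples=30, deadline=None)
    def test_scale_and_order_invariance(self, c):
        x = np.array([1.0, 2.0, 3.5, 7.2, 2.2])
        assert rcv(c * x) == pytest.approx(rcv(x), rel=1e-9)
        assert rcv(x[::-1]) == pytest.approx(rcv(x), rel=1e-12)

    def test_monotone_in_generating_dispersion(self):
        t1 = simulate_cytometry(MW001, 10_000, seed=8)
        t2 = simulate_cytometry(DELTA_CDVB2, 10_000, seed=8)
        assert rcv(t2[t2.true_ploidy == 1].size_signal) > rcv(
            t1[t1.true_ploidy == 1].size_signal
        )


class TestGate1N:
    def test_perfectly_separable_mixture(self, rng):
        import pandas as pd

        n = 400
        ploidy = np.where(rng.random(n) < 0.5, 1, 2)
        dna = np.where(ploidy == 1, rng.uniform(90, 110, n),
                       rng.uniform(190, 210, n))
        tab = pd.DataFrame({"size_signal": np.ones(n), "dna_signal": dna,
                            "true_ploidy": ploidy})
        gated = gate_1n(tab)
        assert set(gated.index) == set(tab.index[ploidy == 1])

    def test_standard_mixture_purity(self):
        tab = simulate_cytometry(MW001, 5000, seed=3)
        gated = gate_1n(tab)
        purity = (gated.true_ploidy == 1).mean()
        assert purity >= 0.95
        # and the gate keeps most true 1N events
        assert len(gated) >= 0.8 * (tab.true_ploidy == 1).sum()

    def test_unimodal_input_raises(self, rng):
        import pandas as pd

        n = 500
        dna = 100.0 * np.exp(rng.normal(0, 0.15, n))
        tab = pd.DataFrame({"size_signal": np.ones(n), "dna_signal": dna,
                            "true_ploidy": np.ones(n, int)})
        with pytest.raises(GateFailure):
            gate_1n(tab)

    def test_minimum_events(self):
        tab = simulate_cytometry(MW001, 200, seed=1).head(50)
        with pytest.raises(ValueError):
            gate_1n(tab)


class TestMannWhitney:
    def test_textbook_exact_case(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings as extreme

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0] * 5
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        nx=st.integers(2, 7), ny=st.integers(2, 7),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_branch_matches_independent_enumeration(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=nx)
        y = rng.normal(size=ny)
        u, p = mann_whitney_u(x, y)
        ref = scipy_mwu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 30))
        y = rng.normal(size=rng.integers(3, 30))
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_normal_branch_matches_scipy_asymptotic(self, rng):
        x = rng.normal(0.0, 1.0, 40)
        y = rng.normal(0.4, 1.0, 35)
        u, p = mann_whitney_u(x, y)
        ref = scipy_mwu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_branch_with_ties_matches_scipy(self, rng):
        x = rng.integers(0, 6, 30).astype(float)
        y = rng.integers(1, 7, 25).astype(float)
        u, p = mann_whitney_u(x, y)
        ref = scipy_mwu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestMeasureRingImages:
    def test_central_rings_noise_free(self):
        images, pos = simulate_ring_images(
            20, {"kind": "fixed", "value": 0.5}, seed=2, noise=False
        )
        ms = measure_ring_images(images)
        rhos = np.array([m.position_stat for m in ms])
        assert len(ms) == 20
        assert np.median(rhos) >= 0.95
        for m, p in zip(ms, pos):
            true_rho = min(p, 1 - p) / max(p, 1 - p)
            assert abs(m.position_stat - true_rho) <= 0.05

    def test_polar_band(self):
        images, _ = simulate_ring_images(
            8, {"kind": "fixed", "value": 0.02}, seed=2, noise=False
        )
        ms = measure_ring_images(images)
        assert ms, "polar rings should still be measurable"
        assert np.median([m.position_stat for m in ms]) <= 0.1

    def test_offset_vs_central_rings_significant(self):
        im_c, _ = simulate_ring_images(
            60, {"kind": "gaussian", "mean": 0.5, "sd": 0.03}, seed=5
        )
        im_o, _ = simulate_ring_images(
            60, {"kind": "uniform", "lo": 0.1, "hi": 0.45}, seed=6
        )
        rho_c = [m.position_stat for m in measure_ring_images(im_c)]
        rho_o = [m.position_stat for m in measure_ring_images(im_o)]
        _, p = mann_whitney_u(rho_c, rho_o)
        assert p < 1e-4
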