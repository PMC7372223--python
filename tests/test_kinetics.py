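"""Sigmoid furrow-kinetics fitting, the knee window, and DNA-state scoring."""

import math

import numpy as np
import pytest

from sulfodiv import (
    KNEE_FACTOR,
    classify_dna_state,
    division_window,
    dna_state_timeline,
    fit_sigmoid,
)
from sulfodiv.containers import CellObservation, Nucleoid
from sulfodiv.kinetics import SigmoidFit, _logistic


def _series(w_start=10.0, w_end=2.0, t0=600.0, tau=60.0,
            t_min=0.0, t_max=1200.0, n=41):
    t = np.linspace(t_min, t_max, n)
    return t, _logistic(t, w_start, w_end, t0, tau)


class TestFitSigmoid:
    def test_noiseless_parameter_recovery(self):
        t, w = _series()
        fit = fit_sigmoid(t, w)
        assert fit.converged
        assert fit.w_start == pytest.approx(10.0, rel=1e-4)
        assert fit.w_end == pytest.approx(2.0, rel=1e-4)
        assert fit.t0 == pytest.approx(600.0, rel=1e-4)
        assert fit.tau == pytest.approx(60.0, rel=1e-4)

    def test_constant_series_not_converged(self):
        t = np.linspace(0, 100, 11)
        fit = fit_sigmoid(t, np.full(11, 5.0))
        assert not fit.converged

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_sigmoid([0, 1, 2], [1, 2, 3])
        t, w = _series(n=10)
        t2 = t.copy()
        t2[5] = t2[4]
        with pytest.raises(ValueError):
            fit_sigmoid(t2, w)

    def test_time_translation_equivariance(self):
        t, w = _series()
        f0 = fit_sigmoid(t, w)
        f1 = fit_sigmoid(t + 500.0, w)
        assert f1.t0 == pytest.approx(f0.t0 + 500.0, rel=1e-6)
        assert f1.tau == pytest.approx(f0.tau, rel=1e-6)

    def test_width_scaling_equivariance(self):
        t, w = _series()
        f0 = fit_sigmoid(t, w)
        f2 = fit_sigmoid(t, 3.0 * w)
        assert f2.w_start == pytest.approx(3.0 * f0.w_start, rel=1e-6)
        assert f2.w_end == pytest.approx(3.0 * f0.w_end, rel=1e-6)
        assert f2.t0 == pytest.approx(f0.t0, rel=1e-5)
        assert f2.tau == pytest.approx(f0.tau, rel=1e-5)
        assert f2.rss == pytest.approx(9.0 * f0.rss, abs=1e-9)

    def test_noisy_recovery_t0_and_tau(self):
        # median recovery over seeded replicates at SNR >= 10
        rng = np.random.default_rng(42)
        t, w = _series(n=40)
        frame_interval = t[1] - t[0]
        t0_err, tau_err = [], []
        for _ in range(200):
            fit = fit_sigmoid(t, w + rng.normal(0.0, 0.3, w.size))
            if fit.converged:
                t0_err.append(abs(fit.t0 - 600.0))
                tau_err.append(abs(fit.tau - 60.0) / 60.0)
        assert np.median(t0_err) <= frame_interval
        assert np.median(tau_err) <= 0.15


class TestDivisionWindow:
    def test_closed_form_matches_numerical_curvature_extrema(self, rng):
        # the knees are the extrema of d2w/dt2 of the fitted logistic
        for _ in range(100):
            t0 = rng.uniform(-500, 500)
            tau = rng.uniform(5.0, 300.0)
            tt = np.linspace(t0 - 12 * tau, t0 + 12 * tau, 200_001)
            d2 = np.gradient(np.gradient(_logistic(tt, 1.0, 0.0, t0, tau),
                                         tt), tt)
            lo_num = tt[np.argmax(d2)]
            hi_num = tt[np.argmin(d2)]
            lo_cf = t0 - KNEE_FACTOR * tau
            hi_cf = t0 + KNEE_FACTOR * tau
            scale = max(abs(lo_cf), abs(hi_cf), tau)
            assert abs(min(lo_num, hi_num) - lo_cf) / scale < 1e-3
            assert abs(max(lo_num, hi_num) - hi_cf) / scale < 1e-3

    def test_reference_window_values(self):
        fit = SigmoidFit(w_start=10, w_end=2, t0=600.0, tau=60.0,
                         rss=0.0, window=(0, 0), converged=True)
        lo, hi = division_window(fit)
        assert lo == pytest.approx(600.0 - 60.0 * math.log(2 + math.sqrt(3)))
        assert hi == pytest.approx(600.0 + 60.0 * math.log(2 + math.sqrt(3)))
        assert hi - lo == pytest.approx(2 * KNEE_FACTOR * 60.0)
        assert hi - lo == pytest.approx(158.03, abs=0.01)

    def test_window_symmetric_and_vanishing_tau_limit(self):
        for tau in (120.0, 1.0, 1e-6):
            fit = SigmoidFit(w_start=1, w_end=0, t0=50.0, tau=tau,
                             rss=0.0, window=(0, 0), converged=True)
            lo, hi = division_window(fit)
            assert (lo + hi) / 2 == pytest.approx(50.0)
        assert hi - lo == pytest.approx(2 * KNEE_FACTOR * 1e-6)

    def test_non_converged_rejected(self):
        fit = SigmoidFit(w_start=1, w_end=0, t0=0, tau=1,
                         rss=0.0, window=(0, 0), converged=False)
        with pytest.raises(ValueError):
            division_window(fit)


def _obs(nucleoids, area=150):
    return CellObservation(
        frame=0, label=1, centroid=(0.0, 0.0), area_px=area,
        area_um2=0.0, major_len_px=16, minor_len_px=12,
        orientation_rad=0.0, furrow_width_px=12.0,
        nucleoids=nucleoids, dna_measured=True,
    )


class TestClassifyDnaState:
    def test_single_diffuse(self):
        o = _obs([Nucleoid(90, 0.6, (0, 0))])
        assert classify_dna_state(o) == "single_diffuse"

    def test_compact_separated(self):
        o = _obs([Nucleoid(15, 0.95, (0, 0)), Nucleoid(14, 0.93, (5, 5))])
        assert classify_dna_state(o) == "compact_separated"

    def test_two_diffuse_when_large_or_loose(self):
        o = _obs([Nucleoid(40, 0.95, (0, 0)), Nucleoid(40, 0.95, (5, 5))])
        assert classify_dna_state(o) == "two_diffuse"  # area fraction > 0.25
        o = _obs([Nucleoid(10, 0.7, (0, 0)), Nucleoid(10, 0.95, (5, 5))])
        assert classify_dna_state(o) == "two_diffuse"  # one loose nucleoid

    def test_unclassifiable(self):
        with pytest.raises(ValueError):
            classify_dna_state(_obs([]))

    def test_states_recovered_through_division(self, mw001_noiseless):
        """Pipeline-classified states follow the generating state machine."""
        truth = mw001_noiseless["truth"]
        observations = mw001_noiseless["observations"]
        order = {"single_diffuse": 0, "two_diffuse": 1,
                 "compact_separated": 2}
        checked = 0
        agree = 0
        for cell in truth.cells.values():
            if cell.first_frame != 0:
                continue
            for f in (0, len(cell.dna_state) - 1):
                best = min(
                    observations[f],
                    key=lambda o: np.hypot(
                        *(np.array(o.centroid) - cell.centers[0])
                    ),
                )
                if np.hypot(*(np.array(best.centroid) - cell.centers[0])) > 3:
                    continue
                try:
                    got = classify_dna_state(best)
                except ValueError:
                    continue
                checked += 1
                if got == cell.dna_state[f]:
                    agree += 1
        assert checked >= 10
        assert agree / checked >= 0.9


class TestDnaStateTimeline:
    def test_all_compact(self):
        records = {0: {f: "compact_separated" for f in range(5)}}
        df = dna_state_timeline(records, {0: 2})
        assert (df["frac_compact_separated"] == 1.0).all()

    def test_fractions_sum_to_one(self):
        records = {
            0: {0: "single_diffuse", 1: "two_diffuse",
                2: "compact_separated"},
            1: {0: "two_diffuse", 1: "two_diffuse", 2: "single_diffuse"},
        }
        df = dna_state_timeline(records, {0: 1, 1: 1})
        sums = (
            df["frac_single_diffuse"] + df["frac_two_diffuse"]
            + df["frac_compact_separated"]
        )
        assert np.allclose(sums, 1.0)

    def test_transition_ordering_matches_generator(self, mw001_noiseless):
        truth = mw001_noiseless["truth"]
        records = {}
        onsets = {}
        for e in truth.events:
            cell = truth.cells[e.parent_id]
            records[e.parent_id] = dict(enumerate(cell.dna_state))
            onsets[e.parent_id] = e.onset_frame
        df = dna_state_timeline(records, onsets)
        post = df[df.rel_frame >= 0]
        assert (post["frac_compact_separated"] == 1.0).all()
        # per cell the classes appear in order: single -> two -> compact
        order = {"single_diffuse": 0, "two_diffuse": 1,
                 "compact_separated": 2}
        for states in records.values():
            codes = [order[states[f]] for f in sorted(states)]
            assert codes == sorted(codes)
            assert 1 in codes, "the two-diffuse stage must precede compaction"

    def test_no_onsets_rejected(self):
        with pytest.raises(ValueError):
            dna_state_timeline({0: {0: "single_diffuse"}}, {})
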