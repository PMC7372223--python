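"""Synthetic movie, cytometry and ring-image generators against their truth."""

import numpy as np
import pytest

from sulfodiv import (
    DELTA_CDVB1,
    DELTA_CDVB2,
    MW001,
    StrainPreset,
    simulate_cytometry,
    simulate_movie,
    simulate_ring_images,
)
from sulfodiv.stats import rcv, ring_position


def _symmetric_preset(**overrides):
    base = dict(
        name="sym", p_fail=0.0, offset_sd_frac=0.0, offset_dist="gaussian",
        p_ghost=0.0, tau_s=90.0, division_rate_per_h=10.0,
    )
    base.update(overrides)
    return StrainPreset(**base)


class TestPresetValidation:
    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            StrainPreset(name="bad", p_fail=1.5)

    def test_uniform_needs_range(self):
        with pytest.raises(ValueError):
            StrainPreset(name="bad", p_fail=0.1, offset_dist="uniform")

    def test_uniform_range_bounds(self):
        with pytest.raises(ValueError):
            StrainPreset(
                name="bad", p_fail=0.1, offset_dist="uniform",
                offset_range=(0.2, 0.7),
            )

    def test_effective_offset_sd_uniform(self):
        sd = DELTA_CDVB2.effective_offset_sd
        lo, hi = DELTA_CDVB2.offset_range
        assert sd == pytest.approx((hi - lo) / np.sqrt(12.0))


class TestSimulateMovie:
    def test_determinism_bit_identical(self):
        m1, t1 = simulate_movie(MW001, 4, 10, 30.0, seed=7,
                                field_shape=(120, 120))
        m2, t2 = simulate_movie(MW001, 4, 10, 30.0, seed=7,
                                field_shape=(120, 120))
        assert np.array_equal(m1.frames, m2.frames)
        assert np.array_equal(t1.drift, t2.drift)
        assert len(t1.events) == len(t2.events)
        for a, b in zip(t1.events, t2.events):
            assert (a.parent_id, a.onset_frame, a.separation_frame,
                    a.outcome, a.offset_frac) == \
                   (b.parent_id, b.onset_frame, b.separation_frame,
                    b.outcome, b.offset_frac)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_movie(MW001, 0, 10)
        with pytest.raises(ValueError):
            simulate_movie(MW001, 1, 1)
        with pytest.raises(ValueError):
            simulate_movie(MW001, 1, 10, field_shape=(16, 16))

    def test_overfull_field_warns_and_reduces(self):
        with pytest.warns(UserWarning, match="reducing"):
            _, truth = simulate_movie(
                MW001, 500, 4, 30.0, seed=0, field_shape=(100, 100),
                noise=False, drift_step_sd_px=0.0,
            )
        n_founders = sum(1 for c in truth.cells.values() if c.first_frame == 0)
        assert n_founders < 500

    def test_symmetric_division_yields_equal_daughters(self):
        _, truth = simulate_movie(
            _symmetric_preset(), 1, 50, 30.0, seed=3, field_shape=(96, 96),
            noise=False, drift_step_sd_px=0.0,
        )
        assert len(truth.events) == 1
        ev = truth.events[0]
        assert ev.outcome == "success"
        d1, d2 = (truth.cells[d] for d in ev.daughter_ids)
        a1 = d1.length_px[0] * d1.furrow_width_px[0]
        a2 = d2.length_px[0] * d2.furrow_width_px[0]
        assert abs(a1 - a2) / max(a1, a2) < 0.02

    def test_failure_fraction_matches_preset_on_truth(self):
        # >= 1000 division attempts, checked on the truth sidecar alone
        n_fail = n_tot = 0
        for seed in range(18):
            _, truth = simulate_movie(
                DELTA_CDVB1, 60, 60, 30.0, seed=100 + seed,
                field_shape=(360, 360), channels=("membrane",),
                noise=False, drift_step_sd_px=0.0,
            )
            n_tot += len(truth.events)
            n_fail += sum(1 for e in truth.events if e.outcome == "failure")
        assert n_tot >= 1000
        p_hat = n_fail / n_tot
        half = 2.576 * np.sqrt(0.16 * 0.84 / n_tot)
        assert abs(p_hat - 0.16) < half

    def test_drift_sidecar_is_the_applied_translation(self):
        from sulfodiv import estimate_shift

        movie, truth = simulate_movie(
            MW001, 6, 8, 30.0, seed=11, field_shape=(160, 160),
            noise=False, drift_step_sd_px=0.8,
        )
        mem = movie.channel("membrane")
        for f in (3, 7):
            dy, dx = estimate_shift(mem[0], mem[f])
            assert abs(dy - truth.drift[f, 0]) < 0.25
            assert abs(dx - truth.drift[f, 1]) < 0.25

    def test_membrane_intensity_conserved_across_failure(self):
        preset = _symmetric_preset(name="fail", p_fail=1.0)
        movie, truth = simulate_movie(
            preset, 1, 50, 30.0, seed=5, field_shape=(96, 96),
            noise=False, drift_step_sd_px=0.0,
        )
        assert truth.events and truth.events[0].outcome == "failure"
        mem = movie.channel("membrane")
        before = mem[0].sum()
        after = mem[-1].sum()
        assert abs(after - before) / before < 0.02

    def test_dna_state_sequence_monotone_with_compact_at_onset(self):
        _, truth = simulate_movie(
            MW001, 12, 50, 30.0, seed=2, field_shape=(200, 200),
            noise=False, drift_step_sd_px=0.0,
        )
        order = {"single_diffuse": 0, "two_diffuse": 1, "compact_separated": 2}
        for ev in truth.events:
            states = truth.cells[ev.parent_id].dna_state
            codes = [order[s] for s in states]
            assert codes == sorted(codes), "states must progress monotonically"
            first_compact = codes.index(2)
            assert abs(first_compact - ev.onset_frame) <= 1


class TestSimulateCytometry:
    def test_minimum_events(self):
        with pytest.raises(ValueError):
            simulate_cytometry(MW001, 50)

    def test_degenerate_dispersion_gives_zero_rcv(self):
        preset = _symmetric_preset(name="tight")
        tab = simulate_cytometry(preset, 500, seed=1, size_noise_cv=0.0)
        ones = tab[tab.true_ploidy == 1].size_signal
        assert rcv(ones) == 0.0

    def test_wider_offsets_give_wider_newborn_sizes(self):
        t_wt = simulate_cytometry(MW001, 10_000, seed=4)
        t_mut = simulate_cytometry(DELTA_CDVB2, 10_000, seed=4)
        r_wt = rcv(t_wt[t_wt.true_ploidy == 1].size_signal)
        r_mut = rcv(t_mut[t_mut.true_ploidy == 1].size_signal)
        assert r_mut > r_wt

    def test_determinism_and_schema(self):
        a = simulate_cytometry(MW001, 200, seed=9)
        b = simulate_cytometry(MW001, 200, seed=9)
        assert a.equals(b)
        assert list(a.columns) == ["size_signal", "dna_signal", "true_ploidy"]
        assert (a.size_signal > 0).all() and (a.dna_signal > 0).all()
        assert set(a.true_ploidy.unique()) == {1, 2}


class TestSimulateRingImages:
    def test_central_rings_score_unity(self):
        _, pos = simulate_ring_images(5, {"kind": "fixed", "value": 0.5},
                                      seed=1)
        for p in pos:
            # a ring exactly at mid-cell scores 1 by definition
            assert ring_position(p, 0.0, 1.0) == 1.0

    def test_quarter_position_scores_one_third(self):
        _, pos = simulate_ring_images(3, {"kind": "fixed", "value": 0.25},
                                      seed=1)
        for p in pos:
            assert ring_position(p, 0.0, 1.0) == pytest.approx(1.0 / 3.0)

    def test_boundary_and_validation(self):
        with pytest.raises(ValueError):
            simulate_ring_images(0, {"kind": "fixed", "value": 0.5})
        with pytest.raises(ValueError):
            simulate_ring_images(3, {"kind": "fixed", "value": 1.2})
        with pytest.raises(ValueError):
            simulate_ring_images(3, {"kind": "uniform", "lo": -0.1, "hi": 0.5})
        with pytest.raises(ValueError):
            simulate_ring_images(3, {"kind": "spam"})

    def test_image_shape_and_determinism(self):
        im1, p1 = simulate_ring_images(4, {"kind": "uniform", "lo": 0.2,
                                           "hi": 0.8}, seed=3)
        im2, p2 = simulate_ring_images(4, {"kind": "uniform", "lo": 0.2,
                                           "hi": 0.8}, seed=3)
        assert im1.shape == (4, 2, 64, 64)
        assert np.array_equal(im1, im2) and np.array_equal(p1, p2)
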