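"""Respirometry oracles: slope fits, the uptake equation, trait definitions."""

import numpy as np
import pytest

from scopetrack.respirometry import (
    EmptyTraceError,
    MeasurementCycle,
    MetabolicTraits,
    RespirometryTrace,
    TraitConfig,
    compute_mo2,
    extract_traits,
    segment_cycles,
    traits_from_trace,
)
from scopetrack.synthetic import SimConfig, simulate_respirometry_trace


def _trace_from_phases(phases, **kwargs):
    """Assemble a labelled trace from (duration_s, fn(t_s)->kPa, label) parts."""
    t, o2, lab = [], [], []
    cursor = 0.0
    for dur, fn, label in phases:
        tt = cursor + np.arange(0.0, dur, 5.0)
        t.append(tt)
        o2.append(fn(tt))
        lab.append(np.full(len(tt), label))
        cursor += dur
    defaults = dict(chamber_volume=0.54, body_mass_kg=0.054)
    defaults.update(kwargs)
    return RespirometryTrace(
        fish_id="T",
        time_h=np.concatenate(t) / 3600.0,
        o2_kpa=np.concatenate(o2),
        phase=np.concatenate(lab),
        **defaults,
    )


class TestSegmentCycles:
    def test_exact_line_recovers_slope(self):
        """o2(t) = 20 - 2t kPa/h gives slope_k = 2, r2 = 1."""
        trace = _trace_from_phases(
            [(600.0, lambda ts: 20.0 - 2.0 * ts / 3600.0, "measure")]
        )
        (cycle,) = segment_cycles(trace)
        assert cycle.slope_k == pytest.approx(2.0, rel=1e-12)
        assert cycle.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_noise_phase_has_no_fit(self):
        rng = np.random.default_rng(0)
        trace = _trace_from_phases(
            [(600.0, lambda ts: 19.0 + rng.normal(0, 0.05, len(ts)), "measure")]
        )
        (cycle,) = segment_cycles(trace)
        assert cycle.r_squared < 0.2  # later rejected by the r2 >= 0.9 filter

    def test_leading_clip_skips_mixing_transient(self):
        # a 30 s spike at the phase start must not corrupt the slope
        def o2(ts):
            base = 20.0 - 2.0 * ts / 3600.0
            base[ts < 30.0] += 1.5
            return base

        trace = _trace_from_phases([(600.0, o2, "measure")])
        (cycle,) = segment_cycles(trace, leading_clip_s=30.0)
        assert cycle.slope_k == pytest.approx(2.0, rel=1e-9)

    def test_no_measure_phase_raises(self):
        trace = _trace_from_phases([(300.0, lambda ts: 20.0 + 0 * ts, "flush")])
        with pytest.raises(EmptyTraceError):
            segment_cycles(trace)

    def test_unlabelled_trace_detected_from_rises(self, example_phenotype):
        cfg = SimConfig(n_fish=1, seed=3, sensor_noise_sd=0.0)
        trace = simulate_respirometry_trace(example_phenotype, cfg)
        labelled = segment_cycles(trace)
        trace.phase = np.array([])  # force the unlabelled dialect
        detected = segment_cycles(trace)
        assert len(detected) == len(labelled)
        got = [c.slope_k for c in detected]
        want = [c.slope_k for c in labelled]
        assert np.allclose(got, want, rtol=0.05)

    def test_synthetic_slopes_within_1pct_at_low_noise(self, example_phenotype):
        cfg = SimConfig(n_fish=1, seed=12, sensor_noise_sd=0.005)
        trace = simulate_respirometry_trace(example_phenotype, cfg)
        cycles = segment_cycles(trace)
        truth = (
            trace.true_cycle_mo2
            * trace.body_mass_kg
            / (trace.effective_volume * trace.beta)
            + trace.blank_slope
        )
        rel = np.abs(np.array([c.slope_k for c in cycles]) - truth) / truth
        assert np.max(rel) < 0.01


class TestComputeMo2:
    def _trace(self, **kw):
        return _trace_from_phases(
            [(600.0, lambda ts: 20.0 - ts / 3600.0, "measure")], **kw
        )

    def test_printed_equation_hand_value(self):
        """K=10, V=0.54 l, M=0.054 kg, beta=0.4755 -> 42.795 mg O2/kg/h."""
        cycle = MeasurementCycle(0, 0.1, slope_k=10.0, r_squared=1.0, n_samples=100)
        mo2 = compute_mo2(cycle, self._trace())
        assert mo2 == pytest.approx(10.0 * (0.54 - 0.054) * 0.4755 / 0.054, rel=1e-12)
        assert mo2 == pytest.approx(42.795, abs=1e-3)

    def test_zero_corrected_slope_gives_zero(self):
        cycle = MeasurementCycle(0, 0.1, slope_k=0.0, r_squared=1.0, n_samples=10)
        assert compute_mo2(cycle, self._trace()) == 0.0

    def test_blank_exceeding_slope_clamps_with_warning(self):
        cycle = MeasurementCycle(0, 0.1, slope_k=0.5, r_squared=1.0, n_samples=10)
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_mo2(cycle, self._trace(blank_slope=1.0)) == 0.0

    def test_doubling_mass_halves_mo2_at_fixed_geometry(self):
        cycle = MeasurementCycle(0, 0.1, slope_k=10.0, r_squared=1.0, n_samples=10)
        a = compute_mo2(cycle, self._trace(body_mass_kg=0.04, chamber_volume=0.54))
        # keep V_eff fixed by growing the chamber with the fish
        b = compute_mo2(cycle, self._trace(body_mass_kg=0.08, chamber_volume=0.58))
        assert a == pytest.approx(2.0 * b, rel=1e-12)

    def test_fish_displacing_chamber_is_rejected(self):
        with pytest.raises(ValueError):
            self._trace(body_mass_kg=0.6, chamber_volume=0.54)


def _cycles(mo2_values, times=None, width=0.08):
    times = times if times is not None else np.linspace(0.1, 21.9, len(mo2_values))
    return [
        MeasurementCycle(t - width, t + width, slope_k=1.0, r_squared=1.0,
                         n_samples=50, mo2=m)
        for t, m in zip(times, mo2_values)
    ]


class TestExtractTraits:
    def test_descending_ladder_definitions(self):
        """10 cycles at 100..10: SMR = 10 (lowest decile), MMR = 100."""
        traits = extract_traits(_cycles(list(range(100, 0, -10))), trace_end=22.0)
        assert traits.smr == 10.0
        assert traits.mmr == 100.0
        assert traits.ams == 90.0

    def test_recovery_rate_exact_ols(self):
        """Five collinear cycles, 400..200 over 0.1..0.9 h -> slope -250."""
        cyc = _cycles([400, 350, 300, 250, 200, 150, 150, 150, 150, 150],
                      times=[0.1, 0.3, 0.5, 0.7, 0.9, 5, 9, 13, 17, 21])
        traits = extract_traits(cyc, trace_end=22.0)
        assert traits.recovery_rate == pytest.approx(-250.0, rel=1e-12)

    def test_r2_filter_drops_bad_cycles(self):
        cyc = _cycles([100, 90, 80, 70, 60, 50, 40, 30, 20, 10])
        cyc[0].r_squared = 0.5  # the would-be MMR cycle fails QC
        traits = extract_traits(cyc, trace_end=22.0)
        assert traits.n_rejected == 1
        assert traits.mmr == 90.0

    def test_identities_hold(self, small_cohort, small_sim_config):
        for p in small_cohort:
            trace = simulate_respirometry_trace(p, small_sim_config)
            t = traits_from_trace(trace)
            assert t.ams == pytest.approx(t.mmr - t.smr, rel=1e-12)
            assert t.spont_ams == pytest.approx(t.spont_max - t.spont_min, rel=1e-12)
            assert t.mmr >= t.smr

    def test_smr_monotone_in_percentile(self):
        rng = np.random.default_rng(1)
        cyc = _cycles(rng.uniform(60, 400, 40))
        smrs = [
            extract_traits(cyc, config=TraitConfig(smr_percentile=p),
                           trace_end=22.0).smr
            for p in (5, 10, 20, 50, 100)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(smrs, smrs[1:]))

    def test_invariant_to_resegmentation(self):
        """Traits depend only on the per-cycle (time, mo2) pairs."""
        rng = np.random.default_rng(2)
        vals = rng.uniform(60, 400, 30)
        a = extract_traits(_cycles(vals, width=0.05), trace_end=22.0)
        b = extract_traits(_cycles(vals, width=0.002), trace_end=22.0)
        for name in MetabolicTraits.TRAIT_NAMES:
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)

    def test_too_few_cycles_flag_missing_not_fabricated(self):
        traits = extract_traits(_cycles([100, 50], times=[0.1, 0.4]), trace_end=22.0)
        assert np.isnan(traits.mmr)
        assert np.isnan(traits.recovery_rate)
        assert traits.smr == 50.0  # lowest decile always exists

    def test_sliding_mmr_mode(self):
        cyc = _cycles([100, 350, 400, 390, 100, 90, 80, 70, 60, 50])
        first3 = extract_traits(cyc, config=TraitConfig(mmr_mode="first3"),
                                trace_end=22.0)
        sliding = extract_traits(cyc, config=TraitConfig(mmr_mode="sliding"),
                                 trace_end=22.0)
        assert first3.mmr == 400.0
        assert sliding.mmr == pytest.approx((350 + 400 + 390) / 3.0)


class TestRoundTrip:
    def test_noise_free_trace_recovers_ground_truth(self, example_phenotype):
        """Traits from a noise-free trace equal the generator's own truth."""
        cfg = SimConfig(n_fish=1, seed=21, sensor_noise_sd=0.0)
        trace = simulate_respirometry_trace(example_phenotype, cfg)
        got = traits_from_trace(trace)
        width = cfg.measure_duration / 3600.0 / 2.0
        true_cycles = [
            MeasurementCycle(t - width, t + width, slope_k=1.0, r_squared=1.0,
                             n_samples=10, mo2=m)
            for t, m in zip(trace.true_cycle_time, trace.true_cycle_mo2)
        ]
        want = extract_traits(true_cycles, trace_end=trace.time_h[-1])
        for name in MetabolicTraits.TRAIT_NAMES:
            assert getattr(got, name) == pytest.approx(
                getattr(want, name), rel=1e-6, abs=1e-9
            ), name
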