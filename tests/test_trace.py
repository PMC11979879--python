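"""Trace reduction tests: I/O, drift QC, segmentation, plateaus, metric."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from looselayer import (
    OvertoneTrace,
    PhaseSegment,
    QcmdExperiment,
    StabilityCriteria,
    SyntheticScenario,
    ValidationError,
    add_irreversible_offset,
    assess_baseline,
    bsa_buffer_preset,
    loose_layer_metric,
    mab_panel_preset,
    plateau_value,
    read_qcmd_table,
    sauerbrey_mass,
    segment_phases,
    simulate_qcmd,
    write_qcmd_table,
)


def _flat_experiment(f3_level=0.0, n=1200, extra_overtones=()):
    t = np.arange(float(n))
    traces = {3: OvertoneTrace(3, t, np.full(n, f3_level), np.zeros(n))}
    for m in extra_overtones:
        traces[m] = OvertoneTrace(m, t, np.full(n, f3_level), np.zeros(n))
    return QcmdExperiment(traces=traces)


class TestIO:
    def test_round_trip_bit_exact(self, tmp_path, noisy_trastuzumab):
        exp, _, _ = noisy_trastuzumab
        path = tmp_path / "trace.tsv"
        write_qcmd_table(exp, path)
        back = read_qcmd_table(path)
        assert set(back.traces) == set(exp.traces)
        for n in exp.traces:
            np.testing.assert_array_equal(back.traces[n].delta_f, exp.traces[n].delta_f)
            np.testing.assert_array_equal(back.traces[n].delta_d, exp.traces[n].delta_d)
        assert back.schedule is not None
        assert [s.label for s in back.schedule.segments] == \
            [s.label for s in exp.schedule.segments]

    def test_single_overtone_file(self, tmp_path):
        path = tmp_path / "f3only.tsv"
        path.write_text("time_s\tf3\td3\n0\t0.0\t0.0\n1\t-1.0\t0.1\n2\t-2.0\t0.2\n")
        exp = read_qcmd_table(path)
        assert list(exp.traces) == [3]

    def test_shuffled_time_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time_s\tf3\td3\n0\t0\t0\n2\t-1\t0\n1\t-2\t0\n")
        with pytest.raises(ValidationError):
            read_qcmd_table(path)

    def test_missing_f3_rejected(self, tmp_path):
        path = tmp_path / "nof3.tsv"
        path.write_text("time_s\tf5\td5\n0\t0\t0\n1\t-1\t0\n")
        with pytest.raises(ValidationError):
            read_qcmd_table(path)


class TestBaselineAssessment:
    def test_flat_trace_stable(self):
        exp = _flat_experiment()
        est = assess_baseline(exp.primary, at_time=600.0)
        assert est.stable and est.f_drift == pytest.approx(0.0, abs=1e-12)

    def test_known_slope_flagged(self):
        """0.004 Hz/s drifts 2.4 Hz per 10 min window: unstable."""
        t = np.arange(1200.0)
        tr = OvertoneTrace(3, t, 0.004 * t, np.zeros_like(t))
        est = assess_baseline(tr, at_time=1100.0)
        assert est.f_drift == pytest.approx(2.4, rel=1e-9)
        assert not est.stable

    def test_window_before_start_rejected(self):
        exp = _flat_experiment()
        with pytest.raises(ValidationError):
            assess_baseline(exp.primary, at_time=100.0)

    def test_noise_rarely_flags(self, rng):
        """Pure noise (sigma_f = 0.1 Hz) passes the drift test >= 99% of windows."""
        t = np.arange(601.0)
        stable = 0
        n_trials = 1000
        for _ in range(n_trials):
            tr = OvertoneTrace(3, t, rng.normal(0, 0.1, len(t)),
                               rng.normal(0, 0.02, len(t)))
            stable += assess_baseline(tr, at_time=600.0).stable
        assert stable / n_trials >= 0.99


class TestSegmentation:
    def test_supplied_schedule_passes_through(self, noisy_trastuzumab):
        exp, _, schedule = noisy_trastuzumab
        segs = segment_phases(exp, events=schedule)
        assert [s.label for s in segs] == ["baseline", "sample", "rinse"]
        assert segs[1].t_start == pytest.approx(900.0)

    def test_events_outside_range_rejected(self, noisy_trastuzumab):
        exp, _, _ = noisy_trastuzumab
        bad = [PhaseSegment("baseline", 0.0, 2 * exp.time_s[-1])]
        with pytest.raises(ValidationError):
            segment_phases(exp, events=bad)

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_auto_detection_accuracy(self, seed):
        """Detected boundaries land within 30 s of the true pump events."""
        scenario, schedule = mab_panel_preset("trastuzumab", seed=seed)
        exp = simulate_qcmd(scenario, schedule)
        exp.schedule = None
        segs = segment_phases(exp)
        assert [s.label for s in segs] == ["baseline", "sample", "rinse"]
        assert segs[1].t_start == pytest.approx(900.0, abs=30.0)
        assert segs[2].t_start == pytest.approx(2100.0, abs=30.0)

    def test_flat_trace_has_no_transitions(self, rng):
        t = np.arange(2000.0)
        tr = OvertoneTrace(3, t, rng.normal(0, 0.1, len(t)), np.zeros(len(t)))
        with pytest.raises(ValidationError):
            segment_phases(QcmdExperiment(traces={3: tr}))

    def test_bsa_cycles_recovered(self):
        """Auto-detection finds 3 sample and 3 rinse segments across buffers."""
        scenario, schedule = bsa_buffer_preset(seed=17)
        exp = simulate_qcmd(scenario, schedule)
        exp.schedule = None
        segs = segment_phases(exp)
        labels = [s.label for s in segs]
        assert labels.count("sample") == 3
        assert labels.count("rinse") == 3
        # every sample is directly followed by its rinse
        for i, lab in enumerate(labels):
            if lab == "sample":
                assert labels[i + 1] == "rinse"


class TestPlateau:
    def test_saturated_segment_exact(self, noiseless_trastuzumab):
        exp, scenario, _ = noiseless_trastuzumab
        seg = PhaseSegment("rinse", 2100.0, 4500.0)
        est = plateau_value(exp.primary, seg)
        g1_end = exp.ground_truth["gamma1"][-1]
        assert est.stable
        assert est.mean_f == pytest.approx(-g1_end / scenario.c_sauerbrey, rel=1e-4)

    def test_rising_segment_flagged_unstable(self):
        t = np.arange(1200.0)
        tr = OvertoneTrace(3, t, -0.01 * t, np.zeros_like(t))
        est = plateau_value(tr, PhaseSegment("sample", 0.0, 1199.0))
        assert not est.stable

    def test_short_segment_rejected(self, noiseless_trastuzumab):
        exp, _, _ = noiseless_trastuzumab
        with pytest.raises(ValidationError):
            plateau_value(exp.primary, PhaseSegment("rinse", 0.0, 100.0))

    def test_noisy_plateau_mean_near_truth(self):
        """Plateau mean sits within 3 sigma/sqrt(N) of the noiseless level."""
        scenario, schedule = mab_panel_preset("tocilizumab", seed=8)
        exp = simulate_qcmd(scenario, schedule)
        clean = simulate_qcmd(
            scenario.replace(noise_sd_f=0.0, noise_sd_d=0.0), schedule)
        seg = PhaseSegment("rinse", 2100.0, 4500.0)
        est = plateau_value(exp.primary, seg)
        truth = plateau_value(clean.primary, seg).mean_f
        n = 601
        assert abs(est.mean_f - truth) < 3 * scenario.noise_sd_f / np.sqrt(n)


class TestLooseLayerMetric:
    def test_subtraction_arithmetic(self):
        """Sample plateau -100 Hz, rinse plateau -40 Hz -> metric -60 Hz."""
        n = 2000
        t = np.arange(float(n))
        f = np.where(t < 1000, -100.0, -40.0)
        tr = OvertoneTrace(3, t, f, np.zeros(n))
        exp = QcmdExperiment(traces={3: tr})
        segs = [PhaseSegment("sample", 0.0, 999.0), PhaseSegment("rinse", 999.0, 1999.0)]
        m = loose_layer_metric(exp, segments=segs)[0]
        assert m.delta_f3 == pytest.approx(-60.0)
        assert m.stable

    def test_identical_plateaus_give_zero(self):
        exp = _flat_experiment(f3_level=-40.0, n=2400)
        segs = [PhaseSegment("sample", 0.0, 1199.0), PhaseSegment("rinse", 1199.0, 2399.0)]
        assert loose_layer_metric(exp, segments=segs)[0].delta_f3 == pytest.approx(0.0)

    def test_missing_rinse_rejected(self, noiseless_trastuzumab):
        exp, _, _ = noiseless_trastuzumab
        segs = [PhaseSegment("baseline", 0.0, 900.0), PhaseSegment("sample", 900.0, 2100.0)]
        with pytest.raises(ValidationError):
            loose_layer_metric(exp, segments=segs)

    def test_dupilumab_preset_value(self):
        scenario, schedule = mab_panel_preset("dupilumab")
        scenario = scenario.replace(noise_sd_f=0.0, noise_sd_d=0.0)
        exp = simulate_qcmd(scenario, schedule)
        assert loose_layer_metric(exp)[0].delta_f3 == pytest.approx(-112.4, abs=0.5)

    def test_metric_additivity(self, noiseless_trastuzumab):
        """delta_f_loose + delta_f_irreversible == delta_f_total at steady state."""
        exp, _, _ = noiseless_trastuzumab
        m = loose_layer_metric(exp)[0]
        total = m.sample_plateau.mean_f
        irreversible = m.rinse_plateau.mean_f
        assert m.delta_f3 + irreversible == pytest.approx(total, abs=1e-9)

    def test_offset_invariance_exact(self, noiseless_trastuzumab):
        """A constant irreversible offset leaves the metric exactly unchanged."""
        exp, _, _ = noiseless_trastuzumab
        shifted = add_irreversible_offset(exp, -8.0)
        m0 = loose_layer_metric(exp)[0].delta_f3
        m1 = loose_layer_metric(shifted)[0].delta_f3
        assert m1 - m0 == pytest.approx(0.0, abs=1e-9)

    def test_generator_round_trip(self):
        """Extracted loose shift equals -Gamma2_plateau/C within 0.5%."""
        for name in ("trastuzumab", "omalizumab"):
            scenario, schedule = mab_panel_preset(name)
            scenario = scenario.replace(noise_sd_f=0.0, noise_sd_d=0.0)
            exp = simulate_qcmd(scenario, schedule)
            m = loose_layer_metric(exp)[0]
            g2 = exp.ground_truth["gamma2"]
            mask = (exp.time_s >= m.sample_plateau.t_start) & \
                   (exp.time_s <= m.sample_plateau.t_end)
            expected = -g2[mask].mean() / scenario.c_sauerbrey
            assert m.delta_f3 == pytest.approx(expected, rel=5e-3)

    def test_noise_scaling(self):
        """Metric SD over seeds tracks sigma_f*sqrt(2/N) within a factor of 2."""
        scenario, schedule = mab_panel_preset("trastuzumab")
        values = []
        for seed in range(30):
            exp = simulate_qcmd(scenario.replace(seed=9000 + seed), schedule)
            values.append(loose_layer_metric(exp)[0].delta_f3)
        sd = np.std(values, ddof=1)
        theory = scenario.noise_sd_f * np.sqrt(2.0 / 601.0)
        assert theory / 2 < sd < theory * 2


class TestSauerbrey:
    def test_raw_overtone_scaling(self):
        assert sauerbrey_mass(-30.0, overtone=3, normalized=False) == pytest.approx(177.0)

    def test_zero(self):
        assert sauerbrey_mass(0.0) == 0.0

    @given(st.floats(min_value=-200, max_value=-0.1),
           st.sampled_from([3, 5, 7, 9, 11, 13]))
    def test_normalized_mass_overtone_independent(self, delta_f, n):
        """For normalized shifts the inferred mass is the same at any overtone."""
        assert sauerbrey_mass(delta_f, overtone=n, normalized=True) == \
            pytest.approx(sauerbrey_mass(delta_f, overtone=3, normalized=True))

    def test_rigid_layer_same_mass_from_every_overtone(self, noiseless_trastuzumab):
        exp, scenario, _ = noiseless_trastuzumab
        masses = [sauerbrey_mass(tr.delta_f[-1], n, normalized=True,
                                 c_sauerbrey=scenario.c_sauerbrey)
                  for n, tr in exp.traces.items()]
        assert np.ptp(masses) == pytest.approx(0.0, abs=1e-9)
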