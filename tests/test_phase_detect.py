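"""Detectors validated against the simulator's ground truth."""

import numpy as np
import pytest

from nanobiopsy.phase_detect import (
    DetectionParams,
    PatternError,
    PhaseAnnotation,
    detect_phases,
    estimate_baseline,
    measure_delta_i,
    qc_classify,
    welch_psd,
)
from nanobiopsy.sicm_model import InvalidParameterError
from nanobiopsy.trace_sim import (
    CellPreset,
    NoiseModel,
    TraceChannel,
    simulate_extraction_trace,
    simulate_injection_trace,
)

SUBPHASES = ("hop_stop", "membrane_touch", "vibration_onset", "substrate_contact")


def constant_trace(level=1e-9, n=2000, bias=0.2):
    return TraceChannel(
        sample_rate=10_000.0,
        current=np.full(n, level),
        bias=np.full(n, bias),
    )


class TestEstimateBaseline:
    def test_constant_trace(self):
        assert estimate_baseline(constant_trace(1.0e-9)) == pytest.approx(1.0e-9)

    def test_median_resists_one_percent_noise(self, rng):
        errs = []
        for _ in range(50):
            tr = constant_trace(1.0e-9, n=2000)
            tr.current = tr.current + rng.normal(0, 0.01e-9, tr.n_samples)
            errs.append(abs(estimate_baseline(tr) - 1.0e-9) / 1.0e-9)
        assert np.median(errs) < 0.005

    def test_approach_trace_baseline_near_bulk(
        self, short_injection_protocol, aqueous_electrics, default_noise, glial_cell
    ):
        tr, _ = simulate_injection_trace(
            short_injection_protocol, aqueous_electrics, default_noise, glial_cell, seed=2
        )
        bulk = aqueous_electrics.bias / aqueous_electrics.bulk_resistance
        assert estimate_baseline(tr) == pytest.approx(bulk, rel=0.002)

    def test_requires_constant_bias(self):
        tr = constant_trace()
        tr.bias[10] = -0.5
        with pytest.raises(InvalidParameterError):
            estimate_baseline(tr)


class TestDetectPhases:
    def test_noise_free_recovery_within_five_samples(
        self, short_injection_protocol, aqueous_electrics, quiet_noise, glial_cell
    ):
        tr, truth = simulate_injection_trace(
            short_injection_protocol, aqueous_electrics, quiet_noise, glial_cell, seed=3
        )
        ann = detect_phases(tr)
        for name in SUBPHASES:
            assert getattr(ann, name) is not None, name
            assert abs(getattr(ann, name) - getattr(truth, name)) <= 5, name

    def test_truncated_trace_reports_absent_phases(
        self, short_injection_protocol, aqueous_electrics, default_noise, glial_cell
    ):
        tr, truth = simulate_injection_trace(
            short_injection_protocol, aqueous_electrics, default_noise, glial_cell, seed=4
        )
        cut = truth.hop_stop + 500
        short = TraceChannel(
            tr.sample_rate, tr.current[:cut], tr.bias[:cut], tr.position[:cut]
        )
        ann = detect_phases(short)
        assert ann.membrane_touch is None
        assert ann.vibration_onset is None
        assert ann.substrate_contact is None

    def test_monte_carlo_recovery_at_default_noise(
        self, short_injection_protocol, aqueous_electrics, default_noise, glial_cell
    ):
        hits = 0
        n = 60
        for seed in range(n):
            tr, truth = simulate_injection_trace(
                short_injection_protocol, aqueous_electrics, default_noise, glial_cell, seed=seed
            )
            ann = detect_phases(tr)
            ok = all(
                getattr(ann, k) is not None
                and abs(getattr(ann, k) - getattr(truth, k)) <= 20
                for k in ("hop_stop", "membrane_touch", "vibration_onset")
            )
            hits += ok
        assert hits / n >= 0.95

    def test_translation_equivariance(
        self, short_injection_protocol, aqueous_electrics, quiet_noise, glial_cell
    ):
        # prepending a stretch of the initial level shifts every detected
        # index by the same amount (noise-free so window statistics agree)
        tr, _ = simulate_injection_trace(
            short_injection_protocol, aqueous_electrics, quiet_noise, glial_cell, seed=6
        )
        k = 137
        shifted = TraceChannel(
            tr.sample_rate,
            np.concatenate([np.full(k, tr.current[0]), tr.current]),
            np.concatenate([np.full(k, tr.bias[0]), tr.bias]),
            np.concatenate([np.full(k, tr.position[0]), tr.position]),
        )
        ann = detect_phases(tr)
        ann_shifted = detect_phases(shifted)
        for name, idx in ann.present().items():
            assert abs(ann_shifted.present()[name] - (idx + k)) <= 5

    def test_ordering_always_valid(
        self, short_injection_protocol, aqueous_electrics, default_noise, glial_cell
    ):
        for seed in range(10):
            tr, _ = simulate_injection_trace(
                short_injection_protocol, aqueous_electrics, default_noise, glial_cell, seed=seed
            )
            assert detect_phases(tr).ordered()

    def test_touch_recall_non_increasing_in_noise(
        self, short_injection_protocol, aqueous_electrics, glial_cell
    ):
        recalls = []
        for sd in (10e-12, 40e-12, 120e-12):
            noise = NoiseModel(white_sd=sd)
            found = 0
            n = 40
            for seed in range(n):
                tr, truth = simulate_injection_trace(
                    short_injection_protocol, aqueous_electrics, noise, glial_cell, seed=seed
                )
                ann = detect_phases(tr)
                found += (
                    ann.membrane_touch is not None
                    and abs(ann.membrane_touch - truth.membrane_touch) <= 50
                )
            recalls.append(found / n)
        assert recalls[0] >= recalls[1] >= recalls[2]


class TestWelchPsd:
    def test_sinusoid_peak_location(self):
        fs, f0 = 10_000.0, 440.0
        t = np.arange(8192) / fs
        freqs, power = welch_psd(np.sin(2 * np.pi * f0 * t), fs, window_len=1024)
        assert abs(freqs[np.argmax(power)] - f0) < fs / 1024

    def test_white_noise_parseval(self, rng):
        x = rng.normal(0, 1.0, 65536)
        freqs, power = welch_psd(x, 10_000.0, window_len=1024)
        total = np.trapezoid(power, freqs)
        assert total == pytest.approx(x.var(), rel=0.05)

    def test_short_segment_rejected(self):
        with pytest.raises(InvalidParameterError):
            welch_psd(np.zeros(100), 10_000.0, window_len=256)


class TestQcClassify:
    def test_success_requires_all_three_in_order(self):
        ann = PhaseAnnotation(hop_stop=10, membrane_touch=100, vibration_onset=200)
        assert qc_classify(ann).success

    def test_missing_vibration_reported(self):
        ann = PhaseAnnotation(hop_stop=10, membrane_touch=100)
        qc = qc_classify(ann)
        assert not qc.success
        assert "vibration_onset missing" in qc.reasons

    def test_simulated_cohort_flags_no_drop_traces(
        self, short_injection_protocol, aqueous_electrics, default_noise
    ):
        correct = 0
        n = 30
        for s in range(n):
            drop = 0.0 if s % 10 == 0 else None  # 10% failed injections
            cell = CellPreset(membrane_drop=drop)
            tr, _ = simulate_injection_trace(
                short_injection_protocol, aqueous_electrics, default_noise, cell, seed=500 + s
            )
            qc = qc_classify(detect_phases(tr))
            correct += qc.success == (s % 10 != 0)
        assert correct == n


class TestMeasureDeltaI:
    def test_printed_example(self, printed_extraction_setup):
        protocol, pipette = printed_extraction_setup
        tr, _ = simulate_extraction_trace(protocol, pipette, NoiseModel(white_sd=0.0), seed=0)
        m = measure_delta_i(tr)
        assert m.delta_i * 1e9 == pytest.approx(0.35, rel=0.02)
        assert m.hold_bias == pytest.approx(0.3)

    def test_invariant_to_one_percent_white_noise(self, printed_extraction_setup):
        protocol, pipette = printed_extraction_setup
        quiet, _ = simulate_extraction_trace(protocol, pipette, NoiseModel(white_sd=0.0), seed=0)
        noisy, _ = simulate_extraction_trace(
            protocol, pipette, NoiseModel(white_sd=0.01 * 0.35e-9), seed=1
        )
        d0 = measure_delta_i(quiet).delta_i
        d1 = measure_delta_i(noisy).delta_i
        assert d1 == pytest.approx(d0, rel=0.01)

    def test_pattern_error_without_three_bias_segments(self):
        tr = constant_trace()
        with pytest.raises(PatternError):
            measure_delta_i(tr)
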