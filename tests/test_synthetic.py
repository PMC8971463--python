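"""Cohort generator: counts, determinism, signal content, error paths."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

from wristhar.registry import confusable_pair, default_registry
from wristhar.synthetic import (
    BACKGROUND,
    ActivityTemplate,
    ConfigurationError,
    GeneratorConfig,
    SchedulingError,
    SubjectProfile,
    activity_signal,
    bout_counts,
    generate_cohort,
    generate_subject,
)
from tests.conftest import make_template


def _flat_profile(n_ch: int = 6) -> SubjectProfile:
    return SubjectProfile("s", (1.0,) * n_ch, 1.0, 0.0)


class TestActivityTemplate:
    def test_rejects_nyquist_is_checked_at_generation(self):
        tpl = make_template("fast", 30.0)  # template itself is rate-agnostic
        with pytest.raises(ValueError, match="Nyquist"):
            activity_signal(tpl, _flat_profile(), 100, np.random.default_rng(0))

    def test_rejects_bad_repeats(self):
        with pytest.raises(ValueError):
            ActivityTemplate(
                "x", "everyday", ((1.0,), (1.0,)), (1.0, 1.0), (1.0, 0.1), (5, 2)
            )

    def test_rejects_negative_amplitude(self):
        with pytest.raises(ValueError):
            ActivityTemplate(
                "x", "everyday", ((1.0,), (1.0,)), (-1.0, 1.0), (1.0, 0.1), (1, 2)
            )

    def test_with_tempo_scales_frequencies(self):
        a, b = confusable_pair("slow", "fast", base_frequency=1.0, tempo_ratio=1.5)
        assert b.base_frequencies[0][0] == pytest.approx(1.5)
        assert a.amplitudes == b.amplitudes


class TestActivitySignal:
    def test_zero_amplitude_zero_noise_is_silent(self):
        tpl = ActivityTemplate(
            "still", "everyday", ((1.0,), (1.0,)), (0.0, 0.0), (1.0, 0.1), (1, 1),
            noise_sd=0.0,
        )
        sig = activity_signal(tpl, _flat_profile(), 200, np.random.default_rng(0))
        assert sig.shape == (200, 6)
        assert np.all(sig == 0.0)

    def test_fft_peak_at_template_frequency(self):
        # single 2 Hz component, no noise, 500 samples at 50 Hz
        tpl = ActivityTemplate(
            "osc", "everyday", ((2.0,), (2.0,)), (1.0, 1.0), (1.0, 0.1), (1, 1),
            noise_sd=0.0,
        )
        sig = activity_signal(tpl, _flat_profile(), 500, np.random.default_rng(0))
        spec = np.abs(np.fft.rfft(sig[:, 0]))
        freqs = np.fft.rfftfreq(500, d=1 / 50.0)
        assert freqs[np.argmax(spec)] == pytest.approx(2.0)

    def test_noise_sd_monte_carlo(self):
        tpl = ActivityTemplate(
            "noise", "everyday", ((1.0,), (1.0,)), (0.0, 0.0), (1.0, 0.1), (1, 1),
            noise_sd=0.1,
        )
        sig = activity_signal(tpl, _flat_profile(), 10_000, np.random.default_rng(7))
        assert np.std(sig) == pytest.approx(0.1, abs=0.01)

    def test_tempo_shifts_effective_frequency(self):
        tpl = ActivityTemplate(
            "osc", "everyday", ((2.0,), (2.0,)), (1.0, 1.0), (1.0, 0.1), (1, 1),
            noise_sd=0.0,
        )
        fast = SubjectProfile("s", (1.0,) * 6, 1.5, 0.0)
        sig = activity_signal(tpl, fast, 1000, np.random.default_rng(0))
        freqs = np.fft.rfftfreq(1000, d=1 / 50.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(sig[:, 0])))]
        assert peak == pytest.approx(3.0, abs=0.1)

    def test_requires_positive_length(self):
        with pytest.raises(ValueError):
            activity_signal(
                make_template("a", 1.0), _flat_profile(), 0, np.random.default_rng(0)
            )


class TestGenerateCohort:
    def test_zero_subjects_empty(self):
        cfg = GeneratorConfig(activities=(make_template("a", 1.0),), n_subjects=0)
        streams, labels = generate_cohort(cfg, 0)
        assert streams == [] and labels == []

    def test_empty_registry_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(activities=(), n_subjects=2)

    def test_fixed_repeat_bout_count(self):
        # 3 subjects x 2 activities x exactly 5 repeats -> 30 intervals
        acts = tuple(
            make_template(n, f, repeats=(5, 5)) for n, f in (("a", 1.0), ("b", 2.5))
        )
        cfg = GeneratorConfig(activities=acts, n_subjects=3)
        _, labels = generate_cohort(cfg, 3)
        assert len(labels) == 30

    def test_reproducible_under_seed(self):
        cfg = GeneratorConfig(
            activities=(make_template("a", 1.0),), n_subjects=2
        )
        s1, l1 = generate_cohort(cfg, 5)
        s2, l2 = generate_cohort(cfg, 5)
        h = lambda arr: hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()
        assert [h(s.samples) for s in s1] == [h(s.samples) for s in s2]
        assert l1 == l2

    def test_different_seed_differs(self):
        cfg = GeneratorConfig(activities=(make_template("a", 1.0),), n_subjects=1)
        s1, _ = generate_cohort(cfg, 5)
        s2, _ = generate_cohort(cfg, 6)
        assert not np.array_equal(s1[0].samples, s2[0].samples)

    def test_adding_subjects_preserves_existing_streams(self):
        acts = (make_template("a", 1.0),)
        small = GeneratorConfig(activities=acts, n_subjects=2)
        big = GeneratorConfig(activities=acts, n_subjects=4)
        s_small, _ = generate_cohort(small, 11)
        s_big, _ = generate_cohort(big, 11)
        for a, b in zip(s_small, s_big):
            assert a.subject_id == b.subject_id
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_labels_inside_streams_and_separated_by_gaps(self, tiny_cohort):
        _, streams, labels = tiny_cohort
        length = {s.subject_id: s.n_samples for s in streams}
        by_subject = {}
        for iv in labels:
            assert 0 <= iv.start_index < iv.end_index <= length[iv.subject_id]
            by_subject.setdefault(iv.subject_id, []).append(iv)
        for ivs in by_subject.values():
            ivs.sort(key=lambda iv: iv.start_index)
            for a, b in zip(ivs, ivs[1:]):
                assert b.start_index > a.end_index  # background gap between bouts

    def test_scheduling_error_names_subject_and_activity(self):
        cfg = GeneratorConfig(
            activities=(make_template("marathon", 1.0, bout=(30.0, 0.0)),),
            n_subjects=1,
            max_duration_s=10.0,
        )
        with pytest.raises(SchedulingError, match="marathon"):
            generate_cohort(cfg, 0)

    def test_imbalance_spans_order_of_magnitude(self):
        acts = (
            make_template("common", 1.0, repeats=(30, 60)),
            make_template("rare", 3.0, repeats=(2, 4)),
        )
        cfg = GeneratorConfig(activities=acts, n_subjects=4)
        _, labels = generate_cohort(cfg, 9)
        counts = bout_counts(labels)
        assert counts["common"] / counts["rare"] >= 10

    def test_background_sentinel_reserved(self):
        # the sentinel never appears as a bout label
        cfg = GeneratorConfig(activities=(make_template("a", 1.0),), n_subjects=1)
        _, labels = generate_cohort(cfg, 1)
        assert all(iv.activity != BACKGROUND for iv in labels)


class TestDefaultRegistry:
    def test_forty_unique_activities(self):
        reg = default_registry()
        assert len({t.name for t in reg}) == 40

    def test_both_activity_types_present(self):
        reg = default_registry()
        kinds = {t.activity_type for t in reg}
        assert kinds == {"playful", "everyday"}
        assert sum(t.activity_type == "playful" for t in reg) >= 10

    def test_confusable_pair_shares_shape(self):
        reg = {t.name: t for t in default_registry()}
        pray, clap = reg["pray"], reg["clapping"]
        ratio = clap.base_frequencies[0][0] / pray.base_frequencies[0][0]
        assert ratio > 1.0
        assert pray.amplitudes == clap.amplitudes

    def test_default_cohort_contract(self):
        # 34 subjects at 50 Hz with the shipped registry
        cfg = GeneratorConfig(activities=default_registry(), n_subjects=34)
        assert len(cfg.subject_ids) == 34
        assert cfg.sampling_rate == 50.0

    def test_frequencies_below_nyquist(self):
        for tpl in default_registry():
            for group in tpl.base_frequencies:
                assert all(f < 25.0 for f in group)
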