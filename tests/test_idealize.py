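"""Half-amplitude idealization and dead-time (imposed resolution) semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gatekin as gk
from gatekin.idealize import RawEvents, impose_resolution


def make_raw(classes, durations_ms):
    return RawEvents(
        is_open=np.array(classes, dtype=bool),
        durations=np.array(durations_ms) * 1e-3,
        total_duration_s=float(np.sum(durations_ms) * 1e-3),
    )


def resolution_oracle(classes, durations, dead_time):
    """Independent reference: repeatedly delete the leftmost sub-resolution
    event (first event exempt), merging it into its predecessor and
    concatenating same-class neighbours, until none remain."""
    cls, dur = list(classes), list(durations)

    def concat():
        i = 1
        while i < len(cls):
            if cls[i] == cls[i - 1]:
                dur[i - 1] += dur[i]
                del cls[i], dur[i]
            else:
                i += 1

    concat()
    while True:
        idx = next((i for i in range(1, len(cls)) if dur[i] < dead_time), None)
        if idx is None:
            return cls, dur
        dur[idx - 1] += dur[idx]
        del cls[idx], dur[idx]
        concat()


class TestDetectEvents:
    def test_single_opening(self, two_state_scheme):
        dw = gk.DwellSequence(
            states=np.array([0, 1, 0]),
            durations=np.array([5e-3, 1e-3, 5e-3]),
            total_duration_s=11e-3,
        )
        acq = gk.AcquisitionConfig(filter_cutoff=None, noise_sd=0.0,
                                   unitary_amplitude=1.5)
        tr = gk.render_trace(dw, two_state_scheme, acq)
        raw = gk.detect_events(tr, baseline_pA=0.0, amplitude_pA=1.5)
        assert raw.is_open.tolist() == [False, True, False]
        assert raw.durations[1] == pytest.approx(1e-3, abs=1.0 / acq.sampling_rate)

    def test_flat_trace_is_one_closed_event(self):
        tr = gk.Trace(
            current=np.zeros(1000),
            acquisition=gk.AcquisitionConfig(filter_cutoff=None),
        )
        raw = gk.detect_events(tr, 0.0, 1.5)
        assert raw.is_open.tolist() == [False]
        rec = impose_resolution(raw, 50e-6)
        assert rec.po == 0.0

    def test_negative_amplitude_channels(self):
        """Inward (negative) unitary currents idealize identically."""
        sig = np.zeros(2000)
        sig[500:1000] = -1.5
        tr = gk.Trace(
            current=sig,
            acquisition=gk.AcquisitionConfig(filter_cutoff=None,
                                             unitary_amplitude=-1.5),
        )
        raw = gk.detect_events(tr, 0.0, -1.5)
        assert raw.is_open.tolist() == [False, True, False]

    def test_zero_amplitude_rejected(self):
        tr = gk.Trace(
            current=np.zeros(10), acquisition=gk.AcquisitionConfig(filter_cutoff=None)
        )
        with pytest.raises(ValueError):
            gk.detect_events(tr, 0.0, 0.0)

    def test_noisy_trace_sample_accuracy(self):
        """At SNR 8 the thresholded classes match ground truth for >=95%
        of samples despite filter smear at transitions."""
        scheme = gk.n133s_like()
        dw = gk.sample_dwell_sequence(scheme, 20.0, seed=21)
        amp = 1.5
        acq = gk.AcquisitionConfig(noise_sd=amp / 8.0, unitary_amplitude=amp, seed=22)
        tr = gk.render_trace(dw, scheme, acq)
        # ground-truth per-sample class from the dwell sequence
        edges = np.concatenate([[0.0], np.cumsum(dw.durations)])
        t = tr.time
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      dw.states.size - 1)
        truth = dw.class_sequence(scheme)[idx]
        measured = (tr.current - 0.0) > amp / 2.0
        assert (measured == truth).mean() >= 0.95


class TestImposeResolution:
    def test_sub_resolution_gap_absorbed(self):
        raw = make_raw([True, False, True], [2.0, 0.030, 3.0])
        rec = impose_resolution(raw, 50e-6)
        assert rec.is_open.tolist() == [True]
        assert rec.durations[0] == pytest.approx(5.03e-3)

    def test_identity_when_all_resolved(self):
        raw = make_raw([False, True, False, True], [1.0, 2.0, 3.0, 4.0])
        rec = impose_resolution(raw, 50e-6)
        assert rec.is_open.tolist() == raw.is_open.tolist()
        np.testing.assert_allclose(rec.durations, raw.durations)

    def test_first_event_exempt(self):
        raw = make_raw([True, False, True], [0.010, 5.0, 5.0])
        rec = impose_resolution(raw, 50e-6)
        assert rec.is_open.tolist() == [True, False, True]
        assert rec.durations[0] == pytest.approx(10e-6)

    def test_dead_time_must_be_positive(self):
        raw = make_raw([True, False], [1.0, 1.0])
        with pytest.raises(ValueError):
            impose_resolution(raw, 0.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        first=st.booleans(),
        durations=st.lists(
            st.floats(min_value=5e-6, max_value=5e-3), min_size=1, max_size=50
        ),
        dead_time=st.floats(min_value=2e-5, max_value=5e-4),
    )
    def test_matches_repeated_deletion_oracle(self, first, durations, dead_time):
        classes = [bool((i + first) % 2) for i in range(len(durations))]
        raw = make_raw(classes, np.array(durations) * 1e3)
        rec = impose_resolution(raw, dead_time)
        o_cls, o_dur = resolution_oracle(classes, durations, dead_time)
        assert rec.is_open.tolist() == o_cls
        np.testing.assert_allclose(rec.durations, o_dur, rtol=1e-12, atol=1e-15)


class TestComputePo:
    def test_hand_sum(self):
        raw = make_raw([True, False, True], [2.0, 3.0, 5.0])
        rec = impose_resolution(raw, 50e-6)
        assert rec.po == pytest.approx(0.7)

    def test_time_reversal_invariance(self, wt_record):
        rev = gk.IdealizedRecord(
            is_open=wt_record.is_open[::-1].copy(),
            durations=wt_record.durations[::-1].copy(),
            dead_time_s=wt_record.dead_time_s,
            total_duration_s=wt_record.total_duration_s,
        )
        assert rev.po == pytest.approx(wt_record.po, rel=1e-12)

    def test_zero_duration_rejected(self):
        raw = make_raw([True, False], [1.0, 1.0])
        rec = impose_resolution(raw, 50e-6)
        object.__setattr__(rec, "total_duration_s", 0.0)
        with pytest.raises(ValueError):
            gk.compute_po(rec)


class TestNoiselessRoundTrip:
    def test_recovers_ground_truth_classes_and_durations(self, task_scheme):
        """Idealizing a noiseless, unfiltered rendering reproduces the
        dwell class/duration list to within one sample per boundary."""
        fs = 200_000.0
        dw = gk.sample_dwell_sequence(task_scheme, 10.0, seed=31)
        # lift any unrepresentable dwell to 3 sample periods
        durations = np.maximum(dw.durations, 3.0 / fs)
        dw = gk.DwellSequence(
            states=dw.states, durations=durations,
            total_duration_s=float(durations.sum()),
        )
        acq = gk.AcquisitionConfig(sampling_rate=fs, filter_cutoff=None,
                                   noise_sd=0.0, unitary_amplitude=1.5)
        tr = gk.render_trace(dw, task_scheme, acq)
        raw = gk.detect_events(tr, 0.0, 1.5)
        truth = gk.record_from_dwells(dw, task_scheme, dead_time_s=1e-9)
        assert raw.is_open.tolist() == truth.is_open.tolist()
        np.testing.assert_allclose(
            raw.durations, truth.durations, atol=2.0 / fs
        )

    def test_full_pipeline_po_accuracy(self, task_scheme):
        """Simulate -> render (SNR 10) -> idealize: Po within 20% of truth."""
        dw = gk.sample_dwell_sequence(task_scheme, 60.0, seed=33)
        acq = gk.AcquisitionConfig(noise_sd=0.15, unitary_amplitude=1.5, seed=34)
        tr = gk.render_trace(dw, task_scheme, acq)
        raw = gk.detect_events(tr, 0.0, 1.5)
        rec = impose_resolution(raw, 50e-6)
        po_true = dw.open_fraction(task_scheme)
        assert rec.po == pytest.approx(po_true, rel=0.20)


class TestEstimateLevels:
    def test_recovers_baseline_and_amplitude(self):
        scheme = gk.n133s_like()
        dw = gk.sample_dwell_sequence(scheme, 10.0, seed=41)
        acq = gk.AcquisitionConfig(noise_sd=0.12, unitary_amplitude=1.5, seed=42)
        tr = gk.render_trace(dw, scheme, acq)
        baseline, amplitude, multi = gk.estimate_levels(tr)
        assert baseline == pytest.approx(0.0, abs=0.1)
        assert amplitude == pytest.approx(1.5, rel=0.15)
        assert not multi
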