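"""Half-amplitude threshold idealization of single-channel traces.

Samples above the half-amplitude threshold (baseline + amplitude/2, taken
on the signed deviation in the direction of the open level) are classified
open, the rest closed; runs of equal class become events with boundaries
at sample boundaries.  A dead time (imposed resolution, default 50 µs) is
then applied: scanning left to right, any event shorter than the dead time
is absorbed into the preceding retained event, and same-class neighbours
produced by the absorption are concatenated.  The first event is exempt
from deletion.  Open probability is the summed open time divided by the
record length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .simulate import Trace

__all__ = [
    "RawEvents",
    "IdealizedRecord",
    "detect_events",
    "impose_resolution",
    "compute_po",
    "estimate_levels",
    "record_from_dwells",
    "DEFAULT_DEAD_TIME_S",
]

DEFAULT_DEAD_TIME_S = 50e-6


@dataclass(frozen=True)
class RawEvents:
    """Alternating open/closed events before resolution imposition."""

    is_open: np.ndarray  # bool per event
    durations: np.ndarray  # seconds
    total_duration_s: float

    def __post_init__(self) -> None:
        is_open = np.asarray(self.is_open, dtype=bool)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "is_open", is_open)
        object.__setattr__(self, "durations", durations)
        if is_open.size == 0 or is_open.shape != durations.shape:
            raise ValueError("need equal-length nonempty event arrays")
        if np.any(durations <= 0):
            raise ValueError("event durations must be > 0")
        if np.any(is_open[1:] == is_open[:-1]):
            raise ValueError("events must alternate in class")


@dataclass(frozen=True)
class IdealizedRecord:
    """Alternating event list at a stated dead time.

    Events are half-open intervals ``[start, start + duration)`` tiling
    ``[0, total_duration_s)``.  All events except possibly the first are at
    least ``dead_time_s`` long.
    """

    is_open: np.ndarray
    durations: np.ndarray
    dead_time_s: float
    total_duration_s: float
    baseline_pA: float = 0.0
    amplitude_pA: float = 1.0

    def __post_init__(self) -> None:
        is_open = np.asarray(self.is_open, dtype=bool)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "is_open", is_open)
        object.__setattr__(self, "durations", durations)
        if is_open.size == 0 or is_open.shape != durations.shape:
            raise ValueError("need equal-length nonempty event arrays")
        if np.any(is_open[1:] == is_open[:-1]):
            raise ValueError("events must alternate in class")
        if np.any(durations <= 0):
            raise ValueError("event durations must be > 0")
        if durations.size > 1 and np.any(durations[1:] < self.dead_time_s - 1e-15):
            raise ValueError("events shorter than the dead time survived")
        if abs(durations.sum() - self.total_duration_s) > 1e-6 * max(
            1.0, self.total_duration_s
        ):
            raise ValueError("events must tile the record exactly")

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations[:-1])])

    @property
    def n_events(self) -> int:
        return int(self.is_open.size)

    @property
    def open_durations(self) -> np.ndarray:
        return self.durations[self.is_open]

    @property
    def closed_durations(self) -> np.ndarray:
        return self.durations[~self.is_open]

    @property
    def po(self) -> float:
        return compute_po(self)


def detect_events(
    trace: Trace | np.ndarray,
    baseline_pA: float,
    amplitude_pA: float,
    sampling_rate: Optional[float] = None,
) -> RawEvents:
    """Threshold a trace at half the open level and run-length encode it.

    The threshold sits at ``baseline + amplitude/2``; comparison is on the
    signed deviation in the direction of ``amplitude``, so inward (negative)
    openings work unchanged.
    """
    if amplitude_pA == 0:
        raise ValueError("amplitude must be nonzero")
    if isinstance(trace, Trace):
        current = trace.current
        fs = trace.acquisition.sampling_rate
    else:
        current = np.asarray(trace, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for bare arrays")
        fs = sampling_rate
    if current.size == 0:
        raise ValueError("empty trace")
    if not np.any(np.isfinite(current)):
        raise ValueError("trace contains no finite samples")
    deviation = (current - baseline_pA) * np.sign(amplitude_pA)
    is_open = deviation > abs(amplitude_pA) / 2.0
    # run-length encode
    change = np.flatnonzero(np.diff(is_open.view(np.int8)))
    bounds = np.concatenate([[0], change + 1, [is_open.size]])
    lengths = np.diff(bounds)
    classes = is_open[bounds[:-1]]
    return RawEvents(
        is_open=classes,
        durations=lengths / fs,
        total_duration_s=is_open.size / fs,
    )


def impose_resolution(
    raw: RawEvents,
    dead_time_s: float = DEFAULT_DEAD_TIME_S,
    baseline_pA: float = 0.0,
    amplitude_pA: float = 1.0,
) -> IdealizedRecord:
    """Apply the imposed resolution (dead time) to a raw event list.

    Left-to-right scan: an event shorter than ``dead_time_s`` is merged
    into the preceding retained event (its duration added); a following
    event of the same class as the now-extended retained event is
    concatenated.  The first event is exempt from deletion.
    """
    if dead_time_s <= 0:
        raise ValueError("dead_time_s must be > 0")
    out_cls: list[bool] = []
    out_dur: list[float] = []
    for c, d in zip(raw.is_open, raw.durations):
        if not out_cls:
            out_cls.append(bool(c))
            out_dur.append(float(d))
        elif d < dead_time_s or bool(c) == out_cls[-1]:
            out_dur[-1] += float(d)
        else:
            out_cls.append(bool(c))
            out_dur.append(float(d))
    return IdealizedRecord(
        is_open=np.array(out_cls),
        durations=np.array(out_dur),
        dead_time_s=dead_time_s,
        total_duration_s=raw.total_duration_s,
        baseline_pA=baseline_pA,
        amplitude_pA=amplitude_pA,
    )


def compute_po(record: IdealizedRecord) -> float:
    """Open probability: summed open durations over the record length."""
    if record.total_duration_s <= 0:
        raise ValueError("record has zero duration")
    return float(record.open_durations.sum() / record.total_duration_s)


def _two_gaussians(x, a1, mu1, sd1, a2, mu2, sd2):
    g = lambda m, s: np.exp(-0.5 * ((x - m) / s) ** 2)  # noqa: E731
    return a1 * g(mu1, sd1) + a2 * g(mu2, sd2)


def estimate_levels(trace: Trace, max_openings_level: float = 1.6) -> tuple[float, float, bool]:
    """Estimate (baseline, amplitude) from the all-points histogram.

    Fits two Gaussians to the amplitude histogram; the taller peak is the
    baseline (single leak channels sit closed most of the time) and the
    other peak the open level.  Returns ``(baseline_pA, amplitude_pA,
    multi_channel_flag)`` where the flag marks records with appreciable
    time spent beyond ``max_openings_level`` x the unitary step (stacked
    openings from more than one active channel).
    """
    x = trace.current
    counts, edges = np.histogram(x, bins=200)
    centers = (edges[:-1] + edges[1:]) / 2
    i_base = int(np.argmax(counts))
    mu1 = centers[i_base]
    # open level: histogram mean of the far tail, on the heavier side
    resid = x - mu1
    heavy_sign = 1.0 if np.abs(resid.max()) >= np.abs(resid.min()) else -1.0
    mu2 = mu1 + heavy_sign * np.quantile(np.abs(resid), 0.999)
    sd0 = max(np.std(x) / 4, 1e-6)
    p0 = [counts.max(), mu1, sd0, max(counts.max() / 50, 1.0), mu2, sd0]
    try:
        popt, _ = curve_fit(_two_gaussians, centers, counts, p0=p0, maxfev=20000)
        peaks = sorted(
            [(popt[0], popt[1]), (popt[3], popt[4])], key=lambda t: -abs(t[0])
        )
        baseline, open_level = peaks[0][1], peaks[1][1]
    except RuntimeError:
        baseline, open_level = mu1, mu2
    amplitude = open_level - baseline
    beyond = np.abs(x - baseline) > max_openings_level * abs(amplitude)
    multi = bool(beyond.mean() > 1e-4)
    return float(baseline), float(amplitude), multi


def record_from_dwells(
    dwells,
    scheme,
    dead_time_s: float = DEFAULT_DEAD_TIME_S,
    baseline_pA: float = 0.0,
    amplitude_pA: float = 1.0,
) -> IdealizedRecord:
    """Idealized record straight from a simulated dwell sequence.

    Collapses the per-state dwells to conductance classes, merges
    same-class neighbours, and imposes the dead time — the event list an
    ideal (noise- and bandwidth-free) idealizer would produce.
    """
    is_open = dwells.class_sequence(scheme)
    change = np.flatnonzero(is_open[1:] != is_open[:-1])
    bounds = np.concatenate([[0], change + 1, [is_open.size]])
    cls = is_open[bounds[:-1]]
    dur = np.add.reduceat(dwells.durations, bounds[:-1])
    raw = RawEvents(
        is_open=cls, durations=dur, total_duration_s=dwells.total_duration_s
    )
    return impose_resolution(
        raw, dead_time_s, baseline_pA=baseline_pA, amplitude_pA=amplitude_pA
    )
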