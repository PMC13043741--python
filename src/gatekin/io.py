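"""Plain-text readers and writers for traces, event lists, and fit reports.

All formats are tab-separated with ``#``-prefixed ``key = value`` metadata
headers so that every artifact carries its acquisition settings, seed and
provenance.  Round trips are lossless (floats serialised at full
precision).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np

from .dwell import DwellHistogram, ExpMixture
from .idealize import IdealizedRecord
from .simulate import AcquisitionConfig, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "write_histogram",
    "format_mixture",
    "write_mixture",
]

logger = logging.getLogger(__name__)

_FLOAT = "%.17g"


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as two-column TSV (time_s, current_pA) with metadata."""
    acq = trace.acquisition
    path = Path(path)
    header = {
        "sampling_rate": acq.sampling_rate,
        "filter_cutoff": "" if acq.filter_cutoff is None else acq.filter_cutoff,
        "unitary_amplitude": acq.unitary_amplitude,
        "noise_sd": acq.noise_sd,
        "n_channels": acq.n_channels,
        "seed": acq.seed,
        **trace.extra_metadata,
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("# time_s\tcurrent_pA\n")
        np.savetxt(fh, np.column_stack([trace.time, trace.current]), fmt=_FLOAT, delimiter="\t")


def read_trace(path: str | Path) -> Trace:
    """Read a TSV trace; the metadata header defines the sampling rate.

    Unknown header keys are preserved in ``extra_metadata``.  A header
    sampling rate disagreeing with the row spacing by more than 1% is
    logged as a warning; the header wins.
    """
    path = Path(path)
    meta, _ = _parse_header(path)
    if "sampling_rate" not in meta or not meta["sampling_rate"]:
        raise ValueError(f"{path}: missing sampling_rate in header")
    data = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_s, current_pA)")
    t, cur = data[:, 0], data[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    fs = float(meta.pop("sampling_rate"))
    if t.size > 1:
        fs_rows = 1.0 / np.median(np.diff(t))
        if abs(fs_rows - fs) > 0.01 * fs:
            logger.warning(
                "%s: header sampling_rate %.6g Hz disagrees with row spacing "
                "%.6g Hz by >1%%; using the header value",
                path,
                fs,
                fs_rows,
            )
    known = {}
    for key, cast in (
        ("filter_cutoff", float),
        ("unitary_amplitude", float),
        ("noise_sd", float),
        ("n_channels", int),
        ("seed", int),
    ):
        raw = meta.pop(key, "")
        if raw != "":
            known[key] = cast(float(raw)) if cast is int else cast(raw)
    if "filter_cutoff" not in known:
        known["filter_cutoff"] = None
    acq = AcquisitionConfig(sampling_rate=fs, **known)
    meta.pop("time_s\tcurrent_pA", None)
    return Trace(current=cur, acquisition=acq, extra_metadata=meta)


def write_events(record: IdealizedRecord, path: str | Path) -> None:
    """Write an event list TSV: ``index  class  start_s  duration_s``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dead_time_s = {record.dead_time_s!r}\n")
        fh.write(f"# total_duration_s = {record.total_duration_s!r}\n")
        fh.write(f"# baseline_pA = {record.baseline_pA!r}\n")
        fh.write(f"# amplitude_pA = {record.amplitude_pA!r}\n")
        fh.write("# index\tclass\tstart_s\tduration_s\n")
        starts = record.starts
        for i, (op, s, d) in enumerate(zip(record.is_open, starts, record.durations)):
            cls = "OPEN" if op else "CLOSED"
            fh.write(f"{i}\t{cls}\t{float(s)!r}\t{float(d)!r}\n")


def read_events(path: str | Path) -> IdealizedRecord:
    """Read an event list TSV written by :func:`write_events`."""
    path = Path(path)
    meta, n_header = _parse_header(path)
    classes: list[bool] = []
    durations: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, cls, _, dur = line.rstrip("\n").split("\t")
            classes.append(cls == "OPEN")
            durations.append(float(dur))
    return IdealizedRecord(
        is_open=np.array(classes),
        durations=np.array(durations),
        dead_time_s=float(meta["dead_time_s"]),
        total_duration_s=float(meta["total_duration_s"]),
        baseline_pA=float(meta.get("baseline_pA", 0.0)),
        amplitude_pA=float(meta.get("amplitude_pA", 1.0)),
    )


def write_histogram(hist: DwellHistogram, path: str | Path) -> None:
    """Export a dwell histogram as ``bin_left_s  bin_right_s  count``."""
    with open(path, "w") as fh:
        fh.write(f"# bins_per_decade = {hist.bins_per_decade}\n")
        fh.write("# bin_left_s\tbin_right_s\tcount\n")
        for left, right, c in zip(hist.edges_s[:-1], hist.edges_s[1:], hist.counts):
            fh.write(f"{float(left)!r}\t{float(right)!r}\t{int(c)}\n")


def format_mixture(mix: ExpMixture, label: str = "") -> str:
    """Human/machine-readable fit report for an exponential mixture."""
    lines = []
    if label:
        lines.append(f"# label = {label}")
    lines += [
        f"# k = {mix.k}",
        f"# dead_time_s = {mix.dead_time_s!r}",
        f"# log_likelihood = {mix.log_likelihood!r}",
        f"# n_obs = {mix.n_obs}",
        "# area\tlifetime_s",
    ]
    for a, t in zip(mix.areas, mix.lifetimes_s):
        lines.append(f"{float(a)!r}\t{float(t)!r}")
    return "\n".join(lines) + "\n"


def write_mixture(mix: ExpMixture, path: str | Path, label: str = "") -> None:
    Path(path).write_text(format_mixture(mix, label))
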