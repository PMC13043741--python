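"""Synthetic single-channel data: CTMC dwell sampling and trace rendering.

Dwell sequences are sampled from a :class:`~gatekin.scheme.KineticScheme`
by the standard construction — exponential holding times with rate
``-q_ii`` and embedded-chain jumps with probability ``q_ij / -q_ii`` — and
rendered as current traces that emulate the acquisition settings of a
patch-clamp rig: 200 kHz sampling, 2 kHz low-pass filtering, a unitary
current step per open channel, and additive Gaussian noise.

The low-pass filter is a Gaussian FIR, the standard analysis approximation
to a 4-pole Bessel response; its 10-90% step rise time is 0.3321/f_c and
its impulse-response sigma is 0.1325/f_c (time units).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .scheme import (
    KineticScheme,
    ModifierSpec,
    apply_modifier,
    equilibrium_occupancy,
)

__all__ = [
    "AcquisitionConfig",
    "DwellSequence",
    "Trace",
    "sample_dwell_sequence",
    "render_trace",
    "simulate_condition_pair",
    "GAUSSIAN_RISE_TIME_COEFF",
    "GAUSSIAN_SIGMA_COEFF",
]

logger = logging.getLogger(__name__)

# Gaussian low-pass filter constants (time-domain), f_c = -3 dB cutoff:
#   sigma_t = 0.1325 / f_c,  10-90% rise time = 0.3321 / f_c
GAUSSIAN_SIGMA_COEFF = 0.1325
GAUSSIAN_RISE_TIME_COEFF = 0.3321


@dataclass(frozen=True)
class AcquisitionConfig:
    """Recording settings for rendered traces.

    Defaults follow a high-bandwidth single-channel protocol: 200 kHz
    sampling with a 2 kHz low-pass filter.  ``filter_cutoff=None`` disables
    filtering.  ``unitary_amplitude`` is the single-channel current step in
    pA at the recording potential (sign free; inward currents negative).
    """

    sampling_rate: float = 200_000.0
    filter_cutoff: Optional[float] = 2_000.0
    unitary_amplitude: float = 1.5
    noise_sd: float = 0.0
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.filter_cutoff is not None and not (
            self.sampling_rate > 2 * self.filter_cutoff
        ):
            raise ValueError("sampling_rate must exceed twice the filter cutoff")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.unitary_amplitude == 0:
            raise ValueError("unitary_amplitude must be nonzero")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass(frozen=True)
class DwellSequence:
    """Ordered (state index, duration) sojourns of one channel."""

    states: np.ndarray  # int state indices
    durations: np.ndarray  # seconds, > 0
    total_duration_s: float

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=int)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "durations", durations)
        if states.shape != durations.shape or states.ndim != 1:
            raise ValueError("states and durations must be equal-length 1-D")
        if states.size == 0:
            raise ValueError("empty dwell sequence")
        if np.any(durations <= 0):
            raise ValueError("durations must be > 0")
        if np.any(states[1:] == states[:-1]):
            raise ValueError("consecutive dwells must be in different states")
        if abs(durations.sum() - self.total_duration_s) > 1e-9:
            raise ValueError("durations must sum to total_duration_s")

    def class_sequence(self, scheme: KineticScheme) -> np.ndarray:
        """Boolean open/closed flag per dwell (True = open)."""
        return scheme.open_mask[self.states]

    def open_fraction(self, scheme: KineticScheme) -> float:
        is_open = self.class_sequence(scheme)
        return float(self.durations[is_open].sum() / self.total_duration_s)


@dataclass(frozen=True)
class Trace:
    """Sampled current trace with acquisition metadata.

    Time origin is 0; sample k sits at ``k / sampling_rate``.  When the
    trace was rendered from a simulation the ground-truth dwell sequence is
    attached for validation.
    """

    current: np.ndarray  # pA
    acquisition: AcquisitionConfig
    ground_truth: Optional[DwellSequence] = field(default=None, repr=False)
    extra_metadata: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        cur = np.asarray(self.current, dtype=np.float64)
        object.__setattr__(self, "current", cur)
        if cur.ndim != 1 or cur.size == 0:
            raise ValueError("current must be a nonempty 1-D array")
        if not np.all(np.isfinite(cur)):
            raise ValueError("current contains non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.current.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.acquisition.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.acquisition.sampling_rate


def sample_dwell_sequence(
    scheme: KineticScheme, duration_s: float, seed: int
) -> DwellSequence:
    """Sample a dwell sequence of the given length from the scheme.

    The initial state is drawn from the equilibrium occupancy, holding
    times are Exp(-q_ii), and jumps follow the embedded chain.  The final
    dwell is truncated at ``duration_s`` so durations sum exactly to the
    requested length.  Reproducible given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    q = scheme.generator
    exit_rates = -np.diag(q)
    n = scheme.n_states
    jump_cdf = np.zeros((n, n))
    for i in range(n):
        p = q[i].copy()
        p[i] = 0.0
        jump_cdf[i] = np.cumsum(p / exit_rates[i])

    pi = equilibrium_occupancy(scheme).occupancy
    state = int(rng.choice(n, p=pi))

    states: list[int] = []
    durations: list[float] = []
    t = 0.0
    # draw holding times and jumps in blocks for speed
    while t < duration_s:
        dwell = rng.exponential(1.0 / exit_rates[state])
        if t + dwell >= duration_s:
            dwell = duration_s - t
            if dwell > 0:
                if states and states[-1] == state:  # pragma: no cover
                    durations[-1] += dwell
                else:
                    states.append(state)
                    durations.append(dwell)
            t = duration_s
            break
        states.append(state)
        durations.append(dwell)
        t += dwell
        u = rng.random()
        state = int(np.searchsorted(jump_cdf[state], u, side="right"))
        state = min(state, n - 1)
    # exact tiling: fix accumulated floating error on the last dwell
    total = float(np.sum(durations))
    durations[-1] += duration_s - total
    return DwellSequence(
        states=np.array(states), durations=np.array(durations),
        total_duration_s=duration_s,
    )


def _ideal_signal(
    dwells: DwellSequence, scheme: KineticScheme, acq: AcquisitionConfig
) -> np.ndarray:
    """Piecewise-constant open-channel count signal, sampled."""
    n_samples = int(round(dwells.total_duration_s * acq.sampling_rate))
    edges = np.concatenate([[0.0], np.cumsum(dwells.durations)])
    # sample k covers time [k, k+1)/fs; classify by its left edge
    sample_times = np.arange(n_samples) / acq.sampling_rate
    dwell_idx = np.clip(
        np.searchsorted(edges, sample_times, side="right") - 1,
        0,
        dwells.states.size - 1,
    )
    is_open = dwells.class_sequence(scheme)[dwell_idx]
    shortest = dwells.durations.min()
    if shortest < 2.0 / acq.sampling_rate:
        logger.warning(
            "shortest dwell %.3g s spans < 2 samples at %.0f Hz; "
            "it may be unrepresentable in the rendered trace",
            shortest,
            acq.sampling_rate,
        )
    return is_open.astype(np.float64)


def render_trace(
    dwells: DwellSequence, scheme: KineticScheme, acq: AcquisitionConfig
) -> Trace:
    """Render a dwell sequence as a noisy, filtered current trace.

    The ideal signal is ``unitary_amplitude`` x (open channel count),
    Gaussian low-pass filtered at ``filter_cutoff``; white Gaussian noise
    of sd ``noise_sd`` is added after filtering the signal.
    """
    if dwells.states.max() >= scheme.n_states:
        raise ValueError("dwell sequence references states outside the scheme")
    signal = _ideal_signal(dwells, scheme, acq) * acq.unitary_amplitude
    if acq.n_channels > 1:
        rng_ch = np.random.default_rng(np.random.SeedSequence([acq.seed, 0x6368]))
        for k in range(1, acq.n_channels):
            extra = sample_dwell_sequence(
                scheme, dwells.total_duration_s, int(rng_ch.integers(2**31))
            )
            signal = signal + _ideal_signal(extra, scheme, acq) * acq.unitary_amplitude
    if acq.filter_cutoff is not None:
        sigma_samples = GAUSSIAN_SIGMA_COEFF * acq.sampling_rate / acq.filter_cutoff
        signal = gaussian_filter1d(signal, sigma_samples, mode="nearest")
    if acq.noise_sd > 0:
        rng = np.random.default_rng(acq.seed)
        signal = signal + rng.normal(0.0, acq.noise_sd, size=signal.size)
    return Trace(current=signal, acquisition=acq, ground_truth=dwells)


def simulate_condition_pair(
    scheme: KineticScheme,
    mod: ModifierSpec,
    duration_s: float,
    acq: AcquisitionConfig,
    seed: int,
) -> tuple[Trace, Trace]:
    """Simulate a control trace and a ligand-modified trace.

    The modified trace uses ``apply_modifier(scheme, mod)``.  Sub-seeds for
    the two dwell samples and the two noise streams are decorrelated but
    derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_ctrl, s_mod, n_ctrl, n_mod = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    modified_scheme = apply_modifier(scheme, mod)
    dw_ctrl = sample_dwell_sequence(scheme, duration_s, s_ctrl)
    dw_mod = sample_dwell_sequence(modified_scheme, duration_s, s_mod)
    tr_ctrl = render_trace(dw_ctrl, scheme, _reseed(acq, n_ctrl))
    tr_mod = render_trace(dw_mod, modified_scheme, _reseed(acq, n_mod))
    return tr_ctrl, tr_mod


def _reseed(acq: AcquisitionConfig, seed: int) -> AcquisitionConfig:
    from dataclasses import replace

    return replace(acq, seed=seed)
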