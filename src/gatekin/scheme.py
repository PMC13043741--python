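"""Continuous-time Markov models of single-channel gating.

A channel is modelled as a finite set of kinetic states, each belonging to a
conductance class (``OPEN`` or ``CLOSED``), connected by first-order
transition rates (s^-1).  The generator matrix Q has off-diagonal entries
``q_ij`` = rate from state i to state j and diagonal entries chosen so that
every row sums to zero.  The stationary distribution ``pi`` (``pi Q = 0``,
``sum(pi) = 1``) gives the equilibrium occupancy of each state; the open
probability Po is the summed occupancy of the OPEN states.

Ligand action is represented mean-field by rescaling rates rather than by
explicit bound states:

* ``OPEN_DESTABILIZE`` — every rate leaving an open state is multiplied by
  an effective factor ``f_eff``, shortening open dwells (the mechanism by
  which diacylglycerol inhibits TASK K2P channels);
* ``CLOSED_STABILIZE`` — every closed->open rate is divided by ``f_eff``,
  lengthening closed dwells;
* ``INDEPENDENT`` — gating untouched; occupancy-independent pore block is
  reported as a separate current scale factor ``1/(1 + X/K_d)``.

``f_eff`` saturates with ligand concentration X as
``f_eff = 1 + (max_factor - 1) * X / (X + K_d)``.

At equilibrium the first two mechanisms are degenerate: for a two-state
channel both yield Po' = beta/(f*alpha + beta), so macroscopic inhibition
alone cannot distinguish them.  Telling them apart requires the
single-channel dwell-time analysis in :mod:`gatekin.dwell` and
:mod:`gatekin.statedep`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StateClass",
    "Mechanism",
    "KineticScheme",
    "ModifierSpec",
    "EquilibriumSummary",
    "equilibrium_occupancy",
    "apply_modifier",
    "predicted_inhibition",
    "two_state",
    "two_state_for_po",
    "task_like",
    "n133s_like",
    "read_scheme",
    "write_scheme",
]

_ROWSUM_TOL = 1e-12
_OCC_TOL = 1e-10


class StateClass(str, enum.Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"


class Mechanism(str, enum.Enum):
    """How a ligand acts on the gating scheme."""

    OPEN_DESTABILIZE = "OPEN_DESTABILIZE"
    CLOSED_STABILIZE = "CLOSED_STABILIZE"
    INDEPENDENT = "INDEPENDENT"


@dataclass(frozen=True)
class KineticScheme:
    """Labelled-state CTMC gating model with conductance classes.

    Parameters
    ----------
    state_labels
        Short names, one per state.
    state_class
        Conductance class per state (``StateClass`` or its string value).
    rates
        Square matrix; entry ``(i, j)`` is the transition rate from state i
        to state j in s^-1 for ``i != j``.  The diagonal is ignored on input
        and defined internally by the generator convention.
    """

    state_labels: tuple[str, ...]
    state_class: tuple[StateClass, ...]
    rates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(s) for s in self.state_labels)
        classes = tuple(StateClass(c) for c in self.state_class)
        rates = np.array(self.rates, dtype=float)
        object.__setattr__(self, "state_labels", labels)
        object.__setattr__(self, "state_class", classes)
        object.__setattr__(self, "rates", rates)

        n = len(labels)
        if rates.ndim != 2 or rates.shape != (n, n):
            raise ValueError(
                f"rates must be a {n}x{n} matrix, got shape {rates.shape}"
            )
        if len(classes) != n:
            raise ValueError("state_class length must match state_labels")
        if len(set(labels)) != n:
            raise ValueError("state labels must be unique")
        off = rates[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)) or np.any(off < 0):
            raise ValueError("off-diagonal rates must be finite and >= 0")
        if StateClass.OPEN not in classes or StateClass.CLOSED not in classes:
            raise ValueError("need at least one OPEN and one CLOSED state")
        # zero the diagonal so .generator is well defined
        np.fill_diagonal(rates, 0.0)
        rates.setflags(write=False)
        self._check_strongly_connected()

    def _check_strongly_connected(self) -> None:
        adj = csr_matrix((self.rates > 0).astype(np.int8))
        ncomp, comp = connected_components(adj, directed=True, connection="strong")
        if ncomp > 1:
            # states outside the component of state 0 are the offenders
            bad = [lab for lab, c in zip(self.state_labels, comp) if c != comp[0]]
            raise ValueError(
                "scheme is reducible; states not mutually reachable with "
                f"state '{self.state_labels[0]}': {bad}"
            )

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def generator(self) -> np.ndarray:
        """Generator matrix Q: off-diagonal rates, rows summing to zero."""
        q = self.rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        assert np.all(np.abs(q.sum(axis=1)) < _ROWSUM_TOL)
        return q

    @property
    def open_mask(self) -> np.ndarray:
        return np.array([c is StateClass.OPEN for c in self.state_class])

    def with_rates(self, rates: np.ndarray) -> "KineticScheme":
        return KineticScheme(self.state_labels, self.state_class, rates)

    def index(self, label: str) -> int:
        return self.state_labels.index(label)


@dataclass(frozen=True)
class ModifierSpec:
    """Concentration-dependent gating modifier.

    ``max_factor`` (dimensionless, > 1) is the saturating rate-change
    factor; ``k_d_um`` the half-saturating concentration (µM);
    ``concentration_um`` the applied dose (µM).
    """

    mechanism: Mechanism
    max_factor: float
    k_d_um: float
    concentration_um: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        if not self.max_factor > 1:
            raise ValueError("max_factor must be > 1")
        if not self.k_d_um > 0:
            raise ValueError("K_d must be > 0")
        if self.concentration_um < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def effective_factor(self) -> float:
        """f_eff = 1 + (max_factor - 1) * X / (X + K_d), in [1, max_factor]."""
        x = self.concentration_um
        return 1.0 + (self.max_factor - 1.0) * x / (x + self.k_d_um)

    @property
    def block_scale(self) -> float:
        """Current scale factor 1/(1 + X/K_d) for INDEPENDENT pore block."""
        return 1.0 / (1.0 + self.concentration_um / self.k_d_um)

    def at(self, concentration_um: float) -> "ModifierSpec":
        return replace(self, concentration_um=concentration_um)


@dataclass(frozen=True)
class EquilibriumSummary:
    """Stationary occupancy and the derived open probability."""

    occupancy: np.ndarray
    open_probability: float


def equilibrium_occupancy(scheme: KineticScheme) -> EquilibriumSummary:
    """Stationary distribution of the gating scheme.

    Solves ``pi Q = 0`` subject to ``sum(pi) = 1`` by least squares on the
    normalisation-augmented system; for an irreducible generator the
    solution is unique and strictly positive.
    """
    q = scheme.generator
    n = scheme.n_states
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    if not np.isfinite(total) or abs(total - 1.0) > _OCC_TOL:
        raise ArithmeticError("stationary solve failed to normalise")
    pi = pi / total
    po = float(pi[scheme.open_mask].sum())
    return EquilibriumSummary(occupancy=pi, open_probability=po)


def apply_modifier(scheme: KineticScheme, mod: ModifierSpec) -> KineticScheme:
    """Return the scheme with the ligand's rate modification applied.

    OPEN_DESTABILIZE multiplies every rate exiting an OPEN state by
    ``f_eff``; CLOSED_STABILIZE divides every CLOSED->OPEN rate by
    ``f_eff``; INDEPENDENT leaves all rates untouched (its pore block is a
    current scale, see :attr:`ModifierSpec.block_scale`).
    """
    f = mod.effective_factor
    rates = scheme.rates.copy()
    open_mask = scheme.open_mask
    if mod.mechanism is Mechanism.OPEN_DESTABILIZE:
        rates[open_mask, :] *= f
    elif mod.mechanism is Mechanism.CLOSED_STABILIZE:
        closed = ~open_mask
        rates[np.ix_(closed, open_mask)] /= f
    elif mod.mechanism is Mechanism.INDEPENDENT:
        pass
    else:  # pragma: no cover - Mechanism() coercion catches this earlier
        raise ValueError(f"unknown mechanism {mod.mechanism!r}")
    return scheme.with_rates(rates)


def predicted_inhibition(scheme: KineticScheme, mod: ModifierSpec) -> float:
    """Fractional equilibrium inhibition ``I = 1 - Po(modified)/Po(baseline)``.

    For the INDEPENDENT mechanism the gating is untouched and the fractional
    current block ``X/(X + K_d)`` is returned instead.
    """
    if mod.mechanism is Mechanism.INDEPENDENT:
        x = mod.concentration_um
        return x / (x + mod.k_d_um)
    po0 = equilibrium_occupancy(scheme).open_probability
    if po0 <= 0:
        raise ValueError("baseline open probability is zero")
    po1 = equilibrium_occupancy(apply_modifier(scheme, mod)).open_probability
    return float(np.clip(1.0 - po1 / po0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# presets

def two_state(opening_rate: float = 10.0, closing_rate: float = 500.0) -> KineticScheme:
    """Minimal C<->O scheme; Po = beta/(alpha + beta)."""
    rates = np.array([[0.0, opening_rate], [closing_rate, 0.0]])
    return KineticScheme(("C", "O"), (StateClass.CLOSED, StateClass.OPEN), rates)


def two_state_for_po(po: float, closing_rate: float = 500.0) -> KineticScheme:
    """Two-state scheme with the requested equilibrium Po.

    The closing rate is held at a reference value and the opening rate
    solved from ``Po = beta/(alpha + beta)``.
    """
    if not 0 < po < 1:
        raise ValueError("po must lie in (0, 1)")
    beta = closing_rate * po / (1.0 - po)
    return two_state(opening_rate=beta, closing_rate=closing_rate)


_CHAIN_LABELS = ("Cdeep", "Cinter", "O", "Cflick")
_CHAIN_CLASSES = (
    StateClass.CLOSED,
    StateClass.CLOSED,
    StateClass.OPEN,
    StateClass.CLOSED,
)


def _chain(
    open_to_inter: float,
    open_to_flick: float,
    flick_to_open: float,
    inter_to_open: float,
    inter_to_deep: float,
    deep_to_inter: float,
) -> KineticScheme:
    r = np.zeros((4, 4))
    i = {lab: k for k, lab in enumerate(_CHAIN_LABELS)}
    r[i["O"], i["Cinter"]] = open_to_inter
    r[i["O"], i["Cflick"]] = open_to_flick
    r[i["Cflick"], i["O"]] = flick_to_open
    r[i["Cinter"], i["O"]] = inter_to_open
    r[i["Cinter"], i["Cdeep"]] = inter_to_deep
    r[i["Cdeep"], i["Cinter"]] = deep_to_inter
    return KineticScheme(_CHAIN_LABELS, _CHAIN_CLASSES, r)


def task_like() -> KineticScheme:
    """Wild-type-like TASK-1 gating preset.

    Linear chain Cdeep <-> Cinter <-> O <-> Cflick with low open
    probability (~0.018), ~1.5 ms mean open lifetime, ~0.3 ms intra-burst
    (flicker) closures, ~50 ms inter-burst closures and a rare ~1 s
    long-closed population — the burst-structured gating of a leak K2P
    channel in a cell-attached patch at -100 mV.
    """
    return _chain(
        open_to_inter=1000.0 / 3,
        open_to_flick=1000.0 / 3,
        flick_to_open=10000.0 / 3,
        inter_to_open=18.0,
        inter_to_deep=2.0,
        deep_to_inter=1.0,
    )


def n133s_like() -> KineticScheme:
    """Gain-of-function (N133S-like) preset with Po ~ 0.2.

    Same chain topology as :func:`task_like` but with briefer, more
    frequent sojourns in the inter-burst closed state, giving an
    equilibrium Po near 0.22 (the regime in which single-channel
    inhibition experiments are feasible).
    """
    return _chain(
        open_to_inter=250.0,
        open_to_flick=250.0,
        flick_to_open=10000.0 / 3,
        inter_to_open=149.0,
        inter_to_deep=1.0,
        deep_to_inter=1.0,
    )


# ---------------------------------------------------------------------------
# plain-text scheme files

def write_scheme(scheme: KineticScheme, path: str | Path) -> None:
    """Write a scheme as a ``[states]`` / ``[rates]`` text file."""
    lines = ["[states]"]
    for lab, cls in zip(scheme.state_labels, scheme.state_class):
        lines.append(f"{lab} {cls.value}")
    lines.append("")
    lines.append("[rates]")
    for i in range(scheme.n_states):
        for j in range(scheme.n_states):
            if i != j and scheme.rates[i, j] > 0:
                lines.append(
                    f"{scheme.state_labels[i]} {scheme.state_labels[j]} "
                    f"{scheme.rates[i, j]:.12g}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path: str | Path) -> KineticScheme:
    """Parse a ``[states]`` / ``[rates]`` scheme file.

    Rejects duplicate edges and rates for unknown states.
    """
    labels: list[str] = []
    classes: list[StateClass] = []
    edges: dict[tuple[str, str], float] = {}
    section = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() == "[states]":
            section = "states"
            continue
        if line.lower() == "[rates]":
            section = "rates"
            continue
        parts = line.split()
        if section == "states":
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'label CLASS'")
            labels.append(parts[0])
            classes.append(StateClass(parts[1].upper()))
        elif section == "rates":
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 'from to rate'")
            src, dst, val = parts[0], parts[1], float(parts[2])
            if (src, dst) in edges:
                raise ValueError(f"line {lineno}: duplicate edge {src}->{dst}")
            edges[(src, dst)] = val
        else:
            raise ValueError(f"line {lineno}: content before any section header")
    if not labels:
        raise ValueError("no [states] section found")
    idx = {lab: k for k, lab in enumerate(labels)}
    rates = np.zeros((len(labels), len(labels)))
    for (src, dst), val in edges.items():
        if src not in idx or dst not in idx:
            raise ValueError(f"rate references unknown state {src!r} or {dst!r}")
        rates[idx[src], idx[dst]] = val
    return KineticScheme(tuple(labels), tuple(classes), rates)
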