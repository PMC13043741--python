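"""Shared fixtures: schemes, simulated records, and saturating modifiers."""

import numpy as np
import pytest

import gatekin as gk

# concentration far above K_d so f_eff ~= max_factor
SATURATING_X = 1e9


def saturating(mechanism: str, max_factor: float, k_d: float = 1.0) -> gk.ModifierSpec:
    return gk.ModifierSpec(mechanism, max_factor, k_d, SATURATING_X)


@pytest.fixture(scope="session")
def task_scheme() -> gk.KineticScheme:
    return gk.task_like()


@pytest.fixture(scope="session")
def two_state_scheme() -> gk.KineticScheme:
    return gk.two_state(opening_rate=10.0, closing_rate=500.0)


@pytest.fixture(scope="session")
def wt_record(task_scheme) -> gk.IdealizedRecord:
    """60 s wild-type-like idealized record (dead time 50 µs)."""
    dw = gk.sample_dwell_sequence(task_scheme, 60.0, seed=101)
    return gk.record_from_dwells(dw, task_scheme)


@pytest.fixture(scope="session")
def destabilized_record(task_scheme) -> gk.IdealizedRecord:
    """60 s record under saturating open-state destabilisation (f=10)."""
    mod = saturating("OPEN_DESTABILIZE", 10.0)
    sch = gk.apply_modifier(task_scheme, mod)
    dw = gk.sample_dwell_sequence(sch, 60.0, seed=202)
    return gk.record_from_dwells(dw, sch)
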