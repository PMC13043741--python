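"""Hill dose–response fitting and model-predicted IC50s.

Concentration–inhibition relations are fitted with the four-parameter
logistic

    Y(X) = base + (max - base) / (1 + (X / X_half)^H)

where ``base`` is the fully inhibited current, ``max`` the control
current, ``X_half`` the half-maximal concentration (the IC50 for an
inhibitor) and ``H`` the Hill coefficient.  For responses normalised to
the pre-drug current, ``max`` is near 1 and the curve decreases with dose.

``ic50_from_model`` closes the loop with the gating model: it evaluates
the fractional equilibrium current ``Po(X)/Po(0)`` of a scheme under a
concentration-dependent modifier over a dose grid and fits the Hill
equation to it.  Under open-state destabilisation the apparent IC50 rises
with baseline Po — the model's account of why gain-of-function channels
lose ligand sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit import Model

from .scheme import (
    KineticScheme,
    Mechanism,
    ModifierSpec,
    equilibrium_occupancy,
    apply_modifier,
)

__all__ = ["DoseResponseData", "HillFit", "fit_hill", "ic50_from_model", "hill_curve"]


def hill_curve(x, base, maximum, x_half, h):
    """Four-parameter logistic, decreasing in x for maximum > base, h > 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / x_half) ** h, 0.0)
    return base + (maximum - base) / (1.0 + ratio)


@dataclass(frozen=True)
class DoseResponseData:
    """Normalised responses (control = 1) at a set of doses (µM)."""

    concentrations_um: np.ndarray
    responses: np.ndarray
    replicates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_um, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations_um", c)
        object.__setattr__(self, "responses", r)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must match 1-D")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        if np.unique(c).size < 4:
            raise ValueError("need at least 4 distinct concentrations")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with standard errors."""

    base: float
    maximum: float
    x_half_um: float
    hill_coefficient: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return hill_curve(x, self.base, self.maximum, self.x_half_um, self.hill_coefficient)


def fit_hill(
    data: DoseResponseData,
    fixed: Optional[dict] = None,
) -> HillFit:
    """Least-squares Hill fit with a deterministic initialisation rule.

    ``fixed`` may pin any of ``base``, ``maximum`` (alias ``max``) or
    ``h`` to a constant.  Initials: X_half at the dose whose response is
    nearest half-way between the extreme responses, H = 1.
    """
    fixed = dict(fixed or {})
    if "max" in fixed:
        fixed["maximum"] = fixed.pop("max")
    c, r = data.concentrations_um, data.responses
    if np.ptp(r) < 1e-9:
        raise ValueError("no dose dependence: all responses equal")

    r_hi, r_lo = float(r[np.argmin(c)]), float(r[np.argmax(c)])
    half = (r.max() + r.min()) / 2.0
    pos = c[c > 0]
    init_xhalf = float(pos[np.argmin(np.abs(r[c > 0] - half))]) if pos.size else 1.0

    model = Model(hill_curve)
    params = model.make_params(
        base=fixed.get("base", min(r_lo, r.min())),
        maximum=fixed.get("maximum", max(r_hi, r.max())),
        x_half=max(init_xhalf, 1e-12),
        h=fixed.get("h", 1.0),
    )
    params["x_half"].min = 1e-12
    params["h"].min = 1e-6
    for name, key in (("base", "base"), ("maximum", "maximum"), ("h", "h")):
        if key in fixed:
            params[name].vary = False
    result = model.fit(r, params, x=c)
    if not result.success:
        raise RuntimeError(f"Hill fit did not converge: {result.message}")
    p = result.params
    stderr = {
        "base": p["base"].stderr,
        "maximum": p["maximum"].stderr,
        "x_half_um": p["x_half"].stderr,
        "hill_coefficient": p["h"].stderr,
    }
    return HillFit(
        base=float(p["base"].value),
        maximum=float(p["maximum"].value),
        x_half_um=float(p["x_half"].value),
        hill_coefficient=float(p["h"].value),
        stderr=stderr,
        rss=float(np.sum(result.residual**2)),
    )


def ic50_from_model(
    scheme: KineticScheme,
    mechanism: Mechanism | str,
    max_factor: float,
    k_d_um: float,
    doses_um: Optional[Sequence[float]] = None,
) -> HillFit:
    """Apparent IC50 of a gating scheme under a modifier family.

    Evaluates the fractional current over a log-spaced dose grid — for
    state-dependent mechanisms ``Po(X)/Po(0)``, for INDEPENDENT the pore
    block ``1/(1 + X/K_d)`` — and fits the Hill equation.  Higher baseline
    Po yields a higher apparent IC50 under OPEN_DESTABILIZE.
    """
    mechanism = Mechanism(mechanism)
    if doses_um is None:
        doses_um = np.concatenate([[0.0], np.geomspace(k_d_um / 300, k_d_um * 3000, 25)])
    doses_um = np.asarray(doses_um, dtype=float)

    if mechanism is Mechanism.INDEPENDENT:
        responses = 1.0 / (1.0 + doses_um / k_d_um)
    else:
        po0 = equilibrium_occupancy(scheme).open_probability
        if po0 <= 0:
            raise ValueError("baseline open probability is zero")
        responses = np.empty_like(doses_um)
        for i, x in enumerate(doses_um):
            mod = ModifierSpec(mechanism, max_factor, k_d_um, x)
            po = equilibrium_occupancy(apply_modifier(scheme, mod)).open_probability
            responses[i] = po / po0
    return fit_hill(DoseResponseData(doses_um, responses))
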