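"""Single-site binder-toxin equilibrium: closed-form free fraction.

For a toxin T binding a single site on a binder A with association
constant ``KB = [AT] / ([T][A_free])``, mass action plus the two mass
balances give a quadratic for the free toxin concentration ``Cs`` in
terms of the totals ``Ct`` (toxin) and ``Ca`` (binder)::

    Cs = ( -(Ca + 1/KB - Ct) + sqrt((Ca + 1/KB - Ct)^2 + 4 Ct/KB) ) / 2

Only the primary binding site is modelled; the secondary site has an
order of magnitude lower affinity and is neglected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ValidationError

__all__ = ["EquilibriumState", "free_toxin", "equilibrium_state"]


@dataclass(frozen=True)
class EquilibriumState:
    c_total_toxin: float  # M
    c_total_binder: float  # M
    c_free_toxin: float  # M
    c_bound: float  # M


def free_toxin(c_total, c_binder, KB):
    """Free toxin concentration at binding equilibrium (M).

    Evaluates the stable root of the binding quadratic.  When the toxin
    is present only in traces relative to the binder the textbook form
    suffers catastrophic cancellation, so the conjugate form
    ``2*Ct / (KB*(sqrt(disc) + q))`` is used whenever ``q > 0``.

    Accepts scalars or numpy arrays (broadcast).
    """
    c_total = np.asarray(c_total, dtype=float)
    c_binder = np.asarray(c_binder, dtype=float)
    scalar = c_total.ndim == 0 and c_binder.ndim == 0
    if np.any(c_total < 0) or np.any(c_binder < 0):
        raise ValidationError("concentrations must be non-negative")
    if KB <= 0:
        raise ValidationError("KB must be positive")

    q = c_binder + 1.0 / KB - c_total
    disc = q * q + 4.0 * c_total / KB
    if np.any(disc < 0):
        # analytically impossible for valid inputs: flag numeric misuse
        raise FloatingPointError("negative discriminant in binding quadratic")
    root = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        stable = np.where(
            q > 0,
            2.0 * c_total / (KB * (root + np.abs(q))),
            0.5 * (root - q),
        )
    cs = np.minimum(stable, c_total)  # guard round-off overshoot
    return float(cs) if scalar else cs


def equilibrium_state(c_total, c_binder, KB) -> EquilibriumState:
    """Full equilibrium bookkeeping for scalar inputs."""
    cs = free_toxin(float(c_total), float(c_binder), KB)
    bound = float(c_total) - cs
    if bound > c_binder * (1 + 1e-12) + 1e-30:
        raise FloatingPointError("bound toxin exceeds binder capacity")
    return EquilibriumState(
        c_total_toxin=float(c_total),
        c_total_binder=float(c_binder),
        c_free_toxin=cs,
        c_bound=bound,
    )
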