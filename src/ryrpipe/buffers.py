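"""Free-Ca2+ solver for 1:1 Ca-EGTA buffering.

Assay solutions set free [Ca2+] by buffering total calcium with EGTA.
For a single 1:1 ligand the equilibrium

    Ca + EGTA <-> CaEGTA,   Kd_app = [Ca][EGTA_free] / [CaEGTA]

with mass conservation gives a quadratic in the free calcium
concentration x:

    x^2 + (Kd + EGTA_total - Ca_total) * x - Kd * Ca_total = 0

whose unique non-negative root is the free [Ca2+].  ``kd_app`` is the
*apparent* dissociation constant at the working pH/ionic strength and is
deliberately a parameter: full chelator calculators apply proton and
competing-ion corrections that a single-ligand model does not carry.

The default ``KD_APP_DEFAULT = 431.5 nM`` is calibrated so that
65 uM total Ca in 1 mM EGTA yields 30 nM free Ca (the screen's resting-
calcium condition).  The alternative high-calcium calibration
(1.02 mM total -> 30 uM free) implies ~303 nM; ``KD_APP_HIGH_CA`` is
provided for that regime.  All concentrations are in molar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BufferSpec",
    "free_ca",
    "total_ca_for_free",
    "KD_APP_DEFAULT",
    "KD_APP_HIGH_CA",
]

#: Apparent Ca-EGTA Kd (molar) calibrated on the (65 uM total, 30 nM free) condition.
KD_APP_DEFAULT = 431.5e-9
#: Apparent Kd implied by the (1.02 mM total, 30 uM free) condition.
KD_APP_HIGH_CA = 303.0e-9


@dataclass(frozen=True)
class BufferSpec:
    """Total calcium, total EGTA and apparent Kd, all in molar."""

    total_ca: float
    total_egta: float
    kd_app: float = KD_APP_DEFAULT

    def validate(self) -> None:
        if self.total_ca < 0 or self.total_egta < 0:
            raise ValueError("total concentrations must be non-negative")
        if self.kd_app <= 0:
            raise ValueError("kd_app must be positive")


def free_ca(spec: BufferSpec) -> float:
    """Free [Ca2+] (molar) of a Ca-EGTA buffer.

    Solves the 1:1 binding quadratic in a numerically stable form (no
    subtraction of nearly equal numbers, which matters when free << total).
    """
    spec.validate()
    ca, egta, kd = spec.total_ca, spec.total_egta, spec.kd_app
    if ca == 0:
        return 0.0
    b = kd + egta - ca
    disc = b * b + 4.0 * kd * ca
    sqrt_disc = float(np.sqrt(disc))
    if b >= 0:
        # root via the conjugate form: (-b + sqrt) = 4*kd*ca / (b + sqrt)
        x = 2.0 * kd * ca / (b + sqrt_disc)
    else:
        x = 0.5 * (-b + sqrt_disc)
    return float(min(x, ca))


def total_ca_for_free(
    target_free: float, total_egta: float, kd_app: float = KD_APP_DEFAULT
) -> float:
    """Total calcium (molar) required to reach a target free [Ca2+].

    Closed-form inverse of :func:`free_ca`:
    ``total = free + egta * free / (kd + free)``.
    """
    if target_free < 0:
        raise ValueError("target_free must be non-negative")
    if total_egta < 0:
        raise ValueError("total_egta must be non-negative")
    if kd_app <= 0:
        raise ValueError("kd_app must be positive")
    return float(target_free + total_egta * target_free / (kd_app + target_free))
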