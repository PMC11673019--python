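"""Resonant-frequency → elastic-modulus calibration.

VOCT estimates tissue stiffness from the resonant frequency ``fn`` through
an empirical calibration established by simultaneous in-vitro uniaxial
tensile testing and VOCT on soft tissues::

    E * d = a * fn**2 + b        (a = 0.0651, b = 233.1)

where ``E`` is the tensile elastic modulus and ``d`` the tissue thickness.

Unit convention
---------------
The calibration's right-hand side is treated as MPa·µm (numerically equal
to Pa·m): with ``d`` in micrometres the formula returns ``E`` in MPa, which
is the only reading consistent with reported corneal moduli of 2–3 MPa for
a ~500 µm cornea resonating near 110–150 Hz.  The source literature prints
"d is in m" alongside MPa moduli, which is dimensionally inconsistent with
those magnitudes; a ``thickness_unit`` flag is exposed so callers may pass
``d`` in metres, in which case it is converted to µm internally and the
returned modulus is still MPa.

Because measurements are made on a 10 Hz frequency grid, every estimate
carries an interval ``[E_low, E_high]`` obtained by evaluating the
calibration at ``fn ∓ 10 Hz`` (floored at 0 Hz) — interval arithmetic on
the stated ±10 Hz resonance accuracy rather than Gaussian propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationModel",
    "ModulusEstimate",
    "modulus_from_resonance",
    "resonance_from_modulus",
    "weighted_average_modulus",
    "GRID_ACCURACY_HZ",
]

GRID_ACCURACY_HZ = 10.0


@dataclass(frozen=True)
class CalibrationModel:
    """Coefficients of the empirical E·d = a·fn² + b calibration.

    ``quadratic_coefficient`` (a) is in MPa·µm/Hz² and ``intercept`` (b) in
    MPa·µm.  ``thickness_unit`` selects the unit of thickness arguments:
    ``"um"`` (default) or ``"m"``.
    """

    quadratic_coefficient: float = 0.0651
    intercept: float = 233.1
    thickness_unit: str = "um"

    def __post_init__(self) -> None:
        if self.quadratic_coefficient <= 0:
            raise ValueError("quadratic coefficient must be positive")
        if self.intercept < 0:
            raise ValueError("intercept must be non-negative")
        if self.thickness_unit not in ("um", "m"):
            raise ValueError("thickness_unit must be 'um' or 'm'")

    def thickness_um(self, d: float) -> float:
        return d * 1e6 if self.thickness_unit == "m" else d

    def rhs(self, fn: float) -> float:
        """a·fn² + b in MPa·µm."""
        return self.quadratic_coefficient * fn**2 + self.intercept


@dataclass(frozen=True)
class ModulusEstimate:
    """A modulus estimate with its ±10 Hz grid-uncertainty interval."""

    fn: float
    thickness: float  # µm
    E: float  # MPa
    E_low: float
    E_high: float
    band: str = "unassigned"

    def __post_init__(self) -> None:
        if not (self.E_low <= self.E <= self.E_high):
            raise ValueError("modulus interval must bracket the point estimate")
        if self.E <= 0 or self.thickness <= 0:
            raise ValueError("modulus and thickness must be positive")


def modulus_from_resonance(
    fn: float,
    d: float,
    model: CalibrationModel | None = None,
    band: str = "unassigned",
) -> ModulusEstimate:
    """Elastic modulus (MPa) of a component resonating at ``fn`` Hz.

    ``d`` is the component thickness in the model's ``thickness_unit``
    (µm by default).  The interval endpoints come from ``fn ∓ 10 Hz``, the
    frequency-grid accuracy, with the lower frequency floored at 0.
    """
    model = model or CalibrationModel()
    if fn < 0:
        raise ValueError("resonant frequency must be non-negative")
    d_um = model.thickness_um(d)
    if d_um <= 0:
        raise ValueError("thickness must be positive")
    e = model.rhs(fn) / d_um
    e_low = model.rhs(max(fn - GRID_ACCURACY_HZ, 0.0)) / d_um
    e_high = model.rhs(fn + GRID_ACCURACY_HZ) / d_um
    return ModulusEstimate(fn=fn, thickness=d_um, E=e, E_low=e_low, E_high=e_high, band=band)


def resonance_from_modulus(
    E: float, d: float, model: CalibrationModel | None = None
) -> float:
    """Invert the calibration: the resonant frequency (Hz) of a component
    with modulus ``E`` (MPa) and thickness ``d``.

    Requires ``E·d ≥ b``; at exact equality the resonance is 0 Hz, and
    below the intercept no real resonance exists.  Used by the synthetic
    generator to place peaks that encode prescribed moduli.
    """
    model = model or CalibrationModel()
    d_um = model.thickness_um(d)
    if d_um <= 0:
        raise ValueError("thickness must be positive")
    ed = E * d_um
    if ed < model.intercept:
        raise ValueError(
            f"E*d = {ed:g} MPa*um is below the calibration intercept "
            f"{model.intercept:g}; no real resonance"
        )
    return float(np.sqrt((ed - model.intercept) / model.quadratic_coefficient))


def weighted_average_modulus(peaks: list[tuple[float, float]]) -> float:
    """Peak-height-weighted mean modulus, Σ(hᵢ·Eᵢ)/Σhᵢ.

    ``peaks`` is a list of ``(height, modulus)`` pairs.  The weighting by
    displacement peak height makes this an average weighted by the light
    reflected back from each tissue component.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    h = np.array([p[0] for p in peaks], dtype=float)
    e = np.array([p[1] for p in peaks], dtype=float)
    if np.any(h <= 0):
        raise ValueError("peak heights must be positive")
    return float(np.sum(h * e) / np.sum(h))
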