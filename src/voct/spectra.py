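"""Mechanovibrational spectrum processing.

A vibrational-OCT (VOCT) measurement drives a tissue with audible sound and
records the in-phase transverse displacement at each driving frequency.  The
resulting *weighted displacement versus frequency* curve shows resonance
peaks that have been assigned to distinct corneal components: epithelial
cells and keratocytes (~80 Hz), anterior collagen lamellae together with
Bowman's layer (110–120 Hz), posterior lamellae (140–150 Hz), and the
limbus/sclera junction (240–250 Hz).

This module provides the spectrum container, the two normalisations used in
practice (division by the speaker's no-sample displacement, and per-spectrum
scaling to a unit maximum), grid-resolution peak detection, and the mapping
from peak frequency to tissue-component band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "VibrationalSpectrum",
    "ResonantPeak",
    "GridMismatchError",
    "BANDS",
    "normalize_by_speaker",
    "normalize_unit_max",
    "detect_peaks",
    "assign_band",
]

#: Tissue-component bands (inclusive frequency windows, Hz).  The cellular
#: band is widened to 70–90 Hz because the cellular resonance is reported
#: anywhere between 60–80 and 80 Hz depending on the sample.
BANDS: dict[str, tuple[float, float]] = {
    "cells_80": (70.0, 90.0),
    "anterior_110_120": (110.0, 120.0),
    "posterior_140_150": (140.0, 150.0),
    "limbus_240_250": (240.0, 250.0),
}

GRID_STEP_HZ = 10.0


class GridMismatchError(ValueError):
    """Two spectra do not share the same frequency grid."""


@dataclass
class VibrationalSpectrum:
    """One eye's weighted displacement versus frequency curve.

    Parameters
    ----------
    frequencies
        Uniform ascending grid in Hz (10 Hz step).
    displacements
        Dimensionless weighted displacement, one value per grid frequency.
    eye_id, species, group, stage, location
        Subject metadata.  ``species`` is ``"human"`` or ``"porcine"``;
        ``group`` is ``"control"``, ``"kc"`` or ``"not_applicable"``;
        ``stage`` is the keratoconus stage 1–4 (``None`` otherwise);
        ``location`` is ``"central"`` or ``"inferior"``.
    normalization_state
        One of ``"raw"``, ``"speaker_normalized"``, ``"unit_max"``.
    """

    frequencies: np.ndarray
    displacements: np.ndarray
    eye_id: str = ""
    species: str = "human"
    group: str = "control"
    stage: int | None = None
    location: str = "central"
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.validate()

    def validate(self) -> None:
        f, d = self.frequencies, self.displacements
        if f.ndim != 1 or f.size < 2:
            raise ValueError("frequency grid must be 1-D with at least 2 points")
        if f.size != d.size:
            raise ValueError(
                f"{f.size} frequencies but {d.size} displacements"
            )
        steps = np.diff(f)
        if not np.allclose(steps, steps[0]) or steps[0] <= 0:
            raise ValueError("frequency grid must be uniform and ascending")
        if self.normalization_state not in ("raw", "speaker_normalized", "unit_max"):
            raise ValueError(f"unknown normalization state {self.normalization_state!r}")
        if self.normalization_state != "raw" and np.any(d < 0):
            raise ValueError("normalized displacements must be non-negative")
        if self.normalization_state == "unit_max" and not np.isclose(d.max(), 1.0):
            raise ValueError("unit_max spectrum must have maximum exactly 1")

    @property
    def grid_step(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def same_grid(self, other: "VibrationalSpectrum") -> bool:
        return self.frequencies.shape == other.frequencies.shape and np.allclose(
            self.frequencies, other.frequencies
        )


@dataclass
class ResonantPeak:
    """A detected resonance: grid frequency, height and component band."""

    frequency: float
    height: float
    band: str = "unassigned"

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")


def normalize_by_speaker(
    raw: VibrationalSpectrum, baseline: VibrationalSpectrum
) -> VibrationalSpectrum:
    """Divide a raw spectrum pointwise by the speaker's no-sample displacement.

    The speaker baseline is measured without the sample; dividing by it
    removes the frequency response of the sound source, leaving the tissue's
    weighted displacement.
    """
    if not raw.same_grid(baseline):
        raise GridMismatchError(
            f"grids differ: {raw.frequencies[0]:g}-{raw.frequencies[-1]:g} Hz "
            f"vs {baseline.frequencies[0]:g}-{baseline.frequencies[-1]:g} Hz"
        )
    bad = np.flatnonzero(baseline.displacements <= 0)
    if bad.size:
        raise ValueError(
            f"baseline is zero or negative at {baseline.frequencies[bad[0]]:g} Hz"
        )
    ratio = raw.displacements / baseline.displacements
    return replace(
        raw,
        displacements=np.maximum(ratio, 0.0),
        normalization_state="speaker_normalized",
    )


def normalize_unit_max(s: VibrationalSpectrum) -> VibrationalSpectrum:
    """Scale a spectrum so its largest value is exactly 1.

    Used before clustering so that spectra from different eyes are
    comparable frequency-by-frequency on a common 0–1 scale.  Idempotent.
    """
    peak = s.displacements.max()
    if peak <= 0:
        raise ValueError("cannot unit-max normalize an all-zero spectrum")
    return replace(
        s, displacements=s.displacements / peak, normalization_state="unit_max"
    )


def detect_peaks(
    s: VibrationalSpectrum,
    min_prominence: float = 0.05,
    bands: dict[str, tuple[float, float]] | None = None,
) -> list[ResonantPeak]:
    """Find resonant peaks on the 10 Hz grid.

    A peak is a strict local maximum over its 3-point neighbourhood whose
    height is at least ``min_prominence`` times the spectrum maximum (so the
    result is invariant under unit-max rescaling).  Resolution is one grid
    step (±10 Hz).  Tie-break: when two adjacent samples are equal and both
    exceed their outer neighbours, the lower frequency is reported.
    Boundary grid points count as peaks when strictly greater than their
    single interior neighbour.
    """
    if s.normalization_state == "raw":
        raise ValueError("detect_peaks requires a speaker_normalized or unit_max spectrum")
    y = s.displacements
    top = y.max()
    if top <= 0:
        return []
    n = y.size
    threshold = min_prominence * top
    peaks: list[ResonantPeak] = []
    for i in range(n):
        left_ok = i == 0 or y[i] > y[i - 1]
        # >= on the right admits the first sample of an equal-adjacent pair
        # (the lower frequency) while rejecting the second (fails left_ok).
        right_ok = i == n - 1 or y[i] >= y[i + 1]
        if i == 0:
            left_ok, right_ok = True, y[0] > y[1]
        if i == n - 1:
            left_ok, right_ok = y[-1] > y[-2], True
        if left_ok and right_ok and y[i] >= threshold:
            f = float(s.frequencies[i])
            peaks.append(ResonantPeak(f, float(y[i]), assign_band(f, bands)))
    return peaks


def assign_band(
    frequency: float, bands: dict[str, tuple[float, float]] | None = None
) -> str:
    """Map a resonance frequency to its tissue-component band label."""
    for name, (lo, hi) in (bands or BANDS).items():
        if lo <= frequency <= hi:
            return name
    return "unassigned"
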