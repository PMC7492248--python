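"""Exchange-efficiency and hemolysis metrics.

TLC densitometry resolves lipid classes, not species, and methyl-α-cyclodextrin
does not extract cholesterol — so the cholesterol band is the per-lane loading
control. Exchange efficiency for a class is the relative drop of its
cholesterol-normalized band intensity across the exchange:

    efficiency = (before − after) / before

Hemolysis is read from 541 nm absorbance (the hemoglobin Soret-region peak used
for RBC lysis assays) by linear interpolation between a negative control (cells
in DPBS) and a positive control (cells fully lysed in water).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping

from .species import HeadgroupClass

__all__ = [
    "TLCProfile",
    "HemolysisReading",
    "NormalizationError",
    "InvalidControlError",
    "AssayWarning",
    "normalize_to_cholesterol",
    "exchange_efficiency",
    "class_efficiencies",
    "hemolysis_percent",
]


class NormalizationError(ValueError):
    """Lane cannot be normalized (cholesterol band missing or non-positive)."""


class InvalidControlError(ValueError):
    """Hemolysis controls are unusable (positive control not above negative)."""


class AssayWarning(UserWarning):
    """Out-of-range assay value reported unclamped (signals an assay problem)."""


@dataclass(frozen=True)
class TLCProfile:
    """Densitometry of one TLC lane: one band intensity per lipid class."""

    lane_id: str
    band_intensity: Mapping[HeadgroupClass, float]
    cholesterol_intensity: float

    def __post_init__(self) -> None:
        for cls, v in self.band_intensity.items():
            if v < 0:
                raise ValueError(f"negative band intensity for {cls}")


@dataclass(frozen=True)
class HemolysisReading:
    """One 541 nm absorbance with its negative (DPBS) and positive (water) controls."""

    a_sample: float
    a_neg: float
    a_pos: float

    def __post_init__(self) -> None:
        if self.a_pos <= self.a_neg:
            raise InvalidControlError(
                f"positive control ({self.a_pos}) must exceed negative "
                f"control ({self.a_neg})"
            )


def normalize_to_cholesterol(profile: TLCProfile) -> Dict[HeadgroupClass, float]:
    """Divide each class band by the lane's cholesterol band."""
    if profile.cholesterol_intensity <= 0:
        raise NormalizationError(
            f"lane {profile.lane_id!r}: cholesterol band missing or non-positive"
        )
    return {
        cls: v / profile.cholesterol_intensity
        for cls, v in profile.band_intensity.items()
    }


def exchange_efficiency(before: float, after: float) -> float:
    """Fraction of a lipid class removed by the exchange.

    ``before`` and ``after`` are cholesterol-normalized band intensities of the
    same class. A negative value (band grew) is reported as-is with an
    :class:`AssayWarning` rather than clamped.
    """
    if before <= 0:
        raise ValueError("before-exchange normalized intensity must be positive")
    if after < 0:
        raise ValueError("after-exchange normalized intensity must be non-negative")
    eff = (before - after) / before
    if eff < -1e-12:  # ignore float round-off on unchanged bands
        warnings.warn(
            f"negative exchange efficiency ({eff:.3g}): band intensity increased",
            AssayWarning,
            stacklevel=2,
        )
    return eff


def class_efficiencies(
    before: TLCProfile, after: TLCProfile
) -> Dict[HeadgroupClass, float]:
    """Per-class efficiencies from a before/after lane pair (shared classes only)."""
    nb = normalize_to_cholesterol(before)
    na = normalize_to_cholesterol(after)
    return {
        cls: exchange_efficiency(nb[cls], na[cls])
        for cls in nb
        if cls in na and nb[cls] > 0
    }


def hemolysis_percent(reading: HemolysisReading) -> float:
    """Percent hemolysis by linear interpolation between the assay controls.

    Values outside [0, 100] (sample darker than the water control, or below
    the DPBS baseline) are reported unclamped with an :class:`AssayWarning`.
    """
    pct = 100.0 * (reading.a_sample - reading.a_neg) / (reading.a_pos - reading.a_neg)
    if pct < 0.0 or pct > 100.0:
        warnings.warn(
            f"hemolysis {pct:.3g}% outside [0, 100]: check controls",
            AssayWarning,
            stacklevel=2,
        )
    return pct
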