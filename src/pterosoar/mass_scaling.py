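"""Mass and size rescaling utilities for fragmentary giant pterosaurs.

Three small tools that carry disproportionate argumentative weight:

* a segment-wise volumetric correction — when a reconstruction's torso is
  too long by some factor, only the axial segment shrinks with it, the
  appendicular mass (limbs, wing) being anchored to the measured wing
  skeleton;
* a span <-> mass power law, the invertible allometry used to translate
  between wingspan caps and mass caps;
* a body-density plausibility check, since mass estimates that imply
  densities far above water are anatomically impossible for a volant animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SegmentedMass",
    "SpanMassRegression",
    "DensityCheck",
    "DEFAULT_SPAN_MASS_REGRESSION",
    "DEFAULT_DENSITY_BAND",
    "segmentwise_correction",
    "mass_from_span",
    "span_from_mass",
    "mass_ratio_between_spans",
    "density_check",
]


@dataclass(frozen=True)
class SegmentedMass:
    """A reconstruction's mass split into axial and appendicular segments."""

    total: float
    axial: float

    def __post_init__(self) -> None:
        if self.total < 0 or self.axial < 0:
            raise ValueError("masses must be non-negative")
        if self.axial > self.total:
            raise ValueError("axial mass cannot exceed total")

    @property
    def appendicular(self) -> float:
        return self.total - self.axial


@dataclass(frozen=True)
class SpanMassRegression:
    """mass = coeff * span**exponent (kg, m); exactly invertible."""

    coeff: float
    exponent: float
    source: str = "anchor-pair calibration"

    def __post_init__(self) -> None:
        if self.coeff <= 0 or self.exponent <= 0:
            raise ValueError("coeff and exponent must be positive")

    @classmethod
    def through_points(
        cls, pair1: tuple[float, float], pair2: tuple[float, float], source: str = ""
    ) -> "SpanMassRegression":
        """Unique power law through two (span m, mass kg) anchor pairs."""
        (s1, m1), (s2, m2) = pair1, pair2
        if min(s1, m1, s2, m2) <= 0 or s1 == s2:
            raise ValueError("anchors must be positive with distinct spans")
        exponent = math.log(m2 / m1) / math.log(s2 / s1)
        coeff = m1 / s1**exponent
        return cls(coeff=coeff, exponent=exponent, source=source or "anchor pair")


# Calibrated through the two printed anchor pairs (6.65 m, 70 kg) and
# (4.2 m, 22 kg) of the 'heavy' pterosaur dataset: exponent ~2.519.
DEFAULT_SPAN_MASS_REGRESSION = SpanMassRegression.through_points(
    (6.65, 70.0), (4.2, 22.0), source="heavy-pterosaur anchor pairs"
)

# Birds run 0.6-0.9 g/cm^3, non-volant animals ~1: anything above the band
# is implausibly dense for a flyer.
DEFAULT_DENSITY_BAND = (0.6, 1.0)


@dataclass(frozen=True)
class DensityCheck:
    density: float  # g/cm^3
    plausible_band: tuple[float, float]
    verdict: str    # "plausible" | "implausible"


def segmentwise_correction(
    masses: SegmentedMass | float,
    axial: float | None = None,
    axial_length_factor: float = 1.0,
) -> float:
    """Corrected total mass after shrinking the axial segment, kg.

    The axial segment's volume (hence mass) scales linearly with torso
    length at fixed cross-section, so an over-long torso is corrected by
    dividing axial mass by the length factor; appendicular mass is left
    untouched.  Accepts either a SegmentedMass or (total, axial) floats.
    """
    if axial_length_factor <= 0:
        raise ValueError("axial_length_factor must be positive")
    if not isinstance(masses, SegmentedMass):
        if axial is None:
            raise ValueError("axial mass required when total given as a float")
        masses = SegmentedMass(total=float(masses), axial=float(axial))
    return masses.axial / axial_length_factor + masses.appendicular


def mass_from_span(span: float, reg: SpanMassRegression | None = None) -> float:
    """Predicted body mass (kg) at a given wingspan (m)."""
    reg = reg or DEFAULT_SPAN_MASS_REGRESSION
    if span <= 0:
        raise ValueError("span must be positive")
    return reg.coeff * span**reg.exponent


def span_from_mass(mass: float, reg: SpanMassRegression | None = None) -> float:
    """Predicted wingspan (m) at a given body mass (kg); inverse of the above."""
    reg = reg or DEFAULT_SPAN_MASS_REGRESSION
    if mass <= 0:
        raise ValueError("mass must be positive")
    return (mass / reg.coeff) ** (1.0 / reg.exponent)


def mass_ratio_between_spans(
    span1: float, span2: float, reg: SpanMassRegression | None = None
) -> float:
    """Mass multiplier implied by growing span1 -> span2."""
    reg = reg or DEFAULT_SPAN_MASS_REGRESSION
    if span1 <= 0 or span2 <= 0:
        raise ValueError("spans must be positive")
    return (span2 / span1) ** reg.exponent


def density_check(
    mass: float,
    volume: float,
    band: tuple[float, float] = DEFAULT_DENSITY_BAND,
) -> DensityCheck:
    """Body density (g/cm^3 = kg/L) and its plausibility for a flyer.

    The verdict is 'plausible' iff the density lies strictly inside the
    band: 1.0 g/cm^3 — the non-volant figure — already fails the flyer test.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if mass < 0:
        raise ValueError("mass must be non-negative")
    rho = mass / volume
    lo, hi = band
    verdict = "plausible" if lo < rho < hi else "implausible"
    return DensityCheck(density=rho, plausible_band=(lo, hi), verdict=verdict)
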