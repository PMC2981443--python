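"""Elliptical-beam model of long-bone midshaft strength.

Pterosaur (and bird) long bones are thin-walled, nearly elliptical tubes at
midshaft.  Treating the midshaft as a hollow ellipse gives closed forms for
the polar second moment of area J and the polar section modulus Zp, from
which a cantilever bending failure force and a size-corrected robustness
index — the Relative Failure Force (RFF), failure force in multiples of body
weight — follow directly.  Comparing a specimen's RFF with the RFF predicted
by avian structural scaling at the same body mass asks whether the element is
built like a scaled-up bird bone or something altogether more robust.

Units follow the morphometric convention: radii and lengths in mm, section
moduli in mm**3, stresses in MPa, so that MPa * mm**3 / mm = N without
conversion factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BoneSection",
    "SectionProperties",
    "MaterialParams",
    "AvianScalingModel",
    "FailureAssessment",
    "polar_second_moment_ellipse",
    "cortical_J",
    "polar_section_modulus",
    "section_properties",
    "cantilever_failure_force",
    "relative_failure_force",
    "avian_expected_rff",
    "rff_ratio",
    "assess_failure",
]

VALID_ELEMENTS = ("humerus", "femur", "cervical", "other")


@dataclass(frozen=True)
class BoneSection:
    """One midshaft cross-section plus the context needed to assess it.

    Outer/inner radii are the dorsoventral (``a``) and anteroposterior
    (``b``) semi-axes of the elliptical section, in mm.  ``length`` is total
    element length (the cantilever moment arm), in mm.  A specimen may carry
    several candidate body masses (kg); the assessment is repeated per
    candidate.
    """

    taxon: str
    element: str
    a_out: float
    b_out: float
    a_in: float
    b_in: float
    length: float
    body_mass_candidates: tuple[float, ...]
    wingspan: float | None = None

    def __post_init__(self) -> None:
        if self.element not in VALID_ELEMENTS:
            raise ValueError(
                f"element must be one of {VALID_ELEMENTS}, got {self.element!r}"
            )
        for name in ("a_out", "b_out", "a_in", "b_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.a_in > self.a_out or self.b_in > self.b_out:
            raise ValueError("inner radii must not exceed outer radii")
        if self.length <= 0:
            raise ValueError("length must be positive")
        masses = tuple(float(m) for m in self.body_mass_candidates)
        if not masses or not any(m > 0 for m in masses):
            raise ValueError("need at least one positive body-mass candidate")
        object.__setattr__(self, "body_mass_candidates", masses)

    @classmethod
    def from_cortical_thickness(
        cls,
        taxon: str,
        element: str,
        a_out: float,
        b_out: float,
        cortical_thickness: float,
        length: float,
        body_mass_candidates,
        wingspan: float | None = None,
    ) -> "BoneSection":
        """Build a section from a uniform wall thickness t.

        Inner radii are a_out - t and b_out - t, floored at zero.  This is
        the form in which broken fossil elements are usually measured.
        """
        if cortical_thickness < 0:
            raise ValueError("cortical thickness must be non-negative")
        return cls(
            taxon=taxon,
            element=element,
            a_out=a_out,
            b_out=b_out,
            a_in=max(a_out - cortical_thickness, 0.0),
            b_in=max(b_out - cortical_thickness, 0.0),
            length=length,
            body_mass_candidates=tuple(body_mass_candidates),
            wingspan=wingspan,
        )


@dataclass(frozen=True)
class SectionProperties:
    """Polar section properties of one hollow elliptical midshaft."""

    J_solid: float      # mm^4
    J_medullary: float  # mm^4
    J_cortical: float   # mm^4
    Zp: float           # mm^3
    Zp_per_length: float  # mm^2, length-corrected modulus


@dataclass(frozen=True)
class MaterialParams:
    """Material/loading constants for the failure model.

    sigma_max: breaking stress of the bone tissue, MPa.  175 MPa is the
        experimental breaking limit of avian bone — conservative for most
        vertebrate bone.
    bending_share: fraction of Zp credited to single-plane bending strength.
        Zp measures torsional and (twice) average bending strength, hence
        the 0.5 default; configurable because absolute failure forces depend
        on this convention while RFF ratios and scalings do not.
    """

    sigma_max: float = 175.0
    bending_share: float = 0.5
    g: float = 9.81

    def __post_init__(self) -> None:
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")
        if not 0 < self.bending_share <= 1:
            raise ValueError("bending_share must be in (0, 1]")
        if self.g <= 0:
            raise ValueError("g must be positive")


@dataclass(frozen=True)
class AvianScalingModel:
    """Power-law expectation of RFF for a bird of given mass.

    expected RFF = 10**(intercept + exponent * log10(mass_kg)).
    """

    intercept: float
    exponent: float
    source: str = "fixture"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intercept) and math.isfinite(self.exponent)):
            raise ValueError("model coefficients must be finite")


@dataclass(frozen=True)
class FailureAssessment:
    """Failure force and its size-corrected comparison for one mass candidate."""

    taxon: str
    element: str
    mass: float                     # kg
    failure_force: float            # N
    rff: float                      # body weights
    avian_expectation: float | None = None
    ratio_observed_expected: float | None = field(default=None)


def polar_second_moment_ellipse(a: float, b: float) -> float:
    """Polar second moment of area of a solid ellipse, mm^4.

    J = pi * a * b * (a**2 + b**2) / 4 for semi-axes a, b.  Symmetric in
    (a, b); reduces to pi r**4 / 2 for a circle.
    """
    if a < 0 or b < 0:
        raise ValueError("radii must be non-negative")
    return math.pi * a * b * (a * a + b * b) / 4.0


def cortical_J(section: BoneSection) -> tuple[float, float, float]:
    """(J_solid, J_medullary, J_cortical) for a hollow elliptical section.

    The medullary-cavity J is subtracted from the solid-section J.
    """
    j_solid = polar_second_moment_ellipse(section.a_out, section.b_out)
    j_med = polar_second_moment_ellipse(section.a_in, section.b_in)
    return j_solid, j_med, j_solid - j_med


def polar_section_modulus(section: BoneSection) -> float:
    """Polar section modulus Zp = cortical J / mean outer radius, mm^3."""
    mean_r = (section.a_out + section.b_out) / 2.0
    if mean_r <= 0:
        raise ValueError("outer radii sum must be positive")
    return cortical_J(section)[2] / mean_r


def section_properties(section: BoneSection) -> SectionProperties:
    """All polar section properties, including the length-corrected modulus."""
    j_solid, j_med, j_cort = cortical_J(section)
    zp = polar_section_modulus(section)
    return SectionProperties(
        J_solid=j_solid,
        J_medullary=j_med,
        J_cortical=j_cort,
        Zp=zp,
        Zp_per_length=zp / section.length,
    )


def cantilever_failure_force(
    Zp: float, length: float, material: MaterialParams | None = None
) -> float:
    """Tip force (N) that brings a cantilevered shaft to breaking stress.

    Maximum bending stress is M/Z with moment M = F * L (total element
    length as moment arm), so failure occurs at
    F = sigma_max * (bending_share * Zp) / L.  With MPa, mm^3 and mm the
    result is in newtons directly.
    """
    material = material or MaterialParams()
    if length <= 0:
        raise ValueError("length must be positive")
    if Zp < 0:
        raise ValueError("Zp must be non-negative")
    return material.sigma_max * material.bending_share * Zp / length


def relative_failure_force(
    F: float, mass: float, material: MaterialParams | None = None
) -> float:
    """Failure force expressed in body weights (the RFF index)."""
    material = material or MaterialParams()
    if mass <= 0:
        raise ValueError("mass must be positive")
    if F < 0:
        raise ValueError("failure force must be non-negative")
    return F / (mass * material.g)


def avian_expected_rff(mass: float, model: AvianScalingModel) -> float:
    """RFF predicted for a bird of the same body mass."""
    if model is None:
        raise ValueError("an AvianScalingModel is required")
    if mass <= 0:
        raise ValueError("mass must be positive")
    return 10.0 ** (model.intercept + model.exponent * math.log10(mass))


def rff_ratio(rff: float, avian_expectation: float) -> float:
    """Observed RFF over the avian expectation (robustness relative to birds)."""
    if avian_expectation <= 0:
        raise ValueError("avian expectation must be positive")
    return rff / avian_expectation


def assess_failure(
    section: BoneSection,
    material: MaterialParams | None = None,
    scaling_models: dict[str, AvianScalingModel] | None = None,
) -> list[FailureAssessment]:
    """Run the full failure pipeline for every body-mass candidate.

    scaling_models maps element name -> AvianScalingModel; elements with no
    model (e.g. cervical vertebrae) get no expectation or ratio.
    """
    material = material or MaterialParams()
    props = section_properties(section)
    force = cantilever_failure_force(props.Zp, section.length, material)
    model = (scaling_models or {}).get(section.element)
    out = []
    for mass in section.body_mass_candidates:
        rff = relative_failure_force(force, mass, material)
        if model is not None:
            expectation = avian_expected_rff(mass, model)
            ratio = rff_ratio(rff, expectation)
        else:
            expectation = ratio = None
        out.append(
            FailureAssessment(
                taxon=section.taxon,
                element=section.element,
                mass=mass,
                failure_force=force,
                rff=rff,
                avian_expectation=expectation,
                ratio_observed_expected=ratio,
            )
        )
    return out


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
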