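"""Glide-polar flight performance for fixed planforms.

The model is the classic two-term gliding polar: parasite drag (wing profile
plus body) grows with dynamic pressure while induced drag decays with it, so
total drag is

    D(V) = A V**2 + B / V**2

with A = 0.5 rho (S cd_profile + Sb cd_body) and
B = 2 k W**2 / (rho pi b**2), where W is weight, b span, S wing area and Sb
an allometric body frontal area.  Best glide speed (minimum drag) is
(B/A)**(1/4); minimum sink speed (minimum D V / W) is (B/3A)**(1/4), a fixed
factor 3**(-1/4) below it.  Stall speed comes from lift equals weight at the
maximum lift coefficient; membrane wings sustain higher maxima (up to ~2.2
transiently) than feathered ones.

Burst performance treats launch-and-climb-out as a short anaerobic effort:
the flyer spends power P = D(V) V + W Vc (Vc a climb rate) and the burst
speed is the largest airspeed the available anaerobic power can sustain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "Planform",
    "GlidePolarParams",
    "BurstModel",
    "GlidePerformance",
    "PRINTED_REFERENCE",
    "body_frontal_area",
    "drag_coefficients",
    "glide_drag",
    "best_glide_speed",
    "minimum_sink_speed",
    "stall_speed",
    "effective_span_fraction",
    "flapping_frequency",
    "anaerobic_power",
    "burst_speed",
    "burst_range",
    "glide_performance",
    "InsufficientPowerError",
]

# Published flight figures for Quetzalcoatlus carried as reference metadata.
# The printed minimum-sink speeds imply v_bg/v_ms ~ 1.51, which no two-term
# polar can produce (the ratio is exactly 3**(1/4) ~ 1.316): they are kept
# for comparison and deliberately not asserted by the model.
PRINTED_REFERENCE = {
    "chatterjee": {"best_glide_speed": 13.3, "min_sink_speed": 8.80},
    "witton": {"best_glide_speed": 24.9, "min_sink_speed": 16.3},
    "witton_burst": {"max_range_speed": 48.3, "one_minute_range_km": 2.88},
}


class InsufficientPowerError(ValueError):
    """Raised when the power budget cannot sustain the requested climb."""


@dataclass(frozen=True)
class Planform:
    """A fixed wing: span b (m), area S (m^2), mass M (kg)."""

    span: float
    area: float
    mass: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.span <= 0 or self.area <= 0 or self.mass <= 0:
            raise ValueError("span, area and mass must all be positive")

    def weight(self, g: float = 9.81) -> float:
        return self.mass * g

    @property
    def aspect_ratio(self) -> float:
        return self.span**2 / self.area

    def wing_loading(self, g: float = 9.81) -> float:
        return self.weight(g) / self.area


@dataclass(frozen=True)
class GlidePolarParams:
    """Aerodynamic constants of the glide polar.

    Defaults are the published flight-mechanics conventions for vertebrate
    gliders: sea-level air density, induced-drag factor 1.1 for an
    elliptically-loaded wing with realistic tip losses, wing profile drag
    0.014, bluff-body drag 0.1 on a frontal area Sb = 0.00813 M**0.666.
    cl_max_unsteady (2.2) is the transient membrane-wing maximum; 1.8 is the
    steady maximum measured for birds.  Span reduction in fast glides is
    floored at min_span_fraction of resting span, reached at twice the stall
    speed.
    """

    rho: float = 1.23
    k_induced: float = 1.1
    cd_profile: float = 0.014
    cd_body: float = 0.1
    body_area_coeff: float = 0.00813
    body_area_exp: float = 0.666
    cl_max_steady: float = 1.8
    cl_max_unsteady: float = 2.2
    min_span_fraction: float = 0.8
    flap_glide_ratio: float = 0.2
    g: float = 9.81

    def __post_init__(self) -> None:
        numeric = (
            self.rho, self.k_induced, self.cd_profile, self.cd_body,
            self.body_area_coeff, self.cl_max_steady, self.cl_max_unsteady,
            self.min_span_fraction, self.flap_glide_ratio, self.g,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("glide polar parameters must be positive")
        if self.body_area_exp < 0:
            raise ValueError("body_area_exp must be non-negative")
        if self.min_span_fraction > 1:
            raise ValueError("min_span_fraction must be <= 1")
        if self.cl_max_steady > self.cl_max_unsteady:
            raise ValueError("cl_max_steady must not exceed cl_max_unsteady")


@dataclass(frozen=True)
class BurstModel:
    """Anaerobic burst budget for launch and climb-out.

    muscle_fraction: flight muscle as a fraction of body mass.
    specific_power: burst (anaerobic) power per kg of that muscle, W/kg.
    burst_duration: how long the burst lasts, s.
    climb_rate: altitude gain demanded during climb-out, m/s.
    """

    muscle_fraction: float = 0.30
    specific_power: float = 400.0
    burst_duration: float = 60.0
    climb_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.muscle_fraction < 1:
            raise ValueError("muscle_fraction must be in [0, 1)")
        if min(self.specific_power, self.burst_duration, self.climb_rate) < 0:
            raise ValueError("burst parameters must be non-negative")


@dataclass(frozen=True)
class GlidePerformance:
    """Characteristic speeds of one planform under one polar."""

    v_stall: float
    v_best_glide: float
    v_min_sink: float
    min_sink_rate: float
    best_glide_ratio: float


def body_frontal_area(M: float, params: GlidePolarParams | None = None) -> float:
    """Allometric body frontal area Sb = c * M**e, m^2."""
    params = params or GlidePolarParams()
    if M <= 0:
        raise ValueError("mass must be positive")
    return params.body_area_coeff * M**params.body_area_exp


def drag_coefficients(
    planform: Planform, params: GlidePolarParams | None = None
) -> tuple[float, float]:
    """(A, B) of the two-term polar D(V) = A V**2 + B / V**2."""
    params = params or GlidePolarParams()
    sb = body_frontal_area(planform.mass, params)
    W = planform.weight(params.g)
    A = 0.5 * params.rho * (planform.area * params.cd_profile + sb * params.cd_body)
    B = 2.0 * params.k_induced * W**2 / (params.rho * math.pi * planform.span**2)
    return A, B


def glide_drag(
    V: float, planform: Planform, params: GlidePolarParams | None = None
) -> float:
    """Total aerodynamic drag (N) in a steady glide at airspeed V."""
    if V <= 0:
        raise ValueError("airspeed must be positive")
    A, B = drag_coefficients(planform, params)
    return A * V**2 + B / V**2


def best_glide_speed(
    planform: Planform, params: GlidePolarParams | None = None
) -> float:
    """Drag-minimising airspeed (m/s): maximises distance per height lost."""
    A, B = drag_coefficients(planform, params)
    return (B / A) ** 0.25


def minimum_sink_speed(
    planform: Planform, params: GlidePolarParams | None = None
) -> tuple[float, float]:
    """(speed, sink rate) minimising altitude loss per unit time.

    Sink rate is D V / W; for the two-term polar the optimum sits at
    (B / 3A)**(1/4), i.e. best-glide speed divided by 3**(1/4).
    """
    params = params or GlidePolarParams()
    A, B = drag_coefficients(planform, params)
    v = (B / (3.0 * A)) ** 0.25
    sink = glide_drag(v, planform, params) * v / planform.weight(params.g)
    return v, sink


def stall_speed(
    planform: Planform,
    params: GlidePolarParams | None = None,
    cl: float | None = None,
) -> float:
    """Minimum airspeed at which lift balances weight at lift coefficient cl.

    Defaults to the unsteady membrane-wing maximum in params.
    """
    params = params or GlidePolarParams()
    cl = params.cl_max_unsteady if cl is None else cl
    if cl <= 0:
        raise ValueError("lift coefficient must be positive")
    W = planform.weight(params.g)
    return math.sqrt(2.0 * W / (params.rho * planform.area * cl))


def effective_span_fraction(
    V: float, planform: Planform, params: GlidePolarParams | None = None
) -> float:
    """Fraction of resting span held at airspeed V.

    Membrane wings flutter when over-slackened, so span reduction is limited:
    full span at stall, declining linearly to min_span_fraction at twice the
    stall speed, hard-stopped there for any faster glide.
    """
    params = params or GlidePolarParams()
    vs = stall_speed(planform, params)
    if V < vs:
        raise ValueError("airspeed below stall")
    frac = 1.0 - (1.0 - params.min_span_fraction) * (V - vs) / vs
    return max(frac, params.min_span_fraction)


def flapping_frequency(
    M: float, b: float, S: float, params: GlidePolarParams | None = None
) -> float:
    """Predicted steady flapping frequency, Hz.

    f = M**(3/8) g**(1/2) b**(-23/24) S**(-1/3) rho**(-3/8): frequency
    scales with the 3/8 power of mass when span and area enter as separate
    terms, and falls as M**(-1/6) under strict geometric similarity.
    """
    params = params or GlidePolarParams()
    if min(M, b, S) <= 0:
        raise ValueError("mass, span and area must be positive")
    return (
        M ** (3.0 / 8.0)
        * params.g**0.5
        * b ** (-23.0 / 24.0)
        * S ** (-1.0 / 3.0)
        * params.rho ** (-3.0 / 8.0)
    )


def anaerobic_power(M: float, burst: BurstModel | None = None) -> float:
    """Total burst power available, W = mass * muscle fraction * W/kg."""
    burst = burst or BurstModel()
    if M <= 0:
        raise ValueError("mass must be positive")
    return M * burst.muscle_fraction * burst.specific_power


def burst_speed(
    planform: Planform,
    params: GlidePolarParams | None = None,
    power: float | None = None,
    climb_rate: float | None = None,
    burst: BurstModel | None = None,
    v_max: float = 100.0,
) -> float:
    """Largest airspeed sustainable on the burst power budget, m/s.

    Solves D(V) V + W Vc = P for its larger root on [v_stall, v_max].
    Raises InsufficientPowerError when even the cheapest speed exceeds the
    budget.
    """
    params = params or GlidePolarParams()
    burst = burst or BurstModel()
    if power is None:
        power = anaerobic_power(planform.mass, burst)
    if climb_rate is None:
        climb_rate = burst.climb_rate
    W = planform.weight(params.g)

    def demand(v: float) -> float:
        return glide_drag(v, planform, params) * v + W * climb_rate - power

    v_lo = stall_speed(planform, params)
    # cheapest point of the demand curve: if positive there, infeasible
    v_ms, _ = minimum_sink_speed(planform, params)
    v_cheap = min(max(v_ms, v_lo), v_max)
    if demand(v_cheap) > 0:
        raise InsufficientPowerError(
            f"power budget {power:.1f} W cannot sustain climb at {climb_rate} m/s"
        )
    hi = max(v_cheap * 2, v_max)
    while demand(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - absurd budget
            raise ValueError("no finite burst speed for this power budget")
    return brentq(demand, v_cheap, hi, rtol=1e-6)


def burst_range(speed: float, burst: BurstModel | None = None) -> float:
    """Ground covered during the burst, m (climb losses reported separately)."""
    burst = burst or BurstModel()
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return speed * burst.burst_duration


def glide_performance(
    planform: Planform, params: GlidePolarParams | None = None
) -> GlidePerformance:
    """Full characteristic-speed summary for one planform."""
    params = params or GlidePolarParams()
    v_bg = best_glide_speed(planform, params)
    v_ms, sink = minimum_sink_speed(planform, params)
    v_st = stall_speed(planform, params)
    glide_ratio = planform.weight(params.g) / glide_drag(v_bg, planform, params)
    return GlidePerformance(
        v_stall=v_st,
        v_best_glide=v_bg,
        v_min_sink=v_ms,
        min_sink_rate=sink,
        best_glide_ratio=glide_ratio,
    )
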