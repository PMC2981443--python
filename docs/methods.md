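# Methods

`pterosoar` implements the quantitative core of the argument that the
largest pterosaurs — 10–11 m span azhdarchids around 200–250 kg — were
volant: their wing bones are far stronger than avian structural scaling
predicts, their glide performance under a standard polar is that of a fast
soarer, and the published half-tonne mass that would ground them dissolves
under a segment-wise volumetric correction.

## Bone strength (elliptical beam model)

Long-bone midshafts are modelled as hollow elliptical beams.  For an
ellipse with semi-axes *a* (dorsoventral) and *b* (anteroposterior), the
polar second moment of area is

    J = π a b (a² + b²) / 4,

exact for a true ellipse.  A hollow section takes the difference between
the outer-ellipse and medullary-cavity values, J_cort = J_out − J_in, and
the polar section modulus is Z_p = J_cort / r̄ with r̄ = (a_out + b_out)/2.
Z_p measures torsional and (twice) average bending strength across any two
perpendicular planes, which is why the failure model credits a configurable
`bending_share` (default 0.5) of Z_p to single-plane bending.

The cantilever failure force takes the whole element length L as moment
arm — few bones load as true cantilevers, but the actual moment arm is
proportional to L, so the convention cancels in comparative ratios:

    F = σ_max · bending_share · Z_p / L,

with σ_max = 175 MPa, the experimental breaking limit of avian bone (a
conservative figure for vertebrate bone generally).  MPa · mm³ / mm gives
newtons directly.  The Relative Failure Force RFF = F / (M g) expresses
failure in body weights; because F is fixed per bone, RFF · M is invariant
across candidate body masses.

The *avian expectation* — the RFF a bird of equal mass would show — is a
log-log power law 10^(c + k·log₁₀M).  The original regression coefficients
are not republished, so the packaged model is calibrated by least squares
to the published (mass, expectation) pairs: the six humerus pairs yield
k = −0.3205, c = 0.6821 (all six reproduced within 0.2%); the femur has a
single published pair, so it shares the humerus slope with its intercept
anchored through that point.  Literature coefficients can be substituted
via configuration.  Absolute failure forces depend on the `bending_share`
and unit conventions, which the source tables leave under-determined; the
exact acceptance surface is therefore the ratio column and the scaling
behaviour, not absolute newtons.

## Glide performance (two-term polar)

Drag for a fixed planform decomposes as parasite plus induced:

    D(V) = A V² + B/V²,
    A = ½ ρ (S C_d,pro + S_b C_d,body),
    B = 2 k W² / (ρ π b²),

with ρ = 1.23 kg/m³, k = 1.1, C_d,pro = 0.014, C_d,body = 0.1 and body
frontal area S_b = 0.00813 M^0.666 m².  These are the standard
flight-mechanics conventions; the original analysis names none of its drag
constants, so reproduction of its printed speeds is banded at ±5% rather
than exact.  Closed forms follow: best glide speed (B/A)^¼, minimum-sink
speed (B/3A)^¼ — their ratio is exactly 3^¼ ≈ 1.316 — and stall speed
√(2W/(ρ S C_L)).  C_L,max is 2.2 for transient membrane-wing conditions
and 1.8 steady.  Span reduction in fast glides is modelled linearly from
full span at stall to a hard stop at 80% of resting span at twice stall
speed (membrane wings flutter when over-slackened); only the endpoints are
prescribed, linearity is this package's choice.

The polar is valid only where its unconstrained minimum-sink speed exceeds
the steady stall speed; planforms violating this (very lightly massed but
heavily loaded, high-aspect-ratio wings outside anything in the empirical
tables) are outside the model's domain, and the test suite's random
planform generator samples wing loading allometrically with mass and
rejects invalid draws.

The published minimum-sink speeds (8.80 and 16.3 m/s for the two
Quetzalcoatlus planforms) imply a best-glide/min-sink ratio ≈ 1.51 that no
two-term polar can produce; the original software evidently uses a
different sink formulation.  These values are carried as reference
metadata (`PRINTED_REFERENCE`) and deliberately not asserted.  The same
applies to the published 48.3 m/s burst speed, whose underlying muscle
parameters are unpublished.

Flapping frequency uses the separate-terms scaling
f = M^(3/8) g^(1/2) b^(−23/24) S^(−1/3) ρ^(−3/8); under strict geometric
similarity it collapses to f ∝ M^(−1/6).

Burst performance: anaerobic power P = M · muscle_fraction ·
specific_power, spent as D(V)·V + W·V_climb.  The burst speed is the larger
root of the power balance (bracketed Brent search, relative tolerance
1e-6), and burst range is speed × duration, with climb losses reported
separately rather than subtracted.  Defaults — muscle fraction 0.30,
400 W/kg, 60 s, 1 m/s climb — reflect the large pterosaur flight-muscle
fractions and anaerobic avian muscle power figures in the comparative
literature; all are configurable and none is asserted against a published
burst number.

## Ecomorphospace

Derived wing metrics are W = Mg, AR = b²/S, loading = W/S.  The
ecomorphospace projection is a PCA of centred log₁₀(mass, span, area):
component 1 is the size axis (sign-fixed so all loadings are positive),
components 2–3 are shape axes.  The original figures' exact variable sets
and rotations are unpublished, so this projection is a faithful convention
rather than a bit-level reproduction, and the external bird/bat reference
datasets are not bundled — the packaged planform table plus synthetic
groups exercise the machinery.  Region membership is a shapely
point-in-polygon test with boundary counting as inside.

## Mass and size rescaling

Segment-wise correction: an over-long torso inflates only axial volume, so
corrected total = axial/factor + appendicular.  For the 544 kg
reconstruction (474 kg axial, torso factor 2.77) this gives 241.1 kg.

The span–mass law M = 0.5924 · b^2.5188 is the unique power law through
the two published heavy-estimate anchors (70 kg ↔ 6.65 m, 22 kg ↔ 4.2 m);
it is exactly invertible and predicts a 13 m span animal masses 1.94× a
10 m one.  Body density M/V in kg/L equals g/cm³; the plausible band for a
flyer is (0.6, 1.0) exclusive — 1.0 is the non-volant figure.  The 93 kg /
40 L check computes 2.325 g/cm³ (the published text prints 2.235, an
apparent transposition; the computed value is the one asserted).

## Synthetic data

The generators produce the statistical structure the analyses assume, not
replicas of fossils.  Bone tables: masses log-uniform over (5, 250) kg,
element length ∝ M^(1/3), ellipse eccentricity uniform in (0.6, 1.0), wall
fraction uniform in (0.1, 0.5), and the outer radius solved so realised
Z_p/L lands on 10^(c + α log₁₀M) with lognormal noise (default α = 1.3,
the positively allometric pterosaur regime; σ = 0.05 dex).  Because the
wall fraction is below one, inner radii can never exceed outer radii and
no rejection is needed.  Planform tables: wing loading and aspect ratio
lognormal about their targets, area and span derived.  Each generator owns
one `numpy.random.default_rng(seed)`; identical specs give identical
tables.

What the synthetic data does not emulate: phylogenetic covariance,
measurement error beyond lognormal scatter, taphonomic bias, and
within-element variation along the shaft.  Passing recovery tests show the
estimators are consistent under the assumed noise model, not that real
fossil tables satisfy it.

## Numerical choices and problem sizes

Closed forms are preferred throughout; the only iterative step is the
burst-speed root search.  Oracle tests integrate r²dA numerically over the
ellipse (0.1% agreement) and grid-search the polar optima (1000-point log
grid, 100 random planforms).  Allometry recovery uses n = 50 records at
0.05 dex noise, where the sampling distribution of the OLS slope is well
inside ±0.05.  Printed-table comparisons round half-up to the published
decimals; table cells whose printed values are not internally consistent
at that precision are flagged in the fixtures (`ratio_consistent`,
`derived_consistent`) and sanity-checked loosely instead of asserted.

## Known limitations

Only the ratio column of the strength table is exactly recoverable — the
published length-corrected moduli do not rederive the published RFFs under
any single obvious unit convention, so absolute failure forces are
parameterised rather than asserted.  The glide polar is steady-state: no
intermittent flap-glide energetics, launch kinematics, thermal or
dynamic-soaring path simulation.  The ecomorphospace hulls of the original
figures are not reproducible without the external datasets.
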