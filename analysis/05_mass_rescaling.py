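"""Size-estimate corrections for the largest azhdarchids.

Three desk calculations with outsized consequences for whether a half-tonne
flightless azhdarchid is plausible: the segment-wise correction of the
544 kg slicing-model reconstruction (whose torso was too long by a factor
of 2.77), the span<->mass power law through the heavy-estimate anchors, and
the body-density implausibility of the heaviest published Pteranodon mass.
"""

import json
from pathlib import Path

from pterosoar.mass_scaling import (
    DEFAULT_SPAN_MASS_REGRESSION,
    density_check,
    mass_from_span,
    mass_ratio_between_spans,
    segmentwise_correction,
    span_from_mass,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    corrected = segmentwise_correction(544.0, 474.0, 2.77)
    print(f"544 kg reconstruction, axial 474 kg, torso factor 2.77 "
          f"-> corrected total {corrected:.1f} kg")

    reg = DEFAULT_SPAN_MASS_REGRESSION
    print(f"span-mass power law: mass = {reg.coeff:.4f} * span^{reg.exponent:.4f}")
    print(f"  70 kg flyer  -> {span_from_mass(70.0):.2f} m span cap")
    print(f"  22 kg flyer  -> {span_from_mass(22.0):.2f} m span cap")
    print(f"  10.4 m span  -> {mass_from_span(10.4):.0f} kg")
    ratio = mass_ratio_between_spans(10.0, 13.0)
    print(f"  13 m vs 10 m span: x{ratio:.2f} mass (almost twice)")

    dens = density_check(93.0, 40.0)
    print(f"93 kg in a 40 L body -> {dens.density:.3f} g/cm^3: {dens.verdict}")
    payload = {
        "corrected_total_kg": corrected,
        "span_mass_regression": {"coeff": reg.coeff, "exponent": reg.exponent},
        "span_cap_70kg_m": span_from_mass(70.0),
        "span_cap_22kg_m": span_from_mass(22.0),
        "mass_at_10p4m_kg": mass_from_span(10.4),
        "mass_ratio_13m_vs_10m": ratio,
        "pteranodon_93kg_density_gcm3": dens.density,
        "density_verdict": dens.verdict,
    }
    (OUT / "mass_rescaling.json").write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )
    print(f"wrote {OUT/'mass_rescaling.json'}")


if __name__ == "__main__":
    main()
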