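"""Project the packaged planform table into wing ecomorphospace.

Derived wing metrics (weight, aspect ratio, wing loading) are recomputed
from span/mass/area, then the full pterosaur + procellariiform table is
projected through a log-space PCA.  Component 1 absorbs size; the shape
axes separate narrow, heavily loaded dynamic-soarer wings from broader
planforms.  A convex hull around the procellariiform scores tests which
pterosaur reconstructions fall inside seabird shape space.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from pterosoar.flight_performance import Planform
from pterosoar.io import load_table1
from pterosoar.planform_ecomorph import (
    ecomorph_pca,
    plot_ecomorphospace,
    region_membership,
    wing_metrics,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    t1 = load_table1()
    t1["is_bird"] = ~t1["taxon"].isin(["Pteranodon", "Quetzalcoatlus"])
    table = pd.DataFrame(
        {
            "label": t1["taxon"] + " (" + t1["reference"] + ")",
            "mass": t1["mass_kg"],
            "span": t1["span_m"],
            "area": t1["area_m2"],
        }
    )
    points, loadings, explained = ecomorph_pca(table)
    print("PCA of log10(mass, span, area):")
    print(f"  size axis loadings (all positive): {np.round(loadings[0], 3)}")
    print(f"  variance explained: {np.round(explained / explained.sum(), 3)}")

    shape = np.array([p.scores[1:3] for p in points])
    bird_mask = t1["is_bird"].to_numpy()
    hull_pts = shape[bird_mask]
    hull = [tuple(hull_pts[v]) for v in ConvexHull(hull_pts).vertices]

    rows = []
    for (_, r), p in zip(t1.iterrows(), points):
        m = wing_metrics(Planform(span=r["span_m"], area=r["area_m2"], mass=r["mass_kg"]))
        inside = region_membership(tuple(p.scores[1:3]), hull)
        rows.append(
            {
                "label": p.label,
                "weight_N": m.weight,
                "aspect_ratio": m.aspect_ratio,
                "wing_loading_Nm2": m.wing_loading,
                "pc1_size": p.scores[0],
                "pc2_shape": p.scores[1],
                "pc3_shape": p.scores[2],
                "in_seabird_hull": inside,
            }
        )
        if not r["is_bird"]:
            verdict = "inside" if inside else "OUTSIDE"
            print(f"  {p.label:<38} {verdict} the procellariiform shape hull")
    pd.DataFrame(rows).to_csv(OUT / "ecomorph_scores.csv", index=False)
    plot_ecomorphospace(points, hulls={"procellariiforms": hull},
                        path=OUT / "ecomorphospace.png", components=(1, 2))
    print(f"wrote {OUT/'ecomorph_scores.csv'} and {OUT/'ecomorphospace.png'}")


if __name__ == "__main__":
    main()
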