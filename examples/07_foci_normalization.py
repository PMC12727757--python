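"""Immunofluorescence foci normalization arithmetic.

Foci counts are rescaled by the ratio of mean nuclear surface areas so that
conditions with larger nuclei are not credited with more foci; radial focus
positions are expressed as a fraction of the nuclear radius.
"""

import pandas as pd

from epiredist.foci import normalize_foci_table

table = pd.DataFrame(
    {"foci_count": [24, 30, 18, 11, 14, 9],
     "nuclear_area": [13500.0, 14100.0, 13650.0, 14200.0, 14700.0, 14300.0],
     "mean_focus_distance_to_center": [30.0, 34.0, 28.0, 18.0, 20.0, 16.0],
     "nuclear_radius": [48.0, 50.0, 47.0, 49.0, 51.0, 48.0],
     "condition": ["parental"] * 3 + ["treated"] * 3}
)
out = normalize_foci_table(table, reference_condition="parental")
summary = out.groupby("condition")[
    ["normalized_foci_count", "normalized_radial_distance"]
].mean()
print(summary.round(3))
print("-> treated nuclei carry fewer heterochromatin foci even after")
print("   correcting for their larger area, and the remaining foci sit")
print("   closer to the nuclear center (radial distance < parental).")
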