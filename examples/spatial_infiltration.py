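"""Cell infiltration by distance from the tumour interface.

Simulates a cell map whose density falls with distance from the tumour
boundary, gates phenotypes from marker positivity, and profiles density in
25 bands of 20 um covering a 500-um range outward from the interface.
"""

import numpy as np

from ecmstruct import RegionGeometry, assign_phenotypes, infiltration_profile
from ecmstruct.synthetic import SpatialGroundTruth, generate_cell_map

tumor = np.zeros((600, 700), dtype=bool)
tumor[:, :100] = True  # tumour occupies the left slab
region = RegionGeometry(tumor, um_per_px=1.0)

gt = SpatialGroundTruth(n_cells=6000, gradient=-0.0015, seed=4)
cells = generate_cell_map(gt, region)
labels = assign_phenotypes(cells)
print("gated phenotype counts:")
print(labels.value_counts().to_string())

profile = infiltration_profile(cells, region, phenotypes=labels,
                               band_width_um=20, n_bands=25)
total = profile.groupby("band").agg(
    count=("count", "sum"), area_mm2=("area_mm2", "first"))
print("\nall-phenotype density (cells/mm^2) in the first 10 bands:")
for band, row in total.head(10).iterrows():
    bar = "#" * int(row["count"] / total["count"].max() * 40)
    print(f"  band {band:2d} [{band*20:3.0f}-{(band+1)*20:3.0f} um) "
          f"{row['count']/row['area_mm2']:8.1f}  {bar}")
print("\nDensity decays with distance from the interface, matching the"
      "\nnegative planted gradient; gradient 0 gives a flat profile.")
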