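"""Inter-subject map averaging in limb-normalised coordinates.

Twelve simulated subjects differ in activation gain (log-normal, sd 0.25)
and carry a residual landmark-placement error of half an electrode pitch
(the anatomical origin electrode anchors the normalised coordinates, so
only palpation error survives alignment).  Maps are normalised to fractions of
segment circumference/length, resampled onto a common grid by cubic
splines, and averaged; variability is the pixel-wise std divided by the
mean intensity -- the statistic used to report between-subject consistency.
"""

import numpy as np

from hdemgmap import (
    ActivationBlob,
    ElectrodeGrid,
    average_maps,
    common_coordinates,
    compute_map,
    generate_from_gains,
    normalize_map_coords,
    resample_common_grid,
    variability_summary,
)

grid = ElectrodeGrid(8, 15, origin_row=3, origin_col=7,
                     circumference_mm=280.0, segment_length_mm=300.0)
rng = np.random.default_rng(0)
maps = []
for subject in range(12):
    gain = rng.lognormal(0.0, 0.25)
    blob = ActivationBlob(x=7 + rng.normal(0, 0.5), y=3.5, peak=gain,
                          sd_x=2.5, sd_y=6.0)
    rec = generate_from_gains(grid, [blob.gain(grid), np.full(grid.shape, 0.01 * gain)],
                              seed=rng, beta=0.3)
    maps.append(normalize_map_coords(compute_map(rec), grid))

x, y = common_coordinates(maps)
mean_map, variability = average_maps([resample_common_grid(m, x, y) for m in maps])
mean_v, min_v, max_v = variability_summary(variability)

print(f"common grid: {len(y)} x {len(x)} pixels over "
      f"x in [{x.min():.2f}, {x.max():.2f}] (circumference fractions)")
print(f"average-map peak intensity: {mean_map.intensity.max():.4f} mV")
print(f"variability (std/intensity): mean {mean_v:.2f}, range [{min_v:.2f}, {max_v:.2f}]")
# With sd-0.25 log-normal subject gains the mean variability sits around
# 0.25, the order observed between real subjects at 50% MVC.
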