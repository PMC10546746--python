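"""A custom-height logo with signed values.

Any letters x positions matrix can be drawn verbatim; negative heights
place upright letters below the axis — useful for depletion/enrichment
style displays.
"""

import matplotlib

matplotlib.use("Agg")

import numpy as np

import seqlayers as sl

heights = np.array([
    [1.0, -0.3, 0.5],   # A
    [-0.5, 0.8, 0.0],   # C
    [0.2, 0.0, -1.2],   # G
    [0.0, 0.4, 0.6],    # T
])
layer = sl.build_logo(heights, method="custom", namespace=sl.DNA)

above = layer.data[layer.data["y"] > 0]["letter"].unique()
below = layer.data[layer.data["y"] < 0]["letter"].unique()
print("letters drawn above the axis:", sorted(above))
print("letters drawn below the axis:", sorted(below))

fig = sl.render_figure(layer)
fig.savefig("logo_custom.png")
print("wrote logo_custom.png")
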