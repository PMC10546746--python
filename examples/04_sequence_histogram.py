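"""Per-position stacked histogram of letter composition.

Counts by default; proportion mode rescales each column to 1.  Segments
stack with the same tallest-on-top rule as logos.
"""

import matplotlib

matplotlib.use("Agg")

import seqlayers as sl

seqs = ["ACGT", "ACGA", "TCGA", "ACTA"]
layer = sl.build_bar(seqs, statistic="count")

for pos, rows in layer.bar_data.groupby("position"):
    parts = ", ".join(f"{r['letter']}:{r['y_hi'] - r['y_lo']:.0f}"
                      for _, r in rows.sort_values("y_lo").iterrows())
    print(f"position {pos} (bottom to top): {parts}")

sl.render_figure(layer).savefig("histogram.png")
print("wrote histogram.png")
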