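"""Logo and alignment drawn in one coordinate system.

``compose`` shifts each layer's y columns by an offset and concatenates
the drawing tables; ``render_composed`` draws the result.  Offsetting the
logo by the number of sequences stacks it directly above the alignment.
"""

import matplotlib

matplotlib.use("Agg")

import seqlayers as sl

seqs = ["ACGTA", "ACGTC", "TCGTA", "ACTTA"]
aln = sl.build_align(seqs, scheme="nucleotide")
logo = sl.build_logo(seqs, method="bits", scheme="nucleotide")

combined = sl.compose([aln, logo], offsets=[0.0, len(seqs)])
for i, rows in combined.groupby("layer"):
    ys = rows[[c for c in ("y", "y_lo", "y_hi") if c in rows]].stack()
    print(f"layer {i}: y extent [{ys.min():.2f}, {ys.max():.2f}]")

fig = sl.render_composed([aln, logo], offsets=[0.0, len(seqs)],
                         figsize=(6, 5))
fig.savefig("composed.png")
print("wrote composed.png")
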