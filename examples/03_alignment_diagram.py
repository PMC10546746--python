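"""Multiple-sequence-alignment tile diagram and its public table.

Every residue becomes one unit tile; the background-tile table is public,
so the example prints its first rows — including the fixed geometry
x = position, y = y_index - 0.5.
"""

import matplotlib

matplotlib.use("Agg")

import seqlayers as sl

seqs = ["ACGT-A", "ACGTCA", "AC-TCA"]
layer = sl.build_align(seqs, scheme="nucleotide",
                       scheme_applied="BACKGROUND")

print(layer.bg_data.head(6).to_string(index=False))
print(f"{len(layer.bg_data)} tiles = "
      f"{len(seqs)} sequences x {len(seqs[0])} positions")

sl.render_figure(layer, figsize=(6, 2)).savefig("alignment.png")
# no-letter mode: colored tiles only
bare = sl.build_align(seqs, show_letters=False)
sl.render_figure(bare, figsize=(6, 2)).savefig("alignment_no_letters.png")
print("wrote alignment.png and alignment_no_letters.png")
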