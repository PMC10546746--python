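"""Color schemes, fonts, and per-record table mutation.

Lists the built-in registries, builds a custom scheme, then recolors one
letter at one position by editing the logo's public drawing table — the
same letter can carry different colors at different positions.
"""

import matplotlib

matplotlib.use("Agg")

import seqlayers as sl

print("schemes:", ", ".join(sl.list_schemes()))
print("fonts:  ", ", ".join(sl.list_fonts()))

custom = sl.make_col_scheme(["A", "C", "G", "T"],
                            colors=["#FF0000", "#00AA00", "#0000FF",
                                    "#AA00AA"])
layer = sl.build_logo(["ACGT", "ACGT", "ACGA"], method="probability",
                      scheme=custom)
edited = sl.mutate_layer(layer, [
    {"letter": "A", "position": 1, "col": "#000000"},
])
colors = edited.data.groupby(["letter", "position"])["col"].first()
print("A at position 1:", colors[("A", 1)])
print("A at position 4:", colors[("A", 4)])

sl.render_figure(edited).savefig("logo_mutated.png")
print("wrote logo_mutated.png")
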