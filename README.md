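# seqlayers

Composable, inspectable sequence visualization for Python: **sequence
logos** (probability, information-bits, and custom-height modes),
**multiple-sequence-alignment tile diagrams**, and **per-position stacked
sequence histograms**.

Every figure is built as a *layer* — a plain pandas drawing table plus
axis/facet metadata — before anything is drawn.  The tables are public:
you can inspect them, mutate them (recolor one letter at one position,
say), and recombine layers in one coordinate system, then hand them to
the bundled matplotlib renderer or to any plotting backend that
understands grouped polygons, rectangles and facet panels.  The package
is aimed at bioinformaticians who need motif and alignment figures that
remain programmable data rather than opaque images.

## The quantities being drawn

For aligned sequences over an alphabet of size *s*, the per-position
letter counts form a position frequency matrix (PFM).  A **probability
logo** draws each letter at its relative frequency *p₍ₗⱼ₎*, so every
column stacks to 1.  An **information logo** scales each column by its
information content in bits,

    Hⱼ = −Σₗ p₍ₗⱼ₎ log₂ p₍ₗⱼ₎        (Shannon entropy, 0·log 0 := 0)
    ICⱼ = log₂ s − Hⱼ                 (0 ≤ ICⱼ ≤ log₂ s)
    height of letter l = p₍ₗⱼ₎ · ICⱼ

so a fully conserved DNA column stands 2 bits tall and a uniform column
vanishes.  An optional small-sample correction subtracts the entropy
bias term eₙ = (s−1)/(2·ln 2·n) and clamps at zero.  Letters stack
tallest-on-top; **custom** mode draws any signed height matrix verbatim,
upright letters below the axis for negative values.

## Worked example

```python
import seqlayers as sl

seqs = sl.simulate_sequences("TGACTCAG", n=50, mutation_rate=0.15, seed=101)
layer = sl.build_logo(seqs, method="bits", scheme="nucleotide")
hm = layer.heights["1"]
for j in range(hm.n_positions):
    print(f"position {j+1}: {hm.heights[:, j].sum():.3f} bits")
sl.render_figure(layer).savefig("logo.png")
```

prints (this exact generator call backs the bundled `SYN0001.1` motif):

```
position 1: 1.158 bits
position 2: 1.434 bits
position 3: 0.887 bits
position 4: 1.141 bits
position 5: 0.981 bits
position 6: 0.911 bits
position 7: 0.727 bits
position 8: 1.617 bits
```

Each number is that column's information content — how far its letter
composition is from uniform, in bits (2.0 would be perfect conservation
for DNA); the logo stacks each column's letters to exactly that height.

More in `examples/`: custom-height logos with negative values,
alignment diagrams with scheme-on-background vs scheme-on-letters,
histograms, custom color schemes, per-position recoloring by table
mutation, and multi-layer composition in one coordinate system.

A thin CLI mirrors the library:

```sh
seqlayers logo --input motif.fa --method bits --out logo.png
seqlayers align --input aln.fa --no-letters --out aln.svg
seqlayers schemes   # 8 color schemes
seqlayers fonts     # 15 fonts
```

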