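# Methods

## Model and drawing pipeline

All three layer kinds share one pipeline: aligned input → per-position
letter heights → stacked y intervals → positioned letter polygons (or
tiles/bars) → a tidy drawing table.  Rendering is deliberately last and
replaceable; the tables plus their aesthetic bindings (x, y, polygon
group, fill color or value, facet panel) are the layer's contract.

**Counts.**  `build_pfm` tallies counts[l, j] = number of sequences with
letter *l* at position *j*.  Positions are 1-based.  The gap character
is fixed to `'-'` and contributes to no letter, so an all-gap column is
all-zero and renders as an empty position rather than erroring —
alignments legitimately contain gap-only columns after slicing.
Characters are case-sensitive: lowercase logos are just logos over a
lowercase alphabet, and the built-in DNA/RNA/amino-acid alphabets are
uppercase, alphabetically ordered.

**Probability heights.**  Columns with positive sums are normalized to
1; zero-sum columns stay zero.  Normalization is exact to the 1e-9
tolerance enforced by the `HeightMatrix` invariant.

**Information heights (bits).**  Per column, H = −Σ p log₂ p with
0·log 0 := 0, IC = log₂ s − H, letter height = p·IC.  The default
applies *no* small-sample correction, which preserves the property that
a fully conserved column reaches exactly log₂ s bits (2.0 for DNA).
The Schneider-style bias correction eₙ = (s−1)/(2·ln 2·nⱼ), with nⱼ the
column's count sum, is available as an opt-in flag and is clamped at
zero so low-count columns cannot go negative.  The convention choice
(correction off by default) follows the dominant logo-drawing practice;
both variants are tested against a brute-force entropy oracle.

**Stacking.**  Positive heights tile [0, Σ⁺] bottom-to-top by
increasing height (tallest letter on top); negative heights tile
[−Σ|·|, 0] downward by increasing magnitude (most negative lowest).
Ties break by alphabet order with the earlier letter nearer the
baseline — an arbitrary but fixed rule chosen so drawing tables are
byte-reproducible.

## Glyphs and fonts

Letters are drawn as filled polygons so each glyph can be stretched to
exactly fill its stacked interval.  The catalog holds 15 fonts (DejaVu
sans/serif/mono families in their weight/slant variants plus three STIX
styles), extracted at first use from the TrueType files matplotlib
ships: bezier outlines are flattened by matplotlib's text-path
machinery at its default chord tolerance (≈1/500 em at the 100-unit em
size used) and normalized per character to a *tight* unit box — every
glyph's x and y extents are exactly [0, 1].  Tight-box normalization
distorts relative letter proportions (a `-` becomes as tall as an `A`)
but is the standard logo convention: a letter must fill its interval.

Outlines keep their contours as separate *pieces* with their original
winding, so holes (the bowl of `O`, the two counters of `B`) render
correctly as compound paths; even-odd containment tests in the suite
confirm hole regions stay unfilled.  Negative placement heights draw
the glyph upright in [y_base − |h|, y_base] rather than mirroring it,
keeping below-axis letters readable.  `build_font_catalog` runs the
same extraction on arbitrary TTF/OTF paths, and `save_catalog` /
`load_catalog` give a documented columnar text serialization (font,
codepoint, piece, vertex order, gx, gy) for auditing or freezing a
catalog; the built-in catalog is regenerated at runtime rather than
shipped because its text form is megabytes while regeneration takes
well under a second and is deterministic.

## Color schemes

Eight built-ins: `nucleotide`, `nucleotide2`, `base_pairing` over
nucleic alphabets; `chemistry`, `chemistry2`, `hydrophobicity`,
`clustalx`, `taylor` over amino acids.  All are discrete except
`hydrophobicity`, which maps residues to the Kyte–Doolittle hydropathy
index and renders through a two-stop blue→red gradient.  The default
DNA background palette pins thymine at `#D62839`; `clustalx` and
`taylor` use the canonical ClustalX and Taylor (1997) residue colors;
the `chemistry` palettes group residues into polar / neutral / basic /
acidic / hydrophobic classes, with `chemistry2` and `nucleotide2` as
alternative hue sets over the same groupings.  Letters outside a scheme
fall back to neutral grey `#808080`, making assignment total over any
alphabet; gap tiles use a paler `#F0F0F0` so gaps and unknown letters
are visually distinct.  Legends default to hidden for discrete schemes
(redundant with the glyphs themselves) and shown for continuous ones.

## Layer geometry

*Logo*: letters are 0.9 of the unit position slot wide, centered, so
adjacent stacks keep a visible gutter.  *Alignment*: one unit tile per
(sequence, position); x = position, y = y_index − 0.5, width = height
= 1, with the first input sequence assigned y_index 1 and the display
axis reversed so it reads at the top (conventional MSA orientation —
only the y = y_index − 0.5 relation is structural).  Letters in
BACKGROUND mode are inked black or white by a relative-luminance 0.5
threshold against their tile.  *Bar*: segments use the logo's 0.9
width; letters overlay only segments taller than 5% of their column
total, since anything smaller is an unreadable sliver; the histogram's
default statistic is raw counts with proportion as an option.
`compose` shifts each layer's y-carrying columns by a per-layer offset
and concatenates tables with layer/table tags, leaving inputs
untouched.

## Synthetic example data

The bundled collections (`pfms_dna`, `seqs_dna`, `seqs_aa`) are
generated at import by `simulate_sequences`: each position keeps a
documented consensus letter with probability 1 − mutation rate (0.15 to
0.3 across the entries), else mutates uniformly to another alphabet
letter, with fixed seeds.  The DNA entries (50 sequences each, 8–10 bp)
emulate transcription-factor motif sets; the amino-acid entries (40
sequences, 9-mers centered on a phosphoacceptor-style residue) emulate
kinase substrate-site collections.  The generator produces
positionally independent multinomial columns; real motifs have
inter-position dependence, mixed-length flanks and database-specific
count conventions, so passing tests demonstrate correctness of the
counting, information and geometry pipeline — not biological fidelity
of any particular motif.

## Numerical and interface choices

Probability/bits invariants are enforced at 1e-9; information content
is clamped at zero against floating-point cancellation in near-uniform
columns.  Degenerate inputs are defined, not errors: zero-height
letters emit no interval, zero-area glyph placements are legal,
all-zero columns draw nothing.  Alphabet auto-detection uses a
character census (any of EFILPQZ ⇒ amino acid, else U ⇒ RNA, else
DNA) and is overridable everywhere via `namespace`.  Matrix input with
4 or 20 rows infers the DNA or amino-acid alphabet; other row counts
require an explicit namespace.  The CLI is a thin click wrapper over
the library (exit 0/2/1 for success/usage/data errors); library users
lose nothing by ignoring it.

## Limitations

No relative-entropy (background-frequency) logos, no degenerate IUPAC
letters as probabilistic symbols, no kerning or variable-width stacks,
no consensus rows or margin trees on alignment diagrams, and pixel
output is backend-dependent — determinism is guaranteed at the drawing
table level, not the image byte level.
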