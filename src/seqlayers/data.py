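"""Bundled trial data: three keyed collections, generated synthetically.

``pfms_dna`` (label -> FrequencyMatrix), ``seqs_dna`` (label ->
SequenceSet) and ``seqs_aa`` (label -> SequenceSet) give users something
to draw straight away.  Every entry is produced at import time by
:func:`seqlayers.seqstats.simulate_sequences` from a documented consensus
string with a fixed seed — the collections *emulate* the shape of real
transcription-factor motifs and kinase phosphosite sets but are entirely
synthetic, so nothing here is a redistribution of any motif database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .seqstats import AA, DNA, FrequencyMatrix, SequenceSet, build_pfm, \
    simulate_sequences

__all__ = ["pfms_dna", "seqs_dna", "seqs_aa", "ExampleData", "load_example_data"]

# (label, consensus, n sequences, mutation rate, seed) per synthetic motif.
# Labels mimic motif-ID / kinase naming style; the "SYN" prefix marks them
# as synthetic.
_DNA_SPECS = [
    ("SYN0001.1", "TGACTCAG", 50, 0.15, 101),
    ("SYN0002.1", "CACGTGAC", 50, 0.25, 102),
    ("SYN0003.1", "TTGACGTCAA", 50, 0.20, 103),
]
_AA_SPECS = [
    ("SYNK-PKA", "RRGSLEAIY", 40, 0.30, 201),
    ("SYNK-CK2", "ADSDDELSD", 40, 0.30, 202),
    ("SYNK-CDK", "TPSPKKRKL", 40, 0.30, 203),
]


def _make_seqs(specs, alphabet) -> dict[str, SequenceSet]:
    return {
        label: simulate_sequences(consensus, n, rate, alphabet=alphabet,
                                  seed=seed, panel_label=label)
        for label, consensus, n, rate, seed in specs
    }


#: Motif-like aligned DNA sequence sets.
seqs_dna: dict[str, SequenceSet] = _make_seqs(_DNA_SPECS, DNA)

#: Position frequency matrices tallied from the DNA sets.
pfms_dna: dict[str, FrequencyMatrix] = {
    label: build_pfm(s) for label, s in seqs_dna.items()
}

#: Kinase-phosphosite-like aligned amino-acid sequence sets.
seqs_aa: dict[str, SequenceSet] = _make_seqs(_AA_SPECS, AA)


@dataclass(frozen=True)
class ExampleData:
    """The three bundled keyed collections."""

    pfms_dna: Mapping[str, FrequencyMatrix]
    seqs_dna: Mapping[str, SequenceSet]
    seqs_aa: Mapping[str, SequenceSet]


def load_example_data() -> ExampleData:
    """All bundled collections in one object."""
    return ExampleData(pfms_dna=pfms_dna, seqs_dna=seqs_dna, seqs_aa=seqs_aa)
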