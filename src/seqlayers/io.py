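"""File ingestion and the figure-rendering entry point.

Readers accept the two standard motif/alignment inputs: FASTA files of
aligned sequences (via Biopython) and position frequency matrices in
either the JASPAR bracket dialect or a plain whitespace grid.  The
JASPAR-dialect parsing is done here rather than through Biopython's
motif reader because that reader fixes the alphabet to ACGT while this
package allows matrices over arbitrary letters, in file order.

``render`` is the one-call path from an input source to an image file,
used by the CLI.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from . import data as _data
from .align import build_align
from .bar import build_bar
from .logo import build_logo
from .render import render_figure
from .seqstats import FrequencyMatrix, SequenceSet, detect_alphabet

__all__ = ["read_fasta", "read_pfm", "RenderJob", "render", "write_fasta"]

_IMAGE_FORMATS = ("png", "svg", "pdf")


class FastaParseError(ValueError):
    """Structurally invalid FASTA, reported with a line number."""


def _check_fasta_structure(path: str | os.PathLike) -> None:
    saw_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                saw_record = True
            elif not saw_record:
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before the first "
                    "'>' header"
                )
    if not saw_record:
        raise FastaParseError(f"{path}: no FASTA records (empty file?)")


def read_fasta(
    path: str | os.PathLike,
    alphabet: Iterable[str] | None = None,
    panel_label: str = "1",
) -> SequenceSet:
    """Read aligned sequences from a FASTA file, in file order.

    The alphabet is auto-detected from a character census (amino acid if
    any of EFILPQZ occur, else RNA if U occurs, else DNA) unless given
    explicitly.  Unequal-length records raise an alignment error, since
    every layer in this package draws positionally aligned input.
    """
    _check_fasta_structure(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records")
    seqs = [str(r.seq) for r in records]
    return SequenceSet(seqs, alphabet=alphabet, panel_label=panel_label)


def write_fasta(path: str | os.PathLike, seqs: SequenceSet,
                names: Iterable[str] | None = None) -> None:
    """Write a sequence set as FASTA (inverse of :func:`read_fasta`)."""
    names = list(names) if names is not None else [
        f"seq{i + 1}" for i in range(len(seqs))
    ]
    with open(path, "w") as fh:
        for name, s in zip(names, seqs.sequences):
            fh.write(f">{name}\n{s}\n")


_JASPAR_ROW = re.compile(r"^\s*(\S+)\s*\[(.*)\]\s*$")


def read_pfm(path: str | os.PathLike, dialect: str = "jaspar",
             panel_label: str = "1") -> FrequencyMatrix:
    """Read a position frequency matrix.

    ``dialect="jaspar"``: an optional ``>`` header line followed by rows
    like ``A  [ 3  1  0 ]``.  ``dialect="plain"``: a whitespace grid,
    each row a letter label followed by its per-position counts.  Letters
    keep file order; fractional counts are allowed, negative ones are
    not; ragged rows raise naming the offending row.
    """
    if dialect not in ("jaspar", "plain"):
        raise ValueError(f"dialect must be 'jaspar' or 'plain', got {dialect!r}")
    letters: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#",)):
                continue
            if stripped.startswith(">"):
                continue
            if dialect == "jaspar":
                m = _JASPAR_ROW.match(stripped)
                if not m:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 'LETTER [ counts ]'"
                    )
                letter, body = m.group(1), m.group(2)
                fields = body.split()
            else:
                fields = stripped.split()
                letter, fields = fields[0], fields[1:]
            if len(letter) != 1:
                raise ValueError(
                    f"{path}: line {lineno}: row label {letter!r} is not a "
                    "single letter"
                )
            try:
                values = [float(v) for v in fields]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric count in row "
                    f"{letter!r}"
                ) from exc
            if any(v < 0 for v in values):
                raise ValueError(
                    f"{path}: line {lineno}: negative count in row {letter!r}"
                )
            if rows and len(values) != len(rows[0]):
                raise ValueError(
                    f"{path}: line {lineno}: row {letter!r} has "
                    f"{len(values)} columns, expected {len(rows[0])}"
                )
            letters.append(letter)
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no matrix rows found")
    return FrequencyMatrix(tuple(letters), np.asarray(rows, dtype=float),
                           panel_label=panel_label)


@dataclass
class RenderJob:
    """Everything needed to turn one input source into one image file.

    ``source`` is a FASTA/matrix path, a bundled-data label, or an
    already-built input object (sequences, matrix, or mapping).
    """

    source: object
    layer: str = "logo"  # logo | align | bar
    input_format: str = "fasta"  # fasta | pfm | jaspar | bundled | object
    method: str = "bits"
    scheme: str | None = None
    font: str | None = None
    out: str = "figure.png"
    show_letters: bool = True
    scheme_applied: str = "BACKGROUND"
    statistic: str = "count"
    small_sample_correction: bool = False
    namespace: str | None = None
    width: float = 8.0
    height: float = 3.0
    facets: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        fmt = Path(self.out).suffix.lstrip(".").lower()
        if fmt not in _IMAGE_FORMATS:
            raise ValueError(
                f"output format {fmt!r} not supported; use one of "
                f"{', '.join(_IMAGE_FORMATS)}"
            )


def _bundled(label: str):
    for coll in (_data.seqs_dna, _data.pfms_dna, _data.seqs_aa):
        if label in coll:
            return coll[label]
    raise KeyError(f"no bundled dataset named {label!r}")


def _load_source(job: RenderJob):
    if job.facets:
        return {label: _load_one(path, job)
                for label, path in job.facets.items()}
    return _load_one(job.source, job)


def _load_one(source, job: RenderJob):
    if job.input_format == "object":
        return source
    if job.input_format == "bundled":
        return _bundled(str(source))
    if job.input_format == "fasta":
        alphabet = tuple(job.namespace) if job.namespace else None
        return read_fasta(source, alphabet=alphabet)
    if job.input_format in ("pfm", "jaspar"):
        dialect = "plain" if job.input_format == "pfm" else "jaspar"
        return read_pfm(source, dialect=dialect)
    raise ValueError(f"unknown input format {job.input_format!r}")


def build_layer(job: RenderJob):
    """Construct the layer a job describes (no drawing)."""
    data = _load_source(job)
    namespace = tuple(job.namespace) if job.namespace else None
    if job.layer == "logo":
        return build_logo(data, method=job.method, font_name=job.font,
                          scheme=job.scheme, namespace=namespace,
                          small_sample_correction=job.small_sample_correction)
    if job.layer == "align":
        return build_align(data, scheme=job.scheme,
                           scheme_applied=job.scheme_applied,
                           show_letters=job.show_letters,
                           font_name=job.font, namespace=namespace)
    if job.layer == "bar":
        return build_bar(data, statistic=job.statistic, scheme=job.scheme,
                         show_letters=job.show_letters, font_name=job.font,
                         namespace=namespace)
    raise ValueError(f"unknown layer kind {job.layer!r}")


def render(job: RenderJob) -> str:
    """Build the job's layer, apply the plain theme, write the image.

    Layer-table content is deterministic for fixed inputs; the image
    bytes depend on the matplotlib backend.  Returns the output path.
    """
    layer = build_layer(job)
    fig = render_figure(layer, figsize=(job.width, job.height))
    try:
        fig.savefig(job.out)
    finally:
        import matplotlib.pyplot as plt

        plt.close(fig)
    return job.out
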