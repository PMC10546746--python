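"""Normalization of the three accepted input shapes.

Layers accept (a) aligned sequences as a list of strings or a
:class:`~seqlayers.seqstats.SequenceSet`, (b) a letters x positions matrix
(raw ndarray, :class:`FrequencyMatrix`, or :class:`HeightMatrix`), or
(c) a mapping of panel label -> either of the above, which becomes one
facet per key in insertion order.  This module funnels all of them into a
list of ``(panel_label, object)`` pairs.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np

from .seqstats import (AA, DNA, FrequencyMatrix, HeightMatrix, SequenceSet,
                       detect_alphabet)


def _coerce_single(data: Any, namespace, panel_label: str,
                   signed: bool = False):
    if isinstance(data, (SequenceSet, FrequencyMatrix, HeightMatrix)):
        if data.panel_label != panel_label:
            if isinstance(data, SequenceSet):
                return SequenceSet(data.sequences, data.alphabet, panel_label)
            if isinstance(data, FrequencyMatrix):
                return FrequencyMatrix(data.letters, data.counts, panel_label)
            return HeightMatrix(data.letters, data.heights, data.mode, panel_label)
        return data
    if isinstance(data, np.ndarray):
        letters = _matrix_letters(data, namespace)
        if signed:  # custom-height logos allow negative values
            return HeightMatrix(letters, data, "custom",
                                panel_label=panel_label)
        return FrequencyMatrix(letters, data, panel_label=panel_label)
    if isinstance(data, (list, tuple)):
        if not data:
            raise ValueError("empty sequence collection")
        if all(isinstance(s, str) for s in data):
            return SequenceSet(data, alphabet=namespace, panel_label=panel_label)
        raise TypeError(
            "sequence collections must contain strings; got "
            f"{type(data[0]).__name__}"
        )
    raise TypeError(
        f"unsupported input type {type(data).__name__}; expected sequences, "
        "a matrix, or a mapping of label -> sequences/matrix"
    )


def _matrix_letters(matrix: np.ndarray, namespace) -> tuple[str, ...]:
    if namespace is not None:
        letters = tuple(namespace)
        if len(letters) != matrix.shape[0]:
            raise ValueError(
                f"matrix has {matrix.shape[0]} rows but namespace has "
                f"{len(letters)} letters"
            )
        return letters
    if matrix.ndim != 2:
        raise ValueError("matrix input must be 2-D (letters x positions)")
    if matrix.shape[0] == len(DNA):
        return DNA
    if matrix.shape[0] == len(AA):
        return AA
    raise ValueError(
        f"cannot infer letters for a {matrix.shape[0]}-row matrix; "
        "pass namespace="
    )


def as_panels(data: Any, namespace=None,
              signed: bool = False) -> list[tuple[str, Any]]:
    """Split input into ``(panel_label, coerced object)`` pairs.

    Flat input yields one panel labeled ``"1"``; mapping input yields one
    panel per key in insertion order, labels being the stringified keys.
    With ``signed`` a raw matrix becomes a custom height matrix (negative
    entries allowed) instead of a frequency matrix.
    """
    if isinstance(data, Mapping):
        if not data:
            raise ValueError("empty mapping input")
        return [(str(k), _coerce_single(v, namespace, str(k), signed))
                for k, v in data.items()]
    return [("1", _coerce_single(data, namespace, "1", signed))]
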