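"""Sequence statistics shared by every drawing layer.

This module owns the quantitative half of the package: turning aligned
sequences into a position frequency matrix (PFM), converting a PFM into
per-position letter heights (relative frequencies, or information content
in bits), and computing the stacking geometry that places each letter's
interval on the y axis.  Everything here is pure computation on small
matrices; no drawing happens in this module.

Conventions
-----------
* Positions are 1-based everywhere.
* The gap character is ``'-'``; gaps never count toward any letter.
* Characters are case-sensitive: ``'a'`` and ``'A'`` are distinct letters,
  so lowercase logos simply use a lowercase alphabet.
* An all-gap alignment column produces an all-zero count column, which
  downstream renders as an empty position rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DNA",
    "RNA",
    "AA",
    "GAP",
    "SequenceSet",
    "FrequencyMatrix",
    "HeightMatrix",
    "StackedInterval",
    "detect_alphabet",
    "build_pfm",
    "to_probability",
    "to_bits",
    "stack",
    "extract",
    "simulate_sequences",
]

#: Built-in alphabets, alphabetical order, uppercase.
DNA: tuple[str, ...] = tuple("ACGT")
RNA: tuple[str, ...] = tuple("ACGU")
AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: The single gap character excluded from all counts.
GAP = "-"

# Residues that only occur in amino-acid sequences; used by auto-detection.
_AA_ONLY = set("EFILPQZ")


class AlignmentError(ValueError):
    """Sequences that are supposed to be aligned have unequal lengths."""


class AlphabetError(ValueError):
    """A sequence character is neither a gap nor a member of the alphabet."""


def detect_alphabet(sequences: Iterable[str]) -> tuple[str, ...]:
    """Guess DNA, RNA or amino-acid alphabet from a character census.

    Any of ``EFILPQZ`` present => amino acid; else ``U`` present => RNA;
    otherwise DNA.  Case-insensitive for the census only — the returned
    built-in alphabets are uppercase.
    """
    census = {c.upper() for s in sequences for c in s if c != GAP}
    if census & _AA_ONLY:
        return AA
    if "U" in census:
        return RNA
    return DNA


@dataclass(frozen=True)
class SequenceSet:
    """Aligned, equal-length sequences over a declared alphabet.

    Parameters
    ----------
    sequences
        Equal-length strings; may contain the gap character ``'-'``.
    alphabet
        Ordered single characters (the *namespace*); defaults to the
        auto-detected built-in alphabet.
    panel_label
        Facet label this set belongs to; ``"1"`` for flat input.
    """

    sequences: tuple[str, ...]
    alphabet: tuple[str, ...] = ()
    panel_label: str = "1"

    def __init__(
        self,
        sequences: Iterable[str],
        alphabet: Iterable[str] | None = None,
        panel_label: str = "1",
    ):
        seqs = tuple(str(s) for s in sequences)
        if not seqs:
            raise ValueError("SequenceSet needs at least one sequence")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences are not aligned: lengths {sorted(lengths)}"
            )
        if min(lengths) < 1:
            raise AlignmentError("aligned length must be >= 1")
        if alphabet is None:
            alpha = detect_alphabet(seqs)
        else:
            alpha = tuple(alphabet)
        if len(set(alpha)) != len(alpha):
            raise ValueError(f"alphabet has duplicate characters: {alpha}")
        if any(len(c) != 1 for c in alpha):
            raise ValueError("alphabet members must be single characters")
        members = set(alpha)
        for i, s in enumerate(seqs):
            for j, c in enumerate(s):
                if c != GAP and c not in members:
                    raise AlphabetError(
                        f"character {c!r} at position {j + 1} of sequence "
                        f"{i + 1} is not in the alphabet {''.join(alpha)!r}"
                    )
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "alphabet", alpha)
        object.__setattr__(self, "panel_label", str(panel_label))

    @property
    def length(self) -> int:
        """Alignment length L."""
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Letters x positions matrix of nonnegative occurrence counts."""

    letters: tuple[str, ...]
    counts: np.ndarray  # shape (len(letters), L), float
    panel_label: str = "1"

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D letters x positions matrix")
        if counts.shape[0] != len(self.letters):
            raise ValueError(
                f"{len(self.letters)} letters but {counts.shape[0]} count rows"
            )
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("duplicate letters")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.shape[1] < 1 or not np.any(counts.sum(axis=0) > 0):
            raise ValueError("at least one column must have a positive sum")
        object.__setattr__(self, "letters", tuple(self.letters))
        object.__setattr__(self, "counts", counts)

    @property
    def n_positions(self) -> int:
        return self.counts.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """1-based position index of each column."""
        return np.arange(1, self.n_positions + 1)


@dataclass(frozen=True)
class HeightMatrix:
    """Signed letter heights per position, in one of three modes.

    ``probability`` heights lie in [0, 1] and nonzero columns sum to 1;
    ``bits`` heights are nonnegative with column sums bounded by
    log2(number of letters); ``custom`` heights are unrestricted in sign.
    """

    letters: tuple[str, ...]
    heights: np.ndarray  # shape (len(letters), L)
    mode: str = "custom"
    panel_label: str = "1"

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or h.shape[0] != len(self.letters):
            raise ValueError("heights must be letters x positions")
        if self.mode not in ("probability", "bits", "custom"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "probability":
            if np.any(h < -1e-9) or np.any(h > 1 + 1e-9):
                raise ValueError("probability heights must lie in [0, 1]")
            sums = h.sum(axis=0)
            bad = (sums > 1e-9) & (np.abs(sums - 1.0) > 1e-9)
            if np.any(bad):
                raise ValueError(
                    "nonzero probability columns must sum to 1 "
                    f"(columns {np.where(bad)[0] + 1})"
                )
        elif self.mode == "bits":
            if np.any(h < -1e-9):
                raise ValueError("bits heights must be nonnegative")
            cap = np.log2(len(self.letters)) + 1e-9
            if np.any(h.sum(axis=0) > cap):
                raise ValueError("bits column sums exceed log2(|letters|)")
        object.__setattr__(self, "letters", tuple(self.letters))
        object.__setattr__(self, "heights", h)

    @property
    def n_positions(self) -> int:
        return self.heights.shape[1]


@dataclass(frozen=True)
class StackedInterval:
    """One letter's y interval at one position of a stacked column."""

    letter: str
    position: int  # 1-based
    y_lo: float
    y_hi: float

    @property
    def height(self) -> float:
        return self.y_hi - self.y_lo


def build_pfm(seqs: SequenceSet) -> FrequencyMatrix:
    """Tally a position frequency matrix from aligned sequences.

    ``counts[l, j]`` is the number of sequences whose j-th character is
    letter ``l``.  Gap characters count toward no letter, so an all-gap
    column is all-zero.  Rows are exactly the alphabet, in alphabet order.
    """
    index = {c: i for i, c in enumerate(seqs.alphabet)}
    counts = np.zeros((len(seqs.alphabet), seqs.length), dtype=float)
    for s in seqs.sequences:
        for j, c in enumerate(s):
            if c != GAP:
                counts[index[c], j] += 1
    return FrequencyMatrix(seqs.alphabet, counts, panel_label=seqs.panel_label)


def to_probability(pfm: FrequencyMatrix) -> HeightMatrix:
    """Column-normalize counts to relative frequencies.

    Each column with a positive sum is divided by that sum; all-zero
    columns stay all-zero (they render as empty positions).
    """
    sums = pfm.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(sums > 0, pfm.counts / np.where(sums > 0, sums, 1.0), 0.0)
    return HeightMatrix(pfm.letters, p, mode="probability",
                        panel_label=pfm.panel_label)


def to_bits(pfm: FrequencyMatrix,
            small_sample_correction: bool = False) -> HeightMatrix:
    """Information-content letter heights in bits.

    Per column ``j`` with relative frequencies ``p``:

    .. math::

        H_j = -\\sum_l p_{lj} \\log_2 p_{lj}, \\qquad
        IC_j = \\log_2 s - H_j, \\qquad
        h_{lj} = p_{lj} \\cdot IC_j

    with ``s`` the number of letters and ``0 log 0 := 0``.  With
    ``small_sample_correction`` the Schneider-style bias term
    ``e_n = (s - 1) / (2 ln 2 n_j)`` (``n_j`` = column count sum) is
    subtracted from ``IC_j`` and the result clamped at zero.  Zero-sum
    columns yield zero heights.
    """
    s = len(pfm.letters)
    p = to_probability(pfm).heights
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -plogp.sum(axis=0)
    ic = np.log2(s) - entropy
    if small_sample_correction:
        n = pfm.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_n = np.where(n > 0, (s - 1) / (2.0 * np.log(2) * np.where(n > 0, n, 1.0)), 0.0)
        ic = np.maximum(0.0, ic - e_n)
    ic = np.where(p.sum(axis=0) > 0, ic, 0.0)
    # tiny negatives from float cancellation in near-uniform columns
    ic = np.maximum(ic, 0.0)
    return HeightMatrix(pfm.letters, p * ic, mode="bits",
                        panel_label=pfm.panel_label)


def stack(heights: HeightMatrix) -> list[StackedInterval]:
    """Assign each nonzero letter height a contiguous y interval.

    Positive heights tile ``[0, sum of positives]`` bottom-to-top by
    increasing height — the tallest letter ends up on top.  Negative
    heights tile ``[-sum |negatives|, 0]`` downward by increasing
    magnitude, so the most negative letter ends lowest.  Ties break by
    alphabet order, the earlier letter sitting closer to the baseline.
    Zero heights emit no interval.
    """
    out: list[StackedInterval] = []
    h = heights.heights
    for j in range(heights.n_positions):
        col = h[:, j]
        pos = [(col[i], i) for i in range(len(col)) if col[i] > 0]
        neg = [(col[i], i) for i in range(len(col)) if col[i] < 0]
        y = 0.0
        for v, i in sorted(pos, key=lambda t: (t[0], t[1])):
            out.append(StackedInterval(heights.letters[i], j + 1, y, y + v))
            y += v
        y = 0.0
        for v, i in sorted(neg, key=lambda t: (-t[0], t[1])):
            out.append(StackedInterval(heights.letters[i], j + 1, y + v, y))
            y += v
    return out


def extract(full_sequences: Iterable[str], start: int, width: int) -> list[str]:
    """Cut the 1-based inclusive window ``[start, start + width - 1]``.

    Order is preserved.  A window that runs past the end of any sequence
    raises, naming that sequence's (1-based) index.
    """
    if start < 1:
        raise ValueError(f"start must be >= 1, got {start}")
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    out = []
    for i, s in enumerate(full_sequences):
        if start + width - 1 > len(s):
            raise IndexError(
                f"window [{start}, {start + width - 1}] exceeds sequence "
                f"{i + 1} of length {len(s)}"
            )
        out.append(s[start - 1:start + width - 1])
    return out


def simulate_sequences(
    consensus: str,
    n: int,
    mutation_rate: float,
    alphabet: Iterable[str] | None = None,
    seed: int | None = None,
    panel_label: str = "1",
) -> SequenceSet:
    """Draw aligned sequences around a consensus.

    Each position independently keeps the consensus letter with
    probability ``1 - mutation_rate`` and otherwise becomes a uniformly
    random *other* alphabet letter.  Deterministic for a fixed ``seed``.
    This generator produces the bundled trial data: motif-like sets whose
    per-position composition is a known multinomial.
    """
    if not consensus:
        raise ValueError("consensus must be nonempty")
    alpha = tuple(alphabet) if alphabet is not None else detect_alphabet([consensus])
    if not alpha:
        raise ValueError("alphabet must be nonempty")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError(f"mutation_rate must be in [0, 1], got {mutation_rate}")
    missing = set(consensus) - set(alpha)
    if missing:
        raise ValueError(f"consensus letters {sorted(missing)} not in alphabet")
    rng = np.random.default_rng(seed)
    L = len(consensus)
    idx = {c: i for i, c in enumerate(alpha)}
    cons_idx = np.array([idx[c] for c in consensus])
    k = len(alpha)
    seqs = []
    for _ in range(n):
        mutate = rng.random(L) < mutation_rate
        chars = list(consensus)
        if k > 1:
            for j in np.where(mutate)[0]:
                # uniform over the k-1 non-consensus letters
                r = rng.integers(0, k - 1)
                if r >= cons_idx[j]:
                    r += 1
                chars[j] = alpha[r]
        seqs.append("".join(chars))
    return SequenceSet(seqs, alphabet=alpha, panel_label=panel_label)
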