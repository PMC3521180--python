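"""Match-style scanning of promoter sequences with positional weight matrices.

A positional weight matrix (PWM) models the binding preference of a
transcription factor as per-position nucleotide frequencies.  Windows of a
promoter sequence are scored with the matrix similarity score (MSS): each
position's contribution is weighted by the information content of that matrix
column and the result is min-max normalised into [0, 1], so that the matrix
consensus scores 1 and the anti-consensus scores 0.  Scanning keeps every
window, on either strand, whose MSS reaches the matrix's minFN ("minimise
false negatives") threshold -- the largest cutoff that would still retain all
the binding sites the matrix was built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "BASE_INDEX",
    "WeightMatrix",
    "PredictedSite",
    "information_vector",
    "score_window",
    "scan_sequence",
    "derive_min_fn_threshold",
    "reverse_complement",
]

ALPHABET = "ACGT"
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
#: index used for the ambiguous base; scores pessimistically (see below)
N_INDEX = 4

CORE_LENGTH = 5


def information_vector(freq: np.ndarray) -> np.ndarray:
    """Per-position information content I(i) = sum_b f(i,b) * ln(4 f(i,b)).

    The convention 0 * ln(0) = 0 applies, so I(i) lies in [0, ln 4]: a
    uniform column carries no information (I = 0), a fully degenerate column
    carries the maximum ln 4.
    """
    freq = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = freq * np.log(4.0 * freq)
    terms[freq == 0.0] = 0.0
    return terms.sum(axis=1)


@dataclass
class WeightMatrix:
    """A PWM with the derived scoring apparatus.

    Parameters
    ----------
    id:
        Matrix identifier, e.g. ``"M$TOY_NFKB_01"``.
    freq:
        ``(L, 4)`` array of per-position nucleotide frequencies in A, C, G, T
        order; every row must sum to 1.
    tf_genes:
        Gene symbols of the factors this matrix represents (may be empty).
    min_fn:
        minFN score threshold in [0, 1].
    """

    id: str
    freq: np.ndarray
    tf_genes: tuple[str, ...] = ()
    min_fn: float = 0.0

    # derived, filled in __post_init__
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError(f"matrix {self.id}: freq must be (L, 4)")
        if len(self.freq) == 0:
            raise ValueError(f"matrix {self.id}: empty matrix")
        rowsums = self.freq.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError(
                f"matrix {self.id}: frequency rows must sum to 1 "
                f"(got {rowsums})"
            )
        if not 0.0 <= self.min_fn <= 1.0:
            raise ValueError(f"matrix {self.id}: min_fn must be in [0, 1]")
        self.info = information_vector(self.freq)
        # Match-style 5-mer core: consecutive run maximising summed information
        L = len(self.freq)
        k = min(CORE_LENGTH, L)
        window_sums = np.convolve(self.info, np.ones(k), mode="valid")
        self.core_start = int(np.argmax(window_sums))

    def __len__(self) -> int:
        return len(self.freq)

    @property
    def length(self) -> int:
        return len(self.freq)

    @property
    def consensus(self) -> str:
        """Per-position argmax base string (ties broken toward A<C<G<T)."""
        return "".join(ALPHABET[i] for i in np.argmax(self.freq, axis=1))

    def contributions(self) -> np.ndarray:
        """``(L, 5)`` table of I(i) * f(i, b), column 4 holding the score an
        ambiguous N receives: the per-position minimum (the most pessimistic
        choice, so N-rich windows rarely pass a threshold)."""
        contrib = self.info[:, None] * self.freq
        n_col = contrib.min(axis=1, keepdims=True)
        return np.hstack([contrib, n_col])

    def score_bounds(self) -> tuple[float, float]:
        contrib = self.info[:, None] * self.freq
        return float(contrib.min(axis=1).sum()), float(contrib.max(axis=1).sum())

    def reverse_complement(self) -> "WeightMatrix":
        """Matrix scoring the reverse-complement strand: rows reversed and
        A<->T, C<->G columns swapped."""
        rc = self.freq[::-1, [3, 2, 1, 0]]
        return WeightMatrix(self.id, rc, self.tf_genes, self.min_fn)


@dataclass(frozen=True)
class PredictedSite:
    """A matrix hit in one promoter of one species.

    ``start`` is the 0-based offset of the leftmost base of the hit in the
    gap-stripped promoter sequence, regardless of strand; ``strand`` carries
    the orientation.
    """

    matrix_id: str
    promoter_id: str
    species: str
    start: int
    strand: str
    score: float
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} to integer codes (N -> 4)."""
    codes = np.full(len(seq), -1, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    codes[arr == ord("N")] = N_INDEX
    if np.any(codes < 0):
        bad = seq[int(np.argmin(codes))]
        raise ValueError(f"invalid character {bad!r} in sequence")
    return codes


def score_window(matrix: WeightMatrix, window: str) -> float:
    """Matrix similarity score of one window.

    MSS = (Current - Min) / (Max - Min) with
    Current = sum_i I(i) f(i, b_i), Min/Max the analogous sums over the
    per-position worst/best base.  A fully uninformative matrix (Max == Min)
    scores 1.0 by convention.
    """
    if len(window) != len(matrix):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(matrix)}"
        )
    codes = encode(window)
    contrib = matrix.contributions()
    current = float(contrib[np.arange(len(matrix)), codes].sum())
    lo, hi = matrix.score_bounds()
    if hi == lo:
        return 1.0
    return (current - lo) / (hi - lo)


def _window_scores(matrix: WeightMatrix, codes: np.ndarray) -> np.ndarray:
    """Scores of all forward windows of an encoded sequence (vectorised)."""
    L = len(matrix)
    n = len(codes) - L + 1
    contrib = matrix.contributions()
    lo, hi = matrix.score_bounds()
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    current = contrib[np.arange(L), windows].sum(axis=1)
    if hi == lo:
        return np.ones(n)
    return (current - lo) / (hi - lo)


def scan_sequence(
    matrix: WeightMatrix,
    sequence: str,
    threshold: float | None = None,
    *,
    promoter_id: str = "",
    species: str = "human",
    core_threshold: float | None = None,
) -> list[PredictedSite]:
    """All windows on both strands scoring at or above ``threshold``.

    ``threshold`` defaults to the matrix minFN cutoff.  Ties with the
    threshold are kept (>=), matching the "at least the quality of the known
    sites" reading of minFN.  Reverse-strand hits are reported with the +
    strand coordinate of their leftmost base.  A sequence shorter than the
    matrix yields an empty list.  ``core_threshold``, if given, additionally
    requires the MSS of the 5-position information-richest core to reach that
    value (off by default).
    """
    if threshold is None:
        threshold = matrix.min_fn
    L = len(matrix)
    if len(sequence) < L:
        return []
    codes = encode(sequence)
    sites: list[PredictedSite] = []
    rc = matrix.reverse_complement()
    for strand, mat in (("+", matrix), ("-", rc)):
        scores = _window_scores(mat, codes)
        keep = scores >= threshold
        if core_threshold is not None:
            keep &= _core_scores(mat, codes) >= core_threshold
        for pos in np.nonzero(keep)[0]:
            sites.append(
                PredictedSite(
                    matrix_id=matrix.id,
                    promoter_id=promoter_id,
                    species=species,
                    start=int(pos),
                    strand=strand,
                    score=float(scores[pos]),
                    length=L,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _core_scores(matrix: WeightMatrix, codes: np.ndarray) -> np.ndarray:
    """MSS of the 5-position core, aligned to full-window start positions."""
    L = len(matrix)
    k = min(CORE_LENGTH, L)
    cs = matrix.core_start
    core = WeightMatrix(matrix.id + "/core", matrix.freq[cs : cs + k])
    n = len(codes) - L + 1
    core_scores = _window_scores(core, codes)
    return core_scores[cs : cs + n]


def derive_min_fn_threshold(
    matrix: WeightMatrix, known_sites: list[str]
) -> float:
    """Largest threshold retaining every known binding site of the matrix:
    the minimum of their window scores."""
    if not known_sites:
        raise ValueError("derive_min_fn_threshold requires at least one site")
    return min(score_window(matrix, s) for s in known_sites)
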