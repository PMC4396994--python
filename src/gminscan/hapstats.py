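"""Haplotype-distance statistics for two-population genomic windows.

The central quantity is ``G_min``, the ratio of the minimum to the mean
between-population pairwise sequence distance within a genomic window.
Recently introgressed haplotypes produce one (or a few) between-population
pairs that are far more similar than the window average, driving ``G_min``
toward zero, while under pure isolation the minimum and the mean track one
another and the ratio sits near one.  The companion statistic is Hudson's
distance-based fixation index,

    F_ST = 1 - (dbar_XX + dbar_YY) / (2 * dbar_XY),

computed from the same pairwise-distance summaries.

Distances are uncorrected Hamming counts, or ``p``-distances (counts divided
by the number of mutually callable sites) when alignments contain missing
data.  No multiple-hit correction is applied.

Undefined values (e.g. ``G_min`` for a window with ``dbar_XY == 0``) are
represented as ``nan``; callers exclude them from downstream
standardization rather than receiving an arbitrary number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MISSING",
    "UNDEFINED",
    "DistanceSummary",
    "HaplotypeWindow",
    "UndefinedDistanceError",
    "distance_summary",
    "encode_sequences",
    "fst_hudson",
    "gmin",
    "is_defined",
    "pairwise_distance",
    "pairwise_distance_matrix",
]

#: Integer code for a missing / uncallable allelic state.
MISSING: int = -1

#: Marker for statistics that are undefined on a window (not an error).
UNDEFINED: float = math.nan

DistanceMode = Literal["count", "p_distance"]

_NUCLEOTIDE_CODES = {
    "A": 0, "C": 1, "G": 2, "T": 3,
    "a": 0, "c": 1, "g": 2, "t": 3,
    "0": 0, "1": 1, "2": 2, "3": 3,
}


class UndefinedDistanceError(ValueError):
    """Raised when a p-distance has no mutually callable sites."""


def is_defined(x: float) -> bool:
    """True unless ``x`` is the undefined (nan) marker."""
    return not math.isnan(x)


def encode_sequences(seqs: Iterable[str | Sequence[int]]) -> np.ndarray:
    """Encode aligned haploid sequences as an int8 matrix.

    Accepts strings over {A,C,G,T,a,c,g,t,0,1,2,3} with any other symbol
    (N, -, ?, ...) treated as missing, or pre-encoded integer rows where
    negative values mark missing states.
    """
    rows = []
    for s in seqs:
        if isinstance(s, str):
            rows.append(np.fromiter(
                (_NUCLEOTIDE_CODES.get(c, MISSING) for c in s),
                dtype=np.int8, count=len(s)))
        else:
            a = np.asarray(s, dtype=np.int8)
            rows.append(np.where(a < 0, np.int8(MISSING), a))
    if not rows:
        raise ValueError("no sequences to encode")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.vstack(rows)


@dataclass(frozen=True)
class HaplotypeWindow:
    """A matrix of aligned haploid sequences plus population labels.

    Parameters
    ----------
    sequences : (n, L) int8 array
        Allelic states; ``MISSING`` (-1) marks uncallable sites.
    pop_labels : (n,) int array
        Population assignment per row, values in {1, 2}.
    window_id : str
        Opaque identifier.
    coords : (chrom, start, end), optional
        0-based half-open genomic coordinates.
    sample_names : tuple of str, optional
        Per-row names (defaults to ``h0, h1, ...``); used for tree leaves.
    """

    sequences: np.ndarray
    pop_labels: np.ndarray
    window_id: str = ""
    coords: Optional[Tuple[str, int, int]] = None
    sample_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        seqs = np.asarray(self.sequences, dtype=np.int8)
        labels = np.asarray(self.pop_labels, dtype=np.int64)
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "pop_labels", labels)
        if seqs.ndim != 2:
            raise ValueError("sequences must be a 2-D matrix")
        if labels.shape != (seqs.shape[0],):
            raise ValueError("pop_labels must have one entry per sequence row")
        if not np.isin(labels, (1, 2)).all():
            raise ValueError("pop_labels must be 1 or 2")
        if (labels == 1).sum() < 1 or (labels == 2).sum() < 1:
            raise ValueError("each population needs at least one sequence")
        if self.sample_names is not None and len(self.sample_names) != seqs.shape[0]:
            raise ValueError("sample_names must match the number of rows")

    @property
    def n1(self) -> int:
        return int((self.pop_labels == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.pop_labels == 2).sum())

    @property
    def n_sites(self) -> int:
        return int(self.sequences.shape[1])

    @property
    def names(self) -> Tuple[str, ...]:
        if self.sample_names is not None:
            return self.sample_names
        return tuple(f"h{i}" for i in range(self.sequences.shape[0]))

    @classmethod
    def from_strings(
        cls,
        pop1: Sequence[str],
        pop2: Sequence[str],
        window_id: str = "",
        coords: Optional[Tuple[str, int, int]] = None,
    ) -> "HaplotypeWindow":
        seqs = encode_sequences(list(pop1) + list(pop2))
        labels = np.array([1] * len(pop1) + [2] * len(pop2))
        return cls(seqs, labels, window_id=window_id, coords=coords)


@dataclass(frozen=True)
class DistanceSummary:
    """Pairwise-distance aggregates of one window.

    ``min_dxy``/``mean_dxy`` are over all n1*n2 between-population pairs;
    ``mean_dxx``/``mean_dyy`` average the unordered within-population pairs
    (``nan`` when the population has a single member).
    """

    min_dxy: float
    mean_dxy: float
    mean_dxx: float
    mean_dyy: float
    n_pairs_between: int
    distance_mode: DistanceMode = "count"
    argmin_pairs: Tuple[Tuple[int, int], ...] = field(default=(), compare=False)


def pairwise_distance(
    seq_a: np.ndarray | str,
    seq_b: np.ndarray | str,
    mode: DistanceMode = "count",
    pair_name: str = "",
) -> float:
    """Hamming distance between two haplotypes under pairwise deletion.

    ``count`` mode returns the number of sites where both states are
    callable and differ; ``p_distance`` divides that count by the number of
    mutually callable sites.
    """
    a = encode_sequences([seq_a])[0] if isinstance(seq_a, str) else np.asarray(seq_a)
    b = encode_sequences([seq_b])[0] if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    both = (a != MISSING) & (b != MISSING)
    diff = int(np.count_nonzero((a != b) & both))
    if mode == "count":
        return float(diff)
    if mode == "p_distance":
        n_comp = int(np.count_nonzero(both))
        if n_comp == 0:
            raise UndefinedDistanceError(
                f"no mutually callable sites for pair {pair_name or '(a, b)'}")
        return diff / n_comp
    raise ValueError(f"unknown distance mode: {mode!r}")


def pairwise_distance_matrix(
    seqs: np.ndarray,
    mode: DistanceMode = "count",
    names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Full symmetric distance matrix over the rows of ``seqs``."""
    n = seqs.shape[0]
    valid = seqs != MISSING
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diffs = ((seqs[i] != seqs[i + 1:]) & both).sum(axis=1)
        if mode == "p_distance":
            comp = both.sum(axis=1)
            for off, c in enumerate(comp):
                if c == 0:
                    j = i + 1 + off
                    pair = (names[i], names[j]) if names else (i, j)
                    raise UndefinedDistanceError(
                        f"no mutually callable sites for pair {pair}")
            row = diffs / comp
        else:
            row = diffs.astype(float)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return d


def distance_summary(
    window: HaplotypeWindow, mode: DistanceMode = "count"
) -> DistanceSummary:
    """Between- and within-population distance aggregates for a window."""
    labels = window.pop_labels
    idx1 = np.flatnonzero(labels == 1)
    idx2 = np.flatnonzero(labels == 2)
    names = window.names
    d = pairwise_distance_matrix(window.sequences, mode=mode, names=names)

    between = d[np.ix_(idx1, idx2)]
    min_dxy = float(between.min())
    mean_dxy = float(between.mean())
    hits = np.argwhere(between == min_dxy)
    argmin_pairs = tuple((int(idx1[i]), int(idx2[j])) for i, j in hits)

    def within_mean(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return UNDEFINED
        sub = d[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())

    return DistanceSummary(
        min_dxy=min_dxy,
        mean_dxy=mean_dxy,
        mean_dxx=within_mean(idx1),
        mean_dyy=within_mean(idx2),
        n_pairs_between=len(idx1) * len(idx2),
        distance_mode=mode,
        argmin_pairs=argmin_pairs,
    )


def gmin(summary: DistanceSummary) -> float:
    """G_min = min(d_XY) / dbar_XY; ``nan`` when dbar_XY == 0."""
    if summary.mean_dxy == 0:
        return UNDEFINED
    return summary.min_dxy / summary.mean_dxy


def fst_hudson(summary: DistanceSummary) -> float:
    """Hudson's F_ST = 1 - (dbar_XX + dbar_YY) / (2 dbar_XY).

    A single-member population contributes a zero within-population term
    (its within diversity is unobservable); ``nan`` when dbar_XY == 0.
    """
    if summary.mean_dxy == 0:
        return UNDEFINED
    dxx = summary.mean_dxx if is_defined(summary.mean_dxx) else 0.0
    dyy = summary.mean_dyy if is_defined(summary.mean_dyy) else 0.0
    return 1.0 - (dxx + dyy) / (2.0 * summary.mean_dxy)
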