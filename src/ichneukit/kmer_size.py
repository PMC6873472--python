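"""K-mer spectrum construction and genome-size estimation.

The estimator is the classic coverage argument: at sequencing depth high
enough for k-mer frequencies to follow a Poisson distribution around the
modal frequency, the genome size is

    G = K_num / K_depth

where K_num is the total number of counted k-mers and K_depth the modal
k-mer frequency. Error-derived k-mers pile up at low frequency; by default
they are excluded by cutting at the first valley of the histogram, which is
also where the Poisson premise starts to hold.

Counting is exact and canonical: each k-mer is identified with the
lexicographic minimum of itself and its reverse complement, because shotgun
reads sample both strands and non-canonical counting would halve per-k-mer
depth. k must be odd so no k-mer is its own reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

DEFAULT_K = 17

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


class EstimationError(RuntimeError):
    """The histogram does not support an automatic estimate."""


def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd (palindrome-free canonicalization), got {k}")
    if not 11 <= k <= 31:
        raise ValueError(f"k must be in [11, 31], got {k}")


def canonical_kmer_codes(seqs: Iterable[str], k: int = DEFAULT_K) -> np.ndarray:
    """Integer codes of all canonical k-mers in the given sequences.

    Windows containing a non-ACGT character contribute nothing; a sequence
    of length L < k contributes nothing. Codes are base-4 integers
    (A=0, C=1, G=2, T=3), canonicalized as min(code, revcomp code).
    """
    _validate_k(k)
    seqs = list(seqs)
    if not seqs:
        return np.empty(0, dtype=np.int64)
    # Joining with 'N' masks windows that would span sequence boundaries.
    joined = "N".join(seqs)
    raw = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if raw.size < k:
        return np.empty(0, dtype=np.int64)
    invalid = raw == 255
    fwd_bases = np.where(invalid, 0, raw).astype(np.int64)
    rc_bases = np.where(invalid, 0, 3 - raw).astype(np.int64)

    pw_desc = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(fwd_bases, k)
    fwd = win @ pw_desc
    # revcomp code of the window at i is sum_m (3 - base[i+m]) * 4^m
    rwin = np.lib.stride_tricks.sliding_window_view(rc_bases, k)
    rev = rwin @ pw_desc[::-1]

    csum = np.concatenate(([0], np.cumsum(invalid)))
    spans_invalid = (csum[k:] - csum[:-k]) > 0
    return np.minimum(fwd, rev)[~spans_invalid]


class KmerCountTable:
    """Exact canonical k-mer counts with vectorized lookup."""

    def __init__(self, codes: np.ndarray, counts: np.ndarray, k: int):
        self.k = k
        self._codes = codes      # sorted unique canonical codes
        self._counts = counts
        self.total = int(counts.sum())

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], k: int = DEFAULT_K) -> "KmerCountTable":
        all_codes = canonical_kmer_codes(seqs, k)
        codes, counts = np.unique(all_codes, return_counts=True)
        return cls(codes, counts, k)

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Counts for the given canonical codes (0 for unseen k-mers)."""
        if len(self._codes) == 0:
            return np.zeros(len(codes), dtype=np.int64)
        idx = np.searchsorted(self._codes, codes)
        idx = np.clip(idx, 0, len(self._codes) - 1)
        return np.where(self._codes[idx] == codes, self._counts[idx], 0)

    def min_count(self, seq: str) -> int:
        """Smallest count among the k-mers of one sequence.

        Raises ValueError when the sequence has no N-free window of
        length k (nothing to evaluate).
        """
        codes = canonical_kmer_codes([seq], self.k)
        if codes.size == 0:
            raise ValueError(f"sequence shorter than k={self.k} or all windows contain N")
        return int(self.lookup(codes).min())


@dataclass
class KmerHistogram:
    """Distinct-canonical-k-mer counts per occurrence frequency."""

    k: int
    occ: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f < 1 or c < 0 for f, c in self.occ.items()):
            raise ValueError("histogram frequencies must be >= 1 with counts >= 0")

    @property
    def total_kmers(self) -> int:
        """Sum of f * occ[f]: the total number of counted k-mers."""
        return sum(f * c for f, c in self.occ.items())

    @property
    def distinct_kmers(self) -> int:
        return sum(self.occ.values())

    def dense(self) -> np.ndarray:
        """Counts as an array indexed by frequency 1..fmax (index 0 unused)."""
        fmax = max(self.occ) if self.occ else 0
        arr = np.zeros(fmax + 1, dtype=np.int64)
        for f, c in self.occ.items():
            arr[f] = c
        return arr


def count_kmers(reads: Iterable, k: int = DEFAULT_K) -> KmerHistogram:
    """Build the canonical k-mer frequency histogram of a read set.

    ``reads`` may be plain strings, FastqRead records or ReadPairs (both
    mates are counted). A read of length L contributes L - k + 1 k-mers
    minus any window spanning an N.
    """
    seqs: list[str] = []
    for r in reads:
        if isinstance(r, str):
            seqs.append(r)
        elif hasattr(r, "mate1_seq"):
            seqs.append(r.mate1_seq)
            seqs.append(r.mate2_seq)
        else:
            seqs.append(r.seq)
    codes = canonical_kmer_codes(seqs, k)
    _, counts = np.unique(codes, return_counts=True)
    freqs, n_distinct = np.unique(counts, return_counts=True)
    occ = {int(f): int(c) for f, c in zip(freqs, n_distinct)}
    return KmerHistogram(k=k, occ=occ)


def find_valley(hist: KmerHistogram) -> int:
    """First local minimum of occ[f] scanning upward from f = 1.

    This is the cutoff separating the error peak (f below the valley) from
    the coverage peak. Raises EstimationError when the histogram decreases
    monotonically to its end (no interior signal peak).
    """
    arr = hist.dense()
    fmax = len(arr) - 1
    if fmax < 1:
        raise EstimationError("empty k-mer histogram")
    f = 1
    while f < fmax and arr[f + 1] < arr[f]:
        f += 1
    if f == fmax:
        raise EstimationError(
            "histogram decreases monotonically: no error/signal valley found; "
            "supply an explicit valley"
        )
    return f


def find_kdepth(hist: KmerHistogram, valley: int | None = None) -> int:
    """Modal k-mer frequency at or above the valley (K_depth).

    Ties break toward the smaller frequency.
    """
    if valley is None:
        valley = find_valley(hist)
    if valley < 1:
        raise ValueError("valley must be >= 1")
    arr = hist.dense()
    if valley >= len(arr):
        raise EstimationError(f"valley {valley} beyond histogram range")
    region = arr[valley:]
    kdepth = valley + int(np.argmax(region))
    if arr[kdepth] == 0:
        raise EstimationError("no k-mers at or above the valley")
    return kdepth


@dataclass(frozen=True)
class GenomeSizeEstimate:
    k_num: int
    k_depth: int
    genome_size: float
    valley: int
    included_range: tuple[int, int]

    def __post_init__(self) -> None:
        assert self.genome_size == self.k_num / self.k_depth


def estimate_genome_size(
    hist: KmerHistogram,
    include_error_kmers: bool = False,
    valley: int | None = None,
) -> GenomeSizeEstimate:
    """Estimate genome size as G = K_num / K_depth.

    K_num sums f * occ[f] over f >= valley by default; with
    ``include_error_kmers`` the sum runs over all frequencies (the literal
    total k-mer count, biased upward when sequencing errors are present).
    """
    if valley is None:
        valley = find_valley(hist)
    k_depth = find_kdepth(hist, valley)
    if k_depth == 0:
        raise EstimationError("K_depth is zero")
    fmax = max(hist.occ)
    lo = 1 if include_error_kmers else valley
    k_num = sum(f * c for f, c in hist.occ.items() if f >= lo)
    return GenomeSizeEstimate(
        k_num=k_num,
        k_depth=k_depth,
        genome_size=k_num / k_depth,
        valley=valley,
        included_range=(lo, fmax),
    )


def write_histogram_tsv(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        for f in sorted(hist.occ):
            fh.write(f"{f}\t{hist.occ[f]}\n")


def read_histogram_tsv(path, k: int = DEFAULT_K) -> KmerHistogram:
    occ: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f, c = line.split("\t")
            occ[int(f)] = int(c)
    return KmerHistogram(k=k, occ=occ)
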