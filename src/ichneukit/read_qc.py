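"""Whole-read filtering of paired-end / mate-pair libraries.

Seven per-pair rules, applied in a fixed order, each with per-species
thresholds ("preset A" for the Cotesia-style run, "preset B" for the
Diadromus-style run):

1/2. N fraction   — a mate with 'N' over the class threshold of its length
3.   low quality  — more than the class threshold of bases at Phred <= 7
4.   adapter      — an ungapped adapter overlap of >= 10 bp with <= 2
                    mismatches anywhere on either mate (3' overhangs
                    included)
5.   overlap      — short-insert mates whose 3' ends overlap >= 10 bp
                    (mate2 reverse-complemented; <= 10% mismatches)
6.   duplicates   — a later pair byte-identical in (mate1_seq, mate2_seq)
                    to an earlier one (PCR duplication); qualities ignored
7.   k-mer freq   — preset B only: any k-mer of either mate with count
                    < 4 in the library-wide table (error-indicative)

A pair is removed whole if either mate fails; every removed pair is
attributed to the FIRST rule it fails, so per-rule counts depend on the
rule order and always sum with kept pairs to the input count.

N-fraction and low-quality thresholds are strict ("over", "more than");
the adapter and overlap lengths are inclusive (>= 10 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import ReadPair, qual_to_phred, revcomp
from .kmer_size import KmerCountTable

#: Widely used sequencing adapter; the default planted/searched sequence.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

#: Rule application order; removed pairs are attributed to the first failure.
RULE_ORDER = ("n_fraction", "low_quality", "adapter", "overlap", "duplicate", "low_kmer_freq")


@dataclass(frozen=True)
class FilterProfile:
    """Thresholds for the seven filter rules.

    Fractions are per-mate; `_short` / `_large` select by the pair's
    library class. ``kmer_rule_active`` enables rule 7 (preset B only).
    """

    name: str = "custom"
    n_frac_short: float = 0.02
    n_frac_large: float = 0.02
    q_cut: int = 7
    lowq_frac_short: float = 0.30
    lowq_frac_large: float = 0.40
    adapter_seq: str = DEFAULT_ADAPTER
    adapter_min_len: int = 10
    adapter_max_mismatch: int = 2
    overlap_min: int = 10
    overlap_max_mismatch_frac: float = 0.10
    kmer_rule_active: bool = False
    kmer_k: int = 17
    kmer_min_freq: int = 4

    def __post_init__(self) -> None:
        for frac in (self.n_frac_short, self.n_frac_large,
                     self.lowq_frac_short, self.lowq_frac_large,
                     self.overlap_max_mismatch_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for thr in (self.q_cut, self.adapter_min_len, self.adapter_max_mismatch,
                    self.overlap_min, self.kmer_min_freq):
            if thr < 0:
                raise ValueError("integer thresholds must be >= 0")
        if len(self.adapter_seq) < self.adapter_min_len:
            raise ValueError("adapter shorter than adapter_min_len")

    @classmethod
    def preset(cls, name: str, adapter_seq: str = DEFAULT_ADAPTER) -> "FilterProfile":
        """Per-species presets.

        ``cvestalis`` (A): N over 2%/5% (short/large), low-quality over
        30%/40%, no k-mer rule. ``dcollaris`` (B): N over 2% for all
        libraries, low-quality over 40%/60%, k-mer rule active.
        """
        if name == "cvestalis":
            return cls(name=name, n_frac_short=0.02, n_frac_large=0.05,
                       lowq_frac_short=0.30, lowq_frac_large=0.40,
                       adapter_seq=adapter_seq, kmer_rule_active=False)
        if name == "dcollaris":
            return cls(name=name, n_frac_short=0.02, n_frac_large=0.02,
                       lowq_frac_short=0.40, lowq_frac_large=0.60,
                       adapter_seq=adapter_seq, kmer_rule_active=True)
        raise ValueError(f"unknown preset {name!r} (expected 'cvestalis' or 'dcollaris')")

    def n_threshold(self, library_class: str) -> float:
        return self.n_frac_short if library_class == "short" else self.n_frac_large

    def lowq_threshold(self, library_class: str) -> float:
        return self.lowq_frac_short if library_class == "short" else self.lowq_frac_large


@dataclass
class FilterReport:
    """Per-rule accounting of a filtering run.

    Invariant: pairs_in == pairs_kept + sum(removed.values()).
    """

    pairs_in: int = 0
    pairs_kept: int = 0
    bases_kept: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def as_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "pairs_kept": self.pairs_kept,
            "bases_kept": self.bases_kept,
            "removed": dict(self.removed),
        }


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------

def fraction_n(seq: str) -> float:
    """Fraction of 'N' bases in a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    return seq.count("N") / len(seq)


def low_quality_fraction(qual: str, q_cut: int = 7) -> float:
    """Fraction of bases with Phred score <= q_cut (Phred+33 encoding)."""
    if not qual:
        raise ValueError("empty quality string")
    phred = qual_to_phred(qual)
    return float(np.count_nonzero(phred <= q_cut)) / len(phred)


def adapter_match(
    seq: str, adapter: str, min_len: int = 10, max_mismatch: int = 2
) -> Optional[tuple[int, int]]:
    """Best ungapped adapter alignment of length >= min_len with <= max_mismatch.

    All offsets are scanned, including dangling overhangs at both read
    ends, so a partial adapter at the 3' terminus is found. Returns
    (read_offset, overlap_length) of the longest qualifying overlap, or
    None. An N in the read counts as a mismatch.
    """
    if len(adapter) < min_len:
        raise ValueError(f"adapter length {len(adapter)} < min_len {min_len}")
    n, m = len(seq), len(adapter)
    best: Optional[tuple[int, int]] = None
    for offset in range(-(m - min_len), n - min_len + 1):
        lo = max(0, offset)
        hi = min(n, offset + m)
        length = hi - lo
        if length < min_len:
            continue
        mism = 0
        for i in range(lo, hi):
            if seq[i] != adapter[i - offset]:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch and (best is None or length > best[1]):
            best = (lo, length)
    return best


def pair_overlap(
    pair: ReadPair, min_overlap: int = 10, max_mismatch_frac: float = 0.10
) -> Optional[int]:
    """Length of the longest mate1-suffix / revcomp(mate2)-prefix overlap.

    Returns the overlap length when it is >= min_overlap with a mismatch
    fraction <= max_mismatch_frac, else None. This detects short-insert
    fragments shorter than the summed read lengths.
    """
    s1 = pair.mate1_seq
    s2 = revcomp(pair.mate2_seq)
    max_len = min(len(s1), len(s2))
    for length in range(max_len, min_overlap - 1, -1):
        tail = s1[len(s1) - length:]
        head = s2[:length]
        allowed = int(max_mismatch_frac * length)
        mism = 0
        ok = True
        for a, b in zip(tail, head):
            if a != b:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            return length
    return None


def deduplicate(pairs: Iterable[ReadPair]) -> tuple[list[ReadPair], int]:
    """Keep the first occurrence of each (mate1_seq, mate2_seq) pair.

    Comparison is sequence-only (qualities ignored); mate order matters,
    so swapped-mate pairs are not collapsed.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    n_dup = 0
    for p in pairs:
        key = (p.mate1_seq, p.mate2_seq)
        if key in seen:
            n_dup += 1
        else:
            seen.add(key)
            kept.append(p)
    return kept, n_dup


def kmer_frequency_rule(
    pair: ReadPair, kmer_counts: KmerCountTable, min_freq: int = 4
) -> bool:
    """True (pass) iff every k-mer of both mates has count >= min_freq.

    K-mers containing N are skipped; a mate with no evaluable k-mer
    (shorter than k) raises ValueError.
    """
    for seq in (pair.mate1_seq, pair.mate2_seq):
        if kmer_counts.min_count(seq) < min_freq:
            return False
    return True


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def first_failing_rule(
    pair: ReadPair,
    profile: FilterProfile,
    seen: Optional[set[tuple[str, str]]] = None,
    kmer_counts: Optional[KmerCountTable] = None,
) -> Optional[str]:
    """Name of the first rule the pair fails, or None if it passes all.

    ``seen`` carries the duplicate-detection state; when None the
    duplicate rule is skipped (single-pair evaluation).
    """
    n_thr = profile.n_threshold(pair.library_class)
    if fraction_n(pair.mate1_seq) > n_thr or fraction_n(pair.mate2_seq) > n_thr:
        return "n_fraction"
    lowq_thr = profile.lowq_threshold(pair.library_class)
    if (low_quality_fraction(pair.mate1_qual, profile.q_cut) > lowq_thr
            or low_quality_fraction(pair.mate2_qual, profile.q_cut) > lowq_thr):
        return "low_quality"
    for seq in (pair.mate1_seq, pair.mate2_seq):
        if adapter_match(seq, profile.adapter_seq, profile.adapter_min_len,
                         profile.adapter_max_mismatch) is not None:
            return "adapter"
    if pair.library_class == "short":
        if pair_overlap(pair, profile.overlap_min,
                        profile.overlap_max_mismatch_frac) is not None:
            return "overlap"
    if seen is not None:
        key = (pair.mate1_seq, pair.mate2_seq)
        if key in seen:
            return "duplicate"
        seen.add(key)
    if profile.kmer_rule_active and kmer_counts is not None:
        if not kmer_frequency_rule(pair, kmer_counts, profile.kmer_min_freq):
            return "low_kmer_freq"
    return None


def filter_library(
    pairs: Sequence[ReadPair],
    profile: FilterProfile,
    kmer_counts: Optional[KmerCountTable] = None,
) -> tuple[list[ReadPair], FilterReport]:
    """Apply the filter rules in order and account every pair exactly once.

    When the profile activates rule 7 and no k-mer table is supplied, one
    is built from the raw input pairs (no error correction is applied
    beforehand). Duplicate state only advances for pairs that survive
    rules 1-5, so a defective copy is attributed to its defect, not to
    duplication.
    """
    pairs = list(pairs)
    if profile.kmer_rule_active and kmer_counts is None:
        seqs = [s for p in pairs for s in (p.mate1_seq, p.mate2_seq)]
        kmer_counts = KmerCountTable.from_sequences(seqs, profile.kmer_k)

    report = FilterReport(pairs_in=len(pairs))
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    for pair in pairs:
        rule = first_failing_rule(pair, profile, seen, kmer_counts)
        if rule is None:
            kept.append(pair)
            report.pairs_kept += 1
            report.bases_kept += pair.n_bases
        else:
            report.removed[rule] += 1
    return kept, report
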