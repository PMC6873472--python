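"""Readers and writers for the plain-text formats the toolkit touches.

Domain types live here: sequencing read pairs, similarity hits and gene
loci are the currency passed between the QC, orthology and synteny modules.

Coordinate conventions: gene loci are GFF3-style (1-based, inclusive);
window and depth-track arithmetic elsewhere is 0-based half-open. The two
only meet in the readers below.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = frozenset("ACGTN")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: BLAST tabular (outfmt 6) column names, 12 columns.
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    """A file did not conform to its declared format."""


class PairingError(ParseError):
    """Two paired FASTQ files went out of sync."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def qual_to_phred(qual: str) -> np.ndarray:
    """Decode a Phred+33 quality string to integer scores.

    Raises ValueError for characters outside the Phred 0-93 range.
    """
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
    if arr.size and (arr.min() < 0 or arr.max() > 93):
        raise ValueError("quality string contains characters outside Phred+33 range 0-93")
    return arr


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; DNA is normalized to uppercase ACGTN."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def is_dna(self) -> bool:
        return set(self.seq) <= DNA_ALPHABET

    def gc_fraction(self) -> float:
        """GC fraction over non-N bases (0.0 if all-N)."""
        non_n = len(self.seq) - self.seq.count("N")
        if non_n == 0:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / non_n


@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id!r}: sequence and quality lengths differ")


@dataclass(frozen=True)
class ReadPair:
    """Two mates of one sequenced fragment with Phred+33 qualities.

    library_class is "short" (insert <= 800 bp paired-end) or "large"
    (2-20 kb mate-pair); the QC thresholds differ by class.
    """

    pair_id: str
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str
    library_class: str = "short"

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual):
            raise ValueError(f"pair {self.pair_id!r}: mate1 seq/qual length mismatch")
        if len(self.mate2_seq) != len(self.mate2_qual):
            raise ValueError(f"pair {self.pair_id!r}: mate2 seq/qual length mismatch")
        if self.library_class not in ("short", "large"):
            raise ValueError(f"library_class must be 'short' or 'large', got {self.library_class!r}")
        for q in (self.mate1_qual, self.mate2_qual):
            qual_to_phred(q)

    @property
    def n_bases(self) -> int:
        return len(self.mate1_seq) + len(self.mate2_seq)


@dataclass(frozen=True)
class HitRecord:
    """One tabular similarity hit (BLASTP-style)."""

    query: str
    subject: str
    identity: float
    aln_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be a percentage in [0, 100]")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")


@dataclass(frozen=True)
class GeneLocus:
    """A gene on a scaffold with 1-based inclusive coordinates.

    rank is the 0-based order index along the scaffold by start position;
    ranks on one scaffold are consecutive integers from 0.
    """

    gene: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene!r}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.gene!r}: coordinates are 1-based, got start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene!r}: strand must be '+' or '-'")
        if self.rank < 0:
            raise ValueError(f"gene {self.gene!r}: rank must be >= 0")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def xopen(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    with xopen(path) as fh:
        return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with xopen(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path) -> Iterator[FastqRead]:
    """Stream single reads from a (possibly gzipped) 4-line-record FASTQ.

    Sequences are uppercased; quality strings are passed through verbatim.
    Malformed records raise ParseError naming the approximate line.
    """
    with xopen(path) as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed FASTQ record {idx + 1} (near line {4 * idx + 1}): {exc}"
                ) from exc
            yield FastqRead(title, seq.upper(), qual)
            idx += 1


def _strip_mate_suffix(title: str) -> str:
    name = title.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def read_fastq_pairs(path1, path2, library_class: str = "short") -> Iterator[ReadPair]:
    """Stream synchronized ReadPairs from two FASTQ files.

    Raises PairingError if the files have different lengths or mate ids
    disagree after stripping /1 and /2 suffixes.
    """
    it1, it2 = read_fastq(path1), read_fastq(path2)
    i = 0
    while True:
        r1, r2 = next(it1, None), next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise PairingError(
                f"{path1}/{path2}: files contain different numbers of records"
            )
        i += 1
        n1, n2 = _strip_mate_suffix(r1.id), _strip_mate_suffix(r2.id)
        if n1 != n2:
            raise PairingError(
                f"{path1}/{path2}: record {i} ids desynchronized ({n1!r} vs {n2!r})"
            )
        yield ReadPair(n1, r1.seq, r1.qual, r2.seq, r2.qual, library_class)


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with xopen(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    with xopen(path1, "wt") as fh1, xopen(path2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.pair_id}/1\n{p.mate1_seq}\n+\n{p.mate1_qual}\n")
            fh2.write(f"@{p.pair_id}/2\n{p.mate2_seq}\n+\n{p.mate2_qual}\n")


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

def assign_ranks(
    rows: Sequence[tuple[str, str, int, int, str]], species: str
) -> list[GeneLocus]:
    """Build ranked GeneLocus records from (gene, scaffold, start, end, strand).

    Loci are sorted by (scaffold, start); start ties break by end then gene
    id; ranks are consecutive from 0 within each scaffold.
    """
    seen: set[str] = set()
    for gene, *_ in rows:
        if gene in seen:
            raise ValueError(f"duplicate gene id {gene!r} in gene table")
        seen.add(gene)
    ordered = sorted(rows, key=lambda r: (r[1], r[2], r[3], r[0]))
    loci: list[GeneLocus] = []
    rank = 0
    prev_scaffold = None
    for gene, scaffold, start, end, strand in ordered:
        if scaffold != prev_scaffold:
            rank = 0
            prev_scaffold = scaffold
        loci.append(GeneLocus(gene, species, scaffold, int(start), int(end), strand, rank))
        rank += 1
    return loci


def read_gene_table(path, dialect: str = "tsv", species: str = "A") -> list[GeneLocus]:
    """Read gene loci from a 5-column TSV or a GFF3 file.

    TSV columns: gene, scaffold, start, end, strand (1-based inclusive,
    no header, '#' comments allowed). GFF3: only ``gene`` features become
    loci; the GFF3 ID attribute is the gene id.
    """
    if dialect == "tsv":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["gene", "scaffold", "start", "end", "strand"],
            dtype={"gene": str, "scaffold": str, "strand": str},
        )
        rows = [
            (r.gene, r.scaffold, int(r.start), int(r.end), r.strand)
            for r in df.itertuples()
        ]
    elif dialect == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = [
            (f.id, f.seqid, f.start, f.end, f.strand)
            for f in db.features_of_type("gene")
        ]
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    for gene, _, start, end, _ in rows:
        if start > end:
            raise ValueError(f"gene {gene!r}: start {start} > end {end}")
    return assign_ranks(rows, species)


def write_gene_table(loci: Iterable[GeneLocus], path) -> None:
    with xopen(path, "wt") as fh:
        for l in sorted(loci, key=lambda x: (x.scaffold, x.start, x.end, x.gene)):
            fh.write(f"{l.gene}\t{l.scaffold}\t{l.start}\t{l.end}\t{l.strand}\n")


# ---------------------------------------------------------------------------
# Hit tables, depth tracks, reports
# ---------------------------------------------------------------------------

def read_hit_table(path) -> list[HitRecord]:
    """Read a 12-column BLAST tabular (outfmt 6) file into HitRecords."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=BLAST6_COLUMNS)
    return [
        HitRecord(
            query=str(r.qseqid), subject=str(r.sseqid), identity=float(r.pident),
            aln_len=int(r.length), evalue=float(r.evalue), bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    """Write HitRecords as 12-column BLAST tabular; unused columns are 0."""
    with xopen(path, "wt") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity:.2f}\t{h.aln_len}"
                f"\t0\t0\t0\t0\t0\t0\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def read_depth_track(path) -> pd.DataFrame:
    """Read a bedGraph-like depth TSV: scaffold, 0-based start, end, depth."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["scaffold", "start", "end", "depth"],
        dtype={"scaffold": str},
    )
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: depth intervals must satisfy 0 <= start < end")
    if (df["depth"] < 0).any():
        raise ParseError(f"{path}: negative depth values")
    return df


def write_depth_track(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["scaffold", "start", "end", "depth"])


def yield_report(
    libraries: Sequence[tuple[str, float]], genome_size_bp: float | None = None
) -> dict:
    """Account sequencing yield per platform, in gigabases.

    Returns per-platform totals, the grand total, and — when a genome size
    in bp is supplied — fold coverage = total bases / genome size, all
    reported to 2 decimals.
    """
    per: dict[str, float] = {}
    for platform, gb in libraries:
        if gb < 0:
            raise ValueError(f"negative yield for platform {platform!r}")
        per[platform] = per.get(platform, 0.0) + gb
    total = sum(gb for _, gb in libraries)
    report = {
        "per_platform_gb": {p: round(v, 2) for p, v in per.items()},
        "total_gb": round(total, 2),
    }
    if genome_size_bp is not None:
        if genome_size_bp <= 0:
            raise ValueError("genome size must be positive")
        report["coverage_fold"] = round(total * 1e9 / genome_size_bp, 2)
    return report


def write_json_report(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    """Load a YAML configuration file (threshold presets etc.)."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}
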