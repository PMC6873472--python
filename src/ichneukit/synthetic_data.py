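"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

- ``simulate_genome`` / ``simulate_reads`` — an i.i.d. genome and a
  paired-end library with planted, mutually exclusive read defects
  (N-rich, low-quality, adapter-contaminated, overlapping short-insert,
  PCR-duplicate, error-k-mer), each labelled, to exercise the seven
  read-filter rules and the k-mer estimator.
- ``simulate_ortho_scenario`` — two species' gene orders derived from a
  common ancestor by block-preserving moves (inversions), plus lineage
  duplications, relocations ("shuffles") and unalignable genes, with
  BLAST-like hit tables whose e-values make true orthologues beat
  paralogues; true orthologue pairs and true microsynteny blocks are
  recorded.
- ``inject_contaminant`` — extra scaffolds of shifted GC and shifted mean
  depth appended to a host assembly, with a bedGraph-like depth track and
  scaffold truth labels, for the GC x depth screen.

All generators are deterministic for a fixed seed. Defect magnitudes are
fixed well beyond the filter thresholds (10% N, 70% low-quality bases,
15 bp planted adapter, 50% mate overlap) so that truth labels and rule
outcomes coincide; reads are drawn from a circular view of the genome so
coverage is uniform and clean reads cannot carry low-frequency k-mers at
contig edges. Optionally each pair is rejection-sampled until its label
equals the first rule it fails under a given profile, removing the small
chance of e.g. a spurious adapter-like 10-mer in an otherwise clean read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    GeneLocus, HitRecord, ReadPair, SequenceRecord, revcomp,
    write_fasta, write_fastq_pairs, write_gene_table, write_hit_table,
)
from .read_qc import DEFAULT_ADAPTER, FilterProfile, first_failing_rule
from .synteny import Anchor, SyntenyBlock, _orientation
from .orthology import OrthologPair

BASES = np.array(list("ACGT"))

# Planted defect magnitudes; chosen beyond every preset threshold.
PLANT_N_FRAC = 0.10          # > 2% and > 5% N thresholds
PLANT_LOWQ_FRAC = 0.70       # > 30/40/60 % low-quality thresholds
PLANT_LOWQ_PHRED = 2         # <= Q7
PLANT_ADAPTER_LEN = 15       # >= 10 bp exact adapter tail
CLEAN_QMIN, CLEAN_QMAX = 30, 40

TRUTH_LABELS = ("clean", "n_rich", "low_qual", "adapter", "overlap",
                "duplicate", "error_kmer")


def simulate_genome(length: int, gc: float, seed: int, id: str = "sim_genome") -> SequenceRecord:
    """An i.i.d. random genome with expected GC fraction ``gc``."""
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(BASES, size=length, p=p))
    return SequenceRecord(id, seq)


@dataclass
class SimulatedLibrary:
    """A simulated paired-end library with one primary truth label per pair."""

    genome: SequenceRecord
    reads: list[ReadPair]
    truth: list[str]  # parallel to reads

    def truth_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.truth:
            counts[t] = counts.get(t, 0) + 1
        return counts


def _rand_qual(rng: np.random.Generator, n: int) -> str:
    scores = rng.integers(CLEAN_QMIN, CLEAN_QMAX + 1, size=n)
    return "".join(chr(33 + int(q)) for q in scores)


def _substitute(rng: np.random.Generator, seq: str, pos: int) -> str:
    old = seq[pos]
    choices = [b for b in "ACGT" if b != old]
    return seq[:pos] + str(rng.choice(choices)) + seq[pos + 1:]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        seq = _substitute(rng, seq, int(pos))
    return seq


def simulate_reads(
    genome: SequenceRecord,
    depth: float = 50.0,
    read_len: int = 100,
    insert_mean: int = 500,
    error_rate: float = 0.0,
    n_rate: float = 0.0,
    adapter: str = DEFAULT_ADAPTER,
    adapter_frac: float = 0.0,
    dup_frac: float = 0.0,
    lowq_frac: float = 0.0,
    overlap_frac: float = 0.0,
    err_kmer_frac: float = 0.0,
    library_class: str = "short",
    seed: int = 0,
    circular: bool = True,
    verify_profile: Optional[FilterProfile] = None,
) -> SimulatedLibrary:
    """Simulate ~ depth * len(genome) / (2 * read_len) read pairs.

    Fragments are forward-reverse oriented (mates face inward). Defect
    classes are drawn per pair from (n_rate, lowq_frac, adapter_frac,
    overlap_frac, err_kmer_frac), the remainder being clean; duplicates
    are byte-identical copies of clean pairs appended afterwards, about
    dup_frac * n_pairs of them. ``error_rate`` plants uniform random
    substitutions on every read without changing its label (use for
    k-mer-spectrum studies, not filter truth). With ``verify_profile``
    each pair is resampled until its truth label matches the first rule
    it fails under that profile.
    """
    if not genome.seq:
        raise ValueError("empty genome")
    glen = len(genome.seq)
    if insert_mean < read_len:
        raise ValueError("insert_mean must be >= read_len")
    if insert_mean > glen:
        raise ValueError("insert_mean exceeds genome length")
    probs = (n_rate, lowq_frac, adapter_frac, overlap_frac, err_kmer_frac)
    if any(p < 0 for p in probs) or sum(probs) > 1:
        raise ValueError("defect fractions must be >= 0 and sum to <= 1")
    if overlap_frac > 0 and library_class != "short":
        raise ValueError("overlapping pairs only occur in short-insert libraries")
    if not 0 <= dup_frac <= 1:
        raise ValueError("dup_frac must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n_pairs = max(1, round(depth * glen / (2 * read_len)))
    labels = rng.choice(
        ["n_rich", "low_qual", "adapter", "overlap", "error_kmer", "clean"],
        size=n_pairs,
        p=[*probs, 1 - sum(probs)],
    )
    overlap_insert = read_len + read_len // 2  # 50% mate overlap
    doubled = genome.seq + genome.seq

    def draw_pair(label: str, idx: int) -> ReadPair:
        insert = overlap_insert if label == "overlap" else insert_mean
        if circular:
            start = int(rng.integers(0, glen))
            frag = doubled[start:start + insert]
        else:
            start = int(rng.integers(0, glen - insert + 1))
            frag = genome.seq[start:start + insert]
        m1 = frag[:read_len]
        m2 = revcomp(frag)[:read_len]
        m1 = _apply_errors(rng, m1, error_rate)
        m2 = _apply_errors(rng, m2, error_rate)
        q1, q2 = _rand_qual(rng, read_len), _rand_qual(rng, read_len)
        if label == "n_rich":
            k = math.ceil(PLANT_N_FRAC * read_len)
            pos = rng.choice(read_len, size=k, replace=False)
            arr = list(m1)
            for p_ in pos:
                arr[p_] = "N"
            m1 = "".join(arr)
        elif label == "low_qual":
            k = math.ceil(PLANT_LOWQ_FRAC * read_len)
            pos = rng.choice(read_len, size=k, replace=False)
            arr = list(q1)
            for p_ in pos:
                arr[p_] = chr(33 + PLANT_LOWQ_PHRED)
            q1 = "".join(arr)
        elif label == "adapter":
            m1 = m1[:read_len - PLANT_ADAPTER_LEN] + adapter[:PLANT_ADAPTER_LEN]
        elif label == "error_kmer":
            m1 = _substitute(rng, m1, int(rng.integers(0, read_len)))
        return ReadPair(f"sim{idx}", m1, q1, m2, q2, library_class)

    expected_rule = {
        "clean": None, "n_rich": "n_fraction", "low_qual": "low_quality",
        "adapter": "adapter", "overlap": "overlap", "error_kmer": None,
    }
    reads: list[ReadPair] = []
    truth: list[str] = []
    seen_keys: set[tuple[str, str]] = set()
    for i, label in enumerate(labels):
        for _ in range(200):
            pair = draw_pair(label, i)
            # originals must be byte-unique so only planted duplicates repeat
            if (pair.mate1_seq, pair.mate2_seq) in seen_keys:
                continue
            # rules 1-5 only: duplicate/k-mer state is library-level
            if (verify_profile is None
                    or first_failing_rule(pair, verify_profile) == expected_rule[label]):
                break
        else:
            raise RuntimeError(
                f"could not realize a {label!r} pair consistent with the profile"
            )
        seen_keys.add((pair.mate1_seq, pair.mate2_seq))
        reads.append(pair)
        truth.append(str(label))

    n_dup = int(rng.binomial(n_pairs, dup_frac)) if dup_frac > 0 else 0
    if n_dup:
        clean_idx = [i for i, t in enumerate(truth) if t == "clean"]
        if not clean_idx:
            raise ValueError("dup_frac > 0 requires at least one clean pair to copy")
        originals = rng.choice(clean_idx, size=n_dup, replace=True)
        for j, oi in enumerate(originals):
            src = reads[int(oi)]
            reads.append(ReadPair(f"dup{j}", src.mate1_seq, src.mate1_qual,
                                  src.mate2_seq, src.mate2_qual, library_class))
            truth.append("duplicate")
    return SimulatedLibrary(genome=genome, reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# Two-species orthology / synteny scenarios
# ---------------------------------------------------------------------------

@dataclass
class OrthoScenario:
    """Two species' gene orders with planted orthology and synteny truth."""

    lociA: list[GeneLocus]
    lociB: list[GeneLocus]
    true_orthologs: list[tuple[str, str]]
    true_blocks: list[SyntenyBlock]
    hitsAB: list[HitRecord]
    hitsBA: list[HitRecord]
    unalignable: list[str] = field(default_factory=list)
    shuffled: list[str] = field(default_factory=list)


def _loci_from_order(order: dict[str, list[str]], species: str) -> list[GeneLocus]:
    loci = []
    for scaffold in sorted(order):
        for rank, gene in enumerate(order[scaffold]):
            start = 1 + rank * 1000
            loci.append(GeneLocus(gene, species, scaffold, start, start + 500, "+", rank))
    return loci


def simulate_ortho_scenario(
    n_genes: int = 100,
    n_scaffolds: int = 2,
    n_blocks: int = 4,
    inversion_frac: float = 0.0,
    shuffle_frac: float = 0.0,
    dup_frac: float = 0.0,
    unalignable_frac: float = 0.0,
    seed: int = 0,
    min_anchors: int = 3,
    max_gap: int = 5,
) -> OrthoScenario:
    """Plant a two-species orthology and microsynteny scenario.

    Species A carries ``n_genes`` genes split into ``n_blocks`` contiguous
    segments distributed over ``n_scaffolds`` scaffolds; species B places
    each segment on its own scaffold, reversed with probability
    ``inversion_frac``. A fraction of genes is then made unalignable
    (absent from both hit tables), relocated in B ("shuffled", breaking
    them out of their block) or duplicated in B (an extra paralogue with
    an e-value at least 10x worse than the orthologue's). True blocks are
    re-derived from the construction with the block definition, so they
    reflect gaps opened by unalignable or relocated genes.
    """
    if n_blocks * min_anchors > n_genes:
        raise ValueError("n_blocks * min_anchors exceeds n_genes: infeasible")
    if not 1 <= n_scaffolds <= n_blocks:
        raise ValueError("need 1 <= n_scaffolds <= n_blocks")
    for name, frac in [("inversion_frac", inversion_frac), ("shuffle_frac", shuffle_frac),
                       ("dup_frac", dup_frac), ("unalignable_frac", unalignable_frac)]:
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    genesA = [f"a{i:04d}" for i in range(n_genes)]
    partner = {a: f"b{i:04d}" for i, a in enumerate(genesA)}

    # contiguous segments of near-equal size; one segment per block
    bounds = np.linspace(0, n_genes, n_blocks + 1).astype(int)
    segments = [genesA[bounds[i]:bounds[i + 1]] for i in range(n_blocks)]

    orderA: dict[str, list[str]] = {f"A_s{j}": [] for j in range(n_scaffolds)}
    for i, seg in enumerate(segments):
        orderA[f"A_s{i % n_scaffolds}"].extend(seg)
    orderB: dict[str, list[str]] = {}
    inverted: list[bool] = []
    for i, seg in enumerate(segments):
        inv = bool(rng.random() < inversion_frac)
        inverted.append(inv)
        bs = [partner[a] for a in seg]
        orderB[f"B_s{i}"] = bs[::-1] if inv else bs

    n_unalign = round(unalignable_frac * n_genes)
    n_shuffle = round(shuffle_frac * n_genes)
    special = rng.choice(n_genes, size=min(n_genes, n_unalign + n_shuffle), replace=False)
    unalignable = {genesA[i] for i in special[:n_unalign]}
    shuffled = {genesA[i] for i in special[n_unalign:n_unalign + n_shuffle]}

    # relocate shuffled genes' B copies to random positions
    scaffoldsB = sorted(orderB)
    for a in sorted(shuffled):
        b = partner[a]
        for sc in scaffoldsB:
            if b in orderB[sc]:
                orderB[sc].remove(b)
                break
        target = scaffoldsB[int(rng.integers(0, len(scaffoldsB)))]
        pos = int(rng.integers(0, len(orderB[target]) + 1))
        orderB[target].insert(pos, b)

    # lineage-specific duplications in B
    n_dup = round(dup_frac * n_genes)
    dup_parents = [genesA[i] for i in rng.choice(n_genes, size=n_dup, replace=False)] if n_dup else []
    dup_of: dict[str, str] = {}
    for a in dup_parents:
        bdup = partner[a] + "_dup"
        dup_of[a] = bdup
        target = scaffoldsB[int(rng.integers(0, len(scaffoldsB)))]
        pos = int(rng.integers(0, len(orderB[target]) + 1))
        orderB[target].insert(pos, bdup)

    lociA = _loci_from_order(orderA, "A")
    lociB = _loci_from_order(orderB, "B")

    # hit tables: orthologues beat any paralogue by >= 10x in e-value
    hitsAB: list[HitRecord] = []
    hitsBA: list[HitRecord] = []
    true_orthologs: list[tuple[str, str]] = []
    pair_meta: dict[str, tuple[float, float]] = {}
    for a in genesA:
        if a in unalignable:
            continue
        b = partner[a]
        ev = 10.0 ** -float(rng.uniform(20, 60))
        ident = float(np.clip(rng.normal(60, 8), 0, 100))
        bits = round(-10 * math.log10(ev), 1)
        hitsAB.append(HitRecord(a, b, ident, 200, ev, bits))
        hitsBA.append(HitRecord(b, a, ident, 200, ev, bits))
        true_orthologs.append((a, b))
        pair_meta[a] = (ev, ident)
        if a in dup_of:
            ev_dup = min(ev * 1e3, 5e-3)
            ident_dup = max(0.0, ident - 10)
            bits_dup = round(-10 * math.log10(ev_dup), 1)
            hitsAB.append(HitRecord(a, dup_of[a], ident_dup, 200, ev_dup, bits_dup))
            hitsBA.append(HitRecord(dup_of[a], a, ident_dup, 200, ev_dup, bits_dup))

    # ground-truth blocks: chain each segment's surviving anchors with the
    # block definition over the FINAL ranks (gaps opened by unalignable,
    # shuffled or duplicated genes are respected)
    rankA = {l.gene: (l.scaffold, l.rank) for l in lociA}
    rankB = {l.gene: (l.scaffold, l.rank) for l in lociB}
    true_blocks: list[SyntenyBlock] = []
    for i, seg in enumerate(segments):
        anchors: list[Anchor] = []
        for a in seg:
            if a in unalignable or a in shuffled:
                continue
            b = partner[a]
            sa, ra = rankA[a]
            sb, rb = rankB[b]
            ev, ident = pair_meta[a]
            anchors.append(Anchor(OrthologPair(a, b, ev, ev, ident), sa, sb, ra, rb))
        anchors.sort(key=lambda x: x.rankA)
        chain: list[Anchor] = []
        for anc in anchors:
            if chain:
                gap_a = anc.rankA - chain[-1].rankA - 1
                gap_b = abs(anc.rankB - chain[-1].rankB) - 1
                if gap_a > max_gap or gap_b > max_gap:
                    if len(chain) >= min_anchors:
                        true_blocks.append(_truth_block(chain))
                    chain = []
            chain.append(anc)
        if len(chain) >= min_anchors:
            true_blocks.append(_truth_block(chain))

    return OrthoScenario(
        lociA=lociA, lociB=lociB, true_orthologs=true_orthologs,
        true_blocks=true_blocks, hitsAB=hitsAB, hitsBA=hitsBA,
        unalignable=sorted(unalignable), shuffled=sorted(shuffled),
    )


def _truth_block(chain: list[Anchor]) -> SyntenyBlock:
    return SyntenyBlock(
        scaffoldA=chain[0].scaffoldA, scaffoldB=chain[0].scaffoldB,
        anchors=tuple(chain), orientation=_orientation([a.rankB for a in chain]),
    )


# ---------------------------------------------------------------------------
# Contaminated assemblies
# ---------------------------------------------------------------------------

def inject_contaminant(
    assembly: Sequence[SequenceRecord],
    n_scaffolds: int,
    gc_shift: float,
    depth_shift: float,
    seed: int,
    host_depth: float = 100.0,
    contaminant_length: Optional[int] = None,
    segment: int = 1000,
):
    """Append contaminant scaffolds of shifted GC and depth to an assembly.

    Returns (assembly incl. contaminants, depth-track DataFrame with
    columns scaffold/start/end/depth, {scaffold: "host"|"contaminant"}).
    Host scaffolds get depth ~ Normal(host_depth, 5% CV) per ``segment``
    bp; contaminants get mean ``depth_shift * host_depth`` and GC equal to
    the host mean GC plus ``gc_shift`` (|gc_shift| must be >= 0.10).
    """
    import pandas as pd

    if n_scaffolds < 0:
        raise ValueError("n_scaffolds must be >= 0")
    if n_scaffolds > 0 and abs(gc_shift) < 0.10:
        raise ValueError("contaminant GC must be shifted by at least 0.10")
    if depth_shift <= 0:
        raise ValueError("depth_shift must be positive")
    rng = np.random.default_rng(seed)
    host_gc = float(np.mean([rec.gc_fraction() for rec in assembly])) if assembly else 0.5
    out = list(assembly)
    labels = {rec.id: "host" for rec in assembly}

    if n_scaffolds > 0:
        target_gc = host_gc + gc_shift
        if not 0 < target_gc < 1:
            raise ValueError(f"shifted contaminant GC {target_gc:.2f} outside (0, 1)")
        length = contaminant_length or int(np.median([len(r.seq) for r in assembly]))
        for i in range(n_scaffolds):
            rec = simulate_genome(length, target_gc, int(rng.integers(0, 2**31)),
                                  id=f"contam_{i}")
            out.append(rec)
            labels[rec.id] = "contaminant"

    rows = []
    for rec in out:
        mean = host_depth if labels[rec.id] == "host" else depth_shift * host_depth
        for start in range(0, len(rec.seq), segment):
            end = min(start + segment, len(rec.seq))
            depth = max(0.0, float(rng.normal(mean, 0.05 * mean)))
            rows.append((rec.id, start, end, round(depth, 2)))
    track = pd.DataFrame(rows, columns=["scaffold", "start", "end", "depth"])
    return out, track, labels


# ---------------------------------------------------------------------------
# Writers (used by the `ichneukit simulate` subcommand)
# ---------------------------------------------------------------------------

def write_library(lib: SimulatedLibrary, prefix: str) -> None:
    write_fasta([lib.genome], f"{prefix}.genome.fa")
    write_fastq_pairs(lib.reads, f"{prefix}.R1.fq", f"{prefix}.R2.fq")
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump({p.pair_id: t for p, t in zip(lib.reads, lib.truth)}, fh, indent=0)


def write_scenario(sc: OrthoScenario, prefix: str) -> None:
    write_gene_table(sc.lociA, f"{prefix}.A.genes.tsv")
    write_gene_table(sc.lociB, f"{prefix}.B.genes.tsv")
    write_hit_table(sc.hitsAB, f"{prefix}.AB.hits.tsv")
    write_hit_table(sc.hitsBA, f"{prefix}.BA.hits.tsv")
    truth = {
        "true_orthologs": sc.true_orthologs,
        "true_blocks": [list(b.gene_pairs) for b in sc.true_blocks],
        "unalignable": sc.unalignable,
        "shuffled": sc.shuffled,
    }
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
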