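"""Microsynteny block detection from orthologue anchors and gene order.

A microsynteny block is a run of at least 3 orthologous counterparts that
are clustered — not interrupted by more than 5 genes between consecutive
anchors — and located on a single scaffold per species. The gap constraint
is applied symmetrically in both genomes (the stricter reading), counting
intervening gene ranks; collinearity is NOT required, so blocks may be
forward, reverse (inverted) or mixed in orientation, and the orientation
is reported so a collinear-only analysis is a filter away.

Chaining is greedy along species-A gene order: within each scaffold pair,
anchors sorted by rank in A are split wherever the gap constraint fails
between consecutive anchors. Each anchor therefore belongs to at most one
block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneLocus
from .orthology import OrthologPair

MIN_ANCHORS = 3
MAX_GAP = 5


@dataclass(frozen=True)
class Anchor:
    """One orthologue pair placed on both gene orders."""

    pair: OrthologPair
    scaffoldA: str
    scaffoldB: str
    rankA: int
    rankB: int


@dataclass(frozen=True)
class SyntenyBlock:
    scaffoldA: str
    scaffoldB: str
    anchors: tuple[Anchor, ...]
    orientation: str  # collinear_forward | collinear_reverse | mixed

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def gene_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((a.pair.geneA, a.pair.geneB) for a in self.anchors)


def _orientation(ranksB: Sequence[int]) -> str:
    inc = all(b > a for a, b in zip(ranksB, ranksB[1:]))
    dec = all(b < a for a, b in zip(ranksB, ranksB[1:]))
    if inc:
        return "collinear_forward"
    if dec:
        return "collinear_reverse"
    return "mixed"


def build_anchors(
    pairs: Sequence[OrthologPair],
    lociA: Mapping[str, GeneLocus] | Sequence[GeneLocus],
    lociB: Mapping[str, GeneLocus] | Sequence[GeneLocus],
) -> list[Anchor]:
    """Place orthologue pairs on both gene orders.

    Raises ValueError when a pair references a gene missing from the loci.
    """
    if not isinstance(lociA, Mapping):
        lociA = {l.gene: l for l in lociA}
    if not isinstance(lociB, Mapping):
        lociB = {l.gene: l for l in lociB}
    anchors = []
    for p in pairs:
        la = lociA.get(p.geneA)
        lb = lociB.get(p.geneB)
        if la is None:
            raise ValueError(f"gene {p.geneA!r} in a pair but absent from species-A loci")
        if lb is None:
            raise ValueError(f"gene {p.geneB!r} in a pair but absent from species-B loci")
        anchors.append(Anchor(p, la.scaffold, lb.scaffold, la.rank, lb.rank))
    return anchors


def gap_ok(prev: Anchor, cur: Anchor, max_gap: int = MAX_GAP) -> bool:
    """True when <= max_gap genes intervene between two anchors in BOTH species."""
    gap_a = cur.rankA - prev.rankA - 1
    gap_b = abs(cur.rankB - prev.rankB) - 1
    return gap_a <= max_gap and gap_b <= max_gap


def find_synteny_blocks(
    pairs: Sequence[OrthologPair],
    lociA,
    lociB,
    min_anchors: int = MIN_ANCHORS,
    max_gap: int = MAX_GAP,
) -> list[SyntenyBlock]:
    """Chain orthologue anchors into microsynteny blocks.

    Anchors are grouped by (scaffoldA, scaffoldB), sorted by rank in A,
    and split wherever consecutive anchors are separated by more than
    max_gap intervening gene ranks in either species; chains with at
    least min_anchors anchors are emitted.
    """
    if min_anchors < 1:
        raise ValueError("min_anchors must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    anchors = build_anchors(pairs, lociA, lociB)
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.scaffoldA, a.scaffoldB), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (sa, sb) in sorted(groups):
        chain: list[Anchor] = []
        for anchor in sorted(groups[(sa, sb)], key=lambda x: (x.rankA, x.rankB)):
            if chain and not gap_ok(chain[-1], anchor, max_gap):
                if len(chain) >= min_anchors:
                    blocks.append(_make_block(sa, sb, chain))
                chain = []
            chain.append(anchor)
        if len(chain) >= min_anchors:
            blocks.append(_make_block(sa, sb, chain))
    return blocks


def _make_block(sa: str, sb: str, chain: list[Anchor]) -> SyntenyBlock:
    return SyntenyBlock(
        scaffoldA=sa, scaffoldB=sb, anchors=tuple(chain),
        orientation=_orientation([a.rankB for a in chain]),
    )


def validate_block(
    block: SyntenyBlock, min_anchors: int = MIN_ANCHORS, max_gap: int = MAX_GAP
) -> bool:
    """Independent check of the three defining block constraints.

    (1) at least min_anchors anchors; (2) a single scaffold per species;
    (3) consecutive anchors separated by <= max_gap intervening gene ranks
    in each species. Kept free of the chaining code on purpose.
    """
    if block.n_anchors < min_anchors:
        return False
    for a in block.anchors:
        if a.scaffoldA != block.scaffoldA or a.scaffoldB != block.scaffoldB:
            return False
    for prev, cur in zip(block.anchors, block.anchors[1:]):
        if cur.rankA <= prev.rankA:
            return False
        if cur.rankA - prev.rankA - 1 > max_gap:
            return False
        if abs(cur.rankB - prev.rankB) - 1 > max_gap:
            return False
    return True


def syntenic_ratio(
    blocks: Sequence[SyntenyBlock],
    lociA: Sequence[GeneLocus],
    lociB: Sequence[GeneLocus],
    n_pairs: int | None = None,
) -> dict:
    """Fraction of genes anchored in at least one block, per species.

    Also reports the anchored-orthologue fraction (anchors in blocks over
    total RBH pairs) when ``n_pairs`` is given.
    """
    anchoredA = {a.pair.geneA for b in blocks for a in b.anchors}
    anchoredB = {a.pair.geneB for b in blocks for a in b.anchors}
    out = {
        "ratio_A": len(anchoredA) / len(lociA) if lociA else 0.0,
        "ratio_B": len(anchoredB) / len(lociB) if lociB else 0.0,
        "n_blocks": len(blocks),
        "n_anchored_pairs": sum(b.n_anchors for b in blocks),
    }
    if n_pairs is not None:
        out["anchored_pair_fraction"] = (
            out["n_anchored_pairs"] / n_pairs if n_pairs else 0.0
        )
    return out
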