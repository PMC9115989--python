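"""SINEUP candidate search.

A canonical SINEUP is a natural antisense lncRNA that overlaps an mRNA
head-to-head (divergent overlap: opposite strands with both transcripts'
5' ends inside the genomic overlap) and carries a SINE fragment in the
part of the lncRNA *outside* the overlap.  This module finds overlapping
coding/noncoding pairs on a genome and classifies them against that
architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from intervaltree import IntervalTree

from .models import GenomePlacement, RepeatFragment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapPair:
    mrna_id: str
    lncrna_id: str
    scaffold: str
    overlap_start: int
    overlap_end: int


@dataclass(frozen=True)
class SineupCandidate:
    mrna_id: str
    lncrna_id: str
    scaffold: str
    overlap_start: int
    overlap_end: int
    orientation: str  # head_to_head | other
    sine_fragments_outside_overlap: int
    canonical: bool


@dataclass
class PairCounts:
    mrna_mrna: int = 0
    lncrna_lncrna: int = 0
    mrna_lncrna: int = 0


def find_overlapping_pairs(placements: Dict[str, GenomePlacement],
                           classes: Dict[str, str]) -> Tuple[List[OverlapPair], PairCounts]:
    """All overlapping transcript pairs per scaffold, by class combination.

    Returns the mRNA/lncRNA pairs (the SINEUP search space) plus counts
    of all three pair types (mRNA/mRNA, lncRNA/lncRNA, mRNA/lncRNA).
    """
    trees: Dict[str, IntervalTree] = {}
    for tid, p in placements.items():
        trees.setdefault(p.scaffold, IntervalTree()).addi(p.start, p.end, tid)
    counts = PairCounts()
    pairs = []
    seen = set()
    for scaffold, tree in trees.items():
        for iv in tree:
            for other in tree.overlap(iv.begin, iv.end):
                if other.data == iv.data:
                    continue
                key = tuple(sorted((iv.data, other.data)))
                if key in seen:
                    continue
                seen.add(key)
                ka = classes.get(iv.data, "other")
                kb = classes.get(other.data, "other")
                combo = tuple(sorted((ka, kb)))
                if combo == ("coding", "coding"):
                    counts.mrna_mrna += 1
                elif combo == ("lncRNA", "lncRNA"):
                    counts.lncrna_lncrna += 1
                elif combo == ("coding", "lncRNA"):
                    counts.mrna_lncrna += 1
                    mrna, lnc = (iv.data, other.data) if ka == "coding" else (other.data, iv.data)
                    ov_start = max(placements[mrna].start, placements[lnc].start)
                    ov_end = min(placements[mrna].end, placements[lnc].end)
                    pairs.append(OverlapPair(
                        mrna_id=mrna, lncrna_id=lnc, scaffold=scaffold,
                        overlap_start=ov_start, overlap_end=ov_end))
    pairs.sort(key=lambda p: (p.scaffold, p.overlap_start, p.mrna_id))
    return pairs, counts


def transcript_to_genome(placement: GenomePlacement, t_start: int, t_end: int) -> Tuple[int, int]:
    """Map a transcript-coordinate interval onto the genome through the
    placement's exon blocks (strand-aware); returns the genomic span
    between the two mapped end points."""
    blocks = placement.blocks or ((placement.start, placement.end),)
    if placement.strand == "-":
        # transcript coordinates run along the minus strand
        total = sum(b1 - b0 for b0, b1 in blocks)
        t_start, t_end = total - t_end, total - t_start

    def map_pos(pos):
        off = 0
        for b0, b1 in blocks:
            if pos < off + (b1 - b0):
                return b0 + (pos - off)
            off += b1 - b0
        return blocks[-1][1]

    g0 = map_pos(t_start)
    g1 = map_pos(max(t_start, t_end - 1)) + 1
    return (g0, max(g1, g0 + 1))


def classify_sineup(pair: OverlapPair,
                    placements: Dict[str, GenomePlacement],
                    lnc_fragments: Iterable[RepeatFragment],
                    five_prime_slack: int = 0) -> SineupCandidate:
    """Classify one mRNA/lncRNA overlapping pair against the canonical
    SINEUP architecture.

    Head-to-head requires opposite strands with both 5' ends inside the
    overlap (optionally padded by ``five_prime_slack`` nt).  SINE
    fragments of the lncRNA are lifted to genome coordinates; only those
    entirely outside the overlap interval count toward canonicity.
    """
    pm = placements[pair.mrna_id]
    pl = placements[pair.lncrna_id]
    ov0, ov1 = pair.overlap_start - five_prime_slack, pair.overlap_end + five_prime_slack

    def in_overlap(pos):
        return ov0 <= pos <= ov1

    if pm.strand == pl.strand:
        orientation = "other"
    elif in_overlap(pm.five_prime) and in_overlap(pl.five_prime):
        orientation = "head_to_head"
    else:
        orientation = "other"

    n_outside = 0
    for f in lnc_fragments:
        if f.transcript_id != pair.lncrna_id or f.major_class != "SINE":
            continue
        g0, g1 = transcript_to_genome(pl, *f.q_interval)
        if g1 <= pair.overlap_start or g0 >= pair.overlap_end:
            n_outside += 1
    canonical = orientation == "head_to_head" and n_outside >= 1
    return SineupCandidate(
        mrna_id=pair.mrna_id, lncrna_id=pair.lncrna_id, scaffold=pair.scaffold,
        overlap_start=pair.overlap_start, overlap_end=pair.overlap_end,
        orientation=orientation, sine_fragments_outside_overlap=n_outside,
        canonical=canonical)


def find_sineup_candidates(placements: Dict[str, GenomePlacement],
                           classes: Dict[str, str],
                           fragments: Iterable[RepeatFragment],
                           five_prime_slack: int = 0) -> Tuple[List[SineupCandidate], PairCounts]:
    """End-to-end search: overlapping mRNA/lncRNA pairs classified
    against the canonical architecture."""
    pairs, counts = find_overlapping_pairs(placements, classes)
    fragments = list(fragments)
    return [classify_sineup(p, placements, fragments, five_prime_slack) for p in pairs], counts
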