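"""Cross-species conservation: reciprocal best hits, promoter
conservation with a randomization null, and positional conservation.

Promoters are the 1000 nt upstream of the annotated transcription start
site, extracted strand-aware; ortholog promoter pairs are globally
aligned (Needleman-Wunsch) and called conserved at >= 50% identity.
Because the identity verdict depends on the scoring scheme and the
identity denominator — neither of which is dictated by the method itself
— both are explicit, configurable parameters here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from Bio import Align
from scipy import stats

from .models import GenomePlacement, HitRecord
from .orf import reverse_complement


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring for promoter comparisons.

    ``identity_denominator`` is 'columns' (all alignment columns,
    gap columns included — the strict convention, default) or 'aligned'
    (aligned columns only).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    identity_denominator: str = "columns"

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    bitscore_ab: float
    bitscore_ba: float
    identity_pct: float


@dataclass(frozen=True)
class PromoterPair:
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str
    identity_pct: float
    conserved: bool


def _best_hits(hits: Iterable[HitRecord]) -> Dict[str, HitRecord]:
    """Best hit per query: highest bitscore, ties by lowest e-value then
    lexicographic subject id."""
    best: Dict[str, HitRecord] = {}
    for h in hits:
        b = best.get(h.query_id)
        if b is None or (-h.bitscore, h.evalue, h.subject_id) < (-b.bitscore, b.evalue, b.subject_id):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(hits_ab: Iterable[HitRecord],
                         hits_ba: Iterable[HitRecord]) -> List[OrthologPair]:
    """Ortholog pairs (a, b) where a's best hit is b and b's best hit is a."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for qa, ha in sorted(best_ab.items()):
        hb = best_ba.get(ha.subject_id)
        if hb is not None and hb.subject_id == qa:
            pairs.append(OrthologPair(
                id_a=qa, id_b=ha.subject_id,
                bitscore_ab=ha.bitscore, bitscore_ba=hb.bitscore,
                identity_pct=(ha.percent_identity + hb.percent_identity) / 2.0))
    return pairs


def mapping_filter(placements: Dict[str, GenomePlacement],
                   min_cov: float = 0.9, min_ident: float = 0.9) -> Dict[str, GenomePlacement]:
    """Keep placements aligning >= 90% of the transcript at >= 90% identity (inclusive)."""
    return {tid: p for tid, p in placements.items()
            if p.coverage_fraction >= min_cov and p.identity_fraction >= min_ident}


def extract_promoter(placement: Optional[GenomePlacement], genome: Dict[str, str],
                     length: int = 1000) -> Optional[str]:
    """The ``length`` nt upstream of the TSS, strand-aware; None when the
    transcript is unplaced or lacks enough upstream sequence (such
    transcripts are skipped, never truncated)."""
    if placement is None:
        return None
    scaffold = genome.get(placement.scaffold)
    if scaffold is None:
        return None
    if placement.strand == "+":
        if placement.start < length:
            return None
        return scaffold[placement.start - length:placement.start]
    if placement.end + length > len(scaffold):
        return None
    return reverse_complement(scaffold[placement.end:placement.end + length])


def global_identity(seq_a: str, seq_b: str,
                    scoring: AlignmentScoring = AlignmentScoring()) -> float:
    """Percent identity of the optimal global alignment of two sequences."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = scoring.make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    if scoring.identity_denominator == "columns":
        denom = aln.length
    elif scoring.identity_denominator == "aligned":
        denom = counts.identities + counts.mismatches
    else:
        raise ValueError(f"unknown identity_denominator {scoring.identity_denominator!r}")
    return 100.0 * counts.identities / denom


@dataclass
class PromoterConservationResult:
    pairs: List[PromoterPair]
    conserved_fraction: float
    random_conserved_fraction: float
    n_random: int


def promoter_conservation(promoter_seqs: List[Tuple[str, str, str, str]],
                          n_random: Optional[int] = None,
                          seed: int = 0,
                          identity_threshold: float = 50.0,
                          scoring: AlignmentScoring = AlignmentScoring()) -> PromoterConservationResult:
    """Align real ortholog promoter pairs and a randomized null.

    ``promoter_seqs`` is a list of (id_a, id_b, seq_a, seq_b).  The null
    re-pairs species-A promoters with species-B promoters of *other*
    pairs (a seeded derangement), so no true pair appears in it;
    ``n_random`` defaults to the number of real pairs.
    """
    if len(promoter_seqs) < 2:
        raise ValueError("need >= 2 promoter pairs")
    real = []
    for id_a, id_b, sa, sb in promoter_seqs:
        ident = global_identity(sa, sb, scoring)
        real.append(PromoterPair(id_a=id_a, id_b=id_b, seq_a=sa, seq_b=sb,
                                 identity_pct=ident, conserved=ident >= identity_threshold))
    n_pairs = len(real)
    if n_random is None:
        n_random = n_pairs
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    drawn = 0
    while drawn < n_random:
        # each derangement yields n non-matching cross-species pairs
        perm = _derangement(n_pairs, rng)
        for i in range(n_pairs):
            if drawn >= n_random:
                break
            ident = global_identity(promoter_seqs[i][2], promoter_seqs[perm[i]][3], scoring)
            if ident >= identity_threshold:
                hits += 1
            drawn += 1
    conserved = sum(p.conserved for p in real)
    return PromoterConservationResult(
        pairs=real,
        conserved_fraction=conserved / n_pairs,
        random_conserved_fraction=hits / n_random,
        n_random=n_random)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A permutation of range(n) with no fixed point (rejection sampling)."""
    if n < 2:
        raise ValueError("derangement requires n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def promoter_enrichment_test(k_nc: int, n_nc: int, k_cod: int, n_cod: int) -> float:
    """One-sided exact binomial test: is the noncoding conserved-promoter
    proportion greater than the coding proportion (used as the null p0)?"""
    if n_cod <= 0:
        raise ValueError("coding denominator must be > 0")
    if not (0 <= k_nc <= n_nc and 0 <= k_cod <= n_cod):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p0 = k_cod / n_cod
    return float(stats.binomtest(k_nc, n_nc, p0, alternative="greater").pvalue)


def identity_comparison(identities_coding, identities_noncoding) -> tuple:
    """Welch two-sample t-test of per-pair identities; returns
    (mean_coding, mean_noncoding, t_statistic, p_value)."""
    a = np.asarray(identities_coding, dtype=float)
    b = np.asarray(identities_noncoding, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), float(b.mean()), float(t), float(p)


@dataclass
class PositionalConservationResult:
    per_scaffold_mean: float
    pooled_fraction: float
    n_scaffolds: int
    n_pairs: int


def positional_conservation(placements_a: Dict[str, GenomePlacement],
                            placements_b: Dict[str, GenomePlacement],
                            pairs: Iterable[OrthologPair],
                            min_transcripts: int = 10) -> PositionalConservationResult:
    """Shared-scaffold fraction of ortholog pairs.

    Species-A scaffolds carrying at least ``min_transcripts`` mapped
    transcripts are considered; for each, the fraction of its ortholog
    pairs whose species-B partners co-locate on a single (the modal) B
    scaffold is computed.  Reported both as the mean of per-scaffold
    fractions and as the pooled fraction over all pairs considered.
    """
    by_scaffold: Dict[str, list] = {}
    for tid, p in placements_a.items():
        by_scaffold.setdefault(p.scaffold, []).append(tid)
    eligible = {s for s, tids in by_scaffold.items() if len(tids) >= min_transcripts}
    if not eligible:
        raise ValueError(f"no scaffold carries >= {min_transcripts} mapped transcripts")
    partner_b = {p.id_a: p.id_b for p in pairs}
    fractions = []
    colocated_total = 0
    pairs_total = 0
    for scaffold in sorted(eligible):
        b_scaffolds = []
        for tid in by_scaffold[scaffold]:
            b_id = partner_b.get(tid)
            if b_id is None or b_id not in placements_b:
                continue
            b_scaffolds.append(placements_b[b_id].scaffold)
        if not b_scaffolds:
            continue
        modal = max(set(b_scaffolds), key=b_scaffolds.count)
        colocated = b_scaffolds.count(modal)
        fractions.append(colocated / len(b_scaffolds))
        colocated_total += colocated
        pairs_total += len(b_scaffolds)
    if not fractions:
        raise ValueError("no ortholog pairs on qualifying scaffolds")
    return PositionalConservationResult(
        per_scaffold_mean=float(np.mean(fractions)),
        pooled_fraction=colocated_total / pairs_total,
        n_scaffolds=len(fractions),
        n_pairs=pairs_total)
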