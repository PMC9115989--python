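"""Stringent five-criterion lncRNA classification.

A transcript is called a putative lncRNA only when *all* of the
following hold: length >= 200 nt; no similarity hit (at the search
e-value cutoff) against proteins, domain profiles, rRNA, or other small
ncRNAs; longest permissive-mode ORF < 100 amino acids; and a non-coding
potential score >= 0.95.  Transcripts with a protein hit are labeled
coding; everything else is 'other'.

The non-coding potential is an injectable per-transcript score in
[0, 1].  ``baseline_ncpotential`` provides a transparent, deterministic
ORF-density baseline for self-contained runs; scores from any external
coding-potential classifier can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

from .models import HitRecord, Transcript
from .orf import OrfCall


@dataclass(frozen=True)
class LncrnaCriteria:
    min_length: int = 200           # inclusive
    hit_evalue_max: float = 1e-5    # inclusive
    max_orf_aa: int = 100           # exclusive
    min_ncpotential: float = 0.95   # inclusive

    def __post_init__(self):
        if min(self.min_length, self.hit_evalue_max, self.max_orf_aa, self.min_ncpotential) <= 0:
            raise ValueError("all criteria must be positive")
        if not 0 <= self.min_ncpotential <= 1:
            raise ValueError("min_ncpotential must be in [0,1]")


@dataclass(frozen=True)
class HitFlags:
    has_protein_hit: bool = False
    has_domain_hit: bool = False
    has_rrna_hit: bool = False
    has_ncrna_hit: bool = False

    @property
    def any(self) -> bool:
        return self.has_protein_hit or self.has_domain_hit or self.has_rrna_hit or self.has_ncrna_hit


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    length: int
    flags: HitFlags
    longest_orf_aa: int
    ncpotential: float
    klass: str  # coding | lncRNA | other


_TAG_TO_FLAG = {"protein": "has_protein_hit", "domain": "has_domain_hit",
                "rrna": "has_rrna_hit", "ncrna": "has_ncrna_hit"}


def summarize_hits(hits: Iterable[HitRecord],
                   criteria: LncrnaCriteria = LncrnaCriteria()) -> Dict[str, HitFlags]:
    """Per-transcript flags: one per database class, true when any hit
    at e-value <= the search cutoff exists in that class."""
    acc: Dict[str, dict] = {}
    for h in hits:
        if h.evalue > criteria.hit_evalue_max:
            continue
        acc.setdefault(h.query_id, {v: False for v in _TAG_TO_FLAG.values()})
        acc[h.query_id][_TAG_TO_FLAG[h.database_tag]] = True
    return {tid: HitFlags(**flags) for tid, flags in acc.items()}


def baseline_ncpotential(transcript: Transcript, orf_call: OrfCall) -> float:
    """Deterministic ORF-density stand-in score: 1 - min(1, ORF nt / length).

    A transcript whose permissive ORF spans it entirely scores 0; one
    with no ORF scores 1.  This is a coarse baseline, not a trained
    coding-potential model; supply external scores for real analyses.
    """
    if transcript.length == 0:
        raise ValueError("zero-length transcript")
    return 1.0 - min(1.0, 3.0 * orf_call.aa_length / transcript.length)


def classify(transcripts: Iterable[Transcript],
             flags: Dict[str, HitFlags],
             orf_calls: Dict[str, OrfCall],
             ncpotential_scores: Dict[str, float],
             criteria: LncrnaCriteria = LncrnaCriteria()) -> List[TranscriptAnnotation]:
    """Apply the stringent conjunction rule to every transcript."""
    transcripts = list(transcripts)
    missing_orf = [t.id for t in transcripts if t.id not in orf_calls]
    missing_score = [t.id for t in transcripts if t.id not in ncpotential_scores]
    if missing_orf or missing_score:
        raise ValueError(
            f"missing ORF calls for {missing_orf[:5]} and scores for {missing_score[:5]} "
            f"({len(missing_orf)} / {len(missing_score)} transcripts total)")
    out = []
    for t in transcripts:
        f = flags.get(t.id, HitFlags())
        aa = orf_calls[t.id].aa_length
        score = ncpotential_scores[t.id]
        if (t.length >= criteria.min_length and not f.any
                and aa < criteria.max_orf_aa and score >= criteria.min_ncpotential):
            klass = "lncRNA"
        elif f.has_protein_hit:
            klass = "coding"
        else:
            klass = "other"
        out.append(TranscriptAnnotation(
            transcript_id=t.id, length=t.length, flags=f,
            longest_orf_aa=aa, ncpotential=score, klass=klass))
    return out


def class_counts(annotations: Iterable[TranscriptAnnotation]) -> dict:
    """Totals and lncRNA fraction, the headline proportions of a run."""
    annotations = list(annotations)
    counts = {"total": len(annotations), "coding": 0, "lncRNA": 0, "other": 0}
    for a in annotations:
        counts[a.klass] += 1
    counts["lncrna_fraction"] = counts["lncRNA"] / counts["total"] if annotations else 0.0
    return counts
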