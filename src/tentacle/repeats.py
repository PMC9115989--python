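"""Repeat-content summarization and full-length LINE detection.

A transcript is a *full-length* autonomous LINE candidate when its
annotated fragments cover at least 80% of the repeat-library consensus
(interval union on consensus coordinates), it carries a complete
strict-mode ORF (ATG start, canonical stop), and the translated ORF
shows both an endonuclease (EN) and a reverse-transcriptase (RT) domain.
A zinc finger (ZF) is recorded but never required — it is relatively
rare in the RTE clade these elements belong to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd

from .models import ConsensusModel, HitRecord, RepeatFragment, Transcript
from .models import INTERSPERSED_CLASSES, REPEAT_SUMMARY_CLASSES
from .orf import OrfCall, longest_orf

#: Case-insensitive keywords mapping domain-hit subject names to the
#: three LINE-machinery domain classes.  Editable: pass your own table
#: to ``detect_full_length`` for other nomenclatures.
DOMAIN_KEYWORDS = {
    "EN": ("endonuclease", "exo_endo_phos", "endo", "ape"),
    "RT": ("reverse transcriptase", "rvt", "rt_like", "rt_nlr"),
    "ZF": ("zinc finger", "zf-c2h2", "zf_c2h2", "znf", "c2h2"),
}


@dataclass(frozen=True)
class FullLengthCandidate:
    transcript_id: str
    consensus_name: str
    consensus_coverage: float
    strict_orf: OrfCall
    domains_present: frozenset
    verdict: bool


@dataclass
class RepeatSummary:
    """Per-summary-class repeat content of a transcriptome."""

    transcripts_total: int
    total_nt: int
    per_class: pd.DataFrame  # index=class, columns=[transcripts_with_fragment, fraction_of_transcripts, nucleotides_masked]
    interspersed_nt: int = 0
    interspersed_fraction: float = 0.0
    transcripts_with_interspersed: int = 0


def _merge_intervals(intervals) -> list:
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def _union_length(intervals) -> int:
    return sum(e - s for s, e in _merge_intervals(intervals))


def consensus_coverage(fragments: Iterable[RepeatFragment], model: ConsensusModel) -> float:
    """Fraction of the consensus covered by the union of fragment spans."""
    intervals = []
    for f in fragments:
        if f.consensus_name != model.name:
            raise ValueError(f"fragment references {f.consensus_name!r}, not {model.name!r}")
        if f.c_end > model.length:
            raise ValueError(
                f"fragment consensus span {f.c_begin}-{f.c_end} exceeds consensus length {model.length}")
        intervals.append(f.c_interval)
    if not intervals:
        return 0.0
    return _union_length(intervals) / model.length


def classify_domains(domain_hits: Iterable[HitRecord], transcript_id: str,
                     keywords: dict = DOMAIN_KEYWORDS) -> Set[str]:
    """Map domain-table subject names to {EN, RT, ZF} by keyword."""
    present = set()
    for h in domain_hits:
        if h.query_id != transcript_id:
            continue
        name = h.subject_id.lower().replace("_", " ").replace("-", " ")
        for domain, keys in keywords.items():
            if any(k.replace("_", " ").replace("-", " ") in name for k in keys):
                present.add(domain)
    return present


def detect_full_length(transcripts: Iterable[Transcript],
                       fragments: Iterable[RepeatFragment],
                       models: Iterable[ConsensusModel],
                       domain_hits: Iterable[HitRecord],
                       coverage_min: float = 0.8,
                       keywords: dict = DOMAIN_KEYWORDS) -> List[FullLengthCandidate]:
    """Emit a candidate per transcript x consensus with coverage >= the
    threshold; verdict requires a complete strict ORF plus EN and RT.

    When all of a transcript's fragments for the consensus lie on one
    strand, the strict ORF must lie on that strand; mixed or unknown
    strand tries both orientations.
    """
    transcripts = {t.id: t for t in transcripts}
    models_by_name = {m.name: m for m in models}
    domain_hits = list(domain_hits)
    by_pair: Dict[tuple, list] = {}
    for f in fragments:
        if f.transcript_id in transcripts and f.consensus_name in models_by_name:
            by_pair.setdefault((f.transcript_id, f.consensus_name), []).append(f)

    candidates = []
    for (tid, cname), frags in sorted(by_pair.items()):
        cov = consensus_coverage(frags, models_by_name[cname])
        if cov < coverage_min:
            continue
        t = transcripts[tid]
        strands = {f.strand for f in frags}
        orf = longest_orf(tid, t.sequence, mode="strict", frames="six")
        if len(strands) == 1 and orf.aa_length > 0:
            wanted = "+" if strands == {"+"} else "-"
            if not orf.frame.startswith(wanted):
                orf = OrfCall(transcript_id=tid, frame=orf.frame, nt_start=0, nt_end=0,
                              aa_length=0, peptide="", mode="strict")
        domains = classify_domains(domain_hits, tid, keywords)
        verdict = orf.aa_length > 0 and {"EN", "RT"} <= domains
        candidates.append(FullLengthCandidate(
            transcript_id=tid, consensus_name=cname, consensus_coverage=cov,
            strict_orf=orf, domains_present=frozenset(domains), verdict=verdict))
    return candidates


def mask_fraction(transcripts: Iterable[Transcript],
                  fragments: Iterable[RepeatFragment]) -> RepeatSummary:
    """Per-class masked-nucleotide totals and transcript counts.

    Nucleotide totals use the per-class interval union on each
    transcript, so overlapping fragments of one class are not
    double-counted; interspersed content excludes tandem and
    low-complexity classes.
    """
    transcripts = list(transcripts)
    total_nt = sum(t.length for t in transcripts)
    classes = sorted(set(REPEAT_SUMMARY_CLASSES.values()))
    by_class_tx: Dict[str, dict] = {c: {} for c in classes}
    for f in fragments:
        by_class_tx[f.summary_class].setdefault(f.transcript_id, []).append(f.q_interval)
    rows = []
    n = len(transcripts)
    for c in classes:
        tx = by_class_tx[c]
        masked = sum(_union_length(iv) for iv in tx.values())
        rows.append((c, len(tx), len(tx) / n if n else 0.0, masked))
    per_class = pd.DataFrame(
        rows, columns=["summary_class", "transcripts_with_fragment",
                       "fraction_of_transcripts", "nucleotides_masked"],
    ).set_index("summary_class")

    inter_tx: Dict[str, list] = {}
    for f in fragments:
        if f.summary_class in INTERSPERSED_CLASSES:
            inter_tx.setdefault(f.transcript_id, []).append(f.q_interval)
    inter_nt = sum(_union_length(iv) for iv in inter_tx.values())
    return RepeatSummary(
        transcripts_total=n, total_nt=total_nt, per_class=per_class,
        interspersed_nt=inter_nt,
        interspersed_fraction=inter_nt / total_nt if total_nt else 0.0,
        transcripts_with_interspersed=len(inter_tx),
    )


def repeat_segregation(expressed_sets: Dict[str, set],
                       fragments: Iterable[RepeatFragment],
                       classes: Optional[list] = None) -> pd.DataFrame:
    """Part x repeat-class matrix of expressed-transcript fractions.

    Cell (part, class) is the fraction of the part's expressed
    transcripts containing at least one fragment of that class (a
    transcript with several fragments counts once).  Empty expressed
    sets yield NaN rows rather than silent zeros.
    """
    tx_classes: Dict[str, set] = {}
    for f in fragments:
        tx_classes.setdefault(f.transcript_id, set()).add(f.major_class)
    if classes is None:
        classes = sorted({c for s in tx_classes.values() for c in s})
    rows = {}
    for part, expressed in expressed_sets.items():
        if not expressed:
            rows[part] = {c: float("nan") for c in classes}
            continue
        rows[part] = {
            c: sum(1 for tid in expressed if c in tx_classes.get(tid, ())) / len(expressed)
            for c in classes
        }
    return pd.DataFrame.from_dict(rows, orient="index")[classes]
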