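"""Mobile-element insertion-site filtering, sharing analysis and qPCR
copy-number arithmetic.

Insertion sites (ISs) called against a reference genome are filtered on
call quality (PASS), per-side discordant-pair support (>= 3 on both
breakpoint sides), scaffold length (>= 10 kb) and proximity to an
annotated copy of the element consensus (a 260-bp window around the
breakpoint must be clean, or a call is likely a mismapping artifact).
Filtered sites from a 2-individual x 2-tissue design are then
partitioned by their presence pattern into germline-shared,
individual-specific, single-sample (the putative somatic class) and
inconsistent categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from scipy import stats

from .models import IntegrationSiteRecord, SampleDesign

logger = logging.getLogger(__name__)

CATEGORIES = ("common_all", "individual_specific", "sample_specific", "inconsistent")


@dataclass(frozen=True)
class SharingCall:
    site: IntegrationSiteRecord
    category: str
    individual: Optional[str] = None
    part: Optional[str] = None


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    target_ct: float
    reference_ct: float
    calibrator: bool = False

    def __post_init__(self):
        for v in (self.target_ct, self.reference_ct):
            if not 0 < v < 60:
                raise ValueError(f"Ct value {v} outside the plausible (0, 60) range")


def filter_sites(sites: Iterable[IntegrationSiteRecord],
                 consensus_hits: Iterable[Tuple[str, int, int]],
                 scaffold_lengths: Dict[str, int],
                 min_support: int = 3,
                 exclusion_window: int = 260,
                 min_scaffold_len: int = 10_000) -> List[IntegrationSiteRecord]:
    """Apply the IS quality filters.

    ``consensus_hits`` are genomic intervals (scaffold, start, end;
    0-based half-open) where the element consensus aligns to the
    reference; a site is excluded when any such hit intersects the
    ``exclusion_window``-wide window centered on its breakpoint.
    """
    hits_by_scaffold: Dict[str, list] = {}
    for scf, s, e in consensus_hits:
        hits_by_scaffold.setdefault(scf, []).append((s, e))
    half = exclusion_window / 2.0
    kept = []
    for site in sites:
        if site.scaffold not in scaffold_lengths:
            raise KeyError(f"unknown scaffold {site.scaffold!r} for site at {site.position}")
        if site.filter_status != "PASS":
            continue
        if site.left_support < min_support or site.right_support < min_support:
            continue
        if scaffold_lengths[site.scaffold] < min_scaffold_len:
            continue
        w0, w1 = site.position - half, site.position + half
        if any(s < w1 and e > w0 for s, e in hits_by_scaffold.get(site.scaffold, ())):
            continue
        kept.append(site)
    return kept


def classify_sharing(sites: Iterable[IntegrationSiteRecord],
                     design: SampleDesign) -> List[SharingCall]:
    """Partition filtered sites by 4-sample presence pattern.

    Requires a 2-individual x 2-part design.  Missing genotypes count as
    absent (logged, so the class remains auditable).  Every site maps to
    exactly one of: common_all, individual_specific, sample_specific,
    inconsistent; a site present in no sample should not have survived
    filtering and raises.
    """
    individuals = design.individuals
    if len(individuals) != 2 or len(design.parts) != 2 or len(design.samples) != 4:
        raise ValueError("sharing classification requires a 2-individual x 2-part design")
    calls = []
    for site in sites:
        present = set()
        for s in design.samples:
            state = site.sample_presence.get(s.sample_id)
            if state is None:
                raise ValueError(f"site {site.key} lacks presence for sample {s.sample_id!r}")
            if state == "missing":
                logger.warning("site %s: missing genotype in %s treated as absent",
                               site.key, s.sample_id)
            if state == "present":
                present.add(s.sample_id)
        if not present:
            raise ValueError(f"site {site.key} present in no sample; it should not pass filtering")
        by_ind = {ind: {s.sample_id for s in design.samples if s.individual == ind} & present
                  for ind in individuals}
        full_inds = [ind for ind in individuals if by_ind[ind] ==
                     {s.sample_id for s in design.samples if s.individual == ind}]
        if len(present) == 4:
            calls.append(SharingCall(site=site, category="common_all"))
        elif len(present) == 1:
            sid = next(iter(present))
            info = design.sample(sid)
            calls.append(SharingCall(site=site, category="sample_specific",
                                     individual=info.individual, part=info.part))
        elif len(full_inds) == 1 and all(not by_ind[ind] for ind in individuals if ind != full_inds[0]):
            calls.append(SharingCall(site=site, category="individual_specific",
                                     individual=full_inds[0]))
        else:
            calls.append(SharingCall(site=site, category="inconsistent"))
    return calls


def sharing_counts(calls: Iterable[SharingCall]) -> Dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    counts["total"] = sum(counts[c] for c in CATEGORIES)
    return counts


def compare_individuals(count_a: int, count_b: int,
                        normalizer_a: float, normalizer_b: float) -> Tuple[float, float, float]:
    """Compare raw non-reference IS counts between two individuals.

    Returns (normalized_a, normalized_b, p) where normalized counts are
    per million units of the normalizer (for example mapped read pairs)
    and p is a two-sided exact binomial test of the raw count split
    against the split expected from the normalizers alone.
    """
    if normalizer_a <= 0 or normalizer_b <= 0:
        raise ValueError("normalizers must be > 0")
    n = count_a + count_b
    if n == 0:
        raise ValueError("no integration sites to compare")
    p_expected = normalizer_a / (normalizer_a + normalizer_b)
    p = float(stats.binomtest(count_a, n, p_expected, alternative="two-sided").pvalue)
    return (count_a / normalizer_a * 1e6, count_b / normalizer_b * 1e6, p)


def ddct(measurements: Iterable[QpcrMeasurement]) -> Dict[str, float]:
    """Relative copy number by the 2^-ddCt method.

    dCt = target Ct - reference Ct per sample; ddCt subtracts the
    calibrator sample's dCt; fold change is 2^-ddCt (the calibrator maps
    to 1.0 by construction).  Replicates must be pre-averaged to one
    measurement per sample.
    """
    measurements = list(measurements)
    seen = set()
    for m in measurements:
        if m.sample_id in seen:
            raise ValueError(f"duplicate measurement for sample {m.sample_id!r}; pre-average replicates")
        seen.add(m.sample_id)
    calibrators = [m for m in measurements if m.calibrator]
    if len(calibrators) != 1:
        raise ValueError(f"exactly one calibrator required, got {len(calibrators)}")
    cal = calibrators[0]
    dct_cal = cal.target_ct - cal.reference_ct
    return {m.sample_id: 2.0 ** (-((m.target_ct - m.reference_ct) - dct_cal))
            for m in measurements}
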