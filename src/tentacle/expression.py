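"""CPM normalization, expressed-set classification and peak detection.

The transcriptome-retention filter keeps transcripts with at least
``cpm_floor`` CPM in at least ``min_samples`` samples (inclusive bounds).
Per-part expression and expression peaks deliberately use *strict*
inequalities (> 0.5 CPM in every replicate of the part, < 0.5 in every
replicate of every other part for a peak): both conventions are part of
the method and the asymmetry is preserved.

Library sizes are the column sums of the raw (pre-filter) count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import SampleDesign


@dataclass(frozen=True)
class ExpressionThresholds:
    cpm_floor: float = 0.5
    min_samples: int = 2
    peak_cpm: float = 0.5

    def __post_init__(self):
        if self.cpm_floor <= 0 or self.min_samples <= 0 or self.peak_cpm <= 0:
            raise ValueError("all expression thresholds must be > 0")


#: The stricter single-sample variant used for the second species'
#: reassembly (at least 1 CPM in at least 1 sample).
BIMACULOIDES_THRESHOLDS = ExpressionThresholds(cpm_floor=1.0, min_samples=1, peak_cpm=0.5)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: counts / library size x 1e6, per sample column."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    return counts / lib * 1e6


def filter_expressed(counts: pd.DataFrame,
                     thresholds: ExpressionThresholds = ExpressionThresholds()) -> list:
    """Transcripts retained by the low-expression filter (>= floor in >= k samples)."""
    c = cpm(counts)
    keep = (c >= thresholds.cpm_floor).sum(axis=1) >= thresholds.min_samples
    return list(counts.index[keep])


def expressed_in_part(counts: pd.DataFrame, design: SampleDesign, part: str,
                      peak_cpm: float = 0.5) -> set:
    """Transcripts expressed in a part: > peak_cpm CPM in *all* its replicates."""
    samples = [s.sample_id for s in design.samples_of_part(part)]
    c = cpm(counts)[samples]
    return set(counts.index[(c > peak_cpm).all(axis=1)])


def expression_peaks(counts: pd.DataFrame, design: SampleDesign,
                     thresholds: ExpressionThresholds = ExpressionThresholds()) -> dict:
    """Map transcript -> part for transcripts peaking in exactly one part.

    A peak requires CPM > peak_cpm in every replicate of the part and
    CPM < peak_cpm in every replicate of every other part; a value equal
    to the threshold anywhere disqualifies the transcript.
    """
    parts = design.parts
    if len(parts) < 2:
        raise ValueError("peak detection requires a design with >= 2 parts")
    c = cpm(counts)
    above = {}
    below = {}
    for part in parts:
        samples = [s.sample_id for s in design.samples_of_part(part)]
        above[part] = (c[samples] > thresholds.peak_cpm).all(axis=1)
        below[part] = (c[samples] < thresholds.peak_cpm).all(axis=1)
    peaks = {}
    for part in parts:
        others_low = np.logical_and.reduce([below[p].values for p in parts if p != part])
        hit = above[part].values & others_low
        for tid in counts.index[hit]:
            peaks[tid] = part
    return peaks


def percentile_of_cpm(counts: pd.DataFrame, q: float) -> float:
    """q-th percentile of the pooled CPM distribution (linear interpolation)."""
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    if counts.size == 0:
        raise ValueError("empty count matrix")
    return float(np.percentile(cpm(counts).values.ravel(), q))
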