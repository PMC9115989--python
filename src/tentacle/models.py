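"""Domain objects shared across the pipeline.

All genomic coordinates stored on these objects are 0-based half-open.
External formats that use 1-based inclusive coordinates (GFF3,
RepeatMasker ``.out``, VCF) are converted at the I/O boundary in
:mod:`tentacle.formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PARTS_BRAIN = ("SEM", "SUB", "OL")
PART_PERIPHERY = "ARM"

#: RepeatMasker class/family strings mapped to the seven summary classes
#: used when reporting repeat composition.  The left component of the
#: class/family string (before '/') is looked up here; anything absent
#: falls through to "Unknown".
REPEAT_SUMMARY_CLASSES = {
    "LINE": "Retroelement",
    "SINE": "Retroelement",
    "LTR": "Retroelement",
    "Retroposon": "Retroelement",
    "DNA": "DNA transposon",
    "RC": "DNA transposon",
    "Satellite": "Satellite",
    "Simple_repeat": "Simple repeat",
    "Low_complexity": "Low complexity",
    "rRNA": "Other",
    "tRNA": "Other",
    "snRNA": "Other",
    "scRNA": "Other",
    "Other": "Other",
    "ARTEFACT": "Other",
    "Unknown": "Unknown",
}

#: Summary classes counted as interspersed repeats (tandem/low-complexity
#: annotation is excluded from interspersed-content totals).
INTERSPERSED_CLASSES = ("Retroelement", "DNA transposon", "Other", "Unknown")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomePlacement:
    """A transcript's alignment onto a genome scaffold.

    ``blocks`` are the exon intervals, sorted and non-overlapping, all
    within ``[start, end)``.  ``coverage_fraction`` and
    ``identity_fraction`` are the aligner's transcript coverage and
    percent identity expressed as fractions in [0, 1].
    """

    scaffold: str
    strand: str
    start: int
    end: int
    blocks: tuple = ()
    coverage_fraction: float = 1.0
    identity_fraction: float = 1.0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"placement start {self.start} must be < end {self.end}")
        prev = self.start
        for b0, b1 in self.blocks:
            if b0 < prev or b1 > self.end or b0 >= b1:
                raise ValueError(f"blocks must be sorted, non-overlapping and within [{self.start},{self.end})")
            prev = b1
        for name in ("coverage_fraction", "identity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def five_prime(self) -> int:
        return self.tss


@dataclass
class Transcript:
    id: str
    sequence: str
    placement: Optional[GenomePlacement] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"transcript {self.id!r} contains non-ACGTN characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular similarity search."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    database_tag: str = "protein"

    VALID_TAGS = ("protein", "domain", "rrna", "ncrna")

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.database_tag not in self.VALID_TAGS:
            raise ValueError(f"database_tag must be one of {self.VALID_TAGS}, got {self.database_tag!r}")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end after normalization")


@dataclass(frozen=True)
class RepeatFragment:
    """One RepeatMasker fragment on a transcript.

    Query coordinates follow the ``.out`` convention (1-based inclusive)
    as documented on the fields; consensus coordinates are normalized so
    ``c_begin <= c_end`` regardless of strand.
    """

    transcript_id: str
    q_begin: int
    q_end: int
    consensus_name: str
    repeat_class: str
    c_begin: int
    c_end: int
    c_left: int
    strand: str = "+"

    def __post_init__(self):
        if self.q_begin > self.q_end:
            raise ValueError("q_begin must be <= q_end")
        if self.c_begin > self.c_end:
            raise ValueError("c_begin must be <= c_end")
        if self.strand not in ("+", "C"):
            raise ValueError("strand must be '+' or 'C'")

    @property
    def major_class(self) -> str:
        """Left component of the class/family string (LINE, SINE, ...)."""
        return self.repeat_class.split("/")[0] if self.repeat_class else "Unknown"

    @property
    def subclass(self) -> Optional[str]:
        parts = self.repeat_class.split("/")
        return parts[1] if len(parts) > 1 else None

    @property
    def summary_class(self) -> str:
        return REPEAT_SUMMARY_CLASSES.get(self.major_class, "Unknown")

    @property
    def q_interval(self) -> tuple:
        """Query span as a 0-based half-open interval."""
        return (self.q_begin - 1, self.q_end)

    @property
    def c_interval(self) -> tuple:
        """Consensus span as a 0-based half-open interval."""
        return (self.c_begin - 1, self.c_end)


@dataclass(frozen=True)
class ConsensusModel:
    name: str
    length: int
    repeat_class: str = "Unknown"
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("consensus length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"consensus {self.name!r}: sequence length != declared length")


@dataclass
class IntegrationSiteRecord:
    """A non-reference mobile-element insertion call at one locus.

    ``position`` is the 0-based breakpoint; ``sample_presence`` maps
    every sample in the design to 'present', 'absent' or 'missing'.
    """

    scaffold: str
    position: int
    element: str
    filter_status: str
    left_support: int
    right_support: int
    sample_presence: dict = field(default_factory=dict)
    site_id: Optional[str] = None

    def __post_init__(self):
        if self.left_support < 0 or self.right_support < 0:
            raise ValueError("support counts must be non-negative")
        bad = {v for v in self.sample_presence.values()} - {"present", "absent", "missing"}
        if bad:
            raise ValueError(f"invalid presence states: {sorted(bad)}")

    @property
    def key(self) -> tuple:
        return (self.scaffold, self.position, self.element)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    individual: str
    part: str
    mapped_reads: int = 1

    def __post_init__(self):
        if self.mapped_reads <= 0:
            raise ValueError(f"sample {self.sample_id!r}: mapped_reads must be > 0")


@dataclass
class SampleDesign:
    """Sample sheet: which individual and body part each library comes from."""

    samples: list

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")
        if not self.samples:
            raise ValueError("design must contain at least one sample")

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def parts(self) -> list:
        seen = []
        for s in self.samples:
            if s.part not in seen:
                seen.append(s.part)
        return seen

    @property
    def individuals(self) -> list:
        seen = []
        for s in self.samples:
            if s.individual not in seen:
                seen.append(s.individual)
        return seen

    def samples_of_part(self, part: str) -> list:
        out = [s for s in self.samples if s.part == part]
        if not out:
            raise KeyError(f"part {part!r} not present in design")
        return out

    def sample(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"sample {sample_id!r} not in design")
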