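"""Open-reading-frame scanning and translation.

Two scanning modes are provided.  *Permissive* mode reports the longest
stop-free codon run in any scanned frame, with no requirement for a
methionine start — the convention used when an ORF length is a feature
for coding-potential assessment.  *Strict* mode reports the longest run
that begins with ATG and ends immediately before a canonical stop codon
(TAA/TAG/TGA) in the same frame — the convention for calling a complete,
translatable ORF.  In strict mode an ORF running off the end of the
transcript without a stop is not reported.

Reported nucleotide extents exclude the stop codon, so
``nt_end - nt_start == 3 * aa_length`` in both modes.  Coordinates are
0-based half-open positions on the forward strand of the input
transcript, for reverse frames as well.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
FRAME_LABELS = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class OrfCall:
    transcript_id: str
    frame: str
    nt_start: int
    nt_end: int
    aa_length: int
    peptide: str
    mode: str

    def __post_init__(self):
        if self.nt_end - self.nt_start != 3 * self.aa_length:
            raise ValueError("ORF nucleotide extent must equal 3 x aa_length (stop excluded)")


def translate(seq_in_frame: str) -> str:
    """Translate an in-frame nucleotide sequence with the standard code.

    Codons containing N translate to 'X'; stop codons yield '*'.
    """
    seq_in_frame = seq_in_frame.upper()
    if len(seq_in_frame) % 3 != 0:
        raise ValueError(f"sequence length {len(seq_in_frame)} is not divisible by 3")
    peptide = list(str(Seq(seq_in_frame).translate()))
    for i in range(len(peptide)):  # any ambiguity masks the residue
        if "N" in seq_in_frame[3 * i:3 * i + 3]:
            peptide[i] = "X"
    return "".join(peptide)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq.upper()).reverse_complement())


def _frame_runs(codons, mode):
    """Yield (start_codon_index, n_codons) for candidate ORFs in one frame."""
    n = len(codons)
    stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    if mode == "permissive":
        # maximal stop-free runs, including runs touching either end
        bounds = [-1] + stops + [n]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo - 1 > 0:
                yield (lo + 1, hi - lo - 1)
    elif mode == "strict":
        # earliest ATG in each stop-terminated segment gives the longest ORF
        prev = -1
        for stop in stops:
            for i in range(prev + 1, stop):
                if codons[i] == "ATG":
                    yield (i, stop - i)
                    break
            prev = stop
    else:
        raise ValueError(f"unknown mode {mode!r}")


def longest_orf(transcript_id: str, sequence: str, mode: str = "permissive",
                frames: str = "six") -> OrfCall:
    """Find the longest ORF across reading frames.

    ``frames`` is 'six' (both strands; assemblies from non-strand-specific
    libraries) or 'three' (forward strand only).  Ties break on the lowest
    frame index (+1,+2,+3,-1,-2,-3) and then the lowest start position in
    the scanned orientation.  A sequence with no qualifying ORF returns an
    ``aa_length == 0`` call rather than raising.
    """
    if frames not in ("three", "six"):
        raise ValueError(f"frames must be 'three' or 'six', got {frames!r}")
    sequence = sequence.upper()
    length = len(sequence)
    scan = [("+", sequence)]
    if frames == "six":
        scan.append(("-", reverse_complement(sequence)))

    best = None  # (aa_length, frame_rank, start) with max aa, min rank, min start
    for strand_idx, (strand, seq) in enumerate(scan):
        for offset in range(3):
            frame_rank = strand_idx * 3 + offset
            codons = [seq[i:i + 3] for i in range(offset, len(seq) - 2, 3)]
            for start_codon, n_codons in _frame_runs(codons, mode):
                key = (-n_codons, frame_rank, start_codon)
                if best is None or key < best[0]:
                    s = offset + 3 * start_codon
                    e = s + 3 * n_codons
                    best = (key, strand, frame_rank, s, e, seq[s:e])

    if best is None:
        return OrfCall(transcript_id=transcript_id, frame="+1", nt_start=0, nt_end=0,
                       aa_length=0, peptide="", mode=mode)
    _, strand, frame_rank, s, e, orf_seq = best
    if strand == "+":
        nt_start, nt_end = s, e
    else:  # map back onto the forward strand
        nt_start, nt_end = length - e, length - s
    return OrfCall(
        transcript_id=transcript_id,
        frame=FRAME_LABELS[frame_rank],
        nt_start=nt_start, nt_end=nt_end,
        aa_length=(e - s) // 3,
        peptide=translate(orf_seq),
        mode=mode,
    )
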