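"""Readers and writers for every external format the pipeline touches.

Supported formats: FASTA (transcripts, repeat consensus libraries),
gmap-style GFF3 transcript placements, RepeatMasker ``.out``, 12-column
tabular similarity hits, VCF 4.x mobile-element insertion calls, TSV
count matrices and TSV sample designs.

Everything is validated on read; coordinates are converted to the
package-internal 0-based half-open convention at this boundary (repeat
fragments keep their native 1-based fields and expose converted
intervals as properties).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, List, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    ConsensusModel,
    FormatError,
    GenomePlacement,
    HitRecord,
    IntegrationSiteRecord,
    RepeatFragment,
    SampleDesign,
    SampleInfo,
    Transcript,
)

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "align_len", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[Transcript]:
    """Read a transcript FASTA file, rejecting duplicate identifiers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or non-FASTA input")
    transcripts, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate transcript id {rec.id!r}")
        seen.add(rec.id)
        transcripts.append(Transcript(id=rec.id, sequence=str(rec.seq)))
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_consensus_library(path) -> List[ConsensusModel]:
    """Read a repeat consensus FASTA whose headers carry ``name#class/family`` labels."""
    models = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "#" in rec.id:
            name, klass = rec.id.split("#", 1)
        else:
            name, klass = rec.id, "Unknown"
        seq = str(rec.seq).upper()
        models.append(ConsensusModel(name=name, length=len(seq), repeat_class=klass, sequence=seq))
    if not models:
        raise FormatError(f"{path}: empty consensus library")
    return models


def write_consensus_library(models: Iterable[ConsensusModel], path) -> None:
    records = []
    for m in models:
        if m.sequence is None:
            raise ValueError(f"consensus {m.name!r} has no sequence to write")
        records.append(SeqRecord(Seq(m.sequence), id=f"{m.name}#{m.repeat_class}", description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 transcript placements (gmap-style)

def read_placements_gff3(path) -> dict:
    """Read gmap-style GFF3 into a mapping transcript_id -> GenomePlacement.

    mRNA features carry ``Name`` (the transcript id) plus ``coverage`` and
    ``identity`` attributes as percentages; exon children give the blocks.
    GFF3 1-based inclusive coordinates become 0-based half-open here.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    placements = {}
    for mrna in db.features_of_type("mRNA"):
        name = mrna.attributes.get("Name", [mrna.id])[0]
        if name in placements:
            raise FormatError(f"{path}: duplicate placement for transcript {name!r}")
        cov = float(mrna.attributes.get("coverage", ["100"])[0]) / 100.0
        ident = float(mrna.attributes.get("identity", ["100"])[0]) / 100.0
        blocks = tuple(sorted((e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")))
        placements[name] = GenomePlacement(
            scaffold=mrna.seqid, strand=mrna.strand,
            start=mrna.start - 1, end=mrna.end,
            blocks=blocks, coverage_fraction=min(cov, 1.0), identity_fraction=min(ident, 1.0),
        )
    return placements


def write_placements_gff3(placements: dict, path) -> None:
    """Write placements as gmap-style GFF3 (gene/mRNA/exon per transcript)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid in sorted(placements):
            p = placements[tid]
            cov = f"{p.coverage_fraction * 100:.1f}"
            ident = f"{p.identity_fraction * 100:.1f}"
            fh.write(f"{p.scaffold}\tgmap\tgene\t{p.start + 1}\t{p.end}\t.\t{p.strand}\t.\tID={tid}.gene\n")
            fh.write(
                f"{p.scaffold}\tgmap\tmRNA\t{p.start + 1}\t{p.end}\t.\t{p.strand}\t.\t"
                f"ID={tid}.mrna;Parent={tid}.gene;Name={tid};coverage={cov};identity={ident}\n"
            )
            blocks = p.blocks or ((p.start, p.end),)
            for b0, b1 in blocks:
                fh.write(f"{p.scaffold}\tgmap\texon\t{b0 + 1}\t{b1}\t.\t{p.strand}\t.\tParent={tid}.mrna\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

def read_repeatmasker_out(path) -> List[RepeatFragment]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The standard layout is three header lines followed by whitespace-
    delimited rows.  On '+' rows the consensus columns are
    ``begin end (left)``; on complement ('C') rows they are
    ``(left) end begin``.  Both are normalized to ``c_begin <= c_end``.
    """
    fragments = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("SW", "score", "There were no")):
            continue
        fields = stripped.split()
        if len(fields) < 14:
            raise FormatError(f"{path}: unparsable RepeatMasker row at line {lineno}")
        try:
            q_name = fields[4]
            q_begin, q_end = int(fields[5]), int(fields[6])
            strand = fields[8]
            consensus_name = fields[9]
            repeat_class = fields[10]
            if strand == "+":
                c_begin, c_end = int(fields[11]), int(fields[12])
                c_left = int(fields[13].strip("()"))
            elif strand == "C":
                c_left = int(fields[11].strip("()"))
                c_end, c_begin = int(fields[12]), int(fields[13])
            else:
                raise ValueError(f"unknown strand {strand!r}")
        except ValueError as exc:
            raise FormatError(f"{path}: unparsable RepeatMasker row at line {lineno}: {exc}") from exc
        frag = RepeatFragment(
            transcript_id=q_name, q_begin=q_begin, q_end=q_end,
            consensus_name=consensus_name, repeat_class=repeat_class,
            c_begin=c_begin, c_end=c_end, c_left=c_left, strand=strand,
        )
        if frag.summary_class == "Unknown" and frag.major_class != "Unknown":
            logger.warning("%s line %d: unknown repeat class %r mapped to 'Unknown'",
                           path, lineno, repeat_class)
        fragments.append(frag)
    return fragments


def write_repeatmasker_out(fragments: Iterable[RepeatFragment], path) -> None:
    header = (
        "   SW   perc perc perc  query      position in query           matching"
        "       repeat              position in repeat\n"
        "score   div. del. ins.  sequence    begin    end     (left)    repeat"
        "         class/family       begin   end    (left)   ID\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, f in enumerate(fragments, start=1):
            if f.strand == "+":
                cons_cols = f"{f.c_begin} {f.c_end} ({f.c_left})"
            else:
                cons_cols = f"({f.c_left}) {f.c_end} {f.c_begin}"
            fh.write(
                f"  500   10.0  0.0  0.0  {f.transcript_id} {f.q_begin} {f.q_end} (0) "
                f"{f.strand} {f.consensus_name} {f.repeat_class} {cons_cols} {i}\n"
            )


# ---------------------------------------------------------------------------
# 12-column tabular hits

_EVALUE_RE = re.compile(r"^[0-9.]*e?-?[0-9]*$", re.IGNORECASE)


def _parse_evalue(text: str) -> float:
    """Parse an e-value, accepting '10e-5'-style scientific notation."""
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(f"unparsable e-value {text!r}") from exc
    if value < 0:
        raise FormatError(f"negative e-value {text!r}")
    return value


def read_hit_table(path, database_tag: str = "protein") -> List[HitRecord]:
    """Read a 12-column tabular similarity-hit file (BLAST outfmt-6 dialect)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path}: expected 12 columns at line {lineno}, got {len(fields)}")
            q_start, q_end = int(fields[6]), int(fields[7])
            if q_start > q_end:
                q_start, q_end = q_end, q_start
            hits.append(HitRecord(
                query_id=fields[0], subject_id=fields[1],
                percent_identity=float(fields[2]), align_len=int(fields[3]),
                mismatches=int(fields[4]), gap_opens=int(fields[5]),
                q_start=q_start, q_end=q_end,
                s_start=int(fields[8]), s_end=int(fields[9]),
                evalue=_parse_evalue(fields[10]), bitscore=float(fields[11]),
                database_tag=database_tag,
            ))
    return hits


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, h.percent_identity, h.align_len,
                h.mismatches, h.gap_opens, h.q_start, h.q_end,
                h.s_start, h.s_end, h.evalue, h.bitscore,
            )) + "\n")


# ---------------------------------------------------------------------------
# Integration-site VCF (MELT-style)

def read_is_vcf(path, design: SampleDesign,
                left_key: str = "LP", right_key: str = "RP") -> List[IntegrationSiteRecord]:
    """Read MELT-style insertion calls from a VCF.

    Genotypes map to presence: 0/0 -> absent, any non-reference allele ->
    present, missing -> missing.  ``left_key``/``right_key`` name the INFO
    fields carrying per-side discordant-pair support (tools differ here,
    so they are configurable).
    """
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if set(vcf_samples) != set(design.sample_ids):
            raise FormatError(
                f"{path}: VCF samples {vcf_samples} do not match design samples {design.sample_ids}")
        for rec in vcf:
            presence = {}
            for sid in design.sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or all(a is None for a in gt):
                    presence[sid] = "missing"
                elif any(a is not None and a >= 1 for a in gt):
                    presence[sid] = "present"
                else:
                    presence[sid] = "absent"
            filters = list(rec.filter.keys())
            status = "PASS" if (not filters or filters == ["PASS"]) else ";".join(filters)
            element = rec.info.get("MEI", None)
            if element is None:
                alt = rec.alts[0] if rec.alts else ""
                element = alt.strip("<>").replace("INS:ME:", "") or "ME"
            sites.append(IntegrationSiteRecord(
                scaffold=rec.contig, position=rec.start, element=str(element),
                filter_status=status,
                left_support=int(rec.info.get(left_key, 0)),
                right_support=int(rec.info.get(right_key, 0)),
                sample_presence=presence,
                site_id=rec.id,
            ))
    return sites


def write_is_vcf(sites: Iterable[IntegrationSiteRecord], design: SampleDesign,
                 scaffold_lengths: dict, path,
                 left_key: str = "LP", right_key: str = "RP") -> None:
    header = pysam.VariantHeader()
    for name in sorted(scaffold_lengths):
        header.contigs.add(name, length=scaffold_lengths[name])
    header.info.add("MEI", 1, "String", "Mobile element name")
    header.info.add(left_key, 1, "Integer", "Discordant pairs supporting the left breakpoint side")
    header.info.add(right_key, 1, "Integer", "Discordant pairs supporting the right breakpoint side")
    header.formats.add("GT", 1, "String", "Genotype")
    sites = list(sites)
    for reason in sorted({s.filter_status for s in sites} - {"PASS"}):
        for tag in reason.split(";"):
            if tag not in header.filters:
                header.filters.add(tag, None, None, "Failed upstream check")
    for sid in design.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, s in enumerate(sites):
            rec = vcf.new_record(contig=s.scaffold, start=s.position, stop=s.position + 1,
                                 alleles=("N", "<INS:ME>"), id=s.site_id or f"IS{i + 1}")
            rec.info["MEI"] = s.element
            rec.info[left_key] = s.left_support
            rec.info[right_key] = s.right_support
            for tag in s.filter_status.split(";"):
                rec.filter.add(tag)
            for sid in design.sample_ids:
                state = s.sample_presence[sid]
                rec.samples[sid]["GT"] = {
                    "present": (0, 1), "absent": (0, 0), "missing": (None, None)}[state]
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Count matrix and sample design TSVs

def read_counts_tsv(path, design: Optional[SampleDesign] = None) -> pd.DataFrame:
    """Read a raw count matrix (rows = transcripts, columns = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty count matrix")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    if design is not None:
        missing = set(design.sample_ids) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: count matrix lacks design samples {sorted(missing)}")
        df = df[design.sample_ids]
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def read_design_tsv(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "individual", "part", "mapped_reads"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: design requires columns {sorted(required)}")
    return SampleDesign(samples=[
        SampleInfo(sample_id=str(r.sample_id), individual=str(r.individual),
                   part=str(r.part), mapped_reads=int(r.mapped_reads))
        for r in df.itertuples()
    ])


def write_design_tsv(design: SampleDesign, path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.individual, s.part, s.mapped_reads) for s in design.samples],
        columns=["sample_id", "individual", "part", "mapped_reads"],
    ).to_csv(path, sep="\t", index=False)


def read_genome_fasta(path) -> dict:
    """Read a genome FASTA into a mapping scaffold -> uppercase sequence."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate scaffold {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"{path}: empty genome FASTA")
    return genome


def write_genome_fasta(genome: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
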