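"""Stage orchestration over the library modules.

Each stage reads its inputs from the paths in the config, writes a TSV
with its per-entity results plus a JSON summary, and returns the
summary.  ``run_pipeline`` runs the stages in dependency order and
aggregates the summaries into a single report; any stage failure halts
the run naming the stage, keeping partial outputs on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import activity, conservation, expression, formats, lncrna, repeats, sineup
from .orf import longest_orf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    All threshold defaults are the method's published operating points:
    0.5 CPM in 2 samples (1 CPM / 1 sample for the variant filter),
    200 nt / 100 aa / 0.95 score / 1e-5 e-value for the lncRNA rule,
    80% consensus coverage, 1000-nt promoters at 50% identity, 90/90
    mapping, 10 transcripts per scaffold, 3 discordant pairs, a 260-bp
    exclusion window and a 10-kb scaffold floor.
    """

    data_dir: str = "."
    out_dir: str = "results"
    seed: int = 0
    # expression
    cpm_floor: float = 0.5
    min_samples: int = 2
    peak_cpm: float = 0.5
    # lncRNA
    min_length: int = 200
    hit_evalue_max: float = 1e-5
    max_orf_aa: int = 100
    min_ncpotential: float = 0.95
    ncpotential_scores: Optional[str] = None  # TSV transcript_id<TAB>score
    # repeats
    coverage_min: float = 0.8
    # conservation
    promoter_length: int = 1000
    identity_threshold: float = 50.0
    n_random: Optional[int] = None
    min_cov: float = 0.9
    min_ident: float = 0.9
    min_transcripts_per_scaffold: int = 10
    # sineup
    five_prime_slack: int = 0
    # activity
    min_support: int = 3
    exclusion_window: int = 260
    min_scaffold_len: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def path(self, name: str) -> Path:
        return Path(self.data_dir) / name

    def out(self, name: str) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name


def _write_summary(config: PipelineConfig, stage: str, summary: dict) -> dict:
    with open(config.out(f"{stage}_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def stage_expression(config: PipelineConfig) -> dict:
    design = formats.read_design_tsv(config.path("design.tsv"))
    counts = formats.read_counts_tsv(config.path("counts.tsv"), design)
    thresholds = expression.ExpressionThresholds(
        cpm_floor=config.cpm_floor, min_samples=config.min_samples, peak_cpm=config.peak_cpm)
    retained = expression.filter_expressed(counts, thresholds)
    peaks = expression.expression_peaks(counts, design, thresholds)
    expressed = {part: expression.expressed_in_part(counts, design, part, config.peak_cpm)
                 for part in design.parts}
    pd.Series(retained, name="transcript_id").to_csv(
        config.out("retained_transcripts.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(peaks.items()), columns=["transcript_id", "part"]).to_csv(
        config.out("expression_peaks.tsv"), sep="\t", index=False)
    rows = [(part, tid) for part in design.parts for tid in sorted(expressed[part])]
    pd.DataFrame(rows, columns=["part", "transcript_id"]).to_csv(
        config.out("expressed_by_part.tsv"), sep="\t", index=False)
    return _write_summary(config, "expression", {
        "transcripts_total": int(counts.shape[0]),
        "retained": len(retained),
        "peaks": len(peaks),
        "expressed_per_part": {p: len(s) for p, s in expressed.items()},
        "cpm_25th_percentile": expression.percentile_of_cpm(counts, 25.0),
    })


def _load_retained(config: PipelineConfig) -> set:
    path = config.out("retained_transcripts.tsv")
    if not path.exists():
        raise RuntimeError("expression stage must run before this stage")
    return set(pd.read_csv(path, sep="\t")["transcript_id"])


def stage_lncrna(config: PipelineConfig) -> dict:
    transcripts = formats.read_fasta(config.path("transcripts.fasta"))
    retained = _load_retained(config)
    transcripts = [t for t in transcripts if t.id in retained]
    hits = []
    for tag in ("protein", "domain", "rrna", "ncrna"):
        path = config.path(f"hits_{tag}.tsv")
        if path.exists():
            hits.extend(formats.read_hit_table(path, database_tag=tag))
    criteria = lncrna.LncrnaCriteria(
        min_length=config.min_length, hit_evalue_max=config.hit_evalue_max,
        max_orf_aa=config.max_orf_aa, min_ncpotential=config.min_ncpotential)
    flags = lncrna.summarize_hits(hits, criteria)
    orfs = {t.id: longest_orf(t.id, t.sequence, mode="permissive", frames="six")
            for t in transcripts}
    if config.ncpotential_scores:
        scores_df = pd.read_csv(config.ncpotential_scores, sep="\t")
        scores = dict(zip(scores_df.iloc[:, 0], scores_df.iloc[:, 1]))
    else:
        scores = {t.id: lncrna.baseline_ncpotential(t, orfs[t.id]) for t in transcripts}
    annotations = lncrna.classify(transcripts, flags, orfs, scores, criteria)
    pd.DataFrame([{
        "transcript_id": a.transcript_id, "length": a.length,
        "protein_hit": a.flags.has_protein_hit, "domain_hit": a.flags.has_domain_hit,
        "rrna_hit": a.flags.has_rrna_hit, "ncrna_hit": a.flags.has_ncrna_hit,
        "longest_orf_aa": a.longest_orf_aa, "ncpotential": a.ncpotential, "class": a.klass,
    } for a in annotations]).to_csv(config.out("lncrna_annotation.tsv"), sep="\t", index=False)
    return _write_summary(config, "lncrna", lncrna.class_counts(annotations))


def stage_repeats(config: PipelineConfig) -> dict:
    transcripts = formats.read_fasta(config.path("transcripts.fasta"))
    fragments = formats.read_repeatmasker_out(config.path("repeats.out"))
    models = formats.read_consensus_library(config.path("consensus_library.fasta"))
    domain_path = config.path("hits_domain.tsv")
    domain_hits = (formats.read_hit_table(domain_path, "domain")
                   if domain_path.exists() else [])
    summary = repeats.mask_fraction(transcripts, fragments)
    summary.per_class.to_csv(config.out("repeat_summary.tsv"), sep="\t")
    candidates = repeats.detect_full_length(
        transcripts, fragments, models, domain_hits, coverage_min=config.coverage_min)
    pd.DataFrame([{
        "transcript_id": c.transcript_id, "consensus": c.consensus_name,
        "coverage": c.consensus_coverage, "strict_orf_aa": c.strict_orf.aa_length,
        "domains": ",".join(sorted(c.domains_present)), "full_length": c.verdict,
    } for c in candidates]).to_csv(config.out("full_length_candidates.tsv"), sep="\t", index=False)
    expressed = {}
    by_part = config.out("expressed_by_part.tsv")
    if by_part.exists():
        df = pd.read_csv(by_part, sep="\t")
        expressed = {p: set(g["transcript_id"]) for p, g in df.groupby("part")}
        seg = repeats.repeat_segregation(expressed, fragments)
        seg.to_csv(config.out("repeat_segregation.tsv"), sep="\t")
    return _write_summary(config, "repeats", {
        "interspersed_nt": summary.interspersed_nt,
        "interspersed_fraction": summary.interspersed_fraction,
        "transcripts_with_interspersed": summary.transcripts_with_interspersed,
        "full_length_elements": sorted(c.transcript_id for c in candidates if c.verdict),
    })


def stage_conserve(config: PipelineConfig) -> dict:
    hits_ab = formats.read_hit_table(config.path("hits_ab.tsv"))
    hits_ba = formats.read_hit_table(config.path("hits_ba.tsv"))
    pairs = conservation.reciprocal_best_hits(hits_ab, hits_ba)
    genome_a = formats.read_genome_fasta(config.path("genome_a.fasta"))
    genome_b = formats.read_genome_fasta(config.path("genome_b.fasta"))
    placements_a = conservation.mapping_filter(
        formats.read_placements_gff3(config.path("placements_a.gff3")),
        config.min_cov, config.min_ident)
    placements_b = conservation.mapping_filter(
        formats.read_placements_gff3(config.path("placements_b.gff3")),
        config.min_cov, config.min_ident)
    pd.DataFrame([(p.id_a, p.id_b, p.bitscore_ab, p.bitscore_ba, p.identity_pct)
                  for p in pairs],
                 columns=["id_a", "id_b", "bitscore_ab", "bitscore_ba", "identity_pct"]
                 ).to_csv(config.out("orthologs.tsv"), sep="\t", index=False)
    promoter_seqs = []
    for p in pairs:
        pa = conservation.extract_promoter(placements_a.get(p.id_a), genome_a,
                                           config.promoter_length)
        pb = conservation.extract_promoter(placements_b.get(p.id_b), genome_b,
                                           config.promoter_length)
        if pa and pb:
            promoter_seqs.append((p.id_a, p.id_b, pa, pb))
    summary = {"rbh_pairs": len(pairs), "promoter_pairs": len(promoter_seqs)}
    if len(promoter_seqs) >= 2:
        res = conservation.promoter_conservation(
            promoter_seqs, n_random=config.n_random, seed=config.seed,
            identity_threshold=config.identity_threshold)
        pd.DataFrame([(q.id_a, q.id_b, q.identity_pct, q.conserved) for q in res.pairs],
                     columns=["id_a", "id_b", "identity_pct", "conserved"]
                     ).to_csv(config.out("promoters.tsv"), sep="\t", index=False)
        summary["conserved_promoter_fraction"] = res.conserved_fraction
        summary["random_conserved_fraction"] = res.random_conserved_fraction
    try:
        pos = conservation.positional_conservation(
            placements_a, placements_b, pairs, config.min_transcripts_per_scaffold)
        summary["positional_per_scaffold_mean"] = pos.per_scaffold_mean
        summary["positional_pooled"] = pos.pooled_fraction
    except ValueError as exc:
        summary["positional"] = f"not computed: {exc}"
    return _write_summary(config, "conserve", summary)


def stage_sineup(config: PipelineConfig) -> dict:
    placements = formats.read_placements_gff3(config.path("placements_a.gff3"))
    fragments = formats.read_repeatmasker_out(config.path("repeats.out"))
    ann_path = config.out("lncrna_annotation.tsv")
    if not ann_path.exists():
        raise RuntimeError("lncrna stage must run before sineup")
    ann = pd.read_csv(ann_path, sep="\t")
    classes = dict(zip(ann["transcript_id"], ann["class"]))
    candidates, counts = sineup.find_sineup_candidates(
        placements, classes, fragments, config.five_prime_slack)
    pd.DataFrame([{
        "mrna_id": c.mrna_id, "lncrna_id": c.lncrna_id, "scaffold": c.scaffold,
        "overlap_start": c.overlap_start, "overlap_end": c.overlap_end,
        "orientation": c.orientation,
        "sine_fragments_outside_overlap": c.sine_fragments_outside_overlap,
        "canonical": c.canonical,
    } for c in candidates]).to_csv(config.out("sineup_candidates.tsv"), sep="\t", index=False)
    return _write_summary(config, "sineup", {
        "mrna_mrna_pairs": counts.mrna_mrna,
        "lncrna_lncrna_pairs": counts.lncrna_lncrna,
        "mrna_lncrna_pairs": counts.mrna_lncrna,
        "canonical_candidates": sum(c.canonical for c in candidates),
    })


def stage_activity(config: PipelineConfig) -> dict:
    design = formats.read_design_tsv(config.path("is_design.tsv"))
    sites = formats.read_is_vcf(config.path("is_calls.vcf"), design)
    hits_df = pd.read_csv(config.path("is_consensus_hits.tsv"), sep="\t")
    consensus_hits = list(hits_df.itertuples(index=False, name=None))
    with pysam_lengths(config.path("is_calls.vcf")) as scaffold_lengths:
        filtered = activity.filter_sites(
            sites, consensus_hits, scaffold_lengths,
            min_support=config.min_support,
            exclusion_window=config.exclusion_window,
            min_scaffold_len=config.min_scaffold_len)
    calls = activity.classify_sharing(filtered, design)
    pd.DataFrame([{
        "site_id": c.site.site_id, "scaffold": c.site.scaffold,
        "position": c.site.position, "category": c.category,
        "individual": c.individual or "", "part": c.part or "",
    } for c in calls]).to_csv(config.out("is_sharing.tsv"), sep="\t", index=False)
    summary = {"sites_raw": len(sites), "sites_filtered": len(filtered)}
    summary.update(activity.sharing_counts(calls))
    qpcr_path = config.path("qpcr.tsv")
    if qpcr_path.exists():
        q = pd.read_csv(qpcr_path, sep="\t")
        measurements = [activity.QpcrMeasurement(
            sample_id=r.sample_id, target_ct=r.target_ct,
            reference_ct=r.reference_ct, calibrator=bool(r.calibrator))
            for r in q.itertuples()]
        folds = activity.ddct(measurements)
        pd.DataFrame(sorted(folds.items()), columns=["sample_id", "fold_change"]
                     ).to_csv(config.out("qpcr_folds.tsv"), sep="\t", index=False)
        summary["qpcr_samples"] = len(folds)
    return _write_summary(config, "activity", summary)


class pysam_lengths:
    """Scaffold lengths from the VCF's contig header lines."""

    def __init__(self, vcf_path):
        self.vcf_path = str(vcf_path)

    def __enter__(self):
        import pysam
        with pysam.VariantFile(self.vcf_path) as vcf:
            return {name: c.length for name, c in vcf.header.contigs.items()}

    def __exit__(self, *exc):
        return False


STAGES = {
    "expression": stage_expression,
    "lncrna": stage_lncrna,
    "repeats": stage_repeats,
    "conserve": stage_conserve,
    "sineup": stage_sineup,
    "activity": stage_activity,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order and aggregate their summaries."""
    report = {}
    for name in ("expression", "lncrna", "repeats", "conserve", "sineup", "activity"):
        logger.info("[%s] running", name)
        try:
            report[name] = STAGES[name](config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    with open(config.out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
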