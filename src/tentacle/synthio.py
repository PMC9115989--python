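"""Self-consistent synthetic datasets with a ground-truth manifest.

The generator emulates the statistical structure the analysis assumes:
a transcript population with a planted coding/noncoding mixture and
embedded repeat fragments, one planted full-length autonomous LINE
(single 3327-nt ORF translating to 1109 aa, EN/RT/ZF domains, ~600-nt
UTRs, a 3' microsatellite) plus 5'-truncated copies, ortholog pairs
with a tunable promoter-divergence mixture, negative-binomial count
noise implementing planted expression peaks and a brain bias of lncRNA
expression, and mobile-element insertion-site call sets with planted
4-sample presence patterns and discordant-read support.

Everything is deterministic given the seed; every generated file parses
back through :mod:`tentacle.formats`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import formats
from .activity import QpcrMeasurement
from .models import (
    ConsensusModel,
    GenomePlacement,
    HitRecord,
    IntegrationSiteRecord,
    RepeatFragment,
    SampleDesign,
    SampleInfo,
    Transcript,
)
from .orf import longest_orf

BASES = np.array(list("ACGT"))

#: 12-mer with a stop codon in every frame of both strands (it equals its
#: own reverse complement); interspersing it bounds ORF lengths by
#: construction, so noncoding sequences need no rejection sampling.
STOP_CASSETTE = "TTAATTAATTAA"

SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real study design where one exists (four body
    parts sampled in three individuals, a ~12% lncRNA and ~33% coding
    transcriptome composition, a 1109-aa LINE ORF with ~600-nt UTRs,
    the 55-site sharing pattern) and desk-scale choices documented in
    the methods note everywhere else.
    """

    seed: int
    n_transcripts: int = 300
    coding_fraction: float = 0.33
    lncrna_fraction: float = 0.12
    noise_fraction: float = 0.05
    parts: Tuple[str, ...] = ("SEM", "SUB", "OL", "ARM")
    n_individuals: int = 3
    nb_mean: float = 30.0
    nb_dispersion: float = 0.3
    peak_fraction: float = 0.03
    line_orf_aa: int = 1109
    line_utr_nt: int = 600
    ortholog_set_size: int = 96
    promoter_conserved_weight: float = 0.5
    conserved_divergence: float = 0.15
    diverged_divergence: float = 0.70
    promoter_length: int = 1000

    def __post_init__(self):
        bad = []
        for name in ("coding_fraction", "lncrna_fraction", "noise_fraction",
                     "peak_fraction", "promoter_conserved_weight"):
            if not 0 <= getattr(self, name) <= 1:
                bad.append(name)
        if self.coding_fraction + self.lncrna_fraction + self.noise_fraction > 1:
            bad.append("coding_fraction+lncrna_fraction+noise_fraction")
        if self.n_transcripts < 50:
            bad.append("n_transcripts")
        if bad:
            raise ValueError(f"inconsistent simulation config fields: {bad}")


@dataclass
class TruthManifest:
    """Ground truth for every generated entity."""

    true_class: Dict[str, str] = field(default_factory=dict)
    profile: Dict[str, str] = field(default_factory=dict)
    peak_part: Dict[str, str] = field(default_factory=dict)
    fragment_classes: Dict[str, List[str]] = field(default_factory=dict)
    line_id: str = ""
    truncated_ids: List[str] = field(default_factory=list)
    antagonist_id: str = ""
    ortholog_map: Dict[str, str] = field(default_factory=dict)
    promoter_label: Dict[str, str] = field(default_factory=dict)
    sineup_truth: Dict[str, List[List[str]]] = field(default_factory=dict)
    is_category: Dict[str, str] = field(default_factory=dict)
    qpcr_fold: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    transcripts: List[Transcript]          # species A, specials included
    transcripts_b: List[Transcript]        # species B ortholog partners
    design: SampleDesign
    counts: pd.DataFrame
    fragments: List[RepeatFragment]
    consensus_models: List[ConsensusModel]
    hits: List[HitRecord]                  # protein/domain/rrna/ncrna searches
    hits_ab: List[HitRecord]               # species A -> B
    hits_ba: List[HitRecord]
    genome_a: Dict[str, str]
    genome_b: Dict[str, str]
    placements_a: Dict[str, GenomePlacement]
    placements_b: Dict[str, GenomePlacement]
    is_sites: List[IntegrationSiteRecord]
    is_design: SampleDesign
    is_scaffold_lengths: Dict[str, int]
    is_consensus_hits: List[Tuple[str, int, int]]
    qpcr: List[QpcrMeasurement]
    manifest: TruthManifest

    @property
    def transcript_ids(self) -> List[str]:
        return [t.id for t in self.transcripts]

    def oracle_ncpotential(self) -> Dict[str, float]:
        """Planted non-coding potential scores: 1.0 for true noncoding
        transcripts, 0.0 for coding, 0.5 for everything else."""
        lookup = {"lncRNA": 1.0, "coding": 0.0}
        return {t.id: lookup.get(self.manifest.true_class[t.id], 0.5)
                for t in self.transcripts}


# ---------------------------------------------------------------------------
# sequence construction

def _random_dna(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _orf_nt(rng, aa: int) -> str:
    """ATG + (aa-1) sense codons + TAA: a complete ORF of ``aa`` residues."""
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=aa - 1)]
    return "ATG" + "".join(codons) + "TAA"


def _noncoding_dna(rng, n: int, cassette_every: int = 120) -> str:
    """Random DNA with the stop cassette interspersed: no frame on either
    strand can hold a stop-free run longer than ~50 codons."""
    chunks, remaining = [], n
    while remaining > 0:
        gap = int(min(remaining, cassette_every))
        chunks.append(_random_dna(rng, gap))
        remaining -= gap
        if remaining > 0:
            take = min(remaining, len(STOP_CASSETTE))
            chunks.append(STOP_CASSETTE[:take])
            remaining -= take
    return "".join(chunks)


def _mutate(rng, seq: str, rate: float) -> str:
    """Substitute ``rate`` of positions with a different base."""
    arr = np.array(list(seq))
    k = int(round(rate * len(arr)))
    pos = rng.choice(len(arr), size=k, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _nb_counts(rng, mu: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + dispersion*mu^2."""
    if mu <= 0:
        return np.zeros(size, dtype=np.int64)
    nb_n = 1.0 / dispersion
    p = nb_n / (nb_n + mu)
    return rng.negative_binomial(nb_n, p, size=size)


def _hit(query, subject, evalue, bitscore, tag, identity=90.0) -> HitRecord:
    return HitRecord(query_id=str(query), subject_id=str(subject),
                     percent_identity=identity, align_len=100, mismatches=10,
                     gap_opens=0, q_start=1, q_end=100, s_start=1, s_end=100,
                     evalue=evalue, bitscore=bitscore, database_tag=tag)


# ---------------------------------------------------------------------------
# main generator

def simulate(config: SimulationConfig) -> SyntheticBundle:
    rng = np.random.default_rng(config.seed)
    manifest = TruthManifest()

    n = config.n_transcripts
    n_coding = round(config.coding_fraction * n)
    n_lnc = round(config.lncrna_fraction * n)
    n_noise = round(config.noise_fraction * n)
    core_ids = [f"t{i:05d}" for i in range(1, n + 1)]
    core_classes = (["coding"] * n_coding + ["lncRNA"] * n_lnc + ["noise"] * n_noise
                    + ["other"] * (n - n_coding - n_lnc - n_noise))

    line_seq = _build_line_consensus(rng, config)
    models = [
        ConsensusModel("RTE2_OV", len(line_seq), "LINE/RTE", line_seq),
        ConsensusModel("SINE_OCT", 300, "SINE/Octo", _random_dna(rng, 300)),
        ConsensusModel("CR1_OV", 4000, "LINE/CR1", _random_dna(rng, 4000)),
        ConsensusModel("GYPSY_OV", 5000, "LTR/Gypsy", _random_dna(rng, 5000)),
        ConsensusModel("TCMAR_OV", 2000, "DNA/TcMar", _random_dna(rng, 2000)),
        ConsensusModel("(CA)n", 100, "Simple_repeat", "CA" * 50),
        ConsensusModel("A-rich", 100, "Low_complexity", "A" * 100),
    ]

    transcripts: List[Transcript] = []
    hits: List[HitRecord] = []
    for tid, klass in zip(core_ids, core_classes):
        seq = _core_sequence(rng, tid, klass, hits)
        transcripts.append(Transcript(id=tid, sequence=seq))
        manifest.true_class[tid] = klass

    line_id, trunc_ids, specials, fragments = _plant_line(rng, config, line_seq, n)
    sineup_specials = _make_sineup_transcripts(rng, manifest, hits)
    specials += sineup_specials
    transcripts += specials
    for t in specials:
        manifest.true_class.setdefault(t.id, "other")
    manifest.line_id = line_id
    manifest.truncated_ids = trunc_ids
    for dom in ("OV_endonuclease_APE", "RVT_1_reverse_transcriptase", "zf-C2H2_zinc_finger"):
        hits.append(_hit(line_id, dom, 1e-15, 300.0, "domain"))
    manifest.antagonist_id = core_ids[0]  # a coding transcript plays the repressor homolog

    _assign_profiles(rng, config, manifest, core_ids, core_classes)
    _plant_fragments(rng, manifest, transcripts, models, fragments)
    design, counts = _simulate_counts(rng, config, manifest, transcripts)

    (genome_a, genome_b, placements_a, placements_b,
     hits_ab, hits_ba, transcripts_b) = _simulate_genomes(
        rng, config, manifest, transcripts, core_ids, core_classes)

    is_sites, is_design, is_lengths, is_hits = paper_pattern_fixture()
    for site in is_sites:
        manifest.is_category[site.site_id] = _pattern_category(site, is_design)
    qpcr = _simulate_qpcr(rng, config, manifest)

    return SyntheticBundle(
        config=config, transcripts=transcripts, transcripts_b=transcripts_b,
        design=design, counts=counts, fragments=fragments,
        consensus_models=models, hits=hits, hits_ab=hits_ab, hits_ba=hits_ba,
        genome_a=genome_a, genome_b=genome_b,
        placements_a=placements_a, placements_b=placements_b,
        is_sites=is_sites, is_design=is_design,
        is_scaffold_lengths=is_lengths, is_consensus_hits=is_hits,
        qpcr=qpcr, manifest=manifest)


def _core_sequence(rng, tid, klass, hits) -> str:
    if klass == "coding":
        aa = int(rng.integers(150, 400))
        hits.append(_hit(tid, f"sp|P{rng.integers(10000, 99999)}|OCT", 1e-20, 800.0, "protein"))
        return (_noncoding_dna(rng, int(rng.integers(100, 300)))
                + _orf_nt(rng, aa)
                + _noncoding_dna(rng, int(rng.integers(100, 300))))
    if klass == "lncRNA":
        return _noncoding_dna(rng, int(rng.integers(300, 1500)))
    if klass == "noise":
        return _noncoding_dna(rng, int(rng.integers(250, 600)))
    # "other": borderline transcripts failing exactly one lncRNA criterion
    style = rng.integers(0, 3)
    if style == 0:  # ORF of 100-140 aa, no database hit
        return _noncoding_dna(rng, 80) + _orf_nt(rng, int(rng.integers(100, 140))) + _noncoding_dna(rng, 80)
    if style == 1:  # shorter than the 200-nt floor
        return _noncoding_dna(rng, int(rng.integers(80, 199)))
    hits.append(_hit(tid, "rRNA_18S", 1e-30, 500.0, "rrna"))
    return _noncoding_dna(rng, int(rng.integers(300, 900)))


def _build_line_consensus(rng, config: SimulationConfig) -> str:
    """5' UTR, single complete ORF, 3' UTR dominated by a microsatellite.

    The stop cassette bounds every UTR reading frame, and the cassette
    placed immediately before the ATG guarantees the strict-mode ORF is
    exactly the planted one.
    """
    utr5 = _noncoding_dna(rng, config.line_utr_nt - len(STOP_CASSETTE)) + STOP_CASSETTE
    orf = _orf_nt(rng, config.line_orf_aa)
    micro = "CA" * ((config.line_utr_nt - 40) // 2)
    tail = config.line_utr_nt - len(micro) - len(STOP_CASSETTE)
    utr3 = micro + STOP_CASSETTE + _random_dna(rng, tail)
    seq = utr5 + orf + utr3
    call = longest_orf("consensus", seq, mode="strict", frames="six")
    assert call.aa_length == config.line_orf_aa, "planted LINE ORF construction failed"
    return seq


def _plant_line(rng, config, line_seq, n):
    """The full-length LINE transcript plus two 5'-truncated copies."""
    line_id = f"t{n + 1:05d}"
    trunc_ids = [f"t{n + 2:05d}", f"t{n + 3:05d}"]
    L = len(line_seq)
    tx = [Transcript(id=line_id, sequence=line_seq)]
    frags = [RepeatFragment(transcript_id=line_id, q_begin=1, q_end=L,
                            consensus_name="RTE2_OV", repeat_class="LINE/RTE",
                            c_begin=1, c_end=L, c_left=0, strand="+")]
    for tid, frac in zip(trunc_ids, (0.40, 0.60)):
        start = int(L * (1 - frac))
        sub = line_seq[start:]
        tx.append(Transcript(id=tid, sequence=sub))
        frags.append(RepeatFragment(
            transcript_id=tid, q_begin=1, q_end=len(sub),
            consensus_name="RTE2_OV", repeat_class="LINE/RTE",
            c_begin=start + 1, c_end=L, c_left=0, strand="+"))
    return line_id, trunc_ids, tx, frags


#: Fixed lengths for the SINEUP-layout transcripts so the planted genomic
#: geometry is consistent with the sequences.
_SINEUP_LENGTHS = {
    "sm1": 3000, "sm2": 2000, "sm3": 2500, "sm4": 2000, "sm5": 2000,
    "sl1": 3000, "sl2": 2000, "sl3": 3000, "sl4": 1200, "sl5": 1200,
}


def _make_sineup_transcripts(rng, manifest, hits) -> List[Transcript]:
    tx = []
    for tid, length in _SINEUP_LENGTHS.items():
        if tid.startswith("sm"):
            aa = 200
            flank = (length - (3 * aa + 3)) // 2
            seq = (_noncoding_dna(rng, flank) + _orf_nt(rng, aa)
                   + _noncoding_dna(rng, length - flank - 3 * aa - 3))
            hits.append(_hit(tid, f"sp|Q{rng.integers(10000, 99999)}|OCT", 1e-25, 700.0, "protein"))
            manifest.true_class[tid] = "coding"
        else:
            seq = _noncoding_dna(rng, length)
            manifest.true_class[tid] = "lncRNA"
        tx.append(Transcript(id=tid, sequence=seq))
    return tx


def _assign_profiles(rng, config, manifest, core_ids, core_classes):
    """Expression-profile groups drive both counts and repeat segregation."""
    n_peak = round(config.peak_fraction * config.n_transcripts)
    antagonist = manifest.antagonist_id
    eligible = [tid for tid, k in zip(core_ids, core_classes)
                if k != "noise" and tid != antagonist]
    peak_ids = [str(t) for t in rng.choice(eligible, size=n_peak, replace=False)]
    for i, tid in enumerate(peak_ids):
        part = config.parts[i % len(config.parts)]
        manifest.profile[tid] = f"peak:{part}"
        manifest.peak_part[tid] = part
    for tid, klass in zip(core_ids, core_classes):
        if tid in manifest.profile:
            continue
        if tid == antagonist:
            manifest.profile[tid] = "antagonist"
        elif klass == "noise":
            manifest.profile[tid] = "silent"
        elif klass == "lncRNA":
            # plants the brain bias of lncRNA expression
            manifest.profile[tid] = "brain" if rng.random() < 0.7 else "broad"
        else:
            r = rng.random()
            manifest.profile[tid] = "brain" if r < 0.3 else ("arm" if r < 0.6 else "broad")
    manifest.profile[manifest.line_id] = "line"
    for tid in manifest.truncated_ids:
        manifest.profile[tid] = "broad"
    for tid in _SINEUP_LENGTHS:
        manifest.profile[tid] = "broad"


#: Per-profile probability that a transcript carries a fragment of each
#: repeat family: brain-expressed transcripts are SINE-biased, periphery-
#: expressed ones LINE/LTR/DNA-biased.
_FRAGMENT_PROBS = {
    "brain": {"SINE_OCT": 0.40, "CR1_OV": 0.06, "GYPSY_OV": 0.04, "TCMAR_OV": 0.04},
    "arm": {"SINE_OCT": 0.08, "CR1_OV": 0.30, "GYPSY_OV": 0.18, "TCMAR_OV": 0.18},
    "broad": {"SINE_OCT": 0.15, "CR1_OV": 0.15, "GYPSY_OV": 0.10, "TCMAR_OV": 0.10},
}
_TANDEM_PROBS = {"(CA)n": 0.10, "A-rich": 0.05}


def _plant_fragments(rng, manifest, transcripts, models, fragments):
    by_name = {m.name: m for m in models}
    skip = set(manifest.truncated_ids) | set(_SINEUP_LENGTHS) | {manifest.line_id}
    for t in transcripts:
        if t.id in skip:
            continue
        base = manifest.profile.get(t.id, "broad").split(":")[0]
        probs = _FRAGMENT_PROBS.get(base, _FRAGMENT_PROBS["broad"])
        for cname, p in list(probs.items()) + list(_TANDEM_PROBS.items()):
            if rng.random() >= p:
                continue
            model = by_name[cname]
            span = int(min(rng.integers(50, 200), t.length, model.length))
            q0 = int(rng.integers(0, t.length - span + 1))
            c0 = int(rng.integers(0, model.length - span + 1))
            strand = "+" if rng.random() < 0.7 else "C"
            frag = RepeatFragment(
                transcript_id=t.id, q_begin=q0 + 1, q_end=q0 + span,
                consensus_name=cname, repeat_class=model.repeat_class,
                c_begin=c0 + 1, c_end=c0 + span,
                c_left=model.length - (c0 + span), strand=strand)
            fragments.append(frag)
            manifest.fragment_classes.setdefault(t.id, []).append(frag.major_class)


_PROFILE_MU = {
    # multiplier on the per-transcript base mean, by body part
    "brain": {"SEM": 1.0, "SUB": 1.0, "OL": 1.0, "ARM": 0.0},
    # periphery-leaning transcripts stay visible in one brain part so that
    # no profile other than the planted peaks is single-part by design
    "arm": {"SEM": 0.0, "SUB": 0.0, "OL": 1.0, "ARM": 1.0},
    "broad": {"SEM": 1.0, "SUB": 1.0, "OL": 1.0, "ARM": 1.0},
    "line": {"SEM": 1.3, "SUB": 4.0, "OL": 1.3, "ARM": 0.3},
    "antagonist": {"SEM": 1.5, "SUB": 0.15, "OL": 1.5, "ARM": 1.5},
}


def _simulate_counts(rng, config, manifest, transcripts):
    samples = []
    for i in range(1, config.n_individuals + 1):
        for part in config.parts:
            samples.append((f"O{i}_{part}", f"O{i}", part))
    tids = [t.id for t in transcripts]
    mat = np.zeros((len(tids), len(samples)), dtype=np.int64)
    for r, tid in enumerate(tids):
        profile = manifest.profile[tid]
        base = float(rng.lognormal(np.log(config.nb_mean), 0.5))
        if profile == "silent":
            # detectable in at most one sample: fails the retention filter
            col = int(rng.integers(0, len(samples)))
            mat[r, col] = int(rng.integers(1, 3))
            continue
        if profile.startswith("peak:"):
            target = profile.split(":")[1]
            mus = {p: (max(base, 25.0) if p == target else 0.0) for p in config.parts}
        else:
            mult = _PROFILE_MU[profile]
            mus = {p: base * mult.get(p, 1.0) for p in config.parts}
        for c, (sid, ind, part) in enumerate(samples):
            mat[r, c] = _nb_counts(rng, mus[part], config.nb_dispersion, 1)[0]
    counts = pd.DataFrame(mat, index=tids, columns=[s[0] for s in samples])
    design = SampleDesign(samples=[
        SampleInfo(sample_id=sid, individual=ind, part=part,
                   mapped_reads=max(int(counts[sid].sum()), 1))
        for sid, ind, part in samples])
    return design, counts


def _simulate_genomes(rng, config, manifest, transcripts, core_ids, core_classes):
    """Genomes for both species, syntenic ortholog placements, the
    promoter-divergence mixture and the planted SINEUP layout."""
    by_id = {t.id: t for t in transcripts}
    mapped_pool = sorted(tid for tid, k in zip(core_ids, core_classes)
                         if k in ("coding", "lncRNA", "other"))
    k_orth = min(config.ortholog_set_size, len(mapped_pool) - 20)
    orth_a = sorted(str(t) for t in rng.choice(mapped_pool, size=k_orth, replace=False))

    per_scaffold = 12
    spacing = 1600
    genome_a: Dict[str, str] = {}
    genome_b: Dict[str, str] = {}
    placements_a: Dict[str, GenomePlacement] = {}
    placements_b: Dict[str, GenomePlacement] = {}
    hits_ab: List[HitRecord] = []
    hits_ba: List[HitRecord] = []
    transcripts_b: List[Transcript] = []

    n_scaffolds = (k_orth + per_scaffold - 1) // per_scaffold
    pair_idx = 0
    for s in range(n_scaffolds):
        members = orth_a[s * per_scaffold:(s + 1) * per_scaffold]
        length = 1500 + spacing * (len(members) + 1)
        scf_a, scf_b = f"A_scf{s + 1}", f"B_scf{s + 1}"
        seq_a = _random_dna(rng, length)
        seq_b = _random_dna(rng, length)
        for j, tid in enumerate(members):
            b_id = f"b{pair_idx + 1:05d}"
            pair_idx += 1
            start = 1200 + spacing * j
            end = start + min(by_id[tid].length, 1200)
            placements_a[tid] = GenomePlacement(
                scaffold=scf_a, strand="+", start=start, end=end,
                blocks=((start, end),),
                coverage_fraction=float(rng.uniform(0.9, 1.0)),
                identity_fraction=float(rng.uniform(0.9, 1.0)))
            placements_b[b_id] = GenomePlacement(
                scaffold=scf_b, strand="+", start=start, end=end,
                blocks=((start, end),),
                coverage_fraction=float(rng.uniform(0.9, 1.0)),
                identity_fraction=float(rng.uniform(0.9, 1.0)))
            manifest.ortholog_map[tid] = b_id
            # the species-B promoter is a mutated copy of the species-A one
            label = ("conserved" if rng.random() < config.promoter_conserved_weight
                     else "diverged")
            rate = (config.conserved_divergence if label == "conserved"
                    else config.diverged_divergence)
            prom_a = seq_a[start - config.promoter_length:start]
            prom_b = _mutate(rng, prom_a, rate)
            seq_b = seq_b[:start - config.promoter_length] + prom_b + seq_b[start:]
            manifest.promoter_label[tid] = label
            transcripts_b.append(Transcript(
                id=b_id, sequence=_mutate(rng, by_id[tid].sequence, 0.08)))
            score = float(rng.uniform(800, 1200))
            hits_ab.append(_hit(tid, b_id, 1e-50, score, "protein",
                                identity=float(rng.uniform(88, 99))))
            hits_ba.append(_hit(b_id, tid, 1e-50, score - 5.0, "protein",
                                identity=float(rng.uniform(88, 99))))
        genome_a[scf_a] = seq_a
        genome_b[scf_b] = seq_b

    # decoy paralog hits: each ortholog also hits the *next* partner, weaker
    all_pairs = sorted(manifest.ortholog_map.items())
    for (a1, _b1), (_a2, b2) in zip(all_pairs, all_pairs[1:]):
        hits_ab.append(_hit(a1, b2, 1e-20, 350.0, "protein"))
    for (a1, b1), (a2, _b2) in zip(all_pairs, all_pairs[1:]):
        hits_ba.append(_hit(b1, a2, 1e-20, 350.0, "protein"))

    # pairs without room upstream of the TSS: promoter extraction must skip
    edge_pool = [tid for tid in mapped_pool if tid not in placements_a][:4]
    genome_a["A_edge"] = _random_dna(rng, 12_000)
    genome_b["B_edge"] = _random_dna(rng, 12_000)
    for j, tid in enumerate(edge_pool):
        b_id = f"bedge{j + 1}"
        start = 300 + 900 * j  # the first is < 1000 nt from the scaffold edge
        end = start + 500
        placements_a[tid] = GenomePlacement(scaffold="A_edge", strand="+",
                                            start=start, end=end)
        placements_b[b_id] = GenomePlacement(scaffold="B_edge", strand="+",
                                             start=start, end=end)
        manifest.ortholog_map[tid] = b_id
        manifest.promoter_label[tid] = ("no_promoter" if start < config.promoter_length
                                        else "unlabeled")
        transcripts_b.append(Transcript(
            id=b_id, sequence=_mutate(rng, by_id[tid].sequence[:500], 0.1)))
        hits_ab.append(_hit(tid, b_id, 1e-40, 700.0, "protein"))
        hits_ba.append(_hit(b_id, tid, 1e-40, 700.0, "protein"))

    _plant_sineup_layout(rng, manifest, genome_a, placements_a)
    return (genome_a, genome_b, placements_a, placements_b,
            hits_ab, hits_ba, transcripts_b)


def _plant_sineup_layout(rng, manifest, genome_a, placements_a):
    """One canonical SINEUP pair plus near-miss geometries and same-class
    overlapping pairs, on a dedicated scaffold."""
    scf = "A_sineup"
    genome_a[scf] = _random_dna(rng, 30_000)

    def place(tid, strand, start, end):
        assert end - start == _SINEUP_LENGTHS[tid]
        placements_a[tid] = GenomePlacement(scaffold=scf, strand=strand,
                                            start=start, end=end,
                                            blocks=((start, end),))

    # canonical: divergent (head-to-head) overlap at 4500-5000 with the
    # SINE in the lncRNA's non-overlapping tail
    place("sl1", "-", 2000, 5000)
    place("sm1", "+", 4500, 7500)
    # tail-to-tail: opposite strands, 3'/3' overlap
    place("sm2", "+", 10_000, 12_000)
    place("sl2", "-", 11_500, 13_500)
    # head-to-head but the SINE lies inside the overlap
    place("sl3", "-", 16_000, 19_000)
    place("sm3", "+", 18_500, 21_000)
    # same-class overlaps: counted, never SINEUP candidates
    place("sm4", "+", 23_000, 25_000)
    place("sm5", "-", 24_500, 26_500)
    place("sl4", "+", 27_000, 28_200)
    place("sl5", "-", 28_000, 29_200)
    manifest.sineup_truth = {
        "canonical": [["sm1", "sl1"]],
        "tail_to_tail": [["sm2", "sl2"]],
        "sine_inside": [["sm3", "sl3"]],
    }


def sineup_fragments() -> List[RepeatFragment]:
    """Repeat fragments for the planted SINEUP layout, in transcript
    coordinates consistent with the genomic placements."""
    return [
        # sl1 spans genome 2000-5000 on '-', overlap 4500-5000; transcript
        # coordinate 0 sits at genomic 5000, so transcript 1000-1200 maps
        # to genomic 3800-4000: outside the overlap.
        RepeatFragment(transcript_id="sl1", q_begin=1001, q_end=1200,
                       consensus_name="SINE_OCT", repeat_class="SINE/Octo",
                       c_begin=1, c_end=200, c_left=100, strand="+"),
        # sl3 spans 16000-19000 on '-'; overlap 18500-19000; transcript
        # 200-400 maps to genomic 18600-18800: wholly inside the overlap.
        RepeatFragment(transcript_id="sl3", q_begin=201, q_end=400,
                       consensus_name="SINE_OCT", repeat_class="SINE/Octo",
                       c_begin=1, c_end=200, c_left=100, strand="+"),
    ]


# ---------------------------------------------------------------------------
# integration-site fixture

IS_SAMPLES = ("OB1_SUB", "OB1_GILL", "OB2_SUB", "OB2_GILL")

#: The sharing partition planted in the fixture: 25 sites in all four
#: samples, 15 in both tissues of the first individual, 9 in both of the
#: second, 3 in the SUB of the first individual only (putative somatic),
#: 3 split across individuals but not tissues (inconsistent).
IS_PATTERNS = (
    (25, ("OB1_SUB", "OB1_GILL", "OB2_SUB", "OB2_GILL")),
    (15, ("OB1_SUB", "OB1_GILL")),
    (9, ("OB2_SUB", "OB2_GILL")),
    (3, ("OB1_SUB",)),
    (3, ("OB1_SUB", "OB2_GILL")),
)


def is_fixture_design() -> SampleDesign:
    return SampleDesign(samples=[
        SampleInfo("OB1_SUB", "OB1", "SUB", 50_000_000),
        SampleInfo("OB1_GILL", "OB1", "GILL", 50_000_000),
        SampleInfo("OB2_SUB", "OB2", "SUB", 50_000_000),
        SampleInfo("OB2_GILL", "OB2", "GILL", 50_000_000),
    ])


def paper_pattern_fixture():
    """Deterministic IS call set: 55 filter-eligible records with the
    planted presence patterns plus 10 decoys, each violating exactly one
    filter.  Returns (sites, design, scaffold_lengths, consensus_hits)."""
    design = is_fixture_design()
    scaffold_lengths = {"scf_main": 60_000, "scf_short": 8_000}
    consensus_hits = [("scf_main", 40_000, 41_000)]
    sites: List[IntegrationSiteRecord] = []

    def record(pos, present, scaffold="scf_main", status="PASS", left=4, right=4):
        presence = {s: ("present" if s in present else "absent") for s in IS_SAMPLES}
        sites.append(IntegrationSiteRecord(
            scaffold=scaffold, position=pos, element="RTE", filter_status=status,
            left_support=left, right_support=right, sample_presence=presence,
            site_id=f"IS{len(sites) + 1:03d}"))

    pos, i = 1000, 0
    for count, present in IS_PATTERNS:
        for _ in range(count):
            # supports cycle through values >= 3, touching the boundary
            record(pos, present, left=3 + i % 3, right=3 + (i + 1) % 5)
            pos += 500
            i += 1

    all4 = IS_SAMPLES  # decoys: exactly one violated filter each
    record(pos + 0, all4, status="lc")                # failed an upstream check
    record(pos + 500, all4, status="hDP")
    record(pos + 1000, all4, left=2, right=5)         # left side under-supported
    record(pos + 1500, all4, left=2, right=4)
    record(pos + 2000, all4, left=5, right=2)         # right side under-supported
    record(pos + 2500, all4, left=4, right=2)
    record(pos + 3000, all4, scaffold="scf_short")    # short scaffold
    record(pos + 3500, all4, scaffold="scf_short")
    record(40_050, all4)                              # consensus copy 50 bp away
    record(40_980, all4)
    return sites, design, scaffold_lengths, consensus_hits


def _pattern_category(site, design: SampleDesign) -> str:
    present = {s for s, v in site.sample_presence.items() if v == "present"}
    if present == set(design.sample_ids):
        return "common_all"
    if len(present) == 1:
        return "sample_specific"
    for ind in design.individuals:
        ind_samples = {s.sample_id for s in design.samples if s.individual == ind}
        if present == ind_samples:
            return "individual_specific"
    return "inconsistent"


# ---------------------------------------------------------------------------
# qPCR

_QPCR_FOLDS = {"SEM": 1.1, "SUB": 1.8, "OL": 1.0, "ARM": 1.0}


def _simulate_qpcr(rng, config, manifest):
    """Ct tables whose 2^-ddCt analysis recovers a planted SUB-enriched
    element copy number; the first individual's ARM is the calibrator."""
    measurements = []
    for i in range(1, config.n_individuals + 1):
        for part in config.parts:
            calibrator = (i == 1 and part == "ARM")
            fold = 1.0 if calibrator else (
                _QPCR_FOLDS.get(part, 1.0) * float(np.exp(rng.normal(0, 0.03))))
            sid = f"O{i}_{part}"
            ref_ct = float(rng.uniform(14, 16))
            target_ct = ref_ct + 8.0 - float(np.log2(fold))
            measurements.append(QpcrMeasurement(sample_id=sid, target_ct=target_ct,
                                                reference_ct=ref_ct, calibrator=calibrator))
            manifest.qpcr_fold[sid] = fold
    return measurements


# ---------------------------------------------------------------------------
# bundle writer

def write_bundle(bundle: SyntheticBundle, outdir) -> Dict[str, Path]:
    """Write the complete directory layout consumed by the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {key: outdir / name for key, name in {
        "transcripts": "transcripts.fasta",
        "transcripts_b": "transcripts_b.fasta",
        "consensus": "consensus_library.fasta",
        "counts": "counts.tsv",
        "design": "design.tsv",
        "repeats": "repeats.out",
        "hits_protein": "hits_protein.tsv",
        "hits_domain": "hits_domain.tsv",
        "hits_rrna": "hits_rrna.tsv",
        "hits_ncrna": "hits_ncrna.tsv",
        "hits_ab": "hits_ab.tsv",
        "hits_ba": "hits_ba.tsv",
        "genome_a": "genome_a.fasta",
        "genome_b": "genome_b.fasta",
        "placements_a": "placements_a.gff3",
        "placements_b": "placements_b.gff3",
        "is_vcf": "is_calls.vcf",
        "is_design": "is_design.tsv",
        "is_consensus_hits": "is_consensus_hits.tsv",
        "qpcr": "qpcr.tsv",
        "manifest": "manifest.json",
    }.items()}
    formats.write_fasta(bundle.transcripts, paths["transcripts"])
    formats.write_fasta(bundle.transcripts_b, paths["transcripts_b"])
    formats.write_consensus_library(bundle.consensus_models, paths["consensus"])
    formats.write_counts_tsv(bundle.counts, paths["counts"])
    formats.write_design_tsv(bundle.design, paths["design"])
    formats.write_repeatmasker_out(bundle.fragments + sineup_fragments(), paths["repeats"])
    for tag in ("protein", "domain", "rrna", "ncrna"):
        formats.write_hit_table([h for h in bundle.hits if h.database_tag == tag],
                                paths[f"hits_{tag}"])
    formats.write_hit_table(bundle.hits_ab, paths["hits_ab"])
    formats.write_hit_table(bundle.hits_ba, paths["hits_ba"])
    formats.write_genome_fasta(bundle.genome_a, paths["genome_a"])
    formats.write_genome_fasta(bundle.genome_b, paths["genome_b"])
    formats.write_placements_gff3(bundle.placements_a, paths["placements_a"])
    formats.write_placements_gff3(bundle.placements_b, paths["placements_b"])
    formats.write_is_vcf(bundle.is_sites, bundle.is_design,
                         bundle.is_scaffold_lengths, paths["is_vcf"])
    formats.write_design_tsv(bundle.is_design, paths["is_design"])
    pd.DataFrame(bundle.is_consensus_hits,
                 columns=["scaffold", "start", "end"]).to_csv(
        paths["is_consensus_hits"], sep="\t", index=False)
    pd.DataFrame(
        [(m.sample_id, round(m.target_ct, 4), round(m.reference_ct, 4), int(m.calibrator))
         for m in bundle.qpcr],
        columns=["sample_id", "target_ct", "reference_ct", "calibrator"],
    ).to_csv(paths["qpcr"], sep="\t", index=False)
    bundle.manifest.to_json(paths["manifest"])
    return paths
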