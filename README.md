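# tentacle

Post-assembly computational analysis of octopus neural transcriptomes.

Octopuses carry an unusually repeat-rich genome, and their de novo
neural transcriptomes mix protein-coding transcripts with thousands of
putative long non-coding RNAs (lncRNAs) and pervasive transposable-
element (TE) fragments — including, potentially, full-length
retrotransposons still competent for mobilization. `tentacle`
implements the downstream analysis stack for this setting as a tested,
reusable library with a thin CLI: everything after assembly, read
mapping and the similarity searches (whose outputs it consumes as
standard files).

## What it computes

- **Expression filtering and peaks.** CPM normalization
  (counts / library size × 10⁶); transcriptome retention at ≥ 0.5 CPM
  in ≥ 2 samples (a 1 CPM / 1 sample variant is provided); per-part
  expressed sets (> 0.5 CPM in every replicate of a part); and
  expression peaks (> 0.5 CPM in all replicates of exactly one part,
  < 0.5 everywhere else).
- **Stringent lncRNA classification.** A transcript is a putative
  lncRNA only if length ≥ 200 nt, no protein/domain/rRNA/small-ncRNA
  similarity at e ≤ 10⁻⁵, longest ORF (six-frame, no start-codon
  requirement) < 100 aa, and non-coding potential score ≥ 0.95. The
  score is an injectable input with a documented deterministic
  ORF-density baseline.
- **Repeat content and full-length LINE detection.** RepeatMasker
  `.out` summarization with per-class interval-union nucleotide totals;
  a transcript is a full-length autonomous LINE candidate when it
  covers ≥ 80% of a repeat consensus, carries a complete strict-mode
  ORF (ATG…canonical stop), and shows endonuclease plus reverse-
  transcriptase domains (zinc finger recorded, never required).
- **Cross-species conservation.** Reciprocal-best-hit orthologs from
  tabular similarity hits; 1000-nt promoter extraction upstream of the
  TSS (strand-aware, skipped where the scaffold lacks room); global
  Needleman–Wunsch alignment with a ≥ 50% identity conservation call
  and a seeded derangement-randomization null; exact binomial
  enrichment tests; Welch t-tests; and positional conservation (shared
  scaffold fraction over scaffolds with ≥ 10 mapped transcripts).
- **SINEUP candidate search.** Head-to-head (divergent) mRNA/lncRNA
  overlaps with a SINE fragment in the non-overlapping part of the
  lncRNA — the canonical SINEUP architecture.
- **Mobile-element insertion-site (IS) activity.** MELT-style VCF
  filtering (PASS, ≥ 3 discordant pairs on both breakpoint sides,
  scaffold ≥ 10 kb, no element-consensus copy within a 260-bp window
  around the breakpoint); a 2-individual × 2-tissue sharing partition
  into germline-common / individual-specific / single-sample (putative
  somatic) / inconsistent; per-individual count comparison; and
  2^−ΔΔCt qPCR copy-number arithmetic.
- **Synthetic data.** `tentacle.synthio` generates fully
  self-consistent datasets (transcripts, counts, repeat annotation,
  hit tables, genomes, placements, IS VCFs, Ct tables) with a
  ground-truth manifest, so every stage is exercised without any
  downloads.

## Worked example

```bash
tentacle simulate --seed 7 --out data
tentacle report --data-dir data --out-dir results --seed 7
```

The report (`results/report.json`) on this seed reads, in part:

```
expression: retained 298 of 313 transcripts, 9 expression peaks
repeats:    full_length_elements ['t00301'], interspersed_fraction 0.103
conserve:   rbh_pairs 100, promoter_pairs 99,
            conserved_promoter_fraction 0.545, random_conserved_fraction 0.0
sineup:     mrna_lncrna_pairs 2, canonical_candidates 1
activity:   sites_raw 65, sites_filtered 55,
            common_all 25, individual_specific 24,
            sample_specific 3, inconsistent 3
```

Reading: the low-expression transcripts were discarded; the single
planted full-length LINE (`t00301`, a 4530-nt transcript whose 3327-nt
ORF translates to 1109 aa with EN/RT/ZF domains) is the only full-length
verdict while its 5′-truncated copies fall below the 80% consensus-
coverage gate; the reciprocal-best-hit map is recovered exactly and
about half of the promoter pairs clear 50% identity while no randomized
pair does; one transcript pair has the canonical SINEUP architecture;
and of the 65 insertion-site calls, 55 pass the filters and partition
into 25 shared by all four samples, 24 individual-specific, 3 putative
somatic (one tissue of one individual) and 3 inconsistent.

Note that the `lncrna` stage above uses the deterministic baseline
coding-potential score; supply trained-classifier scores via the
`ncpotential_scores` config key for real analyses (the test suite
demonstrates exact recovery of the planted lncRNA set when oracle
scores are provided).

## Layout

```
src/tentacle/
  models.py        shared domain objects (0-based half-open internally)
  formats.py       FASTA / GFF3 / RepeatMasker .out / hit-table / VCF / TSV I/O
  expression.py    CPM, retention filter, per-part expression, peaks
  orf.py           six-frame ORF scanning (permissive & strict), translation
  lncrna.py        the five-criterion classifier
  repeats.py       repeat summaries, consensus coverage, full-length LINEs
  conservation.py  RBH, promoters, randomization null, positional conservation
  sineup.py        head-to-head overlap geometry and SINE placement
  activity.py      IS filtering, sharing partition, 2^-ddCt
  synthio.py       synthetic-data generator + truth manifest
  pipeline.py      stage orchestration, config, combined report
  cli.py           `tentacle` command group
```

See `docs/methods.md` for the modeling choices, parameter defaults and
known limitations.
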