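# Methods

This note documents the models, conventions and defaults behind
`tentacle`, the choices made where the procedure was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. GFF3, RepeatMasker
`.out` and VCF use 1-based conventions and are converted at the I/O
boundary; repeat fragments retain their native 1-based fields and
expose converted intervals as properties, so a written file is
bit-identical to its source. On RepeatMasker complement-strand rows the
consensus columns arrive as `(left) end begin` and are normalized to
`c_begin <= c_end`. RepeatMasker class/family strings map to seven
summary classes (retroelement, DNA transposon, satellite, simple
repeat, low complexity, other, unknown) through an explicit editable
table; unmapped strings become "Unknown" with a logged warning.
Similarity hits are the 12-column tabular dialect; e-values accept
`10e-5`-style notation. The insertion-site reader takes the
per-side discordant-pair support from configurable INFO keys (default
`LP`/`RP`), since callers differ in where they record it.

## Expression

CPM uses library sizes equal to the column sums of the raw, pre-filter
count matrix. Two inequality conventions coexist deliberately: the
transcriptome retention filter is inclusive (≥ 0.5 CPM in ≥ 2 samples;
the single-sample variant is ≥ 1 CPM in ≥ 1), while per-part
expression and peak detection are strict (> 0.5 in every replicate of
the part, < 0.5 in every replicate of every other part for a peak). A
replicate sitting exactly at the threshold therefore disqualifies a
peak. The pooled-CPM percentile helper uses linear interpolation
between order statistics, the most common convention.

## ORF scanning

Permissive mode reports the longest stop-free codon run in any frame;
strict mode requires an ATG start and a canonical stop (TAA/TAG/TGA)
inside the sequence — ORFs running off the transcript end are reported
only permissively. Reported nucleotide extents exclude the stop codon,
so `nt_length = 3 × aa_length`; this is the only convention consistent
with a 3327-nt ORF translating to 1109 residues. The default is a
six-frame scan (assemblies from non-strand-specific libraries);
three-frame scanning is available for stranded inputs. Ties break on
the lowest frame index (+1, +2, +3, −1, −2, −3) then the lowest start
position — a fixed convention, since external ORF finders do not
document theirs. Codons containing N translate to X and are treated as
sense codons during scanning.

## lncRNA classification

The classifier is a conjunction: length ≥ 200 nt AND no
protein/domain/rRNA/small-ncRNA hit at e ≤ 1e-5 AND longest permissive
ORF < 100 aa (exclusive) AND non-coding potential ≥ 0.95 (inclusive).
"No hit" is judged at the same e-value cutoff the searches were run
with; no second threshold is introduced. Transcripts failing the rule
with a protein hit are "coding"; the remainder are "other" (a label of
this package — borderline transcripts are neither confidently coding
nor confidently non-coding). The non-coding potential is deliberately
an injectable input: trained coding-potential classifiers are
species- and training-set-specific, and the contribution here is the
conjunction rule. The built-in baseline, `1 − min(1, ORF_nt/length)`,
is deterministic and transparent but coarse; published lncRNA fractions
should not be expected from it.

## Repeats and full-length elements

Consensus coverage is the interval union of a transcript's fragments on
the consensus divided by consensus length — union, not sum, is the only
choice bounded by 1 (whether the original analyses merged fragments is
not documented; union is this package's decision). Full-length
candidacy requires coverage ≥ 0.8; the verdict additionally requires a
complete strict-mode ORF and both endonuclease (EN) and reverse
transcriptase (RT) domain evidence from a consumed domain-hit table,
mapped through a configurable keyword table. The C2H2 zinc finger is
recorded but never required, being rare in RTE-clade LINEs. When all
fragments for a transcript×consensus lie on one strand, the ORF must
lie on that strand. Catalytic-residue verification is left to manual
inspection, as in practice.

Masked-nucleotide totals are per-class interval unions per transcript;
interspersed content excludes simple repeats, low-complexity and
satellite annotation. Repeat segregation reports, per body part, the
fraction of that part's expressed transcripts carrying ≥ 1 fragment of
a class (a transcript counts once however many fragments it has);
empty expressed sets yield NaN rather than silent zeros.

## Conservation

Orthologs are reciprocal best hits; "best" is highest bitscore with
ties broken by lower e-value then lexicographic subject id, making the
result order-independent. Promoters are the 1000 nt upstream of the
TSS, strand-aware; transcripts without that much upstream scaffold are
skipped, never truncated. Global alignment uses Needleman–Wunsch with
match +1, mismatch −1, gap open −5, gap extend −2 — the scoring scheme
is not dictated by the method itself but the 50% identity verdict
depends on it, so it is explicit and configurable. Identity divides
matching columns by all alignment columns including gap columns (the
strictest common convention; a match-columns-only option exists). The
randomization null re-pairs species-A promoters with species-B
promoters of other pairs via seeded derangements, so no true pair can
enter the null; its size defaults to the number of real pairs.

The promoter enrichment test is a one-sided (greater) exact binomial
test of the noncoding conserved count against the coding proportion as
p0. On the published promoter counts (171/2451 noncoding vs 712/15493
coding) this arithmetic gives p ≈ 9e-8; the originally reported value
(5.3e-7) evidently used a different, unstated null convention, so only
the order of magnitude — strong enrichment — is reproducible.
Positional conservation considers species-A scaffolds with ≥ 10 mapped
transcripts and reports both the mean per-scaffold fraction of ortholog
partners co-located on a single (modal) species-B scaffold and the
pooled fraction, since the aggregation used originally is ambiguous.

## SINEUP architecture

"Head-to-head" is operationalized as opposite strands with both
transcripts' 5′ ends inside the genomic overlap (divergent geometry);
no base-pair tolerance is applied by default, with a configurable 5′
window slack. SINE membership means RepeatMasker major class "SINE" of
any family. Fragments are lifted from transcript to genome coordinates
through the placement's exon blocks, strand-aware; only fragments
entirely outside the overlap count toward canonicity.

## Insertion-site activity

Filters: PASS status, ≥ 3 discordant pairs on *both* breakpoint sides
(inclusive), scaffold ≥ 10 kb, and no element-consensus alignment
intersecting a 260-bp window around the breakpoint. "A range of 260 bp
around" is read literally as a window of total width 260 (± 130);
± 260 is available by configuration. Sharing classification on a
2-individual × 2-tissue design assigns each of the 15 possible nonzero
presence patterns to exactly one of: common to all four samples,
individual-specific (both tissues of exactly one individual),
sample-specific (one sample only — the putative somatic class), or
inconsistent (any other pattern). Missing genotypes count as absent
but are logged so the class remains auditable. The per-individual
count comparison is a two-sided exact binomial test of the raw count
split against the split expected from the supplied normalizers
(defaulting to mapped reads per individual, reported per million).
qPCR copy number uses 2^−ΔΔCt with one pre-averaged measurement per
sample and a single calibrator.

## Synthetic data generator

`synthio.simulate` draws everything from one `numpy` generator seeded
by the config, making bundles byte-reproducible. Defaults describe the
study conditions where those exist — four body parts (SEM, SUB, OL,
ARM) × three individuals, ~33% coding / ~12% lncRNA composition, a
LINE with a 1109-aa ORF, ~600-nt UTRs and a 3′ microsatellite, the
55-site sharing pattern (25/15/9/3/3) — and desk-scale choices
elsewhere: 300 core transcripts, negative-binomial counts with mean 30
and dispersion 0.3 (the standard bulk-RNA-seq noise family; the
original work did not model counts), 96 syntenic ortholog pairs plus 4
scaffold-edge pairs, a promoter mixture of 15%-diverged "conserved"
and 70%-diverged "diverged" pairs at weight 0.5, and a 3% peak
fraction.

Construction guarantees replace rejection sampling: noncoding
sequences intersperse a 12-mer stop cassette (`TTAATTAATTAA`, its own
reverse complement, containing a stop in all six frames) so no frame
can hold a long ORF, and the cassette placed immediately before the
planted ATG makes the LINE's strict ORF exactly the planted one.
Coding transcripts embed complete ORFs of 150–400 aa built from sense
codons and carry planted protein hits. Expression profiles (brain /
periphery / broad / peak / silent) drive both the count means and the
repeat-class planting probabilities, implementing the brain bias of
lncRNA expression and SINE content. Profiles are designed so that only
planted peak transcripts are single-part by construction (periphery
profiles stay visible in the optic lobe), which is what makes the
planted peak set exactly identifiable. Planted-peak means are ≥ 25
counts, so every target replicate clears 0.5 CPM with probability
> 0.99 at the bundled library sizes.

What the generator does **not** emulate: read-level noise and mapping
ambiguity, assembly chimerism and fragmentation, homology structure
inside sequences (hit tables are synthesized, not computed by
alignment), GC/length biases, isoforms, and real TE family phylogenies.
Passing recovery tests therefore demonstrates the correctness of the
decision rules and their boundary behavior on well-formed inputs — not
robustness to upstream artifacts of real data, and not the published
dataset-level totals (64,477 transcripts, 7,806 lncRNAs, 33,322 RBHs,
883 conserved promoters), which require the original accessions.

## Problem sizes and numerics

Default test and acceptance runs use 300-transcript bundles, ~100
ortholog pairs with 1000-nt promoters, and the 65-record insertion-site
fixture; the full pipeline completes in seconds on one core. Exhaustive
alignment-oracle checks cover all sequence pairs up to length 6 over a
two-letter alphabet; ORF scanning is verified against brute-force
enumeration on 1000 random sequences up to 120 nt. Degenerate inputs
fail loudly: empty FASTA, zero library sizes, unknown scaffolds,
missing scores, absent calibrators and all-absent insertion sites raise
errors naming the offender rather than propagating silently.

## Known limitations

* The baseline non-coding potential is intentionally naive; without
  external scores the lncRNA call is very conservative.
* The SINEUP 5′-end rule has no slack by default; assemblies with
  ragged 5′ ends will under-call head-to-head geometry unless
  `five_prime_slack` is raised.
* Promoter conservation verdicts depend on the alignment scoring
  configuration; comparisons across runs are only meaningful at fixed
  scoring.
* The sharing partition assumes exactly two individuals × two tissues;
  other designs need a generalized classifier.
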