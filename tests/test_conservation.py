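"""Orthology, promoter conservation and positional conservation."""

import itertools

import numpy as np
import pytest

from oracles import align_identity_oracle, binom_p_greater
from tentacle.conservation import (
    AlignmentScoring,
    extract_promoter,
    global_identity,
    identity_comparison,
    mapping_filter,
    positional_conservation,
    promoter_conservation,
    promoter_enrichment_test,
    reciprocal_best_hits,
)
from tentacle.models import GenomePlacement, HitRecord
from tentacle.orf import reverse_complement


def hit(q, s, bitscore, evalue=1e-20):
    return HitRecord(query_id=q, subject_id=s, percent_identity=90.0,
                     align_len=100, mismatches=0, gap_opens=0, q_start=1,
                     q_end=100, s_start=1, s_end=100, evalue=evalue,
                     bitscore=bitscore, database_tag="protein")


class TestReciprocalBestHits:
    def test_mutual_best_forms_pair(self):
        pairs = reciprocal_best_hits([hit("A1", "B1", 500)], [hit("B1", "A1", 480)])
        assert [(p.id_a, p.id_b) for p in pairs] == [("A1", "B1")]

    def test_non_mutual_best_is_no_pair(self):
        ab = [hit("A1", "B1", 500)]
        ba = [hit("B1", "A2", 600), hit("B1", "A1", 400)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_tie_broken_by_evalue_then_subject(self):
        ab = [hit("A1", "B2", 500, evalue=1e-10), hit("A1", "B1", 500, evalue=1e-30)]
        ba = [hit("B1", "A1", 500)]
        pairs = reciprocal_best_hits(ab, ba)
        assert [(p.id_a, p.id_b) for p in pairs] == [("A1", "B1")]

    def test_symmetric_under_species_swap(self, bundle):
        fwd = reciprocal_best_hits(bundle.hits_ab, bundle.hits_ba)
        rev = reciprocal_best_hits(bundle.hits_ba, bundle.hits_ab)
        assert {(p.id_a, p.id_b) for p in fwd} == {(p.id_b, p.id_a) for p in rev}

    def test_recovers_planted_map_despite_decoys(self, bundle):
        pairs = reciprocal_best_hits(bundle.hits_ab, bundle.hits_ba)
        assert {p.id_a: p.id_b for p in pairs} == bundle.manifest.ortholog_map


class TestExtractPromoter:
    GENOME = {"scf": "".join(
        np.array(list("ACGT"))[np.random.default_rng(0).integers(0, 4, 8000)])}

    def test_plus_strand_window(self):
        p = GenomePlacement(scaffold="scf", strand="+", start=5000, end=6000)
        assert extract_promoter(p, self.GENOME) == self.GENOME["scf"][4000:5000]

    def test_minus_strand_is_reverse_complement_downstream(self):
        p = GenomePlacement(scaffold="scf", strand="-", start=1000, end=6000)
        expected = reverse_complement(self.GENOME["scf"][6000:7000])
        assert extract_promoter(p, self.GENOME) == expected

    def test_insufficient_upstream_is_skipped_not_truncated(self):
        p = GenomePlacement(scaffold="scf", strand="+", start=500, end=900)
        assert extract_promoter(p, self.GENOME) is None

    def test_exactly_enough_upstream_kept(self):
        p = GenomePlacement(scaffold="scf", strand="+", start=1000, end=1400)
        assert len(extract_promoter(p, self.GENOME)) == 1000

    def test_unplaced_transcript_skipped(self):
        assert extract_promoter(None, self.GENOME) is None


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("ACGT" * 250, "ACGT" * 250) == 100.0

    def test_single_mismatch_four_mer(self):
        assert global_identity("ACGT", "ACGA") == 75.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
            b = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")

    def test_exhaustive_oracle_on_short_two_letter_sequences(self):
        """Identity matches an exhaustive affine-gap alignment oracle on
        every pair of sequences up to length 6 over {A, C}."""
        seqs = []
        for L in range(1, 7):
            seqs += ["".join(p) for p in itertools.product("AC", repeat=L)]
        for a, b in itertools.combinations_with_replacement(seqs, 2):
            _, pcts = align_identity_oracle(a, b)
            got = global_identity(a, b)
            assert any(abs(got - p) < 1e-6 for p in pcts), (a, b, got, pcts)


class TestPromoterConservation:
    def make_pairs(self, rng, n=30, weight=0.5, conserved_rate=0.15,
                   diverged_rate=0.7):
        bases = np.array(list("ACGT"))
        pairs, labels = [], []
        for i in range(n):
            a = "".join(bases[rng.integers(0, 4, 500)])
            conserved = rng.random() < weight
            rate = conserved_rate if conserved else diverged_rate
            arr = np.array(list(a))
            k = int(rate * len(arr))
            pos = rng.choice(len(arr), size=k, replace=False)
            for p in pos:
                arr[p] = bases[(list("ACGT").index(arr[p]) + 1) % 4]
            pairs.append((f"a{i}", f"b{i}", a, "".join(arr)))
            labels.append(conserved)
        return pairs, labels

    def test_planted_mixture_recovered(self):
        rng = np.random.default_rng(8)
        pairs, labels = self.make_pairs(rng, n=40)
        res = promoter_conservation(pairs, seed=1)
        assert res.conserved_fraction == pytest.approx(np.mean(labels))
        for pair, label in zip(res.pairs, labels):
            assert pair.conserved == label

    def test_random_pairs_never_conserved(self):
        rng = np.random.default_rng(9)
        pairs, _ = self.make_pairs(rng, n=30, weight=0.0, diverged_rate=0.75)
        res = promoter_conservation(pairs, n_random=60, seed=2)
        assert res.random_conserved_fraction <= 0.01

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(10)
        pairs, _ = self.make_pairs(rng, n=10)
        r1 = promoter_conservation(pairs, seed=7)
        r2 = promoter_conservation(pairs, seed=7)
        assert r1.random_conserved_fraction == r2.random_conserved_fraction

    def test_n_random_must_be_positive(self):
        rng = np.random.default_rng(11)
        pairs, _ = self.make_pairs(rng, n=3)
        with pytest.raises(ValueError):
            promoter_conservation(pairs, n_random=0, seed=1)


class TestEnrichmentTest:
    def test_null_proportion_gives_large_p(self):
        assert promoter_enrichment_test(10, 100, 100, 1000) >= 0.4

    def test_published_counts_are_strongly_enriched(self):
        # noncoding 171/2451 vs coding 712/15493 conserved promoters
        assert promoter_enrichment_test(171, 2451, 712, 15493) < 1e-4

    def test_matches_enumeration_for_small_n(self):
        for n in range(1, 21):
            for k in range(n + 1):
                got = promoter_enrichment_test(k, n, 3, 10)
                assert got == pytest.approx(binom_p_greater(k, n, 0.3), abs=1e-12)

    def test_zero_coding_denominator_rejected(self):
        with pytest.raises(ValueError):
            promoter_enrichment_test(1, 10, 0, 0)


class TestIdentityComparison:
    def test_identical_samples(self):
        m1, m2, t, p = identity_comparison([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(12)
        a = rng.normal(93.3, 2.0, size=3000)
        b = rng.normal(92.1, 2.0, size=3000)
        m1, m2, t, p = identity_comparison(a, b)
        assert m1 > m2 and p < 1e-10

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
        _, _, t1, p1 = identity_comparison(a, b)
        _, _, t2, p2 = identity_comparison(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestMappingFilter:
    def place(self, cov, ident):
        return GenomePlacement(scaffold="s", strand="+", start=0, end=10,
                               coverage_fraction=cov, identity_fraction=ident)

    @pytest.mark.parametrize("cov,ident,kept", [
        (0.90, 0.90, True),   # inclusive at both bounds
        (0.89, 0.99, False),
        (0.99, 0.89, False),
        (1.00, 1.00, True),
    ])
    def test_boundaries(self, cov, ident, kept):
        got = mapping_filter({"t": self.place(cov, ident)})
        assert ("t" in got) is kept

    def test_idempotent(self, bundle):
        once = mapping_filter(bundle.placements_a)
        assert mapping_filter(once) == once


class TestPositionalConservation:
    def test_perfect_synteny_on_bundle(self, bundle):
        pairs = reciprocal_best_hits(bundle.hits_ab, bundle.hits_ba)
        res = positional_conservation(bundle.placements_a, bundle.placements_b, pairs)
        assert res.per_scaffold_mean == 1.0
        assert res.pooled_fraction == 1.0

    def test_scaffold_below_minimum_ignored(self, bundle):
        pairs = reciprocal_best_hits(bundle.hits_ab, bundle.hits_ba)
        res = positional_conservation(bundle.placements_a, bundle.placements_b,
                                      pairs, min_transcripts=10)
        # the 4-transcript edge scaffold must not contribute
        assert res.n_scaffolds == sum(
            1 for s in {p.scaffold for p in bundle.placements_a.values()}
            if sum(q.scaffold == s for q in bundle.placements_a.values()) >= 10
            and s != "A_sineup")

    def test_permuted_partners_approach_random_expectation(self, bundle):
        """Scattering the species-B partners across scaffolds drops the
        co-location fraction to the permutation oracle's expectation."""
        rng = np.random.default_rng(3)
        pairs = reciprocal_best_hits(bundle.hits_ab, bundle.hits_ba)
        b_ids = sorted(bundle.placements_b)
        scaffolds = sorted({p.scaffold for p in bundle.placements_b.values()})
        shuffled = {}
        for bid in b_ids:
            orig = bundle.placements_b[bid]
            shuffled[bid] = GenomePlacement(
                scaffold=str(rng.choice(scaffolds)), strand=orig.strand,
                start=orig.start, end=orig.end)
        res = positional_conservation(bundle.placements_a, shuffled, pairs)
        # permutation oracle: expectation of the modal-bin fraction
        sims = []
        for _ in range(300):
            draws = rng.integers(0, len(scaffolds), size=12)
            counts = np.bincount(draws, minlength=len(scaffolds))
            sims.append(counts.max() / 12)
        assert res.per_scaffold_mean < 1.0
        assert abs(res.per_scaffold_mean - np.mean(sims)) < 0.15

    def test_no_qualifying_scaffold_raises(self):
        placements = {"t1": GenomePlacement(scaffold="s", strand="+", start=0, end=10)}
        with pytest.raises(ValueError, match="no scaffold"):
            positional_conservation(placements, {}, [], min_transcripts=10)


def test_identity_denominator_convention_switchable():
    scoring = AlignmentScoring(identity_denominator="aligned")
    # one gap column: 'AC' vs 'A' aligns A-A with C gapped
    strict = global_identity("AC", "A")
    aligned_only = global_identity("AC", "A", scoring)
    assert strict == 50.0 and aligned_only == 100.0
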