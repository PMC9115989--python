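"""Insertion-site filtering, sharing partition and qPCR arithmetic."""

import itertools

import numpy as np
import pytest

from oracles import binom_p_twosided
from tentacle.activity import (
    CATEGORIES,
    QpcrMeasurement,
    classify_sharing,
    compare_individuals,
    ddct,
    filter_sites,
    sharing_counts,
)
from tentacle.models import IntegrationSiteRecord
from tentacle.synthio import is_fixture_design

LENGTHS = {"big": 50_000, "small": 8_000}
SAMPLES = ("OB1_SUB", "OB1_GILL", "OB2_SUB", "OB2_GILL")


def site(pos=5000, scaffold="big", status="PASS", left=4, right=4,
         present=SAMPLES):
    return IntegrationSiteRecord(
        scaffold=scaffold, position=pos, element="RTE", filter_status=status,
        left_support=left, right_support=right,
        sample_presence={s: ("present" if s in present else "absent")
                         for s in SAMPLES},
        site_id=f"s{pos}")


class TestFilterSites:
    def keep(self, s, hits=()):
        return filter_sites([s], hits, LENGTHS) == [s]

    def test_boundary_support_kept(self):
        assert self.keep(site(left=3, right=3))

    @pytest.mark.parametrize("left,right", [(5, 2), (2, 5), (2, 2), (3, 2), (0, 9)])
    def test_both_sides_required(self, left, right):
        assert not self.keep(site(left=left, right=right))

    def test_non_pass_dropped(self):
        assert not self.keep(site(status="lc"))

    def test_short_scaffold_dropped(self):
        assert not self.keep(site(scaffold="small"))

    def test_scaffold_length_boundary_inclusive(self):
        assert filter_sites([site(scaffold="small")], [], {"small": 10_000})

    def test_consensus_copy_inside_window_dropped(self):
        # annotated element copy 50 bp from the breakpoint, window +/- 130
        assert not self.keep(site(pos=5000), hits=[("big", 5050, 5400)])

    def test_consensus_copy_outside_window_kept(self):
        assert self.keep(site(pos=5000), hits=[("big", 5200, 5400)])

    def test_unknown_scaffold_raises(self):
        with pytest.raises(KeyError):
            filter_sites([site(scaffold="mystery")], [], LENGTHS)

    def test_idempotent_and_order_invariant(self, is_fixture):
        sites = is_fixture["sites"]
        kwargs = dict(consensus_hits=is_fixture["consensus_hits"],
                      scaffold_lengths=is_fixture["scaffold_lengths"])
        once = filter_sites(sites, **kwargs)
        assert filter_sites(once, **kwargs) == once
        rev = filter_sites(list(reversed(sites)), **kwargs)
        assert sorted(s.site_id for s in rev) == sorted(s.site_id for s in once)


class TestClassifySharing:
    DESIGN = is_fixture_design()

    def expected_category(self, present):
        """Independent statement of the partition rule."""
        ind1 = {"OB1_SUB", "OB1_GILL"}
        ind2 = {"OB2_SUB", "OB2_GILL"}
        if present == ind1 | ind2:
            return "common_all"
        if len(present) == 1:
            return "sample_specific"
        if present in (ind1, ind2):
            return "individual_specific"
        return "inconsistent"

    def test_all_fifteen_nonzero_patterns(self):
        """Exhaustive: every possible presence pattern maps to exactly
        one category, matching an independently stated rule."""
        for r in range(1, 5):
            for present in itertools.combinations(SAMPLES, r):
                (call,) = classify_sharing([site(present=present)], self.DESIGN)
                assert call.category == self.expected_category(set(present))
                assert call.category in CATEGORIES

    def test_sample_specific_records_individual_and_part(self):
        (call,) = classify_sharing([site(present=("OB1_SUB",))], self.DESIGN)
        assert (call.category, call.individual, call.part) == \
            ("sample_specific", "OB1", "SUB")

    def test_individual_specific_records_individual(self):
        (call,) = classify_sharing([site(present=("OB2_SUB", "OB2_GILL"))],
                                   self.DESIGN)
        assert (call.category, call.individual) == ("individual_specific", "OB2")

    def test_cross_individual_single_tissues_inconsistent(self):
        (call,) = classify_sharing([site(present=("OB1_SUB", "OB2_GILL"))],
                                   self.DESIGN)
        assert call.category == "inconsistent"

    def test_absent_everywhere_raises(self):
        with pytest.raises(ValueError, match="present in no sample"):
            classify_sharing([site(present=())], self.DESIGN)

    def test_missing_counts_as_absent_with_log(self, caplog):
        s = site(present=("OB1_SUB", "OB1_GILL"))
        s.sample_presence["OB2_SUB"] = "missing"
        with caplog.at_level("WARNING"):
            (call,) = classify_sharing([s], self.DESIGN)
        assert call.category == "individual_specific"
        assert any("missing" in r.message for r in caplog.records)

    def test_categories_partition_any_input(self):
        rng = np.random.default_rng(17)
        sites = []
        for i in range(60):
            k = int(rng.integers(1, 5))
            present = tuple(rng.choice(SAMPLES, size=k, replace=False))
            sites.append(site(pos=1000 + i, present=present))
        calls = classify_sharing(sites, self.DESIGN)
        counts = sharing_counts(calls)
        assert counts["total"] == len(sites)
        assert len(calls) == len(sites)


class TestCompareIndividuals:
    def test_balanced_counts_give_large_p(self):
        _, _, p = compare_individuals(40, 40, 1e6, 1e6)
        assert p >= 0.9

    def test_strong_imbalance_detected(self):
        _, _, p = compare_individuals(500, 50, 1e6, 1e6)
        assert p < 1e-10

    def test_normalizer_scale_invariance(self):
        a = compare_individuals(30, 50, 2e6, 3e6)
        b = compare_individuals(30, 50, 4e6, 6e6)
        assert a[2] == pytest.approx(b[2])

    def test_matches_enumeration_oracle(self):
        for n_a in range(0, 15):
            n_b = 14 - n_a
            _, _, p = compare_individuals(n_a, n_b, 1e6, 2e6)
            assert p == pytest.approx(binom_p_twosided(n_a, 14, 1 / 3), rel=1e-9)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            compare_individuals(10, 10, 0, 1e6)


class TestDdct:
    def test_calibrator_maps_to_one(self):
        ms = [QpcrMeasurement("cal", 20.0, 15.0, calibrator=True),
              QpcrMeasurement("same", 22.0, 17.0)]
        folds = ddct(ms)
        assert folds["cal"] == 1.0 and folds["same"] == pytest.approx(1.0)

    @pytest.mark.parametrize("ddct_shift,expected", [(1.0, 0.5), (-1.0, 2.0)])
    def test_closed_form(self, ddct_shift, expected):
        ms = [QpcrMeasurement("cal", 20.0, 15.0, calibrator=True),
              QpcrMeasurement("x", 20.0 + ddct_shift, 15.0)]
        assert ddct(ms)["x"] == pytest.approx(expected)

    def test_random_table_matches_hand_arithmetic(self):
        rng = np.random.default_rng(21)
        ms = [QpcrMeasurement("cal", 20.0, 15.0, calibrator=True)]
        for i in range(10):
            ms.append(QpcrMeasurement(f"s{i}", float(rng.uniform(18, 25)),
                                      float(rng.uniform(14, 16))))
        folds = ddct(ms)
        dct_cal = 20.0 - 15.0
        for m in ms:
            expected = 2.0 ** (-((m.target_ct - m.reference_ct) - dct_cal))
            assert folds[m.sample_id] == pytest.approx(expected)

    def test_recovers_planted_copy_number(self, bundle):
        folds = ddct(bundle.qpcr)
        for sid, fold in bundle.manifest.qpcr_fold.items():
            assert folds[sid] == pytest.approx(fold, rel=1e-3)

    def test_missing_calibrator_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            ddct([QpcrMeasurement("x", 20.0, 15.0)])

    def test_duplicate_sample_rejected(self):
        ms = [QpcrMeasurement("x", 20.0, 15.0, calibrator=True),
              QpcrMeasurement("x", 21.0, 15.0)]
        with pytest.raises(ValueError, match="pre-average"):
            ddct(ms)
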