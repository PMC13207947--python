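"""Tier contingency tables, severity-margin histogram, sensitivity run."""

import math

import numpy as np
import pytest

from cardiorisk.engagement import PharmProfile, evaluate_profile
from cardiorisk.io import Concern, DrugRecord, Severity
from cardiorisk.summary import (
    DEFAULT_LOG10_BINS,
    ClassifiedDrug,
    contingency,
    sensitivity_run,
    severity_margin_table,
)
from cardiorisk.synthetic import fixture_from_counts
from cardiorisk.targets import AssignmentRule, PanelAssignment, TargetClass, tier_membership


def _entry(name, concern, panel, severity=Severity.NONE, profile=None):
    record = DrugRecord(raw_name=name, generic_name=name, concern=concern, severity=severity)
    assignment = PanelAssignment(name, panel, AssignmentRule.DIRECT)
    result = None
    if profile is not None and profile.affinity_nM is not None:
        result = evaluate_profile(profile)
    return ClassifiedDrug(record=record, assignment=assignment, profile=profile, result=result)


class TestContingency:
    def test_printed_most_concern_proportion(self):
        entries = fixture_from_counts({Concern.MOST: (276, 51)})
        summary = contingency(entries, 1)
        assert summary.counts[Concern.MOST] == (276, 51)
        assert summary.percent_mapped(Concern.MOST) == 84

    def test_single_unmapped_drug(self):
        entries = fixture_from_counts({Concern.NO: (0, 1)})
        assert contingency(entries, 1).percent_mapped(Concern.NO) == 0

    def test_empty_concern_has_no_percentage(self):
        assert contingency([], 1).percent_mapped(Concern.MOST) is None

    def test_matches_brute_force_count(self, rng):
        for _ in range(20):
            counts = {
                c: (int(rng.integers(0, 50)), int(rng.integers(0, 50))) for c in Concern
            }
            entries = fixture_from_counts(counts)
            rng.shuffle(entries)
            for tier in (1, 2, 3):
                summary = contingency(entries, tier)
                for concern in Concern:
                    mapped = sum(
                        1
                        for e in entries
                        if e.record.concern is concern and tier_membership(e.assignment, tier)
                    )
                    total = sum(1 for e in entries if e.record.concern is concern)
                    assert summary.counts[concern] == (mapped, total - mapped)

    def test_order_invariance(self, rng):
        entries = fixture_from_counts({Concern.MOST: (5, 3), Concern.NO: (2, 7)})
        shuffled = list(entries)
        rng.shuffle(shuffled)
        assert contingency(entries, 2).counts == contingency(shuffled, 2).counts

    def test_tier_percentages_monotone_nonincreasing(self):
        entries = (
            fixture_from_counts({Concern.MOST: (10, 2)})
            + [
                _entry(f"s{i}", Concern.MOST, TargetClass.STATIN)
                for i in range(4)
            ]
            + [
                _entry(f"g{i}", Concern.MOST, TargetClass.GABA)
                for i in range(3)
            ]
        )
        percents = [contingency(entries, t).percent_mapped(Concern.MOST) for t in (1, 2, 3)]
        assert percents == sorted(percents, reverse=True)


def _margin_entry(name, severity, margin):
    # affinity 100 nM, no protein binding: Cmax = margin * affinity
    profile = PharmProfile(name, affinity_nM=100.0, ppb=0.0, cmax_total_nM=100.0 * margin)
    return _entry(name, Concern.MOST, TargetClass.HERG, severity=severity, profile=profile)


class TestSeverityMarginTable:
    def test_one_drug_per_severity_and_bin(self):
        entries = [
            _margin_entry("a", Severity.MILD, 0.1),
            _margin_entry("b", Severity.MODERATE, 1.5),
            _margin_entry("c", Severity.SEVERE, 15.0),
        ]
        table = severity_margin_table(entries)
        assert table.n_drugs == 3
        for sev in (Severity.MILD, Severity.MODERATE, Severity.SEVERE):
            assert sum(table.counts[sev]) == 1
        # margins 0.1, 1.5, 15 land in the [-1,0), [0,1), [1,2) bins
        assert table.counts[Severity.MILD][DEFAULT_LOG10_BINS.index(-1.0)] == 1
        assert table.counts[Severity.MODERATE][DEFAULT_LOG10_BINS.index(0.0)] == 1
        assert table.counts[Severity.SEVERE][DEFAULT_LOG10_BINS.index(1.0)] == 1

    def test_equal_margins_fall_in_one_bin(self):
        entries = [_margin_entry(f"d{i}", Severity.SEVERE, 3.0) for i in range(5)]
        table = severity_margin_table(entries)
        assert max(table.counts[Severity.SEVERE]) == 5

    def test_empty_input(self):
        table = severity_margin_table([])
        assert table.counts == {} and table.n_drugs == 0

    def test_mean_log10_margin_reported(self):
        entries = [
            _margin_entry("a", Severity.SEVERE, 10.0),
            _margin_entry("b", Severity.SEVERE, 1000.0),
        ]
        table = severity_margin_table(entries)
        assert table.mean_log10_margin[Severity.SEVERE] == pytest.approx(2.0)

    def test_matches_brute_force_binning(self, rng):
        entries = [
            _margin_entry(f"d{i}", Severity(rng.choice(["mild", "moderate", "severe"])),
                          float(10 ** rng.uniform(-3.5, 1.5)))
            for i in range(60)
        ]
        table = severity_margin_table(entries)
        edges = list(DEFAULT_LOG10_BINS)
        for sev in set(e.record.severity for e in entries):
            expected = [0] * (len(edges) - 1)
            for e in entries:
                if e.record.severity is not sev:
                    continue
                lm = math.log10(e.margin)
                for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
                    if lo <= lm < hi:
                        expected[i] += 1
                        break
            assert table.counts[sev] == expected
        assert table.n_drugs == len(entries)


class TestSensitivityRun:
    def test_missing_ppb_imputed_at_half(self):
        profile = PharmProfile("x", affinity_nM=100.0, cmax_total_nM=200.0)
        entry = _entry("x", Concern.MOST, TargetClass.HERG, profile=profile)
        _, report, imputed = sensitivity_run([entry])
        assert report.imputed_ppb == ["x"]
        assert imputed[0].profile.cmax_unbound_nM == pytest.approx(100.0)
        assert imputed[0].result.margin == pytest.approx(1.0)

    def test_missing_cmax_excluded_from_margins_but_counted(self):
        profile = PharmProfile("x", affinity_nM=100.0, ppb=0.5)
        entry = _entry("x", Concern.MOST, TargetClass.HERG, profile=profile)
        summaries, report, imputed = sensitivity_run([entry])
        assert report.excluded_cmax == ["x"]
        assert imputed[0].result is not None and imputed[0].result.margin is None
        assert summaries[1].counts[Concern.MOST] == (1, 0)

    def test_missing_affinity_flagged_curve_only(self):
        entry = _entry("x", Concern.LESS, TargetClass.COX, profile=PharmProfile("x"))
        summaries, report, _ = sensitivity_run([entry])
        assert report.curve_only == ["x"]
        assert summaries[1].counts[Concern.LESS] == (1, 0)

    def test_complete_subset_is_noop(self):
        profile = PharmProfile("x", affinity_nM=10.0, ppb=0.2, cmax_total_nM=50.0)
        entry = _entry("x", Concern.MOST, TargetClass.HERG, profile=profile)
        summaries, report, imputed = sensitivity_run([entry])
        assert report.imputed_ppb == [] and report.excluded_cmax == [] and report.curve_only == []
        assert imputed[0].profile == profile
        assert summaries[1].counts == contingency([entry], 1).counts

    def test_classification_counts_unchanged_by_imputation(self, classified):
        summaries, _, _ = sensitivity_run(classified)
        for tier in (1, 2, 3):
            assert summaries[tier].counts == contingency(classified, tier).counts
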