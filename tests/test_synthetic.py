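"""Synthetic dataset generator: determinism, marginals, ground truth."""

import math

import pandas as pd
import pytest

from cardiorisk.io import Concern, consolidate_records, parse_dictrank_table
from cardiorisk.pipeline import annotations_from_frame, run_pipeline
from cardiorisk.summary import contingency
from cardiorisk.synthetic import (
    SyntheticConfig,
    fixture_from_counts,
    generate,
    replica_rank_table,
)
from cardiorisk.targets import TargetClass, tier_membership

def _small_cfg(**kwargs):
    n = {Concern.MOST: 80, Concern.LESS: 100, Concern.AMBIGUOUS: 30, Concern.NO: 80}
    return SyntheticConfig(n_per_concern=n, seed=kwargs.pop("seed", 3), **kwargs)


class TestGenerate:
    def test_same_seed_is_bit_identical(self):
        a, b = generate(_small_cfg()), generate(_small_cfg())
        pd.testing.assert_frame_equal(a.dictrank, b.dictrank)
        pd.testing.assert_frame_equal(a.annotations, b.annotations)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a, b = generate(_small_cfg(seed=1)), generate(_small_cfg(seed=2))
        assert not a.truth.equals(b.truth)

    def test_concern_marginals_exact(self):
        cfg = _small_cfg(duplicate_rate=0.0)
        data = generate(cfg)
        counts = data.truth.concern.value_counts().to_dict()
        assert counts == {c.value: n for c, n in cfg.n_per_concern.items()}

    def test_full_availability_no_duplicates_consolidation_is_identity(self, tmp_path):
        cfg = _small_cfg(
            availability_ppb=1.0,
            availability_affinity=1.0,
            availability_cmax=1.0,
            duplicate_rate=0.0,
        )
        data = generate(cfg)
        assert not data.truth[["masked_ppb", "masked_affinity", "masked_cmax"]].any().any()
        ann = data.annotations
        assert (ann.affinity.astype(str).str.len() > 0).all()
        assert (ann.cmax.astype(str).str.len() > 0).all()
        path = tmp_path / "d.csv"
        data.dictrank.to_csv(path, index=False)
        records, _ = parse_dictrank_table(path)
        assert len(consolidate_records(records).records) == len(records)

    def test_duplicates_consolidate_back_to_unique_count(self, tmp_path):
        cfg = _small_cfg(duplicate_rate=0.1)
        data = generate(cfg)
        n_unique = len(data.truth)
        assert len(data.dictrank) == n_unique + round(0.1 * n_unique)
        path = tmp_path / "d.csv"
        data.dictrank.to_csv(path, index=False)
        records, _ = parse_dictrank_table(path)
        assert len(consolidate_records(records).records) == n_unique

    def test_herg_drugs_carry_qt_keywords(self):
        data = generate(_small_cfg())
        herg = set(data.truth[data.truth.true_class == TargetClass.HERG.value].generic_name)
        kw = dict(zip(data.dictrank["Drug Name"].str.lower(), data.dictrank["Keywords"]))
        for name in herg:
            assert "qt" in str(kw[name]).lower()

    def test_mapped_fraction_within_binomial_error(self):
        n = {c: 2000 for c in Concern}
        cfg = SyntheticConfig(n_per_concern=n, seed=11)
        data = generate(cfg)
        for concern, p in cfg.p_mapped_per_concern.items():
            sub = data.truth[data.truth.concern == concern.value]
            se = math.sqrt(p * (1 - p) / len(sub))
            assert abs(sub.mapped_tier1.mean() - p) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(availability_ppb=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(p_mapped_per_concern={Concern.MOST: -0.1})

    def test_pipeline_recovers_true_classification(self, tmp_path):
        """End to end: ingest -> classify recovers the generated panels."""
        cfg = _small_cfg(duplicate_rate=0.0)
        data = generate(cfg)
        path = tmp_path / "d.csv"
        data.dictrank.to_csv(path, index=False)
        records, _ = parse_dictrank_table(path)
        classified = run_pipeline(records, annotations_from_frame(data.annotations))
        truth_class = dict(zip(data.truth.generic_name, data.truth.true_class))
        for entry in classified:
            assert entry.assignment.panel.value == truth_class[entry.record.generic_name]


class TestFixtureFromCounts:
    def test_printed_proportion_reproduced(self):
        entries = fixture_from_counts({Concern.MOST: (276, 51)})
        assert contingency(entries, 1).percent_mapped(Concern.MOST) == 84

    def test_all_zero_counts_empty(self):
        assert fixture_from_counts({c: (0, 0) for c in Concern}) == []

    def test_round_trip_property(self, rng):
        for _ in range(25):
            counts = {
                c: (int(rng.integers(0, 40)), int(rng.integers(0, 40))) for c in Concern
            }
            entries = fixture_from_counts(counts)
            assert contingency(entries, 1).counts == counts

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fixture_from_counts({Concern.MOST: (-1, 0)})

    def test_tier_nesting_holds_for_fixture(self):
        entries = fixture_from_counts({Concern.MOST: (5, 5)})
        for e in entries:
            t1, t2, t3 = (tier_membership(e.assignment, t) for t in (1, 2, 3))
            assert (not t3 or t2) and (not t2 or t1)


class TestReplicaRankTable:
    def test_duplicate_structure(self, tmp_path):
        unique = {Concern.MOST: 10, Concern.LESS: 12, Concern.AMBIGUOUS: 4, Concern.NO: 9}
        raw = {Concern.MOST: 13, Concern.LESS: 12, Concern.AMBIGUOUS: 5, Concern.NO: 11}
        df = replica_rank_table(unique, raw)
        assert len(df) == sum(raw.values())
        path = tmp_path / "r.csv"
        df.to_csv(path, index=False)
        records, _ = parse_dictrank_table(path)
        consolidated = consolidate_records(records).records
        assert len(consolidated) == sum(unique.values())

    def test_raw_below_unique_rejected(self):
        with pytest.raises(ValueError):
            replica_rank_table({Concern.MOST: 5}, {Concern.MOST: 3})
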