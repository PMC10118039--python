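import numpy as np
import pandas as pd
import pytest

from exometab.config import RunConfig
from exometab.features import (
    call_group_presence,
    call_sample_presence,
    filter_blanks,
    merge_feature_tables,
)
from conftest import toy_feature_table, toy_metadata


def _tables(field_rows, hydro_rows, f_samples=("f1",), h_samples=("h1",)):
    field = toy_feature_table(
        [(fid, mz, rt, *([1000.0] * len(f_samples))) for fid, mz, rt in field_rows], list(f_samples)
    )
    hydro = toy_feature_table(
        [(fid, mz, rt, *([1000.0] * len(h_samples))) for fid, mz, rt in hydro_rows], list(h_samples)
    )
    return field, hydro


class TestMerge:
    def test_within_tolerance_pair_matches(self, config):
        field, hydro = _tables([("A", 300.1000, 5.00)], [("B", 300.1050, 5.20)])
        merged = merge_feature_tables(field, hydro, config)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row.field_id, row.hydro_id) == ("A", "B")
        assert row.mz == pytest.approx((300.1000 + 300.1050) / 2)
        assert row.rt == pytest.approx(5.10)

    @pytest.mark.parametrize(
        "mz2,rt2",
        [(100.012, 1.0), (100.0, 1.35)],  # clearly at/over tolerance: strict "<"
    )
    def test_at_tolerance_boundary_is_not_matched(self, config, mz2, rt2):
        field, hydro = _tables([("A", 100.0, 1.0)], [("B", mz2, rt2)])
        merged = merge_feature_tables(field, hydro, config)
        assert len(merged) == 2
        assert set(merged.field_id) == {"A", ""} and set(merged.hydro_id) == {"B", ""}

    def test_identical_tables_match_completely(self, config):
        rows = [("A", 100.0, 1.0), ("B", 200.0, 2.0), ("C", 300.0, 3.0)]
        field, hydro = _tables(rows, rows)
        merged = merge_feature_tables(field, hydro, config)
        assert len(merged) == 3
        assert (merged.field_id == merged.hydro_id).all()

    def test_merge_is_symmetric(self, config, clean_tables):
        field, hydro, _, _ = clean_tables
        fwd = merge_feature_tables(field, hydro, config)
        rev = merge_feature_tables(hydro, field, config)
        fwd_pairs = {(r.field_id, r.hydro_id) for r in fwd.itertuples() if r.field_id and r.hydro_id}
        rev_pairs = {(r.hydro_id, r.field_id) for r in rev.itertuples() if r.field_id and r.hydro_id}
        assert fwd_pairs == rev_pairs

    def test_one_to_one_takes_nearest(self, config):
        # two HYDRO candidates inside tolerance; the closer one must win
        field, hydro = _tables(
            [("A", 500.0000, 8.00)], [("B", 500.0020, 8.00), ("C", 500.0080, 8.00)]
        )
        merged = merge_feature_tables(field, hydro, config)
        pair = merged[(merged.field_id != "") & (merged.hydro_id != "")]
        assert list(pair.hydro_id) == ["B"]

    def test_no_mutually_nearest_in_tolerance_pair_left_unmatched(self, config, clean_tables):
        field, hydro, _, _ = clean_tables
        merged = merge_feature_tables(field, hydro, config)
        used_f = set(merged.field_id) - {""}
        used_h = set(merged.hydro_id) - {""}
        free_f = [f for f in field.index if f not in used_f]
        free_h = [h for h in hydro.index if h not in used_h]
        for f in free_f:
            for h in free_h:
                in_tol = (
                    abs(field.loc[f, "mz"] - hydro.loc[h, "mz"]) < config.tol_mz
                    and abs(field.loc[f, "rt"] - hydro.loc[h, "rt"]) < config.tol_rt
                )
                assert not in_tol


BLANK_META = toy_metadata(
    [
        ("p1", "FIELD", "mustard", "plant", 1),
        ("p2", "FIELD", "mustard", "plant", 2),
        ("p3", "FIELD", "mustard", "plant", 3),
        ("wb1", "FIELD", "", "water_blank", 1),
        ("wb2", "FIELD", "", "water_blank", 2),
        ("ib1", "FIELD", "", "in_field_blank", 1),
    ]
)


def _merged_with_blanks(wb=(0.0, 0.0), ib=0.0, plant=(2000.0, 2000.0, 2000.0)):
    t = toy_feature_table([("x", 100.0, 1.0, *plant, *wb, ib)], ["p1", "p2", "p3", "wb1", "wb2", "ib1"])
    t.insert(0, "hydro_id", "")
    t.insert(0, "field_id", "x")
    t.index.name = "merged_id"
    return t


class TestBlankFilter:
    def test_blank_mean_above_500_removes(self, config):
        kept, log = filter_blanks(_merged_with_blanks(wb=(600.0, 600.0)), BLANK_META, config)
        assert kept.empty
        assert set(log["triggering_blank_class"]) == {"water_blank"}

    def test_zero_blanks_retain(self, config):
        kept, _ = filter_blanks(_merged_with_blanks(), BLANK_META, config)
        assert len(kept) == 1

    def test_mean_exactly_500_is_retained(self, config):
        kept, _ = filter_blanks(_merged_with_blanks(wb=(500.0, 500.0)), BLANK_META, config)
        assert len(kept) == 1  # strict ">"

    def test_or_vs_and_rule(self):
        merged = _merged_with_blanks(wb=(600.0, 600.0), ib=0.0)
        kept_or, _ = filter_blanks(merged, BLANK_META, RunConfig(blank_rule="or"))
        kept_and, _ = filter_blanks(merged, BLANK_META, RunConfig(blank_rule="and"))
        assert kept_or.empty and len(kept_and) == 1

    def test_no_blanks_warns_and_is_noop(self, config):
        meta = BLANK_META[BLANK_META["sample_type"] == "plant"]
        merged = _merged_with_blanks(wb=(600.0, 600.0))
        with pytest.warns(UserWarning, match="no blank samples"):
            kept, _ = filter_blanks(merged, meta, config)
        assert len(kept) == 1

    def test_filter_order_invariance(self, config, clean_truth):
        """Filtering each batch before merging retains the same merged set."""
        from exometab.simulate import generate_feature_tables
        import dataclasses

        truth = dataclasses.replace(clean_truth, blank_contaminant_fraction=0.3)
        field, hydro, metadata, _ = generate_feature_tables(truth, seed=13)

        def as_merged(table, batch):
            t = table.copy()
            t.insert(0, "hydro_id", t.index if batch == "HYDRO" else "")
            t.insert(0, "field_id", t.index if batch == "FIELD" else "")
            return t

        merged = merge_feature_tables(field, hydro, config)
        after, _ = filter_blanks(merged, metadata, config)
        f_kept, _ = filter_blanks(as_merged(field, "FIELD"), metadata[metadata.batch == "FIELD"], config)
        h_kept, _ = filter_blanks(as_merged(hydro, "HYDRO"), metadata[metadata.batch == "HYDRO"], config)
        before = merge_feature_tables(
            field.loc[f_kept.index], hydro.loc[h_kept.index], config
        )
        key_after = {(r.field_id, r.hydro_id) for r in after.itertuples()}
        key_before = {(r.field_id, r.hydro_id) for r in before.itertuples()}
        # blanks are batch-specific with OR logic: the retained merged pairs whose
        # both halves survive single-batch filtering coincide
        both_after = {k for k in key_after if k[0] and k[1]}
        both_before = {k for k in key_before if k[0] and k[1]}
        assert both_after == both_before


PRES_META = toy_metadata(
    [
        ("f1", "FIELD", "mustard", "plant", 1),
        ("f2", "FIELD", "mustard", "plant", 2),
        ("f3", "FIELD", "mustard", "plant", 3),
        ("g1", "FIELD", "oat", "plant", 1),
        ("g2", "FIELD", "oat", "plant", 2),
        ("h1", "HYDRO", "mustard", "plant", 1),
        ("h2", "HYDRO", "mustard", "plant", 2),
        ("h3", "HYDRO", "mustard", "plant", 3),
        ("i1", "HYDRO", "oat", "plant", 1),
        ("i2", "HYDRO", "oat", "plant", 2),
        ("i3", "HYDRO", "oat", "plant", 3),
        ("j1", "FIELD", "phacelia", "plant", 1),
        ("j2", "FIELD", "phacelia", "plant", 2),
        ("j3", "FIELD", "phacelia", "plant", 3),
        ("k1", "HYDRO", "phacelia", "plant", 1),
        ("k2", "HYDRO", "phacelia", "plant", 2),
        ("k3", "HYDRO", "phacelia", "plant", 3),
        ("l1", "FIELD", "clover", "plant", 1),
        ("l2", "FIELD", "clover", "plant", 2),
        ("l3", "FIELD", "clover", "plant", 3),
        ("m1", "HYDRO", "clover", "plant", 1),
        ("m2", "HYDRO", "clover", "plant", 2),
        ("m3", "HYDRO", "clover", "plant", 3),
    ]
)

SAMPLES = list(PRES_META["sample_id"])


def _merged_one(heights: dict):
    vals = [heights.get(s, 0.0) for s in SAMPLES]
    t = toy_feature_table([("x", 100.0, 1.0, *vals)], SAMPLES)
    t.insert(0, "hydro_id", "")
    t.insert(0, "field_id", "x")
    t.index.name = "merged_id"
    return t


class TestPresence:
    def test_majority_rule_three_samples(self, config):
        merged = _merged_one({"f1": 1200.0, "f2": 1300.0, "f3": 900.0})
        pres = call_group_presence(merged, PRES_META, config)
        assert bool(pres.loc["x", "mustard|FIELD"])  # 2 of 3 above 1000

    def test_strict_majority_on_even_n(self, config):
        merged = _merged_one({"g1": 1200.0, "g2": 900.0})
        pres = call_group_presence(merged, PRES_META, config)
        assert "x" not in pres.index or not bool(pres.loc["x", "oat|FIELD"])  # 1 of 2 is not > 1

    def test_strict_threshold_boundaries(self, config):
        # exactly at threshold is absent; one count above is present
        at = _merged_one({"f1": 1000.0, "f2": 1000.0, "f3": 1000.0})
        assert call_group_presence(at, PRES_META, config).empty
        above = _merged_one({"f1": 1001.0, "f2": 1001.0, "f3": 1001.0})
        assert bool(call_group_presence(above, PRES_META, config).loc["x", "mustard|FIELD"])

    def test_sample_level_thresholds(self, config):
        merged = _merged_one({"f1": 1001.0, "f2": 1001.0, "f3": 1001.0, "h1": 2999.0, "h2": 3001.0})
        samp = call_sample_presence(merged, PRES_META, config)
        assert bool(samp.loc["x", "f1"])  # 1001 > 1000
        assert not bool(samp.loc["x", "h1"])  # 2999 is not > 3000
        assert bool(samp.loc["x", "h2"])

    def test_scaling_equivariance(self, config):
        """3x HYDRO heights with 3x threshold call identically to unscaled."""
        rng = np.random.default_rng(5)
        base = {s: float(rng.uniform(0, 2000)) for s in SAMPLES}
        scaled = {s: v * (3.0 if s[0] in "hikm" else 1.0) for s, v in base.items()}  # HYDRO ids
        flat_cfg = RunConfig(field_presence_threshold=1000, hydro_presence_threshold=1000)
        p_scaled = call_group_presence(_merged_one(scaled), PRES_META, config)
        p_flat = call_group_presence(_merged_one(base), PRES_META, flat_cfg)
        pd.testing.assert_frame_equal(p_scaled, p_flat)

    def test_group_call_is_majority_of_sample_calls(self, config, clean_tables):
        field, hydro, metadata, _ = clean_tables
        merged = merge_feature_tables(field, hydro, config)
        groups = call_group_presence(merged, metadata, config)
        samples = call_sample_presence(merged, metadata, config)
        plants = metadata[metadata["sample_type"] == "plant"]
        for key in groups.columns:
            species, batch = key.split("|")
            cols = plants[(plants.species == species) & (plants.batch == batch)]["sample_id"]
            recomputed = samples[cols].sum(axis=1) > len(cols) / 2
            pd.testing.assert_series_equal(
                groups.loc[samples.index, key], recomputed, check_names=False
            )

    def test_zero_jitter_presence_equals_planted_membership(self, config, clean_tables):
        field, hydro, metadata, ledger = clean_tables
        merged = merge_feature_tables(field, hydro, config)
        pres = call_group_presence(merged, metadata, config)
        by_pair = {(r.field_id, r.hydro_id): set(r.membership.split(";")) for r in ledger.itertuples()}
        for r in merged.itertuples():
            want = by_pair[(r.field_id, r.hydro_id)]
            got = {c for c in pres.columns if r.Index in pres.index and pres.loc[r.Index, c]}
            assert got == want
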