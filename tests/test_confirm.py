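import numpy as np
import pandas as pd
import pytest

from poolscan import confirm
from poolscan.bsa_scan import p_from_z
from poolscan.worked_example import matches_printed, table1_demo


class TestFlankingWindow:
    @pytest.fixture()
    def catalog(self):
        return pd.DataFrame(
            {
                "indel_id": ["near", "edge", "outside", "other_chrom"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "pos": [101_000, 114_999, 115_001, 100_000],
            }
        )

    def test_window_boundaries_inclusive(self, catalog):
        hits = confirm.find_flanking_indels("chr1", 100_000, catalog, window_bp=30_000)
        assert hits["indel_id"].tolist() == ["near", "edge"]

    def test_other_chromosome_never_matches(self, catalog):
        hits = confirm.find_flanking_indels("chr2", 100_000, catalog, window_bp=30_000)
        assert hits["indel_id"].tolist() == ["other_chrom"]


class TestIndelIndexTest:
    def test_reproduces_published_p_from_counts_machinery(self, table1):
        # the published confirmation p is the two-sided uncapped tail of z
        p = p_from_z(table1["z_indel"].to_numpy(), sided="two")
        for computed, printed in zip(p, table1["p_indel_printed"]):
            assert matches_printed(computed, printed)

    def test_background_standardisation(self):
        counts = pd.DataFrame(
            {
                "indel_id": ["i1", "i2"],
                "Maa": [90, 88],
                "Mab": [10, 12],
                "Paa": [10, 12],
                "Pab": [90, 88],
            }
        )
        background = np.array([0.0, 0.01, -0.01, 0.005, -0.005])
        out = confirm.indel_index_test(counts, scale="sd", background_deltas=background)
        # both indels have delta = 0.8; z against the tight null background is huge
        assert (out["delta"] > 0.75).all()
        assert (out["z_indel"] > 50).all()

    def test_too_few_defined_indices_rejected(self):
        counts = pd.DataFrame(
            {"indel_id": ["i1"], "Maa": [50], "Mab": [50], "Paa": [50], "Pab": [50]}
        )
        with pytest.raises(ValueError, match="at least 2"):
            confirm.indel_index_test(counts)


class TestClassify:
    def test_published_verdicts_row_by_row(self, table1):
        # zero-printed p values stand for underflow; substitute the computed tail
        p_indel = np.where(
            table1["p_indel"] == 0,
            p_from_z(table1["z_indel"].to_numpy(), sided="two"),
            table1["p_indel"],
        )
        records = table1.assign(p_indel=p_indel)
        out = confirm.classify(records)
        assert ((out["verdict"] == "positive") == table1["published_positive"]).all()
        assert (out["verdict"] == "positive").sum() == 8
        assert (out["verdict"] == "false_discovery").sum() == 6
        positives = set(out.loc[out["verdict"] == "positive", "indel_id"])
        assert positives == {"M3-2", "M4-1", "M6-8", "M7-4", "M8-1", "M9-1", "M13-1", "M14-1"}

    def test_equality_counts_against_the_marker(self):
        out = confirm.classify(
            pd.DataFrame({"p_bsa": [0.01, 0.01], "p_indel": [0.01, 0.0]})
        )
        assert out["verdict"].tolist() == ["false_discovery", "positive"]

    def test_order_independence(self, table1):
        records = table1.assign(
            p_indel=np.where(table1["p_indel"] == 0, 1e-20, table1["p_indel"])
        )
        forward = confirm.classify(records)
        backward = confirm.classify(records.iloc[::-1].reset_index(drop=True))
        merged = forward.merge(backward, on="indel_id", suffixes=("_f", "_b"))
        assert (merged["verdict_f"] == merged["verdict_b"]).all()

    def test_missing_pair_skipped(self):
        out = confirm.classify(
            pd.DataFrame({"p_bsa": [0.01, np.nan], "p_indel": [0.5, 0.001]})
        )
        assert len(out) == 1


class TestFlankSupport:
    def test_fully_linked_flanks_all_significant(self):
        # 100 aa individuals in the low pool, 100 ab in the high pool at
        # every flanking indel: the strong-QTL limit
        catalog = pd.DataFrame(
            {
                "indel_id": [f"i{k}" for k in range(4)],
                "chrom": "chr1",
                "pos": [95_000, 98_000, 102_000, 105_000],
                "Maa": 100, "Mab": 0, "Paa": 50, "Pab": 50,
            }
        )
        catalog["Maa"] = [100, 99, 100, 98]
        catalog["Mab"] = 100 - catalog["Maa"]
        background = np.random.default_rng(0).normal(0, 0.05, 200)
        report = confirm.flank_support(
            "chr1", 100_000, catalog, window_bp=30_000, scale="sd",
            background_deltas=background,
        )
        assert report["n_flanking"] == 4
        assert report["n_significant"] == 4

    def test_null_flanks_rarely_significant(self, rng):
        # flanking indels with no true linkage: 50/50 composition plus noise
        n = 40
        mab = rng.binomial(100, 0.5, n)
        pab = rng.binomial(100, 0.5, n)
        catalog = pd.DataFrame(
            {
                "indel_id": [f"i{k}" for k in range(n)],
                "chrom": "chr1",
                "pos": rng.integers(90_000, 110_000, n),
                "Maa": 100 - mab, "Mab": mab, "Paa": 100 - pab, "Pab": pab,
            }
        )
        background = rng.normal(0, 0.07, 500)
        report = confirm.flank_support(
            "chr1", 100_000, catalog, window_bp=30_000, scale="sd",
            background_deltas=background,
        )
        # roughly alpha * n false significances expected; allow slack
        assert report["n_significant"] <= 10

    def test_empty_flank_report(self):
        catalog = pd.DataFrame({"indel_id": [], "chrom": [], "pos": []})
        report = confirm.flank_support("chr1", 100_000, catalog)
        assert report == {"n_flanking": 0, "n_significant": 0, "indels": []}


class TestWorkedExampleDemo:
    def test_full_reproduction(self):
        report = table1_demo()
        assert report["all_match"]
        assert report["n_positive"] == 8 and report["n_false_discovery"] == 6
        assert report["bh_calls"] == 14
        assert report["bonferroni_calls"] < 14

    def test_perturbed_z_flags_exactly_one_row(self, monkeypatch):
        import poolscan.worked_example as we

        rows = [list(r) for r in we._ROWS]
        rows[4][3] = 0.5  # misstate M5-8's indel z
        monkeypatch.setattr(we, "_ROWS", [tuple(r) for r in rows])
        report = we.table1_demo()
        assert not report["all_match"]
        assert report["mismatched_rows"] == ["M5-8"]

    def test_empty_table_rejected(self, monkeypatch):
        import poolscan.worked_example as we

        monkeypatch.setattr(we, "_ROWS", [])
        with pytest.raises(ValueError, match="empty"):
            we.table1_demo()
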