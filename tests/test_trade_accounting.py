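"""Trade accounting: end-use filtering, re-exports, export allocation."""

import numpy as np
import pandas as pd
import pytest

from nutrisupply import (
    adjust_trade,
    apparent_consumption,
    estimate_reexports,
    filter_human_consumption,
    remove_freshwater_crustaceans,
    subtract_exports,
    to_live_weight,
)
from nutrisupply.errors import ConfigurationError, DataError


def catch_df(rows):
    return pd.DataFrame(rows, columns=["country", "scientific_name", "sector", "end_use", "tonnes"])


def trade_df(rows):
    return pd.DataFrame(rows, columns=["country", "commodity", "flow", "tonnes"])


def fbs_df(rows):
    return pd.DataFrame(rows, columns=["country", "commodity", "tonnes"])


TAXONOMY = pd.DataFrame(
    {
        "scientific_name": ["A", "B", "C"],
        "genus": ["gA", "gB", "gC"],
        "family": ["f", "f", "f2"],
        "order": ["o", "o", "o"],
        "class_": ["k", "k", "k"],
        "commodity": ["m", "m", "crustaceans"],
    }
)


class TestFilterHumanConsumption:
    def test_discard_and_fmfo_rows_are_removed_from_commercial(self):
        catch = catch_df(
            [
                ("X", "A", "industrial", "direct_human_consumption", 10.0),
                ("X", "A", "industrial", "discard", 2.0),
                ("X", "A", "artisanal", "fishmeal_fish_oil", 3.0),
            ]
        )
        out = filter_human_consumption(catch)
        assert out["tonnes"].tolist() == [10.0]

    def test_noncommercial_sectors_pass_through_untouched(self):
        catch = catch_df(
            [
                ("X", "A", "subsistence", "discard", 1.0),
                ("X", "A", "recreational", "direct_human_consumption", 2.0),
            ]
        )
        assert len(filter_human_consumption(catch)) == 2

    def test_all_direct_consumption_is_identity(self):
        catch = catch_df([("X", "A", "industrial", "direct_human_consumption", 5.0)])
        pd.testing.assert_frame_equal(filter_human_consumption(catch), catch)

    def test_unknown_end_use_is_a_data_error(self):
        with pytest.raises(DataError):
            filter_human_consumption(catch_df([("X", "A", "industrial", "bait", 1.0)]))

    def test_random_table_matches_row_filter_oracle(self):
        rng = np.random.default_rng(0)
        uses = ["direct_human_consumption", "fishmeal_fish_oil", "discard"]
        sectors = ["artisanal", "industrial", "subsistence", "recreational"]
        rows = [
            ("X", f"S{i}", sectors[rng.integers(4)], uses[rng.integers(3)],
             float(rng.uniform(0, 100)))
            for i in range(200)
        ]
        catch = catch_df(rows)
        out = filter_human_consumption(catch)
        expected = sum(
            t for (_, _, sec, use, t) in rows
            if use == "direct_human_consumption" or sec in ("subsistence", "recreational")
        )
        assert out["tonnes"].sum() == pytest.approx(expected)


class TestReexports:
    def test_production_covering_exports_means_no_processed_reexports(self):
        trade = trade_df([("X", "m", "export", 10.0)])
        est = estimate_reexports(trade, fbs_df([("X", "m", 25.0)]))
        row = est.iloc[0]
        assert row["processed"] == 0.0 and row["total"] == 0.0

    def test_exports_beyond_production_become_processed_reexports(self):
        trade = trade_df(
            [("X", "m", "export", 30.0), ("X", "m", "reexport_recorded", 2.0)]
        )
        est = estimate_reexports(trade, fbs_df([("X", "m", 25.0)]))
        row = est.iloc[0]
        assert row["recorded"] == 2.0
        assert row["processed"] == 5.0
        assert row["total"] == 7.0

    def test_total_is_capped_at_exports(self):
        trade = trade_df(
            [("X", "m", "export", 4.0), ("X", "m", "reexport_recorded", 6.0)]
        )
        est = estimate_reexports(trade, fbs_df([("X", "m", 0.0)]))
        assert est.iloc[0]["total"] == 4.0

    def test_randomized_tables_match_cellwise_oracle(self):
        rng = np.random.default_rng(1)
        rows, prod_rows = [], []
        for c in ["X", "Y", "Z"]:
            for m in ["m1", "m2"]:
                e, i, r, p = rng.uniform(0, 50, size=4)
                rows += [(c, m, "export", e), (c, m, "import", i),
                         (c, m, "reexport_recorded", r)]
                prod_rows.append((c, m, p))
        est = estimate_reexports(trade_df(rows), fbs_df(prod_rows)).set_index(
            ["country", "commodity"]
        )
        flows = {(c, m, f): t for (c, m, f, t) in rows}
        for c, m, p in prod_rows:
            e = flows[(c, m, "export")]
            r = flows[(c, m, "reexport_recorded")]
            processed = max(0.0, e - p)
            assert est.loc[(c, m), "processed"] == pytest.approx(processed)
            assert est.loc[(c, m), "total"] == pytest.approx(min(r + processed, e))


class TestAdjustTrade:
    def test_zero_reexports_leave_trade_unchanged(self):
        trade = trade_df([("X", "m", "export", 10.0), ("X", "m", "import", 6.0)])
        est = estimate_reexports(trade, fbs_df([("X", "m", 100.0)]))
        adj = adjust_trade(trade, est).iloc[0]
        assert adj["exports_adj"] == 10.0 and adj["imports_adj"] == 6.0

    def test_reexports_equal_to_exports_zero_them(self):
        trade = trade_df(
            [("X", "m", "export", 10.0), ("X", "m", "import", 12.0),
             ("X", "m", "reexport_recorded", 10.0)]
        )
        est = estimate_reexports(trade, fbs_df([("X", "m", 100.0)]))
        adj = adjust_trade(trade, est).iloc[0]
        assert adj["exports_adj"] == 0.0
        assert adj["imports_adj"] == pytest.approx(2.0)

    def test_adjusted_imports_clamp_at_zero(self):
        trade = trade_df(
            [("X", "m", "export", 30.0), ("X", "m", "import", 3.0),
             ("X", "m", "reexport_recorded", 1.0)]
        )
        est = estimate_reexports(trade, fbs_df([("X", "m", 0.0)]))
        adj = adjust_trade(trade, est).iloc[0]
        assert adj["imports_adj"] == 0.0


class TestFreshwaterCrustaceans:
    @pytest.mark.parametrize(
        "fraction,expected", [(0.0, 40.0), (1.0, 0.0), (0.25, 30.0)]
    )
    def test_crustacean_exports_scaled(self, fraction, expected):
        exports = pd.DataFrame(
            {"country": ["X", "X"], "commodity": ["crustaceans", "m"],
             "exports_adj": [40.0, 40.0]}
        )
        out = remove_freshwater_crustaceans(exports, fraction)
        assert out.loc[out["commodity"] == "crustaceans", "exports_adj"].iloc[0] == pytest.approx(expected)
        assert out.loc[out["commodity"] == "m", "exports_adj"].iloc[0] == 40.0

    def test_fraction_outside_unit_interval_is_a_configuration_error(self):
        exports = pd.DataFrame(
            {"country": ["X"], "commodity": ["crustaceans"], "exports_adj": [1.0]}
        )
        with pytest.raises(ConfigurationError):
            remove_freshwater_crustaceans(exports, 1.5)


def test_live_weight_conversion_scales_per_commodity():
    adj = pd.DataFrame(
        {"country": ["X", "X"], "commodity": ["m", "m2"],
         "imports_adj": [10.0, 10.0], "exports_adj": [4.0, 4.0]}
    )
    out = to_live_weight(adj, {"m": 2.0})
    assert out["exports_adj"].tolist() == [8.0, 4.0]
    assert out["imports_adj"].tolist() == [20.0, 10.0]


class TestSubtractExports:
    def production(self):
        return pd.DataFrame(
            {"country": ["X", "X"], "scientific_name": ["A", "B"],
             "sector": ["industrial", "artisanal"], "tonnes": [60.0, 40.0]}
        )

    def exports(self, tonnes):
        return pd.DataFrame(
            {"country": ["X"], "commodity": ["m"], "exports_adj": [tonnes]}
        )

    def test_allocation_is_proportional_to_production(self):
        retained, surplus = subtract_exports(
            self.production(), self.exports(50.0), TAXONOMY,
            ("artisanal", "industrial", "mariculture"),
        )
        got = retained.set_index("scientific_name")["tonnes"]
        assert got["A"] == pytest.approx(30.0)
        assert got["B"] == pytest.approx(20.0)
        assert len(surplus) == 0

    def test_exports_beyond_production_clamp_to_zero_and_report_surplus(self):
        retained, surplus = subtract_exports(
            self.production(), self.exports(120.0), TAXONOMY,
            ("artisanal", "industrial", "mariculture"),
        )
        assert (retained["tonnes"] == 0.0).all()
        assert surplus.iloc[0]["surplus_tonnes"] == pytest.approx(20.0)

    def test_non_exportable_sectors_are_fully_retained(self):
        retained, _ = subtract_exports(
            self.production(), self.exports(50.0), TAXONOMY,
            ("industrial", "mariculture"),
        )
        got = retained.set_index("scientific_name")["tonnes"]
        assert got["B"] == pytest.approx(40.0)  # artisanal untouched
        assert got["A"] == pytest.approx(10.0)  # industrial bears all exports

    def test_unmapped_taxon_is_a_data_error(self):
        prod = self.production()
        prod.loc[0, "scientific_name"] = "unknown"
        with pytest.raises(DataError):
            subtract_exports(prod, self.exports(1.0), TAXONOMY, ("industrial",))

    def test_randomized_allocation_matches_cellwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(1, 6))
            prod = pd.DataFrame(
                {
                    "country": ["X"] * n,
                    "scientific_name": rng.choice(["A", "B"], size=n),
                    "sector": rng.choice(["artisanal", "industrial"], size=n),
                    "tonnes": rng.uniform(0, 100, size=n),
                }
            )
            prod = prod.groupby(["country", "scientific_name", "sector"], as_index=False).sum()
            e = float(rng.uniform(0, 150))
            retained, surplus = subtract_exports(
                prod, self.exports(e), TAXONOMY, ("artisanal", "industrial"),
            )
            pool = prod["tonnes"].sum()
            ratio = min(1.0, e / pool) if pool > 0 else 0.0
            for (_, row), (_, ret) in zip(prod.iterrows(), retained.iterrows()):
                assert ret["tonnes"] == pytest.approx(row["tonnes"] * (1 - ratio))
            expected_surplus = max(0.0, e - pool)
            got_surplus = surplus["surplus_tonnes"].sum() if len(surplus) else 0.0
            assert got_surplus == pytest.approx(expected_surplus)

    def test_mass_balance_retained_plus_allocation_equals_production(self):
        rng = np.random.default_rng(6)
        prod = pd.DataFrame(
            {
                "country": ["X"] * 4,
                "scientific_name": ["A", "A", "B", "C"],
                "sector": ["artisanal", "industrial", "industrial", "artisanal"],
                "tonnes": rng.uniform(1, 100, size=4),
            }
        )
        exports = pd.DataFrame(
            {"country": ["X", "X"], "commodity": ["m", "crustaceans"],
             "exports_adj": [30.0, 5.0]}
        )
        retained, surplus = subtract_exports(
            prod, exports, TAXONOMY, ("artisanal", "industrial"),
        )
        tax = TAXONOMY.set_index("scientific_name")["commodity"]
        for m in ("m", "crustaceans"):
            mask = prod["scientific_name"].map(tax) == m
            pool = prod.loc[mask, "tonnes"].sum()
            ret = retained.loc[mask, "tonnes"].sum()
            e = float(exports.loc[exports["commodity"] == m, "exports_adj"].iloc[0])
            allocated = min(e, pool)
            assert ret + allocated == pytest.approx(pool, rel=1e-12)


class TestApparentConsumption:
    def test_closed_economy_reproduces_production(self):
        retained = pd.DataFrame(
            {"country": ["X"], "scientific_name": ["A"], "sector": ["industrial"],
             "tonnes": [12.0]}
        )
        imports = pd.DataFrame(columns=["country", "commodity", "imports_adj"])
        noncomm = pd.DataFrame(columns=["country", "scientific_name", "sector", "tonnes"])
        out = apparent_consumption(retained, imports, noncomm)
        assert out["tonnes"].tolist() == [12.0]

    def test_subsistence_catch_is_untouched_by_trade(self):
        retained = pd.DataFrame(columns=["country", "scientific_name", "sector", "tonnes"])
        imports = pd.DataFrame(
            {"country": ["X"], "commodity": ["m"], "imports_adj": [7.0]}
        )
        noncomm = pd.DataFrame(
            {"country": ["X"], "scientific_name": ["A"], "sector": ["subsistence"],
             "tonnes": [3.0]}
        )
        out = apparent_consumption(retained, imports, noncomm)
        sub = out[out["sector"] == "subsistence"]
        assert sub["tonnes"].tolist() == [3.0]
        imp = out[out["sector"] == "imports"]
        assert imp["scientific_name"].iloc[0] == "commodity:m"
        assert imp["tonnes"].iloc[0] == 7.0
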