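import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from lomaspulse.community_metrics import (
    campaign_summary,
    ivi,
    ivi_matrix,
    plot_metrics,
    round_for_report,
    shannon,
    top_abundant_species,
)
from lomaspulse.errors import UndefinedIndexError
from oracles import shannon_oracle


def _row(campaign="C1", date="1998-02", plot="P1", zone="low", sp="a", n=1, cover=10.0):
    return (campaign, date, plot, zone, sp, n, cover)


class TestShannonAlpha:
    def test_single_species_zero(self):
        table = make_table([_row(sp="a", n=10, cover=100.0)])
        pm = plot_metrics(table, "C1")
        assert pm.loc[0, "density"] == 10
        assert pm.loc[0, "alpha"] == 0.0

    def test_equiprobable_four_species(self):
        rows = [_row(sp=s, n=5, cover=10.0) for s in "abcd"]
        pm = plot_metrics(make_table(rows), "C1")
        assert pm.loc[0, "alpha"] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_2_1_1(self):
        # p = (0.5, 0.25, 0.25): H = 0.5·1 + 2·(0.25·2) = 1.5 bits
        rows = [_row(sp="a", n=2), _row(sp="b", n=1), _row(sp="c", n=1)]
        pm = plot_metrics(make_table(rows), "C1")
        assert pm.loc[0, "alpha"] == pytest.approx(1.5, abs=1e-12)

    def test_alpha_bounded_by_log2_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 30, size=rng.integers(1, 8))
            assert shannon(counts) <= np.log2(len(counts)) + 1e-12

    @given(
        st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=10),
        st.integers(min_value=2, max_value=7),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, counts, mult):
        assert shannon(counts) == pytest.approx(shannon_oracle(counts), abs=1e-12)
        # replicating every count leaves the index unchanged
        scaled = [c * mult for c in counts]
        assert shannon(scaled) == pytest.approx(shannon(counts), abs=1e-12)


class TestCampaignSummary:
    def test_empty_campaign_all_zero(self):
        # a campaign whose records exist but a second one queried empty:
        # build an empty campaign by flagging a roster with no records
        table = make_table([_row()], roster=["P1", "P2", "P3"])
        s = campaign_summary(table, "C1")
        assert s.density_range[0] == 0.0  # empty plots pull the min to zero

    def test_disjoint_single_species_plots(self):
        rows = [
            _row(plot="P1", sp="a", n=1, cover=5.0),
            _row(plot="P2", sp="b", n=1, cover=5.0),
        ]
        s = campaign_summary(make_table(rows), "C1")
        assert s.richness == 2
        assert s.gamma == pytest.approx(1.0, abs=1e-12)
        assert s.mean_alpha == 0.0

    def test_mean_over_full_roster(self):
        rows = [_row(plot="P1", sp="a", n=10, cover=100.0)]
        s = campaign_summary(make_table(rows, roster=["P1", "P2", "P3", "P4"]), "C1")
        assert s.mean_density == pytest.approx(2.5)
        assert s.mean_cover == pytest.approx(25.0)

    def test_gamma_pooled_vs_plot_oracle(self, sim_default):
        table, _, _ = sim_default
        cid = table.campaign_ids[0]
        recs = table.campaign_records(cid)
        pooled = recs.groupby("species")["abundance"].sum()
        assert campaign_summary(table, cid).gamma == pytest.approx(
            shannon_oracle(pooled.to_list()), abs=1e-12
        )

    def test_gamma_equals_alpha_when_one_plot_nonempty(self):
        rows = [
            _row(sp="a", n=2),
            _row(sp="b", n=1),
            _row(sp="c", n=1),
        ]
        table = make_table(rows, roster=["P1", "P2", "P3"])
        s = campaign_summary(table, "C1")
        assert s.gamma == pytest.approx(1.5, abs=1e-12)
        assert s.gamma == pytest.approx(
            plot_metrics(table, "C1").loc[0, "alpha"], abs=1e-12
        )

    def test_richness_counts_pooled_species(self, small_table):
        assert [
            campaign_summary(small_table, c).richness
            for c in small_table.campaign_ids
        ] == [5, 3, 2]


class TestIVI:
    def test_single_species_unity(self):
        col = ivi(make_table([_row(n=3, cover=50.0)]), "C1")
        assert col.iloc[0] == pytest.approx(1.0)

    def test_symmetric_counts_and_covers(self):
        rows = [_row(sp="a", n=3, cover=10.0), _row(sp="b", n=1, cover=30.0)]
        col = ivi(make_table(rows), "C1")
        assert col["a"] == pytest.approx(0.5)
        assert col["b"] == pytest.approx(0.5)

    def test_columns_sum_to_one(self, sim_default):
        table, _, _ = sim_default
        mat = ivi_matrix(table)
        np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-9)

    def test_entries_in_unit_interval(self, small_table):
        mat = ivi_matrix(small_table)
        assert ((mat.values >= 0) & (mat.values <= 1)).all()

    def test_absent_species_zero(self, small_table):
        mat = ivi_matrix(small_table)
        assert mat.loc["sp_e", "C2"] == 0.0

    def test_cover_scale_invariance(self, small_table):
        base = ivi(small_table, "C1")
        scaled_rows = small_table.records.copy()
        scaled_rows["cover_cm2"] *= 7.5
        from lomaspulse.survey_io import build_survey_table

        scaled = build_survey_table(scaled_rows, list(small_table.plots))
        np.testing.assert_allclose(
            ivi(scaled, "C1").to_numpy(), base.to_numpy(), atol=1e-12
        )

    def test_abundance_scale_equivariance(self, small_table):
        scaled_rows = small_table.records.copy()
        scaled_rows["abundance"] *= 3
        from lomaspulse.survey_io import build_survey_table

        scaled = build_survey_table(scaled_rows, list(small_table.plots))
        np.testing.assert_allclose(
            ivi(scaled, "C1").to_numpy(), ivi(small_table, "C1").to_numpy(), atol=1e-12
        )
        s0 = campaign_summary(small_table, "C1")
        s1 = campaign_summary(scaled, "C1")
        assert s1.mean_alpha == pytest.approx(s0.mean_alpha, abs=1e-12)
        assert s1.gamma == pytest.approx(s0.gamma, abs=1e-12)
        assert s1.mean_density == pytest.approx(3 * s0.mean_density)

    def test_zero_cover_campaign_undefined(self):
        table = make_table([_row(n=2, cover=0.0)])
        with pytest.raises(UndefinedIndexError, match="zero total cover"):
            ivi(table, "C1")

    def test_zero_cover_species_warns(self):
        rows = [_row(sp="a", n=2, cover=0.0), _row(sp="b", n=1, cover=10.0)]
        with pytest.warns(UserWarning, match="zero cover"):
            col = ivi(make_table(rows), "C1")
        assert col.sum() == pytest.approx(1.0)


class TestTopAbundant:
    def test_hyperdominant_first(self):
        rows = [_row(sp="dom", n=90, cover=10.0), _row(sp="rare", n=10, cover=10.0)]
        assert top_abundant_species(make_table(rows), 1) == ["dom"]

    def test_all_species_ranked(self, small_table):
        ranked = top_abundant_species(small_table, 5)
        totals = small_table.records.groupby("species")["abundance"].sum()
        assert len(ranked) == 5
        assert totals[ranked[0]] == totals.max()

    def test_tie_broken_lexicographically(self):
        rows = [_row(sp="zz", n=5, cover=1.0), _row(sp="aa", n=5, cover=1.0)]
        assert top_abundant_species(make_table(rows), 1) == ["aa"]

    def test_k_validation(self, small_table):
        with pytest.raises(ValueError):
            top_abundant_species(small_table, 0)
        with pytest.raises(ValueError):
            top_abundant_species(small_table, 99)


class TestReportRounding:
    @pytest.mark.parametrize(
        "value,characteristic,expected",
        [
            (75.473, "mean_density", 75.5),
            (18912.4, "mean_cover", 18912),
            (1.0499, "mean_alpha", 1.05),
            (2.634, "gamma", 2.63),
        ],
    )
    def test_print_precision(self, value, characteristic, expected):
        assert round_for_report(value, characteristic) == expected
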