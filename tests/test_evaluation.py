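"""Correlation statistics, star notation, and the summary-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earlyvigor._exceptions import SampleSizeError, UndefinedCorrelationError
from earlyvigor.contour import NDIScreen, aggregate
from earlyvigor.datasets import (
    load_reference_contour,
    load_reference_per_date,
    load_reference_summary,
)
from earlyvigor.evaluation import (
    SummaryTable,
    build_summary,
    r2_and_p,
    rank_methods,
    round_half_up,
    significance_stars,
)
from earlyvigor.synthetic import trial_tables


class TestR2AndP:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r2, p, n = r2_and_p(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert n == 10

    def test_hand_dataset_closed_form(self):
        # closed-form Pearson oracle: r2 = 9409/9535
        r2, _, _ = r2_and_p([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.9])
        assert r2 == pytest.approx(9409 / 9535, abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.1, 3.0, 4.2, np.nan]
        _, _, n = r2_and_p(x, y)
        assert n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(SampleSizeError):
            r2_and_p([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            r2_and_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=40)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(0.1, 5),
        seed=st.integers(0, 100),
    )
    def test_symmetry_and_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r2_xy, p_xy, _ = r2_and_p(x, y)
        r2_yx, p_yx, _ = r2_and_p(y, x)
        assert r2_xy == pytest.approx(r2_yx, abs=1e-12)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)
        r2_aff, _, _ = r2_and_p(a + b * x, y)
        assert r2_aff == pytest.approx(r2_xy, abs=1e-9)


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.0005, "***"),
            (0.009, "**"),
            (0.03, "*"),
            (0.05, ""),  # strict inequality at the boundary
            (0.001, "**"),
            (0.5, ""),
        ],
    )
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


def test_round_half_up_display_convention():
    assert round_half_up(0.605) == 0.61
    assert round_half_up(0.615) == 0.62
    assert round_half_up(0.344) == 0.34
    assert round_half_up(-0.605) == -0.61


class TestSummaryFromPerDate:
    def test_example_row_mean_and_cv(self):
        """Per-date R2 {0.31, 0.75, 0.75, 0.61} displays as mean 0.61,
        CV 0.34."""
        st_ = load_reference_summary()
        mean, cv = st_.aggregate_cell("dw", "NDRE")
        assert round_half_up(mean) == 0.61
        assert round_half_up(cv) == 0.34

    def test_contour_gain_ratio_date1(self):
        """Contour max 0.42 over the best established index 0.31 -> 1.35."""
        st_ = load_reference_summary()
        assert st_.ratio_cell("dw", "D1", "vi") == 1.35

    def test_rows_with_unpublished_cells_have_no_aggregates(self):
        st_ = load_reference_summary()
        mean, cv = st_.aggregate_cell("dw", "spectral_unmixing")
        assert np.isnan(mean) and np.isnan(cv)

    def test_equal_values_zero_cv(self):
        df = pd.DataFrame(
            {
                "trait": "dw",
                "method": "m",
                "date": ["D1", "D2", "D3", "D4"],
                "r2": [0.4, 0.4, 0.4, 0.4],
            }
        )
        st_ = SummaryTable.from_per_date(df)
        _, cv = st_.aggregate_cell("dw", "m")
        assert cv == 0.0

    def test_summary_text_renders(self):
        text = load_reference_summary().summary()
        assert "Trait: dw" in text
        assert "contour_map_best" in text
        assert "0.61" in text


@pytest.fixture(scope="module")
def summary(trial, endmembers):
    from earlyvigor.spectra import index_table
    from earlyvigor.unmixing import unmix_trial

    traits, spectra = trial_tables(trial)
    methods = index_table(spectra)
    um = unmix_trial(spectra, {d: endmembers for d in traits["date"].unique()})
    um = um.assign(method="spectral_unmixing", value=um["cover_estimate"])
    cc = traits[["plot_id", "date", "cc_true"]].assign(
        method="canopy_cover"
    ).rename(columns={"cc_true": "value"})
    methods = pd.concat(
        [methods[["plot_id", "date", "method", "value"]],
         um[["plot_id", "date", "method", "value"]],
         cc[["plot_id", "date", "method", "value"]]],
        ignore_index=True,
    )
    mats = []
    for d in ("D1", "D2", "D3", "D4"):
        sub = [s for s in spectra if s.date == d]
        y = traits[traits["date"] == d]["dw_kg_ha"].to_numpy()
        mats.append(NDIScreen(sub, y, trait="dw", date=d).fit())
    aggs = {"dw": aggregate(mats)}
    return build_summary(methods, traits, contour_aggregates=aggs)


class TestBuildSummary:
    def test_canopy_cover_not_correlated_with_itself(self, summary):
        sub = summary.per_date[
            (summary.per_date["trait"] == "cc")
            & (summary.per_date["method"] == "canopy_cover")
        ]
        assert sub.empty

    def test_all_cells_present_for_dw(self, summary):
        sub = summary.per_date[summary.per_date["trait"] == "dw"]
        assert len(sub) == 11 * 4  # 9 indices + unmixing + canopy cover
        assert sub["r2"].notna().all()
        assert sub["stars"].ne("").any()

    def test_ratio_rows_exist_for_contour_trait(self, summary):
        for col in ("D1", "mean"):
            assert np.isfinite(summary.ratio_cell("dw", col, "vi"))

    def test_canopy_cover_beats_indices_on_date1(self, summary):
        ranking = rank_methods(summary, "dw", "D1")
        assert ranking[0] == "canopy_cover"


class TestRankMethods:
    def _table(self, cells):
        df = pd.DataFrame(
            [
                {"trait": "dw", "method": m, "date": "D1", "r2": v}
                for m, v in cells.items()
            ]
        )
        return SummaryTable.from_per_date(df, dates=("D1",))

    def test_descending_order(self):
        st_ = self._table({"a": 0.5, "b": 0.7})
        assert rank_methods(st_, "dw", "D1") == ["b", "a"]

    def test_ties_alphabetical(self):
        st_ = self._table({"zeta": 0.7, "alpha": 0.7, "mid": 0.71})
        assert rank_methods(st_, "dw", "D1") == ["mid", "alpha", "zeta"]

    def test_missing_ranks_last(self):
        st_ = self._table({"a": np.nan, "b": 0.2})
        assert rank_methods(st_, "dw", "D1") == ["b", "a"]

    def test_unknown_trait_rejected(self):
        st_ = self._table({"a": 0.5})
        with pytest.raises(KeyError):
            rank_methods(st_, "nup", "D1")


def test_reference_per_date_table_is_complete():
    df = load_reference_per_date()
    assert set(df["trait"]) == {"dw", "nc", "nup", "cc"}
    # canopy cover is never a predictor of itself
    assert df[(df.trait == "cc") & (df.method == "canopy_cover")].empty
    contour = load_reference_contour()
    assert contour["dw"].mean_pair == (794.0, 736.0)
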