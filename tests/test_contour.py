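"""Exhaustive normalized-difference screening against a brute-force oracle,
aggregation arithmetic and band-group classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from earlyvigor._exceptions import BandRangeError, SampleSizeError
from earlyvigor.contour import (
    ContourMatrix,
    NDIScreen,
    aggregate,
    classify_band_pair,
    cross_trait_compare,
    ndi,
)
from earlyvigor.spectra import Spectrum
from earlyvigor.synthetic import trial_tables

from conftest import make_spectrum


def brute_force_matrix(spectra, y, min_wavelength=400.0):
    """Independent double-loop reimplementation of the screening stage."""
    wl = spectra[0].wavelengths
    keep = wl >= min_wavelength
    bands = wl[keep]
    R = np.stack([s.reflectance[keep] for s in spectra])
    n = bands.size
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            vals = []
            for p in range(R.shape[0]):
                denom = R[p, i] + R[p, j]
                vals.append(np.nan if denom == 0 else (R[p, i] - R[p, j]) / denom)
            vals = np.asarray(vals)
            ok = np.isfinite(vals)
            if ok.sum() < 3 or np.ptp(vals[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            r = pearsonr(vals[ok], np.asarray(y)[ok]).statistic
            out[i, j] = out[j, i] = r * r
    return bands, out


class TestNdi:
    def test_equal_reflectance_is_zero(self):
        s = make_spectrum([500.0, 600.0], [0.3, 0.3])
        assert ndi(s, 600, 500) == 0.0

    def test_direct_substitution(self):
        s = make_spectrum([500.0, 600.0], [0.1, 0.4])
        assert ndi(s, 600, 500) == pytest.approx(0.6)

    def test_antisymmetric_in_band_order(self):
        s = make_spectrum([500.0, 600.0], [0.1, 0.4])
        assert ndi(s, 500, 600) == -ndi(s, 600, 500)

    def test_same_band_rejected(self):
        s = make_spectrum([500.0, 600.0], [0.1, 0.4])
        with pytest.raises(ValueError):
            ndi(s, 500, 500)

    def test_bands_below_400_rejected(self):
        s = make_spectrum([350.0, 600.0], [0.1, 0.4])
        with pytest.raises(BandRangeError):
            ndi(s, 350, 600)


class TestNDIScreen:
    def test_constructed_perfect_predictor(self):
        wl = np.array([500.0, 600.0, 700.0])
        rng = np.random.default_rng(0)
        spectra = [
            Spectrum(wl, rng.uniform(0.05, 0.6, size=3)) for _ in range(5)
        ]
        y = [3.0 * ndi(s, 700, 500) - 1.0 for s in spectra]
        mat = NDIScreen(spectra, y).fit()
        assert mat.r2[0, 2] == pytest.approx(1.0, abs=1e-12)
        r2max, pair = mat.max_entry()
        assert r2max == pytest.approx(1.0, abs=1e-12)
        assert pair == (700.0, 500.0)

    def test_constant_trait_all_undefined(self):
        wl = np.array([500.0, 600.0, 700.0])
        rng = np.random.default_rng(1)
        spectra = [Spectrum(wl, rng.uniform(0.1, 0.5, 3)) for _ in range(5)]
        mat = NDIScreen(spectra, [2.0] * 5).fit()
        assert np.all(np.isnan(mat.r2))

    def test_matches_brute_force_oracle(self):
        """Full pipeline equals the naive reimplementation to 1e-12 on a
        10-band, 20-plot, 3-date instance."""
        rng = np.random.default_rng(99)
        wl = np.sort(rng.uniform(420.0, 1100.0, size=10))
        mats, oracles = [], []
        for d in range(3):
            spectra = [
                Spectrum(wl, rng.uniform(0.02, 0.8, size=10)) for _ in range(20)
            ]
            y = rng.normal(size=20)
            mats.append(NDIScreen(spectra, y, date=f"D{d}").fit())
            oracles.append(brute_force_matrix(spectra, y))
        for mat, (bands, oracle) in zip(mats, oracles):
            np.testing.assert_array_equal(mat.bands, bands)
            np.testing.assert_allclose(mat.r2, oracle, atol=1e-12)
        agg = aggregate(mats)
        stack = np.stack([o for _, o in oracles])
        np.testing.assert_allclose(agg.mean_r2, stack.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            agg.cv_r2,
            stack.std(axis=0, ddof=1) / stack.mean(axis=0),
            atol=1e-12,
        )

    def test_too_few_plots_rejected(self):
        wl = np.array([500.0, 600.0])
        spectra = [Spectrum(wl, [0.1, 0.2]), Spectrum(wl, [0.2, 0.3])]
        with pytest.raises(SampleSizeError):
            NDIScreen(spectra, [1.0, 2.0])

    def test_no_band_below_400_in_output(self, trial):
        traits, spectra = trial_tables(trial)
        sub = [s for s in spectra if s.date == "D1"]
        y = traits[traits["date"] == "D1"]["dw_kg_ha"].to_numpy()
        mat = NDIScreen(sub, y).fit()
        assert mat.bands.min() >= 400.0
        assert mat.to_long_frame()[["band1_nm", "band2_nm"]].min().min() >= 400.0


def _single_pair_matrix(val, date):
    r2 = np.full((2, 2), np.nan)
    r2[0, 1] = r2[1, 0] = val
    return ContourMatrix(np.array([500.0, 600.0]), r2, trait="t", date=date)


class TestAggregate:
    def test_hand_computed_mean_and_cv(self):
        """Across-date values {0.31, 0.75, 0.75, 0.61}: mean 0.605 and
        sample-SD CV 0.3428839..."""
        mats = [
            _single_pair_matrix(v, f"D{i}")
            for i, v in enumerate((0.31, 0.75, 0.75, 0.61))
        ]
        agg = aggregate(mats)
        assert agg.mean_r2[0, 1] == pytest.approx(0.605, abs=1e-12)
        assert agg.cv_r2[0, 1] == pytest.approx(0.34288392027551756, abs=1e-10)
        assert agg.best_mean_r2 == pytest.approx(0.605, abs=1e-12)

    def test_identical_dates_zero_cv(self):
        mats = [_single_pair_matrix(0.5, f"D{i}") for i in range(3)]
        agg = aggregate(mats)
        assert agg.cv_r2[0, 1] == 0.0

    def test_argmax_tie_prefers_narrow_pairs(self):
        bands = np.array([500.0, 600.0, 640.0])
        r2 = np.full((3, 3), np.nan)
        # two tied maxima: (600, 500) sep 100 and (640, 600) sep 40
        r2[0, 1] = r2[1, 0] = 0.8
        r2[1, 2] = r2[2, 1] = 0.8
        mats = [ContourMatrix(bands, r2, date=f"D{i}") for i in range(2)]
        agg = aggregate(mats)
        assert agg.best_pair == (640.0, 600.0)

    def test_undefined_entries_pairwise_complete(self):
        m1 = _single_pair_matrix(0.6, "D1")
        m2 = _single_pair_matrix(np.nan, "D2")
        m3 = _single_pair_matrix(0.4, "D3")
        agg = aggregate([m1, m2, m3])
        assert agg.mean_r2[0, 1] == pytest.approx(0.5)

    def test_single_date_rejected(self):
        with pytest.raises(ValueError):
            aggregate([_single_pair_matrix(0.5, "D1")])


class TestClassifyBandPair:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            ((792, 736), "red edge/NIR"),
            ((584, 582), "VIS/VIS"),
            ((680, 740), "VIS/red edge"),
            ((400, 1140), "VIS/NIR"),
            ((700, 720), "red edge/red edge"),
            ((900, 1100), "NIR/NIR"),
        ],
    )
    def test_group_labels(self, pair, expected):
        assert classify_band_pair(*pair) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(BandRangeError):
            classify_band_pair(380, 700)


class TestCrossTraitCompare:
    def test_identical_aggregates_on_identity_line(self):
        mats = [_single_pair_matrix(v, f"D{i}") for i, v in enumerate((0.3, 0.5))]
        agg = aggregate(mats)
        df = cross_trait_compare(agg, agg)
        cols = [c for c in df.columns if c.startswith("mean_r2")]
        np.testing.assert_allclose(df[cols[0]], df[cols[1]])

    def test_dw_and_nup_screens_align(self, trial):
        """N uptake is DW-dominated, so the two mean-R2 maps correlate
        strongly pair by pair."""
        traits, spectra = trial_tables(trial)
        aggs = {}
        for trait_col, label in (("dw_kg_ha", "dw"), ("nup_kg_ha", "nup")):
            mats = []
            for d in ("D1", "D2", "D3", "D4"):
                sub = [s for s in spectra if s.date == d]
                y = traits[traits["date"] == d][trait_col].to_numpy()
                mats.append(NDIScreen(sub, y, trait=label, date=d).fit())
            aggs[label] = aggregate(mats)
        df = cross_trait_compare(aggs["dw"], aggs["nup"]).dropna()
        r = pearsonr(df["mean_r2_dw"], df["mean_r2_nup"]).statistic
        assert r > 0.95
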