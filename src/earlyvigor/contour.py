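"""Exhaustive two-band normalized-difference index screening.

For every unordered pair of bands (b1, b2) above 400 nm, the normalized
difference index NDI = (R[b1] - R[b2]) / (R[b1] + R[b2]) is computed per
plot and correlated with a target trait; the squared Pearson correlations
form a symmetric "contour map" matrix per trait x date.  Matrices are
aggregated across dates into an element-wise mean and coefficient of
variation (temporal stability), the best band pair is the argmax of the
mean matrix, and pairs are classified into spectral groups (VIS 400-680,
red edge 680-740, NIR 740-1140 nm).

The screening stage is phrased like a regression package: an
:class:`NDIScreen` model is built from spectra plus trait values and its
``fit()`` returns the :class:`ContourMatrix` results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import (
    BandRangeError,
    GridMismatchError,
    SampleSizeError,
    UndefinedIndexValue,
)
from .spectra import Spectrum

__all__ = [
    "ndi",
    "NDIScreen",
    "ContourMatrix",
    "ContourAggregate",
    "aggregate",
    "classify_band_pair",
    "cross_trait_compare",
    "plot_contour",
    "plot_cv_vs_mean",
]

_VIS_MAX = 680.0  # upper edge of the visible group (inclusive)
_RED_EDGE_MAX = 740.0  # upper edge of the red-edge group (inclusive)


def ndi(spectrum: Spectrum, b1: float, b2: float) -> float:
    """Normalized difference index of two nominal bands (both >= 400 nm)."""
    if b1 == b2:
        raise ValueError("the two bands must differ")
    if b1 < 400.0 or b2 < 400.0:
        raise BandRangeError("bands below 400 nm are excluded from screening")
    r1, r2 = spectrum.band(b1), spectrum.band(b2)
    if r1 + r2 == 0.0:
        raise UndefinedIndexValue(f"NDI({b1:g};{b2:g})")
    return (r1 - r2) / (r1 + r2)


def _nan_r2_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson r of each column of X with y, NaN-aware per column.

    Rows where a column is NaN are dropped for that column; columns with
    fewer than 3 valid rows or (near-)zero variance come back NaN.
    """
    valid = np.isfinite(X)
    n = valid.sum(axis=0).astype(float)
    Xz = np.where(valid, X, 0.0)
    yc = y[:, None] * valid
    sx = Xz.sum(axis=0)
    sy = yc.sum(axis=0)
    sxx = (Xz * Xz).sum(axis=0)
    syy = (yc * yc).sum(axis=0)
    sxy = (Xz * y[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r2 = (cov * cov) / (varx * vary)
    bad = (n < 3) | (varx <= 1e-18 * n) | (vary <= 1e-18 * n)
    r2[bad] = np.nan
    return np.clip(r2, 0.0, 1.0)


@dataclass
class ContourMatrix:
    """Symmetric R^2 matrix over band pairs for one trait x date."""

    bands: np.ndarray
    r2: np.ndarray
    trait: str = ""
    date: str = ""
    n_plots: int = 0

    def max_entry(self) -> tuple[float, tuple[float, float]]:
        """Maximum defined R^2 and its band pair, ordered (high, low) nm.

        Ties go to the pair with the smaller band separation, then the
        lower wavelength.
        """
        return _argmax_pair(self.bands, self.r2)

    def to_long_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.bands), k=1)
        return pd.DataFrame(
            {
                "trait": self.trait,
                "date": self.date,
                "band1_nm": self.bands[iu[1]],  # higher index = higher nm
                "band2_nm": self.bands[iu[0]],
                "r2": self.r2[iu],
            }
        )


def _argmax_pair(bands: np.ndarray, mat: np.ndarray):
    iu = np.triu_indices(len(bands), k=1)
    vals = mat[iu]
    if not np.any(np.isfinite(vals)):
        raise ValueError("no defined entries in the matrix")
    vmax = np.nanmax(vals)
    cand = np.flatnonzero(vals == vmax)
    b_lo = bands[iu[0][cand]]
    b_hi = bands[iu[1][cand]]
    # tie-break: narrowest pair, then lowest low-band wavelength
    order = np.lexsort((b_lo, b_hi - b_lo))
    j = cand[order[0]]
    return float(vmax), (float(bands[iu[1][j]]), float(bands[iu[0][j]]))


class NDIScreen:
    """Model: all pairwise NDIs of one date's spectra against one trait.

    Parameters
    ----------
    spectra
        Plot spectra sharing one wavelength grid.
    trait_values
        One trait value per spectrum, aligned by position.
    min_wavelength
        Bands below this are dropped (default 400 nm, scattering).
    """

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        trait_values: Sequence[float],
        trait: str = "",
        date: str = "",
        min_wavelength: float = 400.0,
    ):
        spectra = list(spectra)
        if len(spectra) < 3:
            raise SampleSizeError("screening needs at least 3 plots")
        if len(spectra) != len(trait_values):
            raise ValueError("spectra and trait values are not aligned")
        wl = spectra[0].wavelengths
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths, wl):
                raise GridMismatchError("spectra are on different grids")
        keep = wl >= min_wavelength
        self.bands = wl[keep]
        self.R = np.stack([s.reflectance[keep] for s in spectra])
        self.y = np.asarray(trait_values, dtype=float)
        self.trait = trait
        self.date = date

    def fit(self) -> ContourMatrix:
        n_bands = self.bands.size
        r2 = np.full((n_bands, n_bands), np.nan)
        y = self.y
        if np.ptp(y) == 0.0:  # constant trait: every entry undefined
            return ContourMatrix(
                self.bands, r2, self.trait, self.date, len(y)
            )
        R = self.R
        for i in range(n_bands - 1):
            ri = R[:, i][:, None]
            rj = R[:, i + 1 :]
            with np.errstate(invalid="ignore", divide="ignore"):
                x = (ri - rj) / (ri + rj)
            x[~np.isfinite(x)] = np.nan
            row = _nan_r2_columns(x, y)
            r2[i, i + 1 :] = row
            r2[i + 1 :, i] = row
        return ContourMatrix(self.bands, r2, self.trait, self.date, len(y))


@dataclass
class ContourAggregate:
    """Across-date aggregation of one trait's contour matrices."""

    bands: np.ndarray
    mean_r2: np.ndarray
    cv_r2: np.ndarray
    best_pair: tuple[float, float]
    best_mean_r2: float
    cv_at_best: float
    per_date: pd.DataFrame  # date, max_r2, band1_nm, band2_nm
    trait: str = ""

    def to_long_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.bands), k=1)
        return pd.DataFrame(
            {
                "trait": self.trait,
                "band1_nm": self.bands[iu[1]],
                "band2_nm": self.bands[iu[0]],
                "mean_r2": self.mean_r2[iu],
                "cv_r2": self.cv_r2[iu],
            }
        )


def aggregate(matrices: Sequence[ContourMatrix]) -> ContourAggregate:
    """Element-wise mean and CV of contour matrices across dates.

    Undefined entries are excluded pairwise-complete (never imputed as 0);
    the CV uses the sample (n-1) standard deviation.  ``cv_at_best`` is
    the CV of the best *mean* pair, not the minimum CV.
    """
    if len(matrices) < 2:
        raise ValueError("aggregation needs at least 2 dates")
    bands = matrices[0].bands
    trait = matrices[0].trait
    for m in matrices[1:]:
        if not np.array_equal(m.bands, bands):
            raise GridMismatchError("contour matrices are on different grids")
    stack = np.stack([m.r2 for m in matrices])
    defined = np.isfinite(stack)
    n_def = defined.sum(axis=0)
    filled = np.where(defined, stack, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=0) / n_def
        sq = np.where(defined, (stack - mean) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(sq / (n_def - 1))
        cv = sd / mean
    mean[n_def == 0] = np.nan
    cv[(n_def < 2) | (mean == 0)] = np.nan

    best_mean_r2, best_pair = _argmax_pair(bands, mean)
    i1 = int(np.argmin(np.abs(bands - best_pair[0])))
    i2 = int(np.argmin(np.abs(bands - best_pair[1])))
    cv_at_best = float(cv[i1, i2])

    per_date = []
    for m in matrices:
        try:
            r2max, pair = m.max_entry()
        except ValueError:  # all entries undefined on this date
            r2max, pair = np.nan, (np.nan, np.nan)
        per_date.append(
            {
                "date": m.date,
                "max_r2": r2max,
                "band1_nm": pair[0],
                "band2_nm": pair[1],
            }
        )
    return ContourAggregate(
        bands=bands,
        mean_r2=mean,
        cv_r2=cv,
        best_pair=best_pair,
        best_mean_r2=best_mean_r2,
        cv_at_best=cv_at_best,
        per_date=pd.DataFrame(per_date),
        trait=trait,
    )


def _band_group(b: float) -> str:
    if not 400.0 <= b <= 1140.0:
        raise BandRangeError(f"band {b} nm outside [400, 1140]")
    if b <= _VIS_MAX:
        return "VIS"
    if b <= _RED_EDGE_MAX:
        return "red edge"
    return "NIR"


_GROUP_ORDER = {"VIS": 0, "red edge": 1, "NIR": 2}


def classify_band_pair(b1: float, b2: float) -> str:
    """Spectral group label of an unordered band pair.

    Boundary wavelengths belong to the lower-named region: 680 nm is VIS,
    740 nm is red edge.
    """
    g = sorted((_band_group(b1), _band_group(b2)), key=_GROUP_ORDER.get)
    return f"{g[0]}/{g[1]}"


def cross_trait_compare(
    agg_a: ContourAggregate, agg_b: ContourAggregate
) -> pd.DataFrame:
    """Pair the mean-R^2 maps of two traits band pair by band pair."""
    if not np.array_equal(agg_a.bands, agg_b.bands):
        raise GridMismatchError("aggregates are on different grids")
    bands = agg_a.bands
    iu = np.triu_indices(len(bands), k=1)
    b_hi, b_lo = bands[iu[1]], bands[iu[0]]
    groups = [classify_band_pair(h, l) for h, l in zip(b_hi, b_lo)]
    name_a, name_b = agg_a.trait or "a", agg_b.trait or "b"
    if name_a == name_b:
        name_a, name_b = f"{name_a}_a", f"{name_b}_b"
    return pd.DataFrame(
        {
            "band1_nm": b_hi,
            "band2_nm": b_lo,
            f"mean_r2_{name_a}": agg_a.mean_r2[iu],
            f"mean_r2_{name_b}": agg_b.mean_r2[iu],
            "group": groups,
        }
    )


# ---------------------------------------------------------------------------
# plotting


def plot_contour(matrix_or_agg, ax=None, cmap="viridis"):
    """Heatmap of a contour matrix (or of an aggregate's mean matrix)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bands = matrix_or_agg.bands
    mat = getattr(matrix_or_agg, "mean_r2", None)
    if mat is None:
        mat = matrix_or_agg.r2
    im = ax.pcolormesh(bands, bands, mat, cmap=cmap, vmin=0, vmax=1)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("wavelength (nm)")
    ax.figure.colorbar(im, ax=ax, label=r"$R^2$")
    return ax


def plot_cv_vs_mean(agg: ContourAggregate, ax=None):
    """Temporal stability view: CV of R^2 against mean R^2 per band pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = agg.to_long_frame().dropna()
    groups = [
        classify_band_pair(h, l)
        for h, l in zip(df["band1_nm"], df["band2_nm"])
    ]
    df = df.assign(group=groups)
    for g, sub in df.groupby("group"):
        ax.scatter(sub["mean_r2"], sub["cv_r2"], s=4, label=g, alpha=0.5)
    ax.set_xlabel(r"mean $R^2$")
    ax.set_ylabel(r"CV of $R^2$")
    ax.legend(markerscale=3, fontsize="small")
    return ax
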