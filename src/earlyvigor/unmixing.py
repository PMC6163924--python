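"""Two-endmember linear spectral unmixing.

The mixed canopy spectrum is regressed, by ordinary least squares, on the
bare-soil and dense-vegetation endmember spectra; the fractional
vegetation cover is the ratio of the vegetation coefficient to the sum of
both coefficients,

    cover = b_veg / (b_veg + b_soil).

By default there is no intercept (the endmembers themselves are the only
predictors) and the coefficients are left unconstrained — no
non-negativity, no sum-to-one — so the estimate may leave [0, 1] for
noisy or poorly matched endmembers.  Bands below 400 nm are excluded from
the fit by default because of strong scattering there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import (
    ConfigurationError,
    DegenerateEndmemberError,
    GridMismatchError,
    UndefinedCoverError,
)
from .spectra import Spectrum
from .synthetic import EndmemberLibrary

__all__ = ["SpectralUnmixing", "UnmixingResult", "fit_unmixing", "unmix_trial"]

#: condition number above which the two endmembers are treated as collinear
_COND_LIMIT = 1e8


@dataclass
class UnmixingResult:
    """Fit results of :class:`SpectralUnmixing`.

    ``cover_estimate`` is ``coef_vegetation / (coef_vegetation +
    coef_soil)``, the fractional-cover reading of the regression.
    """

    coef_vegetation: float
    coef_soil: float
    intercept: float | None
    residual_rms: float
    n_bands_used: int
    condition_number: float

    @property
    def cover_estimate(self) -> float:
        denom = self.coef_vegetation + self.coef_soil
        if denom == 0.0:
            raise UndefinedCoverError("coefficients sum to zero")
        return self.coef_vegetation / denom

    def summary(self) -> str:
        lines = [
            "Two-endmember linear spectral unmixing (OLS)",
            "=" * 46,
            f"bands used            {self.n_bands_used:>12d}",
            f"coef (vegetation)     {self.coef_vegetation:>12.6f}",
            f"coef (soil)           {self.coef_soil:>12.6f}",
        ]
        if self.intercept is not None:
            lines.append(f"intercept             {self.intercept:>12.6f}")
        try:
            cover = f"{self.cover_estimate:>12.6f}"
        except UndefinedCoverError:
            cover = "   undefined"
        lines += [
            f"cover estimate        {cover}",
            f"residual RMS          {self.residual_rms:>12.6f}",
            f"design condition no.  {self.condition_number:>12.3g}",
        ]
        return "\n".join(lines)


class SpectralUnmixing:
    """Model object: one mixed spectrum against a soil/vegetation pair.

    Parameters
    ----------
    mixed, soil, vegetation
        Spectra sharing one wavelength grid.
    band_range
        Wavelength interval (nm) used in the fit; default (400, 1140).
    intercept
        Include an intercept term (off by default; exposed for sensitivity
        analysis only — an intercept absorbs part of the soil signal).
    """

    def __init__(
        self,
        mixed: Spectrum,
        soil: Spectrum,
        vegetation: Spectrum,
        band_range: tuple[float, float] = (400.0, 1140.0),
        intercept: bool = False,
    ):
        for other in (soil, vegetation):
            if not np.array_equal(mixed.wavelengths, other.wavelengths):
                raise GridMismatchError(
                    "mixed spectrum and endmembers are on different grids"
                )
        lo, hi = band_range
        sel = (mixed.wavelengths >= lo) & (mixed.wavelengths <= hi)
        if sel.sum() < 3:
            raise ValueError("band_range keeps fewer than 3 bands")
        self.mixed = mixed
        self.soil = soil
        self.vegetation = vegetation
        self.band_range = band_range
        self.intercept = intercept
        self._sel = sel

    def fit(self) -> UnmixingResult:
        y = self.mixed.reflectance[self._sel]
        cols = [
            self.soil.reflectance[self._sel],
            self.vegetation.reflectance[self._sel],
        ]
        if self.intercept:
            cols.append(np.ones_like(y))
        X = np.column_stack(cols)
        cond = float(np.linalg.cond(X))
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            raise DegenerateEndmemberError(
                f"endmembers are near-collinear (condition number {cond:.3g})"
            )
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return UnmixingResult(
            coef_vegetation=float(beta[1]),
            coef_soil=float(beta[0]),
            intercept=float(beta[2]) if self.intercept else None,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            n_bands_used=int(self._sel.sum()),
            condition_number=cond,
        )


def fit_unmixing(
    mixed: Spectrum,
    soil: Spectrum,
    vegetation: Spectrum,
    band_range: tuple[float, float] = (400.0, 1140.0),
    intercept: bool = False,
) -> UnmixingResult:
    """One-call convenience wrapper around :class:`SpectralUnmixing`."""
    return SpectralUnmixing(
        mixed, soil, vegetation, band_range=band_range, intercept=intercept
    ).fit()


def unmix_trial(
    spectra: Sequence[Spectrum],
    endmembers_by_date: Mapping[str, EndmemberLibrary],
    band_range: tuple[float, float] = (400.0, 1140.0),
) -> pd.DataFrame:
    """Unmix every plot spectrum with its date's endmember pair.

    Returns a frame with columns ``plot_id, date, cover_estimate,
    coef_veg, coef_soil, residual_rms, missing_reason``; degenerate fits
    are kept as missing rows with the reason recorded.
    """
    rows = []
    for s in spectra:
        if s.date not in endmembers_by_date:
            raise ConfigurationError(f"no endmembers for date {s.date!r}")
        lib = endmembers_by_date[s.date]
        row = {
            "plot_id": s.plot_id,
            "date": s.date,
            "cover_estimate": np.nan,
            "coef_veg": np.nan,
            "coef_soil": np.nan,
            "residual_rms": np.nan,
            "missing_reason": "",
        }
        try:
            res = fit_unmixing(
                s,
                lib.soil_spectrum(s.date),
                lib.vegetation_spectrum(s.date),
                band_range=band_range,
            )
            row.update(
                coef_veg=res.coef_vegetation,
                coef_soil=res.coef_soil,
                residual_rms=res.residual_rms,
            )
            row["cover_estimate"] = res.cover_estimate
        except DegenerateEndmemberError:
            row["missing_reason"] = "degenerate_endmembers"
        except UndefinedCoverError:
            row["missing_reason"] = "zero_coefficient_sum"
        rows.append(row)
    return pd.DataFrame(rows)
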