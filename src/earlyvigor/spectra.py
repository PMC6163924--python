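"""Spectral data model and narrow-band vegetation indices.

A :class:`Spectrum` holds one plot's reflectance on a strictly increasing
wavelength grid (nominally 3.3 nm steps spanning 300-1140 nm, as delivered
by diode-array field spectrometers).  Vegetation indices are defined as
:class:`VIDefinition` objects over *nominal* band positions; each nominal
band is resolved to the nearest grid wavelength (ties toward the lower
wavelength, no interpolation), which is how narrow-band indices are
conventionally computed from array spectrometers.

The registry :data:`ESTABLISHED_INDICES` carries the nine classical indices
screened by this package: ATSAVI, EPVI, MCARI, MTCI, NDRE, NDVI, PRI, REIP
and WBI.  :func:`greenseeker_ndvi` emulates an active two-band red/NIR
sensor by averaging reflectance over ~25 nm wide boxcar windows centred at
656 and 774 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import BandRangeError, UndefinedIndexValue

__all__ = [
    "Spectrum",
    "VIDefinition",
    "ESTABLISHED_INDICES",
    "band",
    "compute_index",
    "greenseeker_ndvi",
    "index_table",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass
class Spectrum:
    """Reflectance of one plot at one date on a fixed wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm.
    reflectance
        Unitless reflectance per band, same length as ``wavelengths``.
        Values are expected in [0, 1.5]; mild calibration overshoot above 1
        is tolerated, values outside [0, 1.5] trigger a warning.
    plot_id, date
        Free-form labels identifying the measurement.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    plot_id: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance differ in length")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two bands")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1.5):
            warnings.warn(
                f"spectrum {self.plot_id!r}/{self.date!r} has reflectance "
                "outside [0, 1.5]; check sensor calibration",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def band_index(self, nominal_nm: float) -> int:
        """Index of the grid wavelength nearest ``nominal_nm`` (ties -> lower)."""
        wl = self.wavelengths
        if nominal_nm < wl[0] or nominal_nm > wl[-1]:
            raise BandRangeError(
                f"{nominal_nm} nm outside grid range [{wl[0]}, {wl[-1]}]"
            )
        i = int(np.searchsorted(wl, nominal_nm))
        if i == 0:
            return 0
        # distance to the lower neighbour wins on ties
        if nominal_nm - wl[i - 1] <= wl[i] - nominal_nm:
            return i - 1
        return i

    def band(self, nominal_nm: float) -> float:
        """Reflectance at the grid wavelength nearest ``nominal_nm``."""
        return float(self.reflectance[self.band_index(nominal_nm)])


def band(spectrum: Spectrum, nominal_nm: float) -> float:
    """Functional alias for :meth:`Spectrum.band`."""
    return spectrum.band(nominal_nm)


@dataclass(frozen=True)
class VIDefinition:
    """A vegetation index: named formula over nominal band reflectances.

    ``formula`` receives a mapping from nominal wavelength (as given in
    ``required_bands``) to reflectance and returns a float.  A zero
    denominator inside the formula must surface as ``ZeroDivisionError``;
    :func:`compute_index` converts it into :class:`UndefinedIndexValue`.
    """

    name: str
    required_bands: tuple
    formula: Callable[[Mapping[float, float]], float] = field(repr=False)

    def __post_init__(self) -> None:
        for b in self.required_bands:
            if not 400.0 <= b <= 1140.0:
                raise ValueError(
                    f"index {self.name}: band {b} nm outside [400, 1140]"
                )


def _atsavi(r: Mapping[float, float]) -> float:
    # soil-adjusted index, adjustment constants 1.22 / 0.03 / 0.23
    return (1.22 * (r[800] - 1.22 * r[670] - 0.03)) / (
        1.22 * r[800] + r[670] + 0.23
    )


def _epvi(r: Mapping[float, float]) -> float:
    return (r[750] - r[670]) / r[862]


def _mcari(r: Mapping[float, float]) -> float:
    return ((r[700] - r[670]) - 0.2 * (r[700] - r[550])) * (r[700] / r[670])


def _mtci(r: Mapping[float, float]) -> float:
    return (r[750] - r[710]) / (r[710] - r[680])


def _ndre(r: Mapping[float, float]) -> float:
    return (r[790] - r[720]) / (r[790] + r[720])


def _ndvi(r: Mapping[float, float]) -> float:
    return (r[864] - r[671]) / (r[864] + r[671])


def _pri(r: Mapping[float, float]) -> float:
    return (r[531] - r[570]) / (r[531] + r[570])


def _reip(r: Mapping[float, float]) -> float:
    # red-edge inflection point, Guyot-Baret linear interpolation form
    return 700.0 + 40.0 * (
        ((r[668] + r[778]) / 2.0 - r[698]) / (r[738] - r[698])
    )


def _wbi(r: Mapping[float, float]) -> float:
    return r[900] / r[970]


ESTABLISHED_INDICES: dict[str, VIDefinition] = {
    vi.name: vi
    for vi in (
        VIDefinition("ATSAVI", (670, 800), _atsavi),
        VIDefinition("EPVI", (670, 750, 862), _epvi),
        VIDefinition("MCARI", (550, 670, 700), _mcari),
        VIDefinition("MTCI", (680, 710, 750), _mtci),
        VIDefinition("NDRE", (720, 790), _ndre),
        VIDefinition("NDVI", (671, 864), _ndvi),
        VIDefinition("PRI", (531, 570), _pri),
        VIDefinition("REIP", (668, 698, 738, 778), _reip),
        VIDefinition("WBI", (900, 970), _wbi),
    )
}


def compute_index(spectrum: Spectrum, vi: VIDefinition) -> float:
    """Evaluate one vegetation index on one spectrum.

    Raises
    ------
    UndefinedIndexValue
        If the formula hits a zero denominator (carries ``vi.name``).
    BandRangeError
        If a required band lies outside the spectrum's grid.
    """
    refl = {b: spectrum.band(b) for b in vi.required_bands}
    try:
        return float(vi.formula(refl))
    except ZeroDivisionError as exc:
        raise UndefinedIndexValue(vi.name) from exc


def greenseeker_ndvi(
    spectrum: Spectrum,
    red_center: float = 656.0,
    nir_center: float = 774.0,
    half_width: float = 12.5,
) -> float:
    """Two-band NDVI as reported by an active red/NIR crop sensor.

    The sensor's diodes integrate roughly 25 nm wide bands around 656 nm
    (red) and 774 nm (NIR); here each band is an unweighted boxcar mean of
    the grid wavelengths within ``center +/- half_width``.
    """
    wl = spectrum.wavelengths
    out = []
    for center in (red_center, nir_center):
        sel = (wl >= center - half_width) & (wl <= center + half_width)
        if not np.any(sel):
            raise BandRangeError(
                f"no grid bands within {center} +/- {half_width} nm"
            )
        out.append(float(spectrum.reflectance[sel].mean()))
    r_red, r_nir = out
    if r_nir + r_red == 0.0:
        raise UndefinedIndexValue("greenseeker_ndvi")
    return (r_nir - r_red) / (r_nir + r_red)


def index_table(
    spectra: Iterable[Spectrum],
    vis: Sequence[VIDefinition] | None = None,
) -> pd.DataFrame:
    """Evaluate a set of indices on a collection of spectra.

    Returns a long-format frame with columns ``plot_id, date, method,
    value, missing_reason``.  Undefined values (zero denominators) are kept
    as NaN with the reason recorded, never silently dropped.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra given")
    if vis is None:
        vis = list(ESTABLISHED_INDICES.values())
    if not vis:
        raise ValueError("no index definitions given")
    rows = []
    for s in spectra:
        for vi in vis:
            try:
                value, reason = compute_index(s, vi), ""
            except UndefinedIndexValue:
                value, reason = np.nan, "zero_denominator"
            rows.append(
                {
                    "plot_id": s.plot_id,
                    "date": s.date,
                    "method": vi.name,
                    "value": value,
                    "missing_reason": reason,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV round-trip: wide format, first column wavelength_nm, one column per plot


def write_spectra_csv(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra sharing one grid as a wide CSV.

    Column names are ``plot_id`` when all dates coincide, otherwise
    ``plot_id|date``.
    """
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("spectra do not share one wavelength grid")
    one_date = len({s.date for s in spectra}) == 1
    data = {"wavelength_nm": wl}
    for s in spectra:
        name = s.plot_id if one_date else f"{s.plot_id}|{s.date}"
        data[name] = s.reflectance
    pd.DataFrame(data).to_csv(path, index=False)


def read_spectra_csv(path, date: str = "") -> list[Spectrum]:
    """Read spectra written by :func:`write_spectra_csv`.

    ``date`` is applied to columns without an embedded ``|date`` suffix.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("first column must be 'wavelength_nm'")
    wl = df["wavelength_nm"].to_numpy(float)
    out = []
    for col in df.columns[1:]:
        pid, _, d = col.partition("|")
        out.append(
            Spectrum(wl, df[col].to_numpy(float), plot_id=pid, date=d or date)
        )
    return out
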