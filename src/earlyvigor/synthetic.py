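"""Synthetic four-date early-vigor trial: spectra, quadrat images, traits.

The generator emulates the statistical structure the downstream analysis
assumes for an early-season winter-wheat trial:

* per-plot canopy spectra are linear soil/vegetation endmember mixtures
  with heteroscedastic zero-mean noise, boosted above 1000 nm on the first
  date where field spectra suffer strong scattering;
* dry weight (DW, kg/ha) grows roughly exponentially over the four dates
  (on average from ~73 to ~1812 kg/ha), nitrogen content (NC, %) stays
  near 5% before dropping to ~4.6% on the last date, with a negative
  DW-NC trade-off imposed on dates 3-4 only;
* N uptake is always DW x NC/100, never drawn independently;
* canopy cover (CC) develops sigmoidally from ~4.5% to ~84% ground cover
  and is tied to DW through a logistic link in log(DW) whose midpoint is
  calibrated per date so the realized mean cover matches the design;
* each plot gets a rendered quadrat image whose exact green-pixel
  fraction is the plot's ground-truth cover.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from ._exceptions import ConfigurationError
from .spectra import Spectrum

__all__ = [
    "EndmemberLibrary",
    "TrialDesign",
    "GrowthModel",
    "SyntheticPlot",
    "default_endmembers",
    "generate_spectrum",
    "render_canopy_image",
    "generate_trial",
    "trial_tables",
    "write_trial",
]


@dataclass
class EndmemberLibrary:
    """Pure soil and dense-vegetation reference spectra on one grid."""

    wavelengths: np.ndarray
    soil: np.ndarray
    vegetation: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.soil = np.asarray(self.soil, dtype=float)
        self.vegetation = np.asarray(self.vegetation, dtype=float)
        if not (
            self.wavelengths.shape == self.soil.shape == self.vegetation.shape
        ):
            raise ConfigurationError("endmember arrays differ in length")
        for name, r in (("soil", self.soil), ("vegetation", self.vegetation)):
            if np.any(r < 0) or np.any(r > 1):
                raise ConfigurationError(f"{name} reflectance outside [0, 1]")
        # the red-edge step keeps every red/NIR index non-degenerate
        veg = self.vegetation_spectrum()
        if veg.band(780) - veg.band(670) < 0.25:
            raise ConfigurationError(
                "vegetation endmember lacks a red-edge step "
                "(R780 - R670 < 0.25)"
            )

    def soil_spectrum(self, date: str = "") -> Spectrum:
        return Spectrum(self.wavelengths, self.soil, plot_id="soil", date=date)

    def vegetation_spectrum(self, date: str = "") -> Spectrum:
        return Spectrum(
            self.wavelengths, self.vegetation, plot_id="vegetation", date=date
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "soil": self.soil,
                "vegetation": self.vegetation,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EndmemberLibrary":
        df = pd.read_csv(path)
        return cls(
            df["wavelength_nm"].to_numpy(float),
            df["soil"].to_numpy(float),
            df["vegetation"].to_numpy(float),
        )


def default_endmembers(
    start_nm: float = 300.0, stop_nm: float = 1140.0, step_nm: float = 3.3
) -> EndmemberLibrary:
    """Parametric endmember library on the nominal 3.3 nm grid.

    The soil endmember is a flat brown ramp brightening toward the NIR.
    The vegetation endmember combines a green reflectance bump near 550 nm,
    a chlorophyll absorption trough near 675 nm, a sigmoidal red edge
    rising to a NIR plateau, and a mild water-absorption dip near 975 nm.
    The shapes are qualitatively realistic; they are not measurements.
    """
    wl = np.arange(start_nm, stop_nm + 1e-9, step_nm)
    soil = 0.10 + 0.22 * (wl - 300.0) / 840.0
    veg = (
        0.04
        + 0.055 * np.exp(-(((wl - 552.0) / 35.0) ** 2))
        - 0.015 * np.exp(-(((wl - 675.0) / 30.0) ** 2))
        + 0.43 / (1.0 + np.exp(-(wl - 718.0) / 14.0))
        - 0.04 * np.exp(-(((wl - 975.0) / 45.0) ** 2))
    )
    return EndmemberLibrary(wl, np.clip(soil, 0, 1), np.clip(veg, 0, 1))


@dataclass
class TrialDesign:
    """Factorial layout of the simulated trial.

    Defaults follow a small split-plot early-season trial: four sampling
    dates at seedling to early stem-elongation growth stages, 36 plots per
    date from 2 N levels x 3 sowing densities x 2 cultivars x 3 replicates.
    """

    n_dates: int = 4
    dates: tuple = ("D1", "D2", "D3", "D4")
    growth_stages: tuple = ("12-13", "21", "24", "32")
    density_levels: tuple = (150, 250, 350)
    n_levels: tuple = (30, 60)
    cultivar_labels: tuple = ("Anapolis", "Hybery")
    n_replicates: int = 3
    seed: int = 0

    @property
    def n_plots(self) -> int:
        return (
            len(self.density_levels)
            * len(self.n_levels)
            * len(self.cultivar_labels)
            * self.n_replicates
        )

    def __post_init__(self) -> None:
        if self.n_dates != len(self.dates):
            raise ConfigurationError("n_dates inconsistent with date labels")
        if self.n_plots <= 0:
            raise ConfigurationError("empty factorial structure")

    def plots(self):
        """Yield (plot_id, density, n_level, cultivar) in a fixed order."""
        i = 0
        for n in self.n_levels:
            for d in self.density_levels:
                for c in self.cultivar_labels:
                    for _ in range(self.n_replicates):
                        i += 1
                        yield f"P{i:03d}", d, n, c


@dataclass
class GrowthModel:
    """Trait dynamics and plot-to-plot dispersion of the simulated trial.

    ``plot_cv`` is the log-scale dispersion of the multiplicative plot
    effect on dry weight; the NC standard deviation and the cover logit
    jitter scale proportionally with it (so ``plot_cv = 0`` collapses every
    plot at a date onto the date means).  ``nc_dw_tradeoff`` is the
    correlation imposed between the NC deviation and the DW plot effect on
    dates 3-4 (negative for the late dilution trade-off).
    """

    dw_means: tuple = (73.0, 213.0, 621.0, 1812.0)  # kg/ha
    nc_means: tuple = (5.0, 5.0, 5.0, 4.6)  # %
    cc_means: tuple = (0.045, 0.18, 0.50, 0.84)  # ground-cover fraction
    plot_cv: float = 0.25
    nc_dw_tradeoff: float = -0.6
    cc_logistic_slope: float = 1.6  # d logit(CC) / d log(DW)
    nc_sd: float | None = None  # default 1.6 * plot_cv (% points)
    cc_logit_sd: float | None = None  # default 0.72 * plot_cv

    def __post_init__(self) -> None:
        n = len(self.dw_means)
        if not (len(self.nc_means) == len(self.cc_means) == n):
            raise ConfigurationError("trait mean vectors differ in length")
        if not np.all(np.diff(self.dw_means) > 0):
            raise ConfigurationError("dw_means must be strictly increasing")
        cc = np.asarray(self.cc_means)
        if np.any(cc <= 0) or np.any(cc >= 1) or np.any(np.diff(cc) < 0):
            raise ConfigurationError(
                "cc_means must be non-decreasing fractions in (0, 1)"
            )
        if np.sum(np.abs(np.diff(np.sign(np.diff(cc, 2)))) > 0) > 1:
            raise ConfigurationError("cc_means must be sigmoidal")

    @property
    def nc_sd_effective(self) -> float:
        return 1.6 * self.plot_cv if self.nc_sd is None else self.nc_sd

    @property
    def cc_logit_sd_effective(self) -> float:
        return 0.72 * self.plot_cv if self.cc_logit_sd is None else self.cc_logit_sd


@dataclass
class SyntheticPlot:
    """One plot x date: trait record, spectrum, rendered image, truth."""

    plot_id: str
    date: str
    cultivar: str
    density: int
    n_level: int
    dw: float  # kg/ha
    nc: float  # %
    nup: float  # kg/ha, always dw * nc / 100
    true_cover: float  # exact green-pixel fraction of the image
    spectrum: Spectrum
    image: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# spectra


def generate_spectrum(
    cover: float,
    endmembers: EndmemberLibrary,
    noise_sd: float = 0.005,
    nir_noise_boost: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    plot_id: str = "",
    date: str = "",
) -> Spectrum:
    """Linear soil/vegetation mixture plus heteroscedastic noise.

    The spectrum is ``cover * vegetation + (1 - cover) * soil`` plus
    zero-mean Gaussian noise of standard deviation ``noise_sd``; bands
    above 1000 nm receive ``noise_sd * nir_noise_boost`` instead,
    emulating the stronger scattering seen there on the earliest date.
    Values are clipped to [0, 1].
    """
    if not 0.0 <= cover <= 1.0:
        raise ValueError(f"cover must be in [0, 1], got {cover}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    wl = endmembers.wavelengths
    mixed = cover * endmembers.vegetation + (1.0 - cover) * endmembers.soil
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=wl.size)
        noise[wl > 1000.0] *= nir_noise_boost
        mixed = mixed + noise
    return Spectrum(wl, np.clip(mixed, 0.0, 1.0), plot_id=plot_id, date=date)


# ---------------------------------------------------------------------------
# images


def render_canopy_image(
    target_cover: float,
    width: int = 600,
    height: int = 600,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Render a nadir quadrat image with a known green-pixel fraction.

    Vegetation is painted as elongated organic patches (a thresholded
    anisotropically smoothed random field, mimicking grass blades seen
    from above) in green hues (95-140 degrees) with brightness jitter over
    a brown speckled soil texture (hues 18-42 degrees).  The threshold is
    set at the exact pixel count closest to ``target_cover``, so the
    returned ``true_cover`` is the exact rendered green fraction and
    differs from the target by less than one pixel in the raster
    (always < 0.02 for permitted sizes).

    Returns ``(image, true_cover)`` with ``image`` an (H, W, 3) uint8 RGB
    array.
    """
    if not 0.0 <= target_cover <= 1.0:
        raise ValueError(f"target_cover must be in [0, 1], got {target_cover}")
    if width < 64 or height < 64:
        raise ValueError("image must be at least 64x64 pixels")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_px = width * height
    k = int(round(target_cover * n_px))
    field_ = gaussian_filter(
        rng.standard_normal((height, width)),
        sigma=(max(1.5, 0.006 * height), max(4.0, 0.02 * width)),
        mode="wrap",
    )
    mask = np.zeros(n_px, dtype=bool)
    if k > 0:
        order = np.argpartition(field_.ravel(), n_px - k)
        mask[order[n_px - k:]] = True
    mask = mask.reshape(height, width)
    true_cover = k / n_px

    hsv = np.empty((height, width, 3), dtype=float)
    # soil: brown speckle, saturation above typical thresholds but hue far
    # outside the plant window
    hsv[..., 0] = rng.uniform(18.0, 42.0, size=(height, width))
    hsv[..., 1] = rng.uniform(0.25, 0.55, size=(height, width))
    hsv[..., 2] = rng.uniform(0.25, 0.65, size=(height, width))
    if k > 0:
        nveg = int(mask.sum())
        hsv[..., 0][mask] = rng.uniform(95.0, 140.0, size=nveg)
        hsv[..., 1][mask] = rng.uniform(0.45, 0.90, size=nveg)
        hsv[..., 2][mask] = rng.uniform(0.35, 0.85, size=nveg)
    hsv[..., 0] /= 360.0
    rgb = hsv_to_rgb(hsv)
    image = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    return image, true_cover


# ---------------------------------------------------------------------------
# the trial


def _solve_cover_midpoint(
    log_dw: np.ndarray, logit_noise: np.ndarray, slope: float, cc_mean: float
) -> float:
    """Midpoint of the logistic CC(DW) link hitting the target mean cover."""

    def mean_cover(m: float) -> float:
        return float(
            np.mean(1.0 / (1.0 + np.exp(-(slope * (log_dw - m) + logit_noise))))
        )

    lo = float(log_dw.min()) - 40.0
    hi = float(log_dw.max()) + 40.0
    return brentq(lambda m: mean_cover(m) - cc_mean, lo, hi, xtol=1e-10)


def generate_trial(
    design: TrialDesign | None = None,
    growth: GrowthModel | None = None,
    endmembers: EndmemberLibrary | None = None,
    noise_sd: float = 0.005,
    nir_noise_boosts: Sequence[float] | None = None,
    image_size: int = 600,
    render_images: bool = True,
) -> list[SyntheticPlot]:
    """Generate the full four-date trial.

    Returns ``design.n_dates * design.n_plots`` :class:`SyntheticPlot`
    records.  ``nir_noise_boosts`` gives the above-1000 nm noise multiplier
    per date (default 4x on the first date, 1x after, reproducing the
    stronger early-season NIR scattering).  With ``render_images=False``
    the quadrat images are skipped and ``true_cover`` is the logistic-link
    cover itself (no rasterization granularity).
    """
    design = design or TrialDesign()
    growth = growth or GrowthModel()
    endmembers = endmembers or default_endmembers()
    if len(growth.dw_means) != design.n_dates:
        raise ConfigurationError(
            "growth model and design disagree on the number of dates"
        )
    if nir_noise_boosts is None:
        nir_noise_boosts = [4.0] + [1.0] * (design.n_dates - 1)
    if len(nir_noise_boosts) != design.n_dates:
        raise ConfigurationError("one NIR noise boost per date required")

    root = np.random.SeedSequence(design.seed)
    date_seeds = root.spawn(design.n_dates)
    plots: list[SyntheticPlot] = []
    layout = list(design.plots())
    n = len(layout)
    sigma = growth.plot_cv
    k = growth.cc_logistic_slope

    for di, date in enumerate(design.dates):
        rng = np.random.default_rng(date_seeds[di])
        z_dw = rng.standard_normal(n)
        z_nc = rng.standard_normal(n)
        e_cc = rng.standard_normal(n) * growth.cc_logit_sd_effective

        # mean-corrected log-normal plot effects keep E[DW] at the target
        dw = growth.dw_means[di] * np.exp(sigma * z_dw - 0.5 * sigma**2)

        rho = growth.nc_dw_tradeoff if di >= 2 else 0.0
        z_mix = rho * z_dw + np.sqrt(max(0.0, 1.0 - rho**2)) * z_nc
        nc = np.clip(
            growth.nc_means[di] + growth.nc_sd_effective * z_mix, 2.0, 7.0
        )

        log_dw = np.log(dw)
        if sigma == 0 and growth.cc_logit_sd_effective == 0:
            cc = np.full(n, growth.cc_means[di])
        else:
            m = _solve_cover_midpoint(log_dw, e_cc, k, growth.cc_means[di])
            cc = 1.0 / (1.0 + np.exp(-(k * (log_dw - m) + e_cc)))

        for pi, (plot_id, density, n_level, cultivar) in enumerate(layout):
            if render_images:
                image, true_cover = render_canopy_image(
                    cc[pi], width=image_size, height=image_size, rng=rng
                )
            else:
                image, true_cover = None, float(cc[pi])
            spectrum = generate_spectrum(
                true_cover,
                endmembers,
                noise_sd=noise_sd,
                nir_noise_boost=nir_noise_boosts[di],
                rng=rng,
                plot_id=plot_id,
                date=date,
            )
            plots.append(
                SyntheticPlot(
                    plot_id=plot_id,
                    date=date,
                    cultivar=cultivar,
                    density=density,
                    n_level=n_level,
                    dw=float(dw[pi]),
                    nc=float(nc[pi]),
                    nup=float(dw[pi] * nc[pi] / 100.0),
                    true_cover=true_cover,
                    spectrum=spectrum,
                    image=image,
                )
            )
    return plots


def trial_tables(plots: Sequence[SyntheticPlot]) -> tuple[pd.DataFrame, list[Spectrum]]:
    """Split a generated trial into a trait table and a spectrum list."""
    traits = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "date": [p.date for p in plots],
            "cultivar": [p.cultivar for p in plots],
            "density": [p.density for p in plots],
            "n_level": [p.n_level for p in plots],
            "dw_kg_ha": [p.dw for p in plots],
            "nc_pct": [p.nc for p in plots],
            "nup_kg_ha": [p.nup for p in plots],
            "cc_true": [p.true_cover for p in plots],
        }
    )
    return traits, [p.spectrum for p in plots]


def write_trial(
    plots: Sequence[SyntheticPlot],
    outdir,
    image_format: str = "png",
    jpeg_quality: int = 95,
) -> None:
    """Write traits CSV, per-date spectra CSVs and quadrat images.

    PNG output is lossless (the default); JPEG is offered to study the
    effect of compression on segmentation.
    """
    from .spectra import write_spectra_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits, spectra = trial_tables(plots)
    traits.to_csv(outdir / "traits.csv", index=False)
    for date in traits["date"].unique():
        write_spectra_csv(
            [s for s in spectra if s.date == date],
            outdir / f"spectra_{date}.csv",
        )
    for p in plots:
        if p.image is None:
            continue
        img = Image.fromarray(p.image)
        name = f"{p.plot_id}_{p.date}.{image_format}"
        if image_format.lower() in ("jpg", "jpeg"):
            img.save(outdir / name, quality=jpeg_quality)
        else:
            img.save(outdir / name)
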