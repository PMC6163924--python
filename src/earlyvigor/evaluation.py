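"""Per-date correlation of sensor methods with target traits, and the
summary table aggregating them.

Every sensor method (image canopy cover, the active two-band NDVI, the
nine established hyperspectral indices, spectral unmixing, the best
contour-map index) is linearly correlated with every target trait (dry
weight, N content, N uptake, canopy cover) on every sampling date.  The
squared Pearson correlation is reported with a significance star, then
aggregated across dates into a mean (level) and a coefficient of
variation (temporal stability), both computed over the raw per-date R^2
values, non-significant ones included.  Ratio rows compare the best
contour-map R^2 per date with the best established sensor method and
with the best established hyperspectral index.

Display arithmetic mirrors how such tables are conventionally printed:
values are rounded half-up to two decimals, per-date ratio cells are
computed from the 2-dp per-date values, while mean-column ratios use the
unrounded means.  Full precision is retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import SampleSizeError, UndefinedCorrelationError
from .contour import ContourAggregate
from .spectra import ESTABLISHED_INDICES

__all__ = [
    "ESTABLISHED_VI_METHODS",
    "SENSOR_METHODS",
    "CONTOUR_METHOD",
    "r2_and_p",
    "significance_stars",
    "round_half_up",
    "ContourSummary",
    "SummaryTable",
    "build_summary",
    "rank_methods",
]

#: the nine established hyperspectral vegetation indices
ESTABLISHED_VI_METHODS: tuple = tuple(sorted(ESTABLISHED_INDICES))
#: all established sensor methods (everything except the contour-map best)
SENSOR_METHODS: tuple = (
    "canopy_cover",
    "greenseeker",
    "spectral_unmixing",
) + ESTABLISHED_VI_METHODS
CONTOUR_METHOD = "contour_map_best"

#: target trait label -> column name accepted in a trait table
TRAIT_COLUMNS = {
    "dw": ("dw", "dw_kg_ha"),
    "nc": ("nc", "nc_pct"),
    "nup": ("nup", "nup_kg_ha"),
    "cc": ("cc", "cc_true"),
}


def r2_and_p(x, y) -> tuple[float, float, int]:
    """Squared Pearson correlation with a two-sided p (t transform, n-2 df).

    Pairs with a missing value in either variable are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise SampleSizeError(f"need >= 3 paired observations, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p), int(n)


def significance_stars(p_value: float) -> str:
    """Conventional star notation; thresholds are strict inequalities."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with halves away from zero (display convention)."""
    if not np.isfinite(x):
        return x
    scale = 10.0**decimals
    return math.copysign(
        math.floor(abs(x) * scale + 0.5 + 1e-9) / scale, x
    )


@dataclass
class ContourSummary:
    """Contour-map inputs to the summary table for one trait.

    ``per_date`` has one row per date: ``date, max_r2, band1_nm,
    band2_nm`` (the per-date matrix maxima).  ``mean_max_r2`` is the
    maximum of the across-date *mean* matrix, ``cv_at_best`` the CV of
    that same band pair, and ``mean_pair`` its wavelengths.
    """

    per_date: pd.DataFrame
    mean_max_r2: float
    cv_at_best: float
    mean_pair: tuple[float, float]

    @classmethod
    def from_aggregate(cls, agg: ContourAggregate) -> "ContourSummary":
        return cls(
            per_date=agg.per_date.copy(),
            mean_max_r2=agg.best_mean_r2,
            cv_at_best=agg.cv_at_best,
            mean_pair=agg.best_pair,
        )


def _mean_cv(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    if values.size < 2 or mean == 0:
        return mean, np.nan
    sd = float(np.std(values, ddof=1))
    return mean, sd / mean


@dataclass
class SummaryTable:
    """Method x trait correlation summary with ratio rows.

    Attributes
    ----------
    per_date
        ``trait, method, date, r2, p, stars`` (p/stars NaN/'' when the
        R^2 values were supplied rather than computed).
    aggregates
        ``trait, method, mean_r2, cv_r2``; NaN when any date is missing
        (means over partially unobserved rows are not reconstructable).
    contour
        trait -> :class:`ContourSummary`.
    ratios
        ``trait, column (date label or 'mean'), competitor ('sensor' or
        'vi'), ratio`` — the contour-map gain rows.
    dates
        Ordered date labels.
    """

    per_date: pd.DataFrame
    aggregates: pd.DataFrame
    contour: dict = field(default_factory=dict)
    ratios: pd.DataFrame = field(default_factory=pd.DataFrame)
    dates: tuple = ()

    @classmethod
    def from_per_date(
        cls,
        per_date: pd.DataFrame,
        contour: Mapping[str, ContourSummary] | None = None,
        dates: Sequence[str] | None = None,
    ) -> "SummaryTable":
        """Aggregate a long-format per-date R^2 table.

        ``per_date`` needs columns ``trait, method, date, r2`` (optional
        ``p``).  Missing cells may be absent rows or NaN.
        """
        per_date = per_date.copy()
        if "p" not in per_date.columns:
            per_date["p"] = np.nan
        per_date["stars"] = [
            significance_stars(p) if np.isfinite(p) else ""
            for p in per_date["p"]
        ]
        if dates is None:
            dates = tuple(pd.unique(per_date["date"]))
        dates = tuple(dates)
        contour = dict(contour or {})

        agg_rows = []
        for (trait, method), sub in per_date.groupby(
            ["trait", "method"], sort=False
        ):
            vals = sub.set_index("date")["r2"].reindex(dates).to_numpy(float)
            if np.all(np.isfinite(vals)):
                mean, cv = _mean_cv(vals)
            else:
                mean, cv = np.nan, np.nan
            agg_rows.append(
                {"trait": trait, "method": method, "mean_r2": mean, "cv_r2": cv}
            )
        aggregates = pd.DataFrame(agg_rows)

        ratio_rows = []
        for trait, csum in contour.items():
            tsub = per_date[per_date["trait"] == trait]
            cpd = csum.per_date.set_index("date")["max_r2"]
            for d in dates:
                if d not in cpd.index or not np.isfinite(cpd[d]):
                    continue
                c2 = round_half_up(float(cpd[d]))
                dsub = tsub[tsub["date"] == d].dropna(subset=["r2"])
                for competitor, pool in (
                    ("sensor", SENSOR_METHODS),
                    ("vi", ESTABLISHED_VI_METHODS),
                ):
                    vals = dsub[dsub["method"].isin(pool)]["r2"]
                    if vals.empty:
                        ratio = np.nan
                    else:
                        best = max(round_half_up(float(v)) for v in vals)
                        ratio = round_half_up(c2 / best) if best > 0 else np.nan
                    ratio_rows.append(
                        {
                            "trait": trait,
                            "column": d,
                            "competitor": competitor,
                            "ratio": ratio,
                        }
                    )
            # mean column: unrounded means against the given contour mean max
            asub = aggregates[aggregates["trait"] == trait].dropna(
                subset=["mean_r2"]
            )
            for competitor, pool in (
                ("sensor", SENSOR_METHODS),
                ("vi", ESTABLISHED_VI_METHODS),
            ):
                vals = asub[asub["method"].isin(pool)]["mean_r2"]
                if vals.empty or not np.isfinite(csum.mean_max_r2):
                    ratio = np.nan
                else:
                    best = float(vals.max())
                    ratio = (
                        round_half_up(csum.mean_max_r2 / best)
                        if best > 0
                        else np.nan
                    )
                ratio_rows.append(
                    {
                        "trait": trait,
                        "column": "mean",
                        "competitor": competitor,
                        "ratio": ratio,
                    }
                )
        return cls(
            per_date=per_date,
            aggregates=aggregates,
            contour=contour,
            ratios=pd.DataFrame(ratio_rows),
            dates=dates,
        )

    # -- lookups ---------------------------------------------------------

    def cell(self, trait: str, method: str, date: str) -> float:
        sub = self.per_date[
            (self.per_date["trait"] == trait)
            & (self.per_date["method"] == method)
            & (self.per_date["date"] == date)
        ]
        if sub.empty:
            raise KeyError((trait, method, date))
        return float(sub["r2"].iloc[0])

    def aggregate_cell(self, trait: str, method: str) -> tuple[float, float]:
        sub = self.aggregates[
            (self.aggregates["trait"] == trait)
            & (self.aggregates["method"] == method)
        ]
        if sub.empty:
            raise KeyError((trait, method))
        return float(sub["mean_r2"].iloc[0]), float(sub["cv_r2"].iloc[0])

    def ratio_cell(self, trait: str, column: str, competitor: str) -> float:
        sub = self.ratios[
            (self.ratios["trait"] == trait)
            & (self.ratios["column"] == column)
            & (self.ratios["competitor"] == competitor)
        ]
        if sub.empty:
            raise KeyError((trait, column, competitor))
        return float(sub["ratio"].iloc[0])

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Plain-text rendering, one block per trait."""

        def fmt(v, stars=""):
            if v is None or not np.isfinite(v):
                return "".ljust(9)
            return f"{round_half_up(v):.2f}{stars}".ljust(9)

        out = []
        for trait in pd.unique(self.per_date["trait"]):
            out.append(f"Trait: {trait}")
            head = "method".ljust(20) + "".join(
                str(d).ljust(9) for d in self.dates
            ) + "mean".ljust(9) + "CV".ljust(9)
            out.append(head)
            out.append("-" * len(head))
            tsub = self.per_date[self.per_date["trait"] == trait]
            for method in pd.unique(tsub["method"]):
                msub = tsub[tsub["method"] == method].set_index("date")
                cells = []
                for d in self.dates:
                    if d in msub.index and np.isfinite(msub.loc[d, "r2"]):
                        cells.append(
                            fmt(msub.loc[d, "r2"], msub.loc[d, "stars"])
                        )
                    else:
                        cells.append("".ljust(9))
                try:
                    mean, cv = self.aggregate_cell(trait, method)
                except KeyError:
                    mean, cv = np.nan, np.nan
                out.append(
                    method.ljust(20) + "".join(cells) + fmt(mean) + fmt(cv)
                )
            if trait in self.contour:
                csum = self.contour[trait]
                cpd = csum.per_date.set_index("date")
                cells = [
                    fmt(float(cpd.loc[d, "max_r2"])) if d in cpd.index else "".ljust(9)
                    for d in self.dates
                ]
                out.append(
                    CONTOUR_METHOD.ljust(20)
                    + "".join(cells)
                    + fmt(csum.mean_max_r2)
                    + fmt(csum.cv_at_best)
                )
                for competitor, label in (
                    ("sensor", "gain vs best method"),
                    ("vi", "gain vs best index"),
                ):
                    cells = []
                    for d in self.dates:
                        try:
                            cells.append(fmt(self.ratio_cell(trait, d, competitor)))
                        except KeyError:
                            cells.append("".ljust(9))
                    try:
                        mcell = fmt(self.ratio_cell(trait, "mean", competitor))
                    except KeyError:
                        mcell = "".ljust(9)
                    out.append(label.ljust(20) + "".join(cells) + mcell)
            out.append("")
        return "\n".join(out)

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_date.to_csv(outdir / "per_date_r2.csv", index=False)
        self.aggregates.to_csv(outdir / "aggregates.csv", index=False)
        if len(self.ratios):
            self.ratios.to_csv(outdir / "contour_ratios.csv", index=False)


def _trait_column(traits: pd.DataFrame, trait: str) -> str:
    for cand in TRAIT_COLUMNS.get(trait, (trait,)):
        if cand in traits.columns:
            return cand
    raise KeyError(f"trait column for {trait!r} not found")


def build_summary(
    method_values: pd.DataFrame,
    traits: pd.DataFrame,
    contour_aggregates: Mapping[str, "ContourAggregate | ContourSummary"]
    | None = None,
    trait_labels: Sequence[str] = ("dw", "nc", "nup", "cc"),
) -> SummaryTable:
    """Correlate every method with every trait per date and aggregate.

    Parameters
    ----------
    method_values
        Long format: ``plot_id, date, method, value`` (one row per
        plot x date x method; NaN values allowed).
    traits
        One row per plot x date with ``plot_id, date`` and trait columns
        (``dw``/``dw_kg_ha``, ``nc``/``nc_pct``, ``nup``/``nup_kg_ha``,
        ``cc``/``cc_true``).
    contour_aggregates
        Optional per-trait contour-map results
        (:class:`~earlyvigor.contour.ContourAggregate` or
        :class:`ContourSummary`).

    Canopy cover is never correlated with itself: the ``canopy_cover``
    method is skipped for the ``cc`` trait.  Cells with fewer than three
    complete pairs or zero variance are left missing.
    """
    rows = []
    dates = tuple(pd.unique(traits["date"]))
    for trait in trait_labels:
        col = _trait_column(traits, trait)
        for method in pd.unique(method_values["method"]):
            if trait == "cc" and method == "canopy_cover":
                continue
            for d in dates:
                mv = method_values[
                    (method_values["method"] == method)
                    & (method_values["date"] == d)
                ][["plot_id", "value"]]
                tv = traits[traits["date"] == d][["plot_id", col]]
                merged = mv.merge(tv, on="plot_id")
                try:
                    r2, p, _ = r2_and_p(merged["value"], merged[col])
                except (SampleSizeError, UndefinedCorrelationError):
                    r2, p = np.nan, np.nan
                rows.append(
                    {
                        "trait": trait,
                        "method": method,
                        "date": d,
                        "r2": r2,
                        "p": p,
                    }
                )
    contour = {
        t: (c if isinstance(c, ContourSummary) else ContourSummary.from_aggregate(c))
        for t, c in (contour_aggregates or {}).items()
    }
    return SummaryTable.from_per_date(
        pd.DataFrame(rows), contour=contour, dates=dates
    )


def rank_methods(summary: SummaryTable, trait: str, date: str) -> list[str]:
    """Methods ordered by descending per-date R^2.

    Ties break alphabetically; methods with a missing cell rank last
    (alphabetically among themselves).
    """
    sub = summary.per_date[
        (summary.per_date["trait"] == trait)
        & (summary.per_date["date"] == date)
    ]
    if sub.empty:
        raise KeyError((trait, date))
    present = sub.dropna(subset=["r2"]).sort_values(
        ["r2", "method"], ascending=[False, True]
    )
    missing = sub[~np.isfinite(sub["r2"])].sort_values("method")
    return list(present["method"]) + list(missing["method"])
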