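"""Published reference values from the winter-wheat early-vigor field trial.

The field data behind the published study this package models are not
public; what is available are the per-date squared correlations (R^2) of
each sensor method with each target trait, as printed in the study's
summary table, together with the contour-map maxima and their band pairs.
These numbers serve two purposes here:

* they are the input for checking the summary-table arithmetic (mean, CV
  and contour-gain ratio rows recomputed from the printed per-date cells
  must reproduce the printed aggregate cells), and
* they document the benchmark the synthetic generator is tuned to emulate
  qualitatively.

Cells the publication left blank (non-significant correlations) are
missing here as well; rows containing them cannot be re-aggregated
because the underlying raw values were never printed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import ContourSummary, SummaryTable

__all__ = [
    "REFERENCE_DATES",
    "load_reference_per_date",
    "load_reference_contour",
    "load_reference_printed_aggregates",
    "load_reference_printed_ratios",
    "load_reference_summary",
]

REFERENCE_DATES = ("D1", "D2", "D3", "D4")

# per-date R^2 of each established sensor method with each target trait;
# None marks cells that were not significant and hence not published
_R2 = {
    "dw": {
        "canopy_cover": (0.76, 0.65, 0.62, 0.50),
        "greenseeker": (0.45, 0.53, 0.55, 0.45),
        "spectral_unmixing": (None, 0.74, 0.70, 0.46),
        "ATSAVI": (0.30, 0.71, 0.68, 0.43),
        "EPVI": (0.29, 0.68, 0.63, None),
        "MCARI": (0.23, 0.50, 0.27, None),
        "MTCI": (0.23, 0.63, 0.76, 0.62),
        "NDRE": (0.31, 0.75, 0.75, 0.61),
        "NDVI": (0.30, 0.72, 0.68, 0.43),
        "PRI": (None, None, 0.58, 0.38),
        "REIP": (0.25, 0.46, 0.77, 0.67),
        "WBI": (None, 0.55, 0.71, 0.61),
    },
    "nc": {
        "canopy_cover": (None, None, None, 0.19),
        "greenseeker": (None, None, 0.17, None),
        "spectral_unmixing": (None, None, 0.24, 0.21),
        "ATSAVI": (None, None, 0.20, 0.34),
        "EPVI": (None, None, 0.17, 0.20),
        "MCARI": (None, None, None, None),
        "MTCI": (None, None, 0.35, 0.31),
        "NDRE": (None, None, 0.28, 0.35),
        "NDVI": (None, None, 0.20, 0.34),
        "PRI": (None, None, 0.17, 0.25),
        "REIP": (None, None, 0.34, 0.30),
        "WBI": (None, None, 0.24, 0.36),
    },
    "nup": {
        "canopy_cover": (0.78, 0.67, 0.69, 0.48),
        "greenseeker": (0.45, 0.54, 0.53, 0.46),
        "spectral_unmixing": (None, 0.75, 0.66, 0.40),
        "ATSAVI": (0.34, 0.72, 0.66, 0.31),
        "EPVI": (0.32, 0.69, 0.62, None),
        "MCARI": (0.27, 0.51, 0.31, None),
        "MTCI": (0.25, 0.64, 0.66, 0.52),
        "NDRE": (0.34, 0.76, 0.69, 0.50),
        "NDVI": (0.34, 0.73, 0.66, 0.32),
        "PRI": (None, None, 0.57, 0.30),
        "REIP": (0.27, 0.48, 0.68, 0.58),
        "WBI": (None, 0.56, 0.66, 0.51),
    },
    "cc": {
        "greenseeker": (0.49, 0.42, 0.73, 0.70),
        "spectral_unmixing": (None, 0.56, 0.63, 0.70),
        "ATSAVI": (0.25, 0.52, 0.68, 0.56),
        "EPVI": (0.23, 0.48, 0.68, 0.35),
        "MCARI": (0.21, 0.36, 0.65, 0.35),
        "MTCI": (0.14, 0.45, 0.47, 0.40),
        "NDRE": (0.25, 0.53, 0.62, 0.50),
        "NDVI": (0.25, 0.53, 0.68, 0.56),
        "PRI": (None, None, 0.71, 0.56),
        "REIP": (0.16, 0.37, 0.48, 0.43),
        "WBI": (None, 0.45, 0.62, 0.39),
    },
}

# contour-map maxima: per-date matrix maxima with their band pairs, and the
# maximum of the across-date mean matrix with its pair and the CV of that
# same pair over the four dates
_CONTOUR = {
    "dw": {
        "per_date": (0.42, 0.79, 0.81, 0.74),
        "pairs": ((676, 664), (774, 748), (826, 746), (1030, 740)),
        "mean_max": 0.67,
        "cv": 0.26,
        "mean_pair": (794, 736),
    },
    "nc": {
        "per_date": (0.37, 0.30, 0.43, 0.49),
        "pairs": ((1018, 978), (1110, 1108), (1130, 546), (1030, 986)),
        "mean_max": 0.22,
        "cv": 0.70,
        "mean_pair": (996, 924),
    },
    "nup": {
        "per_date": (0.45, 0.81, 0.75, 0.68),
        "pairs": ((792, 736), (1068, 544), (758, 754), (1018, 994)),
        "mean_max": 0.63,
        "cv": 0.23,
        "mean_pair": (792, 736),
    },
    "cc": {
        "per_date": (0.42, 0.66, 0.74, 0.74),
        "pairs": ((584, 582), (1134, 580), (556, 552), (1108, 726)),
        "mean_max": 0.55,
        "cv": 0.22,
        "mean_pair": (584, 582),
    },
}

# published mean / CV cells for the rows with all four dates printed
_PRINTED_AGGREGATES = {
    ("dw", "canopy_cover"): (0.63, 0.17),
    ("dw", "greenseeker"): (0.50, 0.11),
    ("dw", "ATSAVI"): (0.53, 0.37),
    ("dw", "MTCI"): (0.56, 0.41),
    ("dw", "NDRE"): (0.61, 0.34),
    ("dw", "NDVI"): (0.53, 0.38),
    ("dw", "REIP"): (0.54, 0.43),
    ("nup", "canopy_cover"): (0.66, 0.19),
    ("nup", "greenseeker"): (0.50, 0.09),
    ("nup", "ATSAVI"): (0.51, 0.42),
    ("nup", "MTCI"): (0.52, 0.36),
    ("nup", "NDRE"): (0.57, 0.33),
    ("nup", "NDVI"): (0.51, 0.42),
    ("nup", "REIP"): (0.50, 0.35),
    ("cc", "greenseeker"): (0.59, 0.26),
    ("cc", "ATSAVI"): (0.50, 0.36),
    ("cc", "EPVI"): (0.44, 0.44),
    ("cc", "MCARI"): (0.39, 0.47),
    ("cc", "MTCI"): (0.37, 0.42),
    ("cc", "NDRE"): (0.48, 0.33),
    ("cc", "NDVI"): (0.51, 0.36),
    ("cc", "REIP"): (0.36, 0.39),
}

# published contour-gain ratio cells: (trait, column, competitor) -> value.
# `consistent` marks whether the cell follows the table's own arithmetic
# (contour max over the best competing 2-dp cell); the two date-2 cells
# marked False are internally inconsistent in the publication and the
# 'mean' cells for N content aggregate values that were never printed.
_PRINTED_RATIOS = {
    ("dw", "D1", "sensor"): (0.55, True),
    ("dw", "D2", "sensor"): (1.07, False),
    ("dw", "D3", "sensor"): (1.05, True),
    ("dw", "D4", "sensor"): (1.10, True),
    ("dw", "mean", "sensor"): (1.06, True),
    ("dw", "D1", "vi"): (1.35, True),
    ("dw", "D2", "vi"): (1.05, True),
    ("dw", "D3", "vi"): (1.05, True),
    ("dw", "D4", "vi"): (1.10, True),
    ("dw", "mean", "vi"): (1.11, True),
    ("nc", "D3", "sensor"): (1.23, True),
    ("nc", "D4", "sensor"): (1.36, True),
    ("nc", "mean", "sensor"): (0.67, False),
    ("nc", "D3", "vi"): (1.23, True),
    ("nc", "D4", "vi"): (1.36, True),
    ("nc", "mean", "vi"): (0.67, False),
    ("nup", "D1", "sensor"): (0.58, True),
    ("nup", "D2", "sensor"): (1.08, False),
    ("nup", "D3", "sensor"): (1.09, True),
    ("nup", "D4", "sensor"): (1.17, True),
    ("nup", "mean", "sensor"): (0.96, True),
    ("nup", "D1", "vi"): (1.32, True),
    ("nup", "D2", "vi"): (1.07, True),
    ("nup", "D3", "vi"): (1.09, True),
    ("nup", "D4", "vi"): (1.17, True),
    ("nup", "mean", "vi"): (1.10, True),
    ("cc", "D1", "sensor"): (0.86, True),
    ("cc", "D2", "sensor"): (1.18, True),
    ("cc", "D3", "sensor"): (1.01, True),
    ("cc", "D4", "sensor"): (1.06, True),
    ("cc", "mean", "sensor"): (0.94, True),
    ("cc", "D1", "vi"): (1.68, True),
    ("cc", "D2", "vi"): (1.25, True),
    ("cc", "D3", "vi"): (1.04, True),
    ("cc", "D4", "vi"): (1.32, True),
    ("cc", "mean", "vi"): (1.09, True),
}


def load_reference_per_date() -> pd.DataFrame:
    """Long-format published per-date R^2 cells (missing cells = NaN)."""
    rows = []
    for trait, methods in _R2.items():
        for method, vals in methods.items():
            for d, v in zip(REFERENCE_DATES, vals):
                rows.append(
                    {
                        "trait": trait,
                        "method": method,
                        "date": d,
                        "r2": np.nan if v is None else float(v),
                    }
                )
    return pd.DataFrame(rows)


def load_reference_contour() -> dict[str, ContourSummary]:
    """Published contour-map maxima per trait as summary inputs."""
    out = {}
    for trait, c in _CONTOUR.items():
        per_date = pd.DataFrame(
            {
                "date": REFERENCE_DATES,
                "max_r2": c["per_date"],
                "band1_nm": [p[0] for p in c["pairs"]],
                "band2_nm": [p[1] for p in c["pairs"]],
            }
        )
        out[trait] = ContourSummary(
            per_date=per_date,
            mean_max_r2=c["mean_max"],
            cv_at_best=c["cv"],
            mean_pair=tuple(map(float, c["mean_pair"])),
        )
    return out


def load_reference_printed_aggregates() -> dict:
    """Published mean/CV cells for fully printed rows: (trait, method) ->
    (mean, cv)."""
    return dict(_PRINTED_AGGREGATES)


def load_reference_printed_ratios(consistent_only: bool = False) -> dict:
    """Published contour-gain ratio cells.

    Returns ``(trait, column, competitor) -> value``.  With
    ``consistent_only=True`` the cells that do not follow the table's own
    arithmetic (and hence cannot be recomputed from printed values) are
    dropped.
    """
    return {
        k: v
        for k, (v, ok) in _PRINTED_RATIOS.items()
        if ok or not consistent_only
    }


def load_reference_summary() -> SummaryTable:
    """Summary table re-aggregated from the published per-date cells."""
    return SummaryTable.from_per_date(
        load_reference_per_date(),
        contour=load_reference_contour(),
        dates=REFERENCE_DATES,
    )
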