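"""Derivation of the 19 standard bioclim variables from monthly normals.

Follows the ANUCLIM/WorldClim definitions. Quarters are the 12 consecutive
3-month windows with December-January wraparound; when two quarters tie
(equally wettest, warmest, ...), the earliest window in January-start order
wins. Standard deviations are population SDs (divide by N), the raster-
statistics convention used throughout this package. The precipitation-
seasonality denominator is 1 + BIO12/12 to stay finite in fully arid cells.
"""

from __future__ import annotations

import numpy as np

from .grid import EnvStack
from .simulate import MonthlyClimate

BIOCLIM_NAMES = [f"BIO{i}" for i in range(1, 20)]

BIOCLIM_DESCRIPTIONS = {
    "BIO1": "annual mean temperature",
    "BIO2": "mean diurnal range",
    "BIO3": "isothermality (100 * BIO2 / BIO7)",
    "BIO4": "temperature seasonality (100 * SD of monthly mean temperature)",
    "BIO5": "max temperature of warmest month",
    "BIO6": "min temperature of coldest month",
    "BIO7": "temperature annual range (BIO5 - BIO6)",
    "BIO8": "mean temperature of wettest quarter",
    "BIO9": "mean temperature of driest quarter",
    "BIO10": "mean temperature of warmest quarter",
    "BIO11": "mean temperature of coldest quarter",
    "BIO12": "annual precipitation",
    "BIO13": "precipitation of wettest month",
    "BIO14": "precipitation of driest month",
    "BIO15": "precipitation seasonality (100 * SD / (1 + BIO12/12))",
    "BIO16": "precipitation of wettest quarter",
    "BIO17": "precipitation of driest quarter",
    "BIO18": "precipitation of warmest quarter",
    "BIO19": "precipitation of coldest quarter",
}


def _quarter_windows(monthly: np.ndarray, reduce: str) -> np.ndarray:
    """Stack of the 12 wraparound 3-month quarter aggregates.

    ``monthly`` has shape (12, ...); returns (12, ...) where entry q
    aggregates months (q, q+1, q+2) mod 12.
    """
    wrapped = np.concatenate([monthly, monthly[:2]], axis=0)
    windows = np.stack([wrapped[q:q + 3] for q in range(12)], axis=0)
    if reduce == "mean":
        return windows.mean(axis=1)
    if reduce == "sum":
        return windows.sum(axis=1)
    raise ValueError(reduce)


def _pick(values: np.ndarray, index: np.ndarray) -> np.ndarray:
    """values[(12, ...)] selected per cell by index[(...)]."""
    return np.take_along_axis(values, index[None], axis=0)[0]


def derive_bioclim(monthly: MonthlyClimate,
                   mask: np.ndarray | None = None) -> EnvStack:
    """Compute BIO1-BIO19 as a 19-layer :class:`EnvStack`."""
    tmax, tmin, precip = monthly.tmax, monthly.tmin, monthly.precip
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin at some valid cell")
    tavg = (tmax + tmin) / 2.0

    qtemp = _quarter_windows(tavg, "mean")
    qprec = _quarter_windows(precip, "sum")
    # earliest-window tie-break: argmax/argmin return the first maximizer
    wettest_q = np.argmax(qprec, axis=0)
    driest_q = np.argmin(qprec, axis=0)
    warmest_q = np.argmax(qtemp, axis=0)
    coldest_q = np.argmin(qtemp, axis=0)

    b = {}
    b["BIO1"] = tavg.mean(axis=0)
    b["BIO2"] = (tmax - tmin).mean(axis=0)
    b["BIO4"] = 100.0 * tavg.std(axis=0)  # population SD
    b["BIO5"] = tmax.max(axis=0)
    b["BIO6"] = tmin.min(axis=0)
    b["BIO7"] = b["BIO5"] - b["BIO6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        b["BIO3"] = np.where(b["BIO7"] > 0, 100.0 * b["BIO2"] / b["BIO7"], 0.0)
    b["BIO8"] = _pick(qtemp, wettest_q)
    b["BIO9"] = _pick(qtemp, driest_q)
    b["BIO10"] = _pick(qtemp, warmest_q)
    b["BIO11"] = _pick(qtemp, coldest_q)
    b["BIO12"] = precip.sum(axis=0)
    b["BIO13"] = precip.max(axis=0)
    b["BIO14"] = precip.min(axis=0)
    b["BIO15"] = 100.0 * precip.std(axis=0) / (1.0 + b["BIO12"] / 12.0)
    b["BIO16"] = _pick(qprec, wettest_q)
    b["BIO17"] = _pick(qprec, driest_q)
    b["BIO18"] = _pick(qprec, warmest_q)
    b["BIO19"] = _pick(qprec, coldest_q)

    layers = np.stack([b[name] for name in BIOCLIM_NAMES])
    return EnvStack(spec=monthly.spec, layers=layers,
                    layer_names=list(BIOCLIM_NAMES), mask=mask)
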