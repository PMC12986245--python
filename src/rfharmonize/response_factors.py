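"""Determination of response factors (RF) and the dataset x compound logRF table.

The response factor of a compound is the slope of the peak-area vs
concentration calibration line (area = RF * concentration + intercept).
Because ESI responses span orders of magnitude, all downstream analysis uses
logRF = log10(RF); with areas of ~1e6 counts at nanomolar spikes this puts
logRF in the 11-15 range (units: log10(area * L / mol)).

Calibrants have a 6-point calibration series and get an OLS slope; suspects
are spiked at two levels only, and their logRF is the log10 of the mean of
the two area/concentration ratios, computed from HPLC-water samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import LOGRF_COLUMNS
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CalibrationFit:
    """OLS calibration of peak area on concentration for one compound-ion."""

    dataset_id: str
    compound_id: str
    ion_species: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    logRF: float  # log10(slope); NaN when slope <= 0


def fit_calibration(
    concentrations: np.ndarray,
    areas: np.ndarray,
    dataset_id: str = "",
    compound_id: str = "",
    ion_species: str = "[M+H]+",
) -> CalibrationFit:
    """Unweighted OLS of area on concentration (intercept included).

    Requires >= 3 points with strictly increasing concentrations and
    nonnegative areas.  ``logRF = log10(slope)``; a nonpositive slope is
    recorded with logRF missing (and logged) rather than raising.
    """
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.size < 3:
        raise ValidationError("calibration needs at least 3 points")
    if not np.all(np.diff(conc) > 0):
        raise ValidationError("calibration concentrations must be strictly increasing")
    if np.any(area < 0):
        raise ValidationError("calibration areas must be nonnegative")

    # covariance form: numerically exact for flat series at mol/L x-scales
    xc = conc - conc.mean()
    yc = area - area.mean()
    slope = float(np.sum(xc * yc) / np.sum(xc * xc))
    intercept = float(area.mean() - slope * conc.mean())
    resid = area - (intercept + slope * conc)
    tss = float(np.sum(yc**2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else np.nan

    if slope > 0:
        logrf = float(np.log10(slope))
    else:
        logrf = np.nan
        logger.warning(
            "nonpositive calibration slope for %s/%s in %s; logRF missing",
            compound_id, ion_species, dataset_id,
        )
    return CalibrationFit(
        dataset_id=dataset_id,
        compound_id=compound_id,
        ion_species=ion_species,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points=int(conc.size),
        logRF=logrf,
    )


def suspect_logrf(areas: np.ndarray, concentrations: np.ndarray) -> float:
    """logRF of a suspect: log10 of the mean area/concentration ratio.

    The ratios (one per spike level) are averaged *before* taking the log.
    Returns NaN unless exactly two QA-kept observations are supplied.
    """
    area = np.asarray(areas, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if area.size != 2 or conc.size != 2 or np.any(~np.isfinite(area)) or np.any(conc <= 0):
        return float("nan")
    return float(np.log10(np.mean(area / conc)))


def build_logrf_table(
    filtered_peaks: pd.DataFrame, suspect_matrix: str = "hplc_water"
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the long logRF table from QA-filtered peaks.

    Calibrants: OLS slope over their detected calibration points (HPLC
    water).  Suspects: mean-ratio logRF from the low/high pair in
    ``suspect_matrix`` only.  Returns ``(logrf_long, per_dataset_range)``
    where the range is max - min logRF per dataset (in orders of magnitude;
    missing for datasets with fewer than 2 values).
    """
    rows = []

    cal = filtered_peaks[
        (filtered_peaks["role"] == "calibrant") & filtered_peaks["detected"]
    ]
    for (ds, comp, ion), grp in cal.groupby(
        ["dataset_id", "compound_id", "ion_species"], sort=True
    ):
        grp = grp.sort_values("concentration")
        if len(grp) < 3:
            continue
        fit = fit_calibration(
            grp["concentration"].to_numpy(), grp["peak_area"].to_numpy(),
            dataset_id=ds, compound_id=comp, ion_species=ion,
        )
        rows.append(
            dict(dataset_id=ds, compound_id=comp, ion_species=ion, role="calibrant",
                 logRF=fit.logRF, slope=fit.slope, intercept=fit.intercept,
                 r_squared=fit.r_squared, n_points=fit.n_points)
        )

    sus = filtered_peaks[
        (filtered_peaks["role"] == "suspect")
        & filtered_peaks["detected"]
        & (filtered_peaks["sample_matrix"] == suspect_matrix)
    ]
    for (ds, comp, ion), grp in sus.groupby(
        ["dataset_id", "compound_id", "ion_species"], sort=True
    ):
        if len(grp) != 2:
            continue  # QA should have rejected single-level cells
        logrf = suspect_logrf(grp["peak_area"].to_numpy(), grp["concentration"].to_numpy())
        rows.append(
            dict(dataset_id=ds, compound_id=comp, ion_species=ion, role="suspect",
                 logRF=logrf, slope=np.nan, intercept=np.nan,
                 r_squared=np.nan, n_points=2)
        )

    logrf = pd.DataFrame(rows, columns=LOGRF_COLUMNS)
    logrf = logrf.dropna(subset=["logRF"]).sort_values(
        ["dataset_id", "compound_id", "ion_species"], kind="mergesort"
    ).reset_index(drop=True)

    grouped = logrf.groupby("dataset_id")["logRF"]
    rng = grouped.max() - grouped.min()
    rng[grouped.count() < 2] = np.nan
    return logrf, rng.rename("raw_logRF_range")


def logrf_matrix(logrf_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long logRF table to a dataset x compound-ion matrix.

    Columns are ``"<compound_id>|<ion_species>"`` keys; missing entries are
    compounds not kept by QA in that dataset.
    """
    key = logrf_long["compound_id"] + "|" + logrf_long["ion_species"]
    wide = (
        logrf_long.assign(key=key)
        .pivot(index="dataset_id", columns="key", values="logRF")
        .sort_index()
    )
    wide.columns.name = None
    return wide


def compound_roles(logrf_long: pd.DataFrame) -> pd.Series:
    """Role per compound-ion key (calibrant/suspect), aligned with logrf_matrix."""
    key = logrf_long["compound_id"] + "|" + logrf_long["ion_species"]
    return logrf_long.assign(key=key).groupby("key")["role"].first()
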