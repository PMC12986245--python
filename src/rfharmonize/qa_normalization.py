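"""Quality assurance and internal-standard normalization of peak tables.

The QA rules reflect how interlaboratory suspect-screening data are curated
before response factors can be compared:

* suspects are spiked at two levels 10x apart; a high/low peak-area ratio
  far above 10 indicates a nonlinear (or matrix-suppressed) response, so
  cells with ratio strictly above the threshold (default 20) are rejected;
* suspects detected at only one of the two levels are rejected;
* calibrants are kept when at least 3 of the 6 calibration points are
  detected (the minimum for a slope with a residual);
* all areas are first normalized to the internal standard (atrazine-d5)
  measured in the same sample injection.

QA is evaluated per (dataset, compound, ion, matrix): a compound may pass in
HPLC water and fail in lake water.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import CAL_LEVELS, PEAK_KEY
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

QA_STATUSES = (
    "kept",
    "rejected_ratio",
    "rejected_high_only",
    "rejected_low_only",
    "rejected_not_detected",
)

#: one QA cell = one compound-ion in one matrix of one dataset
QA_KEY = ["dataset_id", "compound_id", "ion_species", "sample_matrix"]


def normalize_to_internal_standard(
    peaks: pd.DataFrame, is_compound_id: str = "atrazine-d5"
) -> pd.DataFrame:
    """Divide every peak area by the internal-standard area of its sample.

    One "sample" is one injection, keyed by (dataset, matrix, spike level).
    The internal-standard rows are retained with normalized area 1.  Samples
    whose internal standard was not detected are flagged non-normalizable
    (``normalized = False``, area set missing) and logged.
    """
    sample_key = ["dataset_id", "sample_matrix", "spike_level"]
    is_rows = peaks[(peaks["compound_id"] == is_compound_id) & peaks["detected"]]
    is_area = is_rows.set_index(sample_key)["peak_area"]
    if is_area.index.has_duplicates:
        is_area = is_area.groupby(level=sample_key).mean()

    out = peaks.copy()
    idx = pd.MultiIndex.from_frame(out[sample_key])
    denom = pd.Series(is_area.reindex(idx).to_numpy(), index=out.index)
    out["normalized"] = denom.notna()
    out["peak_area"] = out["peak_area"] / denom
    n_bad = int((~out["normalized"] & out["detected"]).sum())
    if n_bad:
        logger.warning(
            "internal standard %s missing for %d detected peak(s); "
            "those samples are excluded downstream", is_compound_id, n_bad,
        )
        out.loc[~out["normalized"], "peak_area"] = np.nan
        out.loc[~out["normalized"], "detected"] = False
    return out


def apply_qa_filters(
    peaks: pd.DataFrame,
    ratio_threshold: float = 20.0,
    min_cal_points: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the suspect ratio/one-level rules and the calibrant point rule.

    Returns ``(qa_report, filtered_peaks)``.  The report has exactly one row
    per (dataset, compound, ion, matrix) cell of the design with a status in
    :data:`QA_STATUSES`; ``area_ratio_high_low`` is present iff both spike
    levels were detected.  ``filtered_peaks`` keeps only detected peaks of
    kept cells.

    The ratio rule is strict: ratio > threshold rejects, ratio == threshold
    keeps (a 10x spike has a theoretical ratio of 10).
    """
    if ratio_threshold <= 0:
        raise ConfigurationError("ratio_threshold must be positive")

    suspects = peaks[peaks["role"] == "suspect"]
    calibrants = peaks[peaks["role"] == "calibrant"]
    if not suspects.empty:
        levels = set(suspects["spike_level"].unique())
        if not levels <= {"low", "high"}:
            raise ConfigurationError(
                f"suspect spike levels must be low/high, got {sorted(levels)}"
            )

    reports = []

    if not suspects.empty:
        # unstack (not pivot_table) so fully-undetected cells stay in the report
        wide = suspects.set_index(QA_KEY + ["spike_level"])["peak_area"].unstack(
            "spike_level"
        )
        for lvl in ("low", "high"):
            if lvl not in wide.columns:
                wide[lvl] = np.nan
        high, low = wide["high"], wide["low"]
        ratio = high / low
        status = pd.Series("rejected_not_detected", index=wide.index)
        status[high.notna() & low.isna()] = "rejected_high_only"
        status[low.notna() & high.isna()] = "rejected_low_only"
        both = high.notna() & low.notna()
        status[both & (ratio > ratio_threshold)] = "rejected_ratio"
        status[both & (ratio <= ratio_threshold)] = "kept"
        rep = status.rename("status").reset_index()
        rep["area_ratio_high_low"] = ratio.where(both).to_numpy()
        rep["n_points_detected"] = (
            high.notna().astype(int) + low.notna().astype(int)
        ).to_numpy()
        reports.append(rep)

    if not calibrants.empty:
        n_det = (
            calibrants[calibrants["detected"]]
            .groupby(QA_KEY, observed=True)
            .size()
            .rename("n_points_detected")
        )
        cells = calibrants[QA_KEY].drop_duplicates().set_index(QA_KEY)
        n_det = n_det.reindex(cells.index, fill_value=0)
        rep = n_det.reset_index()
        rep["status"] = np.where(
            rep["n_points_detected"] >= min_cal_points, "kept", "rejected_not_detected"
        )
        rep["area_ratio_high_low"] = np.nan
        reports.append(rep)

    cols = QA_KEY + ["status", "area_ratio_high_low", "n_points_detected"]
    if reports:
        qa_report = pd.concat(reports, ignore_index=True)[cols]
    else:
        qa_report = pd.DataFrame(columns=cols)
    qa_report = qa_report.sort_values(QA_KEY, kind="mergesort").reset_index(drop=True)

    kept = qa_report.loc[qa_report["status"] == "kept", QA_KEY]
    kept_idx = pd.MultiIndex.from_frame(kept)
    mask_role = peaks["role"].isin(["calibrant", "suspect"])
    in_kept = pd.MultiIndex.from_frame(peaks[QA_KEY]).isin(kept_idx)
    filtered = peaks[(mask_role & in_kept & peaks["detected"]) |
                     (peaks["role"] == "internal_standard")]
    filtered = filtered.sort_values(PEAK_KEY, kind="mergesort").reset_index(drop=True)
    return qa_report, filtered


def detection_frequency(
    qa_report: pd.DataFrame,
    metadata: pd.DataFrame,
    design_cells: pd.DataFrame,
    group_by: str | list[str] | None = None,
    role_cells: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fraction of the spiked design kept per dataset, with group means.

    ``design_cells`` is the full candidate list — one row per spiked
    (compound_id, ion_species), the denominator for every dataset.  The
    numerator counts design cells with QA status ``kept`` (any matrix).
    Group means over ``group_by`` metadata fields are unweighted means over
    the datasets in the group; empty groups are reported missing, not zero.
    """
    cells = design_cells[["compound_id", "ion_species"]].drop_duplicates()
    n_design = len(cells)
    if n_design == 0:
        raise ConfigurationError("empty spike design")

    kept = qa_report[qa_report["status"] == "kept"]
    kept_cells = kept.drop_duplicates(["dataset_id", "compound_id", "ion_species"])
    in_design = pd.MultiIndex.from_frame(
        kept_cells[["compound_id", "ion_species"]]
    ).isin(pd.MultiIndex.from_frame(cells))
    counts = kept_cells[in_design].groupby("dataset_id").size()

    per_dataset = metadata[["dataset_id"]].copy()
    per_dataset["n_kept"] = per_dataset["dataset_id"].map(counts).fillna(0).astype(int)
    per_dataset["n_design"] = n_design
    per_dataset["fraction_detected"] = per_dataset["n_kept"] / n_design

    if group_by is None:
        return per_dataset, None
    if isinstance(group_by, str):
        group_by = [group_by]
    merged = per_dataset.merge(metadata[["dataset_id"] + group_by], on="dataset_id")
    group_means = (
        merged.groupby(group_by, dropna=False)["fraction_detected"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "mean_fraction_detected", "size": "n_datasets"})
        .reset_index()
    )
    return per_dataset, group_means


def rare_ion_species(
    qa_report: pd.DataFrame, n_datasets: int | None = None, max_fraction: float = 0.25
) -> pd.DataFrame:
    """Compound-ion species kept in fewer than ``max_fraction`` of datasets.

    The comparison is strict (fraction < max_fraction includes, equal or
    above excludes); results are sorted by detection fraction ascending.
    """
    if n_datasets is None:
        n_datasets = qa_report["dataset_id"].nunique()
    if n_datasets < 1:
        raise ConfigurationError("need at least one dataset")
    kept = qa_report[qa_report["status"] == "kept"]
    counts = (
        kept.drop_duplicates(["dataset_id", "compound_id", "ion_species"])
        .groupby(["compound_id", "ion_species"])
        .size()
    )
    all_cells = qa_report[["compound_id", "ion_species"]].drop_duplicates()
    counts = counts.reindex(
        pd.MultiIndex.from_frame(all_cells), fill_value=0
    )
    frac = (counts / n_datasets).rename("detection_fraction")
    out = frac[frac < max_fraction].reset_index()
    out["n_datasets_kept"] = (out["detection_fraction"] * n_datasets).round().astype(int)
    return out.sort_values(
        ["detection_fraction", "compound_id", "ion_species"], kind="mergesort"
    ).reset_index(drop=True)
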