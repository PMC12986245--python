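"""Domain model and tabular I/O for interlaboratory response-factor studies.

All tables move through the pipeline as pandas DataFrames with fixed column
names (the *canonical schema* below).  Input files may use different column
names; a column map (plain dict or YAML config) translates them on ingest.

Units: spiked concentrations are stored internally in mol/L.  Files commonly
report nM; ``read_peak_table`` converts on ingest (``concentration_unit``).
Peak areas are arbitrary detector counts and stay as given (normalization to
the internal standard happens downstream).
"""

from __future__ import annotations

import io
import math
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, SchemaError, ValidationError

# --- canonical schemas -----------------------------------------------------

ION_SPECIES = ("[M+H]+", "[M+Na]+", "[M+NH4]+")
ROLES = ("calibrant", "suspect", "internal_standard")
MATRICES = ("hplc_water", "tap_water", "lake_water")
CAL_LEVELS = tuple(f"cal{i}" for i in range(1, 7))
SPIKE_LEVELS = CAL_LEVELS + ("low", "high")

PEAK_COLUMNS = [
    "dataset_id",
    "compound_id",
    "ion_species",
    "role",
    "sample_matrix",
    "spike_level",
    "concentration",
    "peak_area",
    "retention_time",
    "detected",
]
#: columns that must be present in an input peak table (retention_time and
#: detected are derivable/optional)
PEAK_REQUIRED = [
    "dataset_id",
    "compound_id",
    "ion_species",
    "role",
    "sample_matrix",
    "spike_level",
    "concentration",
    "peak_area",
]

#: unique key of one measured peak — one injection per (matrix, level)
PEAK_KEY = ["dataset_id", "compound_id", "ion_species", "sample_matrix", "spike_level"]

META_COLUMNS = [
    "dataset_id",
    "organic_modifier",
    "additive_type",
    "additive_description",
    "aqueous_pH",
    "column_chemistry",
    "flow_mode",
    "injection_volume",
    "injection_volume_band",
    "gradient_length",
    "gradient_length_band",
    "analyzer",
    "vendor",
    "spray_voltage",
    "spray_voltage_band",
    "acquisition",
    "source_type",
    "dilution_factor",
]
META_REQUIRED = ["dataset_id"]

PREDICTION_COLUMNS = [
    "dataset_id",
    "compound_id",
    "approach",
    "sample_matrix",
    "spike_level",
    "predicted_concentration",
    "true_concentration",
]
APPROACHES = (
    "parent_TP",
    "structurally_similar",
    "close_eluting",
    "RandFor_IE",
    "MLR_IE",
)

LOGRF_COLUMNS = [
    "dataset_id",
    "compound_id",
    "ion_species",
    "role",
    "logRF",
    "slope",
    "intercept",
    "r_squared",
    "n_points",
]

_UNIT_TO_MOLAR = {"M": 1.0, "mol/L": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
                  "nM": 1e-9, "pM": 1e-12}


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML analysis config (column maps, thresholds, study settings)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(cfg)!r}")
    return cfg


def _read_any(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype={"dataset_id": str, "compound_id": str})


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        # column_map: canonical name -> name in file
        rename = {v: k for k, v in column_map.items() if v in df.columns}
        df = df.rename(columns=rename)
    return df


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_peak_table(
    path,
    column_map: Mapping[str, str] | None = None,
    concentration_unit: str = "nM",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format peak table into the canonical schema.

    Rows with a missing or zero peak area are flagged ``detected=False`` and
    their area set to NaN; concentrations are converted to mol/L; output is
    stably ordered by (dataset, compound, ion, matrix, level).

    Raises
    ------
    SchemaError
        if a required column is absent (the error names the column).
    ValidationError
        for a negative peak area (names the offending row index) or a
        duplicated (dataset, compound, ion, matrix, level) key.
    """
    df = _apply_column_map(_read_any(path, sep), column_map)
    _require(df, PEAK_REQUIRED, f"peak table {path}")
    return validate_peaks(df, concentration_unit=concentration_unit)


def validate_peaks(df: pd.DataFrame, concentration_unit: str = "M") -> pd.DataFrame:
    """Validate/normalize an in-memory peak table (see :func:`read_peak_table`)."""
    df = df.copy()
    _require(df, PEAK_REQUIRED, "peak table")
    factor = _UNIT_TO_MOLAR.get(concentration_unit)
    if factor is None:
        raise ConfigurationError(f"unknown concentration unit {concentration_unit!r}")
    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce") * factor
    df["peak_area"] = pd.to_numeric(df["peak_area"], errors="coerce")

    neg = df.index[df["peak_area"] < 0]
    if len(neg):
        raise ValidationError(f"negative peak area at row(s) {list(neg[:5])}")

    bad_conc = df.index[(df["concentration"] <= 0) | df["concentration"].isna()]
    if len(bad_conc):
        raise ValidationError(
            f"spiked concentration must be > 0; offending row(s) {list(bad_conc[:5])}"
        )

    if "detected" in df.columns:
        det = df["detected"].astype(bool)
    else:
        det = pd.Series(True, index=df.index)
    det &= df["peak_area"].notna() & (df["peak_area"] > 0)
    df["detected"] = det
    df.loc[~det, "peak_area"] = np.nan

    if "retention_time" not in df.columns:
        df["retention_time"] = np.nan

    dup = df.duplicated(subset=PEAK_KEY, keep=False)
    if dup.any():
        first = df.loc[dup, PEAK_KEY].iloc[0].tolist()
        raise ValidationError(f"duplicated peak key {first}")

    bad_ion = set(df["ion_species"].unique()) - set(ION_SPECIES)
    if bad_ion:
        raise ValidationError(f"unknown ion species {sorted(bad_ion)}")
    bad_role = set(df["role"].unique()) - set(ROLES)
    if bad_role:
        raise ValidationError(f"unknown role {sorted(bad_role)}")

    df = df.sort_values(PEAK_KEY, kind="mergesort").reset_index(drop=True)
    return df[PEAK_COLUMNS]


# --- metadata --------------------------------------------------------------

def injection_volume_band(volume_ul: float) -> str | float:
    """Band an injection volume in µL: '<10', '10–25' (closed), '>25'."""
    if volume_ul is None or (isinstance(volume_ul, float) and math.isnan(volume_ul)):
        return np.nan
    if volume_ul < 10:
        return "<10"
    if volume_ul <= 25:
        return "10–25"
    return ">25"


def spray_voltage_band(kv: float) -> str | float:
    """Band a spray voltage in kV: '<3.0', '3.0–3.5' (closed), '>3.5'."""
    if kv is None or (isinstance(kv, float) and math.isnan(kv)):
        return np.nan
    if kv < 3.0:
        return "<3.0 kV"
    if kv <= 3.5:
        return "3.0–3.5 kV"
    return ">3.5 kV"


def gradient_length_band(minutes: float) -> str | float:
    """Band a gradient length in minutes: '≤25 min' or '>25 min'."""
    if minutes is None or (isinstance(minutes, float) and math.isnan(minutes)):
        return np.nan
    return "≤25 min" if minutes <= 25 else ">25 min"


def read_metadata(
    path,
    column_map: Mapping[str, str] | None = None,
    peaks: pd.DataFrame | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read the per-dataset instrument metadata table.

    Bands (injection volume, spray voltage, gradient length) are derived from
    the raw numeric columns when present; categories that are absent stay
    missing — nothing is imputed.  If ``peaks`` is given, every dataset
    referenced by the peak table must have exactly one metadata row.
    """
    df = _apply_column_map(_read_any(path, sep), column_map)
    _require(df, META_REQUIRED, f"metadata table {path}")
    return validate_metadata(df, peaks=peaks)


def validate_metadata(df: pd.DataFrame, peaks: pd.DataFrame | None = None) -> pd.DataFrame:
    df = df.copy()
    if df["dataset_id"].duplicated().any():
        dups = df.loc[df["dataset_id"].duplicated(), "dataset_id"].tolist()
        raise ValidationError(f"metadata has duplicate dataset rows {dups}")
    for col in META_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for raw, band, fn in [
        ("injection_volume", "injection_volume_band", injection_volume_band),
        ("spray_voltage", "spray_voltage_band", spray_voltage_band),
        ("gradient_length", "gradient_length_band", gradient_length_band),
    ]:
        raw_vals = pd.to_numeric(df[raw], errors="coerce")
        df[raw] = raw_vals
        derived = raw_vals.map(fn)
        df[band] = df[band].where(df[band].notna(), derived)
    df["dilution_factor"] = pd.to_numeric(df["dilution_factor"], errors="coerce").fillna(1.0)
    if peaks is not None:
        missing = set(peaks["dataset_id"].unique()) - set(df["dataset_id"])
        if missing:
            raise ValidationError(
                f"dataset(s) {sorted(missing)} present in peaks but absent from metadata"
            )
    df = df.sort_values("dataset_id", kind="mergesort").reset_index(drop=True)
    return df[META_COLUMNS]


def apply_dilution(peaks: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Correct spiked concentrations by each dataset's dilution factor.

    A dataset measured on 10x diluted samples saw 1/10 of the nominal spike;
    its effective concentrations are divided by the factor.
    """
    factors = metadata.set_index("dataset_id")["dilution_factor"]
    out = peaks.copy()
    out["concentration"] = out["concentration"] / out["dataset_id"].map(factors).fillna(1.0).to_numpy()
    return out


def read_predictions(
    path,
    column_map: Mapping[str, str] | None = None,
    concentration_unit: str = "nM",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a predicted-concentration table (one row per prediction)."""
    df = _apply_column_map(_read_any(path, sep), column_map)
    _require(df, PREDICTION_COLUMNS[:5] + ["predicted_concentration", "true_concentration"],
             f"prediction table {path}")
    factor = _UNIT_TO_MOLAR.get(concentration_unit)
    if factor is None:
        raise ConfigurationError(f"unknown concentration unit {concentration_unit!r}")
    df = df.copy()
    for c in ("predicted_concentration", "true_concentration"):
        df[c] = pd.to_numeric(df[c], errors="coerce") * factor
    return df[PREDICTION_COLUMNS].sort_values(
        ["dataset_id", "compound_id", "approach", "sample_matrix", "spike_level"],
        kind="mergesort",
    ).reset_index(drop=True)


# --- output ----------------------------------------------------------------

def write_table(df: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a result table as TSV/CSV with 12-significant-digit numbers.

    Identifiers round-trip bit-exactly; floats are printed with ``%.12g`` so
    that ``read(write(x))`` equals ``x`` to 12 significant digits.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def linkage_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Convert a scipy linkage matrix to a Newick string with branch lengths.

    Leaf labels are the dataset ids; branch length of a node is the merge
    height of its parent minus its own height (leaves sit at height 0).
    """
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(linkage_matrix)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    if tree.is_leaf():
        return f"({labels[tree.id]}:0);"
    left = build(tree.left, tree.dist)
    right = build(tree.right, tree.dist)
    return f"({left},{right});"
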