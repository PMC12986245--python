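"""Synthetic interlaboratory studies with known ground truth.

The generator emulates the structure of a quantitative non-target screening
ring trial: each laboratory (dataset) measures 41 calibrants at six known
concentrations and 45 suspects spiked at two levels (10x apart) into three
water matrices, plus an isotope-labelled internal standard in every sample.

The statistical model:

* every compound c has a latent log10 ionization efficiency ``logIE_c`` on
  the anchor scale (uniform over [11, 15.3]);
* laboratory l observes ``logRF_{l,c} = a_l + b_l * logIE_c + eps_{l,c}``
  with lab offset ``a_l ~ N(0, 1.5)``, lab slope ``b_l`` lognormal (median
  1, sd of log ~0.2), and compound-lab noise ``eps`` whose sd inflates for
  poorly ionizing compounds: ``sd = sigma_l * (1 + gamma * max(0, 15 -
  logIE_c))`` — the heteroscedasticity that makes low-logRF compounds less
  consistent across laboratories;
* the anchor laboratory has (a, b) = (0, 1), so the anchor logRF scale *is*
  the latent logIE scale;
* peak areas are ``10^logRF * conc`` with multiplicative measurement noise
  (sd 0.05 in log10, truncated at 2 sd so a QA-clean high/low pair keeps
  its area ratio inside [5, 20]);
* detection of each peak is Bernoulli with a logistic probability in
  log10(area); the midpoint is lab-specific and lower (more sensitive) for
  methanol-modifier laboratories, reproducing modifier-linked detection
  frequency differences;
* a configurable fraction of suspects violates QA: nonlinear responders
  (area ~ conc^p, p in [1.35, 1.7], so the high/low area ratio exceeds 20)
  and matrix-suppressed compounds (attenuated in tap/lake water);
* optionally one laboratory is a nanospray outlier with a compressed
  logIE dependence and extra compound-specific scatter;
* predicted concentrations per quantification approach are ``true * 10^d``
  with d normal around metadata-linked shifts (default: buffer additive
  shifts log error by -0.5, i.e. underprediction) — ground truth for the
  error analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import APPROACHES, CAL_LEVELS, validate_metadata, validate_peaks
from .exceptions import ConfigurationError

IS_COMPOUND = "atrazine-d5"


@dataclass
class StudyConfig:
    """Design and noise parameters of one synthetic interlaboratory study."""

    n_datasets: int = 37
    n_calibrants: int = 41
    n_suspects: int = 45
    n_cal_levels: int = 6
    cal_conc_range: tuple[float, float] = (5e-10, 5e-8)   # mol/L, 2 orders
    spike_low_range: tuple[float, float] = (0.85e-9, 890e-9)  # mol/L; high = 10x
    spike_ratio: float = 10.0
    logie_range: tuple[float, float] = (11.0, 15.3)
    lab_offset_sd: float = 1.5
    lab_slope_log_sd: float = 0.2
    noise_sd_range: tuple[float, float] = (0.1, 0.4)     # sigma_l, log10 units
    heteroscedasticity: float = 0.2                      # gamma per log-unit below 15
    area_noise_sd: float = 0.05                          # per measurement, log10
    detection_midpoint: float = 4.0                      # log10 area
    detection_midpoint_sd: float = 0.5
    detection_scale: float = 0.4
    meoh_detection_shift: float = -0.5                   # MeOH labs detect more
    frac_nonlinear: float = 0.05
    frac_matrix_suppressed: float = 0.05
    include_nanospray: bool = True
    anchor_id: str = "L38"
    is_logie: float = 8.0          # chosen so IS normalization preserves scale
    is_conc: float = 1e-8          # mol/L
    prediction_shift_buffer: float = -0.5   # planted log-error shift for buffer
    prediction_error_scale: float = 1.0     # multiplies per-approach error sds
    meta_p_meoh: float = 18 / 37
    #: if set, additive type is Bernoulli(p=additive_balance) independent of
    #: the organic modifier — used for designed experiments (e.g. planted
    #: additive effects) where the effect must not be confounded with labs
    additive_balance: float | None = None
    matrix_suppression_range: tuple[float, float] = (0.5, 1.5)  # log10 attenuation

    def validate(self) -> None:
        if min(self.n_datasets, self.n_calibrants, self.n_suspects,
               self.n_cal_levels) < 1:
            raise ConfigurationError("all design counts must be >= 1")
        lo_area = self.logie_range[0] + np.log10(self.cal_conc_range[1])
        if self.detection_midpoint - 2 * self.detection_midpoint_sd > \
                self.logie_range[1] + np.log10(self.cal_conc_range[1]):
            raise ConfigurationError(
                "detection midpoint above the whole achievable area range"
            )
        del lo_area


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    logie: pd.Series                  # latent logIE per compound
    labs: pd.DataFrame                # per-lab a, b, sigma, detection midpoint
    qa_violations: pd.DataFrame       # compound -> violation type
    error_shifts: dict                # metadata level -> planted log-error shift
    config: StudyConfig


def _truncnorm(rng, sd, size, clip=2.0):
    """Normal(0, sd) truncated at +/- clip*sd (resampled, not clipped)."""
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > clip * sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, bad.sum())
        bad = np.abs(out) > clip * sd
    return out


def generate_study(
    config: StudyConfig | None = None, seed: int = 42
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (peaks, metadata, predictions, ground_truth) for one study."""
    config = config or StudyConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    # --- compounds ----------------------------------------------------------
    calibrants = [f"cal_{i:02d}" for i in range(1, config.n_calibrants + 1)]
    suspects = [f"sus_{i:02d}" for i in range(1, config.n_suspects + 1)]
    compounds = calibrants + suspects
    lo, hi = config.logie_range
    logie = pd.Series(rng.uniform(lo, hi, len(compounds)), index=compounds)
    logie[IS_COMPOUND] = config.is_logie

    n_nl = int(round(config.frac_nonlinear * config.n_suspects))
    n_ms = int(round(config.frac_matrix_suppressed * config.n_suspects))
    violators = rng.choice(suspects, size=n_nl + n_ms, replace=False)
    # exponent > 1.5 keeps the high/low area ratio above 20 even at the
    # truncated measurement-noise extremes (+/- 0.2 on the log ratio)
    nonlinear = {c: rng.uniform(1.55, 1.9) for c in violators[:n_nl]}
    # (base attenuation of the high spike, extra attenuation of the low
    # spike) in log10 units: suppression is stronger at low analyte level,
    # which pushes the area ratio above the QA threshold by construction
    suppressed = {c: (rng.uniform(*config.matrix_suppression_range),
                      rng.uniform(0.55, 1.0)) for c in violators[n_nl:]}
    qa_viol = pd.DataFrame(
        [{"compound_id": c, "violation": "nonlinear", "param": p}
         for c, p in nonlinear.items()]
        + [{"compound_id": c, "violation": "matrix_suppressed", "param": p[0]}
           for c, p in suppressed.items()],
        columns=["compound_id", "violation", "param"],
    )

    # --- laboratories ---------------------------------------------------------
    lab_ids = [f"L{i}" for i in range(1, config.n_datasets + 1)]
    if config.anchor_id not in lab_ids:
        lab_ids[-1] = config.anchor_id
    anchor = config.anchor_id

    modifier = np.where(rng.random(config.n_datasets) < config.meta_p_meoh,
                        "MeOH", "MeCN")
    if config.additive_balance is not None:
        additive = np.where(rng.random(config.n_datasets)
                            < config.additive_balance, "buffer", "acid")
    else:
        additive = np.where(
            modifier == "MeOH",
            np.where(rng.random(config.n_datasets) < 0.5, "acid", "buffer"),
            np.where(rng.random(config.n_datasets) < 18 / 19, "acid", "buffer"),
        )
    ph = np.where(additive == "acid", rng.uniform(2.5, 4.0, config.n_datasets),
                  rng.uniform(3.0, 6.8, config.n_datasets))
    analyzer = np.where(rng.random(config.n_datasets) < 0.6, "Orbitrap", "ToF")
    vendors = rng.choice(["VendorA", "VendorB", "VendorC", "VendorD"],
                         config.n_datasets)
    column = rng.choice(["RP", "HILIC", "mixed"], config.n_datasets,
                        p=[0.9, 0.05, 0.05])
    flow = np.where(rng.random(config.n_datasets) < 0.8, "fixed", "varying")
    inj_vol = rng.choice([1.0, 2.0, 5.0, 10.0, 20.0, 30.0], config.n_datasets,
                         p=[0.1, 0.1, 0.2, 0.35, 0.15, 0.1])
    gradient = rng.uniform(10.0, 40.0, config.n_datasets)
    spray = rng.uniform(2.5, 4.0, config.n_datasets)
    acquisition = np.where(rng.random(config.n_datasets) < 0.5, "DDA", "MS1")

    a = rng.normal(0.0, config.lab_offset_sd, config.n_datasets)
    b = np.exp(rng.normal(0.0, config.lab_slope_log_sd, config.n_datasets))
    sigma = rng.uniform(*config.noise_sd_range, config.n_datasets)

    source = np.array(["standard ESI"] * config.n_datasets, dtype=object)
    anchor_idx = lab_ids.index(anchor)
    a[anchor_idx], b[anchor_idx] = 0.0, 1.0
    if config.include_nanospray and config.n_datasets >= 3:
        nano_idx = (anchor_idx + 1) % config.n_datasets
        source[nano_idx] = "nanospray"
        b[nano_idx] = 0.3            # compressed logIE dependence
        a[nano_idx] = 13.0 * (1 - 0.3)  # keep areas in a plausible range

    # a lab's detection limit follows its own response scale: the midpoint
    # (given on the anchor's log-area scale) is mapped through the lab's
    # affine transform at the centre of the latent logIE range
    mid_ie = float(np.mean(config.logie_range))
    midpoint = (a + (b - 1.0) * mid_ie
                + rng.normal(config.detection_midpoint,
                             config.detection_midpoint_sd, config.n_datasets)
                + np.where(modifier == "MeOH", config.meoh_detection_shift, 0.0))

    metadata = pd.DataFrame({
        "dataset_id": lab_ids,
        "organic_modifier": modifier,
        "additive_type": additive,
        "additive_description": np.where(additive == "acid",
                                         "0.1% formic acid", "ammonium acetate"),
        "aqueous_pH": np.round(ph, 2),
        "column_chemistry": column,
        "flow_mode": flow,
        "injection_volume": inj_vol,
        "gradient_length": np.round(gradient, 1),
        "analyzer": analyzer,
        "vendor": vendors,
        "spray_voltage": np.round(spray, 2),
        "acquisition": acquisition,
        "source_type": source,
        "dilution_factor": 1.0,
    })

    labs_truth = pd.DataFrame({
        "dataset_id": lab_ids, "a": a, "b": b, "sigma": sigma,
        "detection_midpoint": midpoint, "organic_modifier": modifier,
        "additive_type": additive, "source_type": source,
    })

    # --- latent logRF per (lab, compound) -----------------------------------
    logie_arr = logie[compounds].to_numpy()
    het = 1.0 + config.heteroscedasticity * np.maximum(0.0, 15.0 - logie_arr)
    eps_sd = sigma[:, None] * het[None, :]
    nano_mask = source == "nanospray"
    if nano_mask.any():
        eps_sd[nano_mask] = np.sqrt(eps_sd[nano_mask] ** 2 + 0.5**2)
    eps = rng.normal(0.0, 1.0, eps_sd.shape) * eps_sd
    logrf = a[:, None] + b[:, None] * logie_arr[None, :] + eps  # (labs, compounds)
    logrf_is = a + b * config.is_logie  # IS measured noiselessly per lab

    # --- samples -------------------------------------------------------------
    cal_conc = np.logspace(np.log10(config.cal_conc_range[0]),
                           np.log10(config.cal_conc_range[1]),
                           config.n_cal_levels)
    sus_low = pd.Series(
        10 ** rng.uniform(np.log10(config.spike_low_range[0]),
                          np.log10(config.spike_low_range[1]),
                          config.n_suspects),
        index=suspects,
    )

    comp_index = {c: i for i, c in enumerate(compounds)}
    rows = []

    def emit(lab_i, comp, role, matrix, level, conc, logrf_val, power=1.0,
             atten=0.0):
        noise = _truncnorm(rng, config.area_noise_sd, 1)[0]
        if power == 1.0:
            log_area = logrf_val + np.log10(conc) + noise - atten
        else:
            # nonlinear responder: area ~ conc^power around a 1 nM pivot
            log_area = logrf_val + power * (np.log10(conc) + 9.0) - 9.0 \
                + noise - atten
        p_det = 1.0 / (1.0 + np.exp(-(log_area - midpoint[lab_i])
                                    / config.detection_scale))
        detected = rng.random() < p_det
        rows.append((
            lab_ids[lab_i], comp, "[M+H]+", role, matrix, level,
            conc * 1e9,  # emitted in nM, as study files report
            10 ** log_area if detected else np.nan,
            float(rng.uniform(1.0, 30.0)),
            detected,
        ))

    for lab_i in range(config.n_datasets):
        for comp in calibrants:
            ci = comp_index[comp]
            for j, conc in enumerate(cal_conc):
                emit(lab_i, comp, "calibrant", "hplc_water", CAL_LEVELS[j],
                     conc, logrf[lab_i, ci])
        for comp in suspects:
            ci = comp_index[comp]
            power = nonlinear.get(comp, 1.0)
            for matrix in ("hplc_water", "tap_water", "lake_water"):
                if matrix != "hplc_water" and comp in suppressed:
                    base, extra_low = suppressed[comp]
                else:
                    base, extra_low = 0.0, 0.0
                for level, conc in (("low", sus_low[comp]),
                                    ("high", sus_low[comp] * config.spike_ratio)):
                    atten = base + (extra_low if level == "low" else 0.0)
                    emit(lab_i, comp, "suspect", matrix, level, conc,
                         logrf[lab_i, ci], power=power, atten=atten)
        # internal standard: one row per sample injection
        for matrix, level in (
            [("hplc_water", lvl) for lvl in CAL_LEVELS]
            + [(m, lvl) for m in ("hplc_water", "tap_water", "lake_water")
               for lvl in ("low", "high")]
        ):
            noise = _truncnorm(rng, config.area_noise_sd, 1)[0]
            area = 10 ** (logrf_is[lab_i] + np.log10(config.is_conc) + noise)
            rows.append((lab_ids[lab_i], IS_COMPOUND, "[M+H]+",
                         "internal_standard", matrix, level,
                         config.is_conc * 1e9, area,
                         float(rng.uniform(1.0, 30.0)), True))

    peaks = pd.DataFrame(rows, columns=[
        "dataset_id", "compound_id", "ion_species", "role", "sample_matrix",
        "spike_level", "concentration", "peak_area", "retention_time",
        "detected",
    ])
    peaks = validate_peaks(peaks, concentration_unit="nM")

    # --- predicted concentrations -------------------------------------------
    shifts = {"buffer": config.prediction_shift_buffer, "acid": 0.0}
    approach_sd = {"parent_TP": 0.5, "structurally_similar": 0.45,
                   "close_eluting": 0.6, "RandFor_IE": 0.3, "MLR_IE": 0.35}
    pred_rows = []
    for lab_i, lab in enumerate(lab_ids):
        shift = shifts[additive[lab_i]]
        for comp in suspects:
            for matrix in ("hplc_water", "tap_water", "lake_water"):
                for level, conc in (("low", sus_low[comp]),
                                    ("high", sus_low[comp] * config.spike_ratio)):
                    for approach in APPROACHES:
                        sd = approach_sd[approach] * config.prediction_error_scale
                        delta = rng.normal(shift, sd)
                        pred_rows.append((lab, comp, approach, matrix, level,
                                          conc * 10**delta, conc))
    predictions = pd.DataFrame(pred_rows, columns=[
        "dataset_id", "compound_id", "approach", "sample_matrix",
        "spike_level", "predicted_concentration", "true_concentration",
    ])

    metadata = validate_metadata(metadata, peaks=peaks)
    truth = GroundTruth(logie=logie, labs=labs_truth, qa_violations=qa_viol,
                        error_shifts=shifts, config=config)
    return peaks, metadata, predictions, truth


def anchor_scale_truth(truth: GroundTruth) -> pd.Series:
    """True logRF on the anchor scale after internal-standard normalization.

    Normalizing to the internal standard divides every area in a sample by
    the IS area, which on the anchor (a=0, b=1) shifts logRF by
    -(logIE_IS + log10(conc_IS)); the defaults make that shift zero, so the
    anchor-scale truth is simply the latent logIE.
    """
    cfg = truth.config
    shift = cfg.is_logie + np.log10(cfg.is_conc * 1e9) - 9.0
    return truth.logie.drop(IS_COMPOUND) - shift


def truth_report(
    truth: GroundTruth,
    projected_wide: pd.DataFrame,
    diagnostics: pd.DataFrame,
    qa_report: pd.DataFrame | None = None,
) -> dict:
    """Recovery metrics of a pipeline run against the generator's truth.

    Returns per-lab slope recovery (fitted LM slope times true lab slope,
    ideally 1), the RMSE of projected logRFs against the anchor-scale truth,
    and — when a QA report is supplied — the fate of the planted
    QA-violating compounds.
    """
    target = anchor_scale_truth(truth)
    key_to_comp = {f"{c}|[M+H]+": c for c in target.index}

    resid = []
    for ds in projected_wide.index:
        row = projected_wide.loc[ds].dropna()
        for key, val in row.items():
            comp = key_to_comp.get(key)
            if comp is not None:
                resid.append(val - target[comp])
    rmse = float(np.sqrt(np.mean(np.square(resid)))) if resid else np.nan

    lab_b = truth.labs.set_index("dataset_id")["b"]
    report = {"projection_rmse": rmse, "n_projected_values": len(resid)}

    if "slope" in diagnostics.columns:
        lm_rows = diagnostics[diagnostics.get("method", "LM") == "LM"]
        prod = lm_rows.set_index("dataset_id")["slope"] * lab_b
        # the fitted projection slope should invert the lab's own slope
        report["slope_recovery"] = prod.dropna().to_dict()
        rel_err = (prod.dropna() - 1.0).abs()
        report["slope_recovery_max_rel_err"] = float(rel_err.max()) if len(rel_err) else np.nan
        report["slope_recovery_median_rel_err"] = float(rel_err.median()) if len(rel_err) else np.nan

    if qa_report is not None and not truth.qa_violations.empty:
        viol = truth.qa_violations.set_index("compound_id")["violation"]
        cells = qa_report[qa_report["compound_id"].isin(viol.index)].copy()
        cells["violation"] = cells["compound_id"].map(viol)
        # the violation only manifests where it was planted: nonlinear
        # responders everywhere, matrix suppression outside HPLC water
        relevant = cells[(cells["violation"] == "nonlinear")
                         | (cells["sample_matrix"] != "hplc_water")]
        n_cells = len(relevant)
        n_flagged = int((relevant["status"] != "kept").sum())
        report["qa_violation_cells"] = n_cells
        report["qa_violation_flagged"] = n_flagged
        report["qa_violation_flag_rate"] = n_flagged / n_cells if n_cells else np.nan
    report["lab_slope_true"] = lab_b.to_dict()
    return report
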