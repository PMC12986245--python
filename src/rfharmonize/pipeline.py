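"""End-to-end orchestration: simulate/ingest -> QA -> logRF -> projection ->
consistency -> error statistics -> report.

Each stage writes its table under the output directory; a run manifest
(JSON) records the config snapshot, seed, input digests and output
inventory so a completed run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import write_table
from .exceptions import RFHarmonizeError
from .qa_normalization import (apply_qa_filters, detection_frequency,
                               normalize_to_internal_standard, rare_ion_species)
from .response_factors import build_logrf_table, compound_roles, logrf_matrix
from .anchor_projection import project_study
from .consistency_stats import (cluster_datasets, similarity_matrix,
                                ss_consistency, ss_spread,
                                ss_vs_logrf_correlation)
from .error_analysis import (attribute_features, compute_errors,
                             fit_error_model, friedman_by_parameter,
                             wilcoxon_by_parameter)
from .synthetic_data import StudyConfig, generate_study, truth_report

logger = logging.getLogger(__name__)

TWO_LEVEL_PARAMS = ["organic_modifier", "additive_type", "analyzer",
                    "gradient_length_band"]
THREE_LEVEL_PARAMS = ["injection_volume_band", "spray_voltage_band"]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    out_dir: str | os.PathLike,
    seed: int = 42,
    study_config: StudyConfig | None = None,
    peaks: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    predictions: pd.DataFrame | None = None,
    anchor_id: str | None = None,
    is_compound: str = "atrazine-d5",
    ratio_threshold: float = 20.0,
    projection_method: str = "both",
    min_overlap: int = 6,
    run_ml: bool = True,
    write_report: bool = True,
) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    When ``peaks`` is None a synthetic study is generated from
    ``study_config`` and ``seed``.  Returns a dict of in-memory results
    (tables, fits, manifest).  Stage failures surface as
    :class:`RFHarmonizeError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {"package_version": __version__, "seed": seed, "stages": [],
                "outputs": {}}

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    def save(name, df):
        path = out / f"{name}.tsv"
        write_table(df, path)
        manifest["outputs"][name] = _digest(path)

    try:
        if peaks is None:
            stage("simulate")
            study_config = study_config or StudyConfig()
            peaks, metadata, predictions, truth = generate_study(study_config, seed)
            results["truth"] = truth
            save("peaks", peaks)
            save("metadata", metadata)
            save("predictions", predictions)
            manifest["study_config"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(study_config).items()
            }
        else:
            truth = None
        if metadata is None:
            raise RFHarmonizeError("qa stage: metadata table is required")
        if anchor_id is None:
            anchor_id = (study_config.anchor_id if study_config is not None
                         else metadata["dataset_id"].iloc[0])
    except RFHarmonizeError:
        raise
    except Exception as exc:
        raise RFHarmonizeError(f"simulate stage failed: {exc}") from exc

    try:
        stage("qa")
        normalized = normalize_to_internal_standard(peaks, is_compound)
        qa_report, filtered = apply_qa_filters(normalized, ratio_threshold)
        design = peaks.loc[peaks["role"].isin(["calibrant", "suspect"]),
                           ["compound_id", "ion_species", "role"]].drop_duplicates()
        det_freq, det_groups = detection_frequency(
            qa_report, metadata, design, group_by="organic_modifier")
        rare = rare_ion_species(qa_report, metadata["dataset_id"].nunique())
        results.update(qa_report=qa_report, filtered=filtered,
                       detection_frequency=det_freq,
                       detection_groups=det_groups, rare_ions=rare)
        save("qa_report", qa_report)
        save("detection_frequency", det_freq)
        save("rare_ion_species", rare)
    except RFHarmonizeError:
        raise
    except Exception as exc:
        raise RFHarmonizeError(f"qa stage failed: {exc}") from exc

    try:
        stage("rf")
        logrf_long, raw_ranges = build_logrf_table(filtered)
        results.update(logrf=logrf_long, raw_ranges=raw_ranges)
        save("logrf", logrf_long)
    except Exception as exc:
        raise RFHarmonizeError(f"rf stage failed: {exc}") from exc

    try:
        stage("project")
        wide = logrf_matrix(logrf_long)
        roles = compound_roles(logrf_long)
        # pass 1: calibrant-only fits for the LM/GAM model comparison
        projected_cal, diag_cal, fits_cal = project_study(
            wide, roles, anchor_id, method=projection_method,
            fit_on="calibrant", min_overlap=min_overlap)
        # pass 2: all-compound LM used for the consistency analysis
        projected_all, diag_all, fits_all = project_study(
            wide, roles, anchor_id, method="lm", fit_on="all",
            min_overlap=min_overlap)
        results.update(logrf_wide=wide, roles=roles,
                       projected=projected_all, diagnostics=diag_cal,
                       diagnostics_all=diag_all, fits=fits_cal)
        save("projection_diagnostics", diag_cal)
        save("projected_logrf",
             projected_all.reset_index().rename(columns={"index": "dataset_id"}))
    except Exception as exc:
        raise RFHarmonizeError(f"project stage failed: {exc}") from exc

    try:
        stage("consistency")
        per_comp = ss_consistency(projected_all, "per_compound")
        per_data = ss_consistency(projected_all, "per_dataset")
        sim, overlaps = similarity_matrix(projected_all)
        z, newick, flat = cluster_datasets(sim, n_clusters=3)
        rho, rho_p = (np.nan, np.nan)
        if len(per_comp) >= 5:
            rho, rho_p = ss_vs_logrf_correlation(per_comp)
        results.update(ss_per_compound=per_comp, ss_per_dataset=per_data,
                       similarity=sim, linkage=z, newick=newick,
                       clusters=flat, ss_logrf_rho=rho, ss_logrf_rho_p=rho_p)
        save("ss_per_compound", per_comp)
        save("ss_per_dataset", per_data)
        save("similarity", sim.reset_index(names="dataset_id"))
        (out / "clusters.nwk").write_text(newick + "\n", encoding="utf-8")
        manifest["outputs"]["clusters"] = _digest(out / "clusters.nwk")
    except Exception as exc:
        raise RFHarmonizeError(f"consistency stage failed: {exc}") from exc

    if predictions is not None:
        try:
            stage("errors")
            errors = compute_errors(predictions)
            wilcoxon_tables = []
            for param in TWO_LEVEL_PARAMS:
                levels = metadata[param].dropna().nunique()
                if levels == 2:
                    wilcoxon_tables.append(
                        wilcoxon_by_parameter(errors, metadata, param))
            wilcoxon_all = (pd.concat(wilcoxon_tables, ignore_index=True)
                            if wilcoxon_tables else pd.DataFrame())
            friedman_results = []
            for param in THREE_LEVEL_PARAMS:
                if metadata[param].dropna().nunique() >= 3:
                    friedman_results.append(
                        friedman_by_parameter(errors, metadata, param))
            results.update(errors=errors, wilcoxon=wilcoxon_all,
                           friedman=friedman_results)
            if not wilcoxon_all.empty:
                save("wilcoxon_tests", wilcoxon_all)
            if run_ml and errors["dataset_id"].nunique() >= 3:
                em = fit_error_model(errors, metadata, target="log_error",
                                     seed=seed)
                attr = attribute_features(em)
                results.update(error_model=em, attribution=attr)
                save("attribution_summary", attr["summary"])
                save("attribution_directions", attr["directions"])
        except Exception as exc:
            raise RFHarmonizeError(f"errors stage failed: {exc}") from exc

    if truth is not None:
        stage("truth")
        results["truth_report"] = truth_report(
            truth, projected_all, diag_all, qa_report)

    if write_report:
        stage("report")
        render_report(results, out)
        report_path = out / "report.md"
        if report_path.exists():
            manifest["outputs"]["report"] = _digest(report_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str),
                             encoding="utf-8")
    results["manifest"] = manifest
    return results


def render_report(results: dict, out_dir: str | os.PathLike) -> Path:
    """Write a static markdown summary with range-bar and heatmap figures.

    Sections for which results are missing are skipped with a notice;
    regeneration from the same results is idempotent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Response-factor harmonization report", ""]

    diag = results.get("diagnostics")
    if diag is not None and not diag.empty:
        lines += ["## Projection diagnostics", "",
                  "Datasets ordered by R^2 (projected vs anchor logRF).", "",
                  "```", diag.sort_values("r_squared", ascending=False)
                  .to_string(index=False, float_format=lambda v: f"{v:.3f}"),
                  "```", ""]
        fig_path = out / "range_bars.png"
        _plot_range_bars(diag, fig_path)
        lines += [f"![logRF ranges]({fig_path.name})", ""]
    else:
        lines += ["## Projection diagnostics", "", "_not available_", ""]

    per_comp = results.get("ss_per_compound")
    per_data = results.get("ss_per_dataset")
    if per_comp is not None and len(per_comp) >= 2 and len(per_data) >= 2:
        lines += [
            "## Consistency (mean squared deviation from consensus)", "",
            f"- SS spread across datasets: {ss_spread(per_data):.3f}",
            f"- SS spread across compounds: {ss_spread(per_comp):.3f}",
            f"- Spearman rho, SS_comp vs mean projected logRF: "
            f"{results.get('ss_logrf_rho', float('nan')):.3f} "
            f"(p={results.get('ss_logrf_rho_p', float('nan')):.3g})", ""]
    else:
        lines += ["## Consistency", "", "_not available_", ""]

    sim = results.get("similarity")
    if sim is not None and not sim.empty:
        fig_path = out / "similarity_heatmap.png"
        _plot_heatmap(sim, fig_path)
        lines += ["## Dataset similarity", "",
                  f"![similarity heatmap]({fig_path.name})", "",
                  "Dendrogram (Newick): see `clusters.nwk`.", ""]

    wil = results.get("wilcoxon")
    if wil is not None and not wil.empty:
        lines += ["## Rank tests on prediction fold errors", "", "```",
                  wil.to_string(index=False,
                                float_format=lambda v: f"{v:.4f}"),
                  "```", ""]

    attr = results.get("attribution")
    if attr is not None:
        lines += ["## Error-model feature attribution", "", "```",
                  attr["summary"].to_string(index=False,
                                            float_format=lambda v: f"{v:.4f}"),
                  "```", ""]

    path = out / "report.md"
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def _plot_range_bars(diag: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = diag.dropna(subset=["r_squared"]).sort_values("r_squared",
                                                      ascending=False)
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(d)), 4))
    x = np.arange(len(d))
    ax.bar(x - 0.2, d["raw_range"], width=0.4, label="raw", color="0.7")
    ax.bar(x + 0.2, d["projected_range"], width=0.4, label="projected",
           color="purple")
    ax.set_xticks(x)
    ax.set_xticklabels(d["dataset_id"], rotation=90, fontsize=7)
    ax.set_ylabel("logRF range (orders of magnitude)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_heatmap(sim: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sim.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(sim)))
    ax.set_xticklabels(sim.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(sim)))
    ax.set_yticklabels(sim.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="squared correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
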