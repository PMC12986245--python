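"""Concentration-prediction error statistics and instrument-parameter effects.

Prediction quality is summarised per record by the ratio predicted/true:
``fold_error = max(ratio, 1/ratio)`` (always >= 1, symmetric in over/under
prediction) and the signed ``log_error = log10(ratio)`` (negative =
underprediction).  Two-level instrument parameters are tested with the
Wilcoxon rank-sum test (effect size r = |Z|/sqrt(N), Bonferroni-adjusted
over the approach x spike-level strata); three-level parameters with the
Friedman test on compound-blocked median fold errors, followed by Nemenyi
all-pairs comparisons when significant.

A random-forest regressor models log error from compound, approach and
instrument descriptors (HPLC-water high spike only, grouped 80:20 split so
no dataset leaks across the split).  Feature attribution walks each tree's
decision path and credits every split's change in node mean to the split
feature, so per-prediction attributions sum exactly to prediction minus
baseline; permutation importance is available as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupShuffleSplit

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

ML_FEATURES = [
    "compound_id",
    "approach",
    "analyzer",
    "additive_type",
    "organic_modifier",
    "injection_volume",
    "spray_voltage",
    "gradient_length",
]


def compute_errors(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-record prediction error measures.

    Records with a nonpositive predicted or true concentration are skipped
    with a log entry.
    """
    df = predictions.copy()
    bad = (df["predicted_concentration"] <= 0) | (df["true_concentration"] <= 0) \
        | df["predicted_concentration"].isna() | df["true_concentration"].isna()
    if bad.any():
        logger.warning("skipping %d prediction record(s) with nonpositive "
                       "concentrations", int(bad.sum()))
        df = df[~bad]
    ratio = df["predicted_concentration"] / df["true_concentration"]
    df = df.assign(
        ratio=ratio,
        fold_error=np.maximum(ratio, 1.0 / ratio),
        log_error=np.log10(ratio),
    )
    df["log_fold_error"] = np.abs(df["log_error"])
    return df.reset_index(drop=True)


# --- rank tests -------------------------------------------------------------

def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> float:
    """Z of the rank-sum statistic, with tie and continuity correction."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0
    diff = u1 - mu
    cc = -0.5 if diff > 0 else (0.5 if diff < 0 else 0.0)
    return float((diff + cc) / np.sqrt(sigma2))


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided rank-sum test with effect size r = |Z|/sqrt(N).

    Exact null enumeration when both groups have <= 10 observations (and no
    ties across groups); otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    exact = len(x) <= 10 and len(y) <= 10 and \
        len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    z = _wilcoxon_z(x, y)
    r = abs(z) / np.sqrt(len(x) + len(y))
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "z": z, "effect_size_r": float(r), "method": method,
            "n": (len(x), len(y))}


def wilcoxon_by_parameter(
    errors: pd.DataFrame,
    metadata: pd.DataFrame,
    parameter: str,
    value: str = "fold_error",
) -> pd.DataFrame:
    """Rank-sum tests of a two-level instrument parameter, per stratum.

    Strata are the approach x spike-level combinations; the Bonferroni
    family is all strata actually tested for this parameter.  Strata where
    either parameter level has fewer than 2 observations are skipped.
    """
    merged = errors.merge(metadata[["dataset_id", parameter]], on="dataset_id")
    merged = merged.dropna(subset=[parameter])
    levels = sorted(merged[parameter].unique())
    if len(levels) != 2:
        raise ConfigurationError(
            f"parameter {parameter!r} has {len(levels)} level(s); need exactly 2"
        )
    rows = []
    for (approach, lvl), grp in merged.groupby(["approach", "spike_level"]):
        g1 = grp.loc[grp[parameter] == levels[0], value].to_numpy()
        g2 = grp.loc[grp[parameter] == levels[1], value].to_numpy()
        if len(g1) < 2 or len(g2) < 2:
            logger.info("stratum (%s, %s) skipped for %s: group too small",
                        approach, lvl, parameter)
            continue
        res = wilcoxon_rank_sum(g1, g2)
        rows.append({
            "parameter": parameter, "groups": f"{levels[0]} vs {levels[1]}",
            "approach": approach, "spike_level": lvl,
            "n1": len(g1), "n2": len(g2),
            "statistic": res["statistic"], "p_value": res["p_value"],
            "effect_size_r": res["effect_size_r"], "method": res["method"],
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    return out


def friedman_by_parameter(
    errors: pd.DataFrame,
    metadata: pd.DataFrame,
    parameter: str,
    value: str = "fold_error",
    alpha: float = 0.05,
) -> dict:
    """Friedman test of a (>= 3)-level parameter on blocked median errors.

    Blocks are compounds; the cell value is the median ``value`` over all
    datasets at that parameter level.  Compounds missing any level are
    dropped.  When significant, Nemenyi all-pairs p-values are computed
    from the studentized-range distribution.
    """
    merged = errors.merge(metadata[["dataset_id", parameter]], on="dataset_id")
    merged = merged.dropna(subset=[parameter])
    levels = sorted(merged[parameter].unique())
    if len(levels) < 3:
        raise ConfigurationError(
            f"parameter {parameter!r} has {len(levels)} level(s); need >= 3"
        )
    table = merged.pivot_table(index="compound_id", columns=parameter,
                               values=value, aggfunc="median")
    table = table.dropna()
    n, k = table.shape
    if n < 3:
        return {"parameter": parameter, "tested": False,
                "reason": f"only {n} complete block(s); need >= 3",
                "statistic": np.nan, "p_value": np.nan, "posthoc": None,
                "n_blocks": n, "levels": levels}
    if np.allclose(table.to_numpy(), table.to_numpy()[:, [0]]):
        # identical columns: no rank variation at all
        statistic, p = 0.0, 1.0
    else:
        statistic, p = stats.friedmanchisquare(*[table[c] for c in table.columns])
    posthoc = None
    if p < alpha:
        posthoc = nemenyi_posthoc(table)
    return {"parameter": parameter, "tested": True, "statistic": float(statistic),
            "p_value": float(p), "posthoc": posthoc, "n_blocks": n,
            "levels": list(table.columns)}


def nemenyi_posthoc(blocked: pd.DataFrame) -> pd.DataFrame:
    """Nemenyi all-pairs comparisons after a Friedman test.

    Within-block mid-ranks are averaged per treatment; the standardized
    mean-rank difference is referred to the studentized range distribution
    with k groups and infinite degrees of freedom.
    """
    ranks = blocked.rank(axis=1)
    mean_ranks = ranks.mean(axis=0)
    n, k = blocked.shape
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    cols = list(blocked.columns)
    p = pd.DataFrame(np.ones((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks.iloc[i] - mean_ranks.iloc[j]) / se
            pij = float(stats.studentized_range.sf(q, k, np.inf)) if q > 0 else 1.0
            p.iloc[i, j] = p.iloc[j, i] = min(1.0, pij)
    return p


# --- random-forest error model ---------------------------------------------

@dataclass
class ErrorModel:
    """Fitted error regressor with its encoders and held-out score."""

    model: RandomForestRegressor
    encoders: dict[str, pd.Index]
    features: list[str]
    target: str
    r2_test: float
    train_datasets: list[str]
    test_datasets: list[str]
    X_test: np.ndarray
    y_test: np.ndarray
    X_all: np.ndarray


def _encode(df: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, dict]:
    """Integer-encode categorical features (sorted label order)."""
    encoders = {}
    cols = []
    for f in features:
        cats = pd.Index(sorted(df[f].astype(str).unique()))
        encoders[f] = cats
        cols.append(cats.get_indexer(df[f].astype(str)))
    return np.column_stack(cols).astype(float), encoders


def fit_error_model(
    errors: pd.DataFrame,
    metadata: pd.DataFrame,
    target: str = "log_error",
    seed: int = 42,
    sample_matrix: str = "hplc_water",
    spike_level: str = "high",
    test_size: float = 0.2,
) -> ErrorModel:
    """Random forest regressing log error on compound/method descriptors.

    Uses only the HPLC-water high-spike records.  100 trees, unlimited
    depth, min split 2, min leaf 1; 80:20 split grouped by dataset so each
    laboratory lands wholly in train or test.  The held-out R^2 is the
    standard coefficient of determination, taken as 0 when the test target
    is constant.
    """
    data = errors[(errors["sample_matrix"] == sample_matrix)
                  & (errors["spike_level"] == spike_level)]
    meta_cols = [c for c in ML_FEATURES if c in metadata.columns]
    data = data.merge(metadata[["dataset_id"] + meta_cols], on="dataset_id")
    data = data.dropna(subset=[target]).reset_index(drop=True)
    if data["dataset_id"].nunique() < 3:
        raise ConfigurationError("need >= 3 distinct datasets for a grouped split")

    X, encoders = _encode(data, ML_FEATURES)
    y = data[target].to_numpy()
    groups = data["dataset_id"].to_numpy()
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    train_idx, test_idx = next(splitter.split(X, y, groups))

    model = RandomForestRegressor(
        n_estimators=100, max_depth=None, min_samples_split=2,
        min_samples_leaf=1, random_state=seed, n_jobs=1,
    )
    model.fit(X[train_idx], y[train_idx])
    y_test = y[test_idx]
    if np.std(y_test) == 0:
        r2 = 0.0
    else:
        r2 = float(model.score(X[test_idx], y_test))
    return ErrorModel(
        model=model, encoders=encoders, features=list(ML_FEATURES),
        target=target, r2_test=r2,
        train_datasets=sorted(set(groups[train_idx])),
        test_datasets=sorted(set(groups[test_idx])),
        X_test=X[test_idx], y_test=y_test, X_all=X,
    )


def _forest_path_attributions(
    model: RandomForestRegressor, X: np.ndarray
) -> tuple[np.ndarray, float]:
    """Additive per-prediction attributions from decision paths.

    For every tree, each split on the path contributes (child mean - parent
    mean) to the split feature; contributions are averaged over trees, so
    baseline + sum(attributions) equals the forest prediction exactly.
    """
    n, p = X.shape
    contrib = np.zeros((n, p))
    baseline = 0.0
    for est in model.estimators_:
        t = est.tree_
        values = t.value.reshape(-1)
        baseline += values[0]
        indicator = est.decision_path(X.astype(np.float32))  # csr (n, nodes)
        # child -> parent and parent split feature
        parent = np.full(t.node_count, -1)
        for node in range(t.node_count):
            for child in (t.children_left[node], t.children_right[node]):
                if child != -1:
                    parent[child] = node
        indptr, indices = indicator.indptr, indicator.indices
        for i in range(n):
            path = indices[indptr[i]:indptr[i + 1]]
            for node in path[1:]:
                par = parent[node]
                contrib[i, t.feature[par]] += values[node] - values[par]
    contrib /= len(model.estimators_)
    baseline /= len(model.estimators_)
    return contrib, float(baseline)


def attribute_features(
    em: ErrorModel,
    data: pd.DataFrame | None = None,
    method: str = "path",
    seed: int = 42,
) -> dict:
    """Per-feature attribution summary for a fitted error model.

    ``method='path'`` gives additive per-prediction attributions (see
    :func:`_forest_path_attributions`); ``method='permutation'`` uses
    scikit-learn permutation importance on the held-out set.  The summary
    reports mean |attribution| per feature and, for categorical levels,
    the mean signed attribution per level (direction).
    """
    X = em.X_all if data is None else data
    if method == "permutation":
        from sklearn.inspection import permutation_importance
        res = permutation_importance(em.model, em.X_test, em.y_test,
                                     n_repeats=10, random_state=seed)
        summary = pd.DataFrame({
            "feature": em.features,
            "mean_abs_attribution": res.importances_mean,
        }).sort_values("mean_abs_attribution", ascending=False, kind="mergesort")
        return {"method": method, "summary": summary.reset_index(drop=True),
                "directions": None, "attributions": None, "baseline": None}

    contrib, baseline = _forest_path_attributions(em.model, X)
    summary = pd.DataFrame({
        "feature": em.features,
        "mean_abs_attribution": np.abs(contrib).mean(axis=0),
    }).sort_values("mean_abs_attribution", ascending=False, kind="mergesort")

    directions = []
    for f_idx, f in enumerate(em.features):
        codes = X[:, f_idx].astype(int)
        for code in np.unique(codes):
            mask = codes == code
            directions.append({
                "feature": f,
                "level": str(em.encoders[f][code]),
                "mean_attribution": float(contrib[mask, f_idx].mean()),
                "n": int(mask.sum()),
            })
    return {"method": method, "summary": summary.reset_index(drop=True),
            "directions": pd.DataFrame(directions),
            "attributions": contrib, "baseline": baseline}
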