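"""Agreement of projected logRFs across datasets and compounds.

After projection to the anchor scale, ideally each compound's logRF would be
identical in every dataset.  Departures are quantified with mean squared
deviations from the compound's cross-dataset mean:

* ``SS_comp`` (per compound): sum((logRF - mean)^2)/n over the n datasets
  detecting that compound — the biased variance of its projected values;
* ``SS_data`` (per dataset): the same deviations (each compound centred on
  its *cross-dataset* mean), averaged over the compounds that dataset
  detected — how far one laboratory sits from the consensus.

Dataset similarity is a matrix of squared Pearson or Spearman correlations
on pairwise-shared compounds, clustered agglomeratively (complete linkage
on 1 - R^2) with a Newick-exportable dendrogram.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import linkage_to_newick
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def ss_consistency(projected_wide: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Consistency statistics per compound or per dataset.

    ``projected_wide`` is the dataset x compound-ion matrix of projected
    logRFs (missing = not detected/kept).  Returns one row per id with
    columns (scope, id, n, mean_logRF, SS).  Entries with n = 0 are omitted;
    n = 1 gives SS = 0.
    """
    if scope not in ("per_compound", "per_dataset"):
        raise ValidationError(f"unknown scope {scope!r}")
    comp_mean = projected_wide.mean(axis=0, skipna=True)
    dev2 = (projected_wide - comp_mean) ** 2

    rows = []
    if scope == "per_compound":
        for comp in projected_wide.columns:
            vals = projected_wide[comp].dropna()
            if len(vals) == 0:
                continue
            rows.append({
                "scope": scope, "id": comp, "n": len(vals),
                "mean_logRF": float(vals.mean()),
                "SS": float(((vals - vals.mean()) ** 2).sum() / len(vals)),
            })
    else:
        for ds in projected_wide.index:
            d = dev2.loc[ds].dropna()
            if len(d) == 0:
                continue
            vals = projected_wide.loc[ds].dropna()
            rows.append({
                "scope": scope, "id": ds, "n": len(d),
                "mean_logRF": float(vals.mean()),
                "SS": float(d.sum() / len(d)),
            })
    return pd.DataFrame(rows, columns=["scope", "id", "n", "mean_logRF", "SS"])


def ss_spread(stats_table: pd.DataFrame) -> float:
    """max - min of the SS values within one scope."""
    if len(stats_table) < 2:
        raise ValidationError("ss_spread needs at least 2 entries")
    return float(stats_table["SS"].max() - stats_table["SS"].min())


def similarity_matrix(
    projected_wide: pd.DataFrame,
    method: str = "pearson",
    min_pair_overlap: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise squared correlations between datasets.

    Correlations are computed on the compounds detected in *both* datasets
    of each pair; pairs sharing fewer than ``min_pair_overlap`` compounds,
    or containing a constant vector, are missing (and logged).  Spearman
    uses mid-ranks for ties.  Returns ``(r2_matrix, overlap_counts)``; the
    matrix is symmetric with unit diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if len(projected_wide.index) < 2:
        raise ValidationError("similarity needs at least 2 datasets")
    ids = list(projected_wide.index)
    n = len(ids)
    r2 = pd.DataFrame(np.eye(n), index=ids, columns=ids)
    counts = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i in range(n):
        counts.iloc[i, i] = int(projected_wide.iloc[i].notna().sum())
        for j in range(i + 1, n):
            a = projected_wide.iloc[i]
            b = projected_wide.iloc[j]
            shared = a.dropna().index.intersection(b.dropna().index)
            counts.iloc[i, j] = counts.iloc[j, i] = len(shared)
            if len(shared) < min_pair_overlap:
                r2.iloc[i, j] = r2.iloc[j, i] = np.nan
                continue
            av, bv = a[shared].to_numpy(), b[shared].to_numpy()
            if np.std(av) == 0 or np.std(bv) == 0:
                logger.warning("constant logRF vector in pair (%s, %s); "
                               "similarity missing", ids[i], ids[j])
                r2.iloc[i, j] = r2.iloc[j, i] = np.nan
                continue
            if method == "pearson":
                r = stats.pearsonr(av, bv).statistic
            else:
                r = stats.spearmanr(av, bv).statistic
            r2.iloc[i, j] = r2.iloc[j, i] = float(r**2)
    return r2, counts


def cluster_datasets(
    r2_matrix: pd.DataFrame, n_clusters: int | None = None
) -> tuple[np.ndarray, str, pd.Series | None]:
    """Agglomerative clustering of datasets on distance 1 - R^2.

    Complete linkage; missing pairs are imputed with the matrix minimum
    similarity (logged).  Dataset order is lexicographic, which makes ties
    deterministic.  Returns ``(linkage_matrix, newick, flat_clusters)``
    (flat clusters only when ``n_clusters`` is given).
    """
    ids = sorted(r2_matrix.index)
    if len(ids) < 2:
        raise ValidationError("clustering needs at least 2 datasets")
    m = r2_matrix.loc[ids, ids].to_numpy(dtype=float).copy()
    off_diag = m[~np.eye(len(ids), dtype=bool)]
    finite = off_diag[np.isfinite(off_diag)]
    if np.isnan(m).any():
        fill = float(finite.min()) if finite.size else 0.0
        logger.warning("imputing %d missing similarity pair(s) with matrix "
                       "minimum %.4f", int(np.isnan(off_diag).sum() // 2), fill)
        m[np.isnan(m)] = fill
    np.fill_diagonal(m, 1.0)
    dist = 1.0 - m
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    newick = linkage_to_newick(z, ids)
    flat = None
    if n_clusters is not None:
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
        flat = pd.Series(labels, index=ids, name="cluster")
    return z, newick, flat


def ss_vs_logrf_correlation(per_compound: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of SS_comp with mean projected logRF.

    Low-logRF compounds sit near detection limits, so their projected
    values tend to scatter more; a negative correlation is the expected
    signature.  Returns (rho, p); (nan, nan) when undefined (constant SS
    or fewer than 5 compounds).
    """
    if len(per_compound) < 5:
        raise ValidationError("need at least 5 compounds")
    ss = per_compound["SS"].to_numpy()
    mean_logrf = per_compound["mean_logRF"].to_numpy()
    if np.ptp(ss) == 0 or np.ptp(mean_logrf) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(ss, mean_logrf)
    return float(res.statistic), float(res.pvalue)
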