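"""Projection of per-dataset logRF scales onto an anchoring dataset.

Instrument and method differences make raw logRF values incomparable across
laboratories; they are therefore projected onto the scale of one anchoring
dataset.  For each dataset a mapping is fitted on the compounds shared with
the anchor — the dataset's logRF is the predictor and the anchor's logRF the
response — and the fitted mapping is then applied to *all* of the dataset's
logRFs (calibrants and suspects).  Regressing onto the anchor keeps the
projection a plain evaluation (no inversion, well defined for the spline
model) and produces the characteristic range compression when the overlap
correlation is poor: the fitted slope attenuates toward zero, so the
projected range shrinks by a factor |slope|.

Two mappings are supported:

* ``LM`` — ordinary least squares line;
* ``GAM`` — penalized cubic regression spline (basis dimension k = 6, knots
  at quantiles of the overlap predictor values, integrated squared second
  derivative penalty) with the smoothing parameter chosen by GCV.

Model choice per dataset uses a two-sided variance-ratio F-test on the
suspect residuals of the two mappings; the simpler LM is preferred unless
the test is significant and the spline has the lower mean squared residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SplineConfig:
    """Cubic-regression-spline settings for the GAM projection."""

    k: int = 6                      # basis dimension (number of knots)
    lambda_grid: tuple[float, float] = (1e-6, 1e6)
    n_grid: int = 61                # log-spaced GCV grid points
    fixed_lambda: float | None = None  # bypass GCV (used for limit checks)

    def __post_init__(self):
        if self.k < 4:
            raise ValidationError("spline basis dimension k must be >= 4")


@dataclass
class ProjectionFit:
    """Fitted anchor mapping for one dataset plus its diagnostics."""

    dataset_id: str
    anchor_id: str
    method: str                     # "LM" or "GAM"
    coefficients: dict
    n_overlap: int
    residuals: pd.Series            # anchor-scale, per overlapping fit compound
    ss_res: float                   # mean squared residual, Eq-style sum/n
    suspect_rmse: float
    r_squared: float                # squared Pearson r of projected vs anchor
    raw_range: float
    projected_range: float
    range_ratio: float
    projected: pd.Series = field(repr=False)  # mapping applied to ALL logRFs
    suspect_residuals: pd.Series = field(repr=False, default=None)


# --- cubic regression spline basis (values-at-knots parameterization) ------

def _cr_penalty(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (F, S): second-derivative map and penalty matrix.

    The spline is parameterized by its values beta at the knots.  With
    natural boundary conditions the second derivatives at the interior knots
    are delta = F_int beta where B delta = D beta; the integrated squared
    second derivative penalty is S = D' B^-1 D.
    """
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    F_int = np.linalg.solve(B, D)
    S = D.T @ F_int
    F = np.zeros((k, k))
    F[1:-1] = F_int  # natural BC: zero second derivative at the end knots
    return F, S


def _cr_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Design matrix mapping knot values beta to spline values at x.

    Inside a knot interval the spline is the cubic Hermite-like form in
    (beta_j, beta_j+1, delta_j, delta_j+1); outside the boundary knots it
    extrapolates linearly with the boundary slope.
    """
    k = len(knots)
    n = len(x)
    X = np.zeros((n, k))
    h = np.diff(knots)

    def slope_rows(j):
        # d/dx at knot j taken from interval j (left boundary) in R^k
        e = np.zeros(k)
        e[j] -= 1.0 / h[j]
        e[j + 1] += 1.0 / h[j]
        return e - h[j] / 3.0 * F[j] - h[j] / 6.0 * F[j + 1]

    def slope_rows_right(j):
        # d/dx at knot j+1 taken from interval j (right boundary)
        e = np.zeros(k)
        e[j] -= 1.0 / h[j]
        e[j + 1] += 1.0 / h[j]
        return e + h[j] / 6.0 * F[j] + h[j] / 3.0 * F[j + 1]

    left_slope = slope_rows(0)
    right_slope = slope_rows_right(k - 2)

    for i, xi in enumerate(x):
        if xi <= knots[0]:
            row = np.zeros(k)
            row[0] = 1.0
            X[i] = row + (xi - knots[0]) * left_slope
        elif xi >= knots[-1]:
            row = np.zeros(k)
            row[-1] = 1.0
            X[i] = row + (xi - knots[-1]) * right_slope
        else:
            j = int(np.searchsorted(knots, xi, side="right") - 1)
            hj = h[j]
            am = (knots[j + 1] - xi) / hj
            ap = (xi - knots[j]) / hj
            cm = ((knots[j + 1] - xi) ** 3 / hj - hj * (knots[j + 1] - xi)) / 6.0
            cp = ((xi - knots[j]) ** 3 / hj - hj * (xi - knots[j])) / 6.0
            row = np.zeros(k)
            row[j] = am
            row[j + 1] = ap
            X[i] = row + cm * F[j] + cp * F[j + 1]
    return X


class CubicRegressionSpline:
    """Penalized cubic regression spline y ~ s(x) with GCV smoothing.

    Knots sit at evenly spaced quantiles of the fitted x values; the
    penalty is the integrated squared second derivative, whose null space
    is the linear functions — so lambda -> infinity reproduces the OLS line
    and lambda = 0 with n = k distinct points interpolates the data.
    """

    def __init__(self, config: SplineConfig | None = None):
        self.config = config or SplineConfig()
        self.knots_: np.ndarray | None = None
        self.beta_: np.ndarray | None = None
        self.lambda_: float | None = None
        self.edf_: float | None = None
        self.gcv_: float | None = None

    def _solve(self, X, y, S, lam):
        XtX = X.T @ X
        A = XtX + lam * S
        # small ridge keeps the lam=0 square system solvable at interpolation
        A_reg = A + np.eye(A.shape[0]) * (1e-10 * max(np.trace(XtX), 1.0) / A.shape[0])
        beta = np.linalg.solve(A_reg, X.T @ y)
        edf = float(np.trace(np.linalg.solve(A_reg, XtX)))
        return beta, edf

    def fit(self, x: np.ndarray, y: np.ndarray) -> "CubicRegressionSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = self.config.k
        if len(x) < k + 1 and self.config.fixed_lambda is None:
            raise ValidationError(
                f"GAM needs at least k+1={k + 1} points, got {len(x)}"
            )
        qs = np.linspace(0.0, 1.0, k)
        knots = np.unique(np.quantile(x, qs))
        if len(knots) < 4:
            raise ValidationError("too few distinct x values for a spline basis")
        F, S = _cr_penalty(knots)
        X = _cr_design(x, knots, F)
        n = len(y)

        def gcv(log10_lam):
            lam = 10.0 ** log10_lam
            beta, edf = self._solve(X, y, S, lam)
            rss = float(np.sum((y - X @ beta) ** 2))
            denom = n - edf
            if denom <= 1e-8:
                return np.inf
            return n * rss / denom**2

        if self.config.fixed_lambda is not None:
            lam = self.config.fixed_lambda
        else:
            lo, hi = np.log10(self.config.lambda_grid[0]), np.log10(self.config.lambda_grid[1])
            grid = np.linspace(lo, hi, self.config.n_grid)
            scores = np.array([gcv(g) for g in grid])
            i = int(np.argmin(scores))
            # golden-section refinement around the grid minimum
            a = grid[max(i - 1, 0)]
            b = grid[min(i + 1, len(grid) - 1)]
            if a < b:
                res = minimize_scalar(gcv, bounds=(a, b), method="bounded",
                                      options={"xatol": 1e-4})
                best = res.x if res.fun <= scores[i] else grid[i]
            else:
                best = grid[i]
            lam = 10.0 ** float(best)
        beta, edf = self._solve(X, y, S, lam)
        rss = float(np.sum((y - X @ beta) ** 2))
        self.knots_, self._F, self.beta_ = knots, F, beta
        self.lambda_, self.edf_ = float(lam), edf
        denom = n - edf
        self.gcv_ = n * rss / denom**2 if denom > 1e-8 else np.inf
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.beta_ is None:
            raise ValidationError("spline not fitted")
        X = _cr_design(np.asarray(x, dtype=float), self.knots_, self._F)
        return X @ self.beta_


# --- projection fits --------------------------------------------------------

def ss_res(residuals: np.ndarray) -> float:
    """Mean squared residual: sum(residuals^2) / n."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValidationError("ss_res of an empty residual vector")
    return float(np.sum(r**2) / r.size)


def _diagnostics(raw: pd.Series, projected: pd.Series, anchor: pd.Series):
    """(r_squared, raw_range, projected_range, range_ratio) of a projection."""
    shared = projected.index.intersection(anchor.dropna().index)
    if len(shared) >= 2 and projected[shared].std() > 0 and anchor[shared].std() > 0:
        r = np.corrcoef(projected[shared], anchor[shared])[0, 1]
        r2 = float(r**2)
    else:
        r2 = np.nan
    raw_range = float(raw.max() - raw.min()) if len(raw) >= 2 else np.nan
    proj_range = float(projected.max() - projected.min()) if len(projected) >= 2 else np.nan
    ratio = raw_range / proj_range if proj_range and proj_range > 0 else np.nan
    return r2, raw_range, proj_range, ratio


def _finalize_fit(dataset_id, anchor_id, method, coefficients, fit_x, fit_y,
                  fitted_at_x, dataset_logrf, projected_all, anchor_logrf,
                  suspect_keys) -> ProjectionFit:
    residuals = pd.Series(np.asarray(fit_y) - np.asarray(fitted_at_x),
                          index=fit_x.index)
    sus_shared = [k for k in suspect_keys
                  if k in projected_all.index and k in anchor_logrf.dropna().index]
    if sus_shared:
        sus_res = projected_all[sus_shared] - anchor_logrf[sus_shared]
        suspect_rmse = float(np.sqrt(np.mean(sus_res**2)))
    else:
        sus_res = pd.Series(dtype=float)
        suspect_rmse = np.nan
    r2, raw_range, proj_range, ratio = _diagnostics(
        dataset_logrf, projected_all, anchor_logrf
    )
    return ProjectionFit(
        dataset_id=dataset_id, anchor_id=anchor_id, method=method,
        coefficients=coefficients, n_overlap=len(fit_x),
        residuals=residuals, ss_res=ss_res(residuals.to_numpy()),
        suspect_rmse=suspect_rmse, r_squared=r2,
        raw_range=raw_range, projected_range=proj_range, range_ratio=ratio,
        projected=projected_all, suspect_residuals=sus_res,
    )


def _overlap(dataset_logrf: pd.Series, anchor_logrf: pd.Series,
             roles: pd.Series | None, fit_on: str) -> pd.Index:
    shared = dataset_logrf.dropna().index.intersection(anchor_logrf.dropna().index)
    if fit_on == "calibrant" and roles is not None:
        shared = pd.Index([k for k in shared if roles.get(k) == "calibrant"])
    return shared


def fit_lm_projection(
    dataset_logrf: pd.Series,
    anchor_logrf: pd.Series,
    roles: pd.Series | None = None,
    fit_on: str = "calibrant",
    min_overlap: int = 6,
    dataset_id: str = "",
    anchor_id: str = "",
) -> ProjectionFit:
    """OLS projection: anchor logRF regressed on the dataset's logRF.

    The line is fitted on the overlap (calibrants kept in both, or all
    shared compounds when ``fit_on='all'``) and applied to every logRF of
    the dataset.  Refuses to fit below ``min_overlap`` shared compounds.
    """
    dataset_logrf = dataset_logrf.dropna()
    overlap = _overlap(dataset_logrf, anchor_logrf, roles, fit_on)
    if len(overlap) < min_overlap:
        raise ValidationError(
            f"dataset {dataset_id}: only {len(overlap)} overlapping compounds "
            f"(< min_overlap={min_overlap})"
        )
    x = dataset_logrf[overlap]
    y = anchor_logrf[overlap]
    slope, intercept = np.polyfit(x.to_numpy(), y.to_numpy(), 1)
    projected = intercept + slope * dataset_logrf
    suspects = ([k for k in dataset_logrf.index if roles is not None
                 and roles.get(k) == "suspect"])
    return _finalize_fit(
        dataset_id, anchor_id, "LM",
        {"intercept": float(intercept), "slope": float(slope)},
        x, y, intercept + slope * x, dataset_logrf, projected, anchor_logrf,
        suspects,
    )


def fit_gam_projection(
    dataset_logrf: pd.Series,
    anchor_logrf: pd.Series,
    roles: pd.Series | None = None,
    fit_on: str = "calibrant",
    config: SplineConfig | None = None,
    dataset_id: str = "",
    anchor_id: str = "",
) -> ProjectionFit:
    """Penalized-spline projection with GCV-selected smoothing.

    Falls back to the LM projection (with a warning) when the spline basis
    is ill-conditioned, e.g. too few distinct predictor values.
    """
    config = config or SplineConfig()
    dataset_logrf = dataset_logrf.dropna()
    overlap = _overlap(dataset_logrf, anchor_logrf, roles, fit_on)
    if len(overlap) < config.k + 1 and config.fixed_lambda is None:
        raise ValidationError(
            f"dataset {dataset_id}: GAM needs >= k+1={config.k + 1} overlapping "
            f"compounds, got {len(overlap)}"
        )
    x = dataset_logrf[overlap]
    y = anchor_logrf[overlap]
    try:
        spline = CubicRegressionSpline(config).fit(x.to_numpy(), y.to_numpy())
    except (np.linalg.LinAlgError, ValidationError) as exc:
        logger.warning("dataset %s: spline basis ill-conditioned (%s); "
                       "falling back to LM", dataset_id, exc)
        return fit_lm_projection(dataset_logrf, anchor_logrf, roles, fit_on,
                                 min_overlap=2, dataset_id=dataset_id,
                                 anchor_id=anchor_id)
    projected = pd.Series(spline.predict(dataset_logrf.to_numpy()),
                          index=dataset_logrf.index)
    suspects = ([k for k in dataset_logrf.index if roles is not None
                 and roles.get(k) == "suspect"])
    fit = _finalize_fit(
        dataset_id, anchor_id, "GAM",
        {"knots": spline.knots_.tolist(), "beta": spline.beta_.tolist(),
         "lambda": spline.lambda_, "edf": spline.edf_},
        x, y, spline.predict(x.to_numpy()), dataset_logrf, projected,
        anchor_logrf, suspects,
    )
    return fit


def compare_projections(lm_fit: ProjectionFit, gam_fit: ProjectionFit,
                        alpha: float = 0.05) -> dict:
    """Two-sided variance-ratio F-test on suspect residuals of LM vs GAM.

    F = RMSE_LM^2 / RMSE_GAM^2 with (n-1, n-1) degrees of freedom.  The
    spline wins only when the test is significant *and* it has the lower
    mean squared residual; otherwise the simpler LM is preferred.  With
    fewer than 3 suspect residuals the test is skipped and LM preferred.
    """
    lm_res = _suspect_residuals(lm_fit)
    gam_res = _suspect_residuals(gam_fit)
    n = min(len(lm_res), len(gam_res))
    if n < 3:
        return {"statistic": np.nan, "df": (np.nan, np.nan), "p_value": np.nan,
                "preferred": "LM", "tested": False}
    v_lm = float(np.mean(lm_res**2))
    v_gam = float(np.mean(gam_res**2))
    f_stat = v_lm / v_gam
    d1, d2 = len(lm_res) - 1, len(gam_res) - 1
    cdf = stats.f.cdf(f_stat, d1, d2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    p = min(p, 1.0)
    if p < alpha:
        preferred = "LM" if lm_fit.ss_res <= gam_fit.ss_res else "GAM"
    else:
        preferred = "LM"
    return {"statistic": f_stat, "df": (d1, d2), "p_value": p,
            "preferred": preferred, "tested": True}


def _suspect_residuals(fit: ProjectionFit) -> np.ndarray:
    """Suspect residuals (projected minus anchor) stored on the fit."""
    if fit.suspect_residuals is None:
        return np.array([])
    return fit.suspect_residuals.to_numpy()


def projection_diagnostics(fit: ProjectionFit) -> dict:
    """Tabular diagnostics row for one projection fit."""
    return {
        "dataset_id": fit.dataset_id,
        "anchor_id": fit.anchor_id,
        "method": fit.method,
        "n_overlap": fit.n_overlap,
        "slope": fit.coefficients.get("slope", np.nan),
        "ss_res": fit.ss_res,
        "suspect_rmse": fit.suspect_rmse,
        "r_squared": fit.r_squared,
        "raw_range": fit.raw_range,
        "projected_range": fit.projected_range,
        "range_ratio": fit.range_ratio,
    }


def project_study(
    logrf_wide: pd.DataFrame,
    roles: pd.Series,
    anchor_id: str,
    method: str = "lm",
    fit_on: str = "calibrant",
    min_overlap: int = 6,
    spline_config: SplineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, ProjectionFit]]:
    """Project every dataset of a logRF matrix onto the anchor.

    Parameters
    ----------
    logrf_wide : dataset x compound-ion matrix (see response_factors).
    roles : role per compound-ion key.
    method : 'lm', 'gam', or 'both' ('both' runs the F-test model choice
        per dataset and keeps the preferred mapping).

    Returns ``(projected_wide, diagnostics, fits)``.  The anchor projects to
    itself via the identity.  Datasets with insufficient overlap are flagged
    in the diagnostics (method 'refused') and omitted from the projection.
    """
    if anchor_id not in logrf_wide.index:
        raise ValidationError(f"anchor dataset {anchor_id!r} not in logRF table")
    anchor = logrf_wide.loc[anchor_id]
    projected = {}
    diag_rows = []
    fits: dict[str, ProjectionFit] = {}

    for ds in logrf_wide.index:
        series = logrf_wide.loc[ds].dropna()
        try:
            if method == "lm":
                fit = fit_lm_projection(series, anchor, roles, fit_on,
                                        min_overlap, ds, anchor_id)
            elif method == "gam":
                fit = fit_gam_projection(series, anchor, roles, fit_on,
                                         spline_config, ds, anchor_id)
            elif method == "both":
                lm = fit_lm_projection(series, anchor, roles, fit_on,
                                       min_overlap, ds, anchor_id)
                try:
                    gam = fit_gam_projection(series, anchor, roles, fit_on,
                                             spline_config, ds, anchor_id)
                    choice = compare_projections(lm, gam)
                    fit = gam if choice["preferred"] == "GAM" else lm
                except ValidationError:
                    fit = lm
            else:
                raise ValidationError(f"unknown projection method {method!r}")
        except ValidationError as exc:
            logger.warning("projection refused: %s", exc)
            diag_rows.append({"dataset_id": ds, "anchor_id": anchor_id,
                              "method": "refused", "n_overlap": 0,
                              "slope": np.nan, "ss_res": np.nan,
                              "suspect_rmse": np.nan, "r_squared": np.nan,
                              "raw_range": np.nan, "projected_range": np.nan,
                              "range_ratio": np.nan})
            continue
        fits[ds] = fit
        projected[ds] = fit.projected
        diag_rows.append(projection_diagnostics(fit))

    projected_wide = pd.DataFrame(projected).T.reindex(columns=logrf_wide.columns)
    projected_wide.index.name = "dataset_id"
    diagnostics = pd.DataFrame(diag_rows)
    return projected_wide, diagnostics, fits
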