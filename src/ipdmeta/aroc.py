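"""Covariate-adjusted ROC analysis of pooled individual patient data.

The covariate-adjusted ROC (AROC) asks how well the test separates diseased
from nondiseased subjects once the covariate's effect on the test in the
*healthy* population is removed.  The estimator is semiparametric:

1. fit the linear location model ``test = b0 + b1 * covariate + sigma * eps``
   by ordinary least squares in the pooled nondiseased sample;
2. estimate ``sigma`` by the residual SD with denominator ``n - p``;
3. form the right-continuous empirical CDF ``F`` of the standardized
   nondiseased residuals;
4. give every diseased subject the placement value
   ``U = 1 - F((y - b0 - b1 x) / sigma)`` — their standing within the
   covariate-matched healthy population;
5. the adjusted ROC is ``AROC(t) = mean(U <= t)`` and the adjusted AUC is
   ``AAUC = 1 - mean(U)``.

One covariate is adjusted at a time; categorical covariates enter through
indicator coding.  The nondiseased regression pools across studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataio import DISEASE, TEST_RESULT, EmptyAnalysisError, IPDDataset

logger = logging.getLogger(__name__)

#: default grid for exporting the adjusted ROC curve
DEFAULT_T_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.005), 3)


class DesignError(ValueError):
    """The nondiseased design matrix is rank deficient or too small."""


@dataclass(frozen=True)
class CovariateRegression:
    """Within-study OLS of the test result on one continuous covariate."""

    study_id: int
    study_label: str
    intercept: float
    slope: float
    slope_se: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class AROCFit:
    """Fitted covariate-adjusted ROC."""

    covariate: str | None
    coefficients: np.ndarray  # nondiseased regression, intercept first
    coefficient_names: tuple[str, ...]
    sigma_hat: float
    standardized_residuals: np.ndarray  # nondiseased, defines the ECDF
    placement_values: np.ndarray  # one per diseased subject, in [0, 1]
    aauc: float
    n_diseased: int
    n_nondiseased: int

    def curve(self, t_grid: np.ndarray = DEFAULT_T_GRID) -> np.ndarray:
        """AROC(t) = fraction of diseased placement values <= t."""
        t = np.asarray(t_grid, float)
        return (self.placement_values[None, :] <= t[:, None]).mean(axis=1)


def covariate_distributions(data: IPDDataset, covariate: str) -> pd.DataFrame:
    """Per-study, per-disease-group distribution summaries of a covariate.

    Continuous covariates yield Gaussian kernel density estimates (Silverman
    bandwidth) on a shared grid, one row per grid point; categorical
    covariates yield level percentages per study and disease group.  A
    constant continuous covariate degenerates to the categorical path.
    """
    if covariate not in data.covariate_types:
        raise KeyError(
            f"unknown covariate {covariate!r}; available: {list(data.covariate_types)}"
        )
    kind = data.covariate_types[covariate]
    labels = data.study_labels()
    if kind == "continuous" and data.frame[covariate].dropna().nunique() <= 1:
        logger.warning("covariate %r is constant; summarizing as categorical", covariate)
        kind = "categorical"

    rows = []
    if kind == "categorical":
        for sid in data.study_ids:
            sub = data.study_frame(sid)
            for gname, gval in (("diseased", 1), ("nondiseased", 0)):
                obs = sub.loc[sub[DISEASE] == gval, covariate].dropna()
                counts = obs.value_counts()
                total = counts.sum()
                for level, n in counts.items():
                    rows.append(
                        {
                            "study": labels[sid],
                            "group": gname,
                            "level": str(level),
                            "count": int(n),
                            "percent": 100.0 * n / total,
                        }
                    )
        return pd.DataFrame(rows)

    vals = data.frame[covariate].dropna().to_numpy(float)
    kdes = {}
    for sid in data.study_ids:
        sub = data.study_frame(sid)
        for gname, gval in (("diseased", 1), ("nondiseased", 0)):
            obs = sub.loc[sub[DISEASE] == gval, covariate].dropna().to_numpy(float)
            if obs.size < 2 or np.ptp(obs) == 0:
                continue
            kdes[(sid, gname)] = stats.gaussian_kde(obs, bw_method="silverman")
    # extend the grid a few bandwidths past the data range to keep tail mass
    pad = 4 * max((np.sqrt(k.covariance[0, 0]) for k in kdes.values()), default=1.0)
    grid = np.linspace(vals.min() - pad, vals.max() + pad, 256)
    for (sid, gname), kde in kdes.items():
        dens = kde(grid)
        for x, y in zip(grid, dens):
            rows.append(
                {"study": labels[sid], "group": gname, "x": float(x), "density": float(y)}
            )
    return pd.DataFrame(rows)


def per_study_regressions(data: IPDDataset, covariate: str) -> list[CovariateRegression]:
    """OLS of test_result on a continuous covariate within each study.

    Complete cases within each study; studies with fewer than three usable
    rows or a constant covariate are skipped with a logged warning.
    """
    if covariate not in data.covariate_types:
        raise KeyError(f"unknown covariate {covariate!r}")
    if data.covariate_types[covariate] != "continuous":
        raise TypeError(
            f"covariate {covariate!r} is categorical; use covariate_distributions instead"
        )
    labels = data.study_labels()
    fits: list[CovariateRegression] = []
    for sid in data.study_ids:
        sub = data.study_frame(sid).dropna(subset=[TEST_RESULT, covariate])
        x = sub[covariate].to_numpy(float)
        y = sub[TEST_RESULT].to_numpy(float)
        if x.size < 3 or np.ptp(x) == 0:
            logger.warning("study %s skipped in test~%s regression (n<3 or constant)", sid, covariate)
            continue
        model = sm.OLS(y, sm.add_constant(x)).fit()
        fits.append(
            CovariateRegression(
                study_id=sid,
                study_label=labels[sid],
                intercept=float(model.params[0]),
                slope=float(model.params[1]),
                slope_se=float(model.bse[1]),
                r_squared=float(model.rsquared),
                n=int(x.size),
            )
        )
    return fits


def _design(frame: pd.DataFrame, covariate: str | None, kind: str | None) -> tuple[np.ndarray, tuple[str, ...]]:
    n = len(frame)
    if covariate is None:
        return np.ones((n, 1)), ("intercept",)
    if kind == "continuous":
        x = frame[covariate].to_numpy(float)
        return np.column_stack([np.ones(n), x]), ("intercept", covariate)
    dummies = pd.get_dummies(frame[covariate].astype(str), drop_first=True)
    cols = tuple(f"{covariate}[{c}]" for c in dummies.columns)
    return np.column_stack([np.ones(n), dummies.to_numpy(float)]), ("intercept",) + cols


def fit_aroc(data: IPDDataset, covariate: str | None) -> AROCFit:
    """Semiparametric covariate-adjusted ROC fit (see module docstring).

    ``covariate=None`` fits the intercept-only model, which reduces the
    adjusted ROC to the pooled empirical ROC of the raw test results.
    """
    if covariate is not None and covariate not in data.covariate_types:
        raise KeyError(f"unknown covariate {covariate!r}")
    kind = None if covariate is None else data.covariate_types[covariate]

    needed = [TEST_RESULT, DISEASE] + ([covariate] if covariate else [])
    frame = data.frame.dropna(subset=needed)
    nd = frame[frame[DISEASE] == 0]
    dis = frame[frame[DISEASE] == 1]
    if dis.empty:
        raise EmptyAnalysisError("no diseased subjects with complete data")
    if nd.empty:
        raise EmptyAnalysisError("no nondiseased subjects with complete data")

    x_nd, names = _design(nd, covariate, kind)
    p = x_nd.shape[1]
    if len(nd) < p + 2:
        raise DesignError(f"nondiseased sample too small ({len(nd)}) for {p} parameters")
    if np.linalg.matrix_rank(x_nd) < p:
        raise DesignError("nondiseased design matrix is rank deficient")

    y_nd = nd[TEST_RESULT].to_numpy(float)
    beta, *_ = np.linalg.lstsq(x_nd, y_nd, rcond=None)
    resid = y_nd - x_nd @ beta
    sigma_hat = float(np.sqrt(np.sum(resid**2) / (len(nd) - p)))
    if sigma_hat == 0:
        raise DesignError("nondiseased residual scale is zero")
    z_nd = np.sort(resid / sigma_hat)

    x_d, _ = _design(dis, covariate, kind)
    if covariate is not None and kind == "categorical":
        # rebuild diseased design on the nondiseased dummy layout
        ref = pd.get_dummies(nd[covariate].astype(str), drop_first=True)
        dd = pd.get_dummies(dis[covariate].astype(str), drop_first=True)
        dd = dd.reindex(columns=ref.columns, fill_value=0)
        x_d = np.column_stack([np.ones(len(dis)), dd.to_numpy(float)])
    z_d = (dis[TEST_RESULT].to_numpy(float) - x_d @ beta) / sigma_hat

    # right-continuous ECDF: F(t) = #(z_nd <= t) / n
    f_at = np.searchsorted(z_nd, z_d, side="right") / z_nd.size
    placement = 1.0 - f_at
    return AROCFit(
        covariate=covariate,
        coefficients=beta,
        coefficient_names=names,
        sigma_hat=sigma_hat,
        standardized_residuals=z_nd,
        placement_values=placement,
        aauc=float(1.0 - placement.mean()),
        n_diseased=len(dis),
        n_nondiseased=len(nd),
    )


def aroc_curve_table(fit: AROCFit, t_grid: np.ndarray = DEFAULT_T_GRID) -> pd.DataFrame:
    """Adjusted ROC curve on a t-grid plus the AAUC, mirroring the unadjusted
    ROC and AUC views, as an exportable table."""
    curve = fit.curve(t_grid)
    out = pd.DataFrame({"t": np.asarray(t_grid, float), "aroc": curve})
    out.attrs["aauc"] = fit.aauc
    return out
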