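"""Bivariate random-effects meta-analysis of sensitivity/specificity and the
hierarchical summary ROC (HSROC) re-parameterization.

The model is the two-stage normal approximation: each study contributes its
logit sensitivity and logit specificity with within-study variances taken from
the 2x2 cell counts (0.5 added to every cell of a study containing a zero
cell), and the pair is modelled as bivariate normal around a common mean with
an unstructured 2x2 between-study covariance matrix estimated by restricted
maximum likelihood (REML).

The fitted bivariate parameters map one-to-one onto the HSROC model's
accuracy (Lambda), threshold (Theta) and shape (beta) parameters, from which
the summary ROC curve is drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .accuracy import ContingencyTable

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-5  # between-study SDs are bounded below here; hitting it flags a boundary fit


class InsufficientDataError(ValueError):
    """Fewer than two usable studies."""


class ConvergenceError(RuntimeError):
    """The REML optimizer failed to converge."""


class DegenerateConversionError(ValueError):
    """HSROC conversion is undefined when a between-study variance is zero."""


@dataclass(frozen=True)
class BivariateParams:
    """Bivariate random-effects parameters on the logit scale.

    ``mu_a`` / ``mu_b`` are the mean logit sensitivity / specificity,
    ``sigma2_a`` / ``sigma2_b`` / ``sigma_ab`` the between-study (co)variances,
    ``cov_mu`` the 2x2 covariance matrix of the (mu_a, mu_b) estimate.
    """

    mu_a: float
    mu_b: float
    sigma2_a: float
    sigma2_b: float
    sigma_ab: float
    cov_mu: np.ndarray
    se_mu_a: float
    se_mu_b: float
    n_studies: int
    converged: bool
    boundary: bool
    neg2_reml: float

    @property
    def summary_sensitivity(self) -> float:
        return float(special.expit(self.mu_a))

    @property
    def summary_specificity(self) -> float:
        return float(special.expit(self.mu_b))


@dataclass(frozen=True)
class HSROCParams:
    """HSROC parameters: accuracy Lambda, threshold Theta, shape beta,
    accuracy variance sigma2_alpha and threshold variance sigma2_theta."""

    lambda_: float
    theta: float
    beta: float
    sigma2_alpha: float
    sigma2_theta: float


@dataclass(frozen=True)
class SummaryPoint:
    """Summary operating point with a confidence region in ROC space."""

    sensitivity: float
    specificity: float
    level: float
    region_fpr: np.ndarray
    region_tpr: np.ndarray


@dataclass(frozen=True)
class SROCCurve:
    """Summary ROC curve sampled on an FPR grid."""

    fpr: np.ndarray
    tpr: np.ndarray
    rule: str = "hsroc-logit-line"
    fpr_range: tuple[float, float] = (0.0, 1.0)


def study_logits(tables: Sequence[ContingencyTable]) -> tuple[np.ndarray, np.ndarray]:
    """Per-study (logit Se, logit Sp) and their within-study variances.

    Studies containing any zero cell get 0.5 added to all four cells before
    both the logits and the variances are computed.
    """
    y, v = [], []
    for t in tables:
        tp, fn, fp, tn = t.tp, t.fn, t.fp, t.tn
        if min(tp, fn, fp, tn) == 0:
            tp, fn, fp, tn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
        y.append([np.log(tp / fn), np.log(tn / fp)])
        v.append([1 / tp + 1 / fn, 1 / tn + 1 / fp])
    return np.asarray(y), np.asarray(v)


def _neg2_reml(params: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    log_sa, log_sb, z = params
    sa, sb = np.exp(log_sa), np.exp(log_sb)
    rho = np.tanh(z)
    psi = np.array([[sa * sa, rho * sa * sb], [rho * sa * sb, sb * sb]])
    wsum = np.zeros((2, 2))
    wy = np.zeros(2)
    logdet = 0.0
    w_list = []
    for i in range(len(y)):
        sigma = psi + np.diag(v[i])
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
        if det <= 0:
            return np.inf
        w = np.array([[sigma[1, 1], -sigma[0, 1]], [-sigma[0, 1], sigma[0, 0]]]) / det
        w_list.append(w)
        wsum += w
        wy += w @ y[i]
        logdet += np.log(det)
    mu = np.linalg.solve(wsum, wy)
    quad = 0.0
    for i, w in enumerate(w_list):
        r = y[i] - mu
        quad += r @ w @ r
    sign, logdet_w = np.linalg.slogdet(wsum)
    if sign <= 0:
        return np.inf
    return logdet + logdet_w + quad


def _gls_mean(psi: np.ndarray, y: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    wsum = np.zeros((2, 2))
    wy = np.zeros(2)
    for i in range(len(y)):
        w = np.linalg.inv(psi + np.diag(v[i]))
        wsum += w
        wy += w @ y[i]
    cov = np.linalg.inv(wsum)
    return cov @ wy, cov


def fit_bivariate(tables: Sequence[ContingencyTable]) -> BivariateParams:
    """REML fit of the bivariate normal-approximation model.

    Requires at least two studies with both disease classes; below four
    studies the variance components are weakly identified and a warning is
    logged.  Between-study SDs are optimized on the log scale with a floor;
    estimates at the floor are reported as (near-)zero with ``boundary=True``.
    """
    tables = [t for t in tables if t.n_diseased > 0 and t.n_nondiseased > 0]
    k = len(tables)
    if k < 2:
        raise InsufficientDataError(f"need at least 2 usable studies, got {k}")
    if k < 4:
        logger.warning("only %d studies: between-study variances are weakly identified", k)

    y, v = study_logits(tables)
    # moment-based start: excess of empirical variance over mean within-study variance
    start_var = np.maximum(y.var(axis=0, ddof=1) - v.mean(axis=0), 1e-3)
    x0 = np.array([0.5 * np.log(start_var[0]), 0.5 * np.log(start_var[1]), 0.0])
    bounds = [(np.log(_SD_FLOOR), np.log(10.0))] * 2 + [(-6.0, 6.0)]
    res = optimize.minimize(
        _neg2_reml,
        x0,
        args=(y, v),
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise ConvergenceError(f"REML optimization failed: {res.message}")

    log_sa, log_sb, z = res.x
    sa, sb, rho = np.exp(log_sa), np.exp(log_sb), np.tanh(z)
    boundary = bool(
        log_sa <= np.log(_SD_FLOOR) + 1e-6 or log_sb <= np.log(_SD_FLOOR) + 1e-6
    )
    psi = np.array([[sa * sa, rho * sa * sb], [rho * sa * sb, sb * sb]])
    mu, cov_mu = _gls_mean(psi, y, v)
    return BivariateParams(
        mu_a=float(mu[0]),
        mu_b=float(mu[1]),
        sigma2_a=float(sa * sa),
        sigma2_b=float(sb * sb),
        sigma_ab=float(rho * sa * sb),
        cov_mu=cov_mu,
        se_mu_a=float(np.sqrt(cov_mu[0, 0])),
        se_mu_b=float(np.sqrt(cov_mu[1, 1])),
        n_studies=k,
        converged=bool(res.success),
        boundary=boundary,
        neg2_reml=float(res.fun),
    )


def bivariate_to_hsroc(b: BivariateParams) -> HSROCParams:
    """Map bivariate parameters to the equivalent HSROC parameters.

    With between-study SDs s_a (logit Se) and s_b (logit Sp):

        beta        = ln(s_b / s_a)
        Lambda      = (s_b/s_a)^{1/2} mu_a + (s_a/s_b)^{1/2} mu_b
        Theta       = [(s_b/s_a)^{1/2} mu_a - (s_a/s_b)^{1/2} mu_b] / 2
        sigma2_alpha = 2 (s_a s_b + sigma_ab)
        sigma2_theta = (s_a s_b - sigma_ab) / 2
    """
    if b.sigma2_a <= _SD_FLOOR**2 * 4 or b.sigma2_b <= _SD_FLOOR**2 * 4:
        raise DegenerateConversionError(
            "between-study variance is (near) zero; the HSROC shape parameter is "
            "undefined in the homogeneity limit"
        )
    sa, sb = np.sqrt(b.sigma2_a), np.sqrt(b.sigma2_b)
    r = np.sqrt(sb / sa)
    return HSROCParams(
        lambda_=float(r * b.mu_a + b.mu_b / r),
        theta=float((r * b.mu_a - b.mu_b / r) / 2.0),
        beta=float(np.log(sb / sa)),
        sigma2_alpha=float(2.0 * (sa * sb + b.sigma_ab)),
        sigma2_theta=float(0.5 * (sa * sb - b.sigma_ab)),
    )


def hsroc_to_bivariate(h: HSROCParams) -> tuple[float, float, float, float, float]:
    """Inverse mapping: returns (mu_a, mu_b, sigma2_a, sigma2_b, sigma_ab)."""
    r = np.exp(h.beta / 2.0)
    mu_a = (h.lambda_ / 2.0 + h.theta) / r
    mu_b = (h.lambda_ / 2.0 - h.theta) * r
    prod = h.sigma2_alpha / 4.0 + h.sigma2_theta  # = s_a * s_b
    sigma_ab = h.sigma2_alpha / 4.0 - h.sigma2_theta
    sigma2_a = prod / np.exp(h.beta)
    sigma2_b = prod * np.exp(h.beta)
    return float(mu_a), float(mu_b), float(sigma2_a), float(sigma2_b), float(sigma_ab)


def sroc_curve(
    h: HSROCParams,
    fpr_grid: np.ndarray | None = None,
    fpr_range: tuple[float, float] = (0.005, 0.995),
    n_points: int = 200,
) -> SROCCurve:
    """Summary ROC curve: logit TPR = Lambda e^{-beta/2} + e^{-beta} logit FPR.

    By default the curve is drawn on ``fpr_range`` (pass the observed
    per-study FPR range to avoid extrapolation; (0, 1) for the full curve).
    """
    if fpr_grid is None:
        lo, hi = fpr_range
        if not (0 < lo < hi < 1):
            raise ValueError("fpr_range must satisfy 0 < lo < hi < 1")
        fpr_grid = np.linspace(lo, hi, n_points)
    fpr_grid = np.asarray(fpr_grid, float)
    if np.any((fpr_grid <= 0) | (fpr_grid >= 1)):
        raise ValueError("fpr grid values must lie strictly inside (0, 1)")
    logit_tpr = h.lambda_ * np.exp(-h.beta / 2.0) + np.exp(-h.beta) * special.logit(fpr_grid)
    return SROCCurve(
        fpr=fpr_grid,
        tpr=special.expit(logit_tpr),
        fpr_range=(float(fpr_grid.min()), float(fpr_grid.max())),
    )


def summary_point_with_region(
    b: BivariateParams, level: float = 0.95, n_points: int = 181
) -> SummaryPoint:
    """Summary Se/Sp with a confidence region for the mean, mapped to ROC space.

    The region is the Hotelling-type ellipse for the bivariate mean on the
    logit plane, ``(mu_hat - mu)' C^{-1} (mu_hat - mu) <= 2(k-1)/(k-2)
    F_{level; 2, k-2}``, mapped pointwise through the inverse logit.  For
    ``k <= 3`` (or on request) the chi-square calibration is used instead.
    """
    if b.cov_mu is None:
        raise ValueError("parameter covariance unavailable; refit the model")
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    k = b.n_studies
    if level == 0:
        c2 = 0.0
    elif k > 3:
        c2 = 2.0 * (k - 1) / (k - 2) * stats.f.ppf(level, 2, k - 2)
    else:
        c2 = stats.chi2.ppf(level, 2)
    L = np.linalg.cholesky(b.cov_mu)
    angles = np.linspace(0, 2 * np.pi, n_points)
    circle = np.column_stack([np.cos(angles), np.sin(angles)])
    pts = np.array([b.mu_a, b.mu_b]) + np.sqrt(c2) * circle @ L.T
    return SummaryPoint(
        sensitivity=b.summary_sensitivity,
        specificity=b.summary_specificity,
        level=level,
        region_fpr=special.expit(-pts[:, 1]),
        region_tpr=special.expit(pts[:, 0]),
    )


def parameter_table(b: BivariateParams, h: HSROCParams | None) -> "pd.DataFrame":
    """Both parameter sets in one exportable table."""
    import pandas as pd

    rows = [
        ("bivariate", "mu_logit_se", b.mu_a, b.se_mu_a),
        ("bivariate", "mu_logit_sp", b.mu_b, b.se_mu_b),
        ("bivariate", "sigma2_logit_se", b.sigma2_a, np.nan),
        ("bivariate", "sigma2_logit_sp", b.sigma2_b, np.nan),
        ("bivariate", "sigma_ab", b.sigma_ab, np.nan),
        ("bivariate", "summary_sensitivity", b.summary_sensitivity, np.nan),
        ("bivariate", "summary_specificity", b.summary_specificity, np.nan),
    ]
    if h is not None:
        rows += [
            ("hsroc", "Lambda", h.lambda_, np.nan),
            ("hsroc", "Theta", h.theta, np.nan),
            ("hsroc", "beta", h.beta, np.nan),
            ("hsroc", "sigma2_alpha", h.sigma2_alpha, np.nan),
            ("hsroc", "sigma2_theta", h.sigma2_theta, np.nan),
        ]
    return pd.DataFrame(rows, columns=["model", "parameter", "estimate", "se"])
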