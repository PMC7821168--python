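"""Fixed-effect and random-effects meta-analysis of per-study empirical AUCs.

Each study contributes its threshold-free Mann-Whitney AUC with a DeLong
standard error.  Pooling uses inverse-variance weights; between-study
variance (tau^2) is estimated with the DerSimonian-Laird moment estimator,
with REML as an option.  Pooling is done on the raw AUC scale by default
(confidence limits clipped to [0, 1]); the logit scale is available for
AUCs near the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .accuracy import auc_ci, empirical_auc
from .dataio import EmptyAnalysisError, IPDDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyAUC:
    study_id: int
    study_label: str
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_diseased: int
    n_nondiseased: int
    se_floored: bool = False


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AUCMetaResult:
    studies: tuple[StudyAUC, ...]
    pooled_fixed: PooledEstimate
    pooled_random: PooledEstimate
    tau2: float
    q: float
    i2: float
    scale: str
    weights_fixed: np.ndarray  # normalized, sum to 1
    weights_random: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study": s.study_label,
                "auc": s.auc,
                "se": s.se,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "weight_fixed": wf,
                "weight_random": wr,
            }
            for s, wf, wr in zip(self.studies, self.weights_fixed, self.weights_random)
        ]
        for name, p in (("fixed effect", self.pooled_fixed), ("random effects", self.pooled_random)):
            rows.append(
                {
                    "study": name,
                    "auc": p.estimate,
                    "se": p.se,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                    "weight_fixed": np.nan,
                    "weight_random": np.nan,
                }
            )
        return pd.DataFrame(rows)


def _hanley_mcneil_se(auc: float, n_d: int, n_n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_d - 1) * (q1 - auc**2) + (n_n - 1) * (q2 - auc**2)) / (n_d * n_n)
    return float(np.sqrt(max(var, 0.0)))


def study_aucs(data: IPDDataset) -> list[StudyAUC]:
    """Empirical AUC with DeLong SE for every analyzable study.

    Studies with a degenerate AUC of exactly 0 or 1 (complete separation)
    get a continuity adjustment of half a concordant pair and a
    Hanley-McNeil SE floor; they are flagged via ``se_floored``.
    """
    labels = data.study_labels()
    out: list[StudyAUC] = []
    for sid in data.analyzable_study_ids:
        d, nd = data.test_values(sid)
        auc, se = empirical_auc(d, nd)
        floored = False
        if auc in (0.0, 1.0) or se == 0.0:
            pairs = d.size * nd.size
            auc = min(max(auc, 0.5 / pairs), 1 - 0.5 / pairs)
            se = _hanley_mcneil_se(auc, d.size, nd.size)
            floored = True
            logger.warning(
                "study %s: degenerate empirical AUC; continuity-adjusted with SE floor", sid
            )
        lo, hi = auc_ci(auc, se)
        out.append(
            StudyAUC(
                study_id=sid,
                study_label=labels[sid],
                auc=auc,
                se=se,
                ci_low=lo,
                ci_high=hi,
                n_diseased=d.size,
                n_nondiseased=nd.size,
                se_floored=floored,
            )
        )
    if not out:
        raise EmptyAnalysisError("no study with both disease classes")
    return out


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    def neg2(log_tau2: float) -> float:
        t2 = np.exp(log_tau2)
        w = 1.0 / (v + t2)
        mu = np.sum(w * y) / np.sum(w)
        return float(np.sum(np.log(v + t2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2))

    res = optimize.minimize_scalar(neg2, bounds=(np.log(1e-10), np.log(10.0)), method="bounded")
    t2 = float(np.exp(res.x))
    return 0.0 if t2 < 1e-9 else t2


def pool_auc(
    studies: Sequence[StudyAUC], scale: str = "raw", tau2_method: str = "dl"
) -> AUCMetaResult:
    """Inverse-variance pooling of study AUCs.

    ``scale="raw"`` pools the AUCs directly; ``scale="logit"`` pools
    logit(AUC) with delta-method SEs and back-transforms the results.
    ``tau2_method`` is ``"dl"`` (DerSimonian-Laird, default) or ``"reml"``.
    """
    if len(studies) < 2:
        raise EmptyAnalysisError("pooling requires at least 2 studies")
    if scale not in ("raw", "logit"):
        raise ValueError("scale must be 'raw' or 'logit'")
    if any(s.se <= 0 or not np.isfinite(s.se) for s in studies):
        raise ValueError("every study must have a finite positive SE")

    auc = np.array([s.auc for s in studies])
    se = np.array([s.se for s in studies])
    if scale == "logit":
        if np.any((auc <= 0) | (auc >= 1)):
            raise ValueError("logit scale requires AUCs strictly inside (0, 1)")
        y = special.logit(auc)
        sey = se / (auc * (1 - auc))
    else:
        y, sey = auc, se

    k = len(y)
    v = sey**2
    w = 1.0 / v
    mu_f = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_f) ** 2))
    if tau2_method == "dl":
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = float(max(0.0, (q - (k - 1)) / c))
    elif tau2_method == "reml":
        tau2 = _reml_tau2(y, v)
    else:
        raise ValueError("tau2_method must be 'dl' or 'reml'")
    i2 = float(max(0.0, (q - (k - 1)) / q)) if q > 0 else 0.0

    wr = 1.0 / (v + tau2)
    mu_r = np.sum(wr * y) / np.sum(wr)
    se_f = float(np.sqrt(1.0 / np.sum(w)))
    se_r = float(np.sqrt(1.0 / np.sum(wr)))
    z = stats.norm.ppf(0.975)

    def back(est: float, s: float) -> PooledEstimate:
        lo, hi = est - z * s, est + z * s
        if scale == "logit":
            return PooledEstimate(
                float(special.expit(est)), s, float(special.expit(lo)), float(special.expit(hi))
            )
        if lo < 0 or hi > 1:
            warnings.warn("raw-scale pooled AUC interval clipped to [0, 1]")
        return PooledEstimate(float(est), s, max(0.0, lo), min(1.0, hi))

    return AUCMetaResult(
        studies=tuple(studies),
        pooled_fixed=back(mu_f, se_f),
        pooled_random=back(mu_r, se_r),
        tau2=tau2,
        q=q,
        i2=i2,
        scale=scale,
        weights_fixed=w / np.sum(w),
        weights_random=wr / np.sum(wr),
    )


def heterogeneity_footer(result: AUCMetaResult) -> str:
    """Conventional forest-plot heterogeneity line."""
    k = len(result.studies)
    p = float(stats.chi2.sf(result.q, k - 1))
    return (
        f"Q = {result.q:.2f} (df = {k - 1}, p = {p:.3f}); "
        f"I² = {100 * result.i2:.1f}%; τ² = {result.tau2:.4f}"
    )
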