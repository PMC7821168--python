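"""Per-study dichotomization of continuous test results and accuracy panels.

Positivity convention: higher test values indicate disease, and a subject is
test-positive when ``test_result >= threshold`` (closed on the positive side).
The direction can be inverted globally by negating the test results upstream.

Three threshold modes are supported:

``per_study``
    one user-chosen threshold per study; unset studies default to the median
    of all test results pooled across studies,
``common_predefined``
    a single threshold applied to every study,
``optimal_youden``
    the per-study cutpoint maximizing Youden's J = Se + Sp - 1.  Optimizing
    the threshold within each primary study biases summary accuracy upward,
    so this mode logs a caution and is intended for exploration only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .dataio import DISEASE, TEST_RESULT, EmptyAnalysisError, IPDDataset

logger = logging.getLogger(__name__)

THRESHOLD_MODES = ("per_study", "optimal_youden", "common_predefined")


class UndefinedThresholdError(ValueError):
    """Threshold optimization needs at least one value in each disease group."""


class EmptyTableError(ValueError):
    """All four cells of the 2x2 table are zero."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Positivity-threshold specification and its per-study resolution."""

    mode: str = "per_study"
    per_study_values: Mapping[int, float] = field(default_factory=dict)
    common_value: float | None = None
    resolved_values: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in THRESHOLD_MODES:
            raise ValueError(f"mode must be one of {THRESHOLD_MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FN/FP/TN cross-classification of one study at one threshold."""

    study_id: int
    threshold: float
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Estimate:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AccuracyEstimates:
    """Full accuracy panel of one study with 95% confidence intervals."""

    study_id: int
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    dor: Estimate
    continuity_corrected: bool


def optimal_youden_threshold(
    diseased_values: Sequence[float], nondiseased_values: Sequence[float]
) -> tuple[float, float]:
    """Cutpoint maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutpoints are the midpoints between consecutive distinct pooled
    values plus a -inf and +inf sentinel; ties in J are broken toward the
    smallest threshold.  Positivity is ``value >= threshold``.
    """
    d = np.asarray(diseased_values, float)
    nd = np.asarray(nondiseased_values, float)
    if d.size == 0 or nd.size == 0:
        raise UndefinedThresholdError("both disease groups must be non-empty")
    pooled = np.unique(np.concatenate([d, nd]))
    candidates = np.concatenate(([-np.inf], (pooled[:-1] + pooled[1:]) / 2.0, [np.inf]))
    best_thr, best_j = -np.inf, -np.inf
    for thr in candidates:  # ascending, so strict improvement keeps smallest tie
        se = np.mean(d >= thr)
        sp = np.mean(nd < thr)
        j = se + sp - 1.0
        if j > best_j:
            best_thr, best_j = float(thr), float(j)
    return best_thr, best_j


def resolve_thresholds(data: IPDDataset, spec: ThresholdSpec) -> ThresholdSpec:
    """Fill ``resolved_values`` with one finite-or-sentinel threshold per study."""
    studies = data.analyzable_study_ids
    for v in list(spec.per_study_values.values()) + (
        [spec.common_value] if spec.common_value is not None else []
    ):
        if v is None or not np.isfinite(v):
            raise ValueError(f"threshold value {v!r} is not finite")

    if spec.mode == "common_predefined":
        if spec.common_value is None:
            raise ValueError("common_predefined mode requires common_value")
        resolved = {sid: float(spec.common_value) for sid in studies}
    elif spec.mode == "per_study":
        pooled_median = float(np.nanmedian(data.frame[TEST_RESULT].to_numpy(float)))
        resolved = {
            sid: float(spec.per_study_values.get(sid, pooled_median)) for sid in studies
        }
        if len(set(resolved.values())) > 1:
            logger.warning(
                "per-study thresholds differ across studies; summary estimates mix "
                "positivity definitions"
            )
    else:  # optimal_youden
        logger.warning(
            "optimal per-study thresholds can bias summary accuracy estimates; "
            "use a common threshold for performance estimates"
        )
        resolved = {}
        for sid in studies:
            d, nd = data.test_values(sid)
            thr, _ = optimal_youden_threshold(d, nd)
            resolved[sid] = thr
    return replace(spec, resolved_values=resolved)


def contingency_from_threshold(
    data: IPDDataset, study_id: int, threshold: float
) -> ContingencyTable:
    """2x2 table of one study at a threshold (positive when value >= threshold)."""
    d, nd = data.test_values(study_id)
    return ContingencyTable(
        study_id=int(study_id),
        threshold=float(threshold),
        tp=int(np.sum(d >= threshold)),
        fn=int(np.sum(d < threshold)),
        fp=int(np.sum(nd >= threshold)),
        tn=int(np.sum(nd < threshold)),
    )


def _proportion_ci(count: int, nobs: int) -> Estimate:
    if nobs == 0:
        return Estimate(np.nan, np.nan, np.nan)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")  # Clopper-Pearson
    return Estimate(count / nobs, float(lo), float(hi))


def _log_wald_ci(est: float, se_log: float) -> Estimate:
    z = stats.norm.ppf(0.975)
    return Estimate(est, est * np.exp(-z * se_log), est * np.exp(z * se_log))


def accuracy_panel(table: ContingencyTable) -> AccuracyEstimates:
    """Se/Sp/PPV/NPV with Clopper-Pearson 95% CIs; LR+/LR-/DOR with log-Wald CIs.

    When any cell is zero, 0.5 is added to all four cells for the ratio
    measures only; the proportion estimates stay uncorrected.
    """
    tp, fn, fp, tn = table.tp, table.fn, table.fp, table.tn
    if tp + fn + fp + tn == 0:
        raise EmptyTableError("all four cells are zero")

    panel = {
        "sensitivity": _proportion_ci(tp, tp + fn),
        "specificity": _proportion_ci(tn, tn + fp),
        "ppv": _proportion_ci(tp, tp + fp),
        "npv": _proportion_ci(tn, tn + fn),
    }

    corrected = min(tp, fn, fp, tn) == 0
    a, b, c, d = (x + 0.5 for x in (tp, fn, fp, tn)) if corrected else (tp, fn, fp, tn)
    se_c, sp_c = a / (a + b), d / (c + d)
    lr_pos = se_c / (1 - sp_c)
    lr_neg = (1 - se_c) / sp_c
    dor = (a * d) / (b * c)
    # Simel et al. log-scale variances for likelihood ratios; Woolf for the DOR
    se_log_lrp = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    se_log_lrn = np.sqrt(1 / b - 1 / (a + b) + 1 / d - 1 / (c + d))
    se_log_dor = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)

    return AccuracyEstimates(
        study_id=table.study_id,
        sensitivity=panel["sensitivity"],
        specificity=panel["specificity"],
        ppv=panel["ppv"],
        npv=panel["npv"],
        lr_pos=_log_wald_ci(lr_pos, se_log_lrp),
        lr_neg=_log_wald_ci(lr_neg, se_log_lrn),
        dor=_log_wald_ci(dor, se_log_dor),
        continuity_corrected=corrected,
    )


def empirical_auc(
    diseased_values: Sequence[float], nondiseased_values: Sequence[float]
) -> tuple[float, float]:
    """Empirical (Mann-Whitney) AUC with DeLong standard error.

    Ties between a diseased and a nondiseased value count one half.  The
    standard error follows DeLong's decomposition into the variances of the
    per-subject placement components.
    """
    d = np.asarray(diseased_values, float)
    nd = np.asarray(nondiseased_values, float)
    if d.size == 0 or nd.size == 0:
        raise UndefinedThresholdError("both disease groups must be non-empty")
    # psi[i, j] = 1, 1/2, 0 for d_i > / = / < nd_j
    psi = (d[:, None] > nd[None, :]).astype(float) + 0.5 * (d[:, None] == nd[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # placement component of each diseased subject
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if d.size > 1 else 0.0
    s01 = v01.var(ddof=1) if nd.size > 1 else 0.0
    se = float(np.sqrt(s10 / d.size + s01 / nd.size))
    return auc, se


def auc_ci(auc: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval for the AUC, clipped to [0, 1]."""
    z = stats.norm.ppf(0.5 + level / 2)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def empirical_roc(
    diseased_values: Sequence[float], nondiseased_values: Sequence[float]
) -> np.ndarray:
    """Empirical ROC step-function vertices as an (m, 2) array of (FPR, TPR).

    One vertex per distinct observed value plus the (0, 0) and (1, 1)
    endpoints, ordered by increasing FPR (threshold decreasing from +inf).
    """
    d = np.asarray(diseased_values, float)
    nd = np.asarray(nondiseased_values, float)
    if d.size == 0 or nd.size == 0:
        raise UndefinedThresholdError("both disease groups must be non-empty")
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([d, nd]))[::-1]))
    fpr = [(nd >= t).mean() for t in thresholds]
    tpr = [(d >= t).mean() for t in thresholds]
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def panel_tables(
    data: IPDDataset, spec: ThresholdSpec
) -> tuple["pd.DataFrame", "pd.DataFrame", list[ContingencyTable]]:
    """The two per-study accuracy exports.

    Table I: threshold, 2x2 cells, sensitivity and specificity with CIs.
    Table II: PPV, NPV, LR+, LR-, DOR and the threshold-free empirical AUC.
    """
    import pandas as pd

    resolved = resolve_thresholds(data, spec)
    labels = data.study_labels()
    tables, rows1, rows2 = [], [], []
    for sid, thr in resolved.resolved_values.items():
        tab = contingency_from_threshold(data, sid, thr)
        tables.append(tab)
        est = accuracy_panel(tab)
        d, nd = data.test_values(sid)
        auc, se = empirical_auc(d, nd)
        lo, hi = auc_ci(auc, se)
        rows1.append(
            {
                "study": labels[sid],
                "threshold": thr,
                "TP": tab.tp,
                "FN": tab.fn,
                "FP": tab.fp,
                "TN": tab.tn,
                "sensitivity": est.sensitivity.value,
                "se_ci_low": est.sensitivity.ci_low,
                "se_ci_high": est.sensitivity.ci_high,
                "specificity": est.specificity.value,
                "sp_ci_low": est.specificity.ci_low,
                "sp_ci_high": est.specificity.ci_high,
            }
        )
        rows2.append(
            {
                "study": labels[sid],
                "PPV": est.ppv.value,
                "ppv_ci_low": est.ppv.ci_low,
                "ppv_ci_high": est.ppv.ci_high,
                "NPV": est.npv.value,
                "npv_ci_low": est.npv.ci_low,
                "npv_ci_high": est.npv.ci_high,
                "LR+": est.lr_pos.value,
                "lrp_ci_low": est.lr_pos.ci_low,
                "lrp_ci_high": est.lr_pos.ci_high,
                "LR-": est.lr_neg.value,
                "lrn_ci_low": est.lr_neg.ci_low,
                "lrn_ci_high": est.lr_neg.ci_high,
                "DOR": est.dor.value,
                "dor_ci_low": est.dor.ci_low,
                "dor_ci_high": est.dor.ci_high,
                "AUC": auc,
                "auc_se": se,
                "auc_ci_low": lo,
                "auc_ci_high": hi,
            }
        )
    if not tables:
        raise EmptyAnalysisError("no analyzable studies")
    return pd.DataFrame(rows1), pd.DataFrame(rows2), tables
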