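"""Figures for the meta-analysis, each with a lossless companion table.

Every plotting function returns ``(figure, table)`` where the table holds
the exact coordinates drawn, so figures can be regenerated from their CSV
exports and tests can target coordinates rather than pixels.  Figures are
written as PDF by default (PNG/SVG optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import ContingencyTable, empirical_roc
from .aroc import AROCFit, CovariateRegression, covariate_distributions
from .auc_meta import AUCMetaResult, heterogeneity_footer
from .bivariate import BivariateParams, HSROCParams, sroc_curve, summary_point_with_region
from .dataio import DISEASE, TEST_RESULT, IPDDataset

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("pdf", "png", "svg")


@dataclass(frozen=True)
class ForestRow:
    label: str
    estimate: float
    ci_low: float
    ci_high: float
    weight: float | None = None
    is_pooled: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"forest row {self.label!r}: CI [{self.ci_low}, {self.ci_high}] "
                f"does not bracket {self.estimate}"
            )


def save_figure(fig, path, formats: Sequence[str] = ("pdf",)) -> list[Path]:
    """Write a figure in one or more formats; returns the paths written."""
    path = Path(path)
    written = []
    for fmt in formats:
        if fmt not in EXPORT_FORMATS:
            raise ValueError(f"format must be one of {EXPORT_FORMATS}")
        out = path.with_suffix(f".{fmt}")
        fig.savefig(out, bbox_inches="tight")
        written.append(out)
    plt.close(fig)
    return written


def _draw_forest(ax, rows: Sequence[ForestRow], xlabel: str):
    n = len(rows)
    for i, r in enumerate(rows):
        y = n - 1 - i
        if r.is_pooled:  # diamond spanning the CI
            ax.fill(
                [r.ci_low, r.estimate, r.ci_high, r.estimate],
                [y, y + 0.25, y, y - 0.25],
                color="tab:blue",
            )
        else:
            size = 6 + 14 * (r.weight or 0.0)
            ax.plot([r.ci_low, r.ci_high], [y, y], color="black", lw=1)
            ax.plot([r.estimate], [y], marker="s", ms=size, color="tab:gray")
    ax.set_yticks(range(n))
    ax.set_yticklabels([r.label for r in reversed(rows)])
    ax.set_xlabel(xlabel)


def forest_plot(
    rows: Sequence[ForestRow],
    pooled: Sequence[ForestRow] = (),
    xlabel: str = "estimate",
    footer: str | None = None,
) -> tuple[plt.Figure, pd.DataFrame]:
    """Single-panel forest plot; pooled rows are drawn as diamonds at the bottom."""
    if not rows:
        raise ValueError("forest plot needs at least one row")
    all_rows = list(rows) + [
        ForestRow(r.label, r.estimate, r.ci_low, r.ci_high, r.weight, True) for r in pooled
    ]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(all_rows) + 1.5))
    _draw_forest(ax, all_rows, xlabel)
    if footer:
        ax.set_title(footer, fontsize=8, loc="left")
    table = pd.DataFrame(
        [
            {
                "label": r.label,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "weight": r.weight,
                "pooled": r.is_pooled,
            }
            for r in all_rows
        ]
    )
    return fig, table


def forest_se_sp(table1: pd.DataFrame) -> tuple[plt.Figure, pd.DataFrame]:
    """Paired forest panels for per-study sensitivity and specificity.

    ``table1`` is the "accuracy per study I" export from
    :func:`ipdmeta.accuracy.panel_tables`.
    """
    fig, axes = plt.subplots(
        1, 2, figsize=(9, 0.35 * len(table1) + 1.5), sharey=True
    )
    rows_se = [
        ForestRow(r["study"], r["sensitivity"], r["se_ci_low"], r["se_ci_high"])
        for _, r in table1.iterrows()
    ]
    rows_sp = [
        ForestRow(r["study"], r["specificity"], r["sp_ci_low"], r["sp_ci_high"])
        for _, r in table1.iterrows()
    ]
    _draw_forest(axes[0], rows_se, "sensitivity")
    _draw_forest(axes[1], rows_sp, "specificity")
    for ax in axes:
        ax.set_xlim(0, 1)
    table = pd.concat(
        [
            pd.DataFrame(
                [
                    {"panel": panel, "label": r.label, "estimate": r.estimate,
                     "ci_low": r.ci_low, "ci_high": r.ci_high}
                    for r in rows
                ]
            )
            for panel, rows in (("sensitivity", rows_se), ("specificity", rows_sp))
        ],
        ignore_index=True,
    )
    return fig, table


def auc_forest(result: AUCMetaResult) -> tuple[plt.Figure, pd.DataFrame]:
    """AUC forest with fixed-effect and random-effects diamonds."""
    rows = [
        ForestRow(s.study_label, s.auc, s.ci_low, s.ci_high, weight=float(w))
        for s, w in zip(result.studies, result.weights_random)
    ]
    pooled = [
        ForestRow("Fixed effect", result.pooled_fixed.estimate,
                  result.pooled_fixed.ci_low, result.pooled_fixed.ci_high),
        ForestRow("Random effects", result.pooled_random.estimate,
                  result.pooled_random.ci_low, result.pooled_random.ci_high),
    ]
    return forest_plot(rows, pooled, xlabel="AUC", footer=heterogeneity_footer(result))


def ridgeline(data: IPDDataset, variable: str = TEST_RESULT) -> tuple[plt.Figure, pd.DataFrame]:
    """Staggered density plots of a numeric variable, one ridge per study,
    overlaid by disease group (Gaussian kernel, Silverman bandwidth)."""
    if variable not in data.frame.columns:
        raise KeyError(f"unknown variable {variable!r}")
    col = data.frame[variable]
    if not pd.api.types.is_numeric_dtype(col):
        raise TypeError(f"variable {variable!r} is not numeric")
    vals = col.dropna().to_numpy(float)
    labels = data.study_labels()

    # estimate all densities first so the grid can extend past the data range
    # by a few bandwidths (otherwise the exported densities lose tail mass)
    kdes: dict[tuple[int, str], stats.gaussian_kde] = {}
    for sid in data.study_ids:
        sub = data.study_frame(sid)
        for gname, gval in (("nondiseased", 0), ("diseased", 1)):
            obs = sub.loc[sub[DISEASE] == gval, variable].dropna().to_numpy(float)
            if obs.size < 2 or np.ptp(obs) == 0:
                continue
            kdes[(sid, gname)] = stats.gaussian_kde(obs, bw_method="silverman")
    if np.ptp(vals) == 0 or not kdes:
        logger.warning("variable %r is constant; ridgeline degenerates to spikes", variable)
        grid = np.array([vals[0] - 1, vals[0], vals[0] + 1])
    else:
        pad = 4 * max(np.sqrt(k.covariance[0, 0]) for k in kdes.values())
        grid = np.linspace(vals.min() - pad, vals.max() + pad, 256)

    fig, ax = plt.subplots(figsize=(7, 0.5 * data.n_studies + 1.5))
    rows = []
    offset = 0.0
    colors = {"diseased": "tab:red", "nondiseased": "tab:blue"}
    for sid in data.study_ids:
        for gname in ("nondiseased", "diseased"):
            kde = kdes.get((sid, gname))
            if kde is None:
                continue
            dens = kde(grid)
            scaled = dens / dens.max() * 0.9
            ax.fill_between(grid, offset, offset + scaled, alpha=0.4, color=colors[gname])
            for x, d in zip(grid, dens):
                rows.append(
                    {"study": labels[sid], "group": gname, "x": float(x), "density": float(d)}
                )
        offset += 1.0
    ax.set_yticks(np.arange(data.n_studies) + 0.3)
    ax.set_yticklabels([labels[s] for s in data.study_ids])
    ax.set_xlabel(variable)
    return fig, pd.DataFrame(rows)


def roc_by_study(data: IPDDataset) -> tuple[plt.Figure, pd.DataFrame]:
    """Empirical step-function ROC curve of every analyzable study in one plot."""
    labels = data.study_labels()
    fig, ax = plt.subplots(figsize=(6, 6))
    rows = []
    for sid in data.analyzable_study_ids:
        d, nd = data.test_values(sid)
        pts = empirical_roc(d, nd)
        ax.step(pts[:, 0], pts[:, 1], where="post", label=labels[sid])
        for fpr, tpr in pts:
            rows.append({"study": labels[sid], "fpr": float(fpr), "tpr": float(tpr)})
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, ncol=2)
    return fig, pd.DataFrame(rows)


def scatter_with_fits(
    data: IPDDataset, covariate: str, fits: Sequence[CovariateRegression]
) -> tuple[plt.Figure, pd.DataFrame]:
    """Pooled test~covariate scatter colored by study with per-study OLS lines,
    each clipped to its study's covariate range."""
    if data.covariate_types.get(covariate) != "continuous":
        raise TypeError(f"covariate {covariate!r} must be continuous")
    fit_ids = {f.study_id for f in fits}
    if not fit_ids <= set(data.study_ids):
        raise ValueError("fits reference studies absent from the dataset")
    labels = data.study_labels()
    fig, ax = plt.subplots(figsize=(7, 5))
    rows = []
    cmap = plt.get_cmap("tab20")
    for j, sid in enumerate(data.study_ids):
        sub = data.study_frame(sid).dropna(subset=[TEST_RESULT, covariate])
        ax.scatter(sub[covariate], sub[TEST_RESULT], s=8, color=cmap(j % 20), alpha=0.5)
    for f in fits:
        sub = data.study_frame(f.study_id).dropna(subset=[covariate])
        x0, x1 = float(sub[covariate].min()), float(sub[covariate].max())
        y0, y1 = f.intercept + f.slope * x0, f.intercept + f.slope * x1
        ax.plot([x0, x1], [y0, y1], color=cmap(data.study_ids.index(f.study_id) % 20))
        rows.append(
            {"study": labels[f.study_id], "x0": x0, "x1": x1, "y0": y0, "y1": y1,
             "slope": f.slope, "intercept": f.intercept}
        )
    ax.set_xlabel(covariate)
    ax.set_ylabel("test result")
    return fig, pd.DataFrame(rows)


def stacked_bar(summary: pd.DataFrame) -> tuple[plt.Figure, pd.DataFrame]:
    """Stacked bars of categorical-covariate level percentages, two bars
    (diseased / nondiseased) per study, each stacking to 100%."""
    if "level" not in summary.columns:
        raise TypeError("stacked_bar expects a categorical covariate summary")
    levels = sorted(summary["level"].unique())
    studies = list(dict.fromkeys(summary["study"]))
    groups = ("nondiseased", "diseased")
    fig, ax = plt.subplots(figsize=(0.8 * len(studies) + 2, 4))
    width = 0.35
    rows = []
    for gi, group in enumerate(groups):
        bottoms = np.zeros(len(studies))
        for level in levels:
            heights = []
            for study in studies:
                sel = summary[
                    (summary["study"] == study)
                    & (summary["group"] == group)
                    & (summary["level"] == level)
                ]
                pct = float(sel["percent"].sum())
                heights.append(pct)
                rows.append({"study": study, "group": group, "level": level, "percent": pct})
            x = np.arange(len(studies)) + (gi - 0.5) * width
            ax.bar(x, heights, width=width, bottom=bottoms, label=level if gi == 0 else None)
            bottoms += np.asarray(heights)
    ax.set_xticks(np.arange(len(studies)))
    ax.set_xticklabels(studies, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("percent")
    ax.legend(fontsize=7)
    return fig, pd.DataFrame(rows)


def sroc_plot(
    tables: Sequence[ContingencyTable],
    b: BivariateParams,
    h: HSROCParams | None = None,
    level: float = 0.95,
    full_range: bool = False,
) -> tuple[plt.Figure, pd.DataFrame]:
    """SROC display: per-study points (sized by sample size), summary point,
    confidence region and the HSROC-derived summary curve.

    The curve is clipped to the observed per-study FPR range unless
    ``full_range`` is set.
    """
    pts = np.array(
        [
            [t.fp / t.n_nondiseased, t.tp / t.n_diseased, t.n]
            for t in tables
            if t.n_diseased > 0 and t.n_nondiseased > 0
        ]
    )
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(pts[:, 0], pts[:, 1], s=pts[:, 2] * 0.5, alpha=0.5, label="studies")
    rows = [
        {"element": "study", "x": float(x), "y": float(y), "size": float(n)}
        for x, y, n in pts
    ]

    sp = summary_point_with_region(b, level=level)
    ax.plot([1 - sp.specificity], [sp.sensitivity], marker="D", color="tab:red",
            label="summary point")
    ax.plot(sp.region_fpr, sp.region_tpr, color="tab:red", lw=1)
    rows.append({"element": "summary", "x": 1 - sp.specificity, "y": sp.sensitivity,
                 "size": np.nan})
    rows += [
        {"element": "region", "x": float(x), "y": float(y), "size": np.nan}
        for x, y in zip(sp.region_fpr, sp.region_tpr)
    ]

    if h is not None:
        if full_range:
            curve = sroc_curve(h)
        else:
            fpr_obs = pts[:, 0]
            lo = float(np.clip(fpr_obs.min(), 0.005, 0.99))
            hi = float(np.clip(fpr_obs.max(), lo + 1e-3, 0.995))
            curve = sroc_curve(h, fpr_range=(lo, hi))
        ax.plot(curve.fpr, curve.tpr, color="tab:blue", label="SROC")
        rows += [
            {"element": "sroc", "x": float(x), "y": float(y), "size": np.nan}
            for x, y in zip(curve.fpr, curve.tpr)
        ]
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    return fig, pd.DataFrame(rows)


def aroc_plot(fit: AROCFit) -> tuple[plt.Figure, pd.DataFrame]:
    """Covariate-adjusted ROC curve with its AAUC annotation."""
    from .aroc import aroc_curve_table

    table = aroc_curve_table(fit)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.step(table["t"], table["aroc"], where="post", color="tab:red")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("false positive rate t")
    ax.set_ylabel("adjusted ROC(t)")
    ax.set_title(f"AAUC = {fit.aauc:.3f} (covariate: {fit.covariate or 'none'})", fontsize=10)
    return fig, table


def covariate_distribution_plot(
    data: IPDDataset, covariate: str
) -> tuple[plt.Figure, pd.DataFrame]:
    """Ridgeline for continuous covariates; stacked bars for categorical ones."""
    summary = covariate_distributions(data, covariate)
    if "level" in summary.columns:
        return stacked_bar(summary)
    return ridgeline(data, covariate)
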