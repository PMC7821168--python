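"""Dichotomization, Youden optima, 2x2 accuracy panels and empirical AUC,
checked against brute-force oracles."""

import subprocess
import sys
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipdmeta import accuracy
from ipdmeta.accuracy import (
    ContingencyTable,
    ThresholdSpec,
    accuracy_panel,
    auc_ci,
    contingency_from_threshold,
    empirical_auc,
    empirical_roc,
    optimal_youden_threshold,
    resolve_thresholds,
)

from conftest import make_dataset


def brute_force_youden(d, nd):
    """Independent exhaustive search over midpoint candidates (positivity >=)."""
    d, nd = np.asarray(d, float), np.asarray(nd, float)
    pooled = np.unique(np.concatenate([d, nd]))
    cands = [-np.inf] + list((pooled[:-1] + pooled[1:]) / 2) + [np.inf]
    best = max(
        ((np.mean(d >= t) + np.mean(nd < t) - 1, -t) for t in cands),
    )
    return -best[1], best[0]


def brute_force_auc(d, nd):
    """All-pairs concordance count with half-credit for ties."""
    total = 0.0
    for x in d:
        for y in nd:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(d) * len(nd))


class TestYouden:
    def test_perfect_separation(self):
        thr, j = optimal_youden_threshold([3, 4, 5], [1, 2])
        assert thr == 2.5 and j == 1.0

    def test_overlapping_groups_match_exhaustive_search(self):
        d, nd = [3, 4, 5], [1, 2, 3]
        thr, j = optimal_youden_threshold(d, nd)
        bthr, bj = brute_force_youden(d, nd)
        assert j == pytest.approx(bj)
        assert thr == bthr

    def test_no_discrimination_returns_sentinel(self):
        thr, j = optimal_youden_threshold([1, 2, 3], [1, 2, 3])
        assert j == 0.0 and thr == -np.inf

    def test_empty_group_rejected(self):
        with pytest.raises(accuracy.UndefinedThresholdError):
            optimal_youden_threshold([], [1.0])

    def test_random_instances_attain_exhaustive_maximum(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            d = rng.normal(1, 1, rng.integers(2, 15))
            nd = rng.normal(0, 1, rng.integers(2, 15))
            thr, j = optimal_youden_threshold(d, nd)
            bthr, bj = brute_force_youden(d, nd)
            assert j == pytest.approx(bj, abs=1e-12)
            assert thr == pytest.approx(bthr)  # smallest-threshold tie-break


class TestResolveThresholds:
    def test_per_study_defaults_to_pooled_median(self):
        data = make_dataset(
            [("A", v, i % 2) for i, v in enumerate([1, 2, 3])]
            + [("B", v, i % 2) for i, v in enumerate([4, 5])]
        )
        spec = resolve_thresholds(data, ThresholdSpec(mode="per_study"))
        assert spec.resolved_values == {1: 3.0, 2: 3.0}

    def test_user_values_override_default(self):
        data = make_dataset(
            [("A", v, i % 2) for i, v in enumerate([1, 2, 3])]
            + [("B", v, i % 2) for i, v in enumerate([4, 5])]
        )
        spec = resolve_thresholds(
            data, ThresholdSpec(mode="per_study", per_study_values={1: 1.5})
        )
        assert spec.resolved_values == {1: 1.5, 2: 3.0}

    def test_common_value_replicated(self, example_data):
        spec = resolve_thresholds(
            example_data, ThresholdSpec(mode="common_predefined", common_value=2.5)
        )
        assert set(spec.resolved_values.values()) == {2.5}
        assert len(spec.resolved_values) == 15

    def test_optimal_mode_matches_per_study_brute_force(self, tiny_data):
        spec = resolve_thresholds(tiny_data, ThresholdSpec(mode="optimal_youden"))
        for sid in tiny_data.analyzable_study_ids:
            d, nd = tiny_data.test_values(sid)
            assert spec.resolved_values[sid] == brute_force_youden(d, nd)[0]

    def test_non_finite_threshold_rejected(self, tiny_data):
        with pytest.raises(ValueError):
            resolve_thresholds(
                tiny_data, ThresholdSpec(mode="common_predefined", common_value=np.nan)
            )


class TestContingency:
    def test_balanced_example(self):
        data = make_dataset([("A", 2, 1), ("A", 4, 1), ("A", 1, 0), ("A", 3, 0)])
        t = contingency_from_threshold(data, 1, 2.5)
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)

    def test_threshold_below_everything(self):
        data = make_dataset([("A", 2, 1), ("A", 4, 1), ("A", 1, 0), ("A", 3, 0)])
        t = contingency_from_threshold(data, 1, 0.0)
        assert t.fn == 0 and t.tn == 0

    def test_margins_preserved_on_random_study(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=200)
        dis = rng.integers(0, 2, 200)
        data = make_dataset(list(zip(["S"] * 200, vals, dis)))
        for thr in rng.normal(size=10):
            t = contingency_from_threshold(data, 1, thr)
            assert t.n_diseased == dis.sum()
            assert t.n_nondiseased == 200 - dis.sum()

    def test_unknown_study_raises(self, tiny_data):
        with pytest.raises(KeyError):
            contingency_from_threshold(tiny_data, 99, 0.0)

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=30),
        st.floats(-5, 5),
        st.floats(0.01, 3),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_threshold(self, vals, thr, delta):
        """Raising the threshold never raises Se, never lowers Sp."""
        n = len(vals)
        dis = [i % 2 for i in range(n)]
        if sum(dis) == 0 or sum(dis) == n:
            return
        data = make_dataset(list(zip(["S"] * n, vals, dis)))
        lo = contingency_from_threshold(data, 1, thr)
        hi = contingency_from_threshold(data, 1, thr + delta)
        assert hi.tp <= lo.tp  # sensitivity non-increasing
        assert hi.tn >= lo.tn  # specificity non-decreasing


class TestAccuracyPanel:
    def test_closed_form_panel(self):
        est = accuracy_panel(ContingencyTable(1, 0.0, tp=90, fn=10, fp=20, tn=80))
        assert est.sensitivity.value == pytest.approx(0.90)
        assert est.specificity.value == pytest.approx(0.80)
        assert est.lr_pos.value == pytest.approx(4.5)
        assert est.lr_neg.value == pytest.approx(0.125)
        assert est.dor.value == pytest.approx(36.0)
        assert not est.continuity_corrected

    def test_zero_cells_corrected_for_ratios_only(self):
        est = accuracy_panel(ContingencyTable(1, 0.0, tp=0, fn=10, fp=0, tn=10))
        assert est.sensitivity.value == 0.0
        assert est.specificity.value == 1.0
        # corrected cells (0.5, 10.5, 0.5, 10.5)
        assert est.dor.value == pytest.approx((0.5 * 10.5) / (10.5 * 0.5))
        assert est.continuity_corrected

    def test_symmetric_table(self):
        est = accuracy_panel(ContingencyTable(1, 0.0, tp=5, fn=5, fp=5, tn=5))
        for e in (est.sensitivity, est.specificity, est.ppv, est.npv):
            assert e.value == pytest.approx(0.5)
        assert est.dor.value == pytest.approx(1.0)

    def test_cis_bracket_estimates_within_support(self):
        est = accuracy_panel(ContingencyTable(1, 0.0, tp=17, fn=3, fp=6, tn=44))
        for e in (est.sensitivity, est.specificity, est.ppv, est.npv):
            assert 0 <= e.ci_low <= e.value <= e.ci_high <= 1
        for e in (est.lr_pos, est.lr_neg, est.dor):
            assert 0 < e.ci_low <= e.value <= e.ci_high

    def test_transposed_table_swaps_roles(self):
        a = accuracy_panel(ContingencyTable(1, 0.0, tp=17, fn=3, fp=6, tn=44))
        b = accuracy_panel(ContingencyTable(1, 0.0, tp=44, fn=6, fp=3, tn=17))
        assert b.sensitivity.value == pytest.approx(a.specificity.value)
        assert b.specificity.value == pytest.approx(a.sensitivity.value)
        assert b.lr_pos.value == pytest.approx(1 / a.lr_neg.value)
        assert b.dor.value == pytest.approx(a.dor.value)

    def test_empty_table_raises(self):
        with pytest.raises(accuracy.EmptyTableError):
            accuracy_panel(ContingencyTable(1, 0.0, 0, 0, 0, 0))


class TestEmpiricalAUC:
    def test_three_of_four_pairs_concordant(self):
        auc, _ = empirical_auc([2, 4], [1, 3])
        assert auc == pytest.approx(0.75)

    def test_tie_symmetry(self):
        auc, _ = empirical_auc([1, 2], [1, 2])
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_count_on_binormal_sample(self):
        rng = np.random.default_rng(5)
        d = rng.normal(1, 1, 50)
        nd = rng.normal(0, 1, 50)
        auc, se = empirical_auc(d, nd)
        assert auc == pytest.approx(brute_force_auc(d, nd), abs=1e-12)
        assert se > 0

    def test_equals_trapezoid_under_empirical_roc(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            d = rng.normal(0.8, 1, rng.integers(3, 25))
            nd = rng.normal(0, 1, rng.integers(3, 25))
            pts = empirical_roc(d, nd)
            trapezoid = np.trapezoid(pts[:, 1], pts[:, 0])
            assert empirical_auc(d, nd)[0] == pytest.approx(trapezoid, abs=1e-12)

    def test_ci_clipped_to_unit_interval(self):
        lo, hi = auc_ci(0.99, 0.05)
        assert 0 <= lo and hi == 1.0

    def test_roc_vertex_count_and_endpoints(self):
        d, nd = [1.0, 2.0, 3.0], [0.5, 1.0]
        pts = empirical_roc(d, nd)
        # one vertex per distinct value (4) plus the (0,0) start
        assert len(pts) == 5
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)


@pytest.mark.parametrize("n_d,n_n", [(25, 30)])
def test_delong_se_matches_r_proc(n_d, n_n, tmp_path):
    """Independent oracle: AUC and DeLong variance from the R pROC package."""
    rng = np.random.default_rng(99)
    d = rng.normal(1.0, 1.0, n_d)
    nd = rng.normal(0.0, 1.0, n_n)
    auc, se = empirical_auc(d, nd)

    df = tmp_path / "vals.csv"
    with open(df, "w") as fh:
        fh.write("value,disease\n")
        for v in d:
            fh.write(f"{float(v):.17g},1\n")
        for v in nd:
            fh.write(f"{float(v):.17g},0\n")
    script = textwrap.dedent(
        f"""
        suppressMessages(library(pROC))
        x <- read.csv("{df}")
        r <- roc(x$disease, x$value, direction="<", quiet=TRUE)
        cat(sprintf("%.15g", c(as.numeric(auc(r)), sqrt(var(r)))), sep="\\n")
        """
    )
    try:
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
    except FileNotFoundError:
        pytest.skip("Rscript unavailable")
    assert out.returncode == 0, out.stderr
    r_auc, r_se = map(float, out.stdout.split())
    assert auc == pytest.approx(r_auc, abs=1e-10)
    assert se == pytest.approx(r_se, rel=1e-6)
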