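"""Statistical stage: severity rule, descriptives, Spearman, group tests,
ROC/Youden machinery against brute-force oracles, ICC, report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from parascint.cohort import default_cohort_spec, simulate_cohort
from parascint.stats import (
    compare_groups,
    descriptive_summary,
    icc,
    roc_curve,
    run_study_analysis,
    severity_group,
    spearman,
    youden_index,
    youden_optimal_cutoff,
)

# ---------------------------------------------------------------------- oracles


def midranks(v):
    """Independent mid-rank computation by explicit tie-group averaging."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(x, y):
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))


def u_statistic_oracle(a, b):
    """All-pairs Mann-Whitney U of a vs b, ties counted one half."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def delong_oracle(pos, neg):
    """O(n^2) structural-component DeLong AUC and variance."""
    psi = np.where(
        pos[:, None] > neg[None, :], 1.0,
        np.where(pos[:, None] == neg[None, :], 0.5, 0.0),
    )
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return auc, s10 / pos.size + s01 / neg.size


def youden_cutoff_oracle(marker, y, direction):
    """Exhaustive enumeration over realized cutoffs with the tie rules:
    max J, then max sensitivity, then cutoff nearest the marker median."""
    med = np.median(marker)
    best = None
    for c in np.unique(marker):
        if direction == "greater_is_positive":
            pred = marker >= c
        else:
            pred = marker <= c
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12), -abs(c - med))
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)
    return best[1:]


# ------------------------------------------------------------------- severity


class TestSeverityGroup:
    @pytest.mark.parametrize(
        "ca,expected",
        [(11.0, "mild"), (11.6, "marked"), (11.5, "marked"), (10.5, "mild"),
         (11.49, "mild")],
    )
    def test_rule(self, ca, expected):
        assert severity_group(ca) == expected

    def test_ineligible_below_bound(self):
        with pytest.raises(ValueError, match="eligibility"):
            severity_group(10.2)

    def test_partition_of_eligible_records(self):
        df = simulate_cohort(default_cohort_spec(n=300, seed=5))
        groups = df["calcium"].map(severity_group)
        assert set(groups.unique()) <= {"mild", "marked"}
        assert ((groups == "mild") ^ (groups == "marked")).all()


# ---------------------------------------------------------------- descriptives


class TestDescriptiveSummary:
    def test_mean_sd_formatting(self):
        out = descriptive_summary([1.0, 2.0, 3.0], normal=True)
        assert out["text"] == "2.00 ± 1.00"

    def test_median_range_formatting(self):
        out = descriptive_summary([1.0, 2.0, 100.0], normal=False)
        assert out["median"] == 2.0
        assert out["text"] == "2.00 (1.00–100.00)"

    def test_lognormal_column_matches_quantile_oracle(self):
        rng = np.random.default_rng(1)
        v = np.exp(rng.normal(0, 1, 500))
        out = descriptive_summary(v)
        assert out["kind"] == "median_range"
        assert out["median"] == pytest.approx(np.quantile(v, 0.5))
        assert out["min"] == v.min() and out["max"] == v.max()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            descriptive_summary([1.0])


# -------------------------------------------------------------------- spearman


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**2)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.integers(0, 5, 10).astype(float)
            y = rng.integers(0, 5, 10).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(pearson(midranks(x), midranks(y)), abs=1e-12)

    def test_p_value_uses_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        from scipy import stats as sps

        t = rho * np.sqrt(28 / (1 - rho**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 28), rel=1e-9)

    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_under_strictly_monotone_transform(self, kind):
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        f = {"exp": np.exp, "cube": lambda v: v**3,
             "affine": lambda v: 3.0 * v + 2.0}[kind]
        assert spearman(f(x), y)[0] == pytest.approx(spearman(x, y)[0], abs=1e-12)

    def test_degenerate_input_flagged(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# -------------------------------------------------------------- compare_groups


class TestCompareGroups:
    def test_identical_groups_null(self):
        v = list(np.arange(10.0)) * 2
        g = ["a"] * 10 + ["b"] * 10
        res = compare_groups(v, g)
        assert res.p_value > 0.9

    def test_separated_normals_use_t(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(10, 1, 30)
        res = compare_groups(np.concatenate([a, b]), ["a"] * 30 + ["b"] * 30)
        assert res.test_used == "t"
        assert res.p_value < 0.001

    def test_nonnormal_groups_use_mann_whitney_and_match_u_oracle(self):
        a = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 50.0, 60.0, 70.0, 500.0])
        b = np.array([2.0, 2.0, 3.0, 3.0, 4.0, 5.0, 5.0, 90.0, 600.0, 700.0])
        res = compare_groups(
            np.concatenate([a, b]), ["a"] * 10 + ["b"] * 10
        )
        assert res.test_used == "mann_whitney"
        assert res.statistic == pytest.approx(u_statistic_oracle(a, b), abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_groups([1, 2, 3, 4], ["a", "a", "b", "b"])


# ------------------------------------------------------------------------- roc


class TestRocCurve:
    def test_perfect_separation(self):
        m = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        roc = roc_curve(m, y)
        assert roc.auc == 1.0
        assert roc.youden_j == pytest.approx(1.0)

    def test_independent_marker_auc_near_half(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=2000)
        y = rng.random(2000) < 0.5
        assert roc_curve(m, y).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_tie_corrected_u_over_n1n2(self):
        """Trapezoid AUC == all-pairs U/(n1 n2) on 200 random tied samples."""
        rng = np.random.default_rng(20)
        for _ in range(200):
            n = rng.integers(6, 41)
            m = rng.integers(0, 8, n).astype(float)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            roc = roc_curve(m, y, direction="greater_is_positive")
            u = u_statistic_oracle(m[y], m[~y])
            # trapezoid over the empirical curve, computed independently
            trap = float(np.trapezoid(roc.curve[:, 1], roc.curve[:, 0]))
            expected = u / (y.sum() * (~y).sum())
            assert roc.auc == pytest.approx(expected, abs=1e-12)
            assert trap == pytest.approx(expected, abs=1e-12)

    def test_delong_matches_structural_component_oracle(self):
        rng = np.random.default_rng(21)
        m = np.round(rng.normal(size=60), 1)
        y = rng.random(60) < 0.4
        roc = roc_curve(m, y, direction="greater_is_positive")
        auc_o, var_o = delong_oracle(m[y], m[~y])
        assert roc.auc == pytest.approx(auc_o, abs=1e-12)
        se = (roc.auc_ci95[1] - roc.auc) / 1.959963984540054
        assert se == pytest.approx(np.sqrt(var_o), rel=1e-6)

    def test_direction_reversal_flips_auc_and_sign(self):
        rng = np.random.default_rng(22)
        m = rng.normal(size=50)
        y = rng.random(50) < 0.5
        g = roc_curve(m, y, direction="greater_is_positive")
        l = roc_curve(m, y, direction="lesser_is_positive")
        assert l.auc == pytest.approx(1.0 - g.auc, abs=1e-12)
        assert g.cutoff_text.startswith(">")
        assert l.cutoff_text.startswith("<")

    def test_auc_matches_sklearn_cross_check(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(25)
        for _ in range(20):
            m = rng.integers(0, 6, 40).astype(float)
            y = rng.random(40) < 0.5
            if y.all() or not y.any():
                continue
            ours = roc_curve(m, y, direction="greater_is_positive").auc
            assert ours == pytest.approx(sk.roc_auc_score(y, m), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], [True, True])

    def test_curve_is_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(23)
        m = rng.integers(0, 5, 30).astype(float)
        y = rng.random(30) < 0.5
        roc = roc_curve(m, y)
        assert tuple(roc.curve[0]) == (0.0, 0.0)
        assert tuple(roc.curve[-1]) == (1.0, 1.0)
        assert (np.diff(roc.curve[:, 0]) >= -1e-15).all()
        assert (np.diff(roc.curve[:, 1]) >= -1e-15).all()


class TestYouden:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.6842, 0.8000, 0.48), (0.85, 0.60, 0.45), (1.0, 1.0, 1.0)],
    )
    def test_published_operating_points(self, sens, spec, expected):
        assert round(youden_index(sens, spec), 2) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            youden_index(1.2, 0.5)

    def test_optimal_cutoff_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            n = rng.integers(8, 30)
            m = rng.integers(0, 6, n).astype(float)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            roc = roc_curve(m, y, direction="greater_is_positive")
            cut, sens, spec, j = youden_optimal_cutoff(roc)
            c_o, s_o, sp_o, j_o = youden_cutoff_oracle(m, y, roc.direction)
            assert j == pytest.approx(j_o, abs=1e-12)
            assert sens == pytest.approx(s_o, abs=1e-12)
            assert cut == pytest.approx(c_o, abs=1e-12)
            assert j == pytest.approx(sens + spec - 1.0, abs=1e-12)

    def test_degenerate_constant_marker(self):
        m = np.full(12, 3.0)
        y = np.arange(12) < 6
        roc = roc_curve(m, y, direction="greater_is_positive")
        assert roc.auc == pytest.approx(0.5)
        assert roc.youden_j == pytest.approx(0.0)


# ------------------------------------------------------------------------- icc


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        assert icc(x) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(400, 2))
        assert abs(icc(x)) < 0.12

    def test_matches_anova_mean_square_oracle(self):
        x = np.array(
            [[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0], [7.0, 6.0], [6.0, 4.0]]
        )
        n, k = x.shape
        # independent route: variance components from raw sums of squares
        grand = x.mean()
        msr = ((x.mean(1) - grand) ** 2).sum() * k / (n - 1)
        msc = ((x.mean(0) - grand) ** 2).sum() * n / (k - 1)
        mse = (
            ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + grand) ** 2)
            .sum() / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(x) == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        subj = rng.normal(0, 2, 12)
        x = subj[:, None] + rng.normal(0, 1, (12, 3))
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(12), 3),
                "r": np.tile(np.arange(3), 12),
                "v": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="v")
        # ICC(A,1): two-way, absolute agreement, single rater == ICC(2,1)
        ref_icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(x) == pytest.approx(ref_icc2, abs=1e-10)

    def test_incomplete_matrix_rejected(self):
        x = np.ones((6, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc(x)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((3, 2)))


# ---------------------------------------------------------------------- report


class TestRunStudyAnalysis:
    def test_smoke_on_default_cohort(self):
        df = simulate_cohort(default_cohort_spec(n=70, seed=0))
        bundle = run_study_analysis(df)
        assert bundle["n"] == 70
        assert set(bundle["severity_counts"]) == {"mild", "marked"}
        for roc in bundle["roc_table"].values():
            assert roc.youden_j == pytest.approx(
                roc.sensitivity + roc.specificity - 1.0, abs=1e-12
            )
            assert 0.0 <= roc.auc <= 1.0
        assert "pth" in bundle["correlations"]
        assert bundle["correlations"]["pth"]["pth_svol"]["n"] == 70

    def test_near_perfect_marker_reaches_auc_one(self):
        df = simulate_cohort(default_cohort_spec(n=70, seed=1))
        rng = np.random.default_rng(0)
        df["pth"] = (df["severity"] == "marked") * 100.0 + 10.0 + rng.normal(
            0, 0.1, len(df)
        )
        bundle = run_study_analysis(df)
        assert bundle["roc_table"]["pth"].auc > 0.99

    def test_location_block_present_with_lower_sites(self):
        df = simulate_cohort(default_cohort_spec(n=200, seed=2))
        bundle = run_study_analysis(df)
        assert "location_comparison" in bundle
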