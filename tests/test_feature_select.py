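import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from methtree.feature_select import (
    anova_screen, boruta_confirm, select_markers, tukey_kramer,
)


def labelled_matrix(groups: dict[str, np.ndarray], probe="cg1"):
    """Build a 1-probe matrix plus labels from {class: values}."""
    cols, vals, labs = [], [], []
    i = 0
    for cls, xs in groups.items():
        for x in xs:
            i += 1
            cols.append(f"s{i}")
            vals.append(x)
            labs.append(cls)
    mat = pd.DataFrame([vals], index=[probe], columns=cols)
    return mat, pd.Series(labs, index=cols)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestAnova:
    def test_matches_scipy_f_oneway(self, rng):
        """Vectorized F statistic equals scipy's per-probe computation."""
        mat = pd.DataFrame(rng.random((20, 18)) * 0.9,
                           columns=[f"s{i}" for i in range(18)],
                           index=[f"cg{i}" for i in range(20)])
        labels = pd.Series(["a"] * 6 + ["b"] * 5 + ["c"] * 7, index=mat.columns)
        out = anova_screen(mat, labels, alpha=1.0)
        for probe in mat.index:
            groups = [mat.loc[probe, labels == c].to_numpy() for c in "abc"]
            F, p = stats.f_oneway(*groups)
            assert out.loc[probe, "F"] == pytest.approx(F, abs=1e-10)
            assert out.loc[probe, "p"] == pytest.approx(p, abs=1e-10)

    def test_constant_probe_excluded(self):
        mat, labels = labelled_matrix({"a": [0.5] * 4, "b": [0.5] * 4})
        out = anova_screen(mat, labels, alpha=0.5)
        assert len(out) == 0

    def test_perfectly_separated_probe_retained(self):
        mat, labels = labelled_matrix({"a": [0.2] * 4, "b": [0.8] * 4})
        out = anova_screen(mat, labels, alpha=0.05)
        assert out.loc["cg1", "p"] == 0.0

    def test_planted_marker_retained(self, small_cohort, rng):
        """A delta-beta 0.3 group marker passes the screen with power ~ 1."""
        _, matrix, manifest, _, truth = small_cohort
        group_of = manifest["cancer_type"].map(truth.group_of_type)
        labels = pd.Series(group_of.to_numpy(), index=manifest["sample_id"].to_numpy())
        some_group = sorted(truth.group_marker_classes)[0]
        markers = sorted(truth.marker_probes[some_group])
        out = anova_screen(matrix.loc[markers], labels, alpha=0.05)
        assert len(out) == len(markers)

    def test_small_class_rejected(self):
        mat, labels = labelled_matrix({"a": [0.1], "b": [0.5, 0.6]})
        with pytest.raises(ValueError):
            anova_screen(mat, labels)


# ---------------------------------------------------------------------------
# Tukey-Kramer
# ---------------------------------------------------------------------------

def studentized_range_sf_by_quadrature(q, k, df):
    """Independent oracle: numerical double integration of the studentized
    range distribution (range CDF of k standard normals, mixed over the
    scaled-chi density of the pooled scale estimate)."""
    import math

    def range_cdf(qs):
        # P(range of k std normals <= qs)
        inner = lambda z: stats.norm.pdf(z) * (
            stats.norm.cdf(z + qs) - stats.norm.cdf(z)) ** (k - 1)
        val, _ = quad(inner, -np.inf, np.inf, limit=200)
        return k * val

    def s_pdf(s):
        # density of s with df * s^2 ~ chi-square(df)
        return (2 * (df / 2.0) ** (df / 2.0) / math.gamma(df / 2.0)
                * s ** (df - 1) * np.exp(-df * s * s / 2.0))

    val, _ = quad(lambda s: s_pdf(s) * range_cdf(q * s), 0, np.inf, limit=200)
    return 1.0 - val


class TestTukeyKramer:
    def test_equal_means_not_significant(self):
        mat, labels = labelled_matrix({
            "a": [0.4, 0.5, 0.6], "b": [0.4, 0.5, 0.6], "c": [0.1, 0.2, 0.3]})
        out = tukey_kramer(mat, labels, "cg1")
        row = out[(out.class_a == "a") & (out.class_b == "b")].iloc[0]
        assert row["mean_diff"] == pytest.approx(0.0)
        assert row["adj_p"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_tukey_hsd(self, rng):
        """Adjusted p equals scipy's Tukey HSD on balanced 3-class data."""
        groups = {c: rng.random(6) * 0.8 for c in "abc"}
        mat, labels = labelled_matrix(groups)
        ours = tukey_kramer(mat, labels, "cg1")
        ref = stats.tukey_hsd(*[np.asarray(groups[c]) for c in "abc"])
        idx = {"a": 0, "b": 1, "c": 2}
        for _, row in ours.iterrows():
            i, j = idx[row.class_a], idx[row.class_b]
            assert row.adj_p == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_matches_quadrature_oracle(self, rng):
        """Adjusted p agrees with direct numerical integration of the
        studentized range distribution."""
        groups = {c: 0.1 + 0.7 * rng.random(5) for c in "abc"}
        mat, labels = labelled_matrix(groups)
        out = tukey_kramer(mat, labels, "cg1")
        k, df = 3, 12
        x = mat.iloc[0]
        mse = np.mean([np.var(x[labels == c], ddof=1) for c in "abc"])
        for _, row in out.iterrows():
            se = np.sqrt(mse / 2 * (1 / 5 + 1 / 5))
            q = abs(row.mean_diff) / se
            oracle = studentized_range_sf_by_quadrature(q, k, df)
            assert row.adj_p == pytest.approx(oracle, abs=1e-6)

    def test_two_classes_agree_with_pooled_t(self, rng):
        """With k = 2 the Tukey decision coincides with the two-sided
        pooled-variance t test (q = t * sqrt(2))."""
        a, b = rng.random(8) * 0.5, 0.2 + rng.random(6) * 0.5
        mat, labels = labelled_matrix({"a": a, "b": b})
        out = tukey_kramer(mat, labels, "cg1").iloc[0]
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert out.adj_p == pytest.approx(t_p, abs=1e-8)

    def test_p_monotone_in_mean_gap(self):
        base = {"a": [0.40, 0.45, 0.50], "c": [0.42, 0.47, 0.52]}
        ps = []
        for shift in (0.05, 0.15, 0.30):
            grp = dict(base, b=[0.40 + shift, 0.45 + shift, 0.50 + shift])
            mat, labels = labelled_matrix(grp)
            out = tukey_kramer(mat, labels, "cg1")
            ps.append(out[(out.class_a == "a") & (out.class_b == "b")].adj_p.iloc[0])
        assert ps[0] > ps[1] > ps[2]

    def test_tiny_class_rejected(self):
        mat, labels = labelled_matrix({"a": [0.1], "b": [0.5, 0.6]})
        with pytest.raises(ValueError, match="< 2 samples"):
            tukey_kramer(mat, labels, "cg1")


# ---------------------------------------------------------------------------
# one-vs-all-others selection
# ---------------------------------------------------------------------------

def three_class_matrix(rng, n_per=12):
    """30 probes: 0-9 mark class a (delta ~0.3), 10-14 differ between a and
    b only, the rest are noise."""
    classes = ["a"] * n_per + ["b"] * n_per + ["c"] * n_per
    cols = [f"s{i}" for i in range(3 * n_per)]
    vals = rng.normal(0.45, 0.02, size=(30, 3 * n_per))
    for p in range(10):
        vals[p, :n_per] += 0.3
    for p in range(10, 15):
        vals[p, n_per:2 * n_per] += 0.3  # b differs from a AND c: marks b
        vals[p, 2 * n_per:] += 0.3       # ... unless c moves too: a-only gap
    mat = pd.DataFrame(np.clip(vals, 0.01, 0.97), columns=cols,
                       index=[f"cg{i:02d}" for i in range(30)])
    return mat, pd.Series(classes, index=cols)


class TestSelectMarkers:
    def test_all_others_rule_brute_force(self, rng):
        """Selected markers satisfy the printed rule exactly when re-checked
        probe by probe with the pairwise test."""
        mat, labels = three_class_matrix(rng)
        panel = select_markers(mat, labels, min_markers=1)
        for cls in ("a", "b", "c"):
            delta = panel.accepted_delta[cls]
            for probe in mat.index:
                pw = tukey_kramer(mat, labels, probe)
                pw = pw[(pw.class_a == cls) | (pw.class_b == cls)]
                qualifies = bool(((pw.adj_p < 0.01)
                                  & (pw.mean_diff.abs() > delta)).all())
                assert (probe in panel.markers[cls]) == qualifies, (cls, probe)

    def test_probe_equal_to_one_other_class_not_selected(self, rng):
        mat, labels = three_class_matrix(rng)
        # probes 10-14: a differs from b and c... b == c there, so they can
        # mark a but never b or c
        panel = select_markers(mat, labels, min_markers=1)
        for p in [f"cg{i:02d}" for i in range(10, 15)]:
            assert p not in panel.markers["b"]
            assert p not in panel.markers["c"]

    def test_marker_sets_nested_across_schedule(self, rng):
        mat, labels = three_class_matrix(rng)
        sets = {}
        for delta in (0.2, 0.15, 0.1):
            panel = select_markers(mat, labels, delta_schedule=(delta,),
                                   min_markers=1)
            sets[delta] = {c: set(panel.markers[c]) for c in panel.markers}
        for c in sets[0.2]:
            assert sets[0.2][c] <= sets[0.15][c] <= sets[0.1][c]

    def test_relaxation_accepts_smaller_delta(self, rng):
        """A class whose markers only reach delta-beta ~ 0.17 is accepted at
        the 0.15 level."""
        n = 15
        cols = [f"s{i}" for i in range(2 * n)]
        vals = rng.normal(0.45, 0.01, size=(25, 2 * n))
        vals[:20, :n] += 0.17
        mat = pd.DataFrame(np.clip(vals, 0.01, 0.97), columns=cols,
                           index=[f"cg{i:02d}" for i in range(25)])
        labels = pd.Series(["a"] * n + ["b"] * n, index=cols)
        panel = select_markers(mat, labels, min_markers=10)
        assert panel.accepted_delta["a"] == 0.15
        assert len(panel.markers["a"]) >= 10
        assert not panel.failures

    def test_failures_recorded(self, rng):
        cols = [f"s{i}" for i in range(20)]
        mat = pd.DataFrame(rng.normal(0.5, 0.01, size=(5, 20)), columns=cols,
                           index=[f"cg{i}" for i in range(5)])
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=cols)
        panel = select_markers(mat, labels, min_markers=3)
        assert set(panel.failures) == {"a", "b"}

    def test_planted_marker_recovery(self):
        """Tukey selection on planted data recovers the group markers with
        precision and recall above 0.9.

        Lineage drift is kept small here so that group separation comes
        from the planted markers alone; a type marker of a singleton-group
        type is counted as planted too, since shifting the only type of a
        group shifts the whole group by the same delta.
        """
        from methtree import SyntheticSpec, generate_cohort

        spec = SyntheticSpec(
            n_groups=4, types_per_group=(1, 2, 2, 1), subtypes_per_type=2,
            samples_per_subtype=10, n_background_probes=300,
            n_markers_per_group=12, n_markers_per_type=8, n_sex_probes=0,
            drift_scale=0.04, seed=13)
        matrix, manifest, _, truth = generate_cohort(spec)
        labels = pd.Series(
            manifest["cancer_type"].map(truth.group_of_type).to_numpy(),
            index=manifest["sample_id"].to_numpy())
        screened = anova_screen(matrix, labels)
        panel = select_markers(matrix.loc[screened.index], labels, min_markers=5)
        singleton_types = [t for t, g in truth.group_of_type.items()
                           if sum(gg == g for gg in truth.group_of_type.values()) == 1]
        planted = set().union(*(truth.marker_probes[g]
                                for g in truth.group_marker_classes))
        planted |= set().union(*(truth.marker_probes[t] for t in singleton_types))
        selected = set(panel.all_probes)
        recall = len(selected & planted) / len(planted)
        precision = len(selected & planted) / len(selected)
        assert recall >= 0.9
        assert precision >= 0.9


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

def boruta_problem(rng, n=60, n_noise=50, informative="copy"):
    y = rng.integers(0, 2, size=n)
    X = pd.DataFrame(rng.normal(size=(n, n_noise)),
                     columns=[f"noise{i}" for i in range(n_noise)])
    if informative == "copy":
        X.insert(0, "label_copy", y.astype(float))
    return X, y


class TestBoruta:
    def test_label_copy_confirmed(self, rng):
        """A noiseless copy of the label among 50 noise features is
        confirmed for every tested seed."""
        hits = 0
        for seed in range(5):
            X, y = boruta_problem(np.random.default_rng(100 + seed))
            conf = boruta_confirm(X, y, max_iter=40, seed=seed,
                                  n_estimators=60, max_depth=5)
            hits += "label_copy" in conf
        assert hits >= 4

    def test_pure_noise_confirms_nothing(self, rng):
        """With enough samples per feature, chance in-sample associations
        are too weak to beat the shadow maximum consistently."""
        empty = 0
        for seed in range(5):
            X, y = boruta_problem(np.random.default_rng(200 + seed),
                                  n=200, n_noise=30, informative=None)
            conf = boruta_confirm(X, y, max_iter=25, seed=seed,
                                  n_estimators=40, max_depth=5)
            empty += (len(conf) == 0)
        assert empty >= 4

    def test_zero_variance_feature_rejected(self, rng):
        X, y = boruta_problem(rng)
        X["dead"] = 0.0
        conf = boruta_confirm(X, y, max_iter=30, seed=0,
                              n_estimators=60, max_depth=5)
        assert "dead" not in conf

    def test_confirmed_is_subset_of_input(self, rng):
        X, y = boruta_problem(rng)
        conf = boruta_confirm(X, y, max_iter=15, seed=0,
                              n_estimators=40, max_depth=5)
        assert set(conf) <= set(X.columns)

    def test_reproducible_given_seed(self, rng):
        X, y = boruta_problem(rng)
        a = boruta_confirm(X, y, max_iter=15, seed=3, n_estimators=40, max_depth=5)
        b = boruta_confirm(X, y, max_iter=15, seed=3, n_estimators=40, max_depth=5)
        assert a == b

    def test_bad_max_iter_rejected(self, rng):
        X, y = boruta_problem(rng)
        with pytest.raises(ValueError):
            boruta_confirm(X, y, max_iter=0)
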