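import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hrvlandscape import cohort as cs


def table_from(values_by_group, index="H1", subjects=None):
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append({"subject_id": subjects[g][i] if subjects else f"{g}{i}",
                         "months_post_htx": 12.0 * (i + 1),
                         "group": g, index: v})
    return pd.DataFrame(rows)


def trend_table(slope_f, slope_nf, noise_sd, rng, n_per_group=17):
    rows = []
    for g, slope in (("F", slope_f), ("NF", slope_nf)):
        for i in range(n_per_group):
            months = float(rng.uniform(6, 96))
            rows.append({"subject_id": f"{g}{i}", "months_post_htx": months,
                         "group": g,
                         "H1": 1.4 + slope * months / 12.0
                         + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


def test_identical_groups_not_separated():
    t = table_from({"F": [1, 2, 3, 4], "NF": [1, 2, 3, 4]})
    r = cs.compare_groups(t, "H1")
    assert r.p > 0.9
    assert r.summaries["F"][0] == r.summaries["NF"][0]


def test_fully_separated_groups_exact_permutation_p():
    t = table_from({"F": [1, 2, 3], "NF": [10, 11, 12]})
    r = cs.compare_groups(t, "H1")
    # exhaustive permutation oracle over the 20 assignments of ranks 3|3
    pooled = [1, 2, 3, 10, 11, 12]
    ranks = stats.rankdata(pooled)
    obs = None
    perm_stats = []
    n = len(pooled)
    for combo in itertools.combinations(range(n), 3):
        ra = ranks[list(combo)]
        rb = ranks[[i for i in range(n) if i not in combo]]
        h = (12 / (n * (n + 1))) * (3 * ra.mean() ** 2 + 3 * rb.mean() ** 2) \
            - 3 * (n + 1)
        perm_stats.append(round(h, 10))
        if set(combo) == {0, 1, 2}:
            obs = round(h, 10)
    p_exact = np.mean([s >= obs for s in perm_stats])
    assert r.statistic == pytest.approx(obs, abs=1e-9)
    # scipy uses the chi-square approximation; check against the exact
    # permutation value at matching order of magnitude
    assert r.p < 0.10 and p_exact == pytest.approx(0.1, abs=1e-12)


def test_kruskal_type_I_error_calibrated():
    rng = np.random.default_rng(12)
    rejections = 0
    n_sim = 1000
    for _ in range(n_sim):
        t = table_from({"F": rng.normal(size=10), "NF": rng.normal(size=10)})
        rejections += cs.compare_groups(t, "H1").p < 0.05
    assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


def test_compare_groups_empty_group():
    t = table_from({"F": [1, 2, 3], "NF": [1.0]})
    with pytest.raises(ValueError):
        cs.compare_groups(t, "H1")


def _entropy_cohort(rng, lag2=False, n_signals=30):
    """Per-signal entropy columns from simulated chains."""
    import hrvlandscape as hl
    from hrvlandscape.symbolize import symbolize
    from hrvlandscape.synth import antipersistent_chain, lag2_mirror_chain, \
        simulate_markov_rr
    chain = lag2_mirror_chain() if lag2 else antipersistent_chain()
    rows = []
    for i in range(n_signals):
        s = simulate_markov_rr(chain, 6000, seed=int(rng.integers(2**31)))
        p = hl.entropy_profile(symbolize(s, 8.0))
        rows.append({"subject_id": f"S{i}", "months_post_htx": 12.0,
                     "group": "F" if i % 2 == 0 else "NF",
                     "H1": p.H1, "H2": p.H2, "H3": p.H3,
                     "S_T": p.S_T, "sTE": p.sTE})
    return pd.DataFrame(rows)


def test_dependence_tests_reject_for_markov_cohort():
    rng = np.random.default_rng(5)
    t = _entropy_cohort(rng)
    res = cs.paired_dependence_tests(t)
    for r in res:
        if r.hypothesis != "sTE != 0":
            assert r.p < 0.01, r  # genuine first-order dependence everywhere


def test_ste_test_detects_lag2_memory():
    rng = np.random.default_rng(6)
    t = _entropy_cohort(rng, lag2=True)
    res = [r for r in cs.paired_dependence_tests(t) if r.hypothesis == "sTE != 0"]
    assert all(r.p < 0.01 for r in res)


def test_ste_estimates_sit_at_bias_scale_for_first_order():
    """First-order cohorts give sTE at the negative plug-in bias scale
    K(K-1)^2/2n — far below genuine lag-2 memory effects."""
    rng = np.random.default_rng(17)
    t = _entropy_cohort(rng, n_signals=12)
    bias_bound = 3 * (3 - 1) ** 2 / (2 * 6000)
    assert np.median(np.abs(t["sTE"])) < 5 * bias_bound
    rng2 = np.random.default_rng(18)
    t2 = _entropy_cohort(rng2, lag2=True, n_signals=6)
    assert np.median(np.abs(t2["sTE"])) > 100 * bias_bound


def test_dependence_tests_refuse_small_groups():
    t = pd.DataFrame({"subject_id": list("abcdefgh"),
                      "months_post_htx": 12.0,
                      "group": ["F"] * 4 + ["NF"] * 4,
                      "H1": 1.0, "H2": 1.8, "H3": 2.5,
                      "S_T": 0.8, "sTE": -0.1})
    with pytest.raises(ValueError, match="fewer than 5"):
        cs.paired_dependence_tests(t)


def test_compare_groups_subject_median_aggregation():
    t = pd.DataFrame({"subject_id": ["a", "a", "b", "c", "c", "d"],
                      "months_post_htx": 12.0,
                      "group": ["F", "F", "F", "NF", "NF", "NF"],
                      "H1": [1.0, 3.0, 2.0, 5.0, 7.0, 6.0]})
    r = cs.compare_groups(t, "H1", aggregate="subjects")
    assert r.summaries["F"][3] == 2       # two subjects
    assert r.summaries["F"][0] == 2.0     # medians of per-subject medians


def test_degenerate_identical_columns():
    t = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(12)],
        "months_post_htx": np.arange(12, dtype=float),
        "group": ["F"] * 6 + ["NF"] * 6,
        "H1": np.ones(12), "H2": 2 * np.ones(12), "H3": 3 * np.ones(12),
        "S_T": np.ones(12), "sTE": np.zeros(12),
    })
    res = {(r.group, r.hypothesis): r for r in cs.paired_dependence_tests(t)}
    for g in ("F", "NF"):
        assert res[(g, "sTE != 0")].p == 1.0
        assert res[(g, "sTE != 0")].test_used == "degenerate"


def test_classification_perfect_separation():
    t = table_from({"F": [1, 2, 3, 4, 5], "NF": [10, 11, 12, 13, 14]})
    counts = cs.classification_counts(t, ["H1"])
    assert counts == {"F": (5, 5), "NF": (5, 5)}


def test_classification_null_feature_majority_rate():
    rng = np.random.default_rng(8)
    accs = []
    for _ in range(50):
        t = table_from({"F": rng.normal(size=12), "NF": rng.normal(size=18)})
        c = cs.classification_counts(t, ["H1"])
        accs.append((c["F"][0] + c["NF"][0]) / 30)
    # uninformative feature: about the majority-class rate (18/30)
    assert np.mean(accs) == pytest.approx(0.6, abs=0.07)


def test_classification_designed_overlap():
    rng = np.random.default_rng(9)
    rates = []
    for _ in range(30):
        # two unit-variance features 2*1.82 sigma apart -> ~10% Bayes error
        n = 40
        f = rng.normal(-1.282, 1.0, (n, 2))
        nf = rng.normal(1.282, 1.0, (n, 2))
        t = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "months_post_htx": 12.0, "group": ["F"] * n + ["NF"] * n,
            "x1": np.concatenate([f[:, 0], nf[:, 0]]),
            "x2": np.concatenate([f[:, 1], nf[:, 1]]),
        })
        c = cs.classification_counts(t, ["x1", "x2"])
        rates.append((c["F"][0] + c["NF"][0]) / (2 * n))
    expected = stats.norm.cdf(1.282 * np.sqrt(2))      # 2-D separation
    assert np.mean(rates) == pytest.approx(expected, abs=0.05)


def test_regress_exact_line():
    months = np.array([0.0, 12, 24, 36, 48])
    t = pd.DataFrame({"subject_id": [f"s{i}" for i in range(5)],
                      "months_post_htx": months, "group": "NF",
                      "H1": 2.0 * months / 12.0 + 1.0})
    r = cs.regress_time(t, "H1", "NF")
    assert r.slope == pytest.approx(2.0, abs=1e-10)
    assert r.r == pytest.approx(1.0, abs=1e-12)
    assert r.stderr == pytest.approx(0.0, abs=1e-8)


def test_regress_slope_coverage():
    rng = np.random.default_rng(10)
    hits = 0
    n_sim = 200
    for _ in range(n_sim):
        t = trend_table(0.0, 0.3, 0.15, rng)
        r = cs.regress_time(t, "H1", "NF")
        hits += abs(r.slope - 0.3) <= 2 * r.stderr
    assert hits / n_sim >= 0.93


def test_regress_null_slope_retained():
    rng = np.random.default_rng(11)
    retained = 0
    n_sim = 200
    for _ in range(n_sim):
        t = trend_table(0.0, 0.0, 0.15, rng)
        retained += cs.regress_time(t, "H1", "F").p >= 0.05
    assert retained / n_sim == pytest.approx(0.95, abs=0.04)


def test_regress_invariances():
    rng = np.random.default_rng(13)
    t = trend_table(0.1, 0.2, 0.1, rng)
    base = cs.regress_time(t, "H1", "NF")
    shuffled = cs.regress_time(t.sample(frac=1, random_state=0), "H1", "NF")
    assert base.slope == pytest.approx(shuffled.slope, rel=1e-12)
    # affine rescale of months: slope transforms correspondingly
    t2 = t.copy()
    t2["months_post_htx"] = t2["months_post_htx"] * 2.0
    assert cs.regress_time(t2, "H1", "NF").slope == \
        pytest.approx(base.slope / 2.0, rel=1e-10)


def test_regress_degenerate_time():
    t = pd.DataFrame({"subject_id": list("abc"), "months_post_htx": 12.0,
                      "group": "F", "H1": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="slope"):
        cs.regress_time(t, "H1", "F")


def test_equal_slopes_same_line():
    months = np.tile(np.array([6.0, 18, 30, 42]), 2)
    t = pd.DataFrame({"subject_id": [f"s{i}" for i in range(8)],
                      "months_post_htx": months,
                      "group": ["F"] * 4 + ["NF"] * 4,
                      "H1": 0.1 * months + 1.0})
    r = cs.equal_slopes_test(t, "H1")
    assert r.slope_difference == pytest.approx(0.0, abs=1e-9)


def test_equal_slopes_power_and_size():
    rng = np.random.default_rng(14)
    reject_alt = reject_null = 0
    n_sim = 120
    for _ in range(n_sim):
        reject_alt += cs.equal_slopes_test(trend_table(0.0, 0.3, 0.15, rng),
                                           "H1") < 0.05
        reject_null += cs.equal_slopes_test(trend_table(0.15, 0.15, 0.15, rng),
                                            "H1") < 0.05
    assert reject_alt / n_sim >= 0.90
    assert reject_null / n_sim == pytest.approx(0.05, abs=0.06)


def test_loso_homogeneous_cohort_stable():
    rng = np.random.default_rng(15)
    rows = []
    for s in range(8):
        for v, m in enumerate([12.0, 24, 36, 48]):
            rows.append({"subject_id": f"NF{s}", "months_post_htx": m,
                         "group": "NF",
                         "H1": 1.3 + 0.2 * m / 12 + rng.normal(0, 0.05)})
    t = pd.DataFrame(rows)
    full = cs.regress_time(t, "H1", "NF")
    loso = cs.loso_slopes(t, "H1", "NF")
    assert len(loso.fits) == 8
    assert loso.slope_range < 2 * full.stderr


def test_loso_identifies_outlier_subject():
    rng = np.random.default_rng(16)
    rows = []
    for s in range(6):
        for m in [12.0, 24, 36, 48]:
            bias = 0.8 * m / 12 if s == 3 else 0.0   # one aberrant subject
            rows.append({"subject_id": f"NF{s}", "months_post_htx": m,
                         "group": "NF",
                         "H1": 1.3 + bias + rng.normal(0, 0.03)})
    t = pd.DataFrame(rows)
    full = cs.regress_time(t, "H1", "NF").slope
    loso = cs.loso_slopes(t, "H1", "NF")
    moved = max(loso.fits, key=lambda sf: abs(sf[1].slope - full))
    assert moved[0] == "NF3"


def test_loso_three_two_point_fits():
    t = pd.DataFrame({"subject_id": ["a", "a", "b", "b", "c", "c"],
                      "months_post_htx": [6.0, 18, 6, 18, 6, 18],
                      "group": "F", "H1": [1.0, 1.2, 1.1, 1.4, 0.9, 1.3]})
    loso = cs.loso_slopes(t, "H1", "F")
    assert len(loso.fits) == 3
    for _, fit in loso.fits:
        assert fit.n == 4
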