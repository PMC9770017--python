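import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import permutations, product
from scipy.stats import friedmanchisquare

from quadgait.stats_report import (aggregate, bonferroni_posthoc, build_report,
                                   build_table, exact_friedman_pvalue,
                                   friedman_statistic, friedman_test,
                                   friedman_type1_error, null_matrix,
                                   percent_change, shapiro_wilk)


def _metrics(rows):
    return pd.DataFrame(rows, columns=["animal", "stim_index", "phase",
                                       "position", "limb", "variable", "value"])


def test_aggregate_takes_per_animal_means():
    rows = []
    for i, v in enumerate([1.0, 2.0, 3.0]):
        rows.append(("a1", i, "mid_swing", "stim", "ipsi_hind", "x", v))
        rows.append(("a1", i, "mid_swing", "control", "ipsi_hind", "x", 1.0))
        rows.append(("a1", i, "mid_swing", "post", "ipsi_hind", "x", 1.0))
    m = aggregate(_metrics(rows), "x", "mid_swing", "ipsi_hind")
    assert m.loc["a1", "stim"] == pytest.approx(2.0)


def test_aggregate_drops_animals_without_triads():
    rows = [("a1", 0, "mid_swing", "stim", "", "x", 1.0)]
    m = aggregate(_metrics(rows), "x", "mid_stance")
    assert m.empty


def test_shapiro_domain_and_constant():
    with pytest.raises(ValueError):
        shapiro_wilk(np.array([1.0, 2.0]))
    w, p = shapiro_wilk(np.full(10, 3.14))
    assert np.isnan(w) and np.isnan(p)
    w, p = shapiro_wilk(np.random.default_rng(0).normal(size=50))
    assert 0.9 < w <= 1.0 and p > 0.01


def test_friedman_statistic_perfectly_ordered_7x3_is_14():
    m = np.tile([1.0, 2.0, 3.0], (7, 1))
    assert friedman_statistic(m) == pytest.approx(14.0)
    _, df, p = friedman_test(m)
    assert df == 2 and p < 0.001


def test_friedman_total_ties_gives_zero_statistic():
    m = np.tile([2.5, 2.5, 2.5], (6, 1))
    stat, _, p = friedman_test(m)
    assert stat == 0.0 and p == pytest.approx(1.0)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_friedman_matches_scipy_and_rank_oracle(seed):
    """Statistic equals scipy and a direct rank-sum computation, ties incl."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    x = rng.integers(0, 5, size=(n, 3)).astype(float)
    try:
        expected = friedmanchisquare(*(x[:, j] for j in range(3))).statistic
    except ValueError:
        return  # scipy rejects fully degenerate inputs
    assert friedman_statistic(x) == pytest.approx(expected, abs=1e-10)


def test_exact_friedman_tail_matches_enumeration():
    n = 4
    for stat in (0.5, 2.0, 6.0, 6.5):
        cnt = tot = 0
        for perms in product(list(permutations([1, 2, 3])), repeat=n):
            r = np.sum(perms, axis=0)
            q = (12 / (n * 12)) * np.sum(r ** 2) - 3 * n * 4
            tot += 1
            cnt += q >= stat - 1e-9
        assert exact_friedman_pvalue(stat, n) == pytest.approx(cnt / tot)


def test_friedman_type1_error_calibrated():
    rate = friedman_type1_error(n_reps=800, rng=np.random.default_rng(7))
    assert 0.03 < rate < 0.075  # near-nominal on a modest replicate count


def test_bonferroni_multiplication_and_cap():
    rng = np.random.default_rng(1)
    base = rng.normal(10, 1, size=12)
    m = pd.DataFrame({"control": base, "stim": base + 2.0,
                      "post": base + rng.normal(0, 0.01, 12)})
    p = bonferroni_posthoc(m)
    from scipy.stats import wilcoxon
    raw = wilcoxon(m["stim"] - m["control"]).pvalue
    assert p["stim_vs_control"] == pytest.approx(min(1.0, 2 * raw))
    allsame = pd.DataFrame({"control": base, "stim": base, "post": base})
    assert bonferroni_posthoc(allsame)["stim_vs_control"] == 1.0


def test_posthoc_power_on_planted_effect():
    """+25% stimulated effect with 5% animal noise is detected reliably."""
    rng = np.random.default_rng(11)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        base = np.exp(rng.normal(0, 0.05, 7))
        ctrl = base * (1 + 0.05 * rng.standard_normal(7))
        stim = base * 1.25 * (1 + 0.05 * rng.standard_normal(7))
        post = base * (1 + 0.05 * rng.standard_normal(7))
        m = pd.DataFrame({"control": ctrl, "stim": stim, "post": post})
        hits += bonferroni_posthoc(m)["stim_vs_control"] < 0.05
    assert hits / n_rep >= 0.90


def test_percent_change_formula_and_identity():
    m = pd.DataFrame({"control": [0.5] * 4, "stim": [0.6175] * 4,
                      "post": [0.5] * 4})
    pc = percent_change(m)
    assert pc["stim"][0] == pytest.approx(23.5)
    assert pc["post"][0] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        percent_change(pd.DataFrame({"control": [0.0], "stim": [1.0],
                                     "post": [1.0]}))


def test_null_matrix_columns_exchangeable():
    rng = np.random.default_rng(3)
    m = null_matrix(7, 10, rng)
    assert m.shape == (7, 3)
    assert np.all(m > 0)


def test_build_report_schema_on_empty_and_populated(tmp_path):
    frame = build_report([], tmp_path)
    assert frame.empty
    assert (tmp_path / "stats.json").exists()
    rows = []
    for a in "abcdefg":
        for i in range(3):
            for pos, v in (("control", 1.0), ("stim", 1.2), ("post", 1.0)):
                rows.append((a, i, "mid_swing", pos, "ipsi_hind",
                             "swing_duration", v * (1 + 0.01 * i)))
    t = build_table(_metrics(rows), "swing_duration", "mid_swing", "ipsi_hind")
    assert t is not None and t.friedman is not None
    frame = build_report([t], tmp_path)
    assert {"variable", "pct_stim", "friedman_p"} <= set(frame.columns)
    assert (tmp_path / "effects_mid_swing.tsv").exists()
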