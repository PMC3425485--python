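"""Community statistics: distances, MRPP, evenness, ANOVA/ANCOVA, rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as strat
from scipy.spatial.distance import pdist, squareform

from gudpeck import (
    DegenerateStatisticsError,
    bray_curtis,
    evenness,
    filter_rare,
    gud_ancova,
    gud_anova,
    kruskal_by_yard_type,
    mrpp,
    paired_microhabitat_test,
    row_normalize,
    wilcoxon_by_species,
)
from gudpeck.community import bray_curtis_matrix, _weighted_delta


# ---------------------------------------------------------------------------
# Bray-Curtis

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 0, 2], [0, 3, 0], 1.0),
        ([1, 2, 3], [2, 2, 1], 3 / 11),
    ],
)
def test_bray_curtis_examples(x, y, expected):
    assert bray_curtis(x, y) == pytest.approx(expected)


def test_bray_curtis_both_zero_undefined():
    with pytest.raises(DegenerateStatisticsError):
        bray_curtis([0, 0], [0, 0])


@settings(max_examples=200, deadline=None)
@given(
    x=strat.lists(strat.floats(0, 100), min_size=1, max_size=10),
    y=strat.lists(strat.floats(0, 100), min_size=1, max_size=10),
)
def test_bray_curtis_properties(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if sum(x) + sum(y) == 0:
        return
    d = bray_curtis(x, y)
    assert 0 <= d <= 1
    assert d == bray_curtis(y, x)
    assert (d == 0) == (x == y)


def test_bray_curtis_matrix_matches_scipy(rng):
    M = rng.integers(0, 20, size=(8, 5)).astype(float)
    M[M.sum(axis=1) == 0, 0] = 1
    D = bray_curtis_matrix(M)
    np.testing.assert_allclose(D, squareform(pdist(M, "braycurtis")), atol=1e-12)


# ---------------------------------------------------------------------------
# matrix preparation

def test_row_normalize_and_idempotence():
    M = pd.DataFrame([[2.0, 2.0, 0.0], [1.0, 3.0, 4.0]], columns=list("abc"))
    N = row_normalize(M)
    assert list(N.iloc[0]) == [0.5, 0.5, 0.0]
    assert np.allclose(N.sum(axis=1), 1.0)
    pd.testing.assert_frame_equal(row_normalize(N), N)


def test_row_normalize_drops_zero_rows_with_warning():
    M = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"])
    with pytest.warns(UserWarning, match="b"):
        N = row_normalize(M)
    assert list(N.index) == ["a"]


def test_filter_rare():
    M = pd.DataFrame(
        np.ones((40, 2)), columns=["common", "rare"]
    )
    M.loc[1:, "rare"] = 0.0  # present at 1 of 40 sites = 2.5%
    out = filter_rare(M, 0.05)
    assert list(out.columns) == ["common"]
    pd.testing.assert_frame_equal(filter_rare(M, 0.0), M)
    assert "common" in filter_rare(M, 0.97).columns
    with pytest.raises(DegenerateStatisticsError):
        filter_rare(M.loc[:, ["rare"]], 0.5)


# ---------------------------------------------------------------------------
# MRPP

def exact_mrpp(M, labels):
    """Exhaustive enumeration over all distinct relabelings (oracle)."""
    D = bray_curtis_matrix(M.to_numpy())
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n = len(labels)
    obs = _weighted_delta(D, labels, uniq)
    sizes = {u: int((labels == u).sum()) for u in uniq}
    deltas = []
    group_a = uniq[0]
    for idx in itertools.combinations(range(n), sizes[group_a]):
        lab = np.full(n, uniq[1], dtype=object)
        lab[list(idx)] = group_a
        deltas.append(_weighted_delta(D, lab, uniq))
    deltas = np.array(deltas)
    return obs, deltas.mean(), (deltas <= obs + 1e-12).mean()


@pytest.fixture
def six_site_matrix(rng):
    M = pd.DataFrame(rng.integers(0, 10, size=(6, 4)).astype(float) + 0.5)
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    return M, labels


def test_mrpp_matches_exhaustive_enumeration(six_site_matrix):
    M, labels = six_site_matrix
    obs, exp_delta, exact_p = exact_mrpp(M, labels)
    res = mrpp(M, labels, n_perm=999, seed=1)
    assert res.delta_observed == pytest.approx(obs, abs=1e-12)
    assert res.delta_expected == pytest.approx(exp_delta, rel=0.05)
    mc_err = 3 * math.sqrt(exact_p * (1 - exact_p) / 999) + 1 / 999
    assert abs(res.p_value - exact_p) <= mc_err + 0.01
    assert res.A == pytest.approx(1 - res.delta_observed / res.delta_expected)


def test_mrpp_perfect_separation():
    M = pd.DataFrame(
        [[1.0, 0.0]] * 3 + [[0.0, 1.0]] * 3, columns=["s1", "s2"]
    )
    labels = ["a"] * 3 + ["b"] * 3
    res = mrpp(M, labels, n_perm=999, seed=0)
    assert res.delta_observed == 0.0
    # minimum attainable p: 2 of the C(6,3)=20 relabelings also give
    # delta = 0 (the split itself and its mirror), so p -> 2/20
    assert res.p_value == pytest.approx(2 / 20, abs=0.04)
    assert res.A > 0


def test_mrpp_null_A_near_zero(rng):
    M = pd.DataFrame(rng.integers(0, 10, size=(20, 6)).astype(float) + 0.1)
    labels = rng.permutation(["a"] * 10 + ["b"] * 10)
    res = mrpp(M, labels, n_perm=499, seed=3)
    assert abs(res.A) < 0.2


def test_mrpp_reproducible_and_validates():
    M = pd.DataFrame(np.arange(24, dtype=float).reshape(6, 4) + 1)
    labels = ["a", "a", "a", "b", "b", "b"]
    r1 = mrpp(M, labels, n_perm=99, seed=5)
    r2 = mrpp(M, labels, n_perm=99, seed=5)
    assert r1.to_dict() == r2.to_dict()
    with pytest.raises(DegenerateStatisticsError):
        mrpp(M, ["a"] * 6, n_perm=9, seed=0)
    with pytest.raises(DegenerateStatisticsError, match="fewer than 2"):
        mrpp(M, ["a", "b", "b", "b", "b", "b"], n_perm=9, seed=0)


def test_mrpp_matches_vegan(tmp_path):
    """Independent cross-check against the R vegan implementation on a
    fixed 6-site matrix (vegan enumerates all relabelings at this size)."""
    import shutil
    import subprocess

    assert shutil.which("Rscript"), "Rscript expected on PATH in this environment"
    script = tmp_path / "mrpp.R"
    script.write_text(
        "suppressMessages(library(vegan))\n"
        "M <- matrix(c(3,1,0, 2,2,1, 0,4,2, 5,0,1, 1,1,3, 2,0,4),"
        " nrow=6, byrow=TRUE)\n"
        'grp <- c("a","a","a","b","b","b")\n'
        "set.seed(1)\n"
        'res <- mrpp(M, grp, permutations=999, distance="bray")\n'
        'cat(res$delta, res$E.delta, res$A, res$Pvalue, "\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    r_delta, r_edelta, r_a, r_p = map(float, out.stdout.split())
    M = pd.DataFrame(
        [[3, 1, 0], [2, 2, 1], [0, 4, 2], [5, 0, 1], [1, 1, 3], [2, 0, 4]],
        dtype=float,
    )
    res = mrpp(M, ["a"] * 3 + ["b"] * 3, n_perm=999, seed=0)
    assert res.delta_observed == pytest.approx(r_delta, abs=1e-6)
    assert res.delta_expected == pytest.approx(r_edelta, rel=0.02)
    assert res.A == pytest.approx(r_a, abs=0.02)
    assert res.p_value == pytest.approx(r_p, abs=0.05)


# ---------------------------------------------------------------------------
# evenness

def test_evenness_examples():
    assert evenness([5, 5, 5, 5]) == pytest.approx(1.0)
    p = np.array([0.99, 0.01])
    H = -(p * np.log(p)).sum()
    assert evenness([99, 1]) == pytest.approx(H / math.log(2))
    assert evenness([99, 1]) < 0.1
    assert evenness([3, 1, 7]) == pytest.approx(evenness([7, 3, 1]))
    with pytest.raises(DegenerateStatisticsError):
        evenness([5, 0, 0])


# ---------------------------------------------------------------------------
# ANOVA / ANCOVA

def test_anova_null_and_t_squared_identity(rng):
    a = rng.normal(size=12)
    b = rng.normal(size=15)
    res = gud_anova(np.concatenate([a, b]), ["m"] * 12 + ["x"] * 15)
    t, _ = st.ttest_ind(a, b)
    assert res["F"] == pytest.approx(t**2, rel=1e-10)
    assert res["df"] == (1, 25)
    null = gud_anova([1.0, 2.0, 1.0, 2.0], ["m", "m", "x", "x"])
    assert null["F"] == pytest.approx(0.0, abs=1e-12)


def test_anova_sums_of_squares_oracle():
    """Hand-computed two-group toy set: groups {1,2,3} and {4,5,6}.

    Grand mean 3.5; SSB = 2*3*(1.25)... computed from first principles
    below and frozen against the closed form."""
    vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    groups = ["a", "a", "a", "b", "b", "b"]
    res = gud_anova(vals, groups)
    # SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5; SSW = 2+2 = 4 ; F = 13.5/ (4/4)
    assert res["F"] == pytest.approx(13.5 / 1.0, abs=1e-10)
    assert res["p"] == pytest.approx(1 - st.f.cdf(13.5, 1, 4), abs=1e-12)
    stats = res["group_stats"]
    assert stats.loc["a", "mean"] == 2.0
    assert stats.loc["a", "sem"] == pytest.approx(1 / math.sqrt(3))


def test_anova_degenerate_flagged():
    res = gud_anova([1.0, 1.0, 2.0, 2.0], ["m", "m", "x", "x"])
    assert res["degenerate"]
    assert math.isnan(res["F"])


def test_ancova_recovers_interaction(rng):
    n = 120
    density = rng.uniform(1, 15, size=n)
    yard = np.where(rng.random(n) < 0.5, "mesic", "xeric")
    slope = np.where(yard == "mesic", -0.5, -0.5 + 0.3)  # interaction 0.3
    gud = 15 + slope * density + rng.normal(0, 0.5, size=n)
    res = gud_ancova(pd.DataFrame({"gud": gud, "yard_type": yard, "density": density}))
    inter = res["coefficients"].loc[res["interaction_term"], "coef"]
    assert inter == pytest.approx(0.3, abs=0.1)
    assert res["interaction_p"] < 1e-6


def test_ancova_matches_least_squares_oracle(rng):
    n = 30
    df = pd.DataFrame(
        {
            "gud": rng.normal(10, 2, size=n),
            "yard_type": rng.choice(["mesic", "xeric"], size=n),
            "density": rng.uniform(1, 10, size=n),
        }
    )
    res = gud_ancova(df)
    x_t = (df["yard_type"] == "xeric").astype(float)
    X = np.column_stack(
        [np.ones(n), x_t, df["density"], x_t * df["density"]]
    )
    beta, *_ = np.linalg.lstsq(X, df["gud"], rcond=None)
    got = res["coefficients"]["coef"].to_numpy()
    np.testing.assert_allclose(np.sort(got), np.sort(beta), atol=1e-8)


def test_ancova_single_group_errors():
    df = pd.DataFrame(
        {"gud": [1.0, 2.0, 3.0], "yard_type": ["m"] * 3, "density": [1.0, 2.0, 3.0]}
    )
    with pytest.raises(DegenerateStatisticsError):
        gud_ancova(df)


# ---------------------------------------------------------------------------
# paired and rank tests

def _pairs(diffs):
    return pd.DataFrame(
        {
            "species": [f"S{i}" for i in range(len(diffs))],
            "yard_id": "Y1",
            "bush": [10.0 + d for d in diffs],
            "open": 10.0,
        }
    )


def test_paired_t_closed_form():
    res = paired_microhabitat_test(_pairs([1.0, 2.0, 3.0]))
    assert res["t"] == pytest.approx(2 * math.sqrt(3), rel=1e-12)
    assert res["df"] == 2
    zero = paired_microhabitat_test(_pairs([0.0, 0.0, 0.0]))
    assert zero["t"] == pytest.approx(0.0)
    assert zero["p"] == pytest.approx(1.0)


def test_paired_t_unvisited_imputed_as_g0():
    pairs = _pairs([1.0, 2.0, 3.0])
    pairs.loc[3] = ["S3", "Y1", 5.0, np.nan]  # open tray never visited
    base = paired_microhabitat_test(pairs)
    assert base["n_pairs"] == 3
    full = paired_microhabitat_test(pairs, include_unvisited=True, g0=20.0)
    assert full["n_pairs"] == 4
    # imputed difference = 5 - 20 = -15
    diffs = [1.0, 2.0, 3.0, -15.0]
    t_manual = np.mean(diffs) / (np.std(diffs, ddof=1) / 2)
    assert full["t"] == pytest.approx(t_manual)
    with pytest.raises(DegenerateStatisticsError):
        paired_microhabitat_test(_pairs([1.0]))


def test_wilcoxon_complete_separation_exact_enumeration():
    """Two groups of 4 with no overlap: the rank sum is the extreme of all
    C(8,4) relabelings and the normal-approximation p is close to the
    exact permutation p of 2/70."""
    a, b = [1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0]
    df = pd.DataFrame(
        {
            "species": "S",
            "yard_type": ["m"] * 4 + ["x"] * 4,
            "gud": a + b,
        }
    )
    res = wilcoxon_by_species(df).iloc[0]
    ranks = st.rankdata(a + b)
    obs_sum = ranks[:4].sum()
    all_sums = [
        sum(ranks[i] for i in idx) for idx in itertools.combinations(range(8), 4)
    ]
    assert obs_sum == min(all_sums)
    exact_p = np.mean(
        [s <= obs_sum or s >= sum(ranks) - obs_sum for s in all_sums]
    )
    assert exact_p == pytest.approx(2 / 70)
    assert res["p"] == pytest.approx(exact_p, abs=0.02)
    z_manual = (obs_sum - 4 * 9 / 2) / math.sqrt(4 * 4 * 9 / 12)
    assert res["Z"] == pytest.approx(z_manual, rel=1e-10)


def test_wilcoxon_null_z_near_zero():
    df = pd.DataFrame(
        {
            "species": "S",
            "yard_type": ["m", "x"] * 6,
            "gud": list(range(12)),
        }
    )
    res = wilcoxon_by_species(df).iloc[0]
    assert abs(res["Z"]) < 0.5


def test_kruskal_two_groups_equals_z_squared(rng):
    a = rng.normal(size=9)
    b = rng.normal(1.0, size=8)  # continuous -> untied
    df = pd.DataFrame(
        {
            "yard_type": "m",
            "species": ["A"] * 9 + ["B"] * 8,
            "rate": np.concatenate([a, b]),
        }
    )
    kw = kruskal_by_yard_type(df).iloc[0]
    z, _ = st.ranksums(a, b)
    assert kw["chi_square"] == pytest.approx(z**2, rel=1e-10)


def test_kruskal_degenerate_all_tied():
    df = pd.DataFrame(
        {"yard_type": "m", "species": ["A"] * 3 + ["B"] * 3, "rate": 1.0}
    )
    out = kruskal_by_yard_type(df).iloc[0]
    assert out["degenerate"]
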