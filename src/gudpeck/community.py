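"""Yard-type comparisons: MRPP, evenness, ANOVA/ANCOVA, paired and rank tests.

The community matrix is a sites x species frame of minimum-individual
densities with a yard-type label per site. MRPP asks whether sites of one
yard type are more similar to each other (Bray-Curtis) than a random
relabeling would make them; the parametric and rank tests compare the
giving-up densities and consumption rates themselves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

from .datatypes import DegenerateStatisticsError, MrppResult


# ---------------------------------------------------------------------------
# distances and matrix preparation

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity Σ|x_i − y_i| / Σ(x_i + y_i), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise DegenerateStatisticsError(
            "Bray-Curtis distance is undefined for two all-zero vectors"
        )
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(M: np.ndarray) -> np.ndarray:
    """Full symmetric Bray-Curtis distance matrix between matrix rows."""
    M = np.asarray(M, dtype=float)
    num = np.abs(M[:, None, :] - M[None, :, :]).sum(axis=2)
    den = (M[:, None, :] + M[None, :, :]).sum(axis=2)
    if (den + np.eye(len(M)) == 0).any():
        raise DegenerateStatisticsError("all-zero site rows: distance undefined")
    np.fill_diagonal(den, 1.0)
    D = num / den
    np.fill_diagonal(D, 0.0)
    return D


def row_normalize(M: pd.DataFrame) -> pd.DataFrame:
    """Divide each site row by its total so rows sum to 1.

    All-zero rows cannot be normalized; they are dropped with a warning.
    """
    totals = M.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero site row(s): {list(M.index[zero])}",
            stacklevel=2,
        )
        M = M.loc[~zero]
        totals = totals[~zero]
    return M.div(totals, axis=0)


def filter_rare(
    M: pd.DataFrame, min_prop: float = 0.05, inclusive: bool = False
) -> pd.DataFrame:
    """Drop species occurring at fewer than ``min_prop`` of the sites.

    Occurrence is the fraction of sites with a nonzero cell. The comparison
    is strict ``<`` by default; ``inclusive=True`` drops at ``<=`` as well.
    """
    if not 0 <= min_prop < 1:
        raise ValueError("min_prop must be in [0, 1)")
    occ = (M > 0).sum(axis=0) / len(M)
    keep = occ > min_prop if inclusive else occ >= min_prop
    if min_prop == 0 and not inclusive:
        keep = pd.Series(True, index=M.columns)
    if not keep.any():
        raise DegenerateStatisticsError("rare-species filter removed every species")
    return M.loc[:, keep]


def community_matrix(density: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Yards x species matrix of minimum-individual densities.

    Per-tray species minima are summed over a yard's trays (different trays
    may be visited by different individuals; the yard-level minimum adds
    tray-level lower bounds). Rows are labeled by yard_id; a ``yard_type``
    grouping series is available via :func:`yard_groups`.
    """
    merged = density.merge(trials[["tray_id", "yard_id"]], on="tray_id")
    mat = (
        merged.pivot_table(
            index="yard_id", columns="species", values="min_individuals",
            aggfunc="sum", fill_value=0,
        )
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    mat.columns.name = None
    mat.index.name = "yard_id"
    return mat


def yard_groups(trials: pd.DataFrame) -> pd.Series:
    """yard_id -> yard_type mapping taken from the trial table."""
    return trials.drop_duplicates("yard_id").set_index("yard_id")["yard_type"]


# ---------------------------------------------------------------------------
# MRPP

def _weighted_delta(D: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """delta = Σ_g (n_g / N) * mean within-group pairwise distance."""
    N = len(labels)
    delta = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        n = len(idx)
        sub = D[np.ix_(idx, idx)]
        delta += (n / N) * (sub.sum() / (n * (n - 1)))
    return delta


def mrpp(
    M: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MrppResult:
    """Multi-response permutation procedure with Bray-Curtis distance.

    ``delta_observed`` is the group-size-weighted mean within-group
    distance; ``delta_expected`` its mean over ``n_perm`` random
    relabelings preserving group sizes. The p-value uses the +1/+1
    convention (the observed labeling counts as one permutation), so it is
    at least ``1/(n_perm+1)``. ``A = 1 - delta_observed/delta_expected``.
    """
    labels = np.asarray(pd.Series(groups).loc[M.index] if isinstance(groups, pd.Series)
                        else groups)
    if len(labels) != len(M):
        raise ValueError("group labels must align with matrix rows")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DegenerateStatisticsError("MRPP needs at least two groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise DegenerateStatisticsError(
            f"group(s) {small} have fewer than 2 sites; within-group distance undefined"
        )
    D = bray_curtis_matrix(M.to_numpy())
    delta_obs = _weighted_delta(D, labels, uniq)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_deltas[i] = _weighted_delta(D, rng.permutation(labels), uniq)
    delta_exp = float(perm_deltas.mean())
    p = (int((perm_deltas <= delta_obs + 1e-12).sum()) + 1) / (n_perm + 1)
    A = 1.0 - delta_obs / delta_exp if delta_exp > 0 else float("nan")
    return MrppResult(
        delta_observed=float(delta_obs),
        delta_expected=delta_exp,
        A=float(A),
        p_value=float(p),
        n_permutations=int(n_perm),
    )


# ---------------------------------------------------------------------------
# diversity

def evenness(abundances) -> float:
    """Pielou's evenness J = H' / ln(S) over positive-count species.

    J = 1 when all species are equally abundant; small values indicate a
    community dominated by one species.
    """
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if a.size < 2:
        raise DegenerateStatisticsError(
            "evenness undefined with fewer than 2 species present"
        )
    p = a / a.sum()
    H = -(p * np.log(p)).sum()
    return float(H / np.log(a.size))


# ---------------------------------------------------------------------------
# parametric and rank tests on GUDs

def gud_anova(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray) -> dict:
    """One-way ANOVA of GUD on yard type, with per-group means and SEs."""
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    df = df.dropna()
    names = sorted(df["group"].unique())
    if len(names) < 2 or (df.groupby("group").size() < 2).any():
        raise DegenerateStatisticsError("ANOVA needs >= 2 groups with >= 2 observations")
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in names]
    degenerate = all(np.var(s) == 0 for s in samples)
    if degenerate:
        F, p = float("nan"), float("nan")
    else:
        F, p = st.f_oneway(*samples)
    stats = df.groupby("group")["value"].agg(["mean", "sem", "count"])
    k, N = len(names), len(df)
    return {
        "F": float(F),
        "df": (k - 1, N - k),
        "p": float(p),
        "group_stats": stats,
        "degenerate": degenerate,
    }


def gud_ancova(data: pd.DataFrame) -> dict:
    """ANCOVA: GUD on yard type, density, and their interaction.

    ``data`` needs columns ``gud``, ``yard_type``, ``density``. Returns the
    OLS coefficient table and the interaction term's t and two-sided p.
    """
    data = data.dropna(subset=["gud", "yard_type", "density"])
    if data["yard_type"].nunique() < 2:
        raise DegenerateStatisticsError("ANCOVA needs at least two yard types")
    if data["density"].nunique() < 2:
        raise DegenerateStatisticsError("density covariate is constant; collinear design")
    res = smf.ols("gud ~ C(yard_type) * density", data=data).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise DegenerateStatisticsError("collinear ANCOVA design matrix")
    table = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
    )
    inter = [name for name in res.params.index if ":" in name][0]
    return {
        "coefficients": table,
        "interaction_term": inter,
        "interaction_t": float(res.tvalues[inter]),
        "interaction_p": float(res.pvalues[inter]),
        "r_squared": float(res.rsquared),
        "df_resid": int(res.df_resid),
    }


def paired_microhabitat_test(
    pairs: pd.DataFrame, include_unvisited: bool = False, g0: float = 20.0
) -> dict:
    """Paired t-test of bush vs open GUDs per species-yard pair.

    ``pairs`` has columns ``species``, ``yard_id``, ``bush``, ``open``
    (grams; NaN when that tray was not visited by the species). By default
    only complete pairs enter; with ``include_unvisited`` a missing side is
    imputed as the full provisioned mass ``g0`` — no pecks means no
    depletion.
    """
    df = pairs.copy()
    if include_unvisited:
        df[["bush", "open"]] = df[["bush", "open"]].fillna(g0)
        df = df.dropna(subset=["bush", "open"], how="all")
    df = df.dropna(subset=["bush", "open"])
    n = len(df)
    if n < 2:
        raise DegenerateStatisticsError(f"need >= 2 complete pairs, have {n}")
    diffs = (df["bush"] - df["open"]).to_numpy()
    if np.std(diffs, ddof=1) == 0:
        # identical differences: t is 0/0 for a zero mean (no effect, p = 1)
        # and unbounded otherwise
        t = 0.0 if diffs.mean() == 0 else float(np.sign(diffs.mean()) * np.inf)
        p = 1.0 if diffs.mean() == 0 else 0.0
    else:
        t, p = st.ttest_rel(df["bush"], df["open"])
    return {"t": float(t), "df": n - 1, "p": float(p), "n_pairs": n}


def wilcoxon_by_species(data: pd.DataFrame, species_list=None) -> pd.DataFrame:
    """Two-sample Wilcoxon rank-sum (normal approximation) per species.

    ``data`` has columns ``species``, ``yard_type``, ``gud``. Species with
    observations in fewer than two yard types are skipped; the statistic is
    Z with average-rank ties, two-sided p.
    """
    rows = []
    species_iter = species_list or sorted(data["species"].unique())
    for sp in species_iter:
        sub = data[data["species"] == sp]
        types = sorted(sub["yard_type"].unique())
        if len(types) < 2:
            continue
        a = sub.loc[sub["yard_type"] == types[0], "gud"].dropna().to_numpy()
        b = sub.loc[sub["yard_type"] == types[1], "gud"].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((sp, len(a), len(b), float("nan"), float("nan"), True))
            continue
        z, p = st.ranksums(a, b)
        rows.append((sp, len(a), len(b), float(z), float(p), False))
    return pd.DataFrame(
        rows, columns=["species", "n_a", "n_b", "Z", "p", "degenerate"]
    )


def kruskal_by_yard_type(data: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis test of rates among species, one test per yard type.

    ``data`` has columns ``yard_type``, ``species``, ``rate``. Returns the
    chi-square statistic (tie-corrected) and p per yard type.
    """
    rows = []
    for yt in sorted(data["yard_type"].unique()):
        sub = data[data["yard_type"] == yt].dropna(subset=["rate"])
        samples = [
            grp["rate"].to_numpy()
            for _, grp in sub.groupby("species")
            if len(grp) >= 2
        ]
        if len(samples) < 2:
            continue
        if np.ptp(np.concatenate(samples)) == 0:
            rows.append((yt, len(samples), float("nan"), float("nan"), True))
            continue
        h, p = st.kruskal(*samples)
        rows.append((yt, len(samples), float(h), float(p), False))
    return pd.DataFrame(
        rows, columns=["yard_type", "n_groups", "chi_square", "p", "degenerate"]
    )
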