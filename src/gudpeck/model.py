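"""The GUD-Peck model: back-estimating every visitor's giving-up density.

A sifted tray yields one measured giving-up density (GUD) — the seed mass
left when the *final* forager quit. The model leverages the tray-wide peck
log to extend that single measurement to every visiting species: final-
forager observations train an ordinary-least-squares relationship

    GUD = beta0 + beta_pecks * total_pecks + beta_density * density
          + species_offset

(density = the tray's total minimum individuals), and each earlier
visitor's GUD is then predicted at the cumulative tray peck count standing
when that species quit. The same fit, evaluated at a species' own peck
count, converts pecks to grams consumed and hence to a consumption rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import RunConfig
from .datatypes import DegenerateStatisticsError, GudPeckFit, UnknownSpeciesError

ESTIMATES_COLUMNS = [
    "tray_id",
    "species",
    "cum_pecks_at_quit",
    "gud_estimate",
    "omitted",
    "omission_reason",
    "is_final_forager",
    "unvisited",
]
RATES_COLUMNS = [
    "tray_id",
    "species",
    "own_total_pecks",
    "grams_consumed",
    "foraging_time_s",
    "rate_g_per_h",
    "omitted",
    "omission_reason",
]


def _design_matrix(
    total_pecks: np.ndarray, density: np.ndarray, species: list[str], levels: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + pecks + density + treatment-coded species dummies."""
    n = len(total_pecks)
    cols = [np.ones(n), np.asarray(total_pecks, float), np.asarray(density, float)]
    names = ["intercept", "total_pecks", "density"]
    for lvl in levels[1:]:
        cols.append(np.array([1.0 if s == lvl else 0.0 for s in species]))
        names.append(f"species[{lvl}]")
    return np.column_stack(cols), names


def fit_gud_peck_model(training: pd.DataFrame) -> GudPeckFit:
    """Fit the GUD-Peck OLS model on final-forager observations.

    Parameters
    ----------
    training : pandas.DataFrame
        One row per visited tray with a measured GUD, columns
        ``measured_final_gud`` (g), ``total_pecks``, ``final_species``,
        ``tray_density`` (total minimum individuals).

    Returns
    -------
    GudPeckFit
        Coefficients with the alphabetically first final-forager species as
        the reference level, training r² and the observed-vs-predicted
        Pearson correlation.

    Raises
    ------
    DegenerateStatisticsError
        Fewer observations than parameters, or a rank-deficient design
        (the offending columns are named).
    """
    required = {"measured_final_gud", "total_pecks", "final_species", "tray_density"}
    missing = required - set(training.columns)
    if missing:
        raise ValueError(f"training frame missing columns {sorted(missing)}")
    training = training.dropna(subset=["measured_final_gud"])
    levels = sorted(training["final_species"].unique())
    y = training["measured_final_gud"].to_numpy(float)
    X, names = _design_matrix(
        training["total_pecks"].to_numpy(),
        training["tray_density"].to_numpy(),
        list(training["final_species"]),
        levels,
    )
    n, p = X.shape
    if n < p:
        raise DegenerateStatisticsError(
            f"cannot fit {p} parameters from {n} training trays"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name columns whose removal restores full column rank
        collinear = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                collinear.append(names[j])
        raise DegenerateStatisticsError(
            f"rank-deficient design matrix; collinear column(s): {collinear}"
        )

    res = sm.OLS(y, X).fit()
    predicted = res.fittedvalues
    if np.std(predicted) == 0 or np.std(y) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(y, predicted)[0, 1])

    effects = {levels[0]: 0.0}
    for i, lvl in enumerate(levels[1:]):
        effects[lvl] = float(res.params[3 + i])
    return GudPeckFit(
        beta0=float(res.params[0]),
        beta_pecks=float(res.params[1]),
        beta_density=float(res.params[2]),
        species_effects=effects,
        reference_species=levels[0],
        r_squared=float(res.rsquared),
        obs_pred_pearson=pearson,
        n_train=int(n),
        residual_sd=float(np.sqrt(res.mse_resid)) if n > p else float("nan"),
        beta_pecks_se=float(res.bse[1]),
    )


def predict_gud(fit: GudPeckFit, cum_pecks: float, species: str, density: float) -> float:
    """Linear-predictor GUD (grams) at a cumulative peck count.

    Not clamped: negative predictions are reported and handled downstream
    by omission rules.
    """
    if species not in fit.species_effects:
        raise UnknownSpeciesError(
            f"species {species!r} was never a final forager in training; "
            "no offset is available"
        )
    return (
        fit.beta0
        + fit.beta_pecks * cum_pecks
        + fit.beta_density * density
        + fit.species_effects[species]
    )


def estimate_species_guds(
    fit: GudPeckFit,
    quit_points: pd.DataFrame,
    densities: pd.Series,
    trials: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Estimate a GUD for every species-tray visit (``ESTIMATES_COLUMNS``).

    The final forager's estimate is evaluated at the tray's total peck
    count (its cumulative count at quitting). Visits with fewer own pecks
    than ``config.peck_min_threshold`` are flagged ``few_pecks``; species
    never seen as final foragers are flagged ``species_not_in_model``.
    Trays without a single peck keep their full provisioned seed mass: the
    estimate is G0 with ``unvisited=True``.
    """
    config = config or RunConfig()
    rows = []
    for rec in quit_points.itertuples(index=False):
        density = float(densities.get(rec.tray_id, 0))
        omitted, reason = False, "none"
        if rec.species not in fit.species_effects:
            gud = float("nan")
            omitted, reason = True, "species_not_in_model"
        else:
            gud = predict_gud(fit, rec.cum_pecks_at_quit, rec.species, density)
            if rec.own_total_pecks < config.peck_min_threshold:
                omitted, reason = True, "few_pecks"
        rows.append(
            (
                rec.tray_id,
                rec.species,
                int(rec.cum_pecks_at_quit),
                gud,
                omitted,
                reason,
                bool(rec.is_final_forager),
                False,
            )
        )
    visited = set(quit_points["tray_id"])
    for trial in trials.itertuples(index=False):
        if trial.tray_id not in visited:
            rows.append(
                (
                    trial.tray_id,
                    "",
                    0,
                    float(trial.initial_seed_mass_g),
                    False,
                    "none",
                    False,
                    True,
                )
            )
    out = pd.DataFrame(rows, columns=ESTIMATES_COLUMNS)
    return out.sort_values(["tray_id", "species"], kind="stable").reset_index(drop=True)


def consumption_rates(
    fit: GudPeckFit,
    quit_points: pd.DataFrame,
    foraging_times: pd.DataFrame,
    densities: pd.Series,
    trials: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Grams consumed and consumption rate per species-tray visit.

    Consumption is ``G0 - predict_gud(fit, pecks, species, density)`` with
    ``pecks`` the species' own total by default (``config.consumption_pecks
    = "cumulative"`` switches to tray-cumulative pecks at quitting). Rows
    with fewer own pecks than the threshold or non-positive estimated
    consumption are flagged omitted; a zero foraging time with pecks
    present leaves the rate undefined (NaN, flagged ``zero_time``).
    """
    config = config or RunConfig()
    g0 = trials.set_index("tray_id")["initial_seed_mass_g"]
    ft = foraging_times.set_index(["tray_id", "species"])["foraging_time_s"]
    rows = []
    for rec in quit_points.itertuples(index=False):
        if rec.own_total_pecks == 0:
            continue
        density = float(densities.get(rec.tray_id, 0))
        pecks = (
            rec.own_total_pecks
            if config.consumption_pecks == "own"
            else rec.cum_pecks_at_quit
        )
        omitted, reason = False, "none"
        if rec.species not in fit.species_effects:
            grams = float("nan")
            omitted, reason = True, "species_not_in_model"
        else:
            grams = float(g0[rec.tray_id]) - predict_gud(fit, pecks, rec.species, density)
            if rec.own_total_pecks < config.peck_min_threshold:
                omitted, reason = True, "few_pecks"
            elif grams <= 0:
                omitted, reason = True, "negative_consumption"
        time_s = float(ft.get((rec.tray_id, rec.species), 0.0))
        if time_s > 0:
            rate = grams / (time_s / 3600.0)
        else:
            rate = float("nan")
            if not omitted:
                omitted, reason = True, "zero_time"
        rows.append(
            (rec.tray_id, rec.species, int(rec.own_total_pecks), grams, time_s, rate,
             omitted, reason)
        )
    out = pd.DataFrame(rows, columns=RATES_COLUMNS)
    return out.sort_values(["tray_id", "species"], kind="stable").reset_index(drop=True)


def training_table(
    trials: pd.DataFrame, quit_points: pd.DataFrame, densities: pd.Series
) -> pd.DataFrame:
    """Assemble the final-forager training frame from pipeline stage outputs.

    One row per visited tray with a measured GUD: the final forager's
    species, the tray's total peck count, and its total minimum
    individuals.
    """
    finals = quit_points[quit_points["is_final_forager"]]
    tray_totals = quit_points.groupby("tray_id")["own_total_pecks"].sum()
    merged = finals.merge(
        trials[["tray_id", "final_gud_g"]], on="tray_id", how="inner"
    )
    out = pd.DataFrame(
        {
            "tray_id": merged["tray_id"],
            "measured_final_gud": merged["final_gud_g"],
            "total_pecks": merged["tray_id"].map(tray_totals).astype(int),
            "final_species": merged["species"],
            "tray_density": merged["tray_id"].map(densities).fillna(0).astype(float),
        }
    )
    return out.dropna(subset=["measured_final_gud"]).reset_index(drop=True)
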