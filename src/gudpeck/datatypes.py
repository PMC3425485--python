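"""Core tabular schemas and containers shared by all pipeline stages.

The package is pandas-centric: event logs, trial metadata and stage outputs
are plain :class:`pandas.DataFrame` objects with fixed column schemas, and
the small record classes here exist to document those schemas and to carry
fitted-model state between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Column schema of the peck-event log (one row per scored peck).
PECKS_COLUMNS = ["tray_id", "species", "class_tag", "t_seconds"]

#: Column schema of the visit-interval log (one row per on-tray presence).
INTERVALS_COLUMNS = ["tray_id", "species", "class_tag", "t_on", "t_off"]

#: Column schema of the tray-trial metadata table.
TRIALS_COLUMNS = [
    "tray_id",
    "yard_id",
    "yard_type",
    "microhabitat",
    "initial_seed_mass_g",
    "duration_s",
    "final_gud_g",
]

YARD_TYPES = ("mesic", "xeric")
MICROHABITATS = ("bush", "open")


class GudpeckError(Exception):
    """Base class for all package errors."""


class FormatError(GudpeckError):
    """A CSV input is structurally malformed (missing columns, bad values)."""


class ReferentialError(GudpeckError):
    """An event references a tray that does not exist or lies outside its trial."""


class UnvisitedTrayError(GudpeckError):
    """An operation requiring at least one peck was applied to an empty tray."""


class UnknownSpeciesError(GudpeckError):
    """A prediction was requested for a species absent from the fitted model."""


class DegenerateStatisticsError(GudpeckError):
    """A statistical routine received input on which its result is undefined."""


@dataclass
class StudyDataset:
    """One complete study: trial metadata plus the event logs for every tray.

    Attributes
    ----------
    trials : pandas.DataFrame
        One row per 24 h tray deployment (``TRIALS_COLUMNS``). ``final_gud_g``
        may be NaN for trials used only for prediction.
    pecks : pandas.DataFrame
        Every scored peck (``PECKS_COLUMNS``), any row order.
    intervals : pandas.DataFrame
        Every on-tray visit interval (``INTERVALS_COLUMNS``).
    """

    trials: pd.DataFrame
    pecks: pd.DataFrame
    intervals: pd.DataFrame

    def tray_ids(self) -> list[str]:
        return list(self.trials["tray_id"])

    def equals(self, other: "StudyDataset") -> bool:
        return (
            self.trials.reset_index(drop=True).equals(other.trials.reset_index(drop=True))
            and self.pecks.reset_index(drop=True).equals(other.pecks.reset_index(drop=True))
            and self.intervals.reset_index(drop=True).equals(
                other.intervals.reset_index(drop=True)
            )
        )


@dataclass
class GudPeckFit:
    """Fitted coefficients and diagnostics of the GUD-Peck linear model.

    The model is an additive ordinary-least-squares fit on final-forager
    observations::

        GUD = beta0 + beta_pecks * total_pecks + beta_density * density
              + species_effect[species]

    with categorical species offsets relative to ``reference_species``
    (alphabetically first; its offset is 0 by construction).
    """

    beta0: float
    beta_pecks: float
    beta_density: float
    species_effects: dict[str, float]
    reference_species: str
    r_squared: float
    obs_pred_pearson: float
    n_train: int
    residual_sd: float = float("nan")
    beta_pecks_se: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta_pecks": self.beta_pecks,
            "beta_density": self.beta_density,
            "species_effects": dict(self.species_effects),
            "reference_species": self.reference_species,
            "r_squared": self.r_squared,
            "obs_pred_pearson": self.obs_pred_pearson,
            "n_train": self.n_train,
            "residual_sd": self.residual_sd,
            "beta_pecks_se": self.beta_pecks_se,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GudPeckFit":
        return cls(**d)


@dataclass
class MrppResult:
    """Outcome of a multi-response permutation procedure run.

    ``A = 1 - delta_observed / delta_expected`` is the chance-corrected
    within-group agreement; A > 0 means sites are more similar within
    groups than expected by chance.
    """

    delta_observed: float
    delta_expected: float
    A: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "delta_observed": self.delta_observed,
            "delta_expected": self.delta_expected,
            "A": self.A,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


@dataclass
class GroundTruth:
    """Simulator bookkeeping for recovery tests.

    All masses are grams; times are seconds from trial start. The mass
    ledger is exact before weighing noise:
    ``g0 - true_final_mass[tray] == sum of true_grams_consumed over species``.
    """

    true_final_mass: dict[str, float] = field(default_factory=dict)
    true_grams_consumed: dict[tuple[str, str], float] = field(default_factory=dict)
    true_quit_time: dict[tuple[str, str], float] = field(default_factory=dict)
    true_gud_at_quit: dict[tuple[str, str], float] = field(default_factory=dict)
    theoretical_gud: dict[str, float] = field(default_factory=dict)
    true_individuals: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "true_final_mass": self.true_final_mass,
            "true_grams_consumed": {
                f"{k[0]}|{k[1]}": v for k, v in self.true_grams_consumed.items()
            },
            "true_quit_time": {f"{k[0]}|{k[1]}": v for k, v in self.true_quit_time.items()},
            "true_gud_at_quit": {
                f"{k[0]}|{k[1]}": v for k, v in self.true_gud_at_quit.items()
            },
            "theoretical_gud": self.theoretical_gud,
            "true_individuals": {
                f"{k[0]}|{k[1]}|{k[2]}": v for k, v in self.true_individuals.items()
            },
        }
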