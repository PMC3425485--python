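"""Mechanistic seed-tray foraging simulator with known ground truth.

The simulator emulates the study design the analysis pipeline is built
for: 20 residential yards (10 mesic, 10 xeric), two 20 g seed trays per
yard (one by a bush, one in the open), filmed for 24 h. Birds arrive as
Poisson processes, peck at a species-typical rate, and — following
optimal-foraging logic — quit the patch permanently once the expected
yield of the next peck falls below their quitting threshold ``q_s``. In
``diminishing_returns`` mode the expected yield per peck is
``y_max * G / G0`` (harder to find seed in a depleted tray), so a species'
theoretical giving-up density is sharp::

    GUD*_s = G0 * q_s / y_max

In ``constant_yield`` mode every peck removes exactly ``y_max`` grams
until the tray is empty, making the GUD-pecks relationship exactly linear
— the mode used for slope-recovery checks.

Every gram is accounted for: the ledger ``G0 - final mass = Σ consumed``
holds exactly before weighing noise is added to the measured GUD.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    GroundTruth,
    INTERVALS_COLUMNS,
    PECKS_COLUMNS,
    StudyDataset,
    TRIALS_COLUMNS,
)


@dataclass
class SpeciesProfile:
    """Behavioral parameters of one simulated species.

    Parameters
    ----------
    species : str
        Four-letter species code (ABTO, HOSP, ...).
    quitting_threshold : float
        Minimum acceptable expected yield per peck, grams. Determines the
        theoretical giving-up density ``GUD* = G0 * q / y_max``.
    peck_rate : float
        Pecks per minute while actively foraging.
    arrival_rates : dict
        Group arrivals per hour by yard type, e.g. ``{"mesic": 0.2,
        "xeric": 0.06}``. Yard types absent from the dict get rate 0.
    group_size_probs : tuple
        Probability of group sizes 1, 2, ... (must sum to 1).
    class_tags : dict
        Demographic class tags with probabilities (e.g. sex for dimorphic
        species); ``{"unknown": 1.0}`` for monomorphic species.
    bout_pause_prob : float
        Per-minute probability that a foraging individual pauses long
        enough (>= the bout gap) to split its pecks into separate bouts.
    mean_visit_pecks : float
        Mean pecks per visit before the bird leaves of its own accord
        (geometric departure), independent of the quitting threshold.
    """

    species: str
    quitting_threshold: float
    peck_rate: float = 40.0
    arrival_rates: dict = field(default_factory=dict)
    group_size_probs: tuple = (0.6, 0.3, 0.1)
    class_tags: dict = field(default_factory=lambda: {"unknown": 1.0})
    bout_pause_prob: float = 0.1
    mean_visit_pecks: float = 150.0


@dataclass
class SimConfig:
    """Study-level simulation parameters (defaults are the study design)."""

    n_yards_per_type: int = 10
    trays_per_yard: int = 2
    g0: float = 20.0
    duration_s: float = 86400.0
    y_max: float = 0.01
    depletion: str = "diminishing_returns"
    gud_weighing_sd: float = 0.05
    xeric_q_scale: float = 1.25
    yard_rate_sigma: float = 0.4
    bout_gap_s: float = 60.0

    def __post_init__(self) -> None:
        if self.y_max <= 0:
            raise FormatError(f"y_max must be positive, got {self.y_max}")
        if self.g0 <= 0:
            raise FormatError("g0 must be positive")
        if self.depletion not in ("constant_yield", "diminishing_returns"):
            raise FormatError(f"unknown depletion mode {self.depletion!r}")


def default_profiles() -> list[SpeciesProfile]:
    """Species pool emulating a Sonoran-desert-city backyard community.

    Quitting thresholds are ordered so synanthropic granivores (house
    sparrow, house finch) tolerate leaner trays than natives (towhee,
    thrasher, quail); arrival mixes make the synanthropes commoner in
    mesic (turf) yards and the natives commoner in xeric (gravel) yards.
    With ``y_max = 0.01`` g/peck the theoretical GUDs span 3–10 g.
    """
    sexed = {"male": 0.5, "female": 0.5}
    return [
        SpeciesProfile("HOSP", 0.0015, 50.0, {"mesic": 0.20, "xeric": 0.05},
                       (0.5, 0.3, 0.2), sexed),
        SpeciesProfile("HOFI", 0.0020, 45.0, {"mesic": 0.10, "xeric": 0.06},
                       (0.6, 0.3, 0.1), sexed),
        SpeciesProfile("INDO", 0.0025, 35.0, {"mesic": 0.08, "xeric": 0.02}),
        SpeciesProfile("ABTO", 0.0030, 40.0, {"mesic": 0.05, "xeric": 0.10}),
        SpeciesProfile("CBTH", 0.0035, 55.0, {"mesic": 0.06, "xeric": 0.10},
                       mean_visit_pecks=250.0),
        SpeciesProfile("MODO", 0.0040, 30.0, {"mesic": 0.05, "xeric": 0.04}),
        SpeciesProfile("GAQU", 0.0045, 30.0, {"mesic": 0.0, "xeric": 0.05},
                       (0.3, 0.4, 0.3)),
        SpeciesProfile("WCSP", 0.0050, 35.0, {"mesic": 0.01, "xeric": 0.04}),
    ]


def recovery_profiles(arrival_rate: float = 0.3) -> list[SpeciesProfile]:
    """Benchmark community for parameter-recovery studies.

    Four species with quitting thresholds spaced 3 g apart in theoretical
    GUD (3, 6, 9, 12 g at ``y_max = 0.01``) and equal arrival rates in both
    yard types. Rank recovery is only a meaningful benchmark when the true
    quitting thresholds are separated by more than the model's residual
    noise and trays are visited heavily enough for every threshold to bind;
    the default community (closely spaced thresholds, sparse visitation)
    emulates a field community instead and does not guarantee either.
    """
    rates = {"mesic": arrival_rate, "xeric": arrival_rate}
    return [
        SpeciesProfile("SPA", 0.0015, 45.0, dict(rates)),
        SpeciesProfile("SPB", 0.0030, 45.0, dict(rates)),
        SpeciesProfile("SPC", 0.0045, 45.0, dict(rates)),
        SpeciesProfile("SPD", 0.0060, 45.0, dict(rates)),
    ]


def _expected_yield(G: float, cfg: SimConfig) -> float:
    if G <= 0:
        return 0.0
    if cfg.depletion == "constant_yield":
        return cfg.y_max
    return cfg.y_max * G / cfg.g0


def simulate_tray(
    profiles: list[SpeciesProfile],
    cfg: SimConfig,
    rng: np.random.Generator,
    tray_id: str = "T1",
    yard_type: str = "mesic",
    q_scale: float = 1.0,
    rate_scale: float = 1.0,
    bout_pauses: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, float, GroundTruth]:
    """Simulate one 24 h tray deployment.

    Returns the peck log, the visit-interval log, the measured final GUD
    (true final mass plus truncated-normal weighing error, recorded to
    0.01 g like a lab balance), and exact ground truth.

    ``q_scale`` multiplies every quitting threshold (used to emulate
    richer alternative resources in xeric yards); ``rate_scale``
    multiplies arrival rates (yard-level attractiveness); ``bout_pauses=
    False`` disables within-visit pauses so each visit yields one bout.
    """
    active_rates = [
        p.arrival_rates.get(yard_type, 0.0) * rate_scale for p in profiles
    ]
    if not any(r > 0 for r in active_rates):
        raise FormatError("at least one species needs a positive arrival rate")
    if all(
        p.quitting_threshold * q_scale >= cfg.y_max
        for p, r in zip(profiles, active_rates)
        if r > 0
    ):
        raise FormatError(
            "every arriving species quits before the first peck "
            "(q >= y_max for all); no foraging is possible"
        )

    # Pre-draw arrival processes per species: Poisson counts, uniform times.
    heap: list = []
    counter = itertools.count()  # tie-break so heap never compares dicts
    for prof, rate in zip(profiles, active_rates):
        if rate <= 0:
            continue
        n_arrivals = rng.poisson(rate * cfg.duration_s / 3600.0)
        times = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_arrivals))
        for t in times:
            size_probs = np.asarray(prof.group_size_probs)
            size = int(rng.choice(np.arange(1, len(size_probs) + 1), p=size_probs))
            for _ in range(size):
                tags = list(prof.class_tags)
                probs = np.asarray([prof.class_tags[k] for k in tags])
                tag = str(rng.choice(tags, p=probs / probs.sum()))
                heapq.heappush(
                    heap,
                    (float(t), next(counter), "arrive",
                     {"prof": prof, "tag": tag}),
                )

    G = cfg.g0
    pecks: list[tuple] = []       # (t, species, class_tag, harvest)
    intervals: list[tuple] = []   # (species, class_tag, t_on, t_off)
    individuals: dict[tuple[str, str], int] = {}  # pecking individuals per class

    while heap:
        t, _, kind, st = heapq.heappop(heap)
        prof: SpeciesProfile = st["prof"]
        q = prof.quitting_threshold * q_scale
        if kind == "arrive":
            if _expected_yield(G, cfg) < q:
                continue  # assesses the tray and moves on without pecking
            st = dict(st, t_on=t, last_peck=None, n_pecks=0)
            first = t + rng.uniform(0.0, 5.0)  # starts pecking within 5 s
            if first <= cfg.duration_s:
                heapq.heappush(heap, (first, next(counter), "peck", st))
            continue

        # peck event: quit permanently if the patch no longer pays
        if _expected_yield(G, cfg) < q:
            _close_visit(st, intervals, rng, cfg.duration_s)
            continue
        harvest = min(_expected_yield(G, cfg), G)
        G -= harvest
        st["last_peck"] = t
        st["n_pecks"] += 1
        pecks.append((t, prof.species, st["tag"], harvest))

        # voluntary departure: geometric visit length in pecks
        if rng.random() < 1.0 / prof.mean_visit_pecks:
            _close_visit(st, intervals, rng, cfg.duration_s)
            continue
        dt = rng.exponential(60.0 / prof.peck_rate)
        if bout_pauses and rng.random() < prof.bout_pause_prob / prof.peck_rate:
            dt += cfg.bout_gap_s + rng.exponential(60.0)
        nxt = t + dt
        if nxt > cfg.duration_s:
            _close_visit(st, intervals, rng, cfg.duration_s)
        else:
            heapq.heappush(heap, (nxt, next(counter), "peck", st))

    truth = GroundTruth()
    truth.true_final_mass[tray_id] = G
    for prof in profiles:
        truth.theoretical_gud[prof.species] = (
            cfg.g0 * prof.quitting_threshold * q_scale / cfg.y_max
        )
    pecks.sort(key=lambda r: r[0])
    running = cfg.g0
    for t, species, tag, harvest in pecks:
        running -= harvest
        key = (tray_id, species)
        truth.true_grams_consumed[key] = truth.true_grams_consumed.get(key, 0.0) + harvest
        truth.true_quit_time[key] = t
        truth.true_gud_at_quit[key] = running
    for species, tag, t_on, t_off in intervals:
        key = (tray_id, species, tag)
        truth.true_individuals[key] = truth.true_individuals.get(key, 0) + 1

    measured = G + rng.normal(0.0, cfg.gud_weighing_sd) if cfg.gud_weighing_sd > 0 else G
    measured = float(np.clip(measured, 0.0, cfg.g0))
    measured = round(measured, 2)  # balance reads to the nearest 0.01 g

    pecks_df = pd.DataFrame(
        [(tray_id, sp, tag, t) for t, sp, tag, _ in pecks], columns=PECKS_COLUMNS
    )
    intervals_df = pd.DataFrame(
        [(tray_id, sp, tag, a, b) for sp, tag, a, b in intervals],
        columns=INTERVALS_COLUMNS,
    )
    return pecks_df, intervals_df, measured, truth


def _close_visit(st: dict, intervals: list, rng: np.random.Generator, duration: float):
    """Record the visit interval; birds linger 1-10 s after the last peck."""
    if st["n_pecks"] == 0:
        return
    t_off = min(st["last_peck"] + rng.uniform(1.0, 10.0), duration)
    intervals.append((st["prof"].species, st["tag"], st["t_on"], t_off))


def generate_study(
    profiles: list[SpeciesProfile] | None = None,
    cfg: SimConfig | None = None,
    seed: int | None = None,
    bout_pauses: bool = True,
) -> tuple[StudyDataset, GroundTruth]:
    """Simulate the full two-yard-type study.

    Yards are named M01.. / X01.. with one bush and one open tray each
    (microhabitat is behaviorally neutral: the field data showed no
    perceived-risk difference, so none is generated). Yard-to-yard
    variation in attractiveness enters as a lognormal multiplier on
    arrival rates; xeric yards scale every quitting threshold by
    ``cfg.xeric_q_scale`` (richer alternative resources make birds
    choosier). Identical seeds give identical output.
    """
    profiles = profiles if profiles is not None else default_profiles()
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    all_pecks, all_intervals, trial_rows = [], [], []
    truth = GroundTruth()

    for yard_type, prefix in (("mesic", "M"), ("xeric", "X")):
        q_scale = cfg.xeric_q_scale if yard_type == "xeric" else 1.0
        for i in range(cfg.n_yards_per_type):
            yard_id = f"{prefix}{i + 1:02d}"
            rate_scale = float(np.exp(rng.normal(0.0, cfg.yard_rate_sigma)))
            for j in range(cfg.trays_per_yard):
                micro = "bush" if j % 2 == 0 else "open"
                tray_id = f"{yard_id}-{micro[0].upper()}{j // 2 + 1 if j >= 2 else ''}"
                p_df, i_df, measured, tr = simulate_tray(
                    profiles, cfg, rng, tray_id=tray_id, yard_type=yard_type,
                    q_scale=q_scale, rate_scale=rate_scale, bout_pauses=bout_pauses,
                )
                all_pecks.append(p_df)
                all_intervals.append(i_df)
                trial_rows.append(
                    (tray_id, yard_id, yard_type, micro, cfg.g0, cfg.duration_s,
                     measured)
                )
                truth.true_final_mass.update(tr.true_final_mass)
                truth.true_grams_consumed.update(tr.true_grams_consumed)
                truth.true_quit_time.update(tr.true_quit_time)
                truth.true_gud_at_quit.update(tr.true_gud_at_quit)
                truth.true_individuals.update(tr.true_individuals)
                for sp, gud in tr.theoretical_gud.items():
                    truth.theoretical_gud.setdefault(f"{yard_type}:{sp}", gud)

    trials = pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS)
    pecks = (
        pd.concat(all_pecks, ignore_index=True)
        if all_pecks
        else pd.DataFrame(columns=PECKS_COLUMNS)
    )
    intervals = (
        pd.concat(all_intervals, ignore_index=True)
        if all_intervals
        else pd.DataFrame(columns=INTERVALS_COLUMNS)
    )
    return StudyDataset(trials=trials, pecks=pecks, intervals=intervals), truth


def constant_yield_config(**overrides) -> SimConfig:
    """Convenience: the study config in exactly-linear depletion mode."""
    base = SimConfig(depletion="constant_yield")
    return replace(base, **overrides)
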