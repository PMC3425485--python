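"""Per-species foraging quantities derived from event logs.

Everything here is deterministic bookkeeping on the scored video events:
segmenting a species' pecks into foraging bouts, timing those bouts,
locating each species' quitting point in the tray-wide peck sequence, and
bounding the number of distinct individuals from visit-interval overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import UnvisitedTrayError

BOUTS_COLUMNS = ["tray_id", "species", "t_start", "t_end", "n_pecks"]
QUIT_COLUMNS = [
    "tray_id",
    "species",
    "t_quit",
    "cum_pecks_at_quit",
    "own_total_pecks",
    "is_final_forager",
]
DENSITY_COLUMNS = ["tray_id", "species", "min_individuals", "tray_total_min_individuals"]


def segment_bouts_times(times: np.ndarray, gap: float) -> list[tuple[float, float, int]]:
    """Partition one species' peck times into bouts.

    A bout ends when ``gap`` seconds or more pass without a peck (a gap of
    exactly ``gap`` terminates the bout). Returns ``(t_start, t_end,
    n_pecks)`` triples; input order is irrelevant.
    """
    if gap <= 0:
        raise ValueError(f"gap must be positive, got {gap}")
    t = np.sort(np.asarray(times, dtype=float))
    if t.size == 0:
        return []
    # boundary after index i when t[i+1] - t[i] >= gap
    breaks = np.flatnonzero(np.diff(t) >= gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    return [(float(t[a]), float(t[b]), int(b - a + 1)) for a, b in zip(starts, ends)]


def segment_bouts(pecks: pd.DataFrame, gap: float = 60.0) -> pd.DataFrame:
    """Segment every (tray, species) peck stream into foraging bouts.

    Returns a frame with ``BOUTS_COLUMNS``, ordered by tray, species, t_start.
    """
    rows = []
    for (tray, species), grp in pecks.groupby(["tray_id", "species"], sort=True):
        for t_start, t_end, n in segment_bouts_times(grp["t_seconds"].to_numpy(), gap):
            rows.append((tray, species, t_start, t_end, n))
    return pd.DataFrame(rows, columns=BOUTS_COLUMNS)


def foraging_time(bouts: pd.DataFrame) -> pd.DataFrame:
    """Total within-bout foraging time per tray and species, in seconds.

    Sums ``t_end - t_start`` over bouts, so single-peck bouts contribute
    zero: this is minimum residency, excluding pre-first-peck and
    post-last-peck presence.
    """
    if bouts.empty:
        return pd.DataFrame(columns=["tray_id", "species", "foraging_time_s"])
    out = (
        (bouts["t_end"] - bouts["t_start"])
        .groupby([bouts["tray_id"], bouts["species"]])
        .sum()
        .rename("foraging_time_s")
        .reset_index()
    )
    return out


def max_concurrent(t_on: np.ndarray, t_off: np.ndarray) -> int:
    """Maximum number of simultaneously open intervals (sweep line).

    Intervals are half-open for concurrency: ``[a, b]`` and ``[c, d]``
    overlap iff ``max(a, c) < min(b, d)``, so touching endpoints do not
    count as simultaneous presence.
    """
    t_on = np.asarray(t_on, dtype=float)
    t_off = np.asarray(t_off, dtype=float)
    if t_on.size == 0:
        return 0
    # close events sort before open events at equal times (flag 0 < 1)
    times = np.concatenate((t_off, t_on))
    flags = np.concatenate((np.full(t_off.size, 0), np.full(t_on.size, 1)))
    deltas = np.concatenate((np.full(t_off.size, -1), np.full(t_on.size, 1)))
    order = np.lexsort((flags, times))
    running = np.cumsum(deltas[order])
    return int(running.max())


def min_individuals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Minimum number of distinct individuals per tray and species.

    Birds are unmarked, so the only safe lower bound combines two rules:
    distinguishable demographic classes cannot share individuals, and
    within one class the bound is the maximum number seen on the tray at
    once (non-overlapping visits are assumed repeat visitors). The
    species-level minimum is therefore the sum over class tags of each
    class's maximum concurrency; ``tray_total_min_individuals`` sums these
    over species.
    """
    if intervals.empty:
        return pd.DataFrame(columns=DENSITY_COLUMNS)
    rows = []
    for (tray, species), grp in intervals.groupby(["tray_id", "species"], sort=True):
        total = 0
        for _, cls_grp in grp.groupby("class_tag"):
            total += max_concurrent(cls_grp["t_on"].to_numpy(), cls_grp["t_off"].to_numpy())
        rows.append((tray, species, total))
    out = pd.DataFrame(rows, columns=["tray_id", "species", "min_individuals"])
    out["tray_total_min_individuals"] = out.groupby("tray_id")["min_individuals"].transform(
        "sum"
    )
    return out


def tray_densities(density: pd.DataFrame) -> pd.Series:
    """Tray-level total minimum individuals, indexed by tray_id."""
    if density.empty:
        return pd.Series(dtype=int, name="tray_total_min_individuals")
    return (
        density.drop_duplicates("tray_id")
        .set_index("tray_id")["tray_total_min_individuals"]
    )


def final_forager(pecks: pd.DataFrame) -> str:
    """Species delivering the last peck on one tray.

    Exact time ties are broken toward the lexicographically smallest
    species code (deterministic; ties are essentially impossible at video
    frame resolution).
    """
    if pecks.empty:
        raise UnvisitedTrayError("tray has no pecks; no final forager exists")
    t_max = pecks["t_seconds"].max()
    at_max = pecks.loc[pecks["t_seconds"] == t_max, "species"]
    return min(at_max)


def quit_points(pecks: pd.DataFrame) -> pd.DataFrame:
    """Quitting point of every species on every tray.

    A species quits at its last peck; ``cum_pecks_at_quit`` counts pecks of
    *all* species up to and including that time — earlier visitors'
    depletion is included, later visitors' is not. The final forager's
    cumulative count therefore equals the tray total.
    """
    rows = []
    for tray, grp in pecks.groupby("tray_id", sort=True):
        t = grp["t_seconds"].to_numpy()
        ff = final_forager(grp)
        last = grp.groupby("species")["t_seconds"].max()
        own = grp.groupby("species").size()
        for species in sorted(last.index):
            t_quit = float(last[species])
            cum = int((t <= t_quit).sum())
            rows.append(
                (tray, species, t_quit, cum, int(own[species]), species == ff)
            )
    return pd.DataFrame(rows, columns=QUIT_COLUMNS)
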