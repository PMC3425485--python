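"""End-to-end pipeline driver: simulate/load -> events -> fit -> estimate -> stats.

Each stage writes its artifacts into the output directory and never
mutates another stage's outputs; a manifest with the config snapshot,
input hashes and produced files is written last, so a complete manifest
certifies a complete run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .datatypes import GudPeckFit, StudyDataset
from . import community, events, io, model, simulate

log = logging.getLogger("gudpeck")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, pd.DataFrame):
        return json.loads(o.to_json(orient="index"))
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default,
                               allow_nan=True) + "\n")
    return path


def run_events_stage(dataset: StudyDataset, config: RunConfig, out_dir: Path) -> dict:
    bouts = events.segment_bouts(dataset.pecks, gap=config.bout_gap_s)
    ftimes = events.foraging_time(bouts)
    density = events.min_individuals(dataset.intervals)
    qpts = events.quit_points(dataset.pecks)
    io.write_results(bouts, out_dir / "bouts.csv", events.BOUTS_COLUMNS)
    io.write_results(qpts, out_dir / "quit_points.csv", events.QUIT_COLUMNS)
    io.write_results(density, out_dir / "density.csv", events.DENSITY_COLUMNS)
    io.write_results(ftimes, out_dir / "foraging_times.csv",
                     ["tray_id", "species", "foraging_time_s"])
    log.info("events: %d bouts, %d quit points, %d density rows",
             len(bouts), len(qpts), len(density))
    return {"bouts": bouts, "foraging_times": ftimes, "density": density,
            "quit_points": qpts}


def run_fit_stage(dataset: StudyDataset, ev: dict, out_dir: Path) -> GudPeckFit:
    densities = events.tray_densities(ev["density"])
    train = model.training_table(dataset.trials, ev["quit_points"], densities)
    fit = model.fit_gud_peck_model(train)
    write_json(fit.to_dict(), out_dir / "gud_peck_fit.json")
    io.write_results(train, out_dir / "training_table.csv")
    log.info("fit: n_train=%d r^2=%.3f pearson=%.3f", fit.n_train, fit.r_squared,
             fit.obs_pred_pearson)
    return fit


def run_estimate_stage(dataset, ev, fit, config, out_dir: Path) -> pd.DataFrame:
    densities = events.tray_densities(ev["density"])
    est = model.estimate_species_guds(fit, ev["quit_points"], densities,
                                      dataset.trials, config)
    io.write_results(est, out_dir / "species_gud_estimates.csv",
                     model.ESTIMATES_COLUMNS)
    log.info("estimate: %d species-tray estimates (%d omitted)", len(est),
             int(est["omitted"].sum()))
    return est


def run_rates_stage(dataset, ev, fit, config, out_dir: Path) -> pd.DataFrame:
    densities = events.tray_densities(ev["density"])
    rates = model.consumption_rates(fit, ev["quit_points"], ev["foraging_times"],
                                    densities, dataset.trials, config)
    io.write_results(rates, out_dir / "consumption_rates.csv", model.RATES_COLUMNS)
    log.info("rates: %d rows (%d omitted)", len(rates), int(rates["omitted"].sum()))
    return rates


def species_yard_guds(est: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-species-per-yard mean GUD, pooling bush and open trays.

    Mirrors the analysis flow: after the paired microhabitat test shows no
    bush/open difference, trays are pooled within yards.
    """
    ok = est[~est["omitted"] & ~est["unvisited"] & (est["species"] != "")]
    merged = ok.merge(trials[["tray_id", "yard_id", "yard_type"]], on="tray_id")
    return (
        merged.groupby(["yard_id", "yard_type", "species"], as_index=False)
        ["gud_estimate"].mean()
        .rename(columns={"gud_estimate": "gud"})
    )


def microhabitat_pairs(est: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Bush/open GUD pairs per species and yard for the paired t-test."""
    ok = est[~est["omitted"] & ~est["unvisited"] & (est["species"] != "")]
    merged = ok.merge(
        trials[["tray_id", "yard_id", "yard_type", "microhabitat"]], on="tray_id"
    )
    wide = merged.pivot_table(
        index=["species", "yard_id", "yard_type"], columns="microhabitat",
        values="gud_estimate", aggfunc="mean",
    ).reset_index()
    for col in ("bush", "open"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide.columns.name = None
    return wide


def run_stats_stage(dataset, ev, est, rates, config, out_dir: Path) -> dict:
    trials = dataset.trials
    results: dict = {}

    # paired bush-vs-open tests per yard type, visited pairs and all pairs
    pairs = microhabitat_pairs(est, trials)
    g0 = float(trials["initial_seed_mass_g"].iloc[0])
    paired = {}
    for yt in sorted(trials["yard_type"].unique()):
        sub = pairs[pairs["yard_type"] == yt]
        for label, include in (("visited_pairs", False), ("all_pairs", True)):
            try:
                paired[f"{yt}_{label}"] = community.paired_microhabitat_test(
                    sub, include_unvisited=include, g0=g0
                )
            except community.DegenerateStatisticsError as e:
                paired[f"{yt}_{label}"] = {"error": str(e)}
    results["paired_microhabitat"] = paired

    # pooled per-species-per-yard GUDs: ANOVA, ANCOVA, per-species Wilcoxon
    pooled = species_yard_guds(est, trials)
    io.write_results(pooled, out_dir / "species_yard_guds.csv")
    anova = community.gud_anova(pooled["gud"], pooled["yard_type"])
    results["gud_anova"] = {
        "F": anova["F"], "df": anova["df"], "p": anova["p"],
        "degenerate": anova["degenerate"],
        "group_stats": anova["group_stats"],
    }

    density = ev["density"]
    yard_density = (
        density.drop_duplicates("tray_id")
        .merge(trials[["tray_id", "yard_id"]], on="tray_id")
        .groupby("yard_id")["tray_total_min_individuals"].mean()
    )
    ancova_data = pooled.assign(density=pooled["yard_id"].map(yard_density))
    results["gud_ancova"] = {
        k: v for k, v in community.gud_ancova(ancova_data).items()
        if k != "coefficients"
    }

    wil = community.wilcoxon_by_species(pooled)
    results["wilcoxon_by_species"] = wil

    rate_data = (
        rates[~rates["omitted"]]
        .merge(trials[["tray_id", "yard_type"]], on="tray_id")
        .rename(columns={"rate_g_per_h": "rate"})
    )
    results["kruskal_rates"] = community.kruskal_by_yard_type(rate_data)

    # community matrix -> evenness and MRPP
    mat = community.community_matrix(density, trials)
    groups = community.yard_groups(trials).loc[mat.index]
    io.write_results(mat.reset_index(), out_dir / "community_matrix.csv")
    even_rows = []
    for yard_id, row in mat.iterrows():
        if (row > 0).sum() >= 2:
            even_rows.append((yard_id, groups[yard_id], community.evenness(row)))
    even = pd.DataFrame(even_rows, columns=["yard_id", "yard_type", "evenness"])
    io.write_results(even, out_dir / "evenness.csv")
    if even["yard_type"].nunique() >= 2 and (even.groupby("yard_type").size() >= 2).all():
        ev_anova = community.gud_anova(even["evenness"], even["yard_type"])
        results["evenness_anova"] = {
            "F": ev_anova["F"], "df": ev_anova["df"], "p": ev_anova["p"],
            "group_stats": ev_anova["group_stats"],
        }

    filtered = community.filter_rare(
        community.row_normalize(mat),
        config.rare_species_min_prop,
        config.rare_filter_inclusive,
    )
    mres = community.mrpp(
        filtered, groups.loc[filtered.index], n_perm=config.n_permutations,
        seed=config.seed,
    )
    results["mrpp"] = mres.to_dict()

    write_json(results, out_dir / "community_stats.json")
    log.info("stats: ANOVA F=%.3f, MRPP A=%.4g p=%.3f", anova["F"], mres.A,
             mres.p_value)
    return results


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    do_simulate: bool = False,
    sim_config: simulate.SimConfig | None = None,
) -> dict:
    """Run every stage in dependency order; returns in-memory stage outputs.

    Exactly one of ``input_dir`` / ``do_simulate`` selects the data source.
    A failure in any stage aborts the run with that stage named; the
    manifest is only written after all stages succeed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_hashes = {}

    stage = "load"
    try:
        if do_simulate:
            dataset, truth = simulate.generate_study(
                cfg=sim_config or simulate.SimConfig(), seed=config.seed
            )
            io.write_study(dataset, out_dir)
            write_json(truth.to_json_dict(), out_dir / "ground_truth.json")
        elif input_dir is not None:
            dataset = io.read_study_dir(input_dir)
            for name in ("pecks.csv", "intervals.csv", "trials.csv"):
                input_hashes[name] = _sha256(Path(input_dir) / name)
        else:
            raise io.FormatError("either input_dir or do_simulate is required")

        stage = "events"
        ev = run_events_stage(dataset, config, out_dir)
        stage = "fit"
        fit = run_fit_stage(dataset, ev, out_dir)
        stage = "estimate"
        est = run_estimate_stage(dataset, ev, fit, config, out_dir)
        stage = "rates"
        rates = run_rates_stage(dataset, ev, fit, config, out_dir)
        stage = "stats"
        stats = run_stats_stage(dataset, ev, est, rates, config, out_dir)
    except Exception as e:
        raise type(e)(f"[stage: {stage}] {e}") from e

    manifest = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "simulated": bool(do_simulate),
        "input_hashes": input_hashes,
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    write_json(manifest, out_dir / "manifest.json")
    return {"dataset": dataset, "events": ev, "fit": fit, "estimates": est,
            "rates": rates, "stats": stats}
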