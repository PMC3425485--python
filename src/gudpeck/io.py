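"""CSV readers and writers for study inputs and stage outputs.

All files are comma-separated UTF-8 with a mandatory header row and "."
decimal separator. Stage outputs are written with a deterministic column
order and floats at six decimal places, so that write -> read -> write is
byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    INTERVALS_COLUMNS,
    MICROHABITATS,
    PECKS_COLUMNS,
    ReferentialError,
    StudyDataset,
    TRIALS_COLUMNS,
    YARD_TYPES,
)

#: Decimal places used for every float column in stage outputs.
FLOAT_DECIMALS = 6
_FLOAT_FORMAT = f"%.{FLOAT_DECIMALS}f"


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _bad_rows(mask: pd.Series, path: Path, why: str, exc=FormatError) -> None:
    """Raise, naming CSV line numbers (header is line 1) of offending rows."""
    if mask.any():
        lines = (mask[mask].index + 2).tolist()
        raise exc(f"{path}: {why} at line(s) {lines[:20]}")


def read_pecks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"tray_id": str, "species": str, "class_tag": str})
    _require_columns(df, PECKS_COLUMNS, path)
    df = df[PECKS_COLUMNS].copy()
    df["t_seconds"] = pd.to_numeric(df["t_seconds"], errors="coerce")
    _bad_rows(df["t_seconds"].isna(), path, "non-numeric t_seconds")
    _bad_rows(df["t_seconds"] < 0, path, "negative t_seconds")
    _bad_rows(df["species"].isna() | (df["species"].str.len() == 0), path, "empty species")
    df["class_tag"] = df["class_tag"].fillna("unknown")
    return df


def read_intervals(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"tray_id": str, "species": str, "class_tag": str})
    _require_columns(df, INTERVALS_COLUMNS, path)
    df = df[INTERVALS_COLUMNS].copy()
    for col in ("t_on", "t_off"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        _bad_rows(df[col].isna(), path, f"non-numeric {col}")
    _bad_rows(df["t_on"] > df["t_off"], path, "t_on > t_off")
    _bad_rows(df["t_on"] < 0, path, "negative t_on")
    df["class_tag"] = df["class_tag"].fillna("unknown")
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"tray_id": str, "yard_id": str, "yard_type": str, "microhabitat": str},
    )
    _require_columns(df, TRIALS_COLUMNS, path)
    df = df[TRIALS_COLUMNS].copy()
    for col in ("initial_seed_mass_g", "duration_s", "final_gud_g"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    _bad_rows(df["initial_seed_mass_g"].isna() | (df["initial_seed_mass_g"] <= 0),
              path, "initial_seed_mass_g missing or non-positive")
    _bad_rows(df["duration_s"].isna() | (df["duration_s"] <= 0),
              path, "duration_s missing or non-positive")
    _bad_rows(~df["yard_type"].isin(YARD_TYPES), path,
              f"yard_type not in {YARD_TYPES}")
    _bad_rows(~df["microhabitat"].isin(MICROHABITATS), path,
              f"microhabitat not in {MICROHABITATS}")
    _bad_rows(df["tray_id"].duplicated(), path, "duplicate tray_id")
    # final_gud_g may be missing; when present it must lie in [0, G0] up to
    # a small weighing tolerance.
    present = df["final_gud_g"].notna()
    tol = 0.5
    _bad_rows(
        present & ((df["final_gud_g"] < -tol)
                   | (df["final_gud_g"] > df["initial_seed_mass_g"] + tol)),
        path, "final_gud_g outside [0, initial mass]")
    return df


def read_study(
    pecks_path: str | Path,
    intervals_path: str | Path,
    trials_path: str | Path,
) -> StudyDataset:
    """Read and cross-validate the three study CSVs.

    Raises
    ------
    FormatError
        Missing columns or malformed values (reported with line numbers).
    ReferentialError
        An event references an unknown tray or exceeds its trial duration.
    """
    trials = read_trials(trials_path)
    pecks = read_pecks(pecks_path)
    intervals = read_intervals(intervals_path)

    known = set(trials["tray_id"])
    for df, path in ((pecks, Path(pecks_path)), (intervals, Path(intervals_path))):
        unknown = ~df["tray_id"].isin(known)
        if unknown.any():
            bad = sorted(df.loc[unknown, "tray_id"].unique())
            raise ReferentialError(f"{path}: unknown tray_id(s) {bad[:10]}")

    durations = trials.set_index("tray_id")["duration_s"]
    late = pecks["t_seconds"] > pecks["tray_id"].map(durations)
    if late.any():
        bad = sorted(pecks.loc[late, "tray_id"].unique())
        _bad_rows(late, Path(pecks_path),
                  f"peck time exceeds trial duration for tray(s) {bad[:10]}",
                  exc=ReferentialError)
    late_iv = intervals["t_off"] > intervals["tray_id"].map(durations)
    if late_iv.any():
        bad = sorted(intervals.loc[late_iv, "tray_id"].unique())
        _bad_rows(late_iv, Path(intervals_path),
                  f"interval end exceeds trial duration for tray(s) {bad[:10]}",
                  exc=ReferentialError)

    return StudyDataset(trials=trials, pecks=pecks, intervals=intervals)


def write_results(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> Path:
    """Write a stage output CSV with deterministic column order and precision.

    Empty frames still produce a header-only file. Re-reading a written file
    and writing it again yields a byte-identical file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        df = df.reindex(columns=columns)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = np.round(out[col], FLOAT_DECIMALS)
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def write_study(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a StudyDataset to pecks.csv / intervals.csv / trials.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pecks": write_results(dataset.pecks, out_dir / "pecks.csv", PECKS_COLUMNS),
        "intervals": write_results(
            dataset.intervals, out_dir / "intervals.csv", INTERVALS_COLUMNS
        ),
        "trials": write_results(dataset.trials, out_dir / "trials.csv", TRIALS_COLUMNS),
    }
    return paths


def read_study_dir(in_dir: str | Path) -> StudyDataset:
    in_dir = Path(in_dir)
    for name in ("pecks.csv", "intervals.csv", "trials.csv"):
        if not (in_dir / name).exists():
            raise FormatError(f"missing input file: {in_dir / name}")
    return read_study(in_dir / "pecks.csv", in_dir / "intervals.csv", in_dir / "trials.csv")
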