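"""Run configuration: analysis knobs shared across pipeline stages."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .datatypes import FormatError


@dataclass
class RunConfig:
    """Analysis parameters with their field defaults.

    Parameters
    ----------
    bout_gap_s : float
        Inter-peck gap (seconds) that terminates a foraging bout. A gap of
        exactly ``bout_gap_s`` ends the bout ("at least one minute" is
        inclusive). Default 60 s.
    peck_min_threshold : int
        Visitors with fewer own pecks than this are omitted from GUD and
        consumption estimates; the linear model extrapolates poorly for
        very light visitors. Default 40 pecks.
    n_permutations : int
        Relabelings used by permutation procedures (MRPP). Default 999.
    seed : int
        Seed for every stochastic component (simulation, permutations).
    rare_species_min_prop : float
        Species occurring at fewer than this fraction of sites are dropped
        from the community matrix before MRPP. Strict ``<`` comparison.
    rare_filter_inclusive : bool
        If True, drop species at ``<=`` the threshold occurrence instead of
        strictly below it (the boundary reading of "less than 5% of sites").
    consumption_pecks : str
        ``"own"`` (default): a species' consumption uses its own total pecks;
        ``"cumulative"``: uses the tray-cumulative pecks at its quit point.
    """

    bout_gap_s: float = 60.0
    peck_min_threshold: int = 40
    n_permutations: int = 999
    seed: int = 0
    rare_species_min_prop: float = 0.05
    rare_filter_inclusive: bool = False
    consumption_pecks: str = "own"

    def __post_init__(self) -> None:
        if self.bout_gap_s <= 0:
            raise FormatError(f"bout_gap_s must be positive, got {self.bout_gap_s}")
        if self.peck_min_threshold < 0:
            raise FormatError("peck_min_threshold must be non-negative")
        if not 0 <= self.rare_species_min_prop < 1:
            raise FormatError("rare_species_min_prop must be in [0, 1)")
        if self.consumption_pecks not in ("own", "cumulative"):
            raise FormatError(
                f"consumption_pecks must be 'own' or 'cumulative', got "
                f"{self.consumption_pecks!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load configuration from a YAML or JSON file; unknown keys rejected."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
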