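"""Per-generation airway morphometry tables.

A morphometry table summarises an asymmetric conducting-airway tree one row per
generation (trachea = generation 1): how many branches the generation holds, how
many of them are terminal (end in an alveolar compartment), and the distribution
of their internal diameters in mm (mean, max, min, sd).

The packaged default table describes a 26-generation human airway tree with
64,893 branches and 32,447 terminal branches, terminals appearing from
generation 9 onward.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: canonical column order of a morphometry table
COLUMNS = (
    "generation",
    "branches",
    "terminal_branches",
    "d_mean",
    "d_max",
    "d_min",
    "d_std",
)

# accepted aliases -> canonical name (case/space/underscore-insensitive)
_ALIASES = {
    "generation": "generation",
    "gen": "generation",
    "branches": "branches",
    "branch_count": "branches",
    "terminal_branches": "terminal_branches",
    "terminals": "terminal_branches",
    "terminal_count": "terminal_branches",
    "d_mean": "d_mean",
    "d_mean_mm": "d_mean",
    "d_max": "d_max",
    "d_max_mm": "d_max",
    "d_min": "d_min",
    "d_min_mm": "d_min",
    "d_std": "d_std",
    "d_std_mm": "d_std",
}


@dataclass(frozen=True)
class MorphometryTable:
    """Validated per-generation branch counts and diameter statistics.

    Wraps a :class:`pandas.DataFrame` with the columns in :data:`COLUMNS`,
    one row per generation, generations contiguous from 1.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self._validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_generations(self) -> int:
        return len(self.frame)

    @property
    def generations(self) -> np.ndarray:
        return self.frame["generation"].to_numpy()

    @property
    def branch_counts(self) -> np.ndarray:
        return self.frame["branches"].to_numpy()

    @property
    def terminal_counts(self) -> np.ndarray:
        return self.frame["terminal_branches"].to_numpy()

    @property
    def total_branches(self) -> int:
        return int(self.branch_counts.sum())

    @property
    def total_terminals(self) -> int:
        return int(self.terminal_counts.sum())

    def row(self, generation: int) -> pd.Series:
        sel = self.frame[self.frame["generation"] == generation]
        if sel.empty:
            raise KeyError(f"generation {generation} not in table")
        return sel.iloc[0]

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        f = self.frame
        missing = [c for c in COLUMNS if c not in f.columns]
        if missing:
            raise FormatError(f"morphometry table missing columns: {missing}")
        gens = f["generation"].to_numpy()
        if len(gens) == 0:
            raise ValidationError("morphometry table is empty")
        if gens[0] != 1 or not np.array_equal(gens, np.arange(1, len(gens) + 1)):
            raise ValidationError(
                "generations must be contiguous integers starting at 1"
            )
        if f["branches"].iloc[0] != 1:
            raise ValidationError("generation 1 must hold exactly one branch")
        if (f["branches"] <= 0).any():
            raise ValidationError("branch counts must be positive")
        if (f["terminal_branches"] < 0).any():
            raise ValidationError("terminal counts must be non-negative")
        if (f["terminal_branches"] > f["branches"]).any():
            raise ValidationError("terminal count exceeds branch count in a row")
        for col in ("d_mean", "d_max", "d_min"):
            if (f[col] <= 0).any():
                raise ValidationError(f"{col} must be positive")
        if (f["d_std"] < 0).any():
            raise ValidationError("d_std must be non-negative")
        if ((f["d_min"] > f["d_mean"]) | (f["d_mean"] > f["d_max"])).any():
            raise ValidationError("need d_min <= d_mean <= d_max per generation")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_morphometry(path: str | Path) -> MorphometryTable:
    """Read a morphometry CSV and validate it.

    Column names are matched case-insensitively; spaces are treated as
    underscores and a trailing ``_mm`` unit suffix on diameter columns is
    accepted.
    """
    frame = pd.read_csv(path)
    renamed = {}
    for col in frame.columns:
        key = col.strip().lower().replace(" ", "_")
        if key in _ALIASES:
            renamed[col] = _ALIASES[key]
    frame = frame.rename(columns=renamed)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"morphometry file {path!s} missing columns: {missing}")
    frame = frame[list(COLUMNS)].copy()
    for col in ("generation", "branches", "terminal_branches"):
        frame[col] = frame[col].astype(int)
    for col in ("d_mean", "d_max", "d_min", "d_std"):
        frame[col] = frame[col].astype(float)
    return MorphometryTable(frame)


def default_morphometry_path() -> Path:
    """Path of the packaged 26-generation morphometry table."""
    return Path(resources.files("lungsim").joinpath("data/airway_morphometry.csv"))


def default_morphometry() -> MorphometryTable:
    """The packaged 26-generation human airway morphometry table."""
    return load_morphometry(default_morphometry_path())
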