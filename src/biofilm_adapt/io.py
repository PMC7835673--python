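"""Shared plumbing: tidy observation tables, CSV/JSON/YAML round trips, seeding.

All observation data flows through :class:`TimeSeriesTable`, a thin
validated wrapper around a tidy :class:`pandas.DataFrame` with columns
``time_h, condition, replicate, variable, value``.  CSV files are
comma-separated UTF-8 with a required header; lines starting with ``#``
before the header carry provenance metadata (config digest, seed,
package version) and are ignored on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeSeriesTable",
    "SchemaError",
    "read_timeseries",
    "write_timeseries",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_config",
    "dump_json",
    "spawn_seeds",
]

TIMESERIES_COLUMNS = ("time_h", "condition", "replicate", "variable", "value")

#: Known observable names and their admissible value ranges (closed).
VARIABLE_RANGES: Mapping[str, tuple[float, float]] = {
    "log10_cfu_biofilm": (-np.inf, np.inf),
    "log10_cfu_plankton": (-np.inf, np.inf),
    "cfu_biofilm_norm24": (0.0, np.inf),
    "cfu_plankton_norm24": (0.0, np.inf),
    "coverage_pct": (0.0, 100.0),
    "od595": (0.0, np.inf),
}


class SchemaError(ValueError):
    """A table or file violates the declared schema."""


@dataclass
class TimeSeriesTable:
    """Tidy observation records shared by inference and synthetic data.

    One row per measurement: time (h), condition label, replicate index
    (>= 1), variable name and value.  Construction validates the
    invariants (non-negative times, per-variable value ranges).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(
                f"missing columns {missing}; expected header {list(TIMESERIES_COLUMNS)}"
            )
        df = df.loc[:, list(TIMESERIES_COLUMNS)].reset_index(drop=True)
        df["time_h"] = df["time_h"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        df["condition"] = df["condition"].astype(str)
        df["variable"] = df["variable"].astype(str)
        if len(df):
            bad = df.index[df["time_h"] < 0]
            if len(bad):
                raise SchemaError(f"negative time_h in row {bad[0]}")
            bad = df.index[df["replicate"] < 1]
            if len(bad):
                raise SchemaError(f"replicate < 1 in row {bad[0]}")
            for var, (lo, hi) in VARIABLE_RANGES.items():
                sel = df["variable"] == var
                bad = df.index[sel & ((df["value"] < lo) | (df["value"] > hi))]
                if len(bad):
                    raise SchemaError(
                        f"value out of range [{lo}, {hi}] for variable {var!r} "
                        f"in row {bad[0]}"
                    )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeriesTable):
            return NotImplemented
        a = self.data.sort_values(list(TIMESERIES_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(TIMESERIES_COLUMNS)).reset_index(drop=True)
        if len(a) != len(b):
            return False
        return bool(
            (a[["condition", "variable"]] == b[["condition", "variable"]]).all().all()
            and (a["replicate"] == b["replicate"]).all()
            and np.allclose(a[["time_h", "value"]], b[["time_h", "value"]])
        )

    def select(self, **filters) -> "TimeSeriesTable":
        """Subset by equality on any schema column, e.g. ``variable=...``."""
        df = self.data
        for col, val in filters.items():
            if col not in TIMESERIES_COLUMNS:
                raise KeyError(col)
            df = df[df[col] == val]
        return TimeSeriesTable(df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "TimeSeriesTable":
        return cls(pd.DataFrame.from_records(records, columns=TIMESERIES_COLUMNS))


def _metadata_lines(metadata: Mapping | None) -> list[str]:
    if not metadata:
        return []
    return [f"# {k} = {v}" for k, v in metadata.items()]


def write_timeseries(table: TimeSeriesTable, path, metadata: Mapping | None = None) -> None:
    """Write a table as CSV, with '#'-prefixed metadata lines before the header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        table.data.to_csv(fh, index=False)


def read_timeseries(path) -> TimeSeriesTable:
    """Read and validate a tidy observation CSV.

    Raises :class:`SchemaError` naming the expected header when columns
    are missing, or the offending row when a value violates its range.
    An empty body under a valid header yields an empty table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(
            f"{path} is empty; expected header {list(TIMESERIES_COLUMNS)}"
        ) from None
    return TimeSeriesTable(df)


TRAJECTORY_COLUMNS = ("time_h", "rho_b", "rho_p", "c_b", "c_p")


def write_trajectory_csv(trajectory, path, metadata: Mapping | None = None) -> None:
    """Export an ODE trajectory with header ``time_h,rho_b,rho_p,c_b,c_p``."""
    df = pd.DataFrame(
        {
            "time_h": trajectory.t,
            "rho_b": trajectory.rho_b,
            "rho_p": trajectory.rho_p,
            "c_b": trajectory.c_b,
            "c_p": trajectory.c_p,
        }
    )
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("params", json.dumps(trajectory.params.to_dict()))
    meta.setdefault("dt_h", trajectory.dt)
    if trajectory.condition:
        meta.setdefault("condition", trajectory.condition)
    with path.open("w", encoding="utf-8") as fh:
        for line in _metadata_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read a trajectory CSV back as a DataFrame (validated header)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing columns {missing}; expected header {list(TRAJECTORY_COLUMNS)}"
        )
    return df


def load_config(path) -> dict:
    """Load a JSON or YAML configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in {".yaml", ".yml"}:
        out = yaml.safe_load(text)
    else:
        out = json.loads(text)
    if not isinstance(out, dict):
        raise SchemaError(f"config root must be a mapping, got {type(out).__name__}")
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def dump_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n", encoding="utf-8"
    )


def spawn_seeds(global_seed: int, n: int) -> list[int]:
    """Expand one global seed into independent per-module stream seeds.

    Uses the SeedSequence spawning protocol so stages rerun in isolation
    reproduce bit-for-bit; all returned seeds are < 2**31.
    """
    ss = np.random.SeedSequence(int(global_seed))
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]
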