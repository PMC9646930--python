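"""Core panel-data types, readers/writers, and variable-role bookkeeping.

Data orientation is wide: rows are participants, file columns are named
``<variable>_<wave>`` (e.g. ``dep_w1``, ``dep_w2``).  Internally a
:class:`PanelDataset` holds a ``participants x variables x waves`` float
array with ``NaN`` marking missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLES = ("symptom", "cognition", "covariate")

#: Accepted missing-value sentinels in delimited files (plus empty cells).
NA_SENTINELS = ["", "NA", "NaN", "nan"]


class SchemaError(ValueError):
    """A file's columns do not match the declared variable schema."""


class ValidationError(ValueError):
    """A cell value violates its variable's declared bounds."""


@dataclass(frozen=True)
class VariableSpec:
    """Declares one network variable: its name, role, and measurement scale.

    Parameters
    ----------
    name:
        Short identifier used in file columns (``<name>_<wave>``).
    role:
        One of ``symptom``, ``cognition`` or ``covariate``.  The role
        determines cluster membership for bridge statistics; covariates
        never belong to a cluster.
    scale_min, scale_max:
        Inclusive bounds of the instrument's score range.
    ordinal_levels:
        If set, the variable is an ordered categorical coded as the
        consecutive integers ``0 .. ordinal_levels - 1``.
    """

    name: str
    role: str
    scale_min: float
    scale_max: float
    ordinal_levels: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}; "
                              f"expected one of {ROLES}")
        if not self.scale_min < self.scale_max:
            raise SchemaError(f"variable {self.name!r}: scale_min must be < scale_max "
                              f"(got {self.scale_min}, {self.scale_max})")
        if self.ordinal_levels is not None and self.ordinal_levels < 1:
            raise SchemaError(f"variable {self.name!r}: ordinal_levels must be positive")


def default_schema() -> tuple[VariableSpec, ...]:
    """The 13-variable layout used throughout: 5 symptom nodes, 4 cognitive
    nodes and 4 covariates, with instrument-calibrated score ranges."""
    return (
        VariableSpec("anx", "symptom", 1, 5),
        VariableSpec("dep", "symptom", 0, 4),
        VariableSpec("som", "symptom", 0, 4),
        VariableSpec("pa", "symptom", 0, 4),
        VariableSpec("ip", "symptom", 0, 4),
        VariableSpec("wm", "cognition", 0, 12),
        VariableSpec("ps", "cognition", 0, 110),
        VariableSpec("fcr", "cognition", 0, 48),
        VariableSpec("vrm", "cognition", 0, 12),
        VariableSpec("age", "covariate", 42, 64),
        VariableSpec("meno", "covariate", 0, 3, ordinal_levels=4),
        VariableSpec("e2", "covariate", 0, 300),
        VariableSpec("fsh", "covariate", 0, 200),
    )


@dataclass
class PanelDataset:
    """Two-wave (extensible) person x variable panel with a missingness mask.

    ``values`` has shape ``(n_participants, n_variables, n_waves)``; missing
    cells are ``NaN``.  Variable order is identical across waves.
    """

    values: np.ndarray
    variables: tuple[VariableSpec, ...]
    wave_labels: tuple[str, ...] = ("w1", "w2")
    participant_ids: tuple | None = None
    standardized: bool = False
    #: per (variable, wave) ``(mean, sd)`` retained by :func:`standardize`
    scaling: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.variables = tuple(self.variables)
        self.wave_labels = tuple(self.wave_labels)
        if self.values.ndim != 3:
            raise ValueError("values must be (participants, variables, waves)")
        n, p, w = self.values.shape
        if p != len(self.variables):
            raise ValueError(f"values has {p} variable slots but schema lists "
                             f"{len(self.variables)} variables")
        if w != len(self.wave_labels):
            raise ValueError(f"values has {w} waves but {len(self.wave_labels)} labels given")
        if self.participant_ids is None:
            self.participant_ids = tuple(range(n))
        else:
            self.participant_ids = tuple(self.participant_ids)
            if len(self.participant_ids) != n:
                raise ValueError("participant_ids length mismatch")

    # -- shape / bookkeeping ------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def n_waves(self) -> int:
        return self.values.shape[2]

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(v.role for v in self.variables)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, ``True`` where the cell is missing."""
        return np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.mask))

    @property
    def is_complete(self) -> bool:
        return not bool(np.any(self.mask))

    def wave_index(self, wave: str) -> int:
        try:
            return self.wave_labels.index(wave)
        except ValueError:
            raise KeyError(f"unknown wave {wave!r}; have {self.wave_labels}") from None

    def variable_index(self, name: str) -> int:
        try:
            return self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None

    def wave_matrix(self, wave: str) -> np.ndarray:
        """Participants x variables matrix for one wave (a copy)."""
        return self.values[:, :, self.wave_index(wave)].copy()

    def column(self, name: str, wave: str) -> np.ndarray:
        return self.values[:, self.variable_index(name), self.wave_index(wave)].copy()

    def subset(self, rows: Sequence[int]) -> "PanelDataset":
        """Row (participant) subset preserving schema and wave labels."""
        rows = np.asarray(rows)
        return PanelDataset(
            self.values[rows].copy(),
            self.variables,
            self.wave_labels,
            tuple(np.asarray(self.participant_ids, dtype=object)[rows]),
            standardized=self.standardized,
            scaling=self.scaling,
        )

    def copy(self) -> "PanelDataset":
        return replace(self, values=self.values.copy())

    def wide(self) -> pd.DataFrame:
        """Wide DataFrame with columns ``<variable>_<wave>``."""
        cols = {}
        for w, wl in enumerate(self.wave_labels):
            for j, v in enumerate(self.variables):
                cols[f"{v.name}_{wl}"] = self.values[:, j, w]
        return pd.DataFrame(cols, index=pd.Index(self.participant_ids, name="participant_id"))

    def validate_bounds(self) -> None:
        """Raise :class:`ValidationError` naming the first out-of-range cell."""
        for w, wl in enumerate(self.wave_labels):
            for j, v in enumerate(self.variables):
                col = self.values[:, j, w]
                bad = np.where((col < v.scale_min) | (col > v.scale_max))[0]
                if bad.size:
                    i = int(bad[0])
                    raise ValidationError(
                        f"value {col[i]!r} for column {v.name}_{wl} (row "
                        f"{self.participant_ids[i]!r}) outside "
                        f"[{v.scale_min}, {v.scale_max}]")


def from_wide(df: pd.DataFrame, schema: Sequence[VariableSpec],
              wave_labels: Sequence[str] = ("w1", "w2")) -> PanelDataset:
    """Build a :class:`PanelDataset` from a wide ``<var>_<wave>`` frame."""
    schema = tuple(schema)
    n = len(df)
    values = np.full((n, len(schema), len(wave_labels)), np.nan)
    for w, wl in enumerate(wave_labels):
        for j, v in enumerate(schema):
            col = f"{v.name}_{wl}"
            if col not in df.columns:
                raise SchemaError(f"missing column {col!r} required by schema")
            values[:, j, w] = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    ids = tuple(df.index) if df.index.name is not None else tuple(range(n))
    ds = PanelDataset(values, schema, tuple(wave_labels), ids)
    ds.validate_bounds()
    return ds


def read_panel(path: str | Path, schema: Sequence[VariableSpec],
               wave_labels: Sequence[str] = ("w1", "w2")) -> PanelDataset:
    """Read a wide CSV (header row, one row per participant) into a panel.

    Empty cells and ``NA`` are treated as missing.  Raises
    :class:`SchemaError` for absent columns and :class:`ValidationError`
    for out-of-range values (naming row and column).
    """
    df = pd.read_csv(path, na_values=NA_SENTINELS, keep_default_na=False)
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    return from_wide(df, schema, wave_labels)


def write_panel(data: PanelDataset, path: str | Path) -> None:
    """Write the panel as a wide CSV; missing cells become empty fields."""
    df = data.wide().reset_index()
    df.to_csv(path, index=False, float_format="%.12g")


def describe(data: PanelDataset) -> pd.DataFrame:
    """Per variable-wave summary: mean, sd (n-1), min, max, missing fraction.

    Statistics use observed values only.  An all-missing variable-wave is
    flagged (``n_observed == 0``) with NaN moments rather than raising.
    """
    rows = []
    n = data.n_participants
    for wl in data.wave_labels:
        w = data.wave_index(wl)
        for j, v in enumerate(data.variables):
            col = data.values[:, j, w]
            obs = col[~np.isnan(col)]
            rows.append({
                "variable": v.name,
                "wave": wl,
                "role": v.role,
                "n_observed": obs.size,
                "mean": float(np.mean(obs)) if obs.size else np.nan,
                "sd": float(np.std(obs, ddof=1)) if obs.size > 1 else np.nan,
                "min": float(np.min(obs)) if obs.size else np.nan,
                "max": float(np.max(obs)) if obs.size else np.nan,
                "missing_fraction": float((n - obs.size) / n),
            })
    return pd.DataFrame(rows)


def standardize(data: PanelDataset) -> PanelDataset:
    """Z-score every variable-wave column (mean 0, sd 1, with sd using n-1).

    Intended for complete (post-imputation) data; missing cells are ignored
    in the moments and left missing.  Transformation parameters are kept in
    ``scaling`` for reporting.  A zero-variance column raises ``ValueError``
    naming the column.
    """
    values = data.values.copy()
    scaling: dict[tuple[str, str], tuple[float, float]] = {}
    for wl in data.wave_labels:
        w = data.wave_index(wl)
        for j, v in enumerate(data.variables):
            col = values[:, j, w]
            obs = ~np.isnan(col)
            mu = float(np.mean(col[obs]))
            sd = float(np.std(col[obs], ddof=1))
            if sd == 0.0 or not np.isfinite(sd):
                raise ValueError(f"cannot standardize constant column {v.name}_{wl}")
            values[:, j, w] = (col - mu) / sd
            scaling[(v.name, wl)] = (mu, sd)
    return PanelDataset(values, data.variables, data.wave_labels,
                        data.participant_ids, standardized=True, scaling=scaling)
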