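"""Domain containers and long-format I/O for nested longitudinal datasets.

The canonical in-memory layout is a long-format :class:`pandas.DataFrame`
with one row per observation and columns

    subject   identifier of the repeatedly-measured unit (e.g. mouse)
    cluster   optional identifier of a higher-level unit (e.g. donor)
    group     two-level treatment factor
    time      continuous measurement time, in days
    response  continuous outcome (e.g. % weight change)

Subjects are strictly nested: a subject belongs to exactly one group and, if
clusters are present, exactly one cluster.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ("subject", "cluster", "group", "time", "response")

__all__ = [
    "LongitudinalDataset",
    "DesignGrid",
    "ValidationReport",
    "SchemaError",
    "NestingError",
    "load_long_csv",
    "write_long_csv",
    "build_design",
    "apply_missingness",
    "validate_dataset",
]


class SchemaError(ValueError):
    """Input table does not have the required columns or factor levels."""


class NestingError(ValueError):
    """A subject maps to more than one group or cluster."""


def _check_nesting(df: pd.DataFrame) -> None:
    per_subj = df.groupby("subject", observed=True)["group"].nunique()
    if (per_subj > 1).any():
        bad = per_subj[per_subj > 1].index.tolist()
        raise NestingError(f"subjects mapped to multiple groups: {bad}")
    if "cluster" in df.columns and df["cluster"].notna().any():
        per_subj = df.groupby("subject", observed=True)["cluster"].nunique()
        if (per_subj > 1).any():
            bad = per_subj[per_subj > 1].index.tolist()
            raise NestingError(f"subjects mapped to multiple clusters: {bad}")


@dataclass
class LongitudinalDataset:
    """Validated long-format longitudinal dataset.

    Parameters
    ----------
    df : pandas.DataFrame
        Long-format table with the canonical columns. ``cluster`` is optional
        and ``response`` may be missing (a design skeleton).
    n_dropped : int
        Number of rows discarded on load because response/time was missing.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ("subject", "group", "time") if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if "response" not in df.columns:
            df = df.assign(response=np.nan)
        keep = [c for c in CANONICAL_COLUMNS if c in df.columns]
        df = df[keep].copy()
        df["time"] = pd.to_numeric(df["time"])
        if not np.isfinite(df["time"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite time values")
        ngroups = df["group"].nunique()
        if ngroups > 2:
            raise SchemaError(
                f"group must have at most two levels, found {ngroups}"
            )
        if df.duplicated(["subject", "time"]).any():
            raise ValueError("duplicate (subject, time) pairs")
        _check_nesting(df)
        self.df = df.reset_index(drop=True)

    # -- basic summaries -------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_subjects(self) -> int:
        return self.df["subject"].nunique()

    @property
    def n_clusters(self) -> int:
        if not self.has_cluster:
            return 0
        return self.df["cluster"].nunique()

    @property
    def has_cluster(self) -> bool:
        return "cluster" in self.df.columns and self.df["cluster"].notna().all()

    @property
    def group_levels(self) -> tuple:
        return tuple(sorted(self.df["group"].unique()))

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.df["time"].unique())

    def group_indicator(self) -> np.ndarray:
        """0/1 coding with the lexicographically first level as reference."""
        ref = self.group_levels[0]
        return (self.df["group"].to_numpy() != ref).astype(float)

    def with_response(self, y: np.ndarray) -> "LongitudinalDataset":
        df = self.df.copy()
        df["response"] = np.asarray(y, dtype=float)
        return LongitudinalDataset(df)

    def to_csv(self, path) -> None:
        write_long_csv(self, path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LongitudinalDataset(n_records={self.n_records}, "
            f"n_subjects={self.n_subjects}, n_clusters={self.n_clusters})"
        )


@dataclass(frozen=True)
class DesignGrid:
    """Fully crossed design: groups x donors x mice x timepoints.

    ``donors_per_group`` is either a single count shared by the groups or a
    mapping from group label to count (the original design had 3 healthy and
    5 undernourished donors).
    """

    groups: tuple
    donors_per_group: object  # int | Mapping[str, int]
    mice_per_donor: int
    timepoints: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        if len(self.groups) < 1:
            raise ValueError("need at least one group")
        if len(self.timepoints) == 0:
            raise ValueError("timepoints must be nonempty")
        t = np.asarray(self.timepoints)
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if self.mice_per_donor < 1:
            raise ValueError("mice_per_donor must be >= 1")
        for g in self.groups:
            if self.donors_for(g) < 1:
                raise ValueError("donors_per_group must be >= 1")

    def donors_for(self, group) -> int:
        if isinstance(self.donors_per_group, Mapping):
            return int(self.donors_per_group[group])
        return int(self.donors_per_group)

    @property
    def n_cells(self) -> int:
        return sum(
            self.donors_for(g) * self.mice_per_donor * len(self.timepoints)
            for g in self.groups
        )


@dataclass
class ValidationReport:
    n_records: int
    n_subjects: int
    n_clusters: int
    n_missing_cells: int | None
    issues: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_subjects": self.n_subjects,
            "n_clusters": self.n_clusters,
            "n_missing_cells": self.n_missing_cells,
            "issues": [{"severity": s, "message": m} for s, m in self.issues],
        }

    def to_text(self) -> str:
        lines = [
            f"records:       {self.n_records}",
            f"subjects:      {self.n_subjects}",
            f"clusters:      {self.n_clusters}",
        ]
        if self.n_missing_cells is not None:
            lines.append(f"missing cells: {self.n_missing_cells}")
        if self.issues:
            lines.append("issues:")
            lines.extend(f"  [{s}] {m}" for s, m in self.issues)
        else:
            lines.append("issues:        none")
        return "\n".join(lines)


def load_long_csv(path, column_map: Mapping[str, str]) -> LongitudinalDataset:
    """Read a long-format CSV, mapping file columns onto canonical roles.

    ``column_map`` maps roles (``response``, ``time``, ``group``, ``subject``
    and optionally ``cluster``) to the column names in the file. Rows with a
    missing response or time are dropped and counted in ``n_dropped``.
    """
    required = {"response", "time", "group", "subject"}
    missing_roles = required - set(column_map)
    if missing_roles:
        raise SchemaError(f"column_map is missing roles: {sorted(missing_roles)}")
    raw = pd.read_csv(path, na_values=["NA", ""])
    missing_cols = [c for c in column_map.values() if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"CSV is missing columns: {missing_cols}")
    df = pd.DataFrame({role: raw[col] for role, col in column_map.items()})
    before = len(df)
    df = df.dropna(subset=["response", "time"])
    return LongitudinalDataset(df.reset_index(drop=True), n_dropped=before - len(df))


def write_long_csv(ds: LongitudinalDataset, path) -> None:
    ds.df.to_csv(path, index=False, na_rep="NA")


def build_design(grid: DesignGrid) -> LongitudinalDataset:
    """Fully crossed design skeleton (responses unset).

    One record per (group, donor, mouse, time) in deterministic ascending
    order. The Blanton layout — {3 healthy, 5 undernourished} donors x 5 mice
    x 12 days — yields 480 records.
    """
    rows = []
    for g in grid.groups:
        for d in range(1, grid.donors_for(g) + 1):
            donor = f"{g}:d{d}"
            for m in range(1, grid.mice_per_donor + 1):
                mouse = f"{donor}:m{m}"
                for t in grid.timepoints:
                    rows.append((mouse, donor, g, t, np.nan))
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return LongitudinalDataset(df)


def apply_missingness(
    ds: LongitudinalDataset, n_missing: int, seed: int, max_tries: int = 1000
) -> LongitudinalDataset:
    """Remove exactly ``n_missing`` records completely at random (MCAR).

    The draw is reproducible for a fixed seed. Draws that would remove every
    record of some subject are rejected and redrawn within the same seed
    stream; if no feasible draw is found the request is infeasible.
    """
    if not 0 <= n_missing < ds.n_records:
        raise ValueError("need 0 <= n_missing < n_records")
    if n_missing == 0:
        return LongitudinalDataset(ds.df.copy(), n_dropped=ds.n_dropped)
    rng = np.random.default_rng(seed)
    counts = ds.df.groupby("subject", observed=True)["time"].size()
    for _ in range(max_tries):
        drop = rng.choice(ds.n_records, size=n_missing, replace=False)
        dropped_per_subject = ds.df.iloc[drop].groupby("subject", observed=True)["time"].size()
        if (counts.loc[dropped_per_subject.index] > dropped_per_subject).all():
            kept = ds.df.drop(index=ds.df.index[drop]).reset_index(drop=True)
            return LongitudinalDataset(kept)
    raise ValueError(
        f"could not remove {n_missing} records without emptying a subject"
    )


def validate_dataset(
    ds: LongitudinalDataset, grid: DesignGrid | None = None
) -> ValidationReport:
    """Summarise a dataset and report potential modelling issues.

    Never mutates the dataset. When a design grid is declared, the number of
    missing cells is the grid size minus the number of records.
    """
    issues: list[tuple[str, str]] = []
    df = ds.df
    n_missing = None
    if grid is not None:
        n_missing = grid.n_cells - ds.n_records
        if n_missing < 0:
            issues.append(("error", "dataset has more records than grid cells"))
    if len(ds.timepoints) < 2:
        issues.append(("warning", "fewer than 2 distinct time values overall"))
    singletons = (
        df.groupby("subject", observed=True)["time"].nunique().pipe(lambda s: s[s < 2])
    )
    for subj in singletons.index:
        issues.append(
            ("warning", f"subject {subj!r} has a single time point; "
                        "its slope is unidentifiable")
        )
    resp = df["response"].to_numpy(dtype=float)
    if np.isnan(resp).any() and not np.isnan(resp).all():
        issues.append(("warning", f"{int(np.isnan(resp).sum())} missing responses"))
    finite = df[np.isfinite(resp)]
    if len(finite):
        # deviations from the per-time median, so trends are not flagged
        dev = (finite["response"]
               - finite.groupby("time")["response"].transform("median"))
        mad = np.median(np.abs(dev))
        scale = 1.4826 * mad if mad > 0 else float(dev.std())
        if scale > 0:
            n_extreme = int((dev.abs() > 6 * scale).sum())
            if n_extreme:
                issues.append(
                    ("warning", f"{n_extreme} extreme response values "
                                "(>6 robust SD from the per-time median)")
                )
    if len(ds.group_levels) < 2:
        issues.append(("warning", "only one group level present"))
    return ValidationReport(
        n_records=ds.n_records,
        n_subjects=ds.n_subjects,
        n_clusters=ds.n_clusters,
        n_missing_cells=n_missing,
        issues=issues,
    )
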