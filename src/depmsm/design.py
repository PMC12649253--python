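"""Stacked counting-process design for multi-state hazard regression.

Each subject contributes, for every transition path h -> g out of every state
h they occupy, one interval record (entry, exit, status) with delayed entry at
the time the origin state was entered.  Event times are placed at the wave
where the destination state is first observed (the panel design only sees
states at scheduled visits).  Records across all paths are stacked into one
table; a coefficient-sharing map assigns each path to a coefficient group
(default: the remission paths 2->4 and 3->4 share one block), while baseline
hazards stay stratified by path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .cesd import OUT_PATHS, TRANSITION_PATHS, StateSequence

DEFAULT_GROUPS = (("12",), ("23",), ("24", "34"), ("45",))


def group_label(paths: Sequence[str]) -> str:
    return "+".join(paths)


@dataclass(frozen=True)
class TransitionStructure:
    """Permissible paths, coefficient-sharing groups and baseline strata.

    ``paths`` defaults to the full five-path set; a subset is allowed for
    reduced designs (e.g. a single-transition simulation study).  Groups and
    strata must each partition ``paths``.
    """

    paths: tuple[str, ...] = TRANSITION_PATHS
    coefficient_groups: tuple[tuple[str, ...], ...] = DEFAULT_GROUPS
    baseline_strata: tuple[tuple[str, ...], ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.baseline_strata is None:
            object.__setattr__(self, "baseline_strata", tuple((p,) for p in self.paths))
        unknown = set(self.paths) - set(TRANSITION_PATHS)
        if unknown:
            raise ConfigurationError(f"unknown transition paths {sorted(unknown)}")
        groups = tuple(tuple(g) for g in self.coefficient_groups)
        if set(self.paths) != {p for p in self.paths}:  # pragma: no cover - tuples unique
            raise ConfigurationError("duplicate paths")
        # allow the default group map to be used with a subset of paths
        groups = tuple(tuple(p for p in g if p in self.paths) for g in groups)
        groups = tuple(g for g in groups if g)
        object.__setattr__(self, "coefficient_groups", groups)
        for partition, name in ((groups, "coefficient_groups"), (self.baseline_strata, "baseline_strata")):
            flat = [p for part in partition for p in part]
            if sorted(flat) != sorted(self.paths):
                raise ConfigurationError(f"{name} must partition the path set exactly once")

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(group_label(g) for g in self.coefficient_groups)

    def group_of(self, path: str) -> str:
        for g in self.coefficient_groups:
            if path in g:
                return group_label(g)
        raise ConfigurationError(f"path {path} not covered by any coefficient group")


@dataclass(frozen=True)
class TransitionRecord:
    """One counting-process row: subject at risk for path h->g on (entry, exit]."""

    subject_id: object
    path: str
    entry: float
    exit: float
    status: int

    def __post_init__(self) -> None:
        if not self.entry < self.exit:
            raise DataError(f"record for {self.subject_id}/{self.path} has entry >= exit")
        if self.status not in (0, 1):
            raise DataError("status must be 0 or 1")


@dataclass
class StackedDesign:
    """All transition records with covariates, ready for the stacked fit.

    ``table`` is a long DataFrame (subject_id, path, group, entry, exit,
    status, covariate columns); ``n`` is the number of distinct subjects and
    ``p`` the covariate count shared across coefficient groups.
    """

    table: pd.DataFrame
    covariate_names: tuple[str, ...]
    structure: TransitionStructure
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = int(self.table["subject_id"].nunique())

    @property
    def p(self) -> int:
        return len(self.covariate_names)

    def path_table(self, path: str) -> pd.DataFrame:
        if path not in self.structure.paths:
            raise DataError(f"unknown path {path!r}")
        return self.table[self.table["path"] == path]

    def event_counts(self) -> dict[str, int]:
        tab = self.table
        return {
            path: int(tab.loc[(tab["path"] == path) & (tab["status"] == 1)].shape[0])
            for path in self.structure.paths
        }


def _records_for_sequence(seq: StateSequence, paths: Sequence[str]) -> list[TransitionRecord]:
    """Occupancy-interval records for one subject.

    Contiguous censored intervals in the same origin state are merged, so a
    never-transitioning subject yields a single record per outgoing path.
    """
    open_records: dict[str, list] = {}  # path -> [entry, exit, status]

    def open_state(state: int, time: float) -> None:
        for path in OUT_PATHS[state]:
            if path in paths:
                open_records[path] = [time, time, 0]

    records: list[TransitionRecord] = []

    def close_all() -> None:
        for path, (entry, exit_, status) in open_records.items():
            if exit_ > entry:
                records.append(TransitionRecord(seq.subject_id, path, entry, exit_, status))
        open_records.clear()

    open_state(seq.states[0], seq.wave_times[0])
    for k in range(len(seq.states) - 1):
        h, g, t_next = seq.states[k], seq.states[k + 1], seq.wave_times[k + 1]
        if h == g:
            for rec in open_records.values():
                rec[1] = t_next
        else:
            if f"{h}{g}" not in TRANSITION_PATHS:
                raise DataError(f"forbidden transition {h}->{g} for subject {seq.subject_id}")
            for path, rec in open_records.items():
                rec[1] = t_next
                if path == f"{h}{g}":
                    rec[2] = 1
            close_all()
            open_state(g, t_next)
    close_all()
    return records


def build_transition_records(
    sequences: Iterable[StateSequence],
    covariates: pd.DataFrame,
    structure: TransitionStructure | None = None,
) -> StackedDesign:
    """Stack per-subject occupancy records with baseline covariates.

    ``covariates`` is the model matrix (one row per subject, indexed by or
    carrying ``subject_id``); covariate values are baseline-fixed.
    """
    structure = structure or TransitionStructure()
    if "subject_id" in covariates.columns:
        covariates = covariates.set_index("subject_id")
    covariate_names = tuple(covariates.columns)
    rows = []
    for seq in sequences:
        if seq.subject_id not in covariates.index:
            raise DataError(f"no covariates for subject {seq.subject_id}")
        xrow = covariates.loc[seq.subject_id]
        for rec in _records_for_sequence(seq, structure.paths):
            rows.append(
                (rec.subject_id, rec.path, structure.group_of(rec.path), rec.entry, rec.exit, rec.status)
                + tuple(xrow.to_numpy(dtype=float))
            )
    table = pd.DataFrame(
        rows, columns=["subject_id", "path", "group", "entry", "exit", "status", *covariate_names]
    )
    return StackedDesign(table, covariate_names, structure)


def design_from_latent(
    latent_paths: Sequence[Sequence[tuple[float, int, int]]],
    subject_ids: Sequence,
    horizon: float,
    covariates: pd.DataFrame,
    structure: TransitionStructure | None = None,
) -> StackedDesign:
    """Design built from exact latent jump times instead of wave-censored ones.

    ``latent_paths[i]`` is subject i's jump list [(time, from_state, to_state),
    ...].  Event times are then continuous and almost surely distinct, which is
    the natural setting for cross-checking against standard Cox software.
    """
    structure = structure or TransitionStructure()
    if "subject_id" in covariates.columns:
        covariates = covariates.set_index("subject_id")
    covariate_names = tuple(covariates.columns)
    rows = []
    for sid, jumps in zip(subject_ids, latent_paths):
        xrow = tuple(covariates.loc[sid].to_numpy(dtype=float))
        state, t0 = 1, 0.0
        for t, h, g in jumps:
            if t > horizon:
                break
            for path in OUT_PATHS[state]:
                if path in structure.paths and t > t0:
                    status = 1 if path == f"{h}{g}" else 0
                    rows.append((sid, path, structure.group_of(path), t0, t, status) + xrow)
            state, t0 = g, t
        if t0 < horizon and OUT_PATHS[state]:
            for path in OUT_PATHS[state]:
                if path in structure.paths:
                    rows.append((sid, path, structure.group_of(path), t0, horizon, 0) + xrow)
    table = pd.DataFrame(
        rows, columns=["subject_id", "path", "group", "entry", "exit", "status", *covariate_names]
    )
    return StackedDesign(table, covariate_names, structure)


def risk_set(design: StackedDesign, path: str, time: float) -> set:
    """Subjects at risk for ``path`` just before ``time``: entry < t <= exit."""
    if path not in TRANSITION_PATHS:
        raise DataError(f"unknown path {path!r}")
    tab = design.table
    mask = (tab["path"] == path) & (tab["entry"] < time) & (time <= tab["exit"])
    return set(tab.loc[mask, "subject_id"])


def write_stacked(design: StackedDesign, path) -> None:
    design.table.to_csv(path, index=False, float_format="%.10g")


def read_stacked(path, structure: TransitionStructure | None = None) -> StackedDesign:
    table = pd.read_csv(path)
    meta = ("subject_id", "path", "group", "entry", "exit", "status")
    covariate_names = tuple(c for c in table.columns if c not in meta)
    table["path"] = table["path"].astype(str)
    table["group"] = table["group"].astype(str)
    return StackedDesign(table, covariate_names, structure or TransitionStructure())
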