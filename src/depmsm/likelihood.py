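"""Stacked Cox partial likelihood over transition strata.

The objective is the (1/n)-scaled negative log partial likelihood summed over
all transition paths, with each path its own baseline stratum and delayed
entry defining the risk sets.  Ties (many events share a wave time) are
handled with the Breslow approximation: every event at a tied time is
compared against the same risk set, so the contribution at time t with d tied
events is  d * log(sum_{j in R(t)} exp(eta_j)) - sum_{events at t} eta_i.
Coefficient vectors are shared across the paths of a coefficient group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._errors import DataError
from .design import StackedDesign


@dataclass
class PathData:
    """Precomputed per-stratum arrays: design matrix, risk-set masks and tied
    event sums at each distinct event time."""

    path: str
    X: np.ndarray          # (m, p) covariate rows
    entry: np.ndarray
    exit: np.ndarray
    status: np.ndarray
    event_times: np.ndarray            # distinct, sorted
    d: np.ndarray                      # tied event count per event time
    event_eta_index: list[np.ndarray]  # row indices of events at each time
    risk_masks: np.ndarray             # (K, m) boolean
    s: np.ndarray                      # (K, p) sum of X over events at each time

    @property
    def n_events(self) -> int:
        return int(self.d.sum())


def build_path_data(design: StackedDesign, path: str) -> PathData:
    tab = design.path_table(path)
    X = tab[list(design.covariate_names)].to_numpy(dtype=float)
    entry = tab["entry"].to_numpy(dtype=float)
    exit_ = tab["exit"].to_numpy(dtype=float)
    status = tab["status"].to_numpy(dtype=int)
    event_times = np.unique(exit_[status == 1])
    masks = np.empty((len(event_times), len(entry)), dtype=bool)
    d = np.empty(len(event_times), dtype=int)
    ev_idx = []
    s = np.empty((len(event_times), X.shape[1]))
    for k, t in enumerate(event_times):
        masks[k] = (entry < t) & (t <= exit_)
        idx = np.flatnonzero((status == 1) & (exit_ == t))
        ev_idx.append(idx)
        d[k] = len(idx)
        s[k] = X[idx].sum(axis=0)
        if not masks[k].any():
            raise DataError(f"empty risk set for path {path} at time {t}")
    return PathData(path, X, entry, exit_, status, event_times, d, ev_idx, masks, s)


@dataclass
class GroupData:
    """All strata sharing one coefficient vector."""

    label: str
    paths: list[PathData]

    @property
    def n_events(self) -> int:
        return sum(pd.n_events for pd in self.paths)

    @property
    def p(self) -> int:
        return self.paths[0].X.shape[1]


def build_group_data(design: StackedDesign) -> dict[str, GroupData]:
    """Group the per-path precomputations by coefficient-sharing group."""
    out = {}
    for group in design.structure.coefficient_groups:
        label = "+".join(group)
        out[label] = GroupData(label, [build_path_data(design, p) for p in group])
    return out


def _path_terms(beta: np.ndarray, pdat: PathData, order: int = 2):
    """(value, grad, hess) of one stratum's unscaled negative log PL."""
    eta = pdat.X @ beta
    value = 0.0
    grad = np.zeros_like(beta) if order >= 1 else None
    hess = np.zeros((len(beta), len(beta))) if order >= 2 else None
    for k in range(len(pdat.event_times)):
        mask = pdat.risk_masks[k]
        eta_r = eta[mask]
        m = eta_r.max()
        w = np.exp(eta_r - m)
        W = w.sum()
        value += pdat.d[k] * (np.log(W) + m) - eta[pdat.event_eta_index[k]].sum()
        if order >= 1:
            Xr = pdat.X[mask]
            xw = w @ Xr
            mu = xw / W
            grad += pdat.d[k] * mu - pdat.s[k]
            if order >= 2:
                hess += pdat.d[k] * ((Xr * w[:, None]).T @ Xr / W - np.outer(mu, mu))
    return value, grad, hess


def group_nll(beta: np.ndarray, group: GroupData, n: int, order: int = 2):
    """(value, gradient, Hessian) of one group's (1/n)-scaled objective."""
    value, grad, hess = 0.0, None, None
    for pdat in group.paths:
        v, g, h = _path_terms(beta, pdat, order=order)
        value += v
        if order >= 1:
            grad = g if grad is None else grad + g
        if order >= 2:
            hess = h if hess is None else hess + h
    value /= n
    if order >= 1:
        grad = grad / n
    if order >= 2:
        hess = hess / n
    return value, grad, hess


def neg_log_partial_likelihood(
    beta: Mapping[str, np.ndarray], design: StackedDesign, order: int = 2
):
    """Total stacked objective with per-group gradient and Hessian.

    ``beta`` maps each coefficient-group label to its coefficient vector.
    Returns (value, {group: gradient}, {group: Hessian}); the total value is
    the sum of the per-group (1/n)-scaled contributions, so with singleton
    groups it coincides with the sum of independent per-path objectives.
    """
    groups = build_group_data(design)
    missing = set(groups) - set(beta)
    if missing:
        raise DataError(f"beta missing coefficient groups {sorted(missing)}")
    value = 0.0
    grads: dict[str, np.ndarray] = {}
    hessians: dict[str, np.ndarray] = {}
    for label, gdat in groups.items():
        b = np.asarray(beta[label], dtype=float)
        if b.shape != (design.p,):
            raise DataError(f"beta for group {label} has shape {b.shape}, expected ({design.p},)")
        v, g, h = group_nll(b, gdat, design.n, order=order)
        value += v
        if order >= 1:
            grads[label] = g
        if order >= 2:
            hessians[label] = h
    if order == 0:
        return value
    if order == 1:
        return value, grads
    return value, grads, hessians
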