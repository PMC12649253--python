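"""Seeded synthetic cohorts for the depressive-symptom multi-state pipeline.

The generator emulates the structure of a CHARLS-like aging panel: ~4,000
subjects, four scheduled waves (default years 0, 2, 4, 7, matching biennial
surveys 2011/2013/2015/2018), baseline covariates with the published
marginals, and a latent continuous-time Markov process over the five symptom
states whose transition intensities follow the proportional-hazards model

    lambda_{i,hg}(t) = lambda_{0,hg} * exp(beta_hg' x_i),

with constant baseline intensities (the semiparametric baseline of the
analysis model is replaced by a constant for simulation, so closed-form
calibration checks are available) on the clock-forward time scale.  The
latent process respects the path set {1->2, 2->3, 2->4, 3->4, 4->5}; state 5
is absorbing.

Observation is wave-censored: only the wave-time symptomatic indicator
(latent state in {2,3,5}) is visible, and the observed state sequence is the
state-classification rule applied to that indicator — exactly what the CES-D
classifier recovers from emitted scores, which makes the emit -> classify
round trip exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .cesd import (
    OUT_PATHS,
    SYMPTOM_CUTOFF,
    SYMPTOMATIC_STATES,
    StateSequence,
    states_from_symptomatic,
)
from .prep import build_model_matrix
from .published import (
    COVARIATE_MARGINALS,
    INTERACTION_PAIRS,
    MODEL_TERMS,
    default_true_betas,
)

#: default constant baseline intensities (per year), chosen once so that the
#: default cohort produces event frequencies of the same order as the
#: published cohort (episodes in roughly a third of subjects, with
#: persistence, remission and relapse in the published proportions).
DEFAULT_BASELINE_RATES = {
    "12": 0.12,
    "23": 0.15,
    "24": 0.50,
    "34": 0.56,
    "45": 0.18,
}


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one baseline covariate.

    Binary covariates are Bernoulli(proportion); continuous ones are normal
    (mean, sd) clipped to ``bounds``.
    """

    name: str
    kind: str
    proportion: float | None = None
    mean: float | None = None
    sd: float | None = None
    bounds: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ConfigurationError(f"covariate {self.name}: kind must be binary or continuous")
        if self.kind == "binary":
            if self.proportion is None or not 0.0 <= self.proportion <= 1.0:
                raise ConfigurationError(f"covariate {self.name}: proportion outside [0,1]")
        else:
            if self.mean is None or self.sd is None or self.sd < 0:
                raise ConfigurationError(f"covariate {self.name}: needs mean and non-negative sd")


def default_covariate_specs() -> tuple[CovariateSpec, ...]:
    specs = []
    for name, m in COVARIATE_MARGINALS.items():
        if m["kind"] == "binary":
            specs.append(CovariateSpec(name, "binary", proportion=m["proportion"]))
        else:
            specs.append(
                CovariateSpec(name, "continuous", mean=m["mean"], sd=m["sd"], bounds=m["bounds"])
            )
    return tuple(specs)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort (all randomness seeded)."""

    n_subjects: int = 4000
    wave_times: tuple[float, ...] = (0.0, 2.0, 4.0, 7.0)
    covariate_specs: tuple[CovariateSpec, ...] = field(default_factory=default_covariate_specs)
    interactions: tuple[tuple[str, str], ...] = INTERACTION_PAIRS
    true_betas: dict[str, np.ndarray] = field(default_factory=default_true_betas)
    baseline_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    missing_item_rate: float = 0.0
    emit_items: bool = True
    center_interactions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        wt = tuple(float(t) for t in self.wave_times)
        if len(wt) < 2 or any(t < 0 for t in wt) or any(b <= a for a, b in zip(wt, wt[1:])):
            raise ConfigurationError("wave_times must be >= 2 non-negative strictly increasing times")
        object.__setattr__(self, "wave_times", wt)
        bad = set(self.baseline_rates) - {"12", "23", "24", "34", "45"}
        if bad:
            raise ConfigurationError(f"unknown baseline-rate paths {sorted(bad)}")
        if any(r < 0 for r in self.baseline_rates.values()):
            raise ConfigurationError("baseline rates must be non-negative")
        if not 0.0 <= self.missing_item_rate <= 1.0:
            raise ConfigurationError("missing_item_rate must lie in [0,1]")
        p = len(self.covariate_specs) + len(self.interactions)
        for group, beta in self.true_betas.items():
            beta = np.asarray(beta, dtype=float)
            if beta.shape != (p,):
                raise ConfigurationError(
                    f"true_betas[{group}] has length {beta.shape}, expected ({p},) after interaction expansion"
                )
            object.__setattr__(self, "true_betas", {**self.true_betas, group: beta})

    @property
    def model_terms(self) -> tuple[str, ...]:
        mains = tuple(s.name for s in self.covariate_specs)
        return mains + tuple(f"{a}_x_{b}" for a, b in self.interactions)

    def group_of_path(self, path: str) -> str | None:
        for group in self.true_betas:
            if path in group.split("+"):
                return group
        return None


def default_cohort_spec(n_subjects: int = 4000, seed: int = 0, **overrides) -> CohortSpec:
    """The default study-like cohort: published covariate marginals, published
    coefficient estimates as true effects, calibrated baseline intensities."""
    return replace(CohortSpec(n_subjects=n_subjects, seed=seed), **overrides)


def _rng(spec: CohortSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), stage]))


def generate_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Baseline covariate table, one row per subject (subject_id + columns)."""
    rng = _rng(spec, 1)
    n = spec.n_subjects
    data = {"subject_id": np.arange(n)}
    for cov in spec.covariate_specs:
        if cov.kind == "binary":
            data[cov.name] = (rng.random(n) < cov.proportion).astype(int)
        else:
            draws = rng.normal(cov.mean, cov.sd, size=n)
            data[cov.name] = np.clip(draws, cov.bounds[0], cov.bounds[1])
    return pd.DataFrame(data)


def model_matrix(spec: CohortSpec, covariates: pd.DataFrame) -> pd.DataFrame:
    """Design-scale covariates: continuous columns min-max normalized, then
    interaction products — the scale on which true_betas act and on which the
    fitting pipeline operates."""
    continuous = [c.name for c in spec.covariate_specs if c.kind == "continuous"]
    return build_model_matrix(
        covariates,
        normalize_columns=continuous,
        interactions=spec.interactions,
        center_interactions=spec.center_interactions,
    )


@dataclass
class SimulatedCohort:
    """Latent histories and wave-censored observations of one cohort."""

    spec: CohortSpec
    covariates: pd.DataFrame
    model: pd.DataFrame                    # subject_id-indexed design matrix
    latent: list[list[tuple[float, int, int]]]   # per subject: (time, from, to)
    observed: np.ndarray                   # (n_subjects, n_waves) state labels

    @property
    def sequences(self) -> list[StateSequence]:
        ids = self.covariates["subject_id"].to_numpy()
        return [
            StateSequence(int(sid), self.spec.wave_times, tuple(int(s) for s in row))
            for sid, row in zip(ids, self.observed)
        ]


def simulate_state_paths(covariates: pd.DataFrame, spec: CohortSpec) -> SimulatedCohort:
    """Simulate latent multi-state histories and wave-censored observations.

    The latent process is a continuous-time Markov chain started in state 1
    with intensities baseline_rate[hg] * exp(beta_group(hg)' x_i).  The
    observed sequence applies the symptom classifier to the wave-time
    symptomatic indicator, so it is closed under the permissible path set by
    construction.
    """
    if len(covariates) != spec.n_subjects:
        raise ConfigurationError("covariate row count differs from n_subjects")
    rng = _rng(spec, 2)
    mm = model_matrix(spec, covariates)
    X = mm.to_numpy(dtype=float)
    n = spec.n_subjects
    horizon = spec.wave_times[-1]

    # per-subject intensity for every path (zero when unparameterized)
    rates = {}
    for path in ("12", "23", "24", "34", "45"):
        base = spec.baseline_rates.get(path, 0.0)
        group = spec.group_of_path(path)
        if base > 0 and group is not None:
            rates[path] = base * np.exp(X @ np.asarray(spec.true_betas[group], dtype=float))
        else:
            rates[path] = np.full(n, float(base))

    state = np.ones(n, dtype=int)
    now = np.zeros(n)
    done = np.zeros(n, dtype=bool)
    latent: list[list[tuple[float, int, int]]] = [[] for _ in range(n)]
    while not done.all():
        progressed = False
        for s in (1, 2, 3, 4):
            idx = np.flatnonzero((state == s) & ~done)
            if idx.size == 0:
                continue
            out = [p for p in OUT_PATHS[s]]
            rmat = np.stack([rates[p][idx] for p in out], axis=1) if out else np.zeros((idx.size, 0))
            total = rmat.sum(axis=1)
            stuck = total <= 0
            done[idx[stuck]] = True
            live = idx[~stuck]
            if live.size == 0:
                continue
            progressed = True
            total_live = total[~stuck]
            dt = rng.exponential(1.0 / total_live)
            t_new = now[live] + dt
            over = t_new > horizon
            done[live[over]] = True
            now[live[over]] = horizon
            jumpers = live[~over]
            if jumpers.size:
                u = rng.random(jumpers.size) * total_live[~over]
                cum = np.cumsum(rmat[~stuck][~over], axis=1)
                choice = (u[:, None] > cum).sum(axis=1)
                for j, sub in enumerate(jumpers):
                    path = out[choice[j]]
                    latent[sub].append((float(t_new[~over][j]), s, int(path[1])))
                now[jumpers] = t_new[~over]
                state[jumpers] = [int(out[c][1]) for c in choice]
        if not progressed:
            break
    # absorbing or outflow-free leftovers
    done[:] = True

    wave_times = np.asarray(spec.wave_times)
    observed = np.empty((n, len(wave_times)), dtype=int)
    for i in range(n):
        s, j = 1, 0
        jumps = latent[i]
        for k, t in enumerate(wave_times):
            while j < len(jumps) and jumps[j][0] <= t:
                s = jumps[j][2]
                j += 1
            observed[i, k] = s
        # restart scan for next subject
        symptomatic = [observed[i, k] in SYMPTOMATIC_STATES for k in range(len(wave_times))]
        observed[i] = states_from_symptomatic(symptomatic)
    return SimulatedCohort(spec, covariates.reset_index(drop=True), mm, latent, observed)


def _decompose_total(total: int, rng: np.random.Generator) -> np.ndarray:
    """Random 10-item composition (post-reversal scale, each item in 0..3)
    summing to ``total``."""
    items = np.zeros(10, dtype=int)
    for _ in range(total):
        open_items = np.flatnonzero(items < 3)
        items[open_items[rng.integers(open_items.size)]] += 1
    return items


def emit_cesd_scores(sim: SimulatedCohort) -> pd.DataFrame:
    """Wave-level panel with CES-D totals consistent with the observed states.

    Symptomatic waves (states 2, 3, 5) draw a total uniformly from [12, 30],
    others from [0, 11].  With ``emit_items`` the total is decomposed into 10
    item responses (the two positively-worded items stored pre-reversal);
    ``missing_item_rate`` masks individual items (at most two per wave, and
    only where rounded person-mean imputation preserves the wave's
    symptomatic status, keeping classification of the emitted panel exact).
    """
    spec = sim.spec
    rng = _rng(spec, 3)
    n, n_waves = sim.observed.shape
    rows = []
    from .cesd import REVERSED_ITEMS, score_cesd  # local to avoid cycle at import time

    for i in range(n):
        sid = int(sim.covariates["subject_id"].iloc[i])
        for k in range(n_waves):
            symptomatic = sim.observed[i, k] in SYMPTOMATIC_STATES
            total = int(rng.integers(SYMPTOM_CUTOFF, 31)) if symptomatic else int(
                rng.integers(0, SYMPTOM_CUTOFF)
            )
            row = [sid, k + 1, spec.wave_times[k], total]
            if spec.emit_items:
                post = _decompose_total(total, rng)
                raw = post.astype(float).copy()
                for j in REVERSED_ITEMS:
                    raw[j] = 3 - raw[j]
                if spec.missing_item_rate > 0:
                    mask = np.flatnonzero(rng.random(10) < spec.missing_item_rate)[:2]
                    if mask.size:
                        cand = raw.copy()
                        cand[mask] = np.nan
                        rescored = score_cesd(cand.tolist())
                        if (rescored >= SYMPTOM_CUTOFF) == symptomatic:
                            raw = cand
                row.extend(raw.tolist())
            rows.append(row)
    cols = ["subject_id", "wave_index", "wave_time", "cesd_total"]
    if spec.emit_items:
        cols += [f"item_{j}" for j in range(1, 11)]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(sim: SimulatedCohort, panel: pd.DataFrame, out_dir) -> None:
    """Write covariates.csv and panel.csv under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.covariates.to_csv(out / "covariates.csv", index=False, float_format="%.10g")
    panel.to_csv(out / "panel.csv", index=False, float_format="%.10g")
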