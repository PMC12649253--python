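"""Effect reporting: transition rate ratios, Wald confidence limits,
significance stars, and onset-age summaries.

A transition rate ratio (TRR) is the exponentiated coefficient: the
multiplicative effect of a one-unit covariate change on a transition
intensity.  Confidence limits use the exact 0.975 normal quantile
(1.959964...), not 1.96.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError
from .adalasso import PenalizedFit, PostSelectionInference, significance_stars
from .cesd import StateSequence

Z_975 = float(stats.norm.ppf(0.975))

#: printing precision of the effect table.
DECIMALS = 4


def trr(est: float) -> float:
    """Transition rate ratio exp(est)."""
    return float(np.exp(est))


def trr_confidence_limits(est: float, se: float) -> tuple[float, float]:
    """95% Wald limits exp(est -/+ z * se) with z the exact 0.975 quantile."""
    if not se > 0:
        raise DataError("standard error must be positive")
    return float(np.exp(est - Z_975 * se)), float(np.exp(est + Z_975 * se))


def effect_table(
    terms: Sequence[str],
    fit: PenalizedFit,
    inference: PostSelectionInference,
    group_order: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tidy per-transition-block effect table.

    Selected coefficients carry the post-selection refit estimate with SE,
    TRR, 95% limits and stars; zeroed coefficients carry Est = 0 with blank
    inference columns, matching the reporting convention of published
    multi-state selection tables.  Values are rounded to 4 decimals.
    """
    rows = []
    groups = list(group_order) if group_order is not None else list(fit.beta_hat)
    for group in groups:
        active = set(int(i) for i in inference.active_set.get(group, []))
        refit = inference.beta_refit[group]
        se_map = {int(i): s for i, s in zip(inference.active_set[group], inference.se[group])}
        p_map = {int(i): p for i, p in zip(inference.active_set[group], inference.wald_p[group])}
        for r, term in enumerate(terms):
            if r in active:
                # round the estimate and SE first, then derive TRR and limits,
                # so the printed columns are exactly self-consistent
                est = round(float(refit[r]), DECIMALS)
                se = round(float(se_map[r]), DECIMALS)
                lo, hi = trr_confidence_limits(est, se)
                rows.append(
                    (group, term, est, se,
                     round(trr(est), DECIMALS), round(lo, DECIMALS), round(hi, DECIMALS),
                     significance_stars(p_map[r]))
                )
            else:
                rows.append((group, term, 0.0, np.nan, np.nan, np.nan, np.nan, ""))
    return pd.DataFrame(
        rows, columns=["group", "term", "est", "se", "trr", "cl_low", "cl_high", "sig"]
    )


def write_effect_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=f"%.{DECIMALS}f")


def read_effect_table(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True, na_values=[""]).fillna({"sig": ""})


def onset_age_summary(
    sequences: Iterable[StateSequence],
    baseline_ages: Mapping[object, float],
    cutoff: float = 60.0,
):
    """Distribution of age at first symptom episode, by state ever reached.

    Onset age is baseline age plus the time of the first 1->2 event; subjects
    with no episode are excluded (onset age undefined for the censored).  For
    each state 2..5 the summary covers the subjects who ever occupied it,
    with early (< cutoff) / late (>= cutoff) onset counts; the default
    boundary is 60 years with late onset at or above it.

    Returns (summary DataFrame, {state: onset-age array}).
    """
    ages_by_state: dict[int, list[float]] = {2: [], 3: [], 4: [], 5: []}
    for seq in sequences:
        onset_time = next((t for path, t in seq.events if path == "12"), None)
        if onset_time is None:
            continue
        onset_age = float(baseline_ages[seq.subject_id]) + onset_time
        for state in set(seq.states) & {2, 3, 4, 5}:
            ages_by_state[state].append(onset_age)
    rows = []
    out: dict[int, np.ndarray] = {}
    for state in (2, 3, 4, 5):
        ages = np.asarray(ages_by_state[state], dtype=float)
        out[state] = ages
        if ages.size:
            rows.append(
                (state, ages.size, float(ages.mean()), int((ages < cutoff).sum()),
                 int((ages >= cutoff).sum()))
            )
        else:
            rows.append((state, 0, np.nan, 0, 0))
    summary = pd.DataFrame(
        rows, columns=["state", "n", "mean_onset_age", "early_onset", "late_onset"]
    )
    return summary, out
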