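"""Covariate preparation for the multi-state fit.

Quantitative covariates (age, income, number of chronic conditions by
default) are min-max normalized to [0,1] before modeling; outliers are
flagged (optionally winsorized) by the scaled median-absolute-deviation rule;
missing covariate entries are completed by chained-equation imputation
(columns missing above a cap are excluded instead, mirroring the study's
exclusion rule); interaction candidates are built as products of the
normalized main effects and screened by a marginal partial-likelihood score
utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError, ExclusionError

#: normal-consistency constant for the MAD scale estimate.
MAD_SCALE = 1.4826

DEFAULT_NORMALIZE = ("age", "income", "n_conditions")
DEFAULT_INTERACTIONS = (
    ("education", "income"),
    ("n_conditions", "income"),
    ("n_conditions", "sex"),
    ("sex", "age"),
    ("age", "education"),
)


@dataclass
class PreprocessConfig:
    normalize_columns: tuple[str, ...] = DEFAULT_NORMALIZE
    mad_k: float = 3.0
    mad_action: str = "flag"            # or "winsorize"
    impute_max_missing_rate: float = 0.30
    interaction_candidates: tuple[tuple[str, str], ...] = DEFAULT_INTERACTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mad_k <= 0:
            raise ConfigurationError("mad_k must be positive")
        if not 0.0 < self.impute_max_missing_rate <= 1.0:
            raise ConfigurationError("impute_max_missing_rate must lie in (0,1]")
        if self.mad_action not in ("flag", "winsorize"):
            raise ConfigurationError("mad_action must be 'flag' or 'winsorize'")


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """(x - min)/(max - min); requires at least two distinct finite values."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or np.nanmax(finite) == np.nanmin(finite):
        raise DataError("min-max normalization needs >= 2 distinct finite values")
    lo, hi = np.nanmin(finite), np.nanmax(finite)
    return (x - lo) / (hi - lo)


def mad_outliers(values: Sequence[float], config: PreprocessConfig | None = None):
    """MAD-rule outlier flags: |x - median| > k * 1.4826 * MAD.

    Returns (flags, column): the column is winsorized to the rule's boundary
    when ``mad_action == 'winsorize'``, otherwise returned unchanged.  A zero
    MAD with non-constant data cannot scale deviations; the rule then flags
    nothing and warns.
    """
    config = config or PreprocessConfig()
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError("MAD outlier rule needs >= 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        if np.unique(x).size > 1:
            warnings.warn("zero MAD with non-constant data; flagging no outliers", stacklevel=2)
        return np.zeros(x.size, dtype=bool), x.copy()
    radius = config.mad_k * MAD_SCALE * mad
    flags = np.abs(x - med) > radius
    out = x.copy()
    if config.mad_action == "winsorize":
        out = np.clip(out, med - radius, med + radius)
    return flags, out


def chained_impute(table: pd.DataFrame, config: PreprocessConfig | None = None,
                   n_sweeps: int = 10) -> pd.DataFrame:
    """Multivariate imputation by chained equations (single completed table).

    Delegates to the chained-equation engine in statsmodels (predictive mean
    matching per column, which keeps binary columns in {0,1}).  Columns whose
    missing rate exceeds ``impute_max_missing_rate`` raise ExclusionError —
    the study rule is to drop such covariates, not to impute them.  The sweep
    order and perturbation stream are seeded, so one seed gives one
    completion.
    """
    config = config or PreprocessConfig()
    rates = table.isna().mean()
    too_missing = rates[rates > config.impute_max_missing_rate]
    if len(too_missing):
        raise ExclusionError(
            "missing rate above cap for columns: "
            + ", ".join(f"{c} ({r:.0%})" for c, r in too_missing.items())
        )
    if not table.isna().to_numpy().any():
        return table.copy()
    from statsmodels.imputation.mice import MICEData

    np.random.seed(config.seed % (2**32 - 1))
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] != table.shape[1]:
        raise DataError("chained imputation expects an all-numeric table")
    mice = MICEData(numeric)
    mice.update_all(n_sweeps)
    completed = mice.data.copy()
    completed.index = table.index
    return completed


def build_model_matrix(
    covariates: pd.DataFrame,
    normalize_columns: Iterable[str] = DEFAULT_NORMALIZE,
    interactions: Iterable[tuple[str, str]] = DEFAULT_INTERACTIONS,
    center_interactions: bool = False,
) -> pd.DataFrame:
    """Design matrix: normalized mains followed by interaction products.

    Interaction columns are products of the already-normalized factors, so
    for non-negative inputs they stay inside [0,1].  With
    ``center_interactions`` the factors are mean-centered before
    multiplying, which decorrelates the products from their parent main
    effects (useful in simulation studies where the identifiability of main
    effects matters; the default reporting pipeline keeps raw products, whose
    coefficients match the published parameterization).  The returned frame
    is indexed by subject_id when present.
    """
    df = covariates.copy()
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    for col in normalize_columns:
        if col in df.columns:
            x = df[col].to_numpy(dtype=float)
            lo, hi = np.nanmin(x), np.nanmax(x)
            if hi > lo:
                df[col] = (x - lo) / (hi - lo)
    for a, b in interactions:
        if a not in df.columns or b not in df.columns:
            raise DataError(f"interaction ({a},{b}) references unknown column")
        if center_interactions:
            df[f"{a}_x_{b}"] = (df[a] - df[a].mean()) * (df[b] - df[b].mean())
        else:
            df[f"{a}_x_{b}"] = df[a] * df[b]
    return df


def screen_interactions(
    candidates: Sequence[tuple[str, str]],
    covariates: pd.DataFrame,
    sequences,
    k: int | None = None,
    normalize_columns: Iterable[str] = DEFAULT_NORMALIZE,
) -> list[tuple[str, str]]:
    """Rank interaction candidates by marginal association with the transitions.

    For each candidate product column the utility is the largest univariate
    partial-likelihood score statistic U(0)^2 / I(0) across transition paths
    (a model-free marginal screen; the screening method of the original
    analysis is not reproducible and this is the package's documented
    stand-in).  Candidates are deduplicated, ranked by decreasing utility and
    the top ``k`` (default: all) are returned.
    """
    from .design import TransitionStructure, build_transition_records
    from .likelihood import build_path_data

    seen = set()
    cands: list[tuple[str, str]] = []
    for pair in candidates:
        pair = tuple(pair)
        if pair not in seen:
            seen.add(pair)
            cands.append(pair)
    for a, b in cands:
        for col in (a, b):
            if col not in covariates.columns:
                raise DataError(f"interaction candidate references unknown column {col!r}")
    mm = build_model_matrix(covariates, normalize_columns=normalize_columns, interactions=cands)
    product_cols = [f"{a}_x_{b}" for a, b in cands]
    design = build_transition_records(sequences, mm[product_cols].reset_index(), TransitionStructure())
    utilities = np.zeros(len(cands))
    for path in design.structure.paths:
        pdat = build_path_data(design, path)
        if pdat.n_events == 0:
            continue
        # score statistic at beta = 0, one column at a time, vectorized
        U = np.zeros(len(cands))
        info = np.zeros(len(cands))
        for kk in range(len(pdat.event_times)):
            mask = pdat.risk_masks[kk]
            Xr = pdat.X[mask]
            mu = Xr.mean(axis=0)
            var = Xr.var(axis=0)
            U += pdat.s[kk] - pdat.d[kk] * mu
            info += pdat.d[kk] * var
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(info > 0, U * U / info, 0.0)
        utilities = np.maximum(utilities, stat)
    order = np.argsort(-utilities, kind="stable")
    ranked = [cands[i] for i in order]
    return ranked if k is None else ranked[: int(k)]
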