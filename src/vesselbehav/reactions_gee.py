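"""Reaction-time GEE analysis: per-event aggregation, model suite, Wald tests.

The response is the positive, continuous time (minutes) a group spent in
each (behavioral state, reaction) cell within an event while a vessel
was within the proximity radius.  Cells that were never observed are
simply absent — the gamma support excludes zero, so nothing is imputed.

Three nested marginal models are fitted by generalized estimating
equations with events as clusters, an exchangeable working correlation,
and a gamma variance function:

* ``M1``: time ~ reaction
* ``M2``: time ~ reaction + behavior
* ``M3``: time ~ reaction + behavior + reaction:behavior

Reference levels are reaction = NEU (neutral) and behavior = TRA
(traveling).  Standard errors are robust (sandwich) estimates clustered
on events, per-coefficient tests are Wald chi-square(1), and nested
models are compared with a Wald test of the larger model's extra
coefficients under its robust covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .obs_model import Event, ReactionType

__all__ = [
    "MODEL_TERMS",
    "GeeFit",
    "ModelComparison",
    "reaction_time_table",
    "reaction_budget",
    "fit_gee",
    "compare_models",
]

_MODEL_REACTIONS = ("NEU", "POS", "NEG")  # NEU first: reference level

#: Design columns per model (treatment coding, NEU/TRA baselines);
#: columns for levels absent from the data are dropped at fit time.
#: M0 (intercept only) exists for validation against marginal-mean limits.
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M0": ("Intercept",),
    "M1": ("Intercept", "reaction[POS]", "reaction[NEG]"),
    "M2": ("Intercept", "reaction[POS]", "reaction[NEG]", "behavior[FEE]",
           "behavior[SOC]", "behavior[RES]"),
    "M3": ("Intercept", "reaction[POS]", "reaction[NEG]", "behavior[FEE]",
           "behavior[SOC]", "behavior[RES]",
           "reaction[POS]:behavior[FEE]", "reaction[NEG]:behavior[FEE]",
           "reaction[POS]:behavior[SOC]", "reaction[NEG]:behavior[SOC]",
           "reaction[POS]:behavior[RES]", "reaction[NEG]:behavior[RES]"),
}


def reaction_time_table(events: Sequence[Event]) -> pd.DataFrame:
    """Sum vessel-present block minutes by (event, behavior, reaction).

    Returns one row per observed combination with columns ``event_id``,
    ``behavior``, ``reaction`` (POS/NEU/NEG) and ``time_min`` > 0;
    zero-time combinations are absent by construction.  An empty table
    (no vessel-present blocks anywhere) is returned with a warning.
    """
    rows = []
    for event in events:
        for b in event.blocks:
            if b.vessel_present and b.reaction is not ReactionType.NONE:
                rows.append(
                    (event.event_id, b.state.value, b.reaction.value, b.duration)
                )
    frame = pd.DataFrame(
        rows, columns=["event_id", "behavior", "reaction", "time_min"]
    )
    if frame.empty:
        warnings.warn("no vessel-present blocks: empty reaction table", stacklevel=2)
        return frame
    out = (
        frame.groupby(["event_id", "behavior", "reaction"], as_index=False)[
            "time_min"
        ]
        .sum()
        .astype({"time_min": float})
    )
    return out[out["time_min"] > 0].reset_index(drop=True)


def reaction_budget(rows: pd.DataFrame) -> pd.Series:
    """Percent of vessel-present time per reaction category (sums to 100)."""
    if rows.empty:
        raise ValueError("reaction_budget requires a nonempty table")
    minutes = rows.groupby("reaction")["time_min"].sum()
    minutes = minutes.reindex(["POS", "NEU", "NEG"], fill_value=0.0)
    return 100.0 * minutes / minutes.sum()


def _design_matrix(rows: pd.DataFrame, model_id: str) -> pd.DataFrame:
    """Treatment-coded design with NEU/TRA reference levels.

    Columns follow :data:`MODEL_TERMS` restricted to levels present in
    the data (a level never observed cannot enter the design).
    """
    behaviors = [b for b in ("FEE", "SOC", "RES") if (rows["behavior"] == b).any()]
    reactions = [r for r in ("POS", "NEG") if (rows["reaction"] == r).any()]
    X = pd.DataFrame(index=rows.index)
    X["Intercept"] = 1.0
    if model_id in ("M1", "M2", "M3"):
        for r in reactions:
            X[f"reaction[{r}]"] = (rows["reaction"] == r).astype(float)
    if model_id in ("M2", "M3"):
        for b in behaviors:
            X[f"behavior[{b}]"] = (rows["behavior"] == b).astype(float)
    if model_id == "M3":
        for b in behaviors:
            for r in reactions:
                X[f"reaction[{r}]:behavior[{b}]"] = (
                    X[f"reaction[{r}]"] * X[f"behavior[{b}]"]
                )
    return X


@dataclass
class GeeFit:
    """A fitted marginal gamma model with exchangeable working correlation."""

    model_id: str
    link: str
    coefficients: pd.Series
    robust_se: pd.Series
    wald_chi2: pd.Series
    p_values: pd.Series
    alpha: float
    dispersion: float
    n_clusters: int
    nobs: int
    working_correlation: str = "exchangeable"
    cluster_ids: tuple = field(default=(), repr=False)
    cov_robust: np.ndarray | None = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "robust_se": self.robust_se,
                "wald_chi2": self.wald_chi2,
                "p": self.p_values,
            }
        )


@dataclass
class ModelComparison:
    """Wald test of the larger model's extra coefficients against zero."""

    pair: tuple[str, str]
    df: int
    wald_statistic: float
    p_value: float


def fit_gee(
    rows: pd.DataFrame,
    model_id: str = "M3",
    link: str = "inverse",
    working_correlation: str = "exchangeable",
) -> GeeFit:
    """Fit one of the nested reaction-time models by GEE.

    Parameters
    ----------
    rows : DataFrame
        Output of :func:`reaction_time_table` (possibly with rare
        behavioral states already excluded), columns ``event_id``,
        ``behavior``, ``reaction``, ``time_min``.
    model_id : {"M1", "M2", "M3"}
    link : {"inverse", "log"}
        Mean link for the gamma family; inverse (canonical) by default.
    working_correlation : {"exchangeable", "independence"}
        Working structure; ``independence`` reduces the fit to a
        clustered-robust gamma GLM (useful as a validation limit).

    Raises a descriptive error on fewer than 2 clusters, a
    rank-deficient design (naming the aliased column), or numerically
    invalid estimates.
    """
    if model_id not in MODEL_TERMS:
        raise ValueError(f"model_id must be one of {tuple(MODEL_TERMS)}")
    if rows.empty:
        raise ValueError("cannot fit a GEE on an empty reaction table")
    if (rows["time_min"] <= 0).any():
        raise ValueError("time_min must be strictly positive (gamma support)")
    groups = rows["event_id"].to_numpy()
    n_clusters = len(pd.unique(groups))
    if n_clusters < 2:
        raise ValueError(f"GEE needs >= 2 clusters, got {n_clusters}")

    X = _design_matrix(rows, model_id)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _find_aliased(X)
        raise ValueError(
            f"design for {model_id} is rank deficient: column {aliased!r} "
            "is aliased; drop the term or pool sparse cells"
        )

    if link == "inverse":
        family = sm.families.Gamma(link=sm.families.links.InversePower())
    elif link == "log":
        family = sm.families.Gamma(link=sm.families.links.Log())
    else:
        raise ValueError("link must be 'inverse' or 'log'")
    if working_correlation == "exchangeable":
        cov_struct = sm.cov_struct.Exchangeable()
    elif working_correlation == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise ValueError("working_correlation must be 'exchangeable' or 'independence'")

    with warnings.catch_warnings():
        # statsmodels warns that the inverse link does not constrain the
        # gamma mean to be positive; convergence is checked explicitly.
        warnings.simplefilter("ignore")
        model = sm.GEE(
            endog=rows["time_min"].to_numpy(),
            exog=X,
            groups=groups,
            family=family,
            cov_struct=cov_struct,
        )
        result = model.fit(maxiter=200)
    params = pd.Series(result.params, index=X.columns)
    if not np.all(np.isfinite(params)):
        raise RuntimeError(
            f"GEE for {model_id} did not converge to finite estimates; "
            f"trace: {params.to_dict()}"
        )
    se = pd.Series(result.bse, index=X.columns)  # robust by default
    wald = (params / se) ** 2
    pvals = pd.Series(stats.chi2.sf(wald, df=1), index=X.columns)
    alpha = (
        float(np.atleast_1d(cov_struct.dep_params)[0])
        if working_correlation == "exchangeable"
        else 0.0
    )
    return GeeFit(
        model_id=model_id,
        link=link,
        coefficients=params,
        robust_se=se,
        wald_chi2=wald,
        p_values=pvals,
        alpha=alpha,
        dispersion=float(result.scale),
        n_clusters=n_clusters,
        nobs=int(result.nobs),
        working_correlation=working_correlation,
        cluster_ids=tuple(sorted(pd.unique(groups))),
        cov_robust=np.asarray(result.cov_params()),
    )


def _find_aliased(X: pd.DataFrame) -> str:
    """Name the first column linearly dependent on its predecessors."""
    cols = list(X.columns)
    M = X.to_numpy()
    for k in range(1, len(cols)):
        if np.linalg.matrix_rank(M[:, : k + 1]) <= np.linalg.matrix_rank(M[:, :k]):
            return cols[k]
    return cols[-1]  # pragma: no cover


def compare_models(fit_a: GeeFit, fit_b: GeeFit) -> ModelComparison:
    """Wald comparison of two nested fits on identical rows.

    The extra coefficients of the larger model are tested against zero
    using its robust covariance: W = b' V^{-1} b ~ chi-square(df), with
    df the number of extra coefficients.  Refuses identical designs
    (df = 0) and non-nested pairs.
    """
    small, large = fit_a, fit_b
    if len(large.coefficients) < len(small.coefficients):
        small, large = large, small
    names_small = set(small.coefficients.index)
    names_large = list(large.coefficients.index)
    if names_small == set(names_large):
        raise ValueError(
            f"models {fit_a.model_id} and {fit_b.model_id} have identical "
            "designs (df = 0): nothing to compare"
        )
    if not names_small <= set(names_large):
        raise ValueError(
            f"models {fit_a.model_id} and {fit_b.model_id} are not nested"
        )
    if small.nobs != large.nobs or small.cluster_ids != large.cluster_ids:
        raise ValueError("models must be fitted on identical rows")
    extra = [n for n in names_large if n not in names_small]
    idx = [names_large.index(n) for n in extra]
    b = large.coefficients.to_numpy()[idx]
    V = large.cov_robust[np.ix_(idx, idx)]
    wald = float(b @ np.linalg.solve(V, b))
    df = len(extra)
    return ModelComparison(
        pair=(small.model_id, large.model_id),
        df=df,
        wald_statistic=wald,
        p_value=float(stats.chi2.sf(wald, df=df)),
    )
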