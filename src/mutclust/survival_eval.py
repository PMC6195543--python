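"""Survival-based evaluation of clusterings.

Cox proportional-hazards regression (Efron tie handling) with the cluster
indicator added on top of the clinical covariates (age, tumour stage with
level I as reference and unclassifiable stages pooled into X, cancer type).
The prognostic value of the clustering is the likelihood-ratio statistic of
the nested models with and without the cluster indicator, referred to the
asymptotic chi-squared distribution with (#clusters - 1) degrees of
freedom.  Per-cluster hazard ratios come from the exponentiated cluster
coefficients of the adjusted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import chi2

from .data_io import STAGE_LEVELS

__all__ = [
    "SurvivalDesign",
    "CoxResult",
    "fit_cox",
    "lr_test_clusters",
    "cluster_hazard_ratios",
    "null_log_partial_likelihood",
]


@dataclass
class SurvivalDesign:
    """Per-sample survival outcome plus covariates.

    Columns: time, event, age, stage (five retained levels, I reference),
    cancer_type, cluster.  Rows with missing required values must be removed
    upstream; the reference cluster is configurable.
    """

    frame: pd.DataFrame
    reference_cluster: str | None = None
    reference_stage: str = "I"

    def __post_init__(self) -> None:
        need = {"time", "event"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        if self.frame[list(need | {"age"} & set(self.frame.columns))].isna().any().any():
            raise ValueError("design contains missing values; drop them upstream")
        if "stage" in self.frame.columns:
            bad = ~self.frame["stage"].isin(STAGE_LEVELS)
            if bad.any():
                raise ValueError("stage must be recoded to the five retained levels")
        if self.reference_cluster is None and "cluster" in self.frame.columns:
            self.reference_cluster = sorted(self.frame["cluster"].astype(str).unique())[0]

    def model_matrix(self, covariates: Sequence[str]) -> pd.DataFrame:
        """Dummy-coded design for lifelines: categorical covariates expand
        against their reference level."""
        out = self.frame[["time", "event"]].copy()
        out["event"] = out["event"].astype(int)
        for cov in covariates:
            col = self.frame[cov]
            if cov == "age" or pd.api.types.is_numeric_dtype(col):
                out[cov] = col.astype(float)
                continue
            ref = {
                "stage": self.reference_stage,
                "cluster": str(self.reference_cluster),
            }.get(cov)
            values = col.astype(str)
            levels = sorted(values.unique())
            if ref is None:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                out[f"{cov}[{lev}]"] = (values == lev).astype(float)
        # exactly duplicated columns (e.g. a cluster indicator that coincides
        # with an adjusted covariate) make the partial likelihood singular;
        # keep the first occurrence
        dupes = [
            c for i, c in enumerate(out.columns[2:], start=2)
            if any(out.iloc[:, j].equals(out[c]) for j in range(2, i))
        ]
        if dupes:
            import warnings

            warnings.warn(f"dropping exactly collinear design columns: {dupes}")
            out = out.drop(columns=dupes)
        return out


@dataclass
class CoxResult:
    """Fitted Cox model: coefficient table and log partial likelihood."""

    summary: pd.DataFrame  # lifelines summary (coef, se, p, ...)
    log_likelihood: float
    n: int
    n_events: int
    fitter: CoxPHFitter | None = field(default=None, repr=False)


def null_log_partial_likelihood(time: np.ndarray, event: np.ndarray) -> float:
    """Efron log partial likelihood of the covariate-free model (all
    coefficients zero): each tied death group of size d in a risk set of
    size r contributes -sum_{l=0}^{d-1} ln(r - l)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d = int(((time == t) & (event == 1)).sum())
        r = int((time >= t).sum())
        ll -= sum(np.log(r - l) for l in range(d))
    return float(ll)


def fit_cox(
    design: SurvivalDesign,
    covariates: Sequence[str],
    penalizer: float = 0.0,
) -> CoxResult:
    """Maximum partial-likelihood Cox fit with Efron tie handling.

    With an empty covariate list the analytic null model is returned.
    Raises on zero events and turns lifelines convergence failures
    (separation etc.) into a diagnostic error.
    """
    df = design.model_matrix(covariates)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events observed; Cox model undefined")
    if df.shape[0] < 2:
        raise ValueError("need at least two samples")
    if df.shape[1] == 2:  # time + event only
        ll = null_log_partial_likelihood(df["time"].to_numpy(), df["event"].to_numpy())
        return CoxResult(pd.DataFrame(), ll, len(df), n_events)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    return CoxResult(cph.summary, float(cph.log_likelihood_), len(df), n_events, cph)


CLINICAL_COVARIATES = ("age", "stage", "cancer_type")


def lr_test_clusters(
    design: SurvivalDesign,
    clinical_covariates: Sequence[str] = CLINICAL_COVARIATES,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of the cluster indicator on top of the
    clinical covariates: LR = 2 (logPL_full - logPL_reduced), df =
    #cluster levels - 1, p from the asymptotic chi-squared."""
    covs = [c for c in clinical_covariates if c in design.frame.columns]
    full = fit_cox(design, list(covs) + ["cluster"])
    reduced = fit_cox(design, list(covs))
    lr = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    df = design.frame["cluster"].astype(str).nunique() - 1
    p = float(chi2.sf(lr, df)) if df > 0 else 1.0
    return lr, df, p


def cluster_hazard_ratios(
    design: SurvivalDesign,
    reference_cluster=None,
    clinical_covariates: Sequence[str] = CLINICAL_COVARIATES,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Hazard ratio, 95% CI and p-value of each cluster vs the reference.

    ``adjusted`` controls whether the clinical covariates enter the model;
    the reference cluster itself has HR 1 by construction and is omitted
    from the table.
    """
    if reference_cluster is not None:
        design = SurvivalDesign(
            design.frame, reference_cluster=str(reference_cluster),
            reference_stage=design.reference_stage,
        )
    covs = [c for c in clinical_covariates if c in design.frame.columns] if adjusted else []
    res = fit_cox(design, list(covs) + ["cluster"])
    rows = res.summary.loc[res.summary.index.str.startswith("cluster[")]
    out = pd.DataFrame(
        {
            "cluster": [i[len("cluster["):-1] for i in rows.index],
            "hr": np.exp(rows["coef"].to_numpy()),
            "ci_low": np.exp(rows["coef"] - 1.96 * rows["se(coef)"]).to_numpy(),
            "ci_high": np.exp(rows["coef"] + 1.96 * rows["se(coef)"]).to_numpy(),
            "p": rows["p"].to_numpy(),
        }
    )
    return out.set_index("cluster")
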