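"""Descriptive outputs of a fitted typology.

Modal class assignment, raw and attrition-weighted prevalences, per-class
profile tables on the raw instrument scales, and the simple percentage of
each variable's variance explained by the typology (one-way ANOVA R^2 over
modal classes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lpa import FittedLPA
from .variables import CohortTable, VariableSpec

log = logging.getLogger(__name__)

CLASS_NAMES_4 = (
    "Best Outcome",
    "High-IQ ASD",
    "Low-IQ ASD without behavioural problems",
    "Low-IQ ASD with behavioural problems",
)


def assign_modal(fitted: FittedLPA) -> tuple[np.ndarray, np.ndarray]:
    """Most-likely class per participant and mean posterior among assignees.

    Exact posterior ties break toward the lowest class index (logged).
    """
    post = fitted.posterior
    labels = post.argmax(axis=1)  # argmax breaks ties toward lowest index
    n_ties = int((np.sum(post == post.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        log.info("modal assignment: %d exact posterior ties broken to lowest class", n_ties)
    K = post.shape[1]
    mean_post = np.array([
        post[labels == k, k].mean() if (labels == k).any() else np.nan
        for k in range(K)
    ])
    return labels, mean_post


def class_prevalence(
    labels: np.ndarray, K: int, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (assigned-fraction) and weighted (weight-share) prevalences."""
    labels = np.asarray(labels, dtype=int)
    raw = np.array([(labels == k).mean() for k in range(K)])
    if weights is None:
        return raw, raw.copy()
    w = np.asarray(weights, dtype=float)
    if w.shape != labels.shape:
        raise ValueError("missing weight for an analysed row")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    weighted = np.array([w[labels == k].sum() for k in range(K)]) / w.sum()
    return raw, weighted


def variance_explained(column: np.ndarray, labels: np.ndarray) -> float:
    """Percent of a variable's variance explained by the class partition.

    100 x between-class SS / total SS over observed rows; ordinal variables
    enter on their integer scores.  Zero total variance yields 0 with a
    warning.
    """
    x = np.asarray(column, dtype=float)
    labels = np.asarray(labels, dtype=int)
    obs = ~np.isnan(x)
    xo, lo = x[obs], labels[obs]
    if np.unique(lo).size < 2:
        raise ValueError("need >= 2 classes present among observed rows")
    grand = xo.mean()
    ss_tot = ((xo - grand) ** 2).sum()
    if ss_tot == 0:
        warnings.warn("zero total variance; variance explained defined as 0")
        return 0.0
    ss_between = 0.0
    for k in np.unique(lo):
        sel = lo == k
        ss_between += sel.sum() * (xo[sel].mean() - grand) ** 2
    return float(100.0 * ss_between / ss_tot)


@dataclass
class ClassProfile:
    """Per-class descriptive summary shaped like a published profile table."""

    table: pd.DataFrame  # MultiIndex columns (class, {mean, sd, n_obs})
    prevalence: np.ndarray
    weighted_prevalence: np.ndarray
    mean_posterior: np.ndarray
    variance_explained: pd.Series


def profile_table(
    data: pd.DataFrame,
    specs: Sequence[VariableSpec],
    labels: np.ndarray,
    K: int | None = None,
) -> pd.DataFrame:
    """Mean (SD) [n observed] per class x variable on the raw scales."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(data):
        raise ValueError("labels must align with data rows")
    K = K if K is not None else int(labels.max()) + 1
    cols = {}
    for k in range(K):
        sel = labels == k
        sub = data.loc[sel, [s.name for s in specs]]
        n_obs = sub.notna().sum()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # empty class cells
            cols[(f"class_{k + 1}", "mean")] = sub.mean()
            cols[(f"class_{k + 1}", "sd")] = sub.std(ddof=1)
        cols[(f"class_{k + 1}", "n_obs")] = n_obs.astype(float)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


def build_class_profile(
    table: CohortTable,
    fitted: FittedLPA,
    specs: Sequence[VariableSpec] | None = None,
) -> ClassProfile:
    """Assemble the full descriptive profile for a fitted model."""
    specs = list(specs) if specs is not None else table.indicator_specs
    labels, mean_post = assign_modal(fitted)
    K = fitted.params.K
    raw, weighted = class_prevalence(
        labels, K,
        None if table.weights is None else table.weights.to_numpy(),
    )
    prof = profile_table(table.data, specs, labels, K=K)
    ve = {}
    for s in specs:
        try:
            ve[s.name] = variance_explained(
                table.data[s.name].to_numpy(dtype=float), labels
            )
        except ValueError:
            ve[s.name] = np.nan
    return ClassProfile(
        table=prof,
        prevalence=raw,
        weighted_prevalence=weighted,
        mean_posterior=mean_post,
        variance_explained=pd.Series(ve),
    )


def relabel_canonical(
    fitted: FittedLPA,
    specs: Sequence[VariableSpec],
    anchor: str = "viq",
) -> FittedLPA:
    """Reorder classes by the anchor indicator so labels are reproducible.

    Classes are sorted best-outcome-first on the anchor's class means.
    Processed indicators are oriented so higher means poorer outcome, so
    the sort is ascending on the fitted means (for a raw-scale fit of a
    non-reversed "higher is better" anchor this still puts the highest raw
    mean first).  Log-likelihood, BIC and the multiset of class parameters
    are unchanged.
    """
    spec = next((s for s in specs if s.name == anchor), None)
    if spec is None or spec.role != "indicator":
        raise ValueError(f"anchor {anchor!r} is not an indicator in this spec set")
    if spec.family == "gaussian":
        key = fitted.params.means[anchor]
    elif spec.family == "ordinal":
        key = fitted.params.locations[anchor]
    else:
        key = fitted.params.log_rates[anchor]
    order = np.argsort(key, kind="stable")
    if np.array_equal(order, np.arange(fitted.params.K)):
        return fitted
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    params = fitted.params.permute(order)
    post = fitted.posterior[:, order]
    modal = inv[fitted.modal_class]
    return FittedLPA(
        params=params,
        neg_loglik=fitted.neg_loglik,
        n_params=fitted.n_params,
        bic=fitted.bic,
        posterior=post,
        modal_class=modal,
        mean_posterior_by_class=fitted.mean_posterior_by_class[order],
        converged=fitted.converged,
        n_iterations=fitted.n_iterations,
        n_restarts=fitted.n_restarts,
        seed=fitted.seed,
        loglik_trace=list(fitted.loglik_trace),
    )


def attrition_weights(
    covariates: pd.DataFrame,
    retained: np.ndarray | pd.Series,
    factors: Sequence[str] = ("non_caucasian", "maternal_edu"),
) -> pd.Series:
    """Inverse-probability-of-retention weights from a logistic dropout model.

    Fit P(retained | factors) by logistic regression on the full recruited
    sample; weights for retained rows are 1/p, normalized to mean 1.
    """
    from sklearn.linear_model import LogisticRegression

    X = covariates[list(factors)].to_numpy(dtype=float)
    y = np.asarray(retained, dtype=int)
    if y.min() == y.max():
        p = np.full(len(X), y.mean() if y.mean() > 0 else 1.0)
    else:
        lr = LogisticRegression(C=1e6, max_iter=1000)
        lr.fit(X, y)
        p = lr.predict_proba(X)[:, 1]
    keep = y == 1
    w = 1.0 / np.clip(p[keep], 1e-3, 1.0)
    w = w / w.mean()
    return pd.Series(w, index=covariates.index[keep])
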