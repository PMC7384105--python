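"""Staged multinomial prediction of adult class from childhood measures.

A stage plan starts from nonclinical covariates (race, gender, maternal
education, site — always retained), adds the first-assessment clinical
measures (symptom severity, then verbal and nonverbal IQ), and from there
freezes the baseline coefficients as per-logit offsets while freely
estimating coefficients on the re-assessed measures at later ages.  Block
significance is judged by Wald tests with (K-1) x (variables in block)
degrees of freedom; likelihood-ratio tests are provided as a companion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    df: pd.DataFrame, cols: Sequence[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix; categorical/object columns become dummies."""
    pieces: list[pd.Series] = []
    for c in cols:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            pieces.extend(d[name] for name in d.columns)
        else:
            pieces.append(col.astype(float))
    names = ["intercept"] if add_intercept else []
    arrs = [np.ones(len(df))] if add_intercept else []
    for s in pieces:
        names.append(str(s.name))
        arrs.append(s.to_numpy(dtype=float))
    X = np.column_stack(arrs) if arrs else np.empty((len(df), 0))
    return X, names


def expand_categoricals(
    df: pd.DataFrame, cols: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Replace object/categorical columns by drop-first dummies.

    Returns the expanded frame and a map from each requested variable to
    the numeric column(s) that represent it; missing values stay NaN in
    the dummy columns so complete-case selection behaves correctly.
    """
    out = {}
    expansion: dict[str, list[str]] = {}
    for c in cols:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            d[col.isna()] = np.nan
            for name in d.columns:
                out[name] = d[name]
            expansion[c] = list(d.columns)
        else:
            out[c] = col.astype(float)
            expansion[c] = [c]
    return pd.DataFrame(out, index=df.index), expansion


# ---------------------------------------------------------------------------
# multinomial logistic regression with offsets


@dataclass
class PredictionModel:
    """Fitted multinomial logit (reference class = class index 0)."""

    coef: np.ndarray  # (P, K-1)
    colnames: list[str]
    K: int
    loglik: float
    ridge: float
    cov: np.ndarray  # ((K-1)P, (K-1)P) for Wald tests
    prob: np.ndarray  # (n, K) fitted probabilities on the training rows
    offset: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0

    def linear_predictor(self, X: np.ndarray, offset: np.ndarray | None = None) -> np.ndarray:
        eta = X @ self.coef  # (n, K-1)
        if offset is not None:
            eta = eta + offset
        return eta

    def predict_proba(self, X: np.ndarray, offset: np.ndarray | None = None) -> np.ndarray:
        eta = self.linear_predictor(X, offset)
        full = np.concatenate([np.zeros((len(X), 1)), eta], axis=1)
        full -= full.max(axis=1, keepdims=True)
        p = np.exp(full)
        return p / p.sum(axis=1, keepdims=True)


def _mnl_loglik(B, X, y_onehot, offset, ridge):
    eta = X @ B
    if offset is not None:
        eta = eta + offset
    full = np.concatenate([np.zeros((len(X), 1)), eta], axis=1)
    m = full.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(full - m).sum(axis=1))
    ll = float((y_onehot * full).sum() - lse.sum())
    return ll - 0.5 * ridge * float((B**2).sum())


def fit_multinomial(
    X: np.ndarray,
    labels: np.ndarray,
    K: int | None = None,
    offset: np.ndarray | None = None,
    ridge: float = 0.0,
    colnames: Sequence[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> PredictionModel:
    """Newton-Raphson fit of the multinomial logit.

    ``offset`` is an (n, K-1) matrix added to the non-reference linear
    predictors and never re-estimated.  On detected separation (diverging
    coefficients) or a singular Hessian with ``ridge == 0``, the fit is
    retried with ridge 1e-4 and a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    n, P = X.shape
    K = K if K is not None else int(y.max()) + 1
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes present")
    y_onehot = np.zeros((n, K))
    y_onehot[np.arange(n), y] = 1.0
    nB = P * (K - 1)
    B = np.zeros((P, K - 1))
    ll = _mnl_loglik(B, X, y_onehot, offset, ridge)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ B
        if offset is not None:
            eta = eta + offset
        full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        full -= full.max(axis=1, keepdims=True)
        p = np.exp(full)
        p /= p.sum(axis=1, keepdims=True)  # (n, K)
        resid = y_onehot[:, 1:] - p[:, 1:]  # (n, K-1)
        grad = (X.T @ resid).reshape(-1, order="F") - ridge * B.reshape(-1, order="F")
        # Hessian blocks H[(k,l)] = -X' diag(p_k (delta_kl - p_l)) X
        H = np.empty((nB, nB))
        for k in range(K - 1):
            for l in range(k, K - 1):
                w = p[:, k + 1] * ((1.0 if k == l else 0.0) - p[:, l + 1])
                block = -(X * w[:, None]).T @ X
                H[k * P:(k + 1) * P, l * P:(l + 1) * P] = block
                if l != k:
                    H[l * P:(l + 1) * P, k * P:(k + 1) * P] = block
        H -= ridge * np.eye(nB)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                warnings.warn("singular Hessian; refitting with ridge 1e-4")
                return fit_multinomial(
                    X, y, K, offset=offset, ridge=1e-4,
                    colnames=colnames, max_iter=max_iter, tol=tol,
                )
            raise RuntimeError(
                "multinomial Newton failed (singular Hessian); increase ridge"
            )
        # step-halving line search on the (penalized) log-likelihood
        scale = 1.0
        for _ in range(30):
            B_new = B + scale * step.reshape(P, K - 1, order="F")
            ll_new = _mnl_loglik(B_new, X, y_onehot, offset, ridge)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        B, ll_prev, ll = B_new, ll, ll_new
        if ridge == 0.0 and np.abs(B).max() > 40.0:
            warnings.warn("perfect separation detected; refitting with ridge 1e-4")
            return fit_multinomial(
                X, y, K, offset=offset, ridge=1e-4,
                colnames=colnames, max_iter=max_iter, tol=tol,
            )
        gnorm = np.abs(grad).max()
        if abs(ll - ll_prev) <= tol * (1.0 + abs(ll)) and gnorm < 1e-6:
            converged = True
            break
    if not converged and np.abs(grad).max() > 1e-4:
        if ridge == 0.0:
            warnings.warn("non-convergence; refitting with ridge 1e-4")
            return fit_multinomial(
                X, y, K, offset=offset, ridge=1e-4,
                colnames=colnames, max_iter=max_iter, tol=tol,
            )
        raise RuntimeError("multinomial Newton did not converge; increase ridge")
    if ridge == 0.0 and np.abs(B).max() > 15.0:
        # likelihood plateau with huge coefficients: (quasi-)separation
        warnings.warn("perfect separation detected; refitting with ridge 1e-4")
        return fit_multinomial(
            X, y, K, offset=offset, ridge=1e-4,
            colnames=colnames, max_iter=max_iter, tol=tol,
        )
    cov = np.linalg.pinv(-H)
    model = PredictionModel(
        coef=B,
        colnames=list(colnames) if colnames is not None else [f"x{i}" for i in range(P)],
        K=K,
        loglik=_mnl_loglik(B, X, y_onehot, offset, 0.0),
        ridge=ridge,
        cov=cov,
        prob=None,  # set below
        offset=offset,
        converged=True,
        n_iter=it,
    )
    model.prob = model.predict_proba(X, offset)
    return model


def wald_block_test(
    model: PredictionModel, block: Sequence[str]
) -> tuple[float, int, float]:
    """Wald chi-square for a block of predictors being jointly zero.

    df = (K-1) x (number of variables in the block).
    """
    P = model.coef.shape[0]
    Km1 = model.K - 1
    idx_vars = []
    for v in block:
        if v not in model.colnames:
            raise ValueError(f"predictor {v!r} not in model")
        idx_vars.append(model.colnames.index(v))
    # coefficient vector is stacked column-major: logit k occupies [kP, (k+1)P)
    flat_idx = [k * P + j for k in range(Km1) for j in idx_vars]
    b = model.coef.reshape(-1, order="F")[flat_idx]
    V = model.cov[np.ix_(flat_idx, flat_idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as e:
        cond = np.linalg.cond(V)
        raise RuntimeError(
            f"singular block covariance (condition number {cond:.3g})"
        ) from e
    df = Km1 * len(block)
    return stat, df, float(stats.chi2.sf(stat, df))


def lr_block_test(
    model_small: PredictionModel, model_large: PredictionModel
) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested models fit to the same rows."""
    p_small = model_small.coef.size
    p_large = model_large.coef.size
    if p_large < p_small or model_large.K != model_small.K:
        raise ValueError("models are not nested (large must add parameters)")
    if not set(model_small.colnames) <= set(model_large.colnames):
        raise ValueError("models are not nested (predictor sets)")
    if len(model_small.prob) != len(model_large.prob):
        raise ValueError("models were fit to different rows")
    stat = 2.0 * (model_large.loglik - model_small.loglik)
    stat = max(stat, 0.0)
    df = p_large - p_small
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# stage plans


@dataclass
class Stage:
    name: str
    variables: list[str]  # added at this stage
    use_baseline_offsets: str | None = None  # name of a previous stage


@dataclass
class StagePlan:
    stages: list[Stage]

    def __post_init__(self) -> None:
        seen = set()
        for i, st in enumerate(self.stages):
            if st.use_baseline_offsets is not None:
                if st.use_baseline_offsets not in seen:
                    raise ValueError(
                        f"stage {st.name!r} references unknown baseline "
                        f"{st.use_baseline_offsets!r}"
                    )
            seen.add(st.name)


def default_stage_plan() -> StagePlan:
    """Nonclinical -> +severity(2) -> +IQ(2) baseline -> offset updates at 3/5/9."""
    nonclin = ["non_caucasian", "female", "maternal_edu", "site"]
    return StagePlan([
        Stage("nonclinical", nonclin),
        Stage("age2_css", ["css_2"]),
        Stage("age2_css_iq", ["viq_2", "nviq_2"]),
        Stage("age3_update", ["css_3", "viq_3", "nviq_3"], "age2_css_iq"),
        Stage("age5_update", ["css_5", "viq_5", "nviq_5"], "age2_css_iq"),
        Stage("age9_update", ["css_9", "viq_9", "nviq_9"], "age2_css_iq"),
    ])


@dataclass
class StageResult:
    stage: Stage
    model: PredictionModel
    rows: np.ndarray  # positional indices of rows used
    summary: pd.DataFrame  # per-class boxplot stats of own-class probability
    chance: np.ndarray  # class prevalences on the rows used


def _own_prob_summary(prob: np.ndarray, labels: np.ndarray, K: int) -> pd.DataFrame:
    rows = []
    own = prob[np.arange(len(labels)), labels]
    for k in range(K):
        sel = labels == k
        if not sel.any():
            rows.append({"class": k + 1, "n": 0})
            continue
        v = own[sel]
        rows.append({
            "class": k + 1,
            "min": float(v.min()),
            "q1": float(np.percentile(v, 25)),
            "median": float(np.median(v)),
            "q3": float(np.percentile(v, 75)),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "n": int(sel.sum()),
        })
    return pd.DataFrame(rows).set_index("class")


def update_with_wave(
    baseline: PredictionModel,
    baseline_X: np.ndarray,
    wave_X: np.ndarray,
    labels: np.ndarray,
    wave_names: Sequence[str],
    baseline_names: Sequence[str] | None = None,
    allow_overlap: bool = False,
    ridge: float = 0.0,
) -> PredictionModel:
    """Refit with baseline linear predictors frozen as per-logit offsets.

    The wave measures (plus a free intercept per logit) get freely
    estimated coefficients on top of the fixed baseline contribution.
    """
    names = list(baseline_names) if baseline_names is not None else baseline.colnames
    overlap = set(wave_names) & (set(names) - {"intercept"})
    if overlap and not allow_overlap:
        raise ValueError(f"frozen and new variables overlap: {sorted(overlap)}")
    # frozen contribution: the baseline coefficients applied to these rows
    # (a baseline with its own offset cannot be transported to new rows)
    if baseline.offset is not None:
        raise ValueError("baseline model must not itself carry an offset")
    offset = baseline.linear_predictor(baseline_X, None)
    X = np.column_stack([np.ones(len(wave_X)), wave_X])
    return fit_multinomial(
        X, labels, baseline.K, offset=offset, ridge=ridge,
        colnames=["intercept", *wave_names],
    )


def run_stage_plan(
    df: pd.DataFrame,
    labels: np.ndarray,
    plan: StagePlan,
    include: np.ndarray | None = None,
    K: int | None = None,
    ridge: float = 0.0,
) -> list[StageResult]:
    """Fit every stage on its complete-case rows; summarize own-class probability.

    Rows not flagged for predictive analysis are excluded throughout.
    Complete cases are taken per stage over the union of that stage's and
    its baseline's predictors (counts are reported in the result).
    """
    labels = np.asarray(labels, dtype=int)
    K = K if K is not None else int(labels.max()) + 1
    base_mask = np.ones(len(df), dtype=bool) if include is None else np.asarray(include, bool)
    # expand categoricals once on the full table so dummy columns are
    # identical across stages regardless of each stage's complete-case rows
    all_vars = list(dict.fromkeys(v for st in plan.stages for v in st.variables))
    dfx, expansion = expand_categoricals(df, all_vars)
    results: list[StageResult] = []
    fitted: dict[str, tuple[PredictionModel, list[str]]] = {}
    cum_cols: list[str] = []
    for stage in plan.stages:
        stage_cols = [c for v in stage.variables for c in expansion[v]]
        if stage.use_baseline_offsets is None:
            cum_cols = cum_cols + stage_cols
            use_cols = list(cum_cols)
            need = use_cols
        else:
            base_model, base_cols = fitted[stage.use_baseline_offsets]
            use_cols = stage_cols
            need = list(dict.fromkeys(base_cols + stage_cols))
        cc = base_mask & dfx[need].notna().all(axis=1).to_numpy()
        rows = np.nonzero(cc)[0]
        if rows.size == 0:
            raise ValueError(
                f"stage {stage.name!r}: no rows with complete data on {need}"
            )
        sub = dfx.iloc[rows]
        y = labels[rows]
        if stage.use_baseline_offsets is None:
            X = np.column_stack([np.ones(rows.size)] + [sub[c].to_numpy(float) for c in use_cols])
            model = fit_multinomial(
                X, y, K, ridge=ridge, colnames=["intercept", *use_cols]
            )
            fitted[stage.name] = (model, use_cols)
        else:
            Xb = np.column_stack(
                [np.ones(rows.size)] + [sub[c].to_numpy(float) for c in base_cols]
            )
            Xw = np.column_stack([sub[c].to_numpy(float) for c in stage_cols])
            model = update_with_wave(
                base_model, Xb, Xw, y, stage_cols, ridge=ridge,
            )
        chance = np.array([(y == k).mean() for k in range(K)])
        results.append(StageResult(
            stage=stage,
            model=model,
            rows=rows,
            summary=_own_prob_summary(model.prob, y, K),
            chance=chance,
        ))
    return results
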