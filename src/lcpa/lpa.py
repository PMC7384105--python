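"""Mixed-family latent class profile model.

The model is a finite mixture over K latent classes whose class-conditional
distributions factorize over the indicators:

* gaussian indicator j: Normal(mu_jk, sigma2_j) with class-specific means
  and a class-invariant variance;
* ordinal indicator j (L_j levels): proportional-odds cumulative logit with
  class-invariant cutpoints tau_j1 < ... < tau_j,L-1 and class-specific
  locations eta_jk anchored at eta_j1 = 0, so
  P(Y = c | k) = F(tau_jc - eta_jk) - F(tau_j,c-1 - eta_jk), F logistic;
* count indicator j: Poisson with class-specific log-rate lambda_jk.

Estimation is by EM under full-information maximum likelihood: each case
contributes the likelihood of its observed indicators only, which is valid
under missing-at-random.  A fully missing row contributes exactly zero to
the log-likelihood.  Model choice across K uses the Bayesian information
criterion, BIC = 2 * neg_loglik + n_params * ln(n), with n the number of
rows with at least one observed indicator.

Free-parameter count for K classes: (K-1) mixing weights, K means + 1
variance per gaussian indicator, (L_j - 1) cutpoints + (K-1) free locations
per ordinal indicator, and K log-rates per count indicator.  For the
default 15-indicator adult-outcome profile this is 16K + 25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .variables import VariableSpec, check_unique_names

_LOG2PI = float(np.log(2.0 * np.pi))
_PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class MixtureParams:
    """Class-conditional parameters of the mixed-family mixture."""

    K: int
    mixing: np.ndarray
    means: dict[str, np.ndarray] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)
    cutpoints: dict[str, np.ndarray] = field(default_factory=dict)
    locations: dict[str, np.ndarray] = field(default_factory=dict)
    log_rates: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        pi = np.asarray(self.mixing, dtype=float)
        if pi.shape != (self.K,) or not np.all(pi > 0):
            raise ValueError("mixing must be length-K and strictly positive")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("mixing must sum to 1")
        for name, v in self.variances.items():
            if v <= 0:
                raise ValueError(f"variance of {name!r} must be positive")
        for name, tau in self.cutpoints.items():
            if np.any(np.diff(tau) <= 0):
                raise ValueError(f"cutpoints of {name!r} must be strictly increasing")
            eta = self.locations[name]
            if eta[0] != 0.0:
                raise ValueError(f"anchor-class location of {name!r} must be 0")

    def copy(self) -> "MixtureParams":
        return MixtureParams(
            K=self.K,
            mixing=self.mixing.copy(),
            means={k: v.copy() for k, v in self.means.items()},
            variances=dict(self.variances),
            cutpoints={k: v.copy() for k, v in self.cutpoints.items()},
            locations={k: v.copy() for k, v in self.locations.items()},
            log_rates={k: v.copy() for k, v in self.log_rates.items()},
        )

    def permute(self, order: Sequence[int]) -> "MixtureParams":
        """Relabel classes by ``order`` (new class i = old class order[i]).

        Ordinal locations are re-anchored so the new first class sits at 0;
        the shift is absorbed into the cutpoints, leaving every cell
        probability unchanged.
        """
        order = np.asarray(order, dtype=int)
        out = self.copy()
        out.mixing = self.mixing[order]
        out.means = {k: v[order] for k, v in self.means.items()}
        out.log_rates = {k: v[order] for k, v in self.log_rates.items()}
        for name in self.cutpoints:
            eta = self.locations[name][order]
            shift = eta[0]
            out.locations[name] = eta - shift
            out.cutpoints[name] = self.cutpoints[name] - shift
        return out

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "mixing": self.mixing.tolist(),
            "means": {k: v.tolist() for k, v in self.means.items()},
            "variances": dict(self.variances),
            "cutpoints": {k: v.tolist() for k, v in self.cutpoints.items()},
            "locations": {k: v.tolist() for k, v in self.locations.items()},
            "log_rates": {k: v.tolist() for k, v in self.log_rates.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        return cls(
            K=int(d["K"]),
            mixing=np.asarray(d["mixing"], dtype=float),
            means={k: np.asarray(v, float) for k, v in d["means"].items()},
            variances={k: float(v) for k, v in d["variances"].items()},
            cutpoints={k: np.asarray(v, float) for k, v in d["cutpoints"].items()},
            locations={k: np.asarray(v, float) for k, v in d["locations"].items()},
            log_rates={k: np.asarray(v, float) for k, v in d["log_rates"].items()},
        )


@dataclass
class FittedLPA:
    params: MixtureParams
    neg_loglik: float
    n_params: int
    bic: float
    posterior: np.ndarray
    modal_class: np.ndarray  # 0-based class indices
    mean_posterior_by_class: np.ndarray
    converged: bool
    n_iterations: int
    n_restarts: int
    seed: int | None
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return -self.neg_loglik


# ---------------------------------------------------------------------------
# densities


def ordinal_level_logprobs(tau: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """(K, L) log P(level c | class k) for the cumulative logit family."""
    a = tau[None, :] - np.asarray(eta, float)[:, None]  # (K, L-1)
    F = expit(a)
    cum = np.concatenate(
        [np.zeros((F.shape[0], 1)), F, np.ones((F.shape[0], 1))], axis=1
    )
    p = np.clip(np.diff(cum, axis=1), _PROB_FLOOR, 1.0)
    return np.log(p)


def component_logdensity(
    spec: VariableSpec, params: MixtureParams, k: int, value: float
) -> float:
    """Log-density (nats) of one observed value under class ``k``."""
    name = spec.name
    if spec.family == "gaussian":
        mu = params.means[name][k]
        var = params.variances[name]
        return float(-0.5 * (_LOG2PI + np.log(var) + (value - mu) ** 2 / var))
    if spec.family == "ordinal":
        c = int(value) - spec.level_min
        if value != np.floor(value) or c < 0 or c >= spec.n_levels:
            raise ValueError(
                f"variable {name!r}: value {value} outside ordinal support "
                f"[{spec.level_min}, {spec.level_max}]"
            )
        logp = ordinal_level_logprobs(
            params.cutpoints[name], params.locations[name]
        )
        return float(logp[k, c])
    if spec.family == "count":
        if value != np.floor(value) or value < 0:
            raise ValueError(
                f"variable {name!r}: value {value} is not a non-negative integer"
            )
        lam = np.exp(params.log_rates[name][k])
        return float(value * np.log(lam) - lam - gammaln(value + 1.0))
    raise ValueError(f"unknown family {spec.family!r}")


def _component_loglik_matrix(
    Y: np.ndarray, specs: Sequence[VariableSpec], params: MixtureParams
) -> np.ndarray:
    """(n, K) sum over observed indicators of class-conditional log-densities."""
    n = Y.shape[0]
    K = params.K
    ll = np.zeros((n, K))
    for j, spec in enumerate(specs):
        y = Y[:, j]
        obs = ~np.isnan(y)
        if not obs.any():
            continue
        yo = y[obs]
        name = spec.name
        if spec.family == "gaussian":
            mu = params.means[name]  # (K,)
            var = params.variances[name]
            ll[obs, :] += -0.5 * (
                _LOG2PI + np.log(var) + (yo[:, None] - mu[None, :]) ** 2 / var
            )
        elif spec.family == "ordinal":
            c = np.rint(yo).astype(int) - spec.level_min
            if c.min() < 0 or c.max() >= spec.n_levels:
                bad = np.nonzero(obs)[0][(c < 0) | (c >= spec.n_levels)]
                raise ValueError(
                    f"variable {name!r}: out-of-support ordinal values in rows "
                    f"{bad[:10].tolist()}"
                )
            logp = ordinal_level_logprobs(
                params.cutpoints[name], params.locations[name]
            )  # (K, L)
            ll[obs, :] += logp[:, c].T
        elif spec.family == "count":
            if np.any(yo < 0) or np.any(yo != np.rint(yo)):
                bad = np.nonzero(obs)[0][(yo < 0) | (yo != np.rint(yo))]
                raise ValueError(
                    f"variable {name!r}: negative/non-integer counts in rows "
                    f"{bad[:10].tolist()}"
                )
            lam = np.exp(params.log_rates[name])  # (K,)
            ll[obs, :] += (
                yo[:, None] * params.log_rates[name][None, :]
                - lam[None, :]
                - gammaln(yo + 1.0)[:, None]
            )
    return ll


def case_loglik(
    params: MixtureParams, row: np.ndarray, specs: Sequence[VariableSpec]
) -> float:
    """FIML log-likelihood of one row: log sum_k pi_k prod_{j obs} f_j(y_j|k)."""
    ll = _component_loglik_matrix(np.atleast_2d(row), specs, params)
    return float(logsumexp(ll[0] + np.log(params.mixing)))


def loglik(
    params: MixtureParams, Y: np.ndarray, specs: Sequence[VariableSpec]
) -> float:
    ll = _component_loglik_matrix(Y, specs, params)
    return float(logsumexp(ll + np.log(params.mixing)[None, :], axis=1).sum())


def e_step(
    params: MixtureParams, Y: np.ndarray, specs: Sequence[VariableSpec]
) -> tuple[np.ndarray, float]:
    """Responsibilities and total observed-data log-likelihood.

    Fully missing rows receive the prior mixing proportions.
    """
    ll = _component_loglik_matrix(Y, specs, params) + np.log(params.mixing)[None, :]
    lse = logsumexp(ll, axis=1)
    post = np.exp(ll - lse[:, None])
    if np.any(~np.isfinite(post)):
        raise FloatingPointError("NaN/Inf posterior in E-step")
    return post, float(lse.sum())


# ---------------------------------------------------------------------------
# M-step


def _ordinal_negll_grad(
    theta: np.ndarray, W: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted cumulative-logit negative log-likelihood and gradient.

    ``W`` is the (K, L) matrix of posterior weight totals per class and
    level; ``theta`` packs (tau_1, log-increments of tau, eta_2..eta_K).
    """
    K, L = W.shape
    ntau = L - 1
    logd = theta[1:ntau]
    tau = theta[0] + np.concatenate([[0.0], np.cumsum(np.exp(logd))])
    eta = np.concatenate([[0.0], theta[ntau:]])
    a = tau[None, :] - eta[:, None]  # (K, L-1)
    F = expit(a)
    cum = np.concatenate([np.zeros((K, 1)), F, np.ones((K, 1))], axis=1)
    p = np.clip(np.diff(cum, axis=1), _PROB_FLOOR, 1.0)
    nll = -float((W * np.log(p)).sum())

    r = W / p  # (K, L)
    f = F * (1.0 - F)  # logistic density at a
    g = (r[:, :-1] - r[:, 1:]) * f  # (K, L-1): dL/d a_kc
    dL_dtau = g.sum(axis=0)  # (L-1,)
    dL_deta = -g.sum(axis=1)  # (K,)
    grad = np.empty_like(theta)
    grad[0] = -dL_dtau.sum()
    # tau_c depends on logd_m for m <= c-1 (c >= 2, 0-based index m-1)
    if ntau > 1:
        tail = np.cumsum(dL_dtau[::-1])[::-1]  # sum_{c >= m} dL/dtau_c
        grad[1:ntau] = -np.exp(logd) * tail[1:]
    grad[ntau:] = -dL_deta[1:]
    return nll, grad


def fit_ordinal_weighted(
    W: np.ndarray,
    tau0: np.ndarray,
    eta0: np.ndarray,
    max_inner: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the weighted cumulative-logit likelihood from a warm start.

    Returns (tau, eta) at least as good as the starting point, so using a
    capped inner iteration count yields a generalized (still monotone) EM.
    """
    K, L = W.shape
    d0 = np.diff(tau0)
    theta0 = np.concatenate([[tau0[0]], np.log(np.maximum(d0, 1e-6)), eta0[1:]])
    res = minimize(
        _ordinal_negll_grad,
        theta0,
        args=(W,),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_inner, "ftol": 1e-12, "gtol": 1e-8},
    )
    f0, _ = _ordinal_negll_grad(theta0, W)
    theta = res.x if res.fun <= f0 else theta0
    ntau = L - 1
    tau = theta[0] + np.concatenate([[0.0], np.cumsum(np.exp(theta[1:ntau]))])
    eta = np.concatenate([[0.0], theta[ntau:]])
    return tau, eta


def m_step(
    posteriors: np.ndarray,
    Y: np.ndarray,
    specs: Sequence[VariableSpec],
    prev: MixtureParams | None = None,
    var_floor: float = 1e-4,
    empty_tol: float = 1e-3,
) -> MixtureParams:
    """Maximization step given responsibilities.

    Raises ``EmptyClassError`` when a class's total responsibility falls
    below ``empty_tol * n`` (the caller restarts from a new initialization).
    """
    n, K = posteriors.shape
    col = posteriors.sum(axis=0)
    if np.any(col < empty_tol * n):
        raise EmptyClassError(
            f"class responsibility collapsed (totals {np.round(col, 3).tolist()})"
        )
    params = MixtureParams(K=K, mixing=col / n)
    for j, spec in enumerate(specs):
        y = Y[:, j]
        obs = ~np.isnan(y)
        yo = y[obs]
        w = posteriors[obs]  # (n_obs, K)
        wsum = np.maximum(w.sum(axis=0), 1e-12)
        name = spec.name
        if spec.family == "gaussian":
            mu = (w * yo[:, None]).sum(axis=0) / wsum
            resid2 = (yo[:, None] - mu[None, :]) ** 2
            var = (w * resid2).sum() / w.sum()
            params.means[name] = mu
            params.variances[name] = float(max(var, var_floor))
        elif spec.family == "count":
            rate = (w * yo[:, None]).sum(axis=0) / wsum
            params.log_rates[name] = np.log(np.maximum(rate, 1e-6))
        elif spec.family == "ordinal":
            L = spec.n_levels
            c = np.rint(yo).astype(int) - spec.level_min
            W = np.zeros((K, L))
            for lev in range(L):
                sel = c == lev
                if sel.any():
                    W[:, lev] = w[sel].sum(axis=0)
            if prev is not None and name in prev.cutpoints:
                tau0, eta0 = prev.cutpoints[name], prev.locations[name]
            else:
                tau0, eta0 = _init_ordinal(W)
            tau, eta = fit_ordinal_weighted(W, tau0, eta0)
            params.cutpoints[name] = tau
            params.locations[name] = eta
    return params


def _init_ordinal(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cutpoints from pooled marginal frequencies, locations at zero."""
    K, L = W.shape
    marg = W.sum(axis=0)
    marg = (marg + 0.5) / (marg.sum() + 0.5 * L)
    cum = np.clip(np.cumsum(marg)[:-1], 1e-4, 1 - 1e-4)
    tau = np.log(cum / (1 - cum))
    tau = np.maximum.accumulate(tau)
    tau += np.arange(L - 1) * 1e-6  # enforce strict increase
    return tau, np.zeros(K)


class EmptyClassError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter counting & BIC


def count_parameters(
    specs: Sequence[VariableSpec], K: int, class_specific_variance: bool = False
) -> int:
    """Free-parameter count of the K-class model, by structural enumeration."""
    check_unique_names(specs)
    p = K - 1  # mixing
    for spec in specs:
        if spec.family == "gaussian":
            p += K  # class means
            p += K if class_specific_variance else 1
        elif spec.family == "ordinal":
            p += spec.n_levels - 1  # shared cutpoints
            p += K - 1  # anchored locations
        elif spec.family == "count":
            p += K  # log-rates
    return p


def bic(neg_loglik: float, n_params: int, n: int) -> float:
    """BIC in nats: 2 * neg_loglik + n_params * ln(n); smaller is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * neg_loglik + n_params * np.log(n)


# ---------------------------------------------------------------------------
# EM driver


def _n_analysed(Y: np.ndarray) -> int:
    """Rows with at least one observed indicator."""
    return int((~np.isnan(Y)).any(axis=1).sum())


def _kmeans_start(
    Y: np.ndarray, specs: Sequence[VariableSpec], K: int, seed: int
) -> np.ndarray:
    """Hard-assignment posterior from k-means on the (imputed) gaussian block."""
    from sklearn.cluster import KMeans

    gauss = [j for j, s in enumerate(specs) if s.family == "gaussian"]
    X = Y[:, gauss] if gauss else Y.copy()
    X = np.asarray(X, dtype=float)
    # column-mean imputation; columns are standardized upstream
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    km = KMeans(n_clusters=K, n_init=1, random_state=seed)
    labels = km.fit_predict(X)
    return _soft_onehot(labels, K)


def _soft_onehot(labels: np.ndarray, K: int, hard: float = 0.9) -> np.ndarray:
    post = np.full((labels.size, K), (1.0 - hard) / max(K - 1, 1))
    if K == 1:
        return np.ones((labels.size, 1))
    post[np.arange(labels.size), labels] = hard
    return post


def fit_em(
    Y: np.ndarray,
    specs: Sequence[VariableSpec],
    K: int,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = 0,
    init_params: MixtureParams | None = None,
    var_floor: float = 1e-4,
) -> FittedLPA:
    """Best-of-restarts EM fit of the K-class mixed-family mixture.

    The observed-data log-likelihood is monotone non-decreasing across
    iterations (checked, tolerance 1e-8); convergence is declared when the
    relative change falls below ``tol``.  With ``init_params`` given, a
    single run starts from those parameters (no random restarts).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    analysed = (~np.isnan(Y)).any(axis=1)
    n_eff = int(analysed.sum())
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_eff <= K:
        raise ValueError("need more analysed rows than classes")
    # fully missing rows carry a likelihood factor of exactly 1 under FIML:
    # estimation runs on analysed rows only (appending empty rows is a no-op)
    Y_fit = Y[analysed]
    rng = np.random.default_rng(seed)

    starts: list[tuple[str, object]] = []
    if init_params is not None:
        starts.append(("init", init_params))
    else:
        starts.append(("kmeans", None))
        for r in range(max(0, n_restarts - 1)):
            starts.append(("random", int(rng.integers(0, 2**31 - 1))))

    best: FittedLPA | None = None
    failures: list[str] = []
    for s_idx, (kind, payload) in enumerate(starts):
        try:
            fit = _run_single_em(
                Y_fit, specs, K, kind, payload,
                tol=tol, max_iter=max_iter,
                seed=seed if seed is not None else 0,
                start_index=s_idx, var_floor=var_floor,
            )
        except EmptyClassError as e:
            failures.append(str(e))
            continue
        if best is None or fit.neg_loglik < best.neg_loglik:
            best = fit
    if best is None:
        raise EmptyClassError(
            f"all {len(starts)} starts hit an empty class for K={K}; "
            "consider a smaller K. " + (failures[0] if failures else "")
        )
    if not analysed.all():
        # expand posteriors back to the full row set (empty rows get the prior)
        post, _ = e_step(best.params, Y, specs)
        best.posterior = post
        best.modal_class = post.argmax(axis=1)
        best.mean_posterior_by_class = np.array([
            post[best.modal_class == k, k].mean()
            if (best.modal_class == k).any() else np.nan
            for k in range(K)
        ])
    best.n_restarts = len(starts)
    best.n_params = count_parameters(specs, K)
    best.bic = bic(best.neg_loglik, best.n_params, n_eff)
    return best


def _run_single_em(
    Y, specs, K, kind, payload, *, tol, max_iter, seed, start_index, var_floor
) -> FittedLPA:
    n = Y.shape[0]
    if kind == "init":
        params = payload.copy()
        params.validate()
    else:
        if K == 1:
            post0 = np.ones((n, 1))
        elif kind == "kmeans":
            post0 = _kmeans_start(Y, specs, K, seed)
        else:
            rng = np.random.default_rng(payload)
            post0 = _soft_onehot(rng.integers(0, K, size=n), K)
        params = m_step(post0, Y, specs, prev=None, var_floor=var_floor)

    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    post, ll = e_step(params, Y, specs)
    trace.append(ll)
    for it in range(1, max_iter + 1):
        params = m_step(post, Y, specs, prev=params, var_floor=var_floor)
        post, ll = e_step(params, Y, specs)
        if ll < trace[-1] - 1e-8 * (1.0 + abs(trace[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased: {trace[-1]:.10f} -> {ll:.10f}"
            )
        trace.append(ll)
        if abs(ll - trace[-2]) <= tol * (1.0 + abs(ll)):
            converged = True
            break
    modal = post.argmax(axis=1)
    mean_post = np.array([
        post[modal == k, k].mean() if (modal == k).any() else np.nan
        for k in range(K)
    ])
    return FittedLPA(
        params=params,
        neg_loglik=-trace[-1],
        n_params=count_parameters(specs, K),
        bic=np.nan,
        posterior=post,
        modal_class=modal,
        mean_posterior_by_class=mean_post,
        converged=converged,
        n_iterations=it,
        n_restarts=1,
        seed=seed,
        loglik_trace=trace,
    )


def enumerate_classes(
    Y: np.ndarray,
    specs: Sequence[VariableSpec],
    K_range: Sequence[int],
    **settings,
):
    """Fit each K and tabulate (n_params, neg_loglik, BIC); pick min-BIC K.

    Ties (within 1e-9) break toward the smaller K.  A failing K is recorded
    with NaNs and does not abort the other fits.
    """
    import pandas as pd

    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be nonempty")
    rows = []
    fits: dict[int, FittedLPA] = {}
    for K in K_range:
        try:
            fit = fit_em(Y, specs, K, **settings)
            fits[K] = fit
            rows.append(
                {"K": K, "n_params": fit.n_params,
                 "neg_loglik": fit.neg_loglik, "bic": fit.bic, "error": ""}
            )
        except Exception as e:  # noqa: BLE001 - per-K isolation is the contract
            warnings.warn(f"K={K} failed: {e}")
            rows.append(
                {"K": K, "n_params": count_parameters(specs, K),
                 "neg_loglik": np.nan, "bic": np.nan, "error": str(e)}
            )
    table = pd.DataFrame(rows).set_index("K")
    ok = table["bic"].dropna()
    if ok.empty:
        raise RuntimeError("every K failed to fit")
    best = ok.min()
    chosen = int(min(k for k, b in ok.items() if b <= best + 1e-9))
    return table, chosen, fits


def dispersion_diagnostic(
    fitted: FittedLPA, Y: np.ndarray, specs: Sequence[VariableSpec]
) -> dict[str, float]:
    """Pearson chi2/df for each count indicator (overdispersion check).

    The likelihood treats counts as plain Poisson; a ratio well above 1
    flags extra-Poisson variation for the fitted rates.
    """
    out: dict[str, float] = {}
    for j, spec in enumerate(specs):
        if spec.family != "count":
            continue
        y = Y[:, j]
        obs = ~np.isnan(y)
        lam = np.exp(fitted.params.log_rates[spec.name])  # (K,)
        mu = (fitted.posterior[obs] * lam[None, :]).sum(axis=1)
        var = (fitted.posterior[obs] * (lam[None, :] + lam[None, :] ** 2)).sum(
            axis=1
        ) - mu**2
        pearson = ((y[obs] - mu) ** 2 / np.maximum(var, 1e-12)).sum()
        out[spec.name] = float(pearson / max(obs.sum() - fitted.params.K, 1))
    return out
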