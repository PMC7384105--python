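"""Bootstrap optimism correction of prediction performance (Harrell).

Apparent (naive) performance of a prognostic model fit and evaluated on
the same sample overstates out-of-sample performance.  The optimism is
estimated by, for each bootstrap replicate: resampling participants with
replacement, refitting the full prediction model from scratch, and taking
the difference between the refit model's apparent performance on the
bootstrap sample and its performance on the original sample.  The mean of
those differences is subtracted from the naive estimate.

Performance here is the per-class mean predicted probability of a
participant's own assigned class (plus an overall mean across all rows).
Class labels are treated as fixed during bootstrapping: only the
prediction model is refit inside the loop, not the latent class model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# fit(X, y) -> predict: callable mapping any X to an (n, K) probability matrix
Fitter = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def apparent_performance(
    prob: np.ndarray, labels: np.ndarray, K: int | None = None
) -> tuple[np.ndarray, float]:
    """Per-class mean own-class predicted probability, and the overall mean.

    A class with no assigned members is reported as NaN.
    """
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels, dtype=int)
    K = K if K is not None else prob.shape[1]
    own = prob[np.arange(len(labels)), labels]
    per_class = np.array([
        own[labels == k].mean() if (labels == k).any() else np.nan
        for k in range(K)
    ])
    return per_class, float(own.mean())


@dataclass
class OptimismReport:
    naive: np.ndarray  # per class
    optimism: np.ndarray
    adjusted: np.ndarray  # = naive - optimism, exactly
    naive_overall: float
    optimism_overall: float
    adjusted_overall: float
    B: int
    seed: int | None
    n_skipped: int
    trace: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        K = len(self.naive)
        return pd.DataFrame(
            {"naive": self.naive, "optimism": self.optimism, "adjusted": self.adjusted},
            index=pd.Index(range(1, K + 1), name="class"),
        )


def bootstrap_optimism(
    X: np.ndarray,
    labels: np.ndarray,
    fitter: Fitter,
    B: int = 100,
    seed: int | None = 0,
    K: int | None = None,
    stratified: bool = False,
    variant: str = "harrell",
    _resampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> OptimismReport:
    """Optimism-corrected per-class performance of ``fitter`` on (X, labels).

    ``fitter`` must refit the full prediction model from scratch on the
    rows it is given.  Replicates in which some class is absent are skipped
    and logged; more than 20% skipped is an error.  ``variant="literal"``
    replaces the refit model's performance on the original sample with the
    whole-sample model's performance on the original sample when forming
    each replicate's difference.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    K = K if K is not None else int(y.max()) + 1
    rng = np.random.default_rng(seed)

    predict_full = fitter(X, y)
    naive, naive_overall = apparent_performance(predict_full(X), y, K)

    rows = []
    n_skipped = 0
    for b in range(B):
        if _resampler is not None:
            idx = np.asarray(_resampler(rng, n), dtype=int)
        elif stratified:
            idx = np.concatenate([
                rng.choice(np.nonzero(y == k)[0], size=(y == k).sum(), replace=True)
                for k in range(K)
            ])
        else:
            idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.unique(yb).size < K:
            n_skipped += 1
            log.info("bootstrap replicate %d skipped: class absent", b)
            continue
        try:
            predict_b = fitter(X[idx], yb)
        except Exception as e:  # noqa: BLE001 - replicate-level isolation
            n_skipped += 1
            log.warning("bootstrap replicate %d failed: %s", b, e)
            continue
        perf_boot, perf_boot_overall = apparent_performance(predict_b(X[idx]), yb, K)
        if variant == "harrell":
            perf_orig, perf_orig_overall = apparent_performance(predict_b(X), y, K)
        elif variant == "literal":
            perf_orig, perf_orig_overall = naive, naive_overall
        else:
            raise ValueError(f"unknown variant {variant!r}")
        rows.append({
            "replicate": b,
            **{f"optimism_class_{k + 1}": perf_boot[k] - perf_orig[k] for k in range(K)},
            "optimism_overall": perf_boot_overall - perf_orig_overall,
        })
    if n_skipped > 0.2 * B:
        raise RuntimeError(
            f"{n_skipped}/{B} bootstrap replicates skipped; sample too small "
            "or model too unstable for optimism correction"
        )
    trace = pd.DataFrame(rows)
    optimism = np.array([
        trace[f"optimism_class_{k + 1}"].mean() for k in range(K)
    ])
    optimism_overall = float(trace["optimism_overall"].mean())
    return OptimismReport(
        naive=naive,
        optimism=optimism,
        adjusted=naive - optimism,
        naive_overall=naive_overall,
        optimism_overall=optimism_overall,
        adjusted_overall=naive_overall - optimism_overall,
        B=B,
        seed=seed,
        n_skipped=n_skipped,
        trace=trace,
    )


def multinomial_fitter(K: int, ridge: float = 0.0) -> Fitter:
    """Fitter adapter around the package's multinomial logit."""
    from .prediction import fit_multinomial

    def fit(X: np.ndarray, y: np.ndarray):
        model = fit_multinomial(X, y, K, ridge=ridge)
        return lambda Xnew: model.predict_proba(np.asarray(Xnew, float))

    return fit
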