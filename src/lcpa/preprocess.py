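"""Scale construction applied before mixture fitting.

Two rules: item totals are prorated when at least 80% of items are
complete, and continuous indicators are standardized (observed values only)
and, where needed, reversed so that higher processed scores consistently
mean a poorer outcome.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .variables import CohortTable, VariableSpec


def prorate_total(
    item_values: Sequence[float | None], min_prop: float = 0.8
) -> float:
    """Prorated scale total from possibly-missing item scores.

    Returns ``(sum of observed) * n_items / n_observed`` when the observed
    fraction is at least ``min_prop``, otherwise NaN (missing).
    """
    if not 0 < min_prop <= 1:
        raise ValueError("min_prop must be in (0, 1]")
    items = np.array(
        [np.nan if v is None else float(v) for v in item_values], dtype=float
    )
    if items.size == 0:
        raise ValueError("malformed scale definition: empty item list")
    obs = ~np.isnan(items)
    n_obs = int(obs.sum())
    if n_obs / items.size < min_prop or n_obs == 0:
        return float("nan")
    return float(items[obs].sum() * items.size / n_obs)


def standardize_and_orient(
    column: np.ndarray, reverse: bool = False
) -> np.ndarray:
    """Standardize observed entries to mean 0, sample variance 1; negate if reversed.

    Missing entries (NaN) pass through untouched.  Uses the ddof=1 sample
    standard deviation over observed values.
    """
    x = np.asarray(column, dtype=float).copy()
    obs = ~np.isnan(x)
    vals = x[obs]
    if vals.size < 2:
        raise ValueError("need at least 2 observed values to standardize")
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate indicator: zero variance")
    z = (vals - vals.mean()) / sd
    x[obs] = -z if reverse else z
    return x


def prepare_indicators(
    table: CohortTable, specs: Sequence[VariableSpec] | None = None
) -> tuple[np.ndarray, list[VariableSpec]]:
    """Processed indicator matrix for mixture fitting.

    Gaussian indicators are standardized and oriented; ordinal and count
    indicators pass through on their raw integer scales (their orientation
    is encoded by the scale itself).
    """
    specs = list(specs) if specs is not None else table.indicator_specs
    Y = table.matrix(specs)
    for j, spec in enumerate(specs):
        if spec.family == "gaussian":
            Y[:, j] = standardize_and_orient(Y[:, j], reverse=spec.reverse)
    return Y, specs


def standardization_stats(
    table: CohortTable, specs: Sequence[VariableSpec] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-gaussian-indicator (mean, sample SD) over observed values.

    Needed to map fitted class means back to the raw instrument scales.
    """
    specs = list(specs) if specs is not None else table.indicator_specs
    out: dict[str, tuple[float, float]] = {}
    for spec in specs:
        if spec.family != "gaussian":
            continue
        vals = table.data[spec.name].dropna().to_numpy(dtype=float)
        out[spec.name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
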