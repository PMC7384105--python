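"""Variable specifications and the participant-by-variable cohort container.

A cohort is a rectangular table of participants by variables with arbitrary
missingness.  Variables are typed by family: ``gaussian`` (continuous scale
totals), ``ordinal`` (small integer scales such as symptom severity or a
work rating), or ``count`` (e.g. number of prescribed medicines).  Each
variable plays a role: adult outcome ``indicator``, childhood ``predictor``,
or nonclinical ``covariate``.

Missing values are carried by an explicit boolean mask (NaN in the numeric
matrix mirrors the mask but the mask is authoritative), because zero is a
legal value for count and some ordinal scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("gaussian", "ordinal", "count")
ROLES = ("indicator", "predictor", "covariate")


@dataclass(frozen=True)
class VariableSpec:
    """Typed description of one cohort variable.

    Parameters
    ----------
    name : str
        Unique identifier (CSV column name).
    family : {"gaussian", "ordinal", "count"}
        Distributional family used by the mixture model.
    n_levels : int, optional
        Number of ordered levels; required iff ``family == "ordinal"``.
    level_min : int
        Integer score of the lowest level (ordinal only; e.g. 0 for a
        friendship scale scored 0-3, 1 for a 1-10 severity score).
    reverse : bool
        If True, the processed score is negated after standardization so
        that higher always means a poorer outcome.
    role : {"indicator", "predictor", "covariate"}
    age_wave : float, optional
        Assessment age in years (predictors only).
    """

    name: str
    family: str
    n_levels: int | None = None
    level_min: int = 1
    reverse: bool = False
    role: str = "indicator"
    age_wave: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.name!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.family == "ordinal":
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError(
                    f"ordinal variable {self.name!r} needs n_levels >= 2"
                )
        elif self.n_levels is not None:
            raise ValueError(
                f"n_levels only applies to ordinal variables ({self.name!r})"
            )

    @property
    def level_max(self) -> int:
        if self.family != "ordinal":
            raise AttributeError("level_max is defined for ordinal variables only")
        return self.level_min + self.n_levels - 1


def check_unique_names(specs: Iterable[VariableSpec]) -> None:
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate variable names: {sorted(dupes)}")


def validate_column(spec: VariableSpec, values: np.ndarray) -> list[int]:
    """Return row indices whose observed values violate the spec's support."""
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    bad: list[int] = []
    if spec.family == "ordinal":
        lo, hi = spec.level_min, spec.level_max
        for i in np.nonzero(obs)[0]:
            x = v[i]
            if x != np.floor(x) or x < lo or x > hi:
                bad.append(int(i))
    elif spec.family == "count":
        for i in np.nonzero(obs)[0]:
            x = v[i]
            if x != np.floor(x) or x < 0:
                bad.append(int(i))
    return bad


@dataclass
class CohortTable:
    """Participants x variables with a missing mask and optional weights.

    ``data`` holds one column per variable (float; NaN where missing) plus
    any untyped covariate columns (e.g. a categorical recruitment site).
    ``include_predictive`` flags rows eligible for the prediction stage
    (late recruits are profiled but not predicted).
    """

    data: pd.DataFrame
    specs: list[VariableSpec] = field(default_factory=list)
    weights: pd.Series | None = None
    include_predictive: pd.Series | None = None

    def __post_init__(self) -> None:
        check_unique_names(self.specs)
        for spec in self.specs:
            if spec.name not in self.data.columns:
                raise ValueError(f"column {spec.name!r} missing from data")
            bad = validate_column(spec, self.data[spec.name].to_numpy(dtype=float))
            if bad:
                raise ValueError(
                    f"variable {spec.name!r}: out-of-support values in rows {bad[:10]}"
                )
        if self.weights is not None:
            w = self.weights.reindex(self.data.index)
            if w.isna().any():
                raise ValueError("weights missing for some analysed rows")
            if (w <= 0).any():
                raise ValueError("weights must be positive")
            self.weights = w
        if self.include_predictive is None:
            self.include_predictive = pd.Series(True, index=self.data.index)
        else:
            self.include_predictive = self.include_predictive.reindex(
                self.data.index
            ).fillna(False).astype(bool)

    @property
    def n(self) -> int:
        return len(self.data)

    def specs_by_role(self, role: str) -> list[VariableSpec]:
        return [s for s in self.specs if s.role == role]

    @property
    def indicator_specs(self) -> list[VariableSpec]:
        return self.specs_by_role("indicator")

    def matrix(self, specs: Sequence[VariableSpec] | None = None) -> np.ndarray:
        """Numeric matrix (NaN = missing) for the given specs, in order."""
        specs = list(specs) if specs is not None else self.specs
        return self.data[[s.name for s in specs]].to_numpy(dtype=float)

    def missing_mask(self, specs: Sequence[VariableSpec] | None = None) -> np.ndarray:
        return np.isnan(self.matrix(specs))


def default_indicator_specs(
    variant: str = "full",
) -> list[VariableSpec]:
    """Adult-outcome indicator set.

    The full profile has 15 measures: ten continuous scale totals, four
    ordinal scales (symptom severity 1-10, work 1-7, living situation 1-3,
    friendships 0-3) and one count (number of medicines).  ``variant``
    selects the reduced profiles used in robustness reruns: ``"minus_iq"``
    drops adult verbal and nonverbal IQ; ``"minus_iq_css"`` additionally
    drops the severity score.
    """
    specs = [
        VariableSpec("css", "ordinal", n_levels=10, level_min=1),
        VariableSpec("viq", "gaussian", reverse=True),
        VariableSpec("nviq", "gaussian", reverse=True),
        VariableSpec("hyperactivity", "gaussian"),
        VariableSpec("irritability", "gaussian"),
        VariableSpec("abcl", "gaussian"),
        VariableSpec("bdi", "gaussian"),
        VariableSpec("panas_pos", "gaussian", reverse=True),
        VariableSpec("panas_neg", "gaussian"),
        VariableSpec("wbq", "gaussian", reverse=True),
        VariableSpec("n_meds", "count"),
        VariableSpec("work", "ordinal", n_levels=7, level_min=1),
        VariableSpec("living", "ordinal", n_levels=3, level_min=1),
        VariableSpec("friends", "ordinal", n_levels=4, level_min=0),
        VariableSpec("daily_living", "gaussian", reverse=True),
    ]
    if variant == "full":
        return specs
    if variant == "minus_iq":
        return [s for s in specs if s.name not in ("viq", "nviq")]
    if variant == "minus_iq_css":
        return [s for s in specs if s.name not in ("viq", "nviq", "css")]
    raise ValueError(f"unknown indicator variant {variant!r}")
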