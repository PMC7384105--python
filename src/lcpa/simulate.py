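"""Seeded generator of EDX-like cohorts with a known four-class structure.

The Early Diagnosis (EDX) cohort followed children referred for possible
autism around age 2 into adulthood; its data were never deposited.  This
module generates synthetic cohorts whose adult-outcome indicators follow
the published four-class typology (class-conditional means/SDs, weighted
prevalences 22/26/25/27%), whose per-variable missingness matches the
published observation counts under a missing-at-random mechanism, and
whose childhood predictors carry class signal that strengthens with
assessment age (2 -> 3 -> 9, with little gain from 3 to 5).  Every draw is
reproducible from a single seed and the true class labels are returned for
testing.

Gaussian indicators are truncated to each instrument's published range;
the underlying truncated-normal parameters are solved numerically so the
post-truncation mean and SD match the target profile cells.  Ordinal
indicators use the same cumulative-logit family as the mixture model, with
per-class locations calibrated so the implied mean integer score matches
the target class mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.special import expit
from scipy.stats import truncnorm

from .variables import CohortTable, VariableSpec, default_indicator_specs

N_STUDY = 123  # analysed sample size of the reference cohort
PREVALENCES = (0.22, 0.26, 0.25, 0.27)

# Published adult-outcome class profiles: per variable, class means, SDs and
# observed counts (classes ordered Best / High-IQ / Low-IQ / Low-IQ+behaviour),
# plus the instrument range for the continuous scales.
ADULT_PROFILE: dict[str, dict] = {
    "css": {
        "family": "ordinal", "n_levels": 10, "level_min": 1,
        "means": (3.2, 6.0, 6.6, 6.4), "sds": (1.7, 2.5, 2.2, 2.9),
        "n_obs": (29, 28, 31, 30),
    },
    "viq": {
        "family": "gaussian", "range": (2.0, 139.0),
        "means": (112.4, 90.1, 32.8, 11.0), "sds": (14.0, 20.6, 10.7, 7.8),
        "n_obs": (31, 29, 31, 32),
    },
    "nviq": {
        "family": "gaussian", "range": (3.0, 133.0),
        "means": (110.2, 92.5, 38.7, 18.0), "sds": (13.5, 14.8, 15.7, 11.0),
        "n_obs": (31, 29, 31, 32),
    },
    "hyperactivity": {
        "family": "gaussian", "range": (0.0, 30.75),
        "means": (1.8, 7.5, 5.7, 14.9), "sds": (1.9, 7.6, 5.3, 8.0),
        "n_obs": (24, 23, 30, 27),
    },
    "irritability": {
        "family": "gaussian", "range": (0.0, 37.5),
        "means": (1.7, 6.6, 5.4, 11.9), "sds": (2.4, 6.8, 5.5, 8.8),
        "n_obs": (24, 23, 30, 27),
    },
    "abcl": {
        "family": "gaussian", "range": (25.0, 77.0),
        "means": (49.0, 56.5, 51.0, 53.2), "sds": (7.9, 10.0, 7.8, 8.0),
        "n_obs": (26, 24, 23, 21),
    },
    "bdi": {
        "family": "gaussian", "range": (0.0, 30.0),
        "means": (4.4, 8.9, 2.2, 4.5), "sds": (5.2, 8.6, 3.6, 4.4),
        "n_obs": (19, 21, 28, 24),
    },
    "panas_pos": {
        "family": "gaussian", "range": (12.0, 45.5),
        "means": (33.4, 27.0, 30.6, 22.9), "sds": (6.9, 7.0, 7.2, 7.9),
        "n_obs": (19, 21, 29, 23),
    },
    "panas_neg": {
        "family": "gaussian", "range": (10.0, 35.5),
        "means": (17.0, 19.1, 16.3, 16.7), "sds": (7.3, 6.6, 6.0, 5.1),
        "n_obs": (19, 21, 29, 24),
    },
    "wbq": {
        "family": "gaussian", "range": (134.0, 248.0),
        "means": (205.1, 183.7, 197.0, 172.5), "sds": (20.6, 22.1, 25.0, 23.8),
        "n_obs": (19, 21, 27, 24),
    },
    "n_meds": {
        "family": "count",
        "means": (0.3, 1.3, 1.2, 2.5), "sds": (0.7, 1.3, 1.3, 1.3),
        "n_obs": (21, 21, 30, 27),
    },
    "work": {
        "family": "ordinal", "n_levels": 7, "level_min": 1,
        "means": (1.3, 4.3, 5.1, 5.9), "sds": (0.6, 2.2, 1.5, 1.0),
        "n_obs": (31, 28, 27, 27),
    },
    "living": {
        "family": "ordinal", "n_levels": 3, "level_min": 1,
        "means": (1.3, 2.0, 2.2, 2.5), "sds": (0.5, 1.0, 0.4, 0.5),
        "n_obs": (31, 29, 31, 32),
    },
    "friends": {
        "family": "ordinal", "n_levels": 4, "level_min": 0,
        "means": (0.2, 1.7, 2.1, 2.8), "sds": (0.5, 1.0, 0.8, 0.4),
        "n_obs": (29, 26, 31, 26),
    },
    "daily_living": {
        "family": "gaussian", "range": (17.0, 112.0),
        "means": (87.7, 69.7, 53.8, 27.8), "sds": (12.3, 12.4, 13.6, 7.7),
        "n_obs": (31, 29, 31, 32),
    },
}

# Childhood measures at recruitment (population mean, SD, plausible range).
# Severity and IQ are published recruitment statistics; the age-2 daily
# living skills entry is a synthetic stand-in (not published).
CHILD_POP: dict[str, tuple[float, float, tuple[float, float]]] = {
    "css": (6.32, 3.07, (1.0, 10.0)),
    "viq": (45.66, 28.44, (1.0, 160.0)),
    "nviq": (71.54, 24.19, (1.0, 160.0)),
    "dls": (55.0, 12.0, (15.0, 120.0)),  # synthetic
}

# Wave signal scalars: fraction of the adult class separation expressed in
# the childhood measure at each age.  Synthetic choices that reproduce the
# qualitative pattern: prediction improves 2 -> 3, little 3 -> 5 gain,
# strongest by 9.
WAVE_SIGNAL: dict[int, float] = {2: 0.55, 3: 0.72, 5: 0.73, 9: 0.85}
PREDICTOR_MEASURES: dict[int, tuple[str, ...]] = {
    2: ("css", "viq", "nviq", "dls"),
    3: ("css", "viq", "nviq"),
    5: ("css", "viq", "nviq"),
    9: ("css", "viq", "nviq"),
}

_LOGISTIC_SD = float(np.pi / np.sqrt(3.0))


@dataclass
class GaussianClassParams:
    means: np.ndarray  # post-truncation target means, (K,)
    sds: np.ndarray
    bounds: tuple[float, float]
    latent_means: np.ndarray  # solved underlying truncated-normal parameters
    latent_sds: np.ndarray
    # per-class SD mismatch left after truncation (0 when both moments match;
    # nonzero flags cells whose published shape a truncated normal cannot take)
    sd_residuals: np.ndarray | None = None


@dataclass
class OrdinalClassParams:
    cutpoints: np.ndarray  # (L-1,)
    locations: np.ndarray  # (K,)
    n_levels: int
    level_min: int
    target_means: np.ndarray


@dataclass
class CountClassParams:
    rates: np.ndarray  # (K,)


@dataclass
class GeneratorConfig:
    K: int
    prevalences: np.ndarray
    gaussian: dict[str, GaussianClassParams] = field(default_factory=dict)
    ordinal: dict[str, OrdinalClassParams] = field(default_factory=dict)
    count: dict[str, CountClassParams] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    wave_signal: dict[int, float] = field(default_factory=lambda: dict(WAVE_SIGNAL))
    indicator_variant: str = "full"

    def validate(self) -> None:
        p = np.asarray(self.prevalences, float)
        if p.shape != (self.K,) or abs(p.sum() - 1.0) > 1e-8 or np.any(p <= 0):
            raise ValueError("prevalences must be K positive values summing to 1")
        for name, g in self.gaussian.items():
            if np.any(np.asarray(g.sds) <= 0) or np.any(g.latent_sds <= 0):
                raise ValueError(f"gaussian {name!r}: SDs must be positive")
        for name, c in self.count.items():
            if np.any(c.rates <= 0):
                raise ValueError(f"count {name!r}: rates must be positive")
        for name, o in self.ordinal.items():
            if np.any(np.diff(o.cutpoints) <= 0):
                raise ValueError(f"ordinal {name!r}: cutpoints must increase")
        for name, r in self.missing_rates.items():
            if not 0 <= r < 1:
                raise ValueError(f"missing rate for {name!r} must be in [0, 1)")


# ---------------------------------------------------------------------------
# calibration helpers


def _truncnorm_stats(mu: float, sig: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sig, (hi - mu) / sig
    m, v = truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
    m, s = float(m), float(np.sqrt(v))
    if not np.isfinite(m):  # deep-tail truncation saturates at the boundary
        m = lo if mu < lo else hi
        s = 0.0
    return m, s


def _mu_matching_mean(mean: float, sig: float, lo: float, hi: float) -> float:
    """The truncated mean is monotone in mu and spans (lo, hi); invert it."""
    f = lambda mu: _truncnorm_stats(mu, sig, lo, hi)[0] - mean  # noqa: E731
    a = b = float(mean)
    step = max(sig, (hi - lo) / 10)
    for _ in range(200):
        if f(a) <= 0:
            break
        a -= step
        step *= 1.5
    step = max(sig, (hi - lo) / 10)
    for _ in range(200):
        if f(b) >= 0:
            break
        b += step
        step *= 1.5
    return brentq(f, a, b, xtol=1e-10)


from functools import lru_cache


@lru_cache(maxsize=1024)
def _solve_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncation has the given moments.

    Some published cells (skewed scales such as depression scores bounded
    at zero) have SD/mean ratios no truncated normal attains; for these the
    class mean is matched exactly and the SD residual is minimized and
    returned so callers can flag it.
    """

    def moments(x):
        mu, logsig = x
        m, s = _truncnorm_stats(mu, np.exp(logsig), lo, hi)
        return [m - mean, s - sd]

    sol = root(moments, x0=[mean, np.log(sd)], method="hybr", tol=1e-12)
    if sol.success and np.max(np.abs(sol.fun)) < 1e-8:
        mu, logsig = sol.x
        return float(mu), float(np.exp(logsig)), 0.0

    # match the mean exactly; pick sigma minimizing the SD mismatch
    from scipy.optimize import minimize_scalar

    def sd_err(logsig):
        sig = float(np.exp(logsig))
        mu = _mu_matching_mean(mean, sig, lo, hi)
        return (_truncnorm_stats(mu, sig, lo, hi)[1] - sd) ** 2

    res = minimize_scalar(
        sd_err, bounds=(np.log(sd / 10), np.log(10 * (hi - lo))),
        method="bounded", options={"xatol": 1e-8},
    )
    sig = float(np.exp(res.x))
    mu = _mu_matching_mean(mean, sig, lo, hi)
    resid = _truncnorm_stats(mu, sig, lo, hi)[1] - sd
    return float(mu), sig, float(resid)


def _ordinal_mean(eta: float, cutpoints: np.ndarray, scores: np.ndarray) -> float:
    F = expit(cutpoints - eta)
    cum = np.concatenate([[0.0], F, [1.0]])
    p = np.diff(cum)
    return float((p * scores).sum())


def _calibrate_ordinal(
    means: np.ndarray, sds: np.ndarray, prevalences: np.ndarray,
    n_levels: int, level_min: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared cutpoints + per-class locations matching the class mean scores.

    Cutpoint spacing on the latent logistic scale is set from the average
    within-class SD (latent SD pi/sqrt(3) divided by the score-scale SD),
    and class locations are solved monotonically by bisection.
    """
    scores = level_min + np.arange(n_levels, dtype=float)
    center = float((prevalences * means).sum())
    delta = _LOGISTIC_SD / float(np.mean(sds))
    bounds = scores[:-1] + 0.5
    cut = delta * (bounds - center)
    locs = []
    for m in means:
        f = lambda e: _ordinal_mean(e, cut, scores) - m  # noqa: E731
        lo_b, hi_b = -40.0, 40.0
        locs.append(brentq(f, lo_b, hi_b, xtol=1e-10))
    return cut, np.asarray(locs)


def default_cohort_config(variant: str = "full") -> GeneratorConfig:
    """Generator calibrated to the published four-class adult typology."""
    K = 4
    prev = np.asarray(PREVALENCES, float)
    cfg = GeneratorConfig(K=K, prevalences=prev, indicator_variant=variant)
    keep = {s.name for s in default_indicator_specs(variant)}
    for name, cell in ADULT_PROFILE.items():
        means = np.asarray(cell["means"], float)
        sds = np.asarray(cell["sds"], float)
        if name in keep:
            cfg.missing_rates[name] = 1.0 - sum(cell["n_obs"]) / N_STUDY
        if cell["family"] == "gaussian":
            lo, hi = cell["range"]
            lat = np.array([
                _solve_truncnorm(m, s, lo, hi) for m, s in zip(means, sds)
            ])
            cfg.gaussian[name] = GaussianClassParams(
                means=means, sds=sds, bounds=(lo, hi),
                latent_means=lat[:, 0], latent_sds=lat[:, 1],
                sd_residuals=lat[:, 2],
            )
        elif cell["family"] == "ordinal":
            cut, locs = _calibrate_ordinal(
                means, sds, prev, cell["n_levels"], cell["level_min"]
            )
            cfg.ordinal[name] = OrdinalClassParams(
                cutpoints=cut, locations=locs,
                n_levels=cell["n_levels"], level_min=cell["level_min"],
                target_means=means,
            )
        else:
            cfg.count[name] = CountClassParams(rates=means.copy())
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation


def _sample_gaussian(
    rng: np.random.Generator, g: GaussianClassParams, labels: np.ndarray
) -> np.ndarray:
    lo, hi = g.bounds
    out = np.empty(labels.size)
    for k in range(len(g.means)):
        sel = labels == k
        if not sel.any():
            continue
        mu, sig = g.latent_means[k], g.latent_sds[k]
        a, b = (lo - mu) / sig, (hi - mu) / sig
        out[sel] = truncnorm.rvs(a, b, loc=mu, scale=sig,
                                 size=int(sel.sum()), random_state=rng)
    return out


def _sample_ordinal(
    rng: np.random.Generator, o: OrdinalClassParams, labels: np.ndarray
) -> np.ndarray:
    eta = o.locations[labels]
    z = eta + rng.logistic(size=labels.size)
    level = np.searchsorted(o.cutpoints, z)
    return (o.level_min + level).astype(float)


def impose_mar_missingness(
    df: pd.DataFrame,
    rates: dict[str, float],
    seed: int | None = 0,
    driver: str = "maternal_edu",
    gamma: float = 0.4,
) -> pd.DataFrame:
    """Mask entries with probability tied only to an always-observed covariate.

    The per-row masking probability is ``rate * exp(gamma * z) / mean(exp)``
    where ``z`` is the standardized driver covariate, so the marginal rate
    stays at ``rate`` while missingness depends only on observed data
    (missing at random by construction, never on the masked value).
    """
    for name, r in rates.items():
        if not 0 <= r < 1:
            raise ValueError(f"missing rate for {name!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = df.copy()
    z = df[driver].to_numpy(dtype=float)
    z = (z - z.mean()) / (z.std() or 1.0)
    mult = np.exp(gamma * z)
    mult = mult / mult.mean()
    for name, r in rates.items():
        if r == 0:
            continue
        p = np.clip(r * mult, 0.0, 0.95)
        mask = rng.random(len(df)) < p
        out.loc[mask, name] = np.nan
    return out


def generate_cohort(
    config: GeneratorConfig,
    n: int = N_STUDY,
    seed: int | None = 0,
    missingness: bool = True,
    predictor_signal: float | None = None,
) -> tuple[CohortTable, np.ndarray]:
    """Draw a cohort and its hidden true class labels.

    ``predictor_signal`` globally rescales the wave signal scalars
    (0 gives class-uninformative childhood predictors, for null studies).
    """
    config.validate()
    if n < config.K:
        raise ValueError("need n >= K")
    rng = np.random.default_rng(seed)
    labels = rng.choice(config.K, size=n, p=np.asarray(config.prevalences, float))

    data: dict[str, np.ndarray | pd.Series] = {}
    # nonclinical covariates (marginals match the reference cohort)
    data["non_caucasian"] = rng.random(n) < 0.17
    data["female"] = rng.random(n) < 0.17
    medu = np.clip(np.rint(rng.normal(2.24, 1.09, size=n)), 1, 5)
    data["maternal_edu"] = medu
    site = rng.choice(["NC", "CHI", "MI"], size=n, p=np.array([61, 45, 17]) / 123)
    data["site"] = site

    specs = default_indicator_specs(config.indicator_variant)
    for spec in specs:
        name = spec.name
        if name in config.gaussian:
            data[name] = _sample_gaussian(rng, config.gaussian[name], labels)
        elif name in config.ordinal:
            data[name] = _sample_ordinal(rng, config.ordinal[name], labels)
        elif name in config.count:
            data[name] = rng.poisson(config.count[name].rates[labels]).astype(float)
        else:
            raise ValueError(f"generator config lacks parameters for {name!r}")

    # childhood predictors: class signal grows with assessment age
    scale = 1.0 if predictor_signal is None else float(predictor_signal)
    adult_for = {"css": "css", "viq": "viq", "nviq": "nviq", "dls": "daily_living"}
    for wave, measures in PREDICTOR_MEASURES.items():
        s_w = np.clip(config.wave_signal[wave] * scale, 0.0, 0.98)
        for meas in measures:
            pop_mean, pop_sd, (lo, hi) = CHILD_POP[meas]
            prof = ADULT_PROFILE[adult_for[meas]]
            adult_means = np.asarray(prof["means"], float)
            grand = float((np.asarray(config.prevalences) * adult_means).sum())
            spread = float(np.sqrt(
                (np.asarray(config.prevalences) * (adult_means - grand) ** 2).sum()
            ))
            d = (adult_means - grand) / (spread or 1.0)
            mu_k = pop_mean + s_w * d * pop_sd
            noise_sd = pop_sd * np.sqrt(max(1.0 - s_w**2, 0.04))
            vals = mu_k[labels] + rng.normal(0.0, noise_sd, size=n)
            data[f"{meas}_{wave}"] = np.clip(vals, lo, hi)

    df = pd.DataFrame(data)
    df["non_caucasian"] = df["non_caucasian"].astype(float)
    df["female"] = df["female"].astype(float)

    # structural wave availability: late recruits (Michigan) lack waves 2-5;
    # the age-5 assessment ran at the North Carolina site only
    late = df["site"] == "MI"
    for wave, measures in PREDICTOR_MEASURES.items():
        for meas in measures:
            col = f"{meas}_{wave}"
            if wave in (2, 3, 5):
                df.loc[late, col] = np.nan
            if wave == 5:
                df.loc[df["site"] != "NC", col] = np.nan

    if missingness:
        rates = {k: v for k, v in config.missing_rates.items() if k in df.columns}
        df = impose_mar_missingness(
            df, rates, seed=int(rng.integers(0, 2**31 - 1))
        )

    # attrition weights: retention falls with minority status and low
    # maternal education, mirroring the reference cohort's attrition pattern
    lin = 0.2 + 0.45 * (medu - medu.mean()) - 1.0 * df["non_caucasian"].to_numpy()
    r = expit(lin)
    w = 1.0 / np.clip(r, 1e-3, 1.0)
    weights = pd.Series(w / w.mean(), index=df.index)

    specs_full = list(specs) + _predictor_specs() + _covariate_specs()
    table = CohortTable(
        data=df,
        specs=[s for s in specs_full if s.name in df.columns],
        weights=weights,
        include_predictive=pd.Series(~late.to_numpy(), index=df.index),
    )
    return table, labels


def _predictor_specs() -> list[VariableSpec]:
    out = []
    for wave, measures in PREDICTOR_MEASURES.items():
        for meas in measures:
            out.append(VariableSpec(
                f"{meas}_{wave}", "gaussian", role="predictor", age_wave=float(wave)
            ))
    return out


def _covariate_specs() -> list[VariableSpec]:
    return [
        VariableSpec("non_caucasian", "gaussian", role="covariate"),
        VariableSpec("female", "gaussian", role="covariate"),
        VariableSpec("maternal_edu", "gaussian", role="covariate"),
    ]
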