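"""Synthetic street-survey cohorts for rank-based social-norms analysis.

Generates a pool of surveyed drinkers (breath alcohol, demographics,
covariates) stratified into gender x location reference groups, and a
judgment subsample whose 1-10 ratings are produced by a configurable
mechanism: rank-based, asymmetrically-weighted-rank-based, or
absolute-BrAC-based.  Every draw is reproducible from a single integer
seed, so the downstream rank / regression / eta-scan machinery is fully
testable without any external data.

BrAC marginals are truncated normals calibrated so that the *observed*
(post-truncation) mean and SD match the configured per-gender values;
per-location additive offsets and multiplicative spread factors create
the between- and within-group heterogeneity that makes rank and absolute
level genuinely different measures.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

GENDERS = ("M", "F")

#: The four judgment questions, each answered on a 1 (low) .. 10 (high) scale.
RATING_COLUMNS = (
    "judge_drunk",        # how drunk are you right now
    "judge_extreme",      # how extreme has your drinking been tonight
    "judge_health15y",    # risk to long-term health over 15 years
    "judge_cirrhosis15y", # risk of liver cirrhosis over 15 years
)

#: Names accepted in JudgementMechanism.covariate_effects (regression scale).
COVARIATE_NAMES = (
    "brac", "rank", "group_mean_distance",
    "duration", "after_11pm", "male", "fast", "age",
)


class ConfigurationError(ValueError):
    """A cohort/mechanism configuration field is invalid."""


class SamplingError(ValueError):
    """A requested subsample cannot be drawn from the pool."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic survey pool.

    BrAC means/SDs are the target moments of the generated (truncated at
    zero) distribution in ug alcohol / 100 ml breath.  Location effects
    are an additive shift plus a multiplicative spread factor applied to
    the gender baseline; together they produce between-group mean
    variation and within-group spread heterogeneity comparable to the
    study's printed location effect and BrAC-vs-rank collinearity.
    """

    pool_size: int = 1862
    male_fraction: float = 0.632
    n_locations: int = 4
    brac_params_by_gender: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"M": (52.3, 30.0), "F": (43.0, 27.8)}
    )
    location_offsets: Sequence[float] = (-8.0, -3.0, 3.0, 8.0)
    location_scales: Sequence[float] = (0.56, 0.80, 1.08, 1.31)
    zero_brac_fraction: float = 0.05
    judgement_subsample: int = 400
    # covariates (independent of BrAC by default)
    duration_mean_h: float = 5.36
    duration_sd_h: float = 3.62
    after_11pm_prob: float = 0.60
    fast_mean: float = 6.18
    fast_sd: float = 3.49
    age_mean_y: float = 26.28
    age_sd_y: float = 8.78
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.pool_size, (int, np.integer)) and self.pool_size >= 1):
            raise ConfigurationError(f"pool_size must be a positive integer, got {self.pool_size!r}")
        if self.pool_size < self.n_locations * len(GENDERS):
            raise ConfigurationError(
                f"pool_size={self.pool_size} smaller than number of groups "
                f"({self.n_locations * len(GENDERS)})"
            )
        for name in ("male_fraction", "zero_brac_fraction", "after_11pm_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_locations < 1:
            raise ConfigurationError(f"n_locations must be >= 1, got {self.n_locations!r}")
        if len(self.location_offsets) != self.n_locations:
            raise ConfigurationError(
                f"location_offsets has {len(self.location_offsets)} entries "
                f"for n_locations={self.n_locations}"
            )
        if len(self.location_scales) != self.n_locations:
            raise ConfigurationError(
                f"location_scales has {len(self.location_scales)} entries "
                f"for n_locations={self.n_locations}"
            )
        if any(s <= 0 for s in self.location_scales):
            raise ConfigurationError("location_scales must all be positive")
        for g in GENDERS:
            if g not in self.brac_params_by_gender:
                raise ConfigurationError(f"brac_params_by_gender missing gender {g!r}")
            mean, sd = self.brac_params_by_gender[g]
            if sd <= 0:
                raise ConfigurationError(f"brac SD for gender {g!r} must be > 0, got {sd!r}")
            if mean <= 0:
                raise ConfigurationError(f"brac mean for gender {g!r} must be > 0, got {mean!r}")
        for name in ("duration_sd_h", "fast_sd", "age_sd_y"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.judgement_subsample < 0:
            raise ConfigurationError("judgement_subsample must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["brac_params_by_gender"] = {k: list(v) for k, v in self.brac_params_by_gender.items()}
        d["location_offsets"] = list(self.location_offsets)
        d["location_scales"] = list(self.location_scales)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class JudgementMechanism:
    """Generative mechanism for the 1-10 judgment ratings.

    rating = intercept + slope * predictor + sum(covariate effects) + noise

    where the predictor is the relative rank R (``kind="rank"``), the
    eta-weighted rank SR(eta) (``kind="weighted_rank"``), or raw BrAC
    (``kind="absolute"``).  Ratings are continuous by default; set
    ``discretize`` to round and clip onto the integer 1-10 instrument
    scale (at the cost of a small attenuation bias in refits).
    """

    kind: str = "rank"
    intercept: float = 2.78
    slope: float = 3.42
    eta: float = 1.0
    noise_sd: float = 1.75
    covariate_effects: Mapping[str, float] | None = None
    discretize: bool = False

    def validate(self) -> None:
        if self.kind not in ("rank", "weighted_rank", "absolute"):
            raise ConfigurationError(f"unknown mechanism kind {self.kind!r}")
        if self.eta <= 0:
            raise ConfigurationError(f"eta must be > 0, got {self.eta!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.covariate_effects:
            for name in self.covariate_effects:
                if name not in COVARIATE_NAMES:
                    raise ConfigurationError(
                        f"unknown covariate effect {name!r}; allowed: {COVARIATE_NAMES}"
                    )


def _hazard(alpha: float) -> float:
    """Standard-normal hazard phi(a) / (1 - Phi(a)), numerically stable."""
    return math.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha))


@lru_cache(maxsize=256)
def truncnorm_params_for_moments(
    target_mean: float, target_sd: float, lower: float = 0.0
) -> tuple[float, float]:
    """Latent (mu, sigma) of a normal truncated below at ``lower`` whose
    truncated distribution has the requested mean and SD.

    With alpha = (lower - mu)/sigma, hazard lam(alpha) and
    delta = lam*(lam - alpha), the truncated moments satisfy
    sd / (mean - lower) = sqrt(1 - delta) / (lam - alpha), a strictly
    increasing function of alpha with range (0, 1) — so the problem
    reduces to a 1-D root find.  Targets with sd >= mean - lower are
    infeasible for a lower-truncated normal and are rejected.
    """
    if target_mean <= lower:
        raise ConfigurationError(
            f"truncated mean target {target_mean} must exceed the truncation point {lower}"
        )
    ratio = target_sd / (target_mean - lower)
    if ratio >= 0.995:
        raise ConfigurationError(
            f"infeasible truncated-normal target: sd={target_sd} too large for "
            f"mean={target_mean} truncated at {lower} (requires sd < mean - lower)"
        )

    def g(alpha: float) -> float:
        lam = _hazard(alpha)
        delta = lam * (lam - alpha)
        return math.sqrt(max(1.0 - delta, 1e-16)) / (lam - alpha) - ratio

    alpha = optimize.brentq(g, -37.0, 30.0, xtol=1e-13)
    lam = _hazard(alpha)
    delta = lam * (lam - alpha)
    sigma = target_sd / math.sqrt(1.0 - delta)
    mu = lower - alpha * sigma
    return float(mu), float(sigma)


def _draw_truncnorm(rng, mean, sd, lower, size):
    """Truncated-normal draws with the given *latent* parameters."""
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_pool(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the full survey pool as one row per respondent.

    Columns follow the survey CSV schema (see :mod:`ranknorms.io`); the
    four rating columns are present but empty (NaN) — ratings are filled
    for a subsample by :func:`generate_judgements`.

    Deterministic for fixed ``seed`` (defaults to ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(config.pool_size)

    n_male = int(round(config.male_fraction * n))
    gender = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(gender)
    location = rng.integers(1, config.n_locations + 1, size=n)

    brac = np.empty(n, dtype=float)
    for g in GENDERS:
        g_mean, g_sd = config.brac_params_by_gender[g]
        for loc in range(1, config.n_locations + 1):
            mask = (gender == g) & (location == loc)
            m = int(mask.sum())
            if m == 0:
                continue
            cell_mean = g_mean + config.location_offsets[loc - 1]
            cell_sd = g_sd * config.location_scales[loc - 1]
            mu, sigma = truncnorm_params_for_moments(round(cell_mean, 9), round(cell_sd, 9))
            brac[mask] = _draw_truncnorm(rng, mu, sigma, 0.0, m)

    n_zero = int(round(config.zero_brac_fraction * n))
    if n_zero > 0:
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        brac[zero_idx] = 0.0

    duration = _draw_truncnorm(rng, config.duration_mean_h, config.duration_sd_h, 0.0, n)
    after_11pm = (rng.random(n) < config.after_11pm_prob).astype(int)
    fast = np.clip(np.round(rng.normal(config.fast_mean, config.fast_sd, n)), 0, 16).astype(int)
    age = _draw_truncnorm(rng, config.age_mean_y, config.age_sd_y, 18.0, n)

    pool = pd.DataFrame(
        {
            "id": [f"P{i + 1:06d}" for i in range(n)],
            "brac_ug_per_100ml": brac,
            "gender": gender,
            "location": location.astype(int),
            "survey_after_23h": after_11pm,
            "session_duration_h": duration,
            "fast_score": fast,
            "age_years": age,
        }
    )
    for col in RATING_COLUMNS:
        pool[col] = np.nan
    return pool


def mechanism_predictor(judgements: pd.DataFrame, mech: JudgementMechanism) -> np.ndarray:
    """The mechanism's predictor values for already-ranked judgment rows.

    Requires rank columns (``below``/``above`` or ``R``) produced by
    :func:`ranknorms.ranks.assign_ranks` on the full pool's groups.
    """
    from .ranks import weighted_rank_from_counts

    if mech.kind == "absolute":
        return judgements["brac_ug_per_100ml"].to_numpy(float)
    if mech.kind == "rank":
        return judgements["R"].to_numpy(float)
    # weighted rank: recompute SR at the mechanism's eta from comparator counts
    return weighted_rank_from_counts(
        judgements["below"].to_numpy(), judgements["above"].to_numpy(), mech.eta
    )


def noise_sd_for_target_r2(signal: np.ndarray, target_r2: float) -> float:
    """Residual SD that makes a simple regression on ``signal`` attain the
    target population R-squared: Var(noise) = Var(signal) * (1 - R2) / R2."""
    if not 0.0 < target_r2 < 1.0:
        raise ConfigurationError(f"target_r2 must lie in (0, 1), got {target_r2!r}")
    sig_var = float(np.var(np.asarray(signal, dtype=float), ddof=1))
    return math.sqrt(sig_var * (1.0 - target_r2) / target_r2)


def generate_judgements(
    pool: pd.DataFrame,
    mech: JudgementMechanism | Mapping[str, JudgementMechanism],
    n_sub: int | None = None,
    seed: int = 0,
    replace: bool = False,
    outcomes: Sequence[str] = RATING_COLUMNS,
) -> pd.DataFrame:
    """Draw a judgment subsample and fill its rating columns.

    Only respondents with BrAC > 0 are judgment-eligible, but everyone in
    the pool — including zero-BrAC respondents — counts as a ranking
    comparator, so ranks are computed within the *full pool's* reference
    groups before ratings are generated.

    ``mech`` may be one mechanism applied to all four outcomes or a
    mapping from rating-column name to mechanism.  With ``replace=True``
    the subsample is drawn with replacement (each drawn row receives
    independent noise), allowing more judgment records than eligible
    respondents.

    Returns the sampled rows (pool columns + rank columns ``below``,
    ``above``, ``n_group``, ``R``, ``group_mean``) with ratings filled.
    """
    from .ranks import assign_ranks

    if isinstance(mech, JudgementMechanism):
        mechs = {out: mech for out in outcomes}
    else:
        mechs = dict(mech)
        unknown = set(mechs) - set(RATING_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown outcome columns: {sorted(unknown)}")
    for m in mechs.values():
        m.validate()

    eligible = pool[pool["brac_ug_per_100ml"] > 0]
    if len(eligible) == 0:
        raise SamplingError("no judgment-eligible respondents (all BrAC = 0)")
    if n_sub is None:
        n_sub = min(len(eligible), 400)
    if n_sub > len(eligible) and not replace:
        raise SamplingError(
            f"requested {n_sub} judgment records but only {len(eligible)} "
            f"pool members have BrAC > 0 (pass replace=True to resample)"
        )

    rng = np.random.default_rng(seed)
    take = rng.choice(eligible.index.to_numpy(), size=n_sub, replace=replace)
    sub = pool.loc[take].reset_index(drop=True).copy()

    ranked = assign_ranks(sub, pool)
    cov_design = _covariate_design(ranked)

    for out in RATING_COLUMNS:
        if out not in mechs:
            continue
        m = mechs[out]
        pred = mechanism_predictor(ranked, m)
        y = m.intercept + m.slope * pred
        if m.covariate_effects:
            for name, coef in m.covariate_effects.items():
                y = y + coef * cov_design[name]
        if m.noise_sd > 0:
            y = y + rng.normal(0.0, m.noise_sd, size=len(y))
        if m.discretize:
            y = np.clip(np.round(y), 1, 10)
        ranked[out] = y
    return ranked


def _covariate_design(ranked: pd.DataFrame) -> dict[str, np.ndarray]:
    """Regression-scale covariate columns from a ranked respondent table."""
    return {
        "brac": ranked["brac_ug_per_100ml"].to_numpy(float),
        "rank": ranked["R"].to_numpy(float),
        "group_mean_distance": (
            ranked["brac_ug_per_100ml"] - ranked["group_mean"]
        ).to_numpy(float),
        "duration": ranked["session_duration_h"].to_numpy(float),
        "after_11pm": ranked["survey_after_23h"].to_numpy(float),
        "male": (ranked["gender"] == "M").to_numpy(float),
        "fast": ranked["fast_score"].to_numpy(float),
        "age": ranked["age_years"].to_numpy(float),
    }
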