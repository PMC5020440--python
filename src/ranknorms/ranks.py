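"""Reference groups and rank statistics for breath alcohol.

The social-comparison model holds that a drinker's judgment of their own
intoxication derives not from their absolute breath alcohol (BrAC) but
from where it *ranks* among the people around them.  Respondents are
partitioned into reference groups (one per gender x location cell); each
judgment-eligible respondent is assigned

* the relative rank ``R = below / (n - 1)``, the proportion of their
  n - 1 comparators with strictly lower BrAC, and
* the weighted rank ``SR = 0.5 + (below - eta*above) / (2*(below + eta*above))``,
  where the comparison-bias parameter eta up-weights the comparators
  above (eta > 1) or below (eta < 1) the respondent.  SR(eta=1) reduces
  algebraically to R.

Ties count in neither ``below`` nor ``above`` (the default, literal
reading of the formula); a mid-rank mode is available for sensitivity.
Zero-BrAC respondents are not judgment-eligible but remain in their
group as comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import RATING_COLUMNS

logger = logging.getLogger(__name__)

#: Covariates Model 4 requires in addition to the ratings.
MODEL4_COVARIATE_COLUMNS = (
    "session_duration_h", "survey_after_23h", "fast_score", "age_years",
)


class RankParameterError(ValueError):
    """Invalid parameter for a rank computation (e.g. eta <= 0)."""


@dataclass(frozen=True)
class ReferenceGroup:
    """One gender x location stratum of the survey pool."""

    gender: str
    location: int
    member_ids: tuple
    brac_sorted: np.ndarray  # ascending, includes zero-BrAC members
    mean_brac: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.gender, self.location)

    @property
    def n(self) -> int:
        return len(self.brac_sorted)


def build_reference_groups(pool: pd.DataFrame) -> dict[tuple[str, int], ReferenceGroup]:
    """Partition the pool into reference groups keyed by (gender, location).

    Every respondent with recorded gender and location belongs to exactly
    one group; rows missing either are rejected with a logged id.  Group
    membership (and hence group size n and the group BrAC mean) includes
    zero-BrAC respondents: they are present in the environment and count
    as comparators even though they are not judgment-eligible themselves.
    """
    ok = pool["gender"].notna() & pool["location"].notna()
    if not ok.all():
        for rid in pool.loc[~ok, "id"]:
            logger.warning("respondent %s rejected: missing gender or location", rid)
    usable = pool[ok]

    groups: dict[tuple[str, int], ReferenceGroup] = {}
    for (gender, location), g in usable.groupby(["gender", "location"], sort=True):
        brac = np.sort(g["brac_ug_per_100ml"].to_numpy(float))
        groups[(gender, int(location))] = ReferenceGroup(
            gender=str(gender),
            location=int(location),
            member_ids=tuple(g["id"]),
            brac_sorted=brac,
            mean_brac=float(brac.mean()),
        )
        if len(brac) == 1:
            logger.warning(
                "singleton reference group %s: rank undefined for its member",
                (gender, int(location)),
            )
    return groups


def mean_comparison_set_size(groups: Mapping[tuple, ReferenceGroup] | Iterable[ReferenceGroup]) -> float:
    """Mean over groups of (n_g - 1), the per-individual comparison-set size.

    For any partition of N respondents into k groups this equals
    (N - k) / k, e.g. 1,862 respondents in 8 groups -> 231.75.
    """
    gs = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    if not gs:
        raise ValueError("no reference groups")
    return float(np.mean([g.n - 1 for g in gs]))


def comparator_counts(brac: float, group: ReferenceGroup) -> tuple[int, int]:
    """(below, above): group members with strictly lower / higher BrAC.

    The respondent is a member of their own group; because the counts are
    strict, they never count themselves (their own value is a tie)."""
    below = int(np.searchsorted(group.brac_sorted, brac, side="left"))
    above = group.n - int(np.searchsorted(group.brac_sorted, brac, side="right"))
    return below, above


def relative_rank(brac: float, group: ReferenceGroup, ties: str = "strict") -> float:
    """Relative rank R = below/(n-1), in [0, 1].

    ``ties="midrank"`` counts half of the tied comparators as below.
    A member tied with every other member sits at R = 0.5 (symmetric
    degenerate case).  Singleton groups have no comparators: returns NaN
    and logs a warning.
    """
    if group.n < 2:
        logger.warning("rank undefined in singleton group %s", group.key)
        return float("nan")
    below, above = comparator_counts(brac, group)
    if ties == "midrank":
        n_ties = (group.n - 1) - below - above
        return (below + 0.5 * n_ties) / (group.n - 1)
    if ties != "strict":
        raise RankParameterError(f"ties must be 'strict' or 'midrank', got {ties!r}")
    if below == 0 and above == 0:
        return 0.5
    return below / (group.n - 1)


def weighted_rank_from_counts(below, above, eta: float):
    """SR from comparator counts; vectorized over below/above arrays.

    SR = 0.5 + (below - eta*above) / (2*(below + eta*above)); the
    all-tied case (below = above = 0) is defined as 0.5.
    """
    if eta <= 0:
        raise RankParameterError(f"eta must be > 0, got {eta!r}")
    below = np.asarray(below, dtype=float)
    above = np.asarray(above, dtype=float)
    denom = below + eta * above
    with np.errstate(invalid="ignore", divide="ignore"):
        sr = 0.5 + (below - eta * above) / (2.0 * denom)
    sr = np.where(denom == 0.0, 0.5, sr)
    return sr if sr.ndim else float(sr)


def weighted_rank(brac: float, group: ReferenceGroup, eta: float) -> float:
    """Weighted rank SR(eta) of a member's BrAC within its group."""
    if group.n < 2:
        logger.warning("weighted rank undefined in singleton group %s", group.key)
        return float("nan")
    below, above = comparator_counts(brac, group)
    return float(weighted_rank_from_counts(below, above, eta))


def judgement_eligible(
    respondent: Mapping, outcome: str | None = None, require_covariates: bool = False
) -> bool:
    """Whether a respondent enters the rank-judgment analyses.

    Zero-BrAC respondents are never eligible (they still serve as
    comparators).  With ``outcome`` given, that rating must be present;
    otherwise all four must be.  ``require_covariates`` additionally
    demands the Model 4 covariates (duration, time band, gender, FAST,
    age).
    """
    if not respondent.get("brac_ug_per_100ml", 0) > 0:
        return False
    outcomes = [outcome] if outcome else list(RATING_COLUMNS)
    for out in outcomes:
        if pd.isna(respondent.get(out)):
            return False
    if require_covariates:
        for col in MODEL4_COVARIATE_COLUMNS:
            if pd.isna(respondent.get(col)):
                return False
        if pd.isna(respondent.get("gender")):
            return False
    return True


def assign_ranks(
    respondents: pd.DataFrame,
    pool: pd.DataFrame,
    eta: float | None = None,
    ties: str = "strict",
) -> pd.DataFrame:
    """Rank each respondent row within the *pool's* reference groups.

    ``respondents`` is typically the judgment subsample and ``pool`` the
    full survey (the study ranks the judgment subsample against everyone
    surveyed in the same gender x location cell, not just against other
    judgment respondents).  Appends columns ``below``, ``above``,
    ``n_group``, ``group_mean``, ``R`` and — when ``eta`` is given —
    ``SR``.  Rows from singleton groups receive NaN ranks.
    """
    if ties not in ("strict", "midrank"):
        raise RankParameterError(f"ties must be 'strict' or 'midrank', got {ties!r}")
    groups = build_reference_groups(pool)
    out = respondents.copy()
    n_rows = len(out)
    below = np.zeros(n_rows, dtype=float)
    above = np.zeros(n_rows, dtype=float)
    n_group = np.zeros(n_rows, dtype=float)
    gmean = np.full(n_rows, np.nan)

    gvals = out["gender"].to_numpy()
    lvals = out["location"].to_numpy()
    bvals = out["brac_ug_per_100ml"].to_numpy(float)
    for i in range(n_rows):
        key = (gvals[i], int(lvals[i]))
        grp = groups.get(key)
        if grp is None:
            raise KeyError(f"respondent row {i} belongs to no pool reference group {key}")
        b, a = comparator_counts(bvals[i], grp)
        below[i], above[i], n_group[i] = b, a, grp.n
        gmean[i] = grp.mean_brac

    out["below"] = below
    out["above"] = above
    out["n_group"] = n_group
    out["group_mean"] = gmean

    nm1 = n_group - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        if ties == "midrank":
            n_ties = nm1 - below - above
            r = (below + 0.5 * n_ties) / nm1
        else:
            r = below / nm1
            r = np.where((below == 0) & (above == 0) & (nm1 > 0), 0.5, r)
    r = np.where(nm1 <= 0, np.nan, r)
    if np.isnan(r).any():
        logger.warning("%d respondents in singleton groups: rank set to NaN", int(np.isnan(r).sum()))
    out["R"] = r
    if eta is not None:
        sr = weighted_rank_from_counts(below, above, eta)
        out["SR"] = np.where(nm1 <= 0, np.nan, sr)
    return out
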