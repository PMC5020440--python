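"""Grid-search estimation of the comparison-bias parameter eta.

For each candidate eta on a grid (default 0.01 .. 5.00 in 0.01 steps)
the weighted rank SR(eta) is recomputed for every judgment-eligible
respondent from their cached below/above comparator counts, the outcome
is regressed on SR alone, and the eta maximizing R-squared is selected.
eta < 1 means judgments track the more sober comparators more strongly
("downward" comparison bias); eta > 1 the more intoxicated ones.

The simple-regression R-squared equals the squared Pearson correlation
of SR(eta) with the outcome, which makes the scan a vectorized pass over
the grid rather than 500 model fits.  Covariate-adjusted scanning is
available behind a flag but is not the default procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ranks import RankParameterError, weighted_rank_from_counts

logger = logging.getLogger(__name__)

#: R2 comparisons within this tolerance are treated as ties (smallest eta wins).
R2_TIE_TOL = 1e-12


@dataclass
class EtaProfile:
    """The (eta, R2) grid for one outcome and the selected maximum."""

    outcome: str
    etas: np.ndarray
    r_squared: np.ndarray
    best_eta: float
    best_r_squared: float

    def r_squared_at(self, eta: float) -> float:
        """Profile value at a grid point (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.etas, eta, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"eta={eta} is not on the scanned grid")
        return float(self.r_squared[idx[0]])

    def to_dict(self, include_grid: bool = False) -> dict:
        d = {
            "outcome": self.outcome,
            "best_eta": float(self.best_eta),
            "best_r_squared": float(self.best_r_squared),
            "grid_start": float(self.etas[0]),
            "grid_stop": float(self.etas[-1]),
            "grid_size": int(len(self.etas)),
        }
        if include_grid:
            d["grid"] = [[float(e), float(r)] for e, r in zip(self.etas, self.r_squared)]
        return d


def make_grid(start: float = 0.01, stop: float = 5.0, step: float = 0.01) -> np.ndarray:
    """The eta grid: start, start+step, ..., stop (inclusive)."""
    if start <= 0:
        raise RankParameterError(f"grid_start must be > 0, got {start!r}")
    if step <= 0 or stop < start:
        raise RankParameterError("grid must satisfy step > 0 and stop >= start")
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


def scan_eta(
    ranked: pd.DataFrame,
    outcome: str,
    grid_start: float = 0.01,
    grid_stop: float = 5.0,
    grid_step: float = 0.01,
    covariates: Sequence[str] | None = None,
) -> EtaProfile:
    """Profile R2 over the eta grid and select the maximizing eta.

    ``ranked`` must carry ``below``/``above`` comparator counts (from
    :func:`ranknorms.ranks.assign_ranks`) and the outcome column; rows
    with a missing outcome or undefined rank are dropped.  Ties in R2
    (within 1e-12) resolve to the smallest eta and are logged.  With
    ``covariates`` the regression at each grid point additionally adjusts
    for those columns (not the default procedure).
    """
    grid = make_grid(grid_start, grid_stop, grid_step)
    need = ["below", "above", outcome] + list(covariates or ())
    missing = [c for c in need if c not in ranked.columns]
    if missing:
        raise KeyError(f"ranked data lacks columns {missing}")
    complete = ranked[need].dropna()
    if len(complete) < 10:
        raise ValueError(
            f"eta scan needs >= 10 usable respondents for {outcome!r}, got {len(complete)}"
        )

    below = complete["below"].to_numpy(float)
    above = complete["above"].to_numpy(float)
    y = complete[outcome].to_numpy(float)
    yc = y - y.mean()
    y_ss = float(yc @ yc)

    if covariates:
        Z = complete[list(covariates)].to_numpy(float)
        r2s = np.array([
            _adjusted_r2(weighted_rank_from_counts(below, above, eta), y, Z)
            for eta in grid
        ])
    elif y_ss == 0:
        r2s = np.zeros(len(grid))
    else:
        r2s = np.empty(len(grid))
        for k, eta in enumerate(grid):
            sr = weighted_rank_from_counts(below, above, eta)
            src = sr - sr.mean()
            s_ss = float(src @ src)
            r2s[k] = (float(src @ yc) ** 2) / (s_ss * y_ss) if s_ss > 0 else 0.0

    best = float(r2s.max())
    idx = int(np.flatnonzero(r2s >= best - R2_TIE_TOL)[0])
    if r2s[idx] < best:  # a smaller eta tied within tolerance
        logger.info(
            "eta scan (%s): R2 tie within %g; smallest eta %.2f selected",
            outcome, R2_TIE_TOL, grid[idx],
        )
    return EtaProfile(
        outcome=outcome,
        etas=grid,
        r_squared=r2s,
        best_eta=float(grid[idx]),
        best_r_squared=float(r2s[idx]),
    )


def _adjusted_r2(sr: np.ndarray, y: np.ndarray, Z: np.ndarray) -> float:
    exog = np.column_stack([np.ones(len(y)), sr, Z])
    coef, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    return 0.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
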