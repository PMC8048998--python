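"""Phase-specific daily mortality and the Friedman rank test.

The 60-day breeding timeline splits into an egg period (days 1-30), a
young-chick period (days 31-45), and an old-chick period (days 46-60).
Phase boundaries are shared: the chick total at day 30 both ends the egg
period and starts the young-chick period, so the three per-day loss rates
telescope exactly to (Z_1 - Z_60) when weighted by phase lengths.

Differences in mortality rate across phases over matched site/years are
tested with a Friedman rank test (self-contained implementation with
midranks, so ties are handled; the statistic is referred to a chi-square
with k-1 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .geometry import SEASON_LENGTH

__all__ = [
    "PhaseMortality", "FriedmanResult", "phase_mortality",
    "phase_mortality_draws", "phase_rate_table", "friedman_test",
    "DEFAULT_BOUNDARIES",
]

#: phase end days (1-based, inclusive): egg, young chick, old chick
DEFAULT_BOUNDARIES = (30, 45, 60)

PHASES = ("egg", "young_chick", "old_chick")


@dataclass
class PhaseMortality:
    """Per-day chick losses in each phase for one site/year."""

    site_id: str
    year_id: str
    egg_rate: float
    young_rate: float
    old_rate: float
    boundaries: tuple[int, int, int] = DEFAULT_BOUNDARIES

    def as_dict(self) -> dict:
        return {
            "site_id": self.site_id, "year_id": self.year_id,
            "egg": self.egg_rate, "young_chick": self.young_rate,
            "old_chick": self.old_rate,
        }


def phase_mortality(
    z_trajectory,
    boundaries: tuple[int, int, int] = DEFAULT_BOUNDARIES,
    site_id: str = "",
    year_id: str = "",
) -> PhaseMortality:
    """Average daily mortality per phase from a chick-total trajectory.

    ``z_trajectory`` is the length-60 posterior-mean (or single-draw) total
    of chicks alive; the rate for a phase is the drop in the total across
    the phase divided by its length in days.
    """
    z = np.asarray(z_trajectory, dtype=float)
    if z.shape != (SEASON_LENGTH,):
        raise ValueError(f"trajectory must have length {SEASON_LENGTH}")
    if np.isnan(z).any():
        raise ValueError("trajectory contains missing values")
    b1, b2, b3 = boundaries
    if not (1 < b1 < b2 < b3 == SEASON_LENGTH):
        raise ValueError(f"invalid phase boundaries {boundaries}")
    egg = (z[0] - z[b1 - 1]) / b1
    young = (z[b1 - 1] - z[b2 - 1]) / (b2 - b1)
    old = (z[b2 - 1] - z[b3 - 1]) / (b3 - b2)
    return PhaseMortality(site_id=site_id, year_id=year_id,
                          egg_rate=float(egg), young_rate=float(young),
                          old_rate=float(old), boundaries=tuple(boundaries))


def phase_mortality_draws(
    z_draws: np.ndarray,
    boundaries: tuple[int, int, int] = DEFAULT_BOUNDARIES,
) -> pd.DataFrame:
    """Full-posterior variant: per-draw phase rates from Z draws of shape
    ``(n_draws, 60)``; returns columns egg, young_chick, old_chick."""
    z = np.asarray(z_draws, dtype=float)
    b1, b2, b3 = boundaries
    return pd.DataFrame({
        "egg": (z[:, 0] - z[:, b1 - 1]) / b1,
        "young_chick": (z[:, b1 - 1] - z[:, b2 - 1]) / (b2 - b1),
        "old_chick": (z[:, b2 - 1] - z[:, b3 - 1]) / (b3 - b2),
    })


def phase_rate_table(results: list[PhaseMortality]) -> pd.DataFrame:
    """Site/years x phases table ready for the Friedman test and for
    density-plot export."""
    return pd.DataFrame([r.as_dict() for r in results]).set_index(
        ["site_id", "year_id"])


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n_blocks: int
    k_treatments: int
    tie_corrected: bool


def friedman_test(rates) -> FriedmanResult:
    """Friedman rank test for treatment differences across matched blocks.

    ``rates`` is an (n_blocks, k) array (or DataFrame) — here, site/years
    by season phases.  Values are ranked within each block with midranks
    for ties; the statistic

        Q = (k-1) * sum_j (R_j - n(k+1)/2)^2 / sum_ij (r_ij - (k+1)/2)^2

    reduces to the classical 12/(nk(k+1)) * sum R_j^2 - 3n(k+1) when there
    are no ties and applies the tie correction automatically otherwise.
    P-values come from the chi-square distribution with k-1 df.  When every
    block is constant the statistic is 0 and p = 1.
    """
    X = np.asarray(rates, dtype=float)
    if X.ndim != 2:
        raise ValueError("rates must be a 2-D blocks x treatments array")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if np.isnan(X).any():
        bad = np.flatnonzero(np.isnan(X).any(axis=1)).tolist()
        raise ValueError(
            f"missing cells in blocks {bad}; remove those blocks before testing")
    r = rankdata(X, axis=1)  # midranks
    ties = bool((np.sort(X, axis=1)[:, 1:] == np.sort(X, axis=1)[:, :-1]).any())
    Rj = r.sum(axis=0)
    num = ((Rj - n * (k + 1) / 2.0) ** 2).sum()
    den = ((r - (k + 1) / 2.0) ** 2).sum()
    if den == 0.0:  # all blocks constant
        return FriedmanResult(statistic=0.0, df=k - 1, p_value=1.0,
                              n_blocks=n, k_treatments=k, tie_corrected=ties)
    Q = (k - 1) * num / den
    p = float(chi2.sf(Q, k - 1))
    return FriedmanResult(statistic=float(Q), df=k - 1, p_value=p,
                          n_blocks=n, k_treatments=k, tie_corrected=ties)
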