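"""Divergence-rate regression: per-species retention counts vs root age,
with an ANCOVA F-test comparing the two slopes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist


@dataclass(frozen=True)
class DivergencePoint:
    species: str
    root_age: float  # million years
    count: float  # retained regions/structures (integer in practice)

    def __post_init__(self) -> None:
        if self.root_age < 0 or self.count < 0:
            raise ValueError("root_age and count must be non-negative")


@dataclass
class RegressionLine:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class AncovaReport:
    regions: RegressionLine
    structures: RegressionLine
    interaction_estimate: float
    f_statistic: float
    p_value: float
    n: int


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _line(ages: np.ndarray, counts: np.ndarray) -> RegressionLine:
    X = np.column_stack([np.ones(len(ages)), ages])
    beta, rss = _ols(X, counts)
    tss = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return RegressionLine(slope=float(beta[1]), intercept=float(beta[0]), r_squared=r2)


def divergence_regression(
    points_regions: list[DivergencePoint],
    points_structures: list[DivergencePoint],
) -> AncovaReport:
    """Per-group OLS of count vs age; interaction F-test (1, n-4 df) for
    equality of slopes."""
    if len(points_regions) < 3 or len(points_structures) < 3:
        raise ValueError("need at least 3 points per group")
    ages_r = np.array([p.root_age for p in points_regions], float)
    cnt_r = np.array([p.count for p in points_regions], float)
    ages_s = np.array([p.root_age for p in points_structures], float)
    cnt_s = np.array([p.count for p in points_structures], float)
    if np.ptp(ages_r) == 0 or np.ptp(ages_s) == 0:
        raise ValueError("degenerate design: ages are constant within a group")
    ages = np.concatenate([ages_r, ages_s])
    counts = np.concatenate([cnt_r, cnt_s])
    group = np.concatenate([np.zeros(len(ages_r)), np.ones(len(ages_s))])
    n = len(ages)
    X_full = np.column_stack([np.ones(n), ages, group, ages * group])
    X_red = X_full[:, :3]
    beta_full, rss_full = _ols(X_full, counts)
    _beta_red, rss_red = _ols(X_red, counts)
    df2 = n - 4
    if df2 <= 0:
        raise ValueError("too few points for the interaction test")
    tss = float(((counts - counts.mean()) ** 2).sum())
    if rss_full <= 1e-9 * max(tss, 1.0):
        # numerically perfect fit: identical slopes give F = 0/0 -> p = 1
        f_stat = 0.0 if abs(beta_full[3]) < 1e-8 else float("inf")
    else:
        f_stat = (rss_red - rss_full) / (rss_full / df2)
    p = float(f_dist.sf(f_stat, 1, df2)) if np.isfinite(f_stat) else 0.0
    return AncovaReport(
        regions=_line(ages_r, cnt_r),
        structures=_line(ages_s, cnt_s),
        interaction_estimate=float(beta_full[3]),
        f_statistic=float(max(f_stat, 0.0)),
        p_value=p,
        n=n,
    )
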