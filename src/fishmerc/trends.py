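"""Broken-line (segmented) regression for annual export series.

Fits y = β₀ + β₁·t + β₂·(t − ψ)₊ by iterative linearization of the breakpoint
ψ (gap-parameter update), seeded by a deterministic grid search over interior
observed years.  The breakpoint standard error comes from the delta-method
ratio SE(γ̂)/|β̂₂| of the working linear model, and the Davies bound supplies
a p-value for the difference-in-slope parameter, whose breakpoint is not
identified under the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SegmentedModel", "SegmentedFit", "fit_segmented", "davies_test", "period_means"]

_MIN_OBS = 8
_MIN_SIDE = 4  # points required on each side of a candidate breakpoint


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = len(y) - X.shape[1]
    sigma2 = rss / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return beta, cov, rss


def _candidates(x: np.ndarray) -> np.ndarray:
    """Interior observed years with at least ``_MIN_SIDE`` points per side."""
    n = len(x)
    return x[_MIN_SIDE - 1 : n - _MIN_SIDE]


@dataclass
class SegmentedFit:
    """Results of a two-segment broken-line fit.

    Attributes mirror the usual broken-line outputs: the breakpoint estimate
    (in year units) and its standard error, the slope on each side, the
    left-segment intercept, and the Davies p-value for a non-zero
    difference in slope.
    """

    breakpoint: float
    breakpoint_se: float
    slope_before: float
    slope_after: float
    intercept: float
    davies_p: float
    converged: bool
    n_obs: int = 0
    rss: float = float("nan")
    n_iter: int = 0

    @property
    def slope_change(self) -> float:
        return self.slope_after - self.slope_before

    def predict(self, years) -> np.ndarray:
        t = np.asarray(years, dtype=float)
        return (
            self.intercept
            + self.slope_before * t
            + self.slope_change * np.clip(t - self.breakpoint, 0.0, None)
        )

    def summary(self) -> str:
        lines = [
            "Segmented regression (one breakpoint)",
            "=" * 45,
            f"n obs            {self.n_obs:>12d}",
            f"breakpoint       {self.breakpoint:>12.2f}  (SE {self.breakpoint_se:.2f})",
            f"slope before     {self.slope_before:>12.4g}",
            f"slope after      {self.slope_after:>12.4g}",
            f"intercept        {self.intercept:>12.4g}",
            f"Davies p-value   {self.davies_p:>12.4g}",
            f"residual SS      {self.rss:>12.4g}",
            f"converged        {str(self.converged):>12s}",
        ]
        return "\n".join(lines)


class SegmentedModel:
    """Two-segment broken-line regression model for a yearly series.

    Parameters
    ----------
    endog : array-like
        Annual values (e.g. THg export in kmol).
    exog_years : array-like
        Strictly increasing observation years.
    """

    def __init__(self, endog, exog_years):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog_years, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("endog and exog_years must be 1-d and equal length")
        if len(y) < _MIN_OBS:
            raise ValueError(f"need at least {_MIN_OBS} observations, got {len(y)}")
        if np.any(np.diff(x) <= 0):
            raise ValueError("years must be strictly increasing")
        self.endog = y
        self.exog_years = x

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str, year_col: str = "year"):
        df = df.sort_values(year_col)
        return cls(df[value_col].to_numpy(), df[year_col].to_numpy())

    def _design(self, psi: float, gap: bool) -> np.ndarray:
        x = self.exog_years
        cols = [np.ones_like(x), x, np.clip(x - psi, 0.0, None)]
        if gap:
            cols.append(-(x > psi).astype(float))
        return np.column_stack(cols)

    def fit(self, max_iter: int = 50, tol: float = 1e-10) -> SegmentedFit:
        """Fit by grid-seeded iterative linearization of the breakpoint."""
        x, y = self.exog_years, self.endog
        span = x[-1] - x[0]
        cands = _candidates(x)
        if len(cands) == 0:
            raise ValueError("fewer than 4 points available per candidate segment")
        # deterministic grid initialization, preferring years outside 10% margins
        lo, hi = x[0] + 0.1 * span, x[-1] - 0.1 * span
        grid = cands[(cands >= lo) & (cands <= hi)]
        if len(grid) == 0:
            grid = cands
        grid_rss = []
        for c in grid:
            _, _, rss = _ols(self._design(c, gap=False), y)
            grid_rss.append(rss)
        psi = float(grid[int(np.argmin(grid_rss))])
        best = (float(grid_rss[int(np.argmin(grid_rss))]), psi)

        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            X = self._design(psi, gap=True)
            beta, cov, rss = _ols(X, y)
            if rss < best[0]:
                best = (rss, psi)
            gamma, b2 = beta[3], beta[2]
            if abs(b2) < 1e-12 * max(1.0, abs(beta[1])):
                # no detectable slope change; breakpoint not identified
                converged = True
                break
            step = gamma / b2
            new_psi = float(np.clip(psi + step, x[1], x[-2]))
            if abs(new_psi - psi) < tol * max(1.0, span) or abs(gamma) < tol * max(
                1.0, float(np.abs(y).max())
            ):
                psi = new_psi
                converged = True
                break
            psi = new_psi
        if not converged:
            psi = best[1]

        X = self._design(psi, gap=True)
        beta, cov, rss = _ols(X, y)
        b0, b1, b2 = beta[0], beta[1], beta[2]
        se_gamma = math.sqrt(max(cov[3, 3], 0.0))
        se_psi = se_gamma / abs(b2) if abs(b2) > 0 else float("inf")
        return SegmentedFit(
            breakpoint=float(psi),
            breakpoint_se=float(se_psi),
            slope_before=float(b1),
            slope_after=float(b1 + b2),
            intercept=float(b0),
            davies_p=davies_test(x, y),
            converged=converged,
            n_obs=len(y),
            rss=rss,
            n_iter=n_iter,
        )


def fit_segmented(years, values, **kwargs) -> SegmentedFit:
    """Convenience wrapper: fit a broken line to (years, values)."""
    return SegmentedModel(values, years).fit(**kwargs)


def davies_test(years, values) -> float:
    """Davies-bound p-value for a non-zero difference-in-slope parameter.

    For each candidate breakpoint ψ_k (interior observed years with at least
    four points per side), the Wald t-statistic s_k of the hinge coefficient
    is computed at fixed ψ_k; with M = max|s_k|, V = Σ|s_{k+1}−s_k| and
    ν = n − 3 residual degrees of freedom, the two-sided small-sample bound is

        p = 2·P(T_ν > M) + V·(1 + M²/ν)^(−(ν−1)/2)/√(8π),

    capped at 1 (the exponential normal-tail form is its ν → ∞ limit).
    A constant series returns 1.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y) or len(x) < _MIN_OBS:
        raise ValueError(f"need at least {_MIN_OBS} paired observations")
    if np.any(np.diff(x) <= 0):
        raise ValueError("years must be strictly increasing")
    if np.ptp(y) == 0:
        return 1.0
    cands = _candidates(x)
    if len(cands) == 0:
        raise ValueError("fewer than 4 points available per candidate segment")
    s = np.empty(len(cands))
    for i, c in enumerate(cands):
        X = np.column_stack([np.ones_like(x), x, np.clip(x - c, 0.0, None)])
        beta, cov, _ = _ols(X, y)
        se = math.sqrt(max(cov[2, 2], 0.0))
        if se == 0.0:
            # perfect fit: infinite evidence if the hinge is non-zero
            s[i] = math.copysign(1e9, beta[2]) if abs(beta[2]) > 1e-12 else 0.0
        else:
            s[i] = beta[2] / se
    m = float(np.max(np.abs(s)))
    total_variation = float(np.sum(np.abs(np.diff(s))))
    dof = len(x) - 3
    correction = total_variation * (1.0 + m * m / dof) ** (-(dof - 1) / 2.0) / math.sqrt(
        8.0 * math.pi
    )
    p = 2.0 * stats.t.sf(m, dof) + correction
    return float(min(1.0, p))


def period_means(
    table: pd.DataFrame,
    periods: Sequence[tuple[int, int]],
    value_col: str,
    year_col: str = "year",
) -> pd.DataFrame:
    """Mean ± SD of annual values inside closed year intervals.

    SD is the sample standard deviation across years (0 for a single year).
    Raises on a period containing no observations.
    """
    rows = []
    for start, end in periods:
        sel = table[(table[year_col] >= start) & (table[year_col] <= end)][value_col]
        if len(sel) == 0:
            raise ValueError(f"period {start}-{end} contains no observations")
        sd = float(sel.std(ddof=1)) if len(sel) > 1 else 0.0
        rows.append(
            {
                "period": f"{start}-{end}",
                "start": start,
                "end": end,
                "mean": float(sel.mean()),
                "sd": sd,
                "n_years": int(len(sel)),
            }
        )
    return pd.DataFrame(rows)
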