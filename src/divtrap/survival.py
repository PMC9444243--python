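"""Population survival statistics on generation-indexed lifespans.

Kaplan–Meier with Greenwood variance and 95% bands, discrete hazard with
bootstrap SD, two-group log-rank, and Wilcoxon rank-sum. The time axis
is the generation index for replicative lifespans; the same code accepts
any non-negative times (e.g. frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from divtrap.lifespan import LifespanRecord


def _extract(records) -> tuple[np.ndarray, np.ndarray]:
    """-> (times, observed) with excluded records dropped."""
    times, observed = [], []
    for r in records:
        if isinstance(r, LifespanRecord):
            if r.excluded:
                continue
            times.append(r.rls)
            observed.append(not r.censored)
        else:
            t, censored = r
            times.append(t)
            observed.append(not censored)
    return np.asarray(times, dtype=np.float64), np.asarray(observed, dtype=bool)


@dataclass
class SurvivalTable:
    grid: np.ndarray  # ascending observed times
    n_at_risk: np.ndarray
    deaths: np.ndarray
    censored: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_records: int
    axis: str = "generation"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.grid,
                "n_at_risk": self.n_at_risk,
                "deaths": self.deaths,
                "censored": self.censored,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        s = 1.0
        for g, sv in zip(self.grid, self.survival):
            if g <= t:
                s = sv
            else:
                break
        return s

    @property
    def median(self) -> float | None:
        """Smallest time with S <= 0.5 (no interpolation)."""
        for g, s in zip(self.grid, self.survival):
            if s <= 0.5:
                return float(g)
        return None


def km_estimate(records, *, ci_method: str = "plain", axis: str = "generation") -> SurvivalTable:
    """Kaplan–Meier estimate with Greenwood variance and 95% CI.

    ``ci_method='plain'``: S +/- 1.96 sqrt(var) clipped to [0, 1];
    ``'loglog'``: log(-log) transformed intervals.
    """
    times, observed = _extract(records)
    if len(times) == 0:
        raise ValueError("no non-excluded records")
    grid = np.unique(times)
    s = 1.0
    gw_sum = 0.0
    rows = []
    for g in grid:
        n_at_risk = int(np.sum(times >= g))
        d = int(np.sum((times == g) & observed))
        c = int(np.sum((times == g) & ~observed))
        if d > 0:
            s *= 1.0 - d / n_at_risk
            if n_at_risk > d:
                gw_sum += d / (n_at_risk * (n_at_risk - d))
        var = s**2 * gw_sum
        rows.append((g, n_at_risk, d, c, s, var))
    grid_a = np.array([r[0] for r in rows])
    surv = np.array([r[4] for r in rows])
    var = np.array([r[5] for r in rows])
    se = np.sqrt(var)
    if ci_method == "plain":
        lo = np.clip(surv - 1.96 * se, 0.0, 1.0)
        hi = np.clip(surv + 1.96 * se, 0.0, 1.0)
    elif ci_method == "loglog":
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(
                (surv > 0) & (surv < 1),
                1.96 * se / (surv * np.abs(np.log(surv))),
                0.0,
            )
            lo = np.where((surv > 0) & (surv < 1), surv ** np.exp(theta), surv)
            hi = np.where((surv > 0) & (surv < 1), surv ** np.exp(-theta), surv)
    else:
        raise ValueError("ci_method must be 'plain' or 'loglog'")
    return SurvivalTable(
        grid=grid_a,
        n_at_risk=np.array([r[1] for r in rows]),
        deaths=np.array([r[2] for r in rows]),
        censored=np.array([r[3] for r in rows]),
        survival=surv,
        greenwood_var=var,
        ci_low=lo,
        ci_high=hi,
        n_records=len(times),
        axis=axis,
    )


def _hazard_on_grid(times: np.ndarray, observed: np.ndarray, grid: np.ndarray) -> np.ndarray:
    n_at_risk = (times[None, :] >= grid[:, None]).sum(axis=1)
    deaths = ((times[None, :] == grid[:, None]) & observed[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_at_risk > 0, deaths / np.maximum(n_at_risk, 1), np.nan)
    return h


def hazard_rate(
    records, *, n_boot: int = 100, seed: int = 0, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Discrete hazard h(g) = d(g)/n(g) with bootstrap SD over resamples."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    times, observed = _extract(records)
    if grid is None:
        grid = np.unique(times)
    grid = np.asarray(grid, dtype=np.float64)
    h = _hazard_on_grid(times, observed, grid)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    n = len(times)
    for b in range(n_boot):
        sel = rng.integers(0, n, size=n)
        boots[b] = _hazard_on_grid(times[sel], observed[sel], grid)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(boots, axis=0, ddof=1)
    return pd.DataFrame({"time": grid, "hazard": h, "hazard_sd": sd})


def logrank_test(records_a, records_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df), censoring-aware, symmetric."""
    ta, oa = _extract(records_a)
    tb, ob = _extract(records_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    grid = np.unique(np.concatenate([ta[oa], tb[ob]]))
    o_minus_e = 0.0
    v = 0.0
    for g in grid:
        n1 = np.sum(ta >= g)
        n2 = np.sum(tb >= g)
        d1 = np.sum((ta == g) & oa)
        d2 = np.sum((tb == g) & ob)
        n = n1 + n2
        d = d1 + d2
        if n < 2 or d == 0:
            o_minus_e += d1 - d * n1 / n if n > 0 else 0.0
            continue
        o_minus_e += d1 - d * n1 / n
        v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / v
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def ranksum_test(durations_a, durations_b) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney with midrank tie handling."""
    a = np.asarray(durations_a, dtype=np.float64)
    b = np.asarray(durations_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
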