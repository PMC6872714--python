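"""Pearson association between Cp* and AHI.

A single pre-specified two-tailed Pearson correlation, significant at
alpha = 0.01, with the p-value from the exact t transform
t = r sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom.  An exact
permutation p-value is available as a cross-check for small cohorts.

The analysis is exposed both as a plain function (:func:`pearson`) and as a
small model/results pair (:class:`CpStarAhiModel` / :class:`CpStarAhiResults`)
for interactive use: build the model from arrays, a DataFrame, or a cohort
table, call ``fit()``, and read ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, ParameterError

__all__ = [
    "CorrelationResult",
    "pearson",
    "pvalue_from_r",
    "permutation_pvalue",
    "CpStarAhiModel",
    "CpStarAhiResults",
]

ALPHA = 0.01  # pre-specified two-tailed significance level


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-tailed p-value."""

    r: float
    p_two_tailed: float
    n: int
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ParameterError("r: must lie in [-1, 1]")
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ParameterError("p_two_tailed: must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < self.alpha

    def to_record(self) -> dict:
        return {
            "r": self.r,
            "p_two_tailed": self.p_two_tailed,
            "n": self.n,
            "significant": self.significant,
        }


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ParameterError("x, y: must be 1-D sequences of equal length")
    if x.size < 3:
        raise ParameterError("x, y: at least 3 observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("x, y: zero variance in one of the sequences")
    return x, y


def pvalue_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n via the t transform."""
    if not -1.0 <= r <= 1.0:
        raise ParameterError("r: must lie in [-1, 1]")
    if n < 3:
        raise ParameterError("n: at least 3 observations are required")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def pearson(x, y, alpha: float = ALPHA) -> CorrelationResult:
    """Two-tailed Pearson correlation between two sequences."""
    x, y = _validate_pair(x, y)
    r = float(sps.pearsonr(x, y).statistic)
    r = max(-1.0, min(1.0, r))
    # a perfect affine relation is exactly +/-1; absorb float rounding
    if 1.0 - abs(r) < 1e-12:
        r = math.copysign(1.0, r)
    return CorrelationResult(r=r, p_two_tailed=pvalue_from_r(r, x.size), n=x.size, alpha=alpha)


def permutation_pvalue(x, y, max_n: int = 8) -> float:
    """Exact two-tailed permutation p-value (all n! pairings).

    Only sensible for tiny cohorts; refuses n > ``max_n``.
    """
    x, y = _validate_pair(x, y)
    n = x.size
    if n > max_n:
        raise ParameterError(f"x, y: exact permutation test limited to n <= {max_n}")
    r_obs = abs(sps.pearsonr(x, y).statistic)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = sps.pearsonr(x, y[list(perm)]).statistic
        count += abs(r) >= r_obs - 1e-12
        total += 1
    return count / total


class CpStarAhiModel:
    """Association model between a flow-derived severity marker and AHI.

    Parameters
    ----------
    cp_star, ahi : array-like
        Paired per-patient values; rows with missing entries are dropped.
    """

    def __init__(self, cp_star, ahi, patient_ids=None):
        cp = np.asarray(cp_star, dtype=float)
        ah = np.asarray(ahi, dtype=float)
        if cp.shape != ah.shape:
            raise ParameterError("cp_star, ahi: must have equal length")
        keep = np.isfinite(cp) & np.isfinite(ah)
        self.cp_star = cp[keep]
        self.ahi = ah[keep]
        if patient_ids is not None:
            self.patient_ids = np.asarray(patient_ids, dtype=object)[keep]
        else:
            self.patient_ids = np.array(
                [f"P{i + 1:03d}" for i in range(self.cp_star.size)], dtype=object
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, cp_col: str = "cp_star", ahi_col: str = "ahi"
    ) -> "CpStarAhiModel":
        for col in (cp_col, ahi_col):
            if col not in df.columns:
                raise ParameterError(f"{col}: column missing from table")
        ids = df["patient_id"] if "patient_id" in df.columns else None
        return cls(df[cp_col].to_numpy(), df[ahi_col].to_numpy(), patient_ids=ids)

    def fit(self, alpha: float = ALPHA, permutation: bool = False) -> "CpStarAhiResults":
        corr = pearson(self.cp_star, self.ahi, alpha=alpha)
        perm_p = (
            permutation_pvalue(self.cp_star, self.ahi)
            if permutation and corr.n <= 8
            else None
        )
        return CpStarAhiResults(model=self, corr=corr, permutation_p=perm_p)


@dataclass
class CpStarAhiResults:
    """Fitted association: r, its two-tailed p, and diagnostics."""

    model: CpStarAhiModel
    corr: CorrelationResult
    permutation_p: float | None = None

    @property
    def rsquared(self) -> float:
        return self.corr.r**2

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        """Fisher-z confidence interval for r."""
        r, n = self.corr.r, self.corr.n
        if n < 4:
            raise ParameterError("n: at least 4 observations for a Fisher interval")
        z = math.atanh(max(-0.999999999, min(0.999999999, r)))
        se = 1.0 / math.sqrt(n - 3)
        crit = sps.norm.ppf(0.5 + level / 2.0)
        return (math.tanh(z - crit * se), math.tanh(z + crit * se))

    def summary(self) -> str:
        c = self.corr
        lines = [
            "Cp*-AHI Pearson association",
            "=" * 43,
            f"{'n patients':<28}{c.n:>15d}",
            f"{'Pearson r':<28}{c.r:>15.4f}",
            f"{'R-squared':<28}{self.rsquared:>15.4f}",
            f"{'p (two-tailed, t transform)':<28}{c.p_two_tailed:>15.4g}",
            f"{'significant at alpha=' + format(c.alpha, 'g'):<28}"
            f"{str(c.significant):>15}",
        ]
        if self.corr.n >= 4:
            lo, hi = self.conf_int()
            lines.append(f"{'95% CI for r (Fisher z)':<28}[{lo:6.3f}, {hi:6.3f}]")
        if self.permutation_p is not None:
            lines.append(f"{'p (exact permutation)':<28}{self.permutation_p:>15.4g}")
        lines.append("=" * 43)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of AHI against Cp* with the fitted least-squares line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        x, y = self.model.cp_star, self.model.ahi
        ax.scatter(x, y, color="tab:blue", zorder=3)
        slope, intercept = np.polyfit(x, y, 1)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, slope * grid + intercept, color="tab:red", lw=1)
        ax.set_xlabel(r"Cp$^*$  [$\sqrt{\mathrm{kg\,m^{-3}}}$]")
        ax.set_ylabel("AHI  [events/h]")
        ax.set_title(
            f"r = {self.corr.r:.2f}, p = {self.corr.p_two_tailed:.3g} "
            f"(n = {self.corr.n})"
        )
        return ax
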