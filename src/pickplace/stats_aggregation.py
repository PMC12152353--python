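"""Aggregation and Bayesian statistics for the dependent variables.

Trial-level measures are first averaged per participant x instruction x
search size. Descriptive reporting uses t-based 95% confidence intervals.
Extreme proportions are variance-stabilized with the arcsine-square-root
transform (arcsin sqrt(p); chance level p = 0.5 maps to 0.785). Hypothesis
tests are default Bayesian t-tests: the JZS Bayes factor with a zero-
centered Cauchy prior (scale r = 1/sqrt(2)) on the standardized effect
size, computed by numerical quadrature of the marginal likelihood ratio.
One-sided variants restrict (and renormalize) the prior to a half-line.

The full Bayesian repeated-measures ANOVA with matched-model inclusion
factors used alongside these tests in the original analyses is external
statistics-package machinery and is deliberately not reimplemented here;
only paired and one-sample Bayes factors are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

DEFAULT_PRIOR_SCALE = 1.0 / np.sqrt(2.0)

Direction = Literal["two_sided", "greater", "less"]


class DegenerateDataError(ValueError):
    """Zero-variance differences: the t statistic is undefined."""


@dataclass
class BayesFactorResult:
    bf10: float
    direction: Direction
    prior_scale: float
    n: int
    t_statistic: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def aggregate(measures: pd.DataFrame,
              keys: Sequence[str] = ("participant", "instruction", "search_size"),
              values: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean of each dependent variable per key combination, with trial counts.

    An empty input yields an empty table.
    """
    if measures.empty:
        return pd.DataFrame(columns=list(keys))
    keys = list(keys)
    missing = [k for k in keys if k not in measures.columns]
    if missing:
        raise KeyError(f"measures table lacks key columns {missing}")
    if values is None:
        values = [c for c in measures.columns
                  if c not in keys and pd.api.types.is_numeric_dtype(measures[c])]
    grouped = measures.groupby(keys, observed=True)
    out = grouped[list(values)].mean()
    out["n_trials"] = grouped.size()
    return out.reset_index()


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a t-based confidence interval."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    m = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    if sem == 0.0:
        return m, m, m
    lo, hi = stats.t.interval(level, df=v.size - 1, loc=m, scale=sem)
    return m, float(lo), float(hi)


def arcsine_transform(p):
    """Variance-stabilizing arcsin(sqrt(p)) for proportions in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def _jzs_bf_from_t(t: float, n: int, direction: Direction,
                   prior_scale: float) -> float:
    """JZS Bayes factor from a one-sample/paired t statistic.

    Marginalizes the noncentral-t likelihood over the Cauchy prior on the
    standardized effect delta via the substitution delta = r tan(theta),
    which maps the integral onto a finite interval. One-sided priors are
    half-Cauchys (density doubled on the allowed side).
    """
    df = n - 1
    root_n = np.sqrt(n)

    def integrand(theta: float) -> float:
        delta = prior_scale * np.tan(theta)
        return stats.nct.pdf(t, df, delta * root_n) / np.pi

    if direction == "two_sided":
        lo, hi, mult = -np.pi / 2, np.pi / 2, 1.0
    elif direction == "greater":
        lo, hi, mult = 0.0, np.pi / 2, 2.0
    elif direction == "less":
        lo, hi, mult = -np.pi / 2, 0.0, 2.0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    m1, _ = integrate.quad(integrand, lo, hi, epsabs=0, epsrel=1e-8,
                           limit=200, points=[0.0] if lo < 0 < hi else None)
    m0 = stats.t.pdf(t, df)
    return mult * m1 / m0


def jzs_ttest_bf(x, y=None, design: Literal["paired", "one_sample"] = "one_sample",
                 direction: Direction = "two_sided",
                 prior_scale: float = DEFAULT_PRIOR_SCALE,
                 null_value: float = 0.0) -> BayesFactorResult:
    """Default Bayesian t-test (JZS Cauchy prior) for paired or one-sample designs.

    For ``paired``, ``y`` is the second sample (equal length); for
    ``one_sample``, ``y`` may be a scalar null value (overrides
    ``null_value``). ``direction='greater'`` tests x > y.
    """
    x = np.asarray(x, dtype=float)
    if design == "paired":
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    elif design == "one_sample":
        if y is not None and np.isscalar(y):
            null_value = float(y)
        elif y is not None:
            raise ValueError("one_sample design takes a scalar null value")
        d = x - null_value
    else:
        raise ValueError(f"unknown design {design!r}")
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    bf = _jzs_bf_from_t(t, n, direction, prior_scale)
    return BayesFactorResult(bf10=float(bf), direction=direction,
                             prior_scale=prior_scale, n=n, t_statistic=t)
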