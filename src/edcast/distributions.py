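"""Exact distribution algebra for aggregate admission counts.

Patient-level admission probabilities are combined into a Poisson-binomial
distribution over the number of admissions among the patients currently in
the department; a truncated Poisson for patients yet to arrive is convolved
on top. Everything here is exact convolution arithmetic on finite pmfs —
snapshot sizes are tens of patients, so there is no need for normal or
Poisson approximations.

Calibration of the resulting count forecasts is assessed with a discrete
probability integral transform (PIT): each observed count is mapped to the
midpoint of the portion of its forecast cdf it occupies, which is uniform
in expectation when the forecasts are correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DiscreteDistribution",
    "poisson_binomial",
    "convolve",
    "pit_midpoint",
    "qq_concordance",
    "summarize",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteDistribution:
    """A pmf over the non-negative integers 0..K (K finite).

    The invariant enforced at construction is that all entries are
    non-negative and sum to 1 within 1e-9.
    """

    pmf: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pmf, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("pmf must be a non-empty 1-d array")
        if np.any(arr < -1e-15):
            raise ValueError("pmf entries must be non-negative")
        total = float(arr.sum())
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"pmf mass {total} deviates from 1 by more than {_MASS_TOL}")
        object.__setattr__(self, "pmf", np.clip(arr, 0.0, None))

    # -- basic queries -------------------------------------------------
    @property
    def support_max(self) -> int:
        return self.pmf.size - 1

    def cdf(self) -> np.ndarray:
        return np.minimum(np.cumsum(self.pmf), 1.0)

    @property
    def mean(self) -> float:
        return float(np.arange(self.pmf.size) @ self.pmf)

    @property
    def variance(self) -> float:
        k = np.arange(self.pmf.size)
        m = self.mean
        return float(((k - m) ** 2) @ self.pmf)

    def quantile(self, alpha: float) -> int:
        """Smallest k with F(k) >= alpha."""
        if not 0.0 < alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        return int(np.searchsorted(self.cdf(), alpha - 1e-12))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.choice(self.pmf.size, size=size, p=self.pmf / self.pmf.sum())

    # -- serialisation -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"support_max": self.support_max, "pmf": self.pmf.tolist()})

    @classmethod
    def from_json(cls, payload: str) -> "DiscreteDistribution":
        obj = json.loads(payload)
        return cls(np.asarray(obj["pmf"], dtype=float))

    @classmethod
    def point_mass(cls, k: int) -> "DiscreteDistribution":
        pmf = np.zeros(k + 1)
        pmf[k] = 1.0
        return cls(pmf)


def poisson_binomial(probs: Sequence[float]) -> DiscreteDistribution:
    """Exact distribution of the sum of independent Bernoulli(p_i) trials.

    Computed by iterative convolution of the individual two-point pmfs;
    support is 0..len(probs). O(n^2), trivial at ED snapshot sizes.
    """
    p = np.asarray(list(probs), dtype=float)
    if p.size and (np.any(p < 0.0) or np.any(p > 1.0)):
        raise ValueError("all probabilities must lie in [0, 1]")
    pmf = np.ones(1)
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    # guard against accumulated rounding before the constructor's mass check
    pmf /= pmf.sum()
    return DiscreteDistribution(pmf)


def convolve(a: DiscreteDistribution, b: DiscreteDistribution) -> DiscreteDistribution:
    """Distribution of the sum of two independent counts."""
    pmf = np.convolve(a.pmf, b.pmf)
    return DiscreteDistribution(pmf / pmf.sum())


def pit_midpoint(dist: DiscreteDistribution, observed: int) -> float:
    """Midpoint probability integral transform of a discrete observation.

    Returns (F(observed-1) + F(observed)) / 2 with F(-1) = 0.  An observed
    count beyond the support uses F(K) = 1 on both sides, i.e. maps to 1
    minus half the (zero) mass above the support.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    cdf = dist.cdf()
    upper = 1.0 if observed > dist.support_max else float(cdf[observed])
    lower = 0.0 if observed == 0 else (1.0 if observed - 1 > dist.support_max else float(cdf[observed - 1]))
    return 0.5 * (lower + upper)


def qq_concordance(pit_values: Iterable[float]) -> tuple[np.ndarray, float]:
    """Empirical-cdf points of the PIT values against the uniform diagonal.

    Returns ``(points, max_deviation)`` where ``points`` is an (n, 2) array
    of (sorted PIT value, empirical cdf) pairs for plotting, and
    ``max_deviation`` is the Kolmogorov–Smirnov-type statistic
    sup_x |ecdf(x) - x| on [0, 1].
    """
    values = np.sort(np.asarray(list(pit_values), dtype=float))
    if values.size == 0:
        raise ValueError("need at least one PIT value")
    if np.any(values < 0.0) or np.any(values > 1.0):
        raise ValueError("PIT values must lie in [0, 1]")
    n = values.size
    ecdf = np.arange(1, n + 1) / n
    # KS distance against U(0,1): check both sides of each jump
    d_plus = np.max(ecdf - values)
    d_minus = np.max(values - np.arange(0, n) / n)
    stat = float(max(d_plus, d_minus))
    return np.column_stack([values, ecdf]), stat


def ks_uniform_critical(n: int, alpha: float = 0.01) -> float:
    """Critical value of the one-sample KS statistic against U(0,1)."""
    return float(stats.kstwo.ppf(1.0 - alpha, n))


def summarize(
    dist: DiscreteDistribution, coverage: float = 0.8
) -> tuple[float, float, tuple[int, int]]:
    """Mean, variance and a central interval of the given coverage.

    The interval uses the quantile convention q(a) = smallest k with
    F(k) >= a, taken at a = (1-coverage)/2 and 1 - (1-coverage)/2; for the
    10th–90th centile band pass coverage=0.8.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    alpha = (1.0 - coverage) / 2.0
    lo = dist.quantile(alpha)
    hi = dist.quantile(1.0 - alpha)
    return dist.mean, dist.variance, (lo, hi)


def truncated_poisson(mean: float, tail: float = 1e-9) -> DiscreteDistribution:
    """Poisson(mean) truncated so the discarded tail mass is < ``tail``.

    The retained pmf is renormalised.  A mean of (numerically) zero gives a
    point mass at 0.
    """
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if mean < 1e-12:
        return DiscreteDistribution.point_mass(0)
    k_max = int(stats.poisson.isf(tail, mean)) + 1
    pmf = stats.poisson.pmf(np.arange(k_max + 1), mean)
    return DiscreteDistribution(pmf / pmf.sum())
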