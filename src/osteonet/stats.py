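"""Inferential statistics for colony experiments.

One-way fixed-effects ANOVA with a Student-Newman-Keuls (SNK) stepwise
post hoc on group means, a Pearson chi-squared test on 2x2 proportion
tables, and an a-priori sample-size helper for the one-way design based on
the noncentral F distribution.

The SNK procedure orders the group means, compares the range of every
contiguous stretch of r means against the studentized-range critical value
q(r, df_within, alpha) * sqrt(MSW / n_h), working from the full range
inward, and never declares a pair significant inside a stretch that already
failed — the coherence property that distinguishes SNK from all-pairs Tukey.
With unequal group sizes, n_h is the harmonic mean (Tukey-Kramer style
adjustment).  Critical values come from the studentized-range distribution
itself (numerical integration via scipy), not from printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "AnovaResult",
    "Chi2Result",
    "PowerSpec",
    "one_way_anova",
    "snk_test",
    "chi_squared_proportions",
    "anova_power",
    "anova_n_per_group",
]


@dataclass
class GroupData:
    label: str
    observations: np.ndarray

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float).ravel()
        if self.observations.size < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p: float


class Chi2Result(NamedTuple):
    chi2: float
    df: int
    p: float


@dataclass
class PowerSpec:
    """A-priori sizing parameters: Cohen's f, alpha, target power, groups."""

    effect_size_f: float
    alpha: float = 0.05
    power: float = 0.80
    n_groups: int = 2

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect_size_f must be > 0")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")


def _as_groups(groups: Sequence) -> list[GroupData]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupData):
            out.append(g)
        else:
            out.append(GroupData(label=f"g{i + 1}", observations=np.asarray(g)))
    if len(out) < 2:
        raise ValueError("at least 2 groups required")
    return out


def _decompose(groups: list[GroupData]):
    all_obs = np.concatenate([g.observations for g in groups])
    grand = all_obs.mean()
    ss_between = sum(
        g.observations.size * (g.observations.mean() - grand) ** 2 for g in groups
    )
    ss_within = sum(
        ((g.observations - g.observations.mean()) ** 2).sum() for g in groups
    )
    df_between = len(groups) - 1
    df_within = all_obs.size - len(groups)
    return ss_between, ss_within, df_between, df_within


def one_way_anova(groups: Sequence) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    Accepts GroupData objects or plain sequences of observations.  With
    zero within-group variance, F is 0 (p = 1) when the means are equal and
    infinite (p = 0) otherwise.
    """
    gs = _as_groups(groups)
    ssb, ssw, dfb, dfw = _decompose(gs)
    if ssw == 0.0:
        if np.isclose(ssb, 0.0):
            return AnovaResult(0.0, dfb, dfw, 1.0)
        return AnovaResult(float("inf"), dfb, dfw, 0.0)
    f = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(f), dfb, dfw, float(sps.f.sf(f, dfb, dfw)))


@lru_cache(maxsize=None)
def studentized_range_quantile(r: int, df: int, alpha: float) -> float:
    """Upper-alpha critical value q(r, df, alpha) of the studentized range."""
    return float(sps.studentized_range.ppf(1.0 - alpha, r, df))


def snk_test(groups: Sequence, alpha: float = 0.05) -> set[tuple[str, str]]:
    """Student-Newman-Keuls stepwise comparisons on ordered group means.

    Returns the set of (label_low_mean, label_high_mean) pairs declared
    significantly different at family level ``alpha``.  Subranges of a
    non-significant stretch are never tested (declared non-significant).
    """
    gs = _as_groups(groups)
    _, ssw, _, dfw = _decompose(gs)
    if dfw <= 0:
        raise ValueError("no within-group degrees of freedom")
    msw = ssw / dfw
    if msw == 0.0:
        means0 = [g.observations.mean() for g in gs]
        if len(set(means0)) == 1:
            return set()
        msw = np.finfo(float).tiny  # degenerate: any separation is infinite
    sizes = np.array([g.observations.size for g in gs], dtype=float)
    n_h = len(sizes) / np.sum(1.0 / sizes)  # harmonic mean group size
    se = np.sqrt(msw / n_h)

    order = sorted(range(len(gs)), key=lambda i: (gs[i].observations.mean(), gs[i].label))
    means = [gs[i].observations.mean() for i in order]
    labels = [gs[i].label for i in order]

    significant: set[tuple[str, str]] = set()
    tested: set[tuple[int, int]] = set()

    def step(i: int, j: int) -> None:
        if j <= i or (i, j) in tested:
            return
        tested.add((i, j))
        r = j - i + 1
        q_obs = (means[j] - means[i]) / se
        if q_obs > studentized_range_quantile(r, dfw, alpha):
            significant.add((labels[i], labels[j]))
            step(i, j - 1)
            step(i + 1, j)
        # a non-significant stretch blocks all nested comparisons

    step(0, len(gs) - 1)
    return significant


def chi_squared_proportions(
    table: Sequence[Sequence[int]], yates: bool = False
) -> Chi2Result:
    """Pearson chi-squared test on a 2x2 contingency table.

    No continuity correction by default; set ``yates=True`` for it.  Any
    zero row or column margin is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    return Chi2Result(chi2=chi2, df=1, p=float(sps.chi2.sf(chi2, 1)))


def anova_power(spec: PowerSpec, n_per_group: int) -> float:
    """Power of the one-way F test at ``n_per_group`` observations/group.

    Noncentrality lambda = f^2 * n_groups * n, df = (k - 1, k (n - 1)).
    """
    k = spec.n_groups
    df1 = k - 1
    df2 = k * (n_per_group - 1)
    if df2 <= 0:
        return 0.0
    fcrit = sps.f.isf(spec.alpha, df1, df2)
    lam = spec.effect_size_f**2 * k * n_per_group
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def anova_n_per_group(spec: PowerSpec, max_n: int = 10**6) -> int:
    """Smallest per-group n whose one-way F-test power reaches the target.

    Monotone search (doubling then bisection) on the noncentral-F power
    curve; n = 2 is the floor.  Raises if the target is unreachable within
    ``max_n``.
    """
    lo, hi = 2, 2
    if anova_power(spec, lo) >= spec.power:
        return lo
    while anova_power(spec, hi) < spec.power:
        hi *= 2
        if hi > max_n:
            raise ValueError(f"target power unreachable within n <= {max_n}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if anova_power(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
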