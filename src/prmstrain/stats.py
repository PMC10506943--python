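"""Cohort statistics: exact Mann-Whitney U, Shapiro-Wilk, Welch t.

The headline comparison of the analysis — normalized strain ratios of an
intact vs a unilateral-avulsion group — is non-parametric: ratios are
strongly right-skewed, so normality is checked with Shapiro-Wilk and the
groups are compared with a two-sided Mann-Whitney U test.  For the small
cohorts this pipeline targets the U test is computed by exact
enumeration of all group assignments of the pooled sample (8 vs 10 women
means C(18, 8) = 43,758 assignments); a tie-corrected normal
approximation with continuity correction takes over when enumeration
would be too large.  Demographic-style comparisons of approximately
normal quantities use Welch's t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import InputError

#: Enumerate exactly whenever C(n_a + n_b, n_a) does not exceed this.
EXACT_ENUMERATION_LIMIT = 200_000


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _u_from_ranksum(rank_sum: float, n_a: int) -> float:
    return rank_sum - n_a * (n_a + 1) / 2.0


def mann_whitney_u(a, b) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p, method)`` with ``U = min(U_a, U_b)`` where ``U_a``
    counts pairs ``x < y`` plus half the ties.  ``method`` is
    ``"exact_enumeration"`` (all C(n_a+n_b, n_a) assignments of the
    pooled values; handles ties by enumerating the observed multiset) or
    ``"normal_approximation"`` (tie-corrected variance, continuity
    correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = _u_from_ranksum(ranks[:n_a].sum(), n_a)
    u_b = n_a * n_b - u_a
    u_obs = min(u_a, u_b)

    if math.comb(n_a + n_b, n_a) <= EXACT_ENUMERATION_LIMIT:
        idx = np.array(list(combinations(range(n_a + n_b), n_a)), dtype=np.intp)
        ua = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2.0
        u_min = np.minimum(ua, n_a * n_b - ua)
        p = float(np.mean(u_min <= u_obs + 1e-9))
        return float(u_obs), p, "exact_enumeration"

    # normal approximation with tie correction and continuity correction
    N = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return float(u_obs), 1.0, "normal_approximation"
    mean = n_a * n_b / 2.0
    z = (u_obs - mean + 0.5) / math.sqrt(var)  # continuity toward the mean
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return float(u_obs), float(p), "normal_approximation"


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) via the Royston approximation."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InputError("Shapiro-Wilk needs at least 3 observations")
    if x.size > 5000:
        raise InputError("Shapiro-Wilk supports at most 5000 observations")
    if np.ptp(x) == 0:
        raise InputError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's two-sample t test (Satterthwaite degrees of freedom)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("Welch t needs at least 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise InputError("Welch t undefined: both groups have zero variance")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class GroupComparison:
    """Result of comparing two groups of normalized strain ratios."""

    ratios_a: np.ndarray
    ratios_b: np.ndarray
    medians: tuple[float, float]
    u_statistic: float
    p_value: float
    method: str
    normality_p: tuple[float, float]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def five_number_summaries(self) -> dict:
        out = {}
        for name, x in (("a", self.ratios_a), ("b", self.ratios_b)):
            q = np.percentile(x, [0, 25, 50, 75, 100])
            out[name] = {
                "min": float(q[0]),
                "q1": float(q[1]),
                "median": float(q[2]),
                "q3": float(q[3]),
                "max": float(q[4]),
            }
        return out

    def to_dict(self) -> dict:
        return {
            "n": [int(self.ratios_a.size), int(self.ratios_b.size)],
            "medians": [float(m) for m in self.medians],
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "method": self.method,
            "normality_p": [float(p) for p in self.normality_p],
            "alpha": self.alpha,
            "significant": self.significant,
            "five_number_summaries": self.five_number_summaries(),
        }


def compare_cohorts(ratios_a, ratios_b, alpha: float = 0.05) -> GroupComparison:
    """Full two-group comparison of normalized strain ratios.

    Accepts raw ratio sequences or
    :class:`~prmstrain.regions.SubjectStrainSummary` lists.
    """
    ratios_a = _extract_ratios(ratios_a)
    ratios_b = _extract_ratios(ratios_b)
    u, p, method = mann_whitney_u(ratios_a, ratios_b)
    norm_p = []
    for x in (ratios_a, ratios_b):
        try:
            norm_p.append(shapiro_wilk(x)[1])
        except InputError:
            norm_p.append(float("nan"))
    return GroupComparison(
        ratios_a=ratios_a,
        ratios_b=ratios_b,
        medians=(float(np.median(ratios_a)), float(np.median(ratios_b))),
        u_statistic=u,
        p_value=p,
        method=method,
        normality_p=tuple(norm_p),
        alpha=alpha,
    )


def _extract_ratios(group) -> np.ndarray:
    vals = []
    for item in group:
        r = getattr(item, "ratio", item)
        if r is None:
            raise InputError("a subject summary is missing its ratio")
        vals.append(float(r))
    if not vals:
        raise InputError("group is empty")
    return np.asarray(vals, dtype=float)
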