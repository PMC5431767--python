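"""Nonparametric statistics: Wilcoxon matched-pairs signed-rank test and
Fleiss' kappa.

The signed-rank test is implemented from first principles because the
analysis depends on a specific variant: zero differences are dropped, tied
absolute differences receive midranks, and the default p-value is the
two-sided normal approximation *without* continuity correction and without
tie-variance correction.  An exact method (full enumeration of sign
assignments over the observed absolute ranks) is provided for small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "WilcoxonResult",
    "RatingTable",
    "KappaResult",
    "wilcoxon_signed_rank",
    "fleiss_kappa",
]

_MAX_EXACT_N = 22


@dataclass(frozen=True)
class WilcoxonResult:
    n_used: int
    w_plus: float
    w_minus: float
    statistic: float  # min(w_plus, w_minus)
    method: str
    p_two_sided: float
    z: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_sided < alpha


def wilcoxon_signed_rank(
    differences,
    method: str = "normal_approx",
    tie_correction: bool = False,
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired differences.

    Parameters
    ----------
    differences
        Paired differences; exact zeros are dropped before ranking.
    method
        ``"normal_approx"`` (default): z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)
        with W = min(W+, W-), no continuity correction.  ``"exact"``: full
        enumeration of all 2^n sign assignments of the observed absolute
        ranks (midranks kept, so ties are handled consistently).
    tie_correction
        Subtract sum(t^3 - t)/48 from the normal-approximation variance.

    Raises
    ------
    ValueError
        If every difference is zero, or the method is unknown.
    """
    if method not in ("exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}; use 'exact' or 'normal_approx'")
    d = np.asarray(differences, dtype=float).ravel()
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero pairs: all differences are zero")

    abs_d = np.abs(d)
    ranks = _sps.rankdata(abs_d)  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if method == "exact":
        if n > _MAX_EXACT_N:
            raise ValueError(f"exact enumeration limited to n <= {_MAX_EXACT_N}, got {n}")
        p = _exact_p(ranks, statistic)
        return WilcoxonResult(n, w_plus, w_minus, statistic, "exact", p)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if tie_correction:
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        raise ValueError("zero variance: all absolute differences tied at one value")
    z = (statistic - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * _sps.norm.cdf(z)))
    return WilcoxonResult(n, w_plus, w_minus, statistic, "normal_approx", p, z=float(z))


def _exact_p(ranks: np.ndarray, statistic: float) -> float:
    """P(min(T+, T-) <= observed) over all 2^n equiprobable sign patterns."""
    total = float(ranks.sum())
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    t_min = np.minimum(sums, total - sums)
    return float(np.mean(t_min <= statistic + 1e-9))


# ---------------------------------------------------------------------------
# Fleiss' kappa


@dataclass
class RatingTable:
    """Items x categories matrix of rating counts."""

    counts: np.ndarray
    categories: tuple[str, ...] | None = None
    items: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("rating table must be 2D (items x categories)")
        if np.any(self.counts < 0):
            raise ValueError("rating counts must be non-negative")
        if self.categories is not None:
            self.categories = tuple(self.categories)
            if len(self.categories) != self.counts.shape[1]:
                raise ValueError("category labels do not match table width")
        if self.items is not None:
            self.items = tuple(self.items)
            if len(self.items) != self.counts.shape[0]:
                raise ValueError("item labels do not match table height")

    @property
    def n_raters(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None  # None when p_e == 1 (undefined)
    p_bar: float
    p_e: float
    per_item_agreement: tuple[float, ...] = field(default=())

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def fleiss_kappa(table: RatingTable | np.ndarray) -> KappaResult:
    """Fleiss' kappa for a fixed number of raters per item.

    Standard formulation: per-item agreement
    ``P_i = (sum_j n_ij^2 - n) / (n (n - 1))``, mean observed agreement
    ``p_bar``, chance agreement ``p_e = sum_j p_j^2`` from the pooled
    category proportions, and ``kappa = (p_bar - p_e) / (1 - p_e)``.
    When every rating falls in one category ``p_e = 1`` and kappa is
    undefined (reported as ``None``).
    """
    if not isinstance(table, RatingTable):
        table = RatingTable(np.asarray(table))
    counts = table.counts
    n_items, n_cats = counts.shape
    if n_items < 2:
        raise ValueError("Fleiss' kappa needs at least 2 items")
    if n_cats < 2:
        raise ValueError("Fleiss' kappa needs at least 2 categories")
    raters = table.n_raters
    if np.any(raters != raters[0]):
        raise ValueError("Fleiss' kappa requires the same number of raters per item")
    n = int(raters[0])
    if n < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters per item")

    p_i = (np.sum(counts.astype(float) ** 2, axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_items * n)
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0 - 1e-15:
        return KappaResult(None, p_bar, p_e, tuple(float(x) for x in p_i))
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(float(kappa), p_bar, p_e, tuple(float(x) for x in p_i))
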