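"""Exact and adjusted statistics used by all screens.

Fisher's exact test and the hypergeometric tail are delegated to scipy;
this module fixes the conventions the pipeline relies on: the two-sided
Fisher p sums hypergeometric point probabilities not exceeding that of
the observed table (the point-probability rule used by mainstream
scientific stacks), a zero margin yields p = 1 by convention, and all
tail probabilities are computed in log space by scipy so they stay
finite at corpus-scale totals (N ~ 1e7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; ``a`` is the joint (both-positive) cell."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total < 1:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def has_zero_margin(self) -> bool:
        return 0 in (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def fisher_exact(table: ContingencyTable2x2, sidedness: str = "two_sided") -> float:
    """Fisher's exact p-value for a 2x2 table.

    ``sidedness`` is ``"two_sided"`` (point-probability rule) or
    ``"greater"`` (upper tail of the joint cell ``a``). Degenerate tables
    with an empty margin carry no information and return 1.0.
    """
    if sidedness not in ("two_sided", "greater"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if table.has_zero_margin():
        logger.info("fisher_exact: zero margin in %s, returning p=1 by convention", table)
        return 1.0
    alternative = "two-sided" if sidedness == "two_sided" else "greater"
    return float(sps.fisher_exact(table.as_array(), alternative=alternative).pvalue)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` population size, ``K`` marked items, ``n`` draws. Exact for any
    ``k``; values of ``k`` beyond ``min(K, n)`` give 0, ``k <= 0`` gives 1.
    """
    if K > N or n > N or min(N, K, n) < 0:
        raise ValueError(f"inconsistent hypergeometric parameters N={N}, K={K}, n={n}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def _check_unit_interval(pvals: np.ndarray) -> None:
    if pvals.size and (pvals.min() < 0 or pvals.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")


def bh_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvals, dtype=float)
    _check_unit_interval(arr)
    if arr.size == 0:
        return arr.copy()
    return multipletests(arr, method="fdr_bh")[1]


def bonferroni_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) with m the family size."""
    arr = np.asarray(pvals, dtype=float)
    _check_unit_interval(arr)
    return np.minimum(1.0, arr * arr.size)


def format_pvalue(p: float) -> str:
    """Scientific notation with 3 significant digits (e.g. ``2.56e-05``)."""
    return f"{p:.2e}"
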