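"""Single-locus McDonald-Kreitman hypothesis tests.

The workhorse is a Yates-corrected log-likelihood-ratio (G) test of the
2x2 polymorphism/divergence table, falling back to Fisher's exact test
when expected counts are small and to "not testable" when a margin is
zero.  A Benjamini-Hochberg FDR correction handles multiplicity across
loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mk_counts import MKTable, pool_polymorphism


@dataclass(frozen=True)
class MKTestResult:
    G: float  # NaN unless method == "g_yates"
    p: float  # NaN when not testable
    method: str  # "g_yates" | "fisher" | "not_testable"
    q: float = float("nan")  # BH-adjusted p, filled in by callers


def g_test_yates(table) -> tuple[float, float]:
    """Yates-corrected G statistic and chi-square (1 df) p-value.

    The continuity correction shifts each observed count 0.5 toward its
    expectation, clamped so it never crosses it; G = 2 sum o' ln(o'/e)
    with 0 ln 0 = 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: G test undefined")
    exp = np.outer(rows, cols) / obs.sum()
    shifted = obs + np.clip(exp - obs, -0.5, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(shifted > 0, shifted * np.log(shifted / exp), 0.0)
    G = max(2.0 * terms.sum(), 0.0)
    return float(G), float(stats.chi2.sf(G, df=1))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by point-probability summation: the sum
    of hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one."""
    obs = np.asarray(table)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(stats.fisher_exact(obs, alternative="two-sided")[1])


def mk_test(
    table: MKTable | np.ndarray,
    pooling: str = "pooled",
    min_expected: float = 2.0,
) -> MKTestResult:
    """Test one locus's MK table for deviation from neutrality.

    Policy: the Yates G test is used when all four margins are positive
    and the minimum expected count is at least ``min_expected``; with
    positive margins but small expected counts Fisher's exact test is
    used; a zero margin makes the locus not testable.
    """
    if isinstance(table, MKTable):
        tab = pool_polymorphism(table, mode=pooling)
    else:
        tab = np.asarray(table, dtype=int)
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return MKTestResult(G=float("nan"), p=float("nan"), method="not_testable")
    exp = np.outer(rows, cols) / tab.sum()
    if exp.min() >= min_expected:
        G, p = g_test_yates(tab)
        return MKTestResult(G=G, p=p, method="g_yates")
    return MKTestResult(
        G=float("nan"), p=fisher_exact_two_sided(tab), method="fisher"
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[MKTestResult]) -> list[MKTestResult]:
    """Attach BH q-values across the testable subset of loci."""
    testable = [i for i, r in enumerate(results) if not math.isnan(r.p)]
    if not testable:
        return results
    qs = bh_fdr([results[i].p for i in testable])
    out = list(results)
    for i, q in zip(testable, qs):
        r = out[i]
        out[i] = MKTestResult(G=r.G, p=r.p, method=r.method, q=float(q))
    return out
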