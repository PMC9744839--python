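"""Shared statistical primitives.

Every enrichment test in the package (cancer-event overlap, protein
domains, TF filters) routes through :func:`fisher_enrichment` so there is
exactly one implementation of the 2x2 machinery to validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "EnrichmentResult",
    "fisher_enrichment",
    "set_enrichment",
    "pearson_with_p",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries are excluded from the family and returned as NaN; the
    remaining values are adjusted with m = number of finite p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    q[mask] = out
    return q


@dataclass
class EnrichmentResult:
    """Outcome of a single 2x2 Fisher enrichment test.

    ``table`` is [[a, b], [c, d]] = [[in-query & in-ref, in-query & not],
    [not-query & in-ref, not-query & not]].  The odds ratio is the sample
    cross-product a*d / (b*c); when any cell is zero, 0.5 is added to all
    cells (Haldane) and ``haldane`` is flagged.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    log_or_ci: tuple[float, float]
    p_value: float
    haldane: bool = False
    q_value: float = field(default=np.nan)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        (a, b), (c, d) = self.table
        return a, b, c, d


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Two-sided Fisher exact test with a cross-product odds ratio.

    The 95% CI on the log-OR uses the normal approximation with the
    Woolf standard error sqrt(sum of reciprocal cells).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("2x2 cell counts must be nonnegative")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = min(a, b, c, d) == 0
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if haldane else (a, b, c, d)
    )
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    lo = np.log(orr) - 1.959963984540054 * se
    hi = np.log(orr) + 1.959963984540054 * se
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=float(orr),
        log_or_ci=(float(lo), float(hi)),
        p_value=float(p),
        haldane=haldane,
    )


def set_enrichment(query: set, reference: set, universe: set) -> EnrichmentResult:
    """Fisher enrichment of ``query`` for ``reference`` within ``universe``."""
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe or not reference <= universe:
        raise ValueError("query and reference must be subsets of the universe")
    a = len(query & reference)
    b = len(query - reference)
    c = len(reference - query)
    d = len(universe) - a - b - c
    return fisher_enrichment(a, b, c, d)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p over paired finite observations.

    Returns (nan, nan) if fewer than 3 complete pairs or either vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return float("nan"), float("nan")
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(xv, yv)
    return float(r), float(p)
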