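"""Method-concordance analysis: confusion tables, Fisher's exact test, QQ pairing.

Two feature-selection methods run on the same universe of features yield a
2x2 confusion table (not-selected/selected by A crossed with B).  Association
is quantified by Fisher's exact test, computed entirely in log space so that
tables with cells of order 10^4 and P-values down to ~10^-300 are represented
without underflow — the regime these concordance tables actually live in.

The two-sided P sums the hypergeometric probabilities of every same-margin
table whose probability does not exceed that of the observed table (the
"minimum-likelihood" rule, as in R's fisher.test), with a small relative
tolerance to absorb round-off in the comparison.

QQ pairing compares two P-value samples of possibly different sizes: the
longer sample's empirical quantile function is interpolated at the plotting
positions (i - 0.5)/n of the shorter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["ConfusionTable", "confusion", "fisher_exact", "qq_points"]

_REL_EPS = 1e-7  # relative tolerance on log-probabilities in the minlike rule


def fisher_exact(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact P for a 2x2 table, computed in log space.

    Hypergeometric log-probabilities over the whole same-margin support are
    evaluated with log-gamma and combined with logsumexp, so the result is
    accurate even when the P-value underflows double precision only in
    intermediate products (tables with P ~ 1e-300 are fine).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("cells must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative integers")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if n == 0:
        return 1.0
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = (
        gammaln(r1 + 1)
        + gammaln(r2 + 1)
        + gammaln(c1 + 1)
        + gammaln(c2 + 1)
        - gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(r1 - ks + 1)
        - gammaln(c1 - ks + 1)
        - gammaln(r2 - c1 + ks + 1)
    )
    # minlike rule with relative tolerance on the probability scale:
    # p_k <= p_obs * (1 + eps)  <=>  logp_k <= log_obs + log1p(eps)
    log_obs = logp[ks == a][0]
    selected = logp <= log_obs + np.log1p(_REL_EPS)
    return float(min(1.0, np.exp(logsumexp(logp[selected]))))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation of two selections over a common feature universe.

    Rows: method A (not-selected, selected).  Columns: method B likewise.
    """

    counts: np.ndarray
    universe_size: int
    fisher_p: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("counts must be a 2x2 non-negative integer table")
        if counts.sum() != self.universe_size:
            raise ValueError("counts must sum to universe_size")
        object.__setattr__(self, "counts", counts)


def confusion(
    selected_a: Sequence[str],
    selected_b: Sequence[str],
    universe: Sequence[str],
) -> ConfusionTable:
    """Cross-tabulate two selected-feature sets over a universe of ids."""
    universe = list(universe)
    uset = set(universe)
    sa, sb = set(selected_a), set(selected_b)
    stray = (sa | sb) - uset
    if stray:
        raise ValueError(f"selected ids outside the universe: {sorted(stray)[:5]}")
    n11 = len(sa & sb)
    n10 = len(sa - sb)
    n01 = len(sb - sa)
    n00 = len(uset) - n11 - n10 - n01
    counts = np.array([[n00, n01], [n10, n11]])
    return ConfusionTable(counts=counts, universe_size=len(uset), fisher_p=fisher_exact(counts))


def qq_points(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """Paired quantiles of two samples for a QQ comparison.

    Equal lengths: pairs of sorted order statistics.  Unequal: the longer
    sample's empirical quantile function (linear interpolation between order
    statistics at positions (j - 0.5)/m) is evaluated at the plotting
    positions (i - 0.5)/n of the shorter.  Returns an (n, 2) array with
    column 0 from ``p_a`` and column 1 from ``p_b``.
    """
    a = np.sort(np.asarray(p_a, dtype=float))
    b = np.sort(np.asarray(p_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size == b.size:
        return np.column_stack([a, b])
    short, long_ = (a, b) if a.size < b.size else (b, a)
    pos_short = (np.arange(1, short.size + 1) - 0.5) / short.size
    pos_long = (np.arange(1, long_.size + 1) - 0.5) / long_.size
    reduced = np.interp(pos_short, pos_long, long_)
    if a.size < b.size:
        return np.column_stack([short, reduced])
    return np.column_stack([reduced, short])
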