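"""Gene-set overlap and percent-rank comparison statistics.

Over-representation of one gene set in another is tested with the
upper-tail hypergeometric probability P(X >= k) (the observed overlap
included), with the expected overlap |A||B|/|U| reported alongside.
Mean percent ranks of a gene set are compared against all testable
genes with a two-sided Student's t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two gene sets within a universe."""

    set_a: str
    set_b: str
    universe_n: int
    n_a: int
    n_b: int
    observed_k: int
    expected: float
    p: float
    percent_of_a: float


def hypergeom_overlap(set_a: GeneSet, set_b: GeneSet,
                      universe: GeneSet) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap |A ∩ B|.

    Members outside the universe are dropped (their counts logged).
    ``p = P(X >= k)`` for X ~ Hypergeom(N=|U|, K=|A|, n=|B|);
    ``expected = |A||B|/|U|``.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    a = set_a.members & universe.members
    b = set_b.members & universe.members
    for original, trimmed, name in ((set_a, a, set_a.name), (set_b, b, set_b.name)):
        dropped = len(original.members) - len(trimmed)
        if dropped:
            logger.info("%s: %d member(s) outside the universe dropped",
                        name, dropped)
    n = len(universe)
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    expected = len(a) * len(b) / n
    percent = 100.0 * k / len(a) if a else float("nan")
    return OverlapResult(
        set_a=set_a.name, set_b=set_b.name, universe_n=n,
        n_a=len(a), n_b=len(b), observed_k=k, expected=expected,
        p=p, percent_of_a=percent,
    )


def overlap_table(results: list[OverlapResult]) -> pd.DataFrame:
    rows = [
        {
            "set_a": r.set_a, "set_b": r.set_b, "N": r.universe_n,
            "nA": r.n_a, "nB": r.n_b, "k": r.observed_k,
            "expected": r.expected, "percent_of_a": r.percent_of_a, "p": r.p,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def mean_rank_comparison(
    set_a: GeneSet, ranks: pd.Series
) -> tuple[float, float, float]:
    """Mean percent rank of a gene set vs all testable genes.

    ``ranks`` maps every testable gene to its mean percent rank (the
    background, which includes the set's own members, as the comparison
    is against *all* testable genes).  Returns
    ``(mean_set, mean_background, p)`` from a two-sided pooled-variance
    Student's t-test.  Requires at least two testable set members.
    """
    members = [g for g in set_a.members if g in ranks.index]
    if len(members) < 2:
        raise ValueError(
            f"gene set {set_a.name!r} has {len(members)} testable member(s); "
            "need >= 2"
        )
    a = ranks.loc[members].to_numpy(dtype=float)
    bg = ranks.to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, bg, equal_var=True)
    return float(a.mean()), float(bg.mean()), float(p)


def frac_with_site_test(k_a: int, n_a: int, k_u: int, n_u: int) -> float:
    """Hypergeometric excess of genes carrying >= 1 seed site.

    ``k_a`` of the set's ``n_a`` genes have a site, against ``k_u`` of
    the universe's ``n_u``; returns P(X >= k_a) for
    X ~ Hypergeom(N=n_u, K=k_u, n=n_a).
    """
    if not (0 <= k_a <= n_a <= n_u and k_a <= k_u <= n_u):
        raise ValueError(
            f"inconsistent counts: k_a={k_a}, n_a={n_a}, k_u={k_u}, n_u={n_u}"
        )
    return float(stats.hypergeom.sf(k_a - 1, n_u, k_u, n_a))
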