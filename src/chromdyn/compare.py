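"""Cross-dataset comparison statistics.

Concordance between two cell lines (or any two runs) is quantified with the
exact two-sided Fisher test on 2×2 overlap tables, a one-sided
hypergeometric test for set overlaps, and per-cluster Pearson correlation of
motif enrichment profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "hypergeom_overlap",
    "profile_correlation",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 overlap table over a defined universe.

    ``a`` = in both sets, ``b`` = set 1 only, ``c`` = set 2 only,
    ``d`` = in neither; ``a+b+c+d`` equals the universe size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact(
    t: ContingencyTable,
    confidence_level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Exact two-sided Fisher test with a conditional-likelihood CI.

    The two-sided p-value uses the probability-mass criterion: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table.  The
    returned odds ratio is the sample ``ad/bc`` (0/inf conventions at zero
    cells); the CI is the exact conditional-likelihood interval.

    Returns ``(odds_ratio, p, (ci_low, ci_high))``.
    """
    arr = t.as_array
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    if t.b * t.c > 0:
        or_sample = (t.a * t.d) / (t.b * t.c)
    elif t.a * t.d > 0:
        or_sample = np.inf
    else:
        or_sample = np.nan  # 0/0: a margin is empty
    res = _odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence_level)
    return float(or_sample), float(p), (float(ci.low), float(ci.high))


def hypergeom_overlap(n1: int, n2: int, overlap: int, universe: int) -> float:
    """One-sided overlap test: ``P(X >= overlap)`` with
    ``X ~ Hypergeom(universe, n1, n2)``."""
    if overlap > min(n1, n2):
        raise ValueError("overlap exceeds the smaller set")
    if max(n1, n2) > universe:
        raise ValueError("set larger than universe")
    if overlap < 0:
        raise ValueError("negative overlap")
    return float(stats.hypergeom.sf(overlap - 1, universe, n1, n2))


def profile_correlation(
    zA: pd.DataFrame,
    zB: pd.DataFrame,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Per-cluster Pearson correlation of motif z-profiles between two runs.

    Inputs are motif × cluster tables; motifs are matched by index, clusters
    by column.  Pairs with missing values are dropped per column; columns
    with fewer than ``min_shared`` complete motif pairs are flagged
    undefined (``r = NaN``).
    """
    shared_motifs = zA.index.intersection(zB.index)
    shared_clusters = [c for c in zA.columns if c in zB.columns]
    rows = []
    for cluster in shared_clusters:
        x = zA.loc[shared_motifs, cluster].astype(float)
        y = zB.loc[shared_motifs, cluster].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_shared:
            rows.append(dict(cluster=cluster, n=n, r=np.nan, defined=False))
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append(dict(cluster=cluster, n=n, r=r, defined=True))
    return pd.DataFrame(rows)
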