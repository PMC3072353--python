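"""Hypergeometric over-representation of a gene list in named gene sets.

Given a query of n genes drawn from a universe of N genes, of which K
belong to a set, the upper-tail hypergeometric p-value is the probability
of an overlap at least as large as the observed k:

    p = sum_{j=k}^{min(n, K)} C(K, j) C(N-K, n-j) / C(N, n)

Raw p-values are reported (matching a raw-alpha workflow); a
Benjamini-Hochberg column across sets is optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .io import GeneSetCollection
from .signature import SignatureResult, stats_bh

__all__ = [
    "EnrichmentResult",
    "EnrichmentReport",
    "hypergeom_upper_tail",
    "enrich",
    "signature_query",
]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap between query and set (within universe)
    n: int  # query size (within universe)
    K: int  # set size within universe
    N: int  # universe size
    p: float


@dataclass(frozen=True)
class EnrichmentReport:
    results: tuple[EnrichmentResult, ...]
    n_query_outside_universe: int

    def to_frame(self, *, bh: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "set_name": [r.set_name for r in self.results],
                "k": [r.k for r in self.results],
                "n": [r.n for r in self.results],
                "K": [r.K for r in self.results],
                "N": [r.N for r in self.results],
                "p": [r.p for r in self.results],
            }
        )
        if bh and len(df):
            df["q"] = stats_bh(df["p"].to_numpy())
        return df


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) for a size-n draw from N genes containing K annotated.

    Evaluated through the log-space survival function of the
    hypergeometric distribution, so tiny tail masses do not underflow.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            raise DomainError(f"{name} must be an integer, got {v!r}")
        if v < 0:
            raise DomainError(f"{name} must be non-negative, got {v}")
    if K > N or n > N:
        raise DomainError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise DomainError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: list[str] | tuple[str, ...],
    sets: GeneSetCollection,
    universe: list[str] | tuple[str, ...],
) -> EnrichmentReport:
    """Test every set for over-representation of ``query`` in ``universe``.

    Query genes outside the universe are dropped (their count is reported);
    each set is intersected with the universe before testing. Results come
    back sorted by ascending p, ties broken by set name.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise DomainError("universe is empty")
    uni_set = set(uni)
    query_unique = list(dict.fromkeys(query))
    query_in = [g for g in query_unique if g in uni_set]
    n_outside = len(query_unique) - len(query_in)
    qset = set(query_in)
    N = len(uni)
    n = len(query_in)
    results = []
    for s in sets:
        members = set(s.members) & uni_set
        K = len(members)
        k = len(qset & members)
        p = hypergeom_upper_tail(k, K, n, N) if K else 1.0
        results.append(EnrichmentResult(s.name, k, n, K, N, p))
    results.sort(key=lambda r: (r.p, r.set_name))
    return EnrichmentReport(tuple(results), n_outside)


def signature_query(signature: SignatureResult, direction: str = "positive") -> list[str]:
    """Signature genes correlated toward one class.

    ``direction='positive'`` keeps genes with r > 0 (up in the class coded
    1, i.e. up-regulated in RB1-positive samples); ``'negative'`` keeps
    r < 0. The direction must be chosen explicitly because "up-regulated"
    is meaningless without fixing the reference class.
    """
    if direction not in ("positive", "negative"):
        raise DomainError("direction must be 'positive' or 'negative'")
    if direction == "positive":
        return [g.gene_id for g in signature.selected if g.r > 0]
    return [g.gene_id for g in signature.selected if g.r < 0]
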