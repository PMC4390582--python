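"""Gene-set overlap statistics and annotation enrichment.

Quantifies how strongly two gene sets drawn from a common universe of N
assayable identifiers co-occur. For sets of sizes K and n overlapping in x
genes,

    fold enrichment = (x / n) / (K / N)

and significance is the hypergeometric upper tail P(X >= x), i.e. the
probability of at least that overlap when the sets are drawn independently
without replacement. The tail is summed in log-space (lgamma combinatorics)
so that values around 1e-40 and below are computed without underflow.

Also provides a Venn partition of up to five sets and a catalog-wide
annotation (e.g. GO term) enrichment scan, with DAVID's conservative EASE
variant (x - 1 substituted for x) available as a mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "OverlapResult",
    "hypergeom_tail",
    "overlap_stats",
    "venn_partition",
    "annotation_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled identifier set with an optional direction tag."""

    label: str
    ids: FrozenSet[str]
    direction: str = "any"  # up | down | any
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))
        if self.direction not in ("up", "down", "any"):
            raise ValueError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def union(self, other: "GeneSet", label: Optional[str] = None) -> "GeneSet":
        """Union set ('affected' = up | down), direction 'any'."""
        return GeneSet(label or f"{self.label}|{other.label}",
                       self.ids | other.ids, "any")


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two sets against a universe: counts, fold, tail P."""

    universe_size: int
    set1_size: int
    set2_size: int
    overlap: int
    fold_enrichment: float
    p_hyper: float

    @property
    def overlap_percent(self) -> float:
        """Overlap as a percentage of set2 (the query set)."""
        return 100.0 * self.overlap / self.set2_size


def _log_weights(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    k = np.asarray(k)
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
    )


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P[X = k]; normalized over the support so the accumulated lgamma
    rounding error cancels and the point masses sum to 1 to machine
    precision."""
    support = np.arange(max(0, n - (N - K)), min(K, n) + 1)
    return _log_weights(k, N, K, n) - logsumexp(_log_weights(support, N, K, n))


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    Exact log-space summation over the support from x to min(K, n); stable
    down to P ~ 1e-60 and beyond. ``x = 0`` returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not (0 <= x <= min(K, n)):
        raise ValueError("require 0 <= x <= min(K, n)")
    if x == 0:
        return 1.0
    ks = np.arange(x, min(K, n) + 1)
    logp = logsumexp(_log_hypergeom_pmf(ks, N, K, n))
    return float(min(1.0, math.exp(logp)))


def overlap_stats(set1: GeneSet, set2: GeneSet, universe_size: int) -> OverlapResult:
    """Fold enrichment and hypergeometric tail P for two sets' intersection.

    ``set1`` plays the K role and ``set2`` the n (query) role; the roles are
    interchangeable for P but define which denominator ``fold`` uses:
    ``fold = (x/|set2|) / (|set1|/N)``.
    """
    K, n = len(set1), len(set2)
    if universe_size < max(K, n):
        raise ValueError("universe smaller than a set")
    x = len(set1.ids & set2.ids)
    fold = (x / n) / (K / universe_size) if (n and K) else math.nan
    return OverlapResult(
        universe_size=universe_size,
        set1_size=K,
        set2_size=n,
        overlap=x,
        fold_enrichment=fold,
        p_hyper=hypergeom_tail(universe_size, K, n, x),
    )


def overlap_counts(N: int, K: int, n: int, x: int) -> OverlapResult:
    """overlap_stats from printed counts instead of explicit id sets."""
    if not (0 <= x <= min(K, n) <= N):
        raise ValueError("inconsistent overlap counts")
    fold = (x / n) / (K / N)
    return OverlapResult(N, K, n, x, fold, hypergeom_tail(N, K, n, x))


__all__.append("overlap_counts")


def venn_partition(
    sets: Sequence[GeneSet],
    universe: Optional[Iterable[str]] = None,
) -> Dict[Tuple[bool, ...], List[str]]:
    """Partition identifiers into the 2^k Venn cells of up to five sets.

    Each id is assigned to exactly one membership-signature cell (a tuple of
    booleans in input-set order). When a universe is supplied, ids in no set
    populate the all-False cell and every set must be contained in the
    universe; otherwise the universe is the union of the sets. Cell id lists
    are sorted; duplicate ids within a set are deduplicated by construction.
    """
    if len(sets) > 5:
        raise ValueError("venn_partition supports at most 5 sets")
    if universe is None:
        univ: Set[str] = set().union(*(s.ids for s in sets)) if sets else set()
    else:
        univ = set(universe)
        for s in sets:
            extra = s.ids - univ
            if extra:
                raise ValueError(
                    f"set {s.label!r} has {len(extra)} id(s) outside the universe"
                )
    cells: Dict[Tuple[bool, ...], List[str]] = {}
    for gid in univ:
        sig = tuple(gid in s.ids for s in sets)
        cells.setdefault(sig, []).append(gid)
    for ids in cells.values():
        ids.sort()
    return cells


def annotation_enrichment(
    query: GeneSet,
    catalog: Sequence[GeneSet],
    universe_size: int,
    mode: str = "hypergeometric",
    universe: Optional[Iterable[str]] = None,
    fdr: bool = True,
) -> pd.DataFrame:
    """Over-representation of each catalog term within a query set.

    For a term of size K and a query of size n overlapping in x genes:
    ``fold = (x/n)/(K/N)`` and ``p = P(X >= x)`` (upper hypergeometric tail).
    ``mode="ease"`` substitutes ``x - 1`` for x in the tail (DAVID's
    conservative EASE score); terms with x = 0 get P = 1 in either mode.
    When an explicit ``universe`` is given, terms and query are intersected
    with it first. Returns a DataFrame with columns
    ``term, K, n, x, fold, p`` plus BH ``q`` when ``fdr`` is set.
    """
    if mode not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    qids = set(query.ids)
    if universe is not None:
        univ = set(universe)
        universe_size = len(univ)
        qids &= univ
    n = len(qids)
    if n == 0:
        logger.warning("annotation_enrichment: empty query, all P = 1")
    rows = []
    for term in catalog:
        tids = set(term.ids)
        if universe is not None:
            tids &= univ
        K = len(tids)
        x = len(tids & qids)
        if n == 0 or K == 0:
            fold, p = math.nan, 1.0
        else:
            fold = (x / n) / (K / universe_size)
            x_eff = max(0, x - 1) if mode == "ease" else x
            p = hypergeom_tail(universe_size, K, n, x_eff)
        rows.append((term.label, K, n, x, fold, p))
    df = pd.DataFrame(rows, columns=["term", "K", "n", "x", "fold", "p"])
    if fdr and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
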