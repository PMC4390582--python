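"""Differential-expression calling on normalized two-condition matrices.

Consumes an already-normalized genes x samples matrix of log2 expression
values with a treated/control condition map, and produces per-gene
directional calls by the classic microarray recipe: a two-sample t-test
(Welch by default) on the log2 values combined with a fold-change
threshold applied to the difference of group means (a ratio of geometric
means on the natural scale). A gene is called

* ``up``   when ``log2fc >= log2(fc_threshold)`` and ``p < alpha``,
* ``down`` when ``log2fc <= -log2(fc_threshold)`` and ``p < alpha``,
* ``flat`` otherwise.

No multiple-testing correction is applied by default (raw P < alpha); the
calls feed set-level overlap statistics downstream where the universe-wide
hypergeometric test absorbs the set sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .overlap_enrichment import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "DECall", "call_de", "calls_to_frame", "to_gene_sets"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2 expression with a two-condition sample map."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    condition_map: Mapping[str, str]  # sample id -> "treated" | "control"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.condition_map]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        bad = {c for c in self.condition_map.values()} - {"treated", "control"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    def samples(self, condition: str) -> List[str]:
        return [s for s in self.values.columns if self.condition_map[s] == condition]


@dataclass(frozen=True)
class DECall:
    gene_id: str
    log2fc: float
    t_stat: float
    p_value: float
    call: str  # up | down | flat


def call_de(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    variant: str = "welch",
) -> List[DECall]:
    """Per-gene t-test plus fold-change thresholding.

    ``fc_threshold`` is on the linear scale (>= 1); the gate on the log2
    difference of means is ``|log2fc| >= log2(fc_threshold)`` (inclusive).
    ``variant`` selects Welch (unequal variances, default) or the pooled
    equal-variance t-test. Genes with zero variance in both groups and
    equal means have an undefined t statistic and are called flat with a
    warning; zero variance with unequal means yields p = 0.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    treated = matrix.samples("treated")
    control = matrix.samples("control")
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 replicates per condition")

    xt = matrix.values[treated].to_numpy(dtype=float)
    xc = matrix.values[control].to_numpy(dtype=float)
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    # degenerate rows: both groups constant
    degenerate = np.isnan(t)
    if degenerate.any():
        unequal = degenerate & (log2fc != 0)
        p[degenerate] = 1.0
        p[unequal] = 0.0
        t[unequal] = np.where(log2fc[unequal] > 0, np.inf, -np.inf)
        n_flat = int((degenerate & ~unequal).sum())
        if n_flat:
            logger.warning("call_de: %d gene(s) with zero variance and equal "
                           "means called flat", n_flat)

    lfc_gate = math.log2(fc_threshold)
    calls = np.where(
        (p < alpha) & (log2fc >= lfc_gate), "up",
        np.where((p < alpha) & (log2fc <= -lfc_gate), "down", "flat"),
    )
    return [
        DECall(g, float(f), float(ts), float(pv), str(c))
        for g, f, ts, pv, c in zip(matrix.values.index, log2fc, t, p, calls)
    ]


def calls_to_frame(calls: List[DECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.log2fc, c.t_stat, c.p_value, c.call) for c in calls],
        columns=["gene_id", "log2fc", "t_stat", "p_value", "call"],
    )


def to_gene_sets(calls: List[DECall], label_prefix: str) -> Tuple[GeneSet, GeneSet]:
    """Partition called genes into (up, down) sets; labels carry the prefix."""
    up = frozenset(c.gene_id for c in calls if c.call == "up")
    down = frozenset(c.gene_id for c in calls if c.call == "down")
    return (
        GeneSet(f"{label_prefix}_up", up, "up"),
        GeneSet(f"{label_prefix}_down", down, "down"),
    )
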