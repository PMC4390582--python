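"""Relative qPCR quantification by the comparative-Ct (delta-delta-Ct) method.

Each well reports a threshold cycle Ct; lower Ct means more template, and
one cycle is one doubling (amplification efficiency fixed at 2). Target
expression is normalized to a reference gene measured in the same samples:

    dCt  = Ct(gene) - Ct(reference)        per replicate
    ddCt = mean dCt(treated) - mean dCt(control)
    fold = 2 ** (-ddCt)

The spread is propagated from the replicate dCt sample standard deviations
as sd(ddCt) = sqrt(sd_t^2 + sd_c^2) (root-sum-square) and reported on the
linear fold scale by the delta method, sd_fold = fold * ln(2) * sd(ddCt).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Dict, List, Tuple

__all__ = ["CtRecord", "CtTable", "relative_fold_change"]


@dataclass(frozen=True)
class CtRecord:
    gene_id: str
    condition: str  # treated | control
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.condition not in ("treated", "control"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class CtTable:
    """Flat collection of Ct measurements, indexable by gene and condition."""

    records: Tuple[CtRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def ct_by_replicate(self, gene_id: str, condition: str) -> Dict[int, float]:
        out = {
            r.replicate: r.ct
            for r in self.records
            if r.gene_id == gene_id and r.condition == condition
        }
        if not out:
            raise KeyError(f"no Ct values for gene {gene_id!r} in {condition!r}")
        return out

    @property
    def gene_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene_id, None)
        return list(seen)


def _delta_ct(table: CtTable, gene: str, reference: str, condition: str) -> List[float]:
    gene_ct = table.ct_by_replicate(gene, condition)
    ref_ct = table.ct_by_replicate(reference, condition)
    shared = sorted(gene_ct.keys() & ref_ct.keys())
    if not shared:
        raise ValueError(
            f"no replicate pairs gene {gene!r} against reference {reference!r} "
            f"in condition {condition!r}"
        )
    return [gene_ct[i] - ref_ct[i] for i in shared]


def relative_fold_change(
    table: CtTable, gene: str, reference_gene: str
) -> Tuple[float, float]:
    """Treated-over-control fold change of a gene, reference-normalized.

    Returns ``(fold, sd)`` where ``fold = 2**(-ddCt)`` and ``sd`` is the
    delta-method standard deviation on the fold scale. Replicate pairing of
    gene against reference is by replicate index. A single replicate per
    condition yields sd = 0.

    Raises ``KeyError`` if the gene or reference is missing in a condition.
    """
    dct_t = _delta_ct(table, gene, reference_gene, "treated")
    dct_c = _delta_ct(table, gene, reference_gene, "control")
    ddct = statistics.fmean(dct_t) - statistics.fmean(dct_c)
    var_t = statistics.variance(dct_t) if len(dct_t) > 1 else 0.0
    var_c = statistics.variance(dct_c) if len(dct_c) > 1 else 0.0
    sd_ddct = math.sqrt(var_t + var_c)
    fold = 2.0 ** (-ddct)
    return fold, fold * math.log(2.0) * sd_ddct
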