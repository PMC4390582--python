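"""Printed-table fixtures from the published H1 modifier screen.

Everything here is a small transcription of numbers printed in the study
this package reimplements: the temperature-series viability counts for the
knockdown driver (and its GAL4-only control), the 61 modifier alleles with
raw counts and printed statistics, the CHD1-interaction counts, and the
microarray cross-referencing count tuples (universe, set sizes, overlaps)
with their printed fold enrichments and hypergeometric P-values. They are
the real-data inputs for the reproduction analyses and tests; no external
download is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .cross_genetics import Arm, CrossDesign, FatherZygosity, ProgenyCounts

__all__ = [
    "table1_counts",
    "table4_counts",
    "table2",
    "table2_progeny",
    "overlap_fixtures",
    "OverlapFixture",
    "MICROARRAY_UNIVERSE",
]

#: transcripts spotted on the expression array (the enrichment universe)
MICROARRAY_UNIVERSE = 18833


def table1_counts() -> pd.DataFrame:
    """Temperature series for the knockdown driver vs the GAL4-only control.

    Columns: arm (screen = knockdown driver cross, control = driver-only),
    temperature, cyplus, cy, printed_percent, printed_p (chi-square P as
    printed, attached to the screen rows). Expected Cy+ fraction is 1/2
    (homozygous w1118 fathers).
    """
    rows = [
        ("screen", 20, 91, 178 - 91, 102, 0.87),
        ("screen", 23, 68, 152 - 68, 89, 0.23),
        ("screen", 26, 40, 155 - 40, 52, 4.4e-5),
        ("screen", 29, 5, 232 - 5, 4, 1.5e-26),
        ("control", 20, 77, 148 - 77, 104, None),
        ("control", 23, 104, 203 - 104, 102, None),
        ("control", 26, 91, 193 - 91, 94, None),
        ("control", 29, 80, 176 - 80, 91, None),
    ]
    return pd.DataFrame(
        rows, columns=["arm", "temperature", "cyplus", "cy", "printed_percent", "printed_p"]
    )


def table4_counts() -> pd.DataFrame:
    """Chd1-null viability in the H1-knockdown background vs inter se control.

    Cy+ adults are Chd1 homozygotes; the expected fraction is 1/3 (CyO
    balancer homozygotes die). printed_p is the printed chi-square P.
    """
    rows = [
        ("screen", 18, 12, 112 - 12, 32, 0.51),
        ("screen", 22, 5, 151 - 5, 10, 0.041),
        ("screen", 26, 1, 83 - 1, 4, 0.0086),
        ("screen", 29, 0, 4 - 0, 0, 0.50),
        ("control", 18, 16, 118 - 16, 41, None),
        ("control", 22, 15, 170 - 15, 26, None),
        ("control", 26, 17, 163 - 17, 31, None),
        ("control", 29, 16, 142 - 16, 34, None),
    ]
    return pd.DataFrame(
        rows, columns=["arm", "temperature", "cyplus", "cy", "printed_percent", "printed_p"]
    )


def _table2_path():
    return resources.files("modscreen.data").joinpath("table2.tsv")


def table2() -> pd.DataFrame:
    """The 61 published modifier alleles: counts plus printed NE / P columns.

    ``ne`` parses the printed "INF" sentinel to ``math.inf``.
    """
    with resources.as_file(_table2_path()) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    df["ne"] = [math.inf if v == "INF" else float(v) for v in df["ne"]]
    return df


def table2_progeny() -> Tuple[List[ProgenyCounts], Dict[str, CrossDesign]]:
    """The modifier-allele counts as progeny records (61 alleles x 2 arms)."""
    df = table2()
    records: List[ProgenyCounts] = []
    designs: Dict[str, CrossDesign] = {}
    for row in df.itertuples(index=False):
        aid = row.allele_id
        designs[aid] = CrossDesign(FatherZygosity(row.father_zygosity))
        records.append(ProgenyCounts(aid, Arm.SCREEN, int(row.screen_cy),
                                     int(row.screen_cyplus)))
        records.append(ProgenyCounts(aid, Arm.CONTROL, int(row.control_cy),
                                     int(row.control_cyplus)))
    return records, designs


@dataclass(frozen=True)
class OverlapFixture:
    """One printed cross-referencing comparison: counts and printed values."""

    name: str
    set1: str  # K role
    set2: str  # n (query) role
    N: int
    K: int
    n: int
    x: int
    printed_fold: float
    printed_p: Optional[float] = None
    printed_percent: Optional[float] = None


def overlap_fixtures() -> List[OverlapFixture]:
    """The seven printed microarray cross-referencing count tuples."""
    N = MICROARRAY_UNIVERSE
    return [
        OverlapFixture("chd1_up_vs_h1_up", "h1_up", "chd1_up",
                       N, 1354, 596, 146, 3.4, 2.3e-41),
        OverlapFixture("chd1_affected_vs_h1_affected", "h1_affected", "chd1_affected",
                       N, 2174, 1012, 291, 2.5, None, 28.8),
        OverlapFixture("hp1_up_vs_h1_up", "h1_up", "hp1_up",
                       N, 1354, 397, 107, 3.7, 2.6e-34, 27.0),
        OverlapFixture("iswi_up_vs_h1_up", "h1_up", "iswi_up",
                       N, 1354, 271, 64, 3.3, 9.7e-18, 23.6),
        OverlapFixture("chd1_up_vs_hp1_up", "hp1_up", "chd1_up",
                       N, 397, 596, 26, 2.1, 4.1e-4),
        OverlapFixture("chd1_up_vs_iswi_up", "iswi_up", "chd1_up",
                       N, 271, 596, 16, 1.9, 0.013),
        OverlapFixture("chd1_up_vs_h1_down", "h1_down", "chd1_up",
                       N, 820, 596, 29, 1.1, 0.32),
    ]
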