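"""Readers and writers for the pipeline's tab-delimited dialects.

All files are UTF-8, tab-delimited, header-required; ``#``-prefixed lines
are comments and are ignored; LF and CRLF line endings are both accepted.
Writers emit a provenance comment line ``# modscreen <version> seed=<s>``
and serialize floats with six significant digits. Malformed input is
reported with its line number.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from . import __version__
from .cross_genetics import Arm, CrossDesign, FatherZygosity, ProgenyCounts
from .de_calls import DECall, ExpressionMatrix
from .overlap_enrichment import GeneSet
from .qpcr import CtRecord, CtTable
from .screen_stats import InteractionResult

PathLike = Union[str, Path]

__all__ = [
    "read_progeny_table",
    "write_progeny_table",
    "read_results",
    "write_results",
    "read_matrix",
    "write_matrix",
    "read_condition_map",
    "write_condition_map",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_ct_table",
    "write_ct_table",
]

PROGENY_COLUMNS = ["allele_id", "arm", "father_zygosity", "cy", "cyplus", "temperature"]
RESULT_COLUMNS = ["allele_id", "ne", "or", "p_fisher", "p_interaction", "label"]


def _provenance(seed: Optional[int]) -> str:
    line = f"# modscreen {__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line


def _fmt(x: float) -> str:
    """Six-significant-digit float serialization with table-style sentinels."""
    if math.isinf(x):
        return "INF" if x > 0 else "-INF"
    if math.isnan(x):
        return "NA"
    return f"{x:.6g}"


def _parse_float(s: str) -> float:
    if s == "INF":
        return math.inf
    if s == "-INF":
        return -math.inf
    if s in ("NA", ""):
        return math.nan
    return float(s)


def _data_rows(path: PathLike) -> Iterable[Tuple[int, List[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if all(not f.strip() for f in row):
                continue
            yield lineno, [f.strip() for f in row]


def _read_table(
    path: PathLike, required: Sequence[str]
) -> Tuple[List[str], List[Tuple[int, Dict[str, str]]]]:
    rows = iter(_data_rows(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        out.append((lineno, dict(zip(header, fields))))
    return header, out


def read_progeny_table(
    path: PathLike,
) -> Tuple[List[ProgenyCounts], Dict[str, CrossDesign]]:
    """Read a progeny TSV into counts plus a per-allele cross-design map.

    Dialect: ``allele_id  arm  father_zygosity  cy  cyplus  [temperature]``;
    ``arm`` in {screen, control}. Negative counts, unknown enum values,
    inconsistent zygosity between a pair of arms, and duplicate
    (allele, arm) pairs are errors naming the offending row.
    """
    _, rows = _read_table(path, PROGENY_COLUMNS[:5])
    records: List[ProgenyCounts] = []
    designs: Dict[str, CrossDesign] = {}
    seen: Dict[Tuple[str, str], int] = {}
    for lineno, row in rows:
        aid = row["allele_id"]
        key = (aid, row["arm"])
        if key in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate (allele, arm) {key}, "
                f"first seen at line {seen[key]}"
            )
        seen[key] = lineno
        try:
            arm = Arm(row["arm"])
            zyg = FatherZygosity(row["father_zygosity"])
            cy, cyplus = int(row["cy"]), int(row["cyplus"])
            if cy < 0 or cyplus < 0:
                raise ValueError("negative count")
            temp_s = row.get("temperature", "")
            temp = float(temp_s) if temp_s not in ("", "NA") else None
            rec = ProgenyCounts(aid, arm, cy, cyplus, temp)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        design = CrossDesign(zyg)
        if aid in designs and designs[aid] != design:
            raise ValueError(f"{path}:{lineno}: zygosity differs between arms of {aid!r}")
        designs[aid] = design
        records.append(rec)
    return records, designs


def write_progeny_table(
    path: PathLike,
    records: Iterable[ProgenyCounts],
    designs: Mapping[str, CrossDesign],
    seed: Optional[int] = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("\t".join(PROGENY_COLUMNS) + "\n")
        for r in records:
            temp = "" if r.temperature is None else _fmt(r.temperature)
            fh.write(
                "\t".join(
                    [
                        r.allele_id,
                        r.arm.value,
                        designs[r.allele_id].father_zygosity.value,
                        str(r.cy_count),
                        str(r.cyplus_count),
                        temp,
                    ]
                )
                + "\n"
            )


def write_results(
    path: PathLike,
    results: Iterable[InteractionResult],
    seed: Optional[int] = None,
) -> None:
    """Write screen results: ``allele_id ne or p_fisher p_interaction label``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            ne = "0.00" if r.ne == 0 else _fmt(r.ne)
            fh.write(
                "\t".join(
                    [r.allele_id, ne, _fmt(r.odds_ratio), _fmt(r.p_fisher),
                     _fmt(r.p_interaction), r.label.value]
                )
                + "\n"
            )


def read_results(path: PathLike) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (INF/NA sentinels parsed)."""
    _, rows = _read_table(path, RESULT_COLUMNS)
    recs = []
    for lineno, row in rows:
        try:
            recs.append(
                {
                    "allele_id": row["allele_id"],
                    "ne": _parse_float(row["ne"]),
                    "or": _parse_float(row["or"]),
                    "p_fisher": _parse_float(row["p_fisher"]),
                    "p_interaction": _parse_float(row["p_interaction"]),
                    "label": row["label"],
                }
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(recs)


def read_matrix(path: PathLike) -> pd.DataFrame:
    """Log2 expression TSV: first column gene_id, header of sample ids."""
    header, rows = _read_table(path, ["gene_id"])
    samples = header[1:]
    index, data = [], []
    seen: Dict[str, int] = {}
    for lineno, row in rows:
        gid = row["gene_id"]
        if gid in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate gene id {gid!r} "
                f"(first at line {seen[gid]})"
            )
        seen[gid] = lineno
        try:
            data.append([_parse_float(row[s]) for s in samples])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        index.append(gid)
    return pd.DataFrame(data, index=pd.Index(index, name="gene_id"), columns=samples)


def write_matrix(path: PathLike, values: pd.DataFrame, seed: Optional[int] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("\t".join(["gene_id", *map(str, values.columns)]) + "\n")
        for gid, row in values.iterrows():
            fh.write("\t".join([str(gid), *(_fmt(v) for v in row)]) + "\n")


def read_condition_map(path: PathLike) -> Dict[str, str]:
    """Two-column TSV ``sample_id  condition`` with condition treated/control."""
    _, rows = _read_table(path, ["sample_id", "condition"])
    cond: Dict[str, str] = {}
    for lineno, row in rows:
        if row["condition"] not in ("treated", "control"):
            raise ValueError(f"{path}:{lineno}: unknown condition {row['condition']!r}")
        if row["sample_id"] in cond:
            raise ValueError(f"{path}:{lineno}: duplicate sample {row['sample_id']!r}")
        cond[row["sample_id"]] = row["condition"]
    return cond


def write_condition_map(
    path: PathLike, condition_map: Mapping[str, str], seed: Optional[int] = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("sample_id\tcondition\n")
        for sample, cond in condition_map.items():
            fh.write(f"{sample}\t{cond}\n")


def read_expression(matrix_path: PathLike, conditions_path: PathLike) -> ExpressionMatrix:
    """Convenience: matrix TSV + condition map TSV -> ExpressionMatrix."""
    return ExpressionMatrix(read_matrix(matrix_path), read_condition_map(conditions_path))


__all__.append("read_expression")


def read_gmt(path: PathLike) -> List[GeneSet]:
    """GMT: one set per line, ``term <tab> description <tab> id...``."""
    sets = []
    for lineno, fields in _data_rows(path):
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs term, description and >= 1 id"
            )
        term, desc, *ids = fields
        sets.append(GeneSet(term, frozenset(i for i in ids if i), description=desc))
    return sets


def write_gmt(path: PathLike, sets: Iterable[GeneSet]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.label, s.description or s.label, *sorted(s.ids)]) + "\n")


def read_gene_list(path: PathLike) -> List[str]:
    """One identifier per line; order preserved, duplicates rejected."""
    ids: List[str] = []
    seen: Dict[str, int] = {}
    for lineno, fields in _data_rows(path):
        if len(fields) != 1:
            raise ValueError(f"{path}:{lineno}: expected one id per line")
        gid = fields[0]
        if gid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate id {gid!r}")
        seen[gid] = lineno
        ids.append(gid)
    return ids


def write_gene_list(path: PathLike, ids: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def read_ct_table(path: PathLike) -> CtTable:
    """Ct TSV: ``gene_id  condition  replicate  ct``."""
    _, rows = _read_table(path, ["gene_id", "condition", "replicate", "ct"])
    records = []
    for lineno, row in rows:
        try:
            records.append(
                CtRecord(row["gene_id"], row["condition"], int(row["replicate"]),
                         float(row["ct"]))
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return CtTable(tuple(records))


def write_ct_table(path: PathLike, table: CtTable, seed: Optional[int] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("gene_id\tcondition\treplicate\tct\n")
        for r in table.records:
            fh.write(f"{r.gene_id}\t{r.condition}\t{r.replicate}\t{_fmt(r.ct)}\n")


def write_de_calls(path: PathLike, calls: Iterable[DECall], seed: Optional[int] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write("gene_id\tlog2fc\tt_stat\tp_value\tcall\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{_fmt(c.log2fc)}\t{_fmt(c.t_stat)}\t"
                f"{_fmt(c.p_value)}\t{c.call}\n"
            )


__all__.append("write_de_calls")
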