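"""Ground-truth generators for every pipeline stage.

Three simulators emulate the data the pipeline consumes, so that hit
calling, differential-expression calling and overlap enrichment can all be
exercised against a known truth without any external download.

Screen counts
    An inverse model of the balancer crosses. Each allele gets a
    mis-expression viability multiplier ``e`` (log-normal) and an
    interaction multiplier ``gamma`` (1 for null alleles, < 1 for planted
    enhancers, > 1 for suppressors). Surviving zygote classes start from
    equal Mendelian fractions; each class's eclosion weight is the product
    of the viability multipliers acting on it (knockdown ``base_kd``, EP
    effect ``e``, interaction ``gamma`` where both perturbations meet) and
    adult counts are drawn multinomially over classes, conditioned on the
    fixed brood size — weights only ever enter through their normalized
    ratios. In heterozygous-father screen crosses the balancer class that
    inherits the driver is itself knocked down (weight ``base_kd``),
    reproducing the escaper distortion seen in real balanced-father data.

Expression matrices
    Two two-condition experiments over a shared gene universe. Baseline
    log2 abundance is Normal(8, 1.5) per gene; planted up/down sets are
    shifted by a fixed log2 effect per factor, with configurable shared and
    cross overlaps between the two factors; replicate noise is i.i.d.
    Normal. Defaults mirror the set sizes of the published H1 / CHD1
    comparison (universe 18833; 1354 up / 820 down for factor 1; 596 up /
    416 down for factor 2; 146 shared up).

Ct tables
    ``Ct = base - log2(expression) + Normal(0, sd_tech)`` per replicate,
    with a reference gene simulated unchanged between conditions.

All generators are deterministic given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .cross_genetics import Arm, CrossDesign, FatherZygosity, ProgenyCounts
from .de_calls import ExpressionMatrix
from .overlap_enrichment import GeneSet
from .qpcr import CtRecord, CtTable

__all__ = [
    "ScreenSimParams",
    "ExprSimParams",
    "simulate_screen",
    "simulate_expression",
    "simulate_ct",
]


@dataclass(frozen=True)
class ScreenSimParams:
    """Study conditions of the simulated screen.

    Defaults are the published screen's conditions: 534 alleles of which
    110 have balanced (heterozygous) fathers, broods of ~150 scored adults
    per arm, knockdown-alone viability ~0.5 of Mendelian at screen
    temperature, and a log-normal mis-expression effect centred slightly
    below 1 (control crosses averaged ~94% of expected). Planted modifier
    fractions give ~43 enhancers and ~21 suppressors per screen.
    """

    n_alleles: int = 534
    n_progeny_per_arm: int = 150
    base_kd_viability: float = 0.5
    ep_log_mu: float = math.log(0.94)
    ep_log_sigma: float = 0.3
    enhancer_fraction: float = 0.08
    suppressor_fraction: float = 0.04
    enhancer_gamma: float = 0.25
    suppressor_gamma: float = 2.0
    het_fraction: float = 110 / 534

    def __post_init__(self) -> None:
        if self.enhancer_fraction + self.suppressor_fraction > 1:
            raise ValueError("modifier fractions must sum to <= 1")
        for name in ("n_alleles", "n_progeny_per_arm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "base_kd_viability", "enhancer_gamma", "suppressor_gamma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _arm_counts(
    rng: np.random.Generator,
    weights: List[float],
    n: int,
) -> Tuple[int, int]:
    """Draw (cy, cyplus) multinomially; last weight is the Cy+ class."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate class weights: all zero")
    draws = rng.multinomial(n, w / total)
    return int(draws[:-1].sum()), int(draws[-1])


def simulate_screen(
    params: ScreenSimParams,
    seed: int,
) -> Tuple[List[ProgenyCounts], Dict[str, CrossDesign], pd.DataFrame]:
    """Simulate a full screen: progeny counts, designs, and a truth table.

    Returns ``(records, designs, truth)`` where ``records`` holds one
    screen and one control arm per allele, ``designs`` maps allele id to
    its cross design, and ``truth`` is a DataFrame with columns
    ``allele_id, zygosity, e_ep, gamma, true_label``.
    """
    rng = np.random.default_rng(seed)
    kd = params.base_kd_viability
    n = params.n_progeny_per_arm

    records: List[ProgenyCounts] = []
    designs: Dict[str, CrossDesign] = {}
    truth_rows = []
    width = len(str(params.n_alleles))
    for i in range(params.n_alleles):
        allele_id = f"EP{i + 1:0{width}d}"
        u = rng.uniform()
        if u < params.enhancer_fraction:
            gamma, label = params.enhancer_gamma, "enhancer"
        elif u < params.enhancer_fraction + params.suppressor_fraction:
            gamma, label = params.suppressor_gamma, "suppressor"
        else:
            gamma, label = 1.0, "neutral"
        e = float(rng.lognormal(params.ep_log_mu, params.ep_log_sigma))
        het = rng.uniform() < params.het_fraction
        zyg = FatherZygosity.HETEROZYGOUS if het else FatherZygosity.HOMOZYGOUS
        designs[allele_id] = CrossDesign(zyg)

        if het:
            # surviving classes: driver/EP (Cy+), driver/SM5 (Cy, knocked
            # down in the screen arm), SM5/EP (Cy); SM5/SM5 dies
            control_w = [1.0, 1.0, e]
            screen_w = [kd, 1.0, e * kd * gamma]
        else:
            control_w = [1.0, e]
            screen_w = [1.0, e * kd * gamma]

        cyc, cypc = _arm_counts(rng, control_w, n)
        cys, cyps = _arm_counts(rng, screen_w, n)
        records.append(ProgenyCounts(allele_id, Arm.CONTROL, cyc, cypc))
        records.append(ProgenyCounts(allele_id, Arm.SCREEN, cys, cyps))
        truth_rows.append((allele_id, zyg.value, e, gamma, label))

    truth = pd.DataFrame(
        truth_rows, columns=["allele_id", "zygosity", "e_ep", "gamma", "true_label"]
    )
    return records, designs, truth


@dataclass(frozen=True)
class ExprSimParams:
    """Planted structure for two two-condition expression experiments.

    Set sizes default to the published H1 (factor 1) / CHD1 (factor 2)
    comparison; ``shared_down`` and ``down1_up2`` are chosen so the planted
    'affected' overlap (146 + 116 + 29 = 291) matches the published total.
    """

    n_genes: int = 18833
    n_reps: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    effect_log2: float = 1.5
    noise_sd: float = 0.25
    up1: int = 1354
    down1: int = 820
    up2: int = 596
    down2: int = 416
    shared_up: int = 146
    shared_down: int = 116
    down1_up2: int = 29
    up1_down2: int = 0

    def __post_init__(self) -> None:
        if self.shared_up > min(self.up1, self.up2):
            raise ValueError("shared_up exceeds a planted up set")
        if self.shared_down > min(self.down1, self.down2):
            raise ValueError("shared_down exceeds a planted down set")
        if self.down1_up2 > min(self.down1, self.up2):
            raise ValueError("down1_up2 exceeds a planted set")
        if self.up1_down2 > min(self.up1, self.down2):
            raise ValueError("up1_down2 exceeds a planted set")
        total = (
            self.up1 + self.down1 + self.up2 + self.down2
            - self.shared_up - self.shared_down - self.down1_up2 - self.up1_down2
        )
        if total > self.n_genes:
            raise ValueError("planted sets exceed the gene universe")


def _gene_ids(n: int) -> List[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_expression(
    params: ExprSimParams,
    seed: int,
) -> Tuple[ExpressionMatrix, ExpressionMatrix, Dict[str, GeneSet]]:
    """Two planted expression experiments over one gene universe.

    Returns ``(matrix1, matrix2, truth)`` where truth maps
    ``factor1_up / factor1_down / factor2_up / factor2_down`` to the
    planted :class:`GeneSet` objects (effects are on treated vs control).
    """
    rng = np.random.default_rng(seed)
    p = params
    genes = _gene_ids(p.n_genes)

    # contiguous blocks realise the planted overlap structure exactly
    blocks = {
        "up_shared": p.shared_up,
        "down_shared": p.shared_down,
        "down1_up2": p.down1_up2,
        "up1_down2": p.up1_down2,
        "up1_only": p.up1 - p.shared_up - p.up1_down2,
        "down1_only": p.down1 - p.shared_down - p.down1_up2,
        "up2_only": p.up2 - p.shared_up - p.down1_up2,
        "down2_only": p.down2 - p.shared_down - p.up1_down2,
    }
    idx: Dict[str, np.ndarray] = {}
    start = 0
    for name, size in blocks.items():
        idx[name] = np.arange(start, start + size)
        start += size

    def signs(up_blocks: Tuple[str, ...], down_blocks: Tuple[str, ...]) -> np.ndarray:
        s = np.zeros(p.n_genes)
        for b in up_blocks:
            s[idx[b]] = 1.0
        for b in down_blocks:
            s[idx[b]] = -1.0
        return s

    sign1 = signs(("up_shared", "up1_only", "up1_down2"),
                  ("down_shared", "down1_only", "down1_up2"))
    sign2 = signs(("up_shared", "up2_only", "down1_up2"),
                  ("down_shared", "down2_only", "up1_down2"))

    baseline = rng.normal(p.baseline_mean, p.baseline_sd, size=p.n_genes)

    def build(sign: np.ndarray, tag: str) -> ExpressionMatrix:
        cols, names, cond = [], [], {}
        for condition, shift in (("control", 0.0), ("treated", 1.0)):
            mean = baseline + shift * sign * p.effect_log2
            for r in range(p.n_reps):
                cols.append(mean + rng.normal(0.0, p.noise_sd, size=p.n_genes))
                name = f"{tag}_{condition}_{r + 1}"
                names.append(name)
                cond[name] = condition
        values = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
        return ExpressionMatrix(values, cond)

    m1 = build(sign1, "f1")
    m2 = build(sign2, "f2")

    garr = np.asarray(genes)
    truth = {
        "factor1_up": GeneSet("factor1_up", frozenset(garr[sign1 > 0]), "up"),
        "factor1_down": GeneSet("factor1_down", frozenset(garr[sign1 < 0]), "down"),
        "factor2_up": GeneSet("factor2_up", frozenset(garr[sign2 > 0]), "up"),
        "factor2_down": GeneSet("factor2_down", frozenset(garr[sign2 < 0]), "down"),
    }
    return m1, m2, truth


def simulate_ct(
    fold_changes: Mapping[str, float],
    seed: int,
    reference_gene: str = "rp49",
    n_reps: int = 3,
    sd_tech: float = 0.15,
    base_ct: float = 24.0,
    baseline_log2_expr: float = 8.0,
) -> CtTable:
    """Ct table with known treated/control fold changes per gene.

    ``fold_changes`` maps gene id to its true treated-over-control fold;
    the reference gene is appended with fold 1 if absent. Each replicate's
    Ct is ``base_ct - log2(expression) + Normal(0, sd_tech)``.
    """
    rng = np.random.default_rng(seed)
    folds = dict(fold_changes)
    folds.setdefault(reference_gene, 1.0)
    records = []
    for gene, fold in folds.items():
        if fold <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
        for condition, lf in (("control", 0.0), ("treated", math.log2(fold))):
            true_ct = base_ct - (baseline_log2_expr + lf)
            for r in range(1, n_reps + 1):
                ct = true_ct + (rng.normal(0.0, sd_tech) if sd_tech > 0 else 0.0)
                records.append(CtRecord(gene, condition, r, float(ct)))
    return CtTable(tuple(records))
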