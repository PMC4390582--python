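"""Per-allele interaction statistics for the viability-based modifier screen.

The screen compares, for each mis-expression allele, the relative viability
of doubly perturbed flies (knockdown driver + mis-expression, the *screen*
arm) with mis-expression alone (the *control* arm). The per-allele measure
is the normalized effect

    NE = (screen/control effect ratio) / M,

where M is the median of the same ratio across the whole allele collection,
standing in for a wild-type isogenic control; ``NE < 1`` marks enhancement
of the knockdown lethality, ``NE > 1`` suppression. The ratio is formed on
the Cy+/Cy odds scale by default, where per-class survival effects compose
multiplicatively and the allele's own mis-expression effect cancels
exactly; the plain relative-viability ratio ``(v_screen / v_control) / M``
is available as an alternative scale (see :func:`normalized_effect`).

Significance is gated by two exact tests computed on the raw counts:

* a two-tailed Fisher exact test on a 2x2 table of (Cy+, Cy) counts
  comparing the allele's screen arm against a *representative reference*:
  by default the pooled screen arms of the stratum's typical alleles (those
  with a viability ratio in the interquartile range), or a named single
  allele's screen arm. Comparing each allele's screen arm against its own
  control arm is also available, but that contrast conflates the knockdown
  main effect with the interaction and has no power against suppressors
  that restore viability to control levels.
* an exact test of the allele's own screen-vs-control 2x2 table against
  the independence null. The default is the *conditional* exact test: under
  no interaction the screen/control odds ratio equals the stratum-typical
  knockdown odds ratio ``m``, and conditional on the table margins the
  screen-arm Cy+ count follows Fisher's noncentral hypergeometric
  distribution with parameter ``m``. Because it conditions on both arms,
  this gate holds its nominal type-I rate. The screen's original
  construction — an exact binomial test of the screen-arm Cy+ count against
  a plug-in expectation composed from the observed control arm — is kept as
  an option (:func:`binomial_interaction_test`); treating the estimated
  expectation as known makes it anti-conservative by design.

Both exact tests use the "minlike" two-sided convention (sum of outcome
probabilities not exceeding that of the observed outcome), evaluated in
log-space so that P-values far below double underflow of individual terms
remain exact. An allele is called an enhancer when ``NE < ne_low`` and both
P-values are below alpha, a suppressor when ``NE > ne_high`` likewise;
boundary values are neutral.

Homozygous-father and heterozygous-father crosses are analyzed as separate
strata, each with its own median and reference allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .cross_genetics import (
    Arm,
    CrossDesign,
    FatherZygosity,
    ProgenyCounts,
    ViabilityResult,
    expected_cyplus_fraction,
    relative_viability,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "Thresholds",
    "InteractionResult",
    "CollectionSummary",
    "normalized_effect",
    "collection_median",
    "fisher_exact_2x2",
    "binomial_two_sided",
    "binomial_interaction_test",
    "conditional_interaction_test",
    "chisq_2x2",
    "odds_ratio_2x2",
    "classify",
    "run_screen_analysis",
]

# relative slack when comparing log point-probabilities for tail membership;
# guards against ties broken the wrong way by rounding
_REL_TOL = 1e-7


class Label(str, Enum):
    ENHANCER = "enhancer"
    SUPPRESSOR = "suppressor"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class Thresholds:
    """Hit-calling gate: NE band and shared alpha for both exact tests."""

    ne_low: float = 0.8
    ne_high: float = 1.25
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.ne_low < self.ne_high):
            raise ValueError("require 0 < ne_low < ne_high")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class CollectionSummary:
    """Collection-wide normalization constants for one father-zygosity stratum.

    ``median_ratio`` is M, the median over alleles of the screen/control
    relative-viability ratio (the NE denominator). ``median_odds_ratio`` is
    the same typical knockdown effect measured on the Cy+/Cy odds scale,
    used by the odds-composed binomial expectation; it defaults to
    ``median_ratio`` when not separately computed.
    """

    median_ratio: float
    n_alleles: int
    median_odds_ratio: Optional[float] = None

    @property
    def odds_ratio_norm(self) -> float:
        return self.median_ratio if self.median_odds_ratio is None else self.median_odds_ratio


@dataclass
class InteractionResult:
    """Per-allele screen outcome: NE, odds ratio, exact-test Ps, label.

    ``p_interaction`` holds the independence-gate P — the conditional exact
    test by default, or the plug-in binomial when the pipeline is run with
    ``interaction_test="binomial"`` (``p_binomial`` aliases it either way).
    """

    allele_id: str
    ne: float
    odds_ratio: float
    p_fisher: float
    p_interaction: float
    label: Label
    v_screen: float = field(default=math.nan)
    v_control: float = field(default=math.nan)
    zygosity: Optional[FatherZygosity] = None

    @property
    def p_binomial(self) -> float:
        return self.p_interaction


def collection_median(ratios: Sequence[float]) -> CollectionSummary:
    """Median of viability ratios, ignoring infinities (logged) and NaNs.

    The median over an even number of values averages the central pair.
    Raises ``ValueError`` when no finite ratio is available.
    """
    arr = np.asarray(list(ratios), dtype=float)
    finite = arr[np.isfinite(arr)]
    n_dropped = arr.size - finite.size
    if n_dropped:
        logger.warning("collection_median: dropped %d non-finite ratio(s)", n_dropped)
    if finite.size == 0:
        raise ValueError("collection_median requires at least one finite ratio")
    return CollectionSummary(median_ratio=float(np.median(finite)), n_alleles=int(finite.size))


def normalized_effect(
    screen: ViabilityResult,
    control: ViabilityResult,
    summary: CollectionSummary,
    scale: str = "odds",
) -> float:
    """Normalized effect of an allele: its screen/control ratio over the
    collection median of such ratios.

    ``scale="odds"`` (default) forms the ratio on the Cy+/Cy odds scale,
    where per-class survival effects compose multiplicatively, so the
    allele's own mis-expression effect cancels exactly and NE estimates
    the interaction multiplier without bias. ``scale="viability"`` forms
    it on relative viabilities, ``NE = (v_screen / v_control) / M`` — the
    direct reading of "viability normalized to viability", but biased
    away from 1 for alleles whose mis-expression alone shifts viability
    far from typical, because Cy+ *fractions* saturate. The two scales
    agree on every sentinel: NE is ``inf`` when the control arm produced
    no Cy+ survivors but the screen arm did, ``0.0`` in the opposite
    case, and ``nan`` (with a warning) when both arms are extinct.
    """
    if scale not in ("odds", "viability"):
        raise ValueError(f"unknown NE scale {scale!r}")
    vs, vc = screen.relative_viability, control.relative_viability
    if vc == 0.0:
        if vs == 0.0:
            logger.warning("normalized_effect: both viabilities zero; NE undefined")
            return math.nan
        return math.inf
    if vs == 0.0:
        return 0.0
    if scale == "viability":
        return (vs / vc) / summary.median_ratio
    os_ = screen.observed_fraction / (1.0 - screen.observed_fraction) \
        if screen.observed_fraction < 1.0 else math.inf
    oc = control.observed_fraction / (1.0 - control.observed_fraction) \
        if control.observed_fraction < 1.0 else math.inf
    if math.isinf(oc):
        return math.inf if not math.isinf(os_) else math.nan
    if math.isinf(os_):
        return math.inf
    return (os_ / oc) / summary.odds_ratio_norm


def _log_hypergeom_pmf(k: np.ndarray, total: int, ngood: int, ndraw: int) -> np.ndarray:
    """log P[X = k] for a hypergeometric(total, ngood, ndraw) variable."""
    k = np.asarray(k)
    return (
        gammaln(ngood + 1)
        - gammaln(k + 1)
        - gammaln(ngood - k + 1)
        + gammaln(total - ngood + 1)
        - gammaln(ndraw - k + 1)
        - gammaln(total - ngood - ndraw + k + 1)
        - (gammaln(total + 1) - gammaln(ndraw + 1) - gammaln(total - ndraw + 1))
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact P for the table ``[[a, b], [c, d]]``.

    Conditions on all margins and sums the hypergeometric point
    probabilities of every table whose probability does not exceed that of
    the observed table (the minlike convention). Computed from log
    combinatorics; no normal approximation. A table with an empty row or
    column carries no information: P = 1 with a warning.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("fisher_exact_2x2 requires non-negative integers")
    r1, c1, total = a + b, a + c, a + b + c + d
    if r1 == 0 or r1 == total or c1 == 0 or c1 == total:
        logger.warning("fisher_exact_2x2: degenerate margin, returning P=1")
        return 1.0
    kmin = max(0, c1 - (total - r1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    logpmf = _log_hypergeom_pmf(ks, total, r1, c1)
    obs = logpmf[a - kmin]
    tail = logpmf[logpmf <= obs + _REL_TOL]
    return float(min(1.0, math.exp(logsumexp(tail))))


def binomial_two_sided(x: int, n: int, p: float) -> float:
    """Exact two-sided binomial P (minlike convention) for x out of n at p.

    Sums Binomial(n, p) point probabilities over all outcomes whose
    probability does not exceed that of the observed count.
    """
    if not (0 <= x <= n):
        raise ValueError("require 0 <= x <= n")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    ks = np.arange(n + 1)
    with np.errstate(divide="ignore"):
        logpmf = (
            gammaln(n + 1)
            - gammaln(ks + 1)
            - gammaln(n - ks + 1)
            + ks * math.log(p)
            + (n - ks) * math.log1p(-p)
        )
    obs = logpmf[x]
    tail = logpmf[logpmf <= obs + _REL_TOL]
    return float(min(1.0, math.exp(logsumexp(tail))))


def binomial_interaction_test(
    counts: ProgenyCounts,
    design: CrossDesign,
    control_v: float,
    summary: CollectionSummary,
    method: str = "odds",
    eps: float = 1e-9,
) -> float:
    """Exact binomial test of a screen arm against the independence model.

    The null hypothesis is that knockdown and mis-expression act
    independently on viability. With ``method="odds"`` (default) the
    expected Cy+ probability composes the control-arm Cy+/Cy odds with the
    stratum's typical knockdown odds ratio — per-class survival effects
    multiply on the odds scale, so this expectation is unbiased however
    strongly the mis-expression alone shifts viability. With
    ``method="fraction"`` it is the naive product
    ``expected_fraction * v_control * median_ratio`` on the fraction scale.
    Either expectation is clamped into ``(eps, 1 - eps)`` with a warning
    when clamping bites.
    """
    if counts.total < 1:
        raise ValueError("binomial_interaction_test requires scored adults")
    if method not in ("odds", "fraction"):
        raise ValueError(f"unknown method {method!r}")
    frac = float(expected_cyplus_fraction(design))
    if method == "fraction":
        p_exp = frac * control_v * summary.median_ratio
    else:
        frac_c = frac * control_v
        frac_c = min(max(frac_c, eps), 1.0 - eps)
        expected_odds = (frac_c / (1.0 - frac_c)) * summary.odds_ratio_norm
        p_exp = expected_odds / (1.0 + expected_odds)
    if not (eps <= p_exp <= 1.0 - eps):
        logger.warning(
            "binomial_interaction_test: expected probability %.3g clamped for %r",
            p_exp,
            counts.allele_id,
        )
        p_exp = min(max(p_exp, eps), 1.0 - eps)
    return binomial_two_sided(counts.cyplus_count, counts.total, p_exp)


def conditional_interaction_test(
    a: int, b: int, c: int, d: int, null_odds_ratio: float
) -> float:
    """Exact conditional test of a 2x2 table against H0: odds ratio = m.

    Rows are (screen Cy+, screen Cy) and (control Cy+, control Cy); under
    no interaction the screen/control odds ratio equals the typical
    knockdown effect ``m = null_odds_ratio``. Conditioning on all margins,
    the top-left count follows Fisher's noncentral hypergeometric
    distribution with odds parameter m; the two-sided P sums the point
    probabilities not exceeding that of the observed table (minlike),
    evaluated in log-space. ``m = 1`` reduces to the ordinary Fisher test.
    Degenerate margins carry no information: P = 1 with a warning.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("conditional_interaction_test requires non-negative integers")
    if not (null_odds_ratio > 0 and math.isfinite(null_odds_ratio)):
        raise ValueError("null odds ratio must be finite and positive")
    r1, c1, total = a + b, a + c, a + b + c + d
    if r1 == 0 or r1 == total or c1 == 0 or c1 == total:
        logger.warning("conditional_interaction_test: degenerate margin, P=1")
        return 1.0
    kmin = max(0, c1 - (total - r1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    # log of C(r1, k) * C(total - r1, c1 - k) * m^k, normalized over support
    logw = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(total - r1 + 1) - gammaln(c1 - ks + 1)
        - gammaln(total - r1 - c1 + ks + 1)
        + ks * math.log(null_odds_ratio)
    )
    logpmf = logw - logsumexp(logw)
    obs = logpmf[a - kmin]
    tail = logpmf[logpmf <= obs + _REL_TOL]
    return float(min(1.0, math.exp(logsumexp(tail))))


def chisq_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on [[a,b],[c,d]].

    Returns ``(statistic, p_value)`` with P from the upper chi-square tail.
    Raises on a zero margin, where expected counts vanish.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("chisq_2x2 requires non-negative counts")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chisq_2x2: zero margin, expected counts undefined")
    total = r1 + r2
    stat = total * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c) with 0/inf/nan conventions at zeros."""
    num, den = a * d, b * c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def classify(
    ne: float,
    p_fisher: float,
    p_binomial: float,
    thresholds: Thresholds = Thresholds(),
) -> Label:
    """Hit label from NE and the two exact-test P-values.

    Strict inequalities throughout: NE exactly at a band edge or P exactly
    at alpha is neutral. ``NE = inf`` is a suppressor when both tests pass;
    ``NE = nan`` (both arms extinct) is always neutral.
    """
    if math.isnan(ne):
        return Label.NEUTRAL
    significant = p_fisher < thresholds.alpha and p_binomial < thresholds.alpha
    if not significant:
        return Label.NEUTRAL
    if ne < thresholds.ne_low:
        return Label.ENHANCER
    if ne > thresholds.ne_high:
        return Label.SUPPRESSOR
    return Label.NEUTRAL


def _pair_arms(
    records: Iterable[ProgenyCounts],
) -> Dict[str, Dict[Arm, ProgenyCounts]]:
    paired: Dict[str, Dict[Arm, ProgenyCounts]] = {}
    for rec in records:
        paired.setdefault(rec.allele_id, {})[rec.arm] = rec
    return paired


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values. Off the default hit-calling path (the
    original screen applies no multiplicity correction across alleles);
    provided for analyses that want it."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(list(pvalues), dtype=float), method="fdr_bh")[1]


__all__.append("adjust_bh")


def _reference_arm(
    ratios: Mapping[str, float],
    screens: Mapping[str, ProgenyCounts],
) -> Tuple[int, int]:
    """Pooled representative reference (cyplus, cy) for the Fisher contrast.

    The reference stands in for the typical doubly perturbed cross of the
    stratum. Alleles whose viability ratio lies in the interquartile range
    (screening out likely modifiers at either tail) contribute their screen
    arms, which are pooled into one (Cy+, Cy) pair.
    """
    if not ratios:
        raise ValueError("no finite viability ratios to build a reference from")
    vals = np.fromiter(ratios.values(), dtype=float)
    q1, q3 = np.percentile(vals, [25, 75])
    candidates = [a for a, r in ratios.items() if q1 <= r <= q3] or list(ratios)
    cyplus = sum(screens[a].cyplus_count for a in candidates)
    cy = sum(screens[a].cy_count for a in candidates)
    return cyplus, cy


def run_screen_analysis(
    records: Iterable[ProgenyCounts],
    designs: Mapping[str, CrossDesign],
    thresholds: Thresholds = Thresholds(),
    fisher_mode: str = "reference",
    reference_allele: Optional[str] = None,
    ne_scale: str = "odds",
    interaction_test: str = "conditional",
) -> List[InteractionResult]:
    """Full screen pipeline: viabilities, stratum medians, NE, tests, labels.

    Parameters
    ----------
    records
        Progeny counts, one screen and one control arm per allele. Alleles
        missing either arm are skipped with a logged warning.
    designs
        Cross design per allele (defines the Mendelian expected fraction).
    fisher_mode
        ``"reference"`` (default): Fisher table compares the allele's screen
        arm against a representative reference screen arm — the pooled
        screen arms of the stratum's interquartile-ratio alleles, or the
        single allele named by ``reference_allele``. ``"control"``: compare
        the allele's screen arm against its own control arm (tests the
        knockdown main effect as well as the interaction).
    ne_scale
        ``"odds"`` (default) or ``"viability"``; see :func:`normalized_effect`.
    interaction_test
        ``"conditional"`` (default, calibrated) or ``"binomial"`` (the
        plug-in construction); see the module docstring.

    Returns results sorted by allele id. Homozygous- and heterozygous-father
    alleles are normalized and referenced within their own strata.
    """
    if fisher_mode not in ("reference", "control"):
        raise ValueError(f"unknown fisher_mode: {fisher_mode!r}")
    if interaction_test not in ("conditional", "binomial"):
        raise ValueError(f"unknown interaction_test: {interaction_test!r}")

    paired = _pair_arms(records)
    # per-allele viabilities, grouped into father-zygosity strata
    strata: Dict[FatherZygosity, List[str]] = {}
    viab: Dict[str, Tuple[ProgenyCounts, ProgenyCounts, float, float]] = {}
    for allele_id in sorted(paired):
        arms = paired[allele_id]
        if Arm.SCREEN not in arms or Arm.CONTROL not in arms:
            logger.warning("allele %r lacks a %s arm; skipped", allele_id,
                           "control" if Arm.SCREEN in arms else "screen")
            continue
        design = designs[allele_id]
        vs = relative_viability(arms[Arm.SCREEN], design).relative_viability
        vc = relative_viability(arms[Arm.CONTROL], design).relative_viability
        viab[allele_id] = (arms[Arm.SCREEN], arms[Arm.CONTROL], vs, vc)
        strata.setdefault(design.father_zygosity, []).append(allele_id)

    results: List[InteractionResult] = []
    for zygosity, allele_ids in strata.items():
        ratios = {}
        odds_ratios = []
        for aid in allele_ids:
            screen, control, vs, vc = viab[aid]
            ratios[aid] = vs / vc if vc > 0 else (math.inf if vs > 0 else math.nan)
            odds_ratios.append(
                odds_ratio_2x2(screen.cyplus_count, screen.cy_count,
                               control.cyplus_count, control.cy_count)
            )
        base = collection_median(list(ratios.values()))
        summary = CollectionSummary(
            median_ratio=base.median_ratio,
            n_alleles=base.n_alleles,
            median_odds_ratio=collection_median(odds_ratios).median_ratio,
        )

        if fisher_mode == "reference":
            if reference_allele is not None:
                if reference_allele not in viab:
                    raise KeyError(f"reference allele {reference_allele!r} not in data")
                ref = viab[reference_allele][0]
                ref_arm = (ref.cyplus_count, ref.cy_count)
            else:
                ref_arm = _reference_arm(
                    {a: r for a, r in ratios.items() if math.isfinite(r)},
                    {a: viab[a][0] for a in allele_ids},
                )
            logger.info(
                "stratum %s: median ratio %.4g (odds scale %.4g) over %d alleles, "
                "reference arm %d Cy+ / %d Cy",
                zygosity.value, summary.median_ratio, summary.median_odds_ratio,
                summary.n_alleles, ref_arm[0], ref_arm[1],
            )

        for aid in allele_ids:
            screen, control, vs, vc = viab[aid]
            design = designs[aid]
            ne = normalized_effect(
                relative_viability(screen, design),
                relative_viability(control, design),
                summary,
                scale=ne_scale,
            )
            if fisher_mode == "reference":
                other = ref_arm
            else:
                other = (control.cyplus_count, control.cy_count)
            table = (
                screen.cyplus_count,
                screen.cy_count,
                other[0],
                other[1],
            )
            p_f = fisher_exact_2x2(*table)
            if interaction_test == "conditional":
                p_b = conditional_interaction_test(
                    screen.cyplus_count, screen.cy_count,
                    control.cyplus_count, control.cy_count,
                    summary.odds_ratio_norm,
                )
            else:
                p_b = binomial_interaction_test(screen, design, vc, summary)
            results.append(
                InteractionResult(
                    allele_id=aid,
                    ne=ne,
                    # the allele's own screen-vs-control odds ratio (tracks NE)
                    odds_ratio=odds_ratio_2x2(
                        screen.cyplus_count, screen.cy_count,
                        control.cyplus_count, control.cy_count,
                    ),
                    p_fisher=p_f,
                    p_interaction=p_b,
                    label=classify(ne, p_f, p_b, thresholds),
                    v_screen=vs,
                    v_control=vc,
                    zygosity=zygosity,
                )
            )
    results.sort(key=lambda r: r.allele_id)
    return results
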