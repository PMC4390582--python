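"""Exact tests, NE, classification and the full screen pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from modscreen.cross_genetics import (
    Arm,
    CrossDesign,
    FatherZygosity,
    ProgenyCounts,
    ViabilityResult,
)
from modscreen.screen_stats import (
    CollectionSummary,
    Label,
    Thresholds,
    binomial_interaction_test,
    binomial_two_sided,
    chisq_2x2,
    classify,
    collection_median,
    conditional_interaction_test,
    fisher_exact_2x2,
    normalized_effect,
    odds_ratio_2x2,
    run_screen_analysis,
)

HOM = CrossDesign(FatherZygosity.HOMOZYGOUS)


def vr(observed, expected=0.5):
    return ViabilityResult(observed, expected, observed / expected)


# ---------------------------------------------------------------- Fisher


@pytest.mark.parametrize(
    "table, expected",
    [
        # an extinct screen arm against its mild control
        ((135, 0, 70, 4), 0.0148969801),
        ((5, 5, 5, 5), 1.0),
        ((10, 0, 0, 10), 2 / math.comb(20, 10)),
    ],
)
def test_fisher_known_values(table, expected):
    assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-6)


@given(
    a=st.integers(0, 40), b=st.integers(0, 40),
    c=st.integers(0, 40), d=st.integers(0, 40),
)
def test_fisher_matches_scipy(a, b, c, d):
    """Independent-library route: scipy's two-sided Fisher uses the same
    minlike convention."""
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        assert fisher_exact_2x2(a, b, c, d) == 1.0
    else:
        expected = stats.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(expected, rel=1e-9)


def test_fisher_rejects_negative():
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------- binomial


@pytest.mark.parametrize(
    "x, n, p, expected",
    [
        (5, 10, 0.5, 1.0),
        (0, 10, 0.5, 2 / 1024),
        (10, 10, 0.5, 2 / 1024),
    ],
)
def test_binomial_two_sided_known_values(x, n, p, expected):
    assert binomial_two_sided(x, n, p) == pytest.approx(expected, rel=1e-12)


def test_binomial_two_sided_brute_force_example():
    # sum of the 21 outcome pmfs with probability <= pmf(2)
    pmf = stats.binom.pmf(np.arange(21), 20, 0.3)
    expected = pmf[pmf <= pmf[2] * (1 + 1e-12)].sum()
    assert binomial_two_sided(2, 20, 0.3) == pytest.approx(expected, rel=1e-10)


@given(
    n=st.integers(1, 200),
    x=st.integers(0, 200),
    p=st.floats(0.01, 0.99),
)
def test_binomial_matches_scipy_binomtest(n, x, p):
    if x > n:
        return
    expected = stats.binomtest(x, n, p).pvalue
    assert binomial_two_sided(x, n, p) == pytest.approx(expected, rel=1e-9)


def test_binomial_interaction_expectation_composition():
    """fraction method: p_exp = f * v_control * M; odds method composes the
    control odds with the stratum odds ratio."""
    counts = ProgenyCounts("a", Arm.SCREEN, 100, 50)
    summary = CollectionSummary(median_ratio=0.5, n_alleles=10, median_odds_ratio=0.5)
    p_frac = binomial_interaction_test(counts, HOM, 1.0, summary, method="fraction")
    assert p_frac == pytest.approx(binomial_two_sided(50, 150, 0.25), rel=1e-12)
    # control_v = 1 -> control fraction 0.5, odds 1; expected odds 0.5 -> p 1/3
    p_odds = binomial_interaction_test(counts, HOM, 1.0, summary, method="odds")
    assert p_odds == pytest.approx(binomial_two_sided(50, 150, 1 / 3), rel=1e-12)


def test_binomial_interaction_clamps_degenerate_expectation(caplog):
    counts = ProgenyCounts("a", Arm.SCREEN, 100, 5)
    summary = CollectionSummary(median_ratio=0.5, n_alleles=10)
    p = binomial_interaction_test(counts, HOM, 0.0, summary, method="fraction")
    assert 0 <= p <= 1


# ------------------------------------------------- conditional interaction


def test_conditional_reduces_to_fisher_at_unit_odds():
    for table in [(12, 8, 7, 13), (40, 2, 35, 9), (0, 10, 5, 5)]:
        assert conditional_interaction_test(*table, 1.0) == pytest.approx(
            fisher_exact_2x2(*table), rel=1e-9
        )


@given(
    a=st.integers(0, 30), b=st.integers(0, 30),
    c=st.integers(0, 30), d=st.integers(0, 30),
    m=st.floats(0.1, 10.0),
)
def test_conditional_matches_scipy_noncentral(a, b, c, d, m):
    """Oracle: Fisher noncentral hypergeometric pmf from scipy."""
    r1, c1, total = a + b, a + c, a + b + c + d
    if r1 in (0, total) or c1 in (0, total):
        assert conditional_interaction_test(a, b, c, d, m) == 1.0
        return
    kmin = max(0, c1 - (total - r1))
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.nchypergeom_fisher.pmf(ks, total, c1, r1, m)
    obs = pmf[a - kmin]
    expected = pmf[pmf <= obs * (1 + 1e-7)].sum()
    assert conditional_interaction_test(a, b, c, d, m) == pytest.approx(
        min(1.0, expected), rel=1e-6, abs=1e-12
    )


def test_conditional_requires_positive_finite_odds():
    with pytest.raises(ValueError):
        conditional_interaction_test(1, 2, 3, 4, 0.0)
    with pytest.raises(ValueError):
        conditional_interaction_test(1, 2, 3, 4, math.inf)


# ---------------------------------------------------------------- chi-square


@pytest.mark.parametrize(
    "table, chi2, p",
    [
        ((40, 115, 91, 102), 16.683, 4.4e-5),
        ((1, 82, 17, 146), 6.901, 0.0086),
    ],
)
def test_chisq_reproduces_printed_viability_pvalues(table, chi2, p):
    stat, pval = chisq_2x2(*table)
    assert stat == pytest.approx(chi2, rel=1e-3)
    assert pval == pytest.approx(p, rel=0.02)


def test_chisq_uniform_table_is_null():
    stat, p = chisq_2x2(7, 7, 7, 7)
    assert stat == 0 and p == 1.0


def test_chisq_zero_margin_errors():
    with pytest.raises(ValueError):
        chisq_2x2(0, 0, 5, 5)


@given(
    a=st.integers(1, 50), b=st.integers(1, 50),
    c=st.integers(1, 50), d=st.integers(1, 50),
)
def test_chisq_invariant_under_transposition_and_swaps(a, b, c, d):
    base = chisq_2x2(a, b, c, d)[0]
    assert chisq_2x2(a, c, b, d)[0] == pytest.approx(base)  # transpose
    assert chisq_2x2(c, d, a, b)[0] == pytest.approx(base)  # row swap
    assert chisq_2x2(b, a, d, c)[0] == pytest.approx(base)  # column swap


# ---------------------------------------------------------------- NE / median


def test_collection_median_basic_and_even():
    assert collection_median([0.2, 0.5, 0.9]).median_ratio == pytest.approx(0.5)
    assert collection_median([0.2, 0.4, 0.6, 0.8]).median_ratio == pytest.approx(0.5)


def test_collection_median_drops_infinities_and_errors_when_empty():
    s = collection_median([0.5, math.inf, 1.5])
    assert s.median_ratio == pytest.approx(1.0)
    assert s.n_alleles == 2
    with pytest.raises(ValueError):
        collection_median([math.inf, math.nan])


def test_normalized_effect_sentinels():
    summary = CollectionSummary(1.0, 5, 1.0)
    for scale in ("odds", "viability"):
        assert normalized_effect(vr(0.0), vr(0.4), summary, scale=scale) == 0.0
        assert math.isinf(normalized_effect(vr(0.4), vr(0.0), summary, scale=scale))
        assert math.isnan(normalized_effect(vr(0.0), vr(0.0), summary, scale=scale))


def test_normalized_effect_identity():
    summary = CollectionSummary(1.0, 5, 1.0)
    for scale in ("odds", "viability"):
        assert normalized_effect(vr(0.3), vr(0.3), summary, scale=scale) == pytest.approx(1.0)


@given(
    fs=st.floats(0.02, 0.95), fc=st.floats(0.02, 0.95),
    c=st.floats(0.1, 5.0), m=st.floats(0.2, 3.0),
)
def test_normalized_effect_equivariance(fs, fc, c, m):
    """Scaling every screen-side ratio by c scales the median by c too, so
    NE is invariant -- on either scale."""
    s_v = CollectionSummary(m, 9, m)
    s_scaled = CollectionSummary(m * c, 9, m * c)
    nv = normalized_effect(vr(fs), vr(fc), s_v, scale="viability")
    # viability scale: multiply v_screen by c
    scaled = ViabilityResult(fs, 0.5, (fs / 0.5) * c)
    nv2 = normalized_effect(scaled, vr(fc), s_scaled, scale="viability")
    assert nv2 == pytest.approx(nv, rel=1e-9)
    # odds scale: multiply the screen odds by c
    no = normalized_effect(vr(fs), vr(fc), s_v, scale="odds")
    os_ = fs / (1 - fs) * c
    fs2 = os_ / (1 + os_)
    no2 = normalized_effect(vr(fs2), vr(fc), s_scaled, scale="odds")
    assert no2 == pytest.approx(no, rel=1e-9)


# ---------------------------------------------------------------- classify


@pytest.mark.parametrize(
    "ne, pf, pb, expected",
    [
        (0.24, 4.1e-3, 1.5e-6, Label.ENHANCER),
        (2.15, 1.3e-5, 1.7e-6, Label.SUPPRESSOR),
        (1.0, 1e-9, 1e-9, Label.NEUTRAL),
        (0.8, 1e-9, 1e-9, Label.NEUTRAL),     # band edges are neutral
        (1.25, 1e-9, 1e-9, Label.NEUTRAL),
        (0.2, 0.01, 1e-9, Label.NEUTRAL),     # P exactly at alpha is neutral
        (0.2, 1e-9, 0.05, Label.NEUTRAL),
        (math.inf, 1e-9, 1e-9, Label.SUPPRESSOR),
        (math.nan, 1e-9, 1e-9, Label.NEUTRAL),
        (0.0, 1e-9, 1e-9, Label.ENHANCER),
    ],
)
def test_classify_gate(ne, pf, pb, expected):
    assert classify(ne, pf, pb) is expected


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(ne_low=1.3, ne_high=1.25)
    with pytest.raises(ValueError):
        Thresholds(alpha=0.0)


# ---------------------------------------------------------------- odds ratio


def test_odds_ratio_conventions():
    assert odds_ratio_2x2(2, 4, 1, 4) == pytest.approx(2.0)
    assert math.isinf(odds_ratio_2x2(1, 0, 1, 1))
    assert odds_ratio_2x2(0, 1, 1, 1) == 0.0
    assert math.isnan(odds_ratio_2x2(0, 1, 0, 1))


# ---------------------------------------------------------------- pipeline


def _mk(aid, scy, scyp, ccy, ccyp):
    return [
        ProgenyCounts(aid, Arm.SCREEN, scy, scyp),
        ProgenyCounts(aid, Arm.CONTROL, ccy, ccyp),
    ]


def test_single_allele_has_unit_ne_and_is_neutral():
    records = _mk("only", 100, 50, 75, 75)
    res = run_screen_analysis(records, {"only": HOM})
    assert len(res) == 1
    assert res[0].ne == pytest.approx(1.0)
    assert res[0].label is Label.NEUTRAL


def test_missing_control_arm_is_skipped(caplog):
    import logging

    caplog.set_level(logging.WARNING, logger="modscreen.screen_stats")
    records = _mk("ok", 100, 50, 75, 75) + [
        ProgenyCounts("orphan", Arm.SCREEN, 10, 10)
    ]
    res = run_screen_analysis(records, {"ok": HOM, "orphan": HOM})
    assert [r.allele_id for r in res] == ["ok"]
    assert any("orphan" in m for m in caplog.messages)


def test_pipeline_sentinel_alleles(table2_records):
    """An allele with an extinct screen arm gets NE=0; one with an extinct
    control arm gets NE=INF (and can only be a suppressor)."""
    records, designs = table2_records
    res = {r.allele_id: r for r in run_screen_analysis(records, designs)}
    assert res["EP2543-Dap160"].ne == 0.0
    assert math.isinf(res["EP578-Traf4"].ne)


def test_pipeline_deterministic_and_sorted(table2_records):
    records, designs = table2_records
    r1 = run_screen_analysis(records, designs)
    r2 = run_screen_analysis(list(reversed(records)), designs)
    assert [x.allele_id for x in r1] == sorted(designs)
    assert [(x.allele_id, x.ne, x.p_fisher, x.p_interaction) for x in r1] == [
        (x.allele_id, x.ne, x.p_fisher, x.p_interaction) for x in r2
    ]


def test_pipeline_strata_are_independent(table2_records):
    """Dropping every heterozygous-father allele must not change any
    homozygous-stratum statistic (separate medians and references)."""
    records, designs = table2_records
    full = {r.allele_id: r for r in run_screen_analysis(records, designs)}
    hom_ids = {a for a, d in designs.items()
               if d.father_zygosity is FatherZygosity.HOMOZYGOUS}
    sub_records = [r for r in records if r.allele_id in hom_ids]
    sub = {r.allele_id: r for r in run_screen_analysis(
        sub_records, {a: designs[a] for a in hom_ids})}
    for aid in hom_ids:
        assert sub[aid].ne == pytest.approx(full[aid].ne, nan_ok=True)
        assert sub[aid].p_fisher == pytest.approx(full[aid].p_fisher)


def test_reference_allele_override(table2_records):
    records, designs = table2_records
    res = run_screen_analysis(records, designs, reference_allele="G2213")
    assert len(res) == len(designs)
    with pytest.raises(KeyError):
        run_screen_analysis(records, designs, reference_allele="nope")


def test_fisher_control_mode_tests_own_arms():
    records = _mk("a", 100, 50, 75, 75) + _mk("b", 90, 60, 80, 70)
    res = {r.allele_id: r for r in run_screen_analysis(
        records, {"a": HOM, "b": HOM}, fisher_mode="control")}
    assert res["a"].p_fisher == pytest.approx(fisher_exact_2x2(50, 100, 75, 75))
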