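# Methods

## The screen model

A balancer cross yields discrete offspring classes in equal Mendelian
proportions among surviving zygotes; each class then survives to adulthood
with some class-specific probability. We treat observed adult counts as a
multinomial draw over classes with probabilities proportional to
per-class *eclosion weights*. In the screen cross the non-balancer (Cy⁺)
class carries driver + H1-knockdown hairpin + mis-expression insertion, so
its weight is the product `e · kd · γ`, where

* `e` — the viability effect of ubiquitous mis-expression alone
  (measured by the allele's control arm, driver without the hairpin),
* `kd` — the knockdown-alone viability at the screen temperature
  (≈ 0.5 of Mendelian expectation),
* `γ` — the interaction multiplier, the screen's estimand: γ = 1 under
  independent action, γ < 1 for enhancers, γ > 1 for suppressors.

Balancer-carrying classes have weight 1, except in balanced-father screen
crosses, where the class inheriting the driver chromosome is itself
knocked down (weight `kd`); this reproduces the escaper excess seen in
balanced-father data and is why homozygous- and heterozygous-father
alleles are analyzed as separate strata throughout (own median, own
reference).

### Relative viability

`relative_viability` is the observed Cy⁺ *fraction of all scored adults*
divided by the Mendelian expected fraction. This fraction-of-total
definition is what the screen's printed "percent of expected" values use,
and the package reproduces all sixteen printed percentages from the raw
counts. It is the right summary for a single cross.

### Normalized effect and its scale

NE is a ratio of the allele's screen-arm effect to its control-arm effect,
normalized by the collection median of such ratios. Two scales are
implemented:

* **odds scale (default).** Under the multinomial model above, class
  weights enter observable *odds* multiplicatively:
  `odds(Cy⁺)_screen / odds(Cy⁺)_control = kd·γ` for homozygous-father
  crosses (a design-dependent constant times γ in general). Dividing by
  the stratum median of the same odds ratio cancels the constant, so NE
  estimates γ directly, with no dependence on `e`.
* **viability scale.** `NE = (v_screen/v_control)/M` on relative
  viabilities. Fractions saturate (a class twice as viable does not
  produce twice the fraction once it dominates the brood), so this ratio
  is biased away from 1 — by roughly ±10–12% for null alleles whose `e`
  sits two standard deviations from typical under the default generator.
  It is retained (`ne_scale="viability"`) because it is the most literal
  reading of "viability normalized to viability", and because the two
  scales agree exactly on the sentinel cases (0, ∞, NaN, and 1 for a
  single-allele collection).

Both scales leave the published hit table's interpretation unchanged: the
printed NE column of the 61-allele fixture cannot be reproduced under any
single global normalization we tested (on either scale), so printed NEs
are treated as classification inputs, never as regression targets.

## Significance gating

A hit must clear an NE band (default < 0.8 or > 1.25) **and** two exact
tests at α = 0.01 each. Strict inequalities everywhere: values exactly at
a boundary are neutral.

**Fisher gate.** A 2×2 Fisher exact test of the allele's screen arm
(Cy⁺, Cy) against a *representative reference* arm. The default reference
pools the screen arms of all alleles whose viability ratio falls in the
stratum's interquartile range — a "typical doubly perturbed cross" with
small sampling error. A single-allele reference (`reference_allele=`) is
supported but measured ~0.55 power against two-fold suppressors at these
brood sizes, because one ~150-adult arm is too noisy a yardstick.
Comparing each allele's screen arm to its own control arm
(`fisher_mode="control"`) is also available but conflates the knockdown
main effect with the interaction: it has essentially no power against a
suppressor whose γ cancels `kd`, and under the null it detects the
knockdown itself.

**Interaction gate.** The exact conditional test of the allele's own 2×2
(screen vs control) against H₀: odds ratio = m, where m is the stratum
median of per-allele screen/control odds ratios. Conditional on the table
margins the screen-arm Cy⁺ count follows Fisher's noncentral
hypergeometric distribution with parameter m; we sum point probabilities
≤ the observed one (minlike convention) in log-space. Because it
conditions on both arms, the gate holds its nominal level: measured null
rejection ≈ 0.004–0.011 at α = 0.01 under the default generator.

The screen's original construction — an exact binomial test of the
screen-arm Cy⁺ count against a plug-in expectation composed from the
observed control arm and the collection median — is implemented as
`binomial_interaction_test` (expectation composed on the odds scale by
default, or the naive fraction product `f·v_control·M`) and selectable in
the pipeline via `interaction_test="binomial"`. Treating the estimated
expectation as known makes it anti-conservative: the control arm
contributes sampling noise comparable to the screen arm's, and we measure
a null rejection rate of ≈ 0.06 at nominal 0.01. It buys extra power at
a type-I cost; the calibrated conditional test is the default.

**Two-sided convention.** All exact tests (Fisher, binomial, conditional)
use the minlike convention — sum of outcome probabilities not exceeding
the observed outcome's, with a 1e-7 relative slack when comparing log
point-probabilities so ties are never dropped by rounding. Doubling the
smaller tail gives different values and is not used.

**Chi-square.** The targeted-cross comparisons use the Pearson 2×2
chi-square, df = 1, *without* Yates continuity correction; with the
correction the printed P-values (4.4·10⁻⁵, 0.0086) are not reproduced.

## Differential expression and enrichment

`call_de` runs a per-gene two-sample *t*-test on log2 values (Welch by
default; pooled for fidelity experiments, since the original analysis
names only "t-test") and thresholds the difference of group means
(|log2fc| ≥ log2(fc), inclusive). Default fc = 2.0 and raw P < 0.05, no
multiple-testing correction — matching the thresholds under which the
published overlap sets were built; BH q-values are available in the
enrichment layer. Genes with zero variance in both groups are called flat
(equal means) or get P = 0 (unequal means) with a warning.

Overlap and annotation enrichment use fold = (x/n)/(K/N) and the exact
hypergeometric upper tail, with log-pmf values normalized over the support
(the accumulated lgamma rounding error cancels, and point masses sum to 1
to machine precision). One-tailed over-representation only, as in the
original analyses; the EASE variant substitutes x−1 for x. The default
universe for the packaged fixtures is the 18,833 arrayed transcripts;
enrichment is universe-sensitive, so it is always a parameter. DAVID-style
term catalogs are user-supplied GMTs; no GO DAG propagation or fuzzy
clustering is attempted, which is why the published DAVID table P-values
(unknown universe) are fixtures, not targets.

## qPCR

Classic ΔΔCt with amplification efficiency fixed at 2 (no standard-curve
correction): ΔCt pairs gene and reference within a replicate; fold =
2^(−ΔΔCt). The spread is the root-sum-square of the two conditions'
replicate ΔCt standard deviations, reported on the linear fold scale via
the delta method (fold·ln2·sd). Whether the original figures' error bars
are this quantity or per-replicate fold SDs is not stated in the source;
we document our choice rather than assert theirs.

## Synthetic data: what it emulates, what it does not

`simulate_screen` defaults are the study conditions: 534 alleles (110
with balanced fathers), 150 scored adults per arm, `kd = 0.5`,
`e ~ logNormal(ln 0.94, 0.3)` (control crosses averaged ~94% of expected,
with lethal-to-beneficial spread), planted γ = 0.25 enhancers (8%) and
γ = 2 suppressors (4%), giving ~43/~21 planted modifiers per screen —
the same order as the published 41/20. Counts are multinomial conditioned
on the brood size, since broods of fixed minimum size were scored.
Measured at defaults over replicate screens: sensitivity ≈ 0.83–0.86,
empirical FDR ≤ 0.05, null-screen hit rate ≤ 0.01. Not modelled:
temperature dependence of GAL4 activity (one scalar `kd` per run),
egg-laying dynamics, two-vial scoring, or real alleles' γ heterogeneity
within a class — so passing recovery tests demonstrates the statistics,
not fly husbandry.

`simulate_expression` plants contiguous directional gene blocks (sizes
mirroring the published Venn: 1354/820 vs 596/416, 146 shared up; the
unprinted shared-down and cross cells chosen as 116 and 29 so the
affected-overlap total matches the printed 291) on a Normal(8, 1.5) log2
baseline with effect 1.5 log2 units and replicate noise sd 0.25 in
triplicate. Effects are clean shifts — no probe effects, batch structure
or fold-dependent variance — so recovery Jaccards near 1 are expected and
the tests validate set construction and overlap arithmetic, not
normalization. `simulate_ct` writes Ct = base − log2(expression) +
N(0, 0.15) per replicate with an unchanged reference gene.

All generators are bit-reproducible given (params, seed), and every
recovery test consumes only the emitted data plus the emitted truth.

## Numerical and degenerate-input choices

* Exact tails in log-space via `gammaln`/`logsumexp`; representable to
  ~10⁻³⁰⁰ (beyond that the returned P underflows to 0.0).
* Degenerate 2×2 margins (empty row/column) carry no information: exact
  tests return P = 1 with a warning; the chi-square raises instead, since
  its expected counts are undefined.
* NE sentinels: 0 (screen arm extinct), ∞ (control arm extinct; such an
  allele can only be called a suppressor, and only if both gates pass),
  NaN (both extinct → always neutral). Collection medians ignore
  non-finite ratios with a logged count; an even-length median averages
  the central pair.
* Zero-total crosses are unscorable and raise.
* Ties in minlike tail membership are resolved with 1e-7 relative slack
  toward inclusion.
* Results TSVs serialize floats at six significant digits with `INF` /
  `0.00` literals matching the published table style.

## Known limitations

* The identity of the original screen's Fisher reference gene and the
  exact construction of its binomial expectation are not recoverable from
  the source; our defaults (pooled representative reference; conditional
  test) are this package's own design, with the alternatives exposed as
  options. Consequently per-allele P-values are not expected to match the
  printed P(FET)/P(bin) columns, and the printed columns are used only to
  verify the 41/20 classification gate.
* Re-scoring the 61 published hit rows from their raw counts alone uses a
  normalization median computed on that hit-biased subset, not the full
  534-allele collection, and therefore recovers direction more reliably
  than significance.
* Enrichment P-values depend entirely on the declared universe; fixture
  comparisons use 18,833 because that is the printed array size.
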