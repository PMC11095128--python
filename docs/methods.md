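# Methods

## Problem setting

National surgical audits benchmark hospitals on quality indicators and flag
outliers from funnel plots with 95% prediction limits around the national
mean. For hepato-pancreato-biliary surgery the relevant indicators are
postoperative mortality, major morbidity (Clavien–Dindo ≥ 3a), failure to
rescue (FTR), and the composites textbook outcome (TO, liver) and ideal
outcome (IO, pancreas), computed per treatment group: minor liver resection
(< 3 adjacent segments), major liver resection (≥ 3), pancreatoduodenectomy
(PD) and distal pancreatectomy (DP). The package answers: *given a
hospital's annual caseload, how large a deviation from the benchmark is
statistically detectable at all?* — and its inversions: the caseload needed
to detect a named deviation, and the fraction of hospitals that reach it
when pooling registration years.

## Power model

Everything rests on the one-sample proportion test in its
variance-stabilized (arcsine) form. The effect size is Cohen's
h = 2·arcsin√p₁ − 2·arcsin√p₀, whose sampling standard deviation is
approximately 1/√n independent of p, giving the required total volume
n = ((z₁₋α/₂ + z₁₋β)/h)² and the closed-form detectable rate
p₁ = sin²(arcsin√p₀ ± (z₁₋α/₂+z₁₋β)/(2√n)). Defaults are α = 0.05
(two-sided) and power 0.80; the normal quantiles are taken at double
precision (1.959964, 0.841621), not the textbook two-decimal values — the
difference is below reporting precision but the choice is fixed for
reproducibility. We verified this formulation against an independent route
(solving Φ(|h|√n − z_α) = 0.80 numerically) and against a Monte-Carlo
design-power recovery: a hospital simulated at exactly its volume's
detectable rate is rejected by the two-sided arcsine z-test in 74–86% of
2000 replicates across adverse and composite scenarios.

Numerical conventions:

* **Direction.** Adverse indicators invert upward from p₀, composites
  downward. When the shifted arcsine argument leaves [0, π/2] the rate is
  clipped to {0, 1} and the cell carries a `saturated` flag — never a
  silent truncation.
* **Degenerate input.** p₁ = p₀ yields an infinite-n signal (`math.inf`),
  not an exception.
* **Rounding.** Detectable differences are reported in percentage points
  rounded half-up to one decimal; annual volumes are floor(n_total/k) for k
  pooled years. The floor rule is the unique rule consistent with the
  published minimum-volume quartet for a 5-point mortality excess
  (25/54/48/25 from totals ≈ 75.4/163.5/145.5/75.4 over k = 3).
* **Scenarios.** The "two-fold of the benchmark" scenario applies to
  adverse indicators only; for a composite a doubling would move in the
  better direction, so those rows are emitted as infeasible.

Known irreproducibilities of the published grid, given benchmarks at their
printed 1-decimal precision: the FTR column for minor and major liver
resections (e.g. 19.8 and 26.2 at volume 20) is not consistent with the
printed FTR benchmarks under this (or any standard one-sample) formulation;
a handful of other cells differ by 0.1 points (e.g. PD mortality at volume
20: computed 18.5 vs printed 18.6), presumably because unrounded internal
benchmarks were used upstream; and the published major-LR composite
minimum-volume value 29 computes to 28 under the floor rule. These cells
are documented here and excluded from exact assertions; all other reference
cells reproduce exactly after rounding.

## Benchmarks and indicators

The benchmark is the **patient-weighted pooled** national rate (total
events / total eligible patients) over a two-year window, not the
unweighted mean of hospital rates — it is the quantity a funnel-plot centre
line uses, and it is reported next to the min–max of per-hospital rates
among hospitals with at least one eligible case. FTR is conditional: its
denominator is exactly the major-morbidity numerator of the same stratum
(an invariant the tests assert). Composite flags are strict conjunctions;
length-of-stay thresholds are national nearest-rank percentiles
(⌈q·n⌉-th order statistic) per procedure group — 90th for TO, 75th for IO —
with the threshold day itself passing (≤ is inclusive). Records missing a
component required by a composite are excluded from that composite's
denominator only, and logged. The single `death` flag deliberately
collapses "in-hospital" and "30-day" timing (the generator does not
distinguish them); TO's and IO's death components are therefore identical.

## Funnel limits and outlier calls

The default prediction region is the exact binomial two-sided (1−α) region
with at most α/2 tail mass strictly outside each limit: the upper limit
count is the largest c with P(X ≥ c) > α/2 under Binomial(n, p₀), the
lower the smallest c with P(X ≤ c) > α/2. At audit-typical volumes
(n ≈ 20) and rare events (p₀ ≈ 0.6%) the normal approximation
p₀ ± z√(p₀(1−p₀)/n) is badly anticonservative; it is retained as an option
for comparability with common funnel-plot software, and the two agree to
< 0.01 in rate once n·p₀·(1−p₀) ≥ 25. Counts exactly on a limit are
WITHIN (outlier requires strictly outside); classification uses counts, not
floating rates, so representation cannot flip a boundary case. WORSE is
above the upper limit for adverse indicators and below the lower limit for
composites; the better side is computed but reported as informational,
matching the audit practice of acting only on worse performance. No
over-dispersion inflation is applied (a possible extension).

## Synthetic registry

The generator emulates the structure of the Dutch national HPB audits so
every stage is testable without confidential data: 24 hospitals (12 doing
both families, 9 liver-only, 3 pancreas-only → 21 liver and 15 pancreas
centres), annual volumes on a deterministic two-segment geometric ladder
hitting the published per-hospital minimum, median and maximum exactly
(minor LR 44 (9–84), major LR 9 (1–54), PD 39 (22–144), DP 13 (5–30)), and
event probabilities at the published national benchmarks. Over the default
eight registration years this yields roughly 9,000 liver and 8,500
pancreatic records per run — the scale of the real audits.

Design choices, and what they imply:

* **Conditional mortality.** Death is generated conditionally on a severe
  complication (two free probabilities), because FTR is defined
  conditionally and must be an independent dial. A consequence of the
  published rates themselves: for major LR, p_severe × FTR
  (0.281 × 0.142 = 0.0399) exceeds the published marginal mortality
  (0.033), which is arithmetically impossible jointly (deaths after severe
  complications are a subset of all deaths) — likely a rounding or
  denominator artefact upstream. The generator clips
  p_death_given_not_severe at zero, so the implied marginal mortality for
  major LR is 3.99% (and 0.69% for DP); recovery tests target these implied
  generating rates.
* **Independent components.** Margin adequacy, readmission, POPF and
  reoperation are independent of each other and of severity; no dependence
  structure is published, so none is invented. Because real components are
  strongly positively correlated (POPF drives Clavien–Dindo grade), the
  *emergent* synthetic composite rates sit below the published TO/IO
  benchmarks at clinically realistic component rates (POPF B/C 12% after
  PD, 18% after DP; reoperation 4–5%; readmission 8–12%; adequate margins
  95–96%). Passing tests therefore demonstrate correct conditional and
  marginal structure, not realistic component correlations — the published
  composite benchmarks enter the power analysis through the transcribed
  benchmark table, not through simulation.
* **Length of stay.** Negative binomial (overdispersed counts),
  parameterized by target median (5–10 days by group) and dispersion size 4;
  only percentile thresholds matter downstream, so any right-skewed count
  model with the right median suffices. Integer stays tie heavily at the
  threshold, so the realised "≤ percentile" pass fraction can exceed the
  nominal 0.90/0.75 — the nearest-rank guarantee is one-sided by design.
* **Randomness.** One master seed; per-(hospital, procedure, year)
  substreams derived from a stable SHA-256 hash of the hospital label, so
  adding a hospital never perturbs the others and a fixed configuration is
  byte-identical across runs.
* **Outlier injection.** A scenario shifts exactly one hospital's
  generative rate: mortality by raising both conditional death
  probabilities by δ (marginal rises by exactly δ), morbidity via p_severe,
  FTR via p_death_given_severe. Composites have no single generative dial;
  the deficit is injected by inflating readmission until the *analytic*
  composite rate (at the nominal LOS pass probability) drops by δ — an
  approximation accurate to the LOS-tie effect above. In detection
  experiments the volume n is the indicator's denominator; for FTR that is
  the number of severely-complicated cases.

## Problem sizes and test design

Stochastic checks are sized to run in seconds while keeping Monte-Carlo
error far from their bounds: design-power recovery uses 2000 replicates per
scenario (binomial MC error ≈ 0.9 points against a 6-point margin); null
funnel coverage uses 5000 hospitals per (p₀, n) cell; distributional
recovery uses 200 seeds at n = 400 with a 4-standard-error band; benchmark
recovery uses one full-size eight-year registry. All seeds are fixed in the
tests.

## Limitations

No case-mix or risk adjustment (the analysis is about detectability given
volume, and adjustment cannot rescue an underpowered comparison); no
tumour-type-stratified benchmarks; no volume–outcome modelling; no
correlation between composite components; no over-dispersed funnel limits;
no multiplicity correction across the threshold grid. The timing of death
(in-hospital vs 30-day) is a single flag throughout.
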