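# Methods

## Model and assumptions

The package composes three sub-models on a daily time grid.

**Responsiveness.** The probability that an adult-born granule neuron of
age `t` (days since its birth date, i.e. the BrdU labelling day of its
cohort) responds to a spatial exploration by expressing Arc is modelled as
a straight line `P(t) = a + r·t`, fitted by ordinary least squares. The
line is parametrized by its age-0 intercept `a` and evaluated wherever
needed; the alternative parametrization around the age-30 value changes
nothing in the fit but makes the zero crossing `-a/r` less direct. Fitting
the three default calibration points gives `a = 0.055947`,
`r = −1.8596×10⁻⁴ d⁻¹`, `R² = 0.99893`, slope p = 0.0208 (two-sided t-test;
the p-value is reported but never used downstream), and a zero crossing of
300.85 d (reported as 301). In *recruitment mode* `P` is additionally
floored to 0 below the maturation age (default 30 d, configurable): the
specific behavioural response only develops between 30 and 45 days of
neuron age, and the non-specific Arc expression of younger neurons is
modelled separately (below). The model is linear by design; a hook for
alternatives exists in that every consumer takes the fitted model object,
but no nonlinear family is shipped.

**Cohort survival.** `N(τ) = scale·τ^exponent` is the number of cells born
on animal-age day τ that survive the early (~first 45 days) attrition;
survivors are assumed immortal. When a proliferation-vs-age table is
supplied, the exponent comes from OLS on (log age, log count) and the scale
is then re-anchored so the curve passes exactly through the anchor
(default `N(150) = 345` cells in the sampled region — the direct 45-day
count). Without a table, the model is built from the published scale
2218.2 via `s = log(345/2218.2)/log(150) = −0.37139`. Both routes satisfy
the two printed constraints (the scale and the anchor); which parameter is
"fitted" and which "solved" is otherwise underdetermined, so the package
supports both and defaults to the parametrized route. Cohorts begin at
sexual maturity, day 70, in the adult variant; the postnatal variant
(start day 1) includes every post-natal cohort and dominates the adult
curve pointwise. The power law diverges toward age 0, which is why the
postnatal variant is truncated at day 1 and treated as qualitative only.

**Recruitment convolution.** `R(t) = Σ_{τ=start}^{t−m} N(τ)·P(t−τ)` with
`m` the maturation age. All sums are daily and discrete — cohorts are
defined by one day of BrdU labelling, so the discrete sum is the model, not
an approximation of an integral; this also makes the brute-force
double-loop oracle in the tests exact. The implementation is a single
`numpy.convolve` of the cohort-size and probability sequences, which is
algebraically identical to the double sum.

### Time-axis convention for the peak

The recruitment curve is indexed by animal age; its support opens at
`onset = start + m` (day 100 for the adult parametrization). With the
default models the maximum falls at animal age 318 (2,084 cells, 60.2% of
the 3,465 responding cells). Peak locations are reported both as animal
age and as **days since onset** (318 − 100 = 218): the headline peak day of
this model is conventionally quoted on the onset-referenced axis (with the
model's parameters rounded to `P₀ = 0.054, r = −2×10⁻⁴` the maximum falls
at exactly day 217 of that axis), and a reader comparing against the
quoted figure should use `peak.days_since_onset`. Given the fitted line's
270-day-wide response window starting at neuron age 30, the curve cannot
peak before animal age ~300, so the onset-referenced reading is the only
one consistent with the model itself. Ties at the maximum break toward the
smaller age; reported days and cell counts are rounded to integers at I/O
boundaries only.

### Early non-specific expression

Neurons aged 1–30 days express Arc at ~1.5–2.5% regardless of behaviour.
This is modelled as two linear segments on neuron age: segment 1 is the
OLS line through the cage-control fractions at ages 1, 7 and 15 (0.013,
0.021, 0.023); segment 2 joins (15, 0.023) to (30, 0.015); breakpoint 15.
These are the only unstimulated values available in the window, hence this
calibration. The background proportion of granule cells at animal age `t`
convolves these probabilities with the **standing** size of each young
cohort: `B(t) = Σ_{a=1..30} N(t−a)·m(a)·p_early(a) / G`, with
`G = 231,000` granule cells in the region. The multiplier `m(a)` accounts
for attrition still ongoing below age 45: `N` counts only eventual
survivors, while a cohort observed at age `a` is larger by the ratio of
the observed BrdU fractions (0.26, 0.35, 0.23, 0.17, 0.15% at ages 1, 7,
15, 30, 45) to the age-45 value, linearly interpolated. Omitting `m`
(pass `attrition=None`) underestimates the standing population of 1–30-day
cohorts by ~40% and drops the background maximum from 0.172% to 0.105%.
With the default calibration the background peaks at 0.172% of granule
cells — 55% of the 0.31% cage-control Arc fraction and 11.5% of the 1.5%
exploration response.

## Census arithmetic

Deterministic bookkeeping: sampled counts scale linearly with the
antero-posterior extent (80,000 cells / 450 µm → 231,111, reported to the
nearest thousand as 231,000; rounding is applied last and is explicit in
the interface); responding populations are products rounded to the nearest
cell (231,000 × 1.5% = 3,465; 1,200,000 × 0.15% = 1,800). The whole-DG
total (1.2 M) and the one-day survival fraction (0.15%) are configuration
constants, not computed quantities. The decline from 0.35% (day 7) to
0.15% (day 45) is reported as the computed 57.1% loss; quoting it as
"~60%" is a rounding choice left to the caller. Group summaries average
per-animal fractions (each animal is the experimental unit); pooled-count
summaries are available behind a flag. ANOVA and Bonferroni-corrected
pairwise comparisons delegate to scipy/statsmodels — they are standard
procedures, not part of the model.

## Synthetic data

`generate_study` emulates the study design: 5 post-injection days
(1, 7, 15, 30, 45) × {cage control, spatial exploration}, group sizes
(SE: 5, 4, 4, 4, 3; CC: 3 each), ~80,000 granule cells per animal with
±10% uniform jitter (identical denominators across animals would be
unrealistic). Noise is the minimal count model consistent with the data:
binomial BrdU incorporation at the observed per-day fractions, multinomial
layer placement following the observed migration schedule, binomial
double-labelling at the observed per-(day, condition) fractions placed
with the observed layer enrichment (89.3% of SE doubles in L1, none in the
SGZ; the multinomial draw is repaired deterministically so no layer holds
more doubles than BrdU cells), and a binomial Arc background on the
remaining cells with a mild inner-layer bias (0/0.5/0.3/0.2 across
SGZ/L1/L2/L3 — the only generator parameter not pinned by a published
value; Arc-expressing cells are reported in all three granule layers with
an inner bias, and the SGZ holds none). The CC double-label fractions are
non-monotone in age (1.5% at day 30, 0.7% at day 45); the defaults follow
the observed values without smoothing. Only group means and layer shares
are constrained by data; the variance model (binomial/multinomial) is an
assumption, so passing recovery tests demonstrates robustness to counting
noise, not to biological overdispersion, between-animal heterogeneity or
spatial correlation, which the generator does not emulate.

Proliferation tables are generated from the power law with mean-one
multiplicative log-normal noise of a given CV; this leaves the log-log
slope estimator unbiased. No external proliferation table ships with the
package — synthetic tables stand in for one wherever a fitted survival
curve is exercised.

`recovery_experiment` reruns the full pipeline per replicate: group means
of a fresh study give the 30- and 45-day response points (the 150-day
point is fixed — the emulated design cannot produce it), a fresh noisy
proliferation table (default CV 10%, 8 log-spaced ages over 30–600 d)
gives the survival fit, and the convolution peak is located. Failures are
recorded per replicate, never fatal.

## Numerical choices and degenerate inputs

- OLS via `scipy.stats.linregress`; tests verify agreement with the
  centered normal-equation closed form to 1e-12 relative. A perfectly flat
  response input returns slope 0, `R² = 1` (exact degenerate fit) and an
  undefined zero crossing (`None`), not an error; `zero_crossing_age`
  raises only for non-negative slopes.
- The anchored survival model validates `N(anchor) = anchor_count` to
  1e-9 relative at construction; re-anchoring is idempotent.
- `cumulative_survivors` returns 0 (not an error) before the start age.
- Convolution values match the brute-force double loop to 1e-9 relative
  across random parametrizations (property-tested).
- All probabilities are fractions internally; percent conversions happen
  only at I/O boundaries (`--percent` flag on CSV readers, report text).
- Problem sizes: the default curve horizon is 600 days (the peak and
  plateau are well inside it); validation experiments use 200 pipeline
  replicates and 500-replicate generator calibrations, which run in
  seconds.

## Known limitations

- Three calibration points fit the responsiveness line; the linear form
  and its 301-day extrapolation are a hypothesis, not an established
  dose-response. A nonlinear model may fit equally well.
- The survival exponent rests on the published scale/anchor pair; the
  original proliferation-vs-age table behind it is not available, so the
  package cannot re-derive `N₀ = 2218.2` from primary data.
- "No mortality after maturation" is a simplification; any late attrition
  would lower the plateau of the recruitment curve.
- The census scaling assumes homogeneity along the antero-posterior axis
  and applies no stereological correction.
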