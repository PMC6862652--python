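# Methods

## The model

`fluorisk` assesses the non-carcinogenic health risk of fluoride ingested
through tea. It follows the standard USEPA exposure framework for a
contaminant dissolved in a beverage:

**Chronic daily intake** (mg of fluoride per kg body weight per day):

    CDI = (C · IR · EF · ED) / (BW · AT)

with C the fluoride concentration in the brewed infusion (mg/L), IR the
daily intake volume (L/day), EF the exposure frequency (days/year), ED the
exposure duration (years), BW body weight (kg), and AT the averaging time in
days. For non-carcinogenic endpoints AT = ED × 365, and with year-round
exposure (EF = 365) the formula reduces algebraically to CDI = C·IR/BW,
independent of ED — an identity the tests assert to 10⁻¹² relative
tolerance.

**Hazard quotient**: HQ = CDI / RfD, with the oral reference dose for
fluoride RfD = 0.06 mg/kg/day. HQ strictly above 1 flags a potential
non-carcinogenic hazard (fluorosis); HQ at or below 1 classifies safe. The
tie at exactly 1 classifies safe because the hazard statement is the strict
inequality.

Three population groups are evaluated with the packaged default parameters:

| group    | IR (L/d) | EF (d/y) | ED (y) | BW (kg) | AT (d) |
|----------|----------|----------|--------|---------|--------|
| men      | 2        | 365      | 40     | 78      | 14,600 |
| women    | 2        | 365      | 40     | 65      | 14,600 |
| children | 1        | 365      | 6      | 14.5    | 2,190  |

Only the ingestion route is modelled; dermal and inhalation routes, and
fluoride from drinking water or food, are out of scope (their omission makes
the assessment an underestimate of total fluoride exposure).

## Two evaluation modes

The packaged results table that this pipeline reproduces contains women and
children CDI cells that are *not* the literal formula applied to the group's
own parameters: every printed cell is instead reproduced exactly (to the
printed 3 significant figures) by a chained scaling in which each group's
CDI equals the previous group's CDI multiplied by its own IR/BW ratio
(women = men × 2/65, children = women × 1/14.5). The two readings coincide
for the first (men) group.

Rather than silently choosing one, the package implements both:

- **`eq1`** (default): the literal formula per group — the physically
  meaningful model.
- **`as_published`**: the chained arithmetic — used only to reproduce the
  published table cell-for-cell. The test suite asserts both that this mode
  regenerates all 30 cells and that the literal formula does *not* reproduce
  the women/children cells, so the divergence can never be papered over.

## Concentration distributions

Each study reports only summary statistics (mean, min, max, sometimes an
SD), so the concentration distribution is reconstructed from summaries with
bounded support equal to the reported [min, max] range. The `auto` rule:

1. **point** mass when min = max;
2. **truncated normal**(mean, SD) on [min, max] when a reported SD is
   arithmetically consistent with the reported range — for any sample of
   size n, range ≤ SD·√(2n), so an SD violating this bound cannot be the
   sample SD of data spanning that range (two of the five packaged studies
   fail the bound and are treated as SD-absent; a warning is raised);
3. **triangular**(min, mean, max) otherwise — the default, because it
   consumes exactly the three statistics every study reports.

The triangular middle parameter is formally a mode; the reported mean stands
in for it. This approximation is exact for symmetric shapes and biased for
skewed ones — the synthetic round-trip test therefore uses a generating
triangle whose mean coincides with its mode, which is what "parameter
recovery" can mean under this convention. Uniform and moment-matched
truncated-lognormal families (μ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²)) are
selectable per study.

Sampling is inverse-transform from a uniform stream: draws can never escape
the support, identical seeds reproduce identical sequences, and the
closed-form quantile used for sampling is the same function validated
against the analytic CDF (cdf(quantile(p)) = p to 10⁻⁹).

## Monte Carlo propagation

For every study × population pair, `n_iterations` (default 10,000)
concentrations are drawn and pushed through the intake model, giving
empirical percentile curves of CDI and HQ over the 1–99% assurance range and
the exceedance probability P(HQ > threshold). Design choices:

- **Percentile estimator**: order statistic (inverted CDF, no
  interpolation). Because HQ is a monotone transform of the concentration
  sample, this makes hq_percentile(p) = cdi_percentile(p)/RfD an exact
  identity for the same sample, not an asymptotic one.
- **Seeding**: one independent substream per (study, population) pair,
  spawned from the master seed via `numpy.random.SeedSequence`. Adding or
  reordering scenarios never perturbs another pair's draws; identical
  settings reproduce bit-identical results, and the emitted
  `run_metadata.json` suffices to reproduce a run.
- **Point risk**: the published evaluation concentration is used verbatim
  when present (those printed values are inputs; their derivation from the
  underlying studies is not reproducible because the original fitting
  software and its distribution choices were not reported). Only when absent
  is the simulated 95th-percentile concentration substituted.
- Only the concentration is treated as random by default. IR and BW enter
  as constants; the engine's factor structure leaves per-parameter
  distributions as a straightforward extension.

Exceedance has a closed form for checking: HQ > t inverts to
C > t·RfD·BW/IR (2.34 mg/L for men at t = 1), so P(HQ > t) = 1 − F(2.34)
for any concentration CDF F; the tests compare the empirical fraction
against this for triangular F.

## Synthetic data

The generator emulates the measurement structure behind a study summary
table: `n_brands × replicates_per_brand` i.i.d. draws from a chosen bounded
family, tagged with brand indices. It emulates marginal concentration
variation only — real surveys have between-brand and brewing-protocol
structure the generator does not model (brands are structural tags; an
optional between-brand shift defaults to 0 because the source tables report
no variance split). Passing round-trip tests therefore demonstrate that the
fitting and simulation machinery is self-consistent, not that any particular
family describes real tea measurements.

## Numerical and degenerate-input choices

- min = max collapses every family to a point mass; the simulation then
  reproduces the deterministic evaluation exactly (asserted in tests).
- Report tables round to 3 significant figures; all CSV outputs carry full
  precision, and write→read round-trips reproduce the in-memory records
  exactly.
- Ranking ties (equal HQ) preserve input order (stable sort).
- Data anomalies that do not prevent computation (impossible SD, evaluation
  concentration outside the reported range, AT ≠ ED×365) warn rather than
  fail; structural problems (min > max, missing columns, non-numeric values)
  are errors naming the offending row or field.

## Problem sizes

Default runs use 10,000 iterations per pair (5 studies × 3 groups),
completing in well under a second. Convergence tests use 10⁵ draws (1%
agreement with closed-form quantiles) and the synthetic round trip uses 10⁴
measurements (5% quantile recovery).

## Known limitations

- The triangular mean-as-mode convention biases quantiles of skewed
  distributions; it is a disclosure-limited reconstruction, not a fit.
- The published evaluation concentrations are trusted inputs; nothing in the
  pipeline can validate how they were derived from the study summaries.
- Total fluoride exposure is underestimated by design (tea only).
- The `as_published` chain is a reproduction device with no exposure-science
  interpretation for the second and later groups.
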