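# Methods

## The diagnostic model

The horsemanship syndrome is treated as a latent condition expressed
through six observable skeletal trait categories. Each trait is recorded
in one of three states — present, absent, or not preserved — and carries
an integer weight in {1, 2, 3} reflecting how specific the trait is to
habitual riding relative to other strenuous activities. The canonical
catalog, in fixed order with weights (3, 3, 2, 2, 1, 1):

1. **Femoral/pelvic entheses (3)** — entheseal stress reactions at the
   hip adductor and gluteal attachment sites, from continuous balancing
   contractions when riding astride.
2. **Ovalization of acetabulum (3)** — anterosuperior extension and
   thickening of the hip-socket rim from pressure in a flexed,
   drawn-up-leg seat.
3. **Femoroacetabular lesion (2)** — impression dent with raised margin
   on the anterosuperior femoral neck from repeated femoroacetabular
   contact.
4. **Platymeric femur (2)** — anteroposterior flattening of the
   subtrochanteric shaft (platymeric index < 85), an adaptation to
   mediolateral bending stress.
5. **Specific vertebral degeneration (1)** — symmetric lower
   thoracic/lumbar spondylosis with concave endplates and Schmorl's
   nodes, from vertical impact stress.
6. **Specific trauma (1)** — healed injuries consistent with falls from
   or handling of horses.

An individual's **trait count** is the number of present traits and its
**base score** the weighted sum over present traits (0–12). The
**dual-threshold rule** classifies an individual positive when trait
count ≥ `min_traits` (default 4) *and* the selected score ≥ `min_points`
(default 7) — both defaults are "more than half" of the respective
maxima. Thresholds are parameters so their operating characteristics can
be swept.

### Missing data

Unpreserved traits contribute zero to both count and score; nothing is
imputed. Instead the engine reports, per individual:

- **score bounds** — the minimum (all unpreserved traits absent, equal
  to the base score) and maximum (all unpreserved traits present) over
  completions of the missing states;
- **max attainable** — the weighted sum over observable traits, the
  ceiling preservation imposes;
- a **preservation-capped** flag, set when the unpreserved traits could
  change the classification: the score bounds straddle the point
  threshold, the hidden traits straddle the trait threshold, or a
  threshold is unreachable outright. The flag is advisory and never
  alters positivity — poorly preserved skeletons are reported as
  undiagnosable-in-principle, not upgraded.

### Score sources

Published per-individual scores embed a severity-of-expression
adjustment whose exact rules are not public; on the packaged reference
data the published score is always ≤ the recomputed base score, with a
gap of 0–3 points. The package therefore never recomputes silently: a
classification names its **score source** — `reported` (transcribed
published score), `base` (recomputed weighted sum), `adjusted` (base
minus user-supplied per-trait deductions, each bounded by the trait's
weight and restricted to present traits), or `auto` (reported when
available, else base). On the reference assemblage the reported and base
sources produce identical classifications (the same nine positives), so
the choice is immaterial there; the equivalence is asserted in the test
suite. Severity deductions are accepted only as explicit input
(`SeverityAdjustment`), since any particular reconstruction of the
unpublished rules would be conjecture.

### Osteometric helper

`platymeric_index(ap, ml)` returns `100·ap/ml` for the subtrochanteric
femoral diameters and the conventional shape class: platymeric below 85,
eurymeric 85–99.9, stenomeric at 100 and above. Boundary values fall in
the upper class. The sources using the trait assume but do not define
these cut-offs; the values follow standard osteometric practice.

## Cohort summaries

Demographic operations are pure functions of counts, because
whole-cohort compositions are typically published only in aggregate:

- **masculinity index** — males per 1000 females, probable
  determinations counted with their sex, rounded half-away-from-zero to
  the nearest integer (132/65 → 2031). Undefined without females; the
  package raises rather than returning infinity.
- **subadult fraction** — percentage dying before the subadult cutoff,
  reported to one decimal (61/217 → 28.1). The cutoff defaults to 18
  years (no standard definition exists in the sources; configurable).
  In per-record summaries an individual is subadult when the *upper*
  bound of its age interval is below the cutoff, so boundary intervals
  like 15–18 count as adult.

`summarize()` rolls a scored assemblage into these indices plus a
trait-count histogram and positives-by-culture counts (cultural
assignments normalized to an enumeration, with parenthetical doubts
preserved as free-text notes).

## The synthetic generator

The generator emulates the data structure the rule is applied to — not
any particular excavated assemblage:

1. latent rider status ~ Bernoulli(`rider_fraction`);
2. each trait present independently with the status-conditional
   probability (`p_trait_given_rider` / `p_trait_given_nonrider`);
3. preservation masking applied afterwards, independent of status and
   presence (taphonomy does not know riders): either a fixed per-trait
   observability vector, or the default completeness-linked model where
   a per-skeleton completeness is drawn uniformly from
   `completeness_range` and every trait is observable with probability
   completeness/100;
4. sex and age class filled per configuration.

Defaults describe a plausible study condition: 217 individuals per
assemblage (a realistic multi-site evaluation campaign), completeness
uniform on 20–95% (mean 57.5%, matching the mediocre preservation
typical of kurgan burials), 67% male, 28.1% subadult. The trait
prevalences are **illustrative**: no non-rider base rates for these
traits have been published, so every specificity or PPV figure is
conditional on the configured rates and is labelled as such in reports.
The default rider prevalences make the strongly diagnostic traits
common but not universal among riders and rarer among non-riders,
reflecting that other strenuous activities can mimic each trait.

Design choices, where the design was genuinely open:

- **Conditional independence of traits given status.** The syndrome
  implies correlated etiology, but no correlation structure has been
  published; independence is the simplest defensible null for
  specificity analysis and leaves the configuration extensible to a
  latent-factor model later.
- **Per-individual RNG substreams** derived from `(seed, index)` via
  numpy `SeedSequence`, so growing `n_individuals` never reshuffles
  earlier individuals, and replicate seeds derive from
  `(seed, constant, replicate)` so replicates are mutually independent
  yet reproducible.
- **Completeness-linked preservation couples the six traits** through
  the shared per-skeleton completeness. Exact calculations under this
  model integrate completeness out by 40-node Gauss–Legendre quadrature
  (the integrand is a degree-≤6 polynomial in the observability, so the
  quadrature is exact up to rounding).

## Performance evaluation

Three routes to the rule's operating characteristics:

- `estimate_performance` — Monte-Carlo: generate replicates, classify on
  the recomputed base score (published-style adjusted scores do not
  exist for synthetic data), pool confusion totals; rates carry pooled
  binomial standard errors, and a rate with an empty denominator is
  reported as undefined rather than zero.
- `exact_positive_probability` — enumerates the 3⁶ = 729 joint
  per-individual outcomes; per trait, observed-present has probability
  `p·q`, observed-absent `(1−p)·q`, unpreserved `1−q`.
- `threshold_sweep` — evaluates a threshold grid on one shared set of
  simulated assemblages (common random numbers), so the positives at a
  stricter threshold pair are exactly a subset of those at a looser
  pair, making monotonicity of sensitivity/specificity along the grid an
  exact property rather than a statistical one.

The test suite checks the simulator against the enumeration at a
4-standard-error tolerance (200 replicates of 500 individuals, a size
chosen to keep the full suite under half a minute) and checks the
degenerate limits: perfectly separating traits give sensitivity =
specificity = 1, uninformative traits give PPV equal to the rider
fraction.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of the analysis
(status-conditional trait expression, status-blind preservation loss,
assemblage-level demography). It does not model age- or sex-dependent
trait expression, inter-trait correlation beyond the shared completeness,
systematic recording differences between observers, or biased selection
of well-preserved individuals for publication — the packaged 24 are
exactly such a selected sample (≥3 traits), which is why no trait
prevalence is ever fitted to them. Passing tests therefore demonstrate
the rule's behaviour under the stated generative model, not the
real-world accuracy of rider diagnosis.

## Numerical conventions

- All scores, weights and thresholds are integers; no floating-point
  comparisons enter classification.
- Trait-state symbols: `+`, `-` (ASCII hyphen and Unicode minus both
  parse; writers emit ASCII), `?`. Unrecognized symbols are reported
  with row and column, never coerced.
- The masculinity index rounds half-away-from-zero; the subadult
  fraction rounds to one decimal; CLI reports emit both the rounded and
  the full-precision value.
- Degenerate inputs: empty assemblages summarize to zeros with undefined
  indices set to `None`; zero-female cohorts raise; non-positive femoral
  diameters raise.
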