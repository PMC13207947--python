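# Methods

## The engagement model

Per-drug risk is summarized by fractional target engagement under the
single-site Emax model, `E(C) = Emax·C/(EC50 + C)`, evaluated at the
unbound peak plasma concentration `Cmax,u = Cmax·(1 − ppb)`. Assumptions
worth keeping in mind:

- **Emax = 1, Hill = 1, everywhere.** Emax is fixed at 1 for agonists and
  antagonists alike, symbolizing full engagement; the Hill coefficient is
  implicitly 1 and deliberately not configurable. Agonist EC50 and
  antagonist/inhibitor IC50 enter identically; the mode of action is kept
  as metadata only.
- **Free-drug hypothesis.** Only unbound drug is treated as active. For
  intracellular targets (topoisomerases, many kinases) unbound plasma
  concentration may misstate exposure at the site of action; the model
  carries no tissue-distribution correction.
- **Static exposure.** A single peak concentration stands in for the full
  concentration-time course; no PK modelling, accumulation, or
  metabolite pharmacology.

The safety margin is `Cmax,u / EC50`, reported both as a ratio and as
log10 for the severity-frequency table. `margin ≥ 1 ⇔ E(Cmax,u) ≥ 0.5` is
exact algebra and is enforced as an invariant in the tests.

## Unit harmonization

All affinities and exposures are converted to nM with exact decimal
factors; mass-per-volume values (ng/mL, µg/mL, mg/L, g/L) convert through
the molecular weight as `nM = mg/L ÷ MW(g/mol) × 10^6`. No density or
temperature corrections are involved — the conversion needs only MW.
When a drug has several reported values, the median is used (midpoint of
the central pair for even counts); aggregation applies uniformly to
affinity, Cmax and protein binding. Unrecognized unit tokens raise
immediately rather than being skipped, so data errors surface at ingest.

## Ingest and consolidation

Drug names are lowercased, trimmed, and stripped of trailing salt/ester/
formulation tokens from an editable suffix list (citrate, hydrochloride,
sodium, 18F, ...); normalization is idempotent. Duplicate rows under
trade names or salt forms are consolidated to one record per generic
name. When duplicates disagree on concern or severity the worse label is
kept (most > less > ambiguous > no; severe > moderate > mild > none) —
a screening tool should not understate risk — and every such conflict is
recorded for audit. Rows with unmappable concern labels are reported,
never silently dropped.

## Panel assignment and tiers

Each drug lands in exactly one panel, by precedence: (1) a two-column
manual-correction table (shipped with the known fixes:
moxifloxacin → hERG, probenecid → other); (2) the hERG priority rule —
an annotated hERG class or any keyword containing "QT" or "Torsade",
matched case-insensitively as substrings over a configurable term list;
(3) the first annotated target class; drugs with no annotated target
fall into a separate no-pharmacological-target bucket.

Tier membership is monotone by construction: tier 1 maps every named
class (only `other` and no-target are unmapped); tier 2 removes the broad
therapeutic classes; tier 3 further removes antineoplastics, GABA,
VEGFR/EGFR and anticoagulants/antiplatelets. Percentages are rounded to
the nearest integer percent, matching the reporting convention of the
summaries they reproduce.

## Sensitivity analysis

Drugs missing protein binding get fraction unbound imputed at 0.5; drugs
missing Cmax keep their concentration-response curve but are excluded
from margin and engagement statistics; drugs missing affinity are carried
as curve-only placeholders and never contribute numeric engagement
values (in figures they appear as horizontal dashed lines at spread-out
heights — a plotting convention only). Imputation touches exposure
metrics exclusively; classification counts are invariant to it, and the
report names every imputed or excluded drug.

## Synthetic data

The generator emulates the structure the analysis assumes, with defaults
fixed at the study conditions: concern marginals (327, 507, 105, 328);
per-concern probabilities of carrying a key risk-target class
(0.84, 0.66, 0.54, 0.44 — the no-concern value being 100% − 56%
unmapped); hERG weighted so it accounts for ~20% of the most-concern
category with the remaining 17 key classes uniform; data availability
81.1% (protein binding), 73.8% (affinity), 53.5% (Cmax) applied
element-wise; and a 4% salt-form duplicate rate (≈51 alias rows on 1267
drugs, matching the 1318-row raw table). Distributional choices are
repository conventions, as no empirical distributions are published:
affinity ~ lognormal(ln 100 nM, 1.5), total Cmax ~ lognormal(ln 300 nM,
1.2), bound fraction ~ Beta(5, 2) — together spanning margins well above
and below 1. Severity is sampled with a logistic coupling on
log10(margin) (slope 1 by default) so the severity-vs-margin trend is
recoverable; affinity strings are emitted in mixed units (nM, µM, ng/mL
via MW) with the central value exact, so the median harmonization
recovers the truth.

What the generator does **not** emulate: real drug names or synonym
structure beyond a single salt suffix, correlated missingness, assay-
to-assay affinity variability, multiple targets per drug, or broad
therapeutic classes among the mapped drugs (mapped drugs are drawn from
the 18 key classes only, so tiers coincide on generated data). Passing
tests on synthetic data therefore demonstrate the pipeline's mechanics
and parameter recovery, not the field accuracy of any annotation source.

A separate deterministic replica builder reproduces only the raw-row /
unique-drug duplicate structure of the full public rank table
(341/528/106/343 raw rows per concern, 1267 unique), for
distribution-scale ingestion tests with no network access.

## Numerical and design choices

- Concentration-response curves are evaluated on a 200-point log-spaced
  grid from 10⁻²× to 10⁴× the affinity (configurable); the axis range of
  the original figures is unpublished, so this is a package convention.
- log10(margin) histogram bins default to integer powers of 10 from
  10⁻⁴ to 10²; out-of-range margins are clamped into the edge bins so
  every complete drug is counted.
- Benchmark ranking sorts by engagement at Cmax,u (descending), breaking
  ties by larger margin then name, so results are order-independent.
  An empty reference panel yields rank 1 of 1 with a warning rather than
  an error.
- Figure styling: curve color encodes concern, marker shape encodes
  severity, and the marker sits on the curve at (Cmax,u, E(Cmax,u)).

## Problem sizes in the test suite

Unit and property tests run at desk scale (hundreds of random cases per
property; the engagement-model algebra is exercised on 1000 random
pharmacology settings). Oracle-equivalence checks compare contingency
tables, medians, ranks and histograms against brute-force re-counts on
100 random datasets of ~20–120 drugs. Parameter recovery uses one
generated dataset of 10,000 drugs (2,500 per concern category), at which
size the configured mapped fractions are recovered within three binomial
standard errors and the imputation report matches ground truth exactly.

## Known limitations

The tiered percentages reproduce published tallies only when fed the
published counts; the underlying per-drug annotations are not public, so
figure panels are reproduced structurally (conventions, marker
placement) rather than drug-by-drug. The no-concern denominator appears
inconsistently in the published tallies (328 vs 321); the package
reports exact computed counts and reproduces each printed figure with
its own printed denominator, making no attempt to reconcile them.
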