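# Methods

## Measurement model and quantification

A sample's *E. coli* population is described by the composition
`(p_A, p_B1, p_B2, p_D)` over the four main phylogroups.  The assay
observes five absolute counts (CFU/g): a 16S-based total `T` and
probe-specific counts for B1, B2, D and *yjaA* (the *yjaA* probe targets
the A1 subgroup together with B2, so its true count is `A1 + B2`).
Quantification divides each probe count by `T`; phylogroup A is the
subtraction remainder `1 − p_B1 − p_B2 − p_D`, and `p_A1 = (yjaA − B2)/T`,
`p_A0 = p_A − p_A1`.

Noise can make probe sums exceed the 16S total, so negative subtraction
remainders (for A or A1) are clamped to 0 and the clamp is recorded as a
warning on the profile; probe proportions above 1 are capped at 1 the same
way.  `p_A1` is additionally capped at `p_A`.  Closure
(`p_A + p_B1 + p_B2 + p_D = 1`) therefore holds exactly whenever no cap
fired.

Detection is compositional: the probe groups are detectable at ≥0.1% of
the population, A by subtraction only at ≥15%.  Thresholds are inclusive
(≥), reading the stated threshold as the smallest detectable value.
Undetected groups keep their numeric proportion but are categorised
"absent" downstream.  A sample with `T = 0` carries no *E. coli*; it is
excluded from composition analyses rather than treated as an error.

## Categorical phenotypes and enterocolitypes

Per phylogroup: dominant (>50%, strict), intermediate (closed [10%, 50%]),
minor (<10%, detected), absent (undetected).  CFU class: high (>10⁷,
strict), low (<10⁶, strict), intermediate otherwise (both boundaries fall
in the intermediate class).  Diversity is high iff all four groups are
detected.

The enterocolitype is implemented as a deterministic per-sample rule —
dominant phylogroup crossed with host domain, with the >90% B2 exclusivity
test taking precedence for humans:

* human: `p_B2 > 0.9` or B2 dominant → E4; A dominant → E5
* animal: B2 dominant → E1; B1 dominant → E2; A dominant → E3
* otherwise (including dominant D): unassigned, a valid outcome.

The source study delineated these types as ordination clusters over host
groups; the deterministic rule is the minimal per-sample operationalization
of those cluster descriptions.  CFU class and diversity are reported
alongside but do not gate assignment (they characterise, rather than
define, the clusters).

## Indicator coding

The 32-variable animal coding comprises 14 phylogroup-category indicators
(DA, DB1, DB2, DD; IA, IB1, IB2, ID; MB1, MB2, MD; AB1, AB2, AD), three
CFU classes, two diversity classes, nine species, two habitats and two
diets, in a fixed documented order (`ANIMAL32_COLUMNS`).  There is no
"minor A" or "absent A" indicator — A is quantified by subtraction with a
15% detection floor, so those states contribute no 1 in the A block.  The
33-variable strain coding is: three origin groups, eight B2 subgroups plus
"unassigned", the 20 virulence genes, and a score ≥ 9 flag.

Mutually exclusive blocks (CFU, diversity, species, habitat, diet; origin,
subgroup) carry exactly one 1 per row.  Categories unobserved in a given
cohort yield all-zero columns; these are pruned (and logged) before
correspondence analysis, since an empty category has no chi-square
profile.

## Correspondence analysis

Computed by SVD of the standardized residuals
`S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}` rather than eigen-decomposition of
a distance matrix — numerically stabler, identical axes.  Total inertia is
`Σ S_ij²`, which equals the Pearson χ² of the table divided by the grand
total; this identity is the main correctness oracle in the tests.
Row/column principal coordinates are the mass-weighted singular vectors
scaled by the singular values (symmetric map); standard coordinates are
also exposed, and supplementary rows are projected by the transition
formula (row profile × column standard coordinates), under which fitted
rows reproduce their own coordinates and the column-mass profile maps to
the origin.  The trivial axis is removed by the centering; singular values
below 1e-12 of the largest are truncated; each axis's sign is fixed by
forcing its largest-magnitude row loading positive, making fits
reproducible across platforms.

## Virulence scoring and group comparisons

The VF score of a strain is the count of the 20 assayed genes present.
Group prevalence tables satisfy the identity mean score = Σ per-gene
prevalence exactly; the score SD uses the n−1 denominator.  Printed
percentages are inverted to integer counts by nearest-integer rounding,
with a consistency flag when re-formatting does not reproduce the printed
value (the count is returned regardless).

Per-gene cross-group tests report both an exact hypergeometric (Fisher)
two-sided p-value — the recommended default at n of 10–20 per group — and
a chi-square with a continuity-correction toggle.  Score comparisons use
the two-sided Wilcoxon rank-sum for two groups (exact when sizes permit
and there are no ties) and Kruskal–Wallis for more; fully tied data yield
p = 1.  Per-gene p-values are uncorrected by default, mirroring the
reporting convention of the source table; a Benjamini–Hochberg helper is
available.

The published survey prints the group score summaries as "median ± sd",
but the ± notation and the exact agreement of the animal value (6.38) with
the prevalence-sum identity identify them as means; the package computes
means.  Only the animal column of the published table is internally
consistent (the two human columns' prevalence sums, 10.20 and 9.20, differ
from the printed 10.45 and 9.40, possibly because pilus-adhesin alleles
were scored separately there), so only the animal column anchors exact
checks.

## Synthetic-data generator

The generator emulates the cohort the analysis assumes:

* **Host**: each template carries a pool of host species; species
  determines habitat and diet through a fixed lookup (nine animal species
  plus humans).
* **Composition**: Dirichlet(`concentration × mean`) around a per-template
  mean composition; mean entries of exactly 0 are dropped from the
  Dirichlet and fixed at 0.
* **Load**: `10^Normal(μ, σ)` CFU/g.  Template defaults span the reported
  range from wild-herbivore loads (5.5 ± 1.0; the reported wild-rabbit
  figure is 5.49 ± 1.45) to human loads (7.9 ± 0.52).
* **Measurement**: each probe count is multiplied by an independent
  `10^Normal(0, sd)` factor — qPCR error is approximately constant on the
  CT (log) scale — and probe counts below 0.1% of the *measured* total are
  censored to 0.  The *yjaA* count is formed as `A1 + B2` before noise;
  noise is applied once per probe.
* **A1 split**: the A1 fraction of A defaults to 0.5 (configurable); no
  published quantification of the A0/A1 split exists.
* **Strain panels**: independent Bernoulli draws per gene at specified
  prevalences.

Template compositions are configurable package defaults consistent with
the qualitative cluster descriptions (they are **not** published mixture
values): E1 (0.15, 0.05, 0.70, 0.10), E2 (0.15, 0.60, 0.05, 0.20), E3
(0.60, 0.20, 0.05, 0.15), E4 (0.02, 0.01, 0.95, 0.02), E5
(0.60, 0.15, 0.10, 0.15) in (A, B1, B2, D) order.

Two free defaults were calibrated analytically at design time, before any
test existed, against the recovery property the pipeline is required to
satisfy (≥99% of samples reassigned to their generating enterocolitype at
zero noise, ≥90% at default noise, per template):

* Dirichlet concentration **200** — keeps a template's nominal dominant
  group above 50% in ≈99.8% of draws for the least-separated templates
  (dominant mean 0.60; Beta(120, 80) marginal);
* measurement sd **0.03 log10** (≈0.1 CT of replicate spread, a realistic
  qPCR precision) — Monte-Carlo evaluation at design time gave per-template
  recovery of 94–100% under noise (worst: E2).

These values were fixed once and not revisited.  Real compositions vary
more between individuals than concentration 200 allows; the generator
states the world in which per-sample typing is reliable, so a green
recovery test establishes correctness of the classification rule, not
field-level typing accuracy.

Randomness uses one root seed with a named substream per sample
(`SeedSequence([seed, template_index, sample_index])`), so enlarging a
cohort never perturbs previously generated samples.

What the generator does **not** emulate: clonal structure within a
phylogroup, the minority phylogroups C/E/F and non-*E. coli* *Escherichia*
(which the real assay mis-assigns to A/B2/D at a few percent), gene–gene
linkage in strain panels (genes are independent Bernoulli), host effects
on composition beyond the template, and *E. coli*-free samples (these are
exercised through hand-written fixtures instead).

## Packaged data

`data/b2_panel_synthetic.tsv` is a 43-strain panel (20 human-exclusive,
10 human non-exclusive, 13 animal) whose per-gene marginals are
reconstructed exactly from the published percentages; the per-strain joint
gene pattern (first-k-strains-positive) and the subgroup labels are a
synthetic convention.  Marginal-dependent statistics (prevalences, mean
scores, per-gene tests) are faithful; joint-pattern statistics (score SD,
strain ordinations) are not, and are only smoke-tested on it.  The example
cohort TSVs are simulator output (seed 7, 3 samples per template).

## Numerical conventions

Proportions are kept at full precision; percentages are display-only.
Detection thresholds are inclusive.  TSV floats are written with `repr`
for lossless round trips.  CA truncates singular values < 1e-12 of the
largest and reports rank-0 fits (perfect independence) as valid results
with zero axes.  The chi-square route of `compare_prevalence` returns
p = 1 on tables with an empty margin, where the statistic is undefined and
no association is testable.
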