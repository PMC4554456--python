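# colitype

Quantitative analysis of commensal *Escherichia coli* population structure
in feces, for microbial ecologists and clinical microbiologists working
with phylogroup-specific qPCR assays.

*E. coli* is structured into four main phylogroups (A, B1, B2, D) whose
relative abundances in the gut differ systematically between hosts.  A
qPCR assay measures the total *E. coli* load per gram of feces (16S rDNA)
and probe-specific counts for B1 (TspE4.C2), B2 (*chuA*/*yjaA*+) and D
(*chuA*/*yjaA*−); phylogroup A carries no specific probe and is quantified
by subtraction,

```
p_B1 = B1/T,  p_B2 = B2/T,  p_D = D/T,  p_A = 1 − p_B1 − p_B2 − p_D,
p_A1 = (yjaA − B2)/T,       p_A0 = p_A − p_A1,
```

with compositional limits of detection: 0.1% of the population for the
probe-based groups, 15% for A by subtraction.  Samples are then reduced to
categorical phenotypes — per-phylogroup abundance category (dominant >50%,
intermediate 10–50%, minor <10%, absent), CFU class (>10⁷ / 10⁶–10⁷ /
<10⁶ CFU/g), diversity class (all four groups detected or not) — and to an
**enterocolitype** E1–E5, the intra-species analogue of a gut enterotype
(B2-, B1- or A-dominated animal communities; exclusive-B2 or A-dominated
human communities).  Cohorts are ordinated by a from-scratch
correspondence analysis (chi-square-distance SVD; total inertia equals the
Pearson χ² of the table divided by its grand total), and B2 strains are
scored for 20 extraintestinal virulence genes with exact and rank-based
group comparisons.

Because the original fecal samples and strain collection are not publicly
deposited, the package ships a synthetic-data generator (Dirichlet
compositions per enterocolitype template, log-normal total loads,
log-normal qPCR measurement error, Bernoulli gene panels) plus a 43-strain
panel reconstructed from published per-group gene prevalences.

## Worked example

```python
from colitype import (QPCRCounts, compute_proportions, apply_detection_thresholds,
                      build_phenotype, host_for_species)

counts = QPCRCounts("sample_042", total_cfu=1e7, b1_cfu=2e6, b2_cfu=1e6,
                    d_cfu=1e6, yjaa_cfu=3e6)
profile = apply_detection_thresholds(compute_proportions(counts))
phenotype = build_phenotype(profile, counts.total_cfu,
                            host_for_species("sample_042", "pig"))
```

This prints (via the obvious inspection code):

```
proportions: {'A': 0.6, 'A1': 0.2, 'A0': 0.4, 'B1': 0.2, 'B2': 0.1, 'D': 0.1}
detected:    {'A': True, 'B1': True, 'B2': True, 'D': True}
categories:  {'A': 'dominant', 'B1': 'intermediate', 'B2': 'intermediate', 'D': 'intermediate'}
cfu_class: intermediate | diversity: high | enterocolitype: E3
```

Reading: 60% of this pig's *E. coli* belong to phylogroup A (one third of
it the A1 subgroup), A is the dominant group, all four groups are
detectable (high diversity), the load sits in the 10⁶–10⁷ CFU/g class, and
an A-dominated animal community is enterocolitype E3 — the pattern typical
of omnivorous farm animals.

Virulence scoring of the reconstructed strain panel:

```python
from colitype import reconstruct_panel, group_prevalence, compare_prevalence
table = group_prevalence(reconstruct_panel("animal"))
# n = 13, mean VF score = 6.38, sd = 4.91
compare_prevalence((29, 30), (6, 13)).exact_p   # usp, human vs animal: 3.64e-04
```

The mean virulence score of the animal B2 strains is 6.38 of 20 genes, and
the *usp* gene (29/30 human carriers vs 6/13 animal) differs between hosts
at exact p = 3.6e-4.

## Command line

```bash
colitype run-all --seed 42 -o out/      # simulate → quantify → classify → CA → VF report
colitype simulate -o out/ --seed 42     # or run the stages separately,
colitype quantify --qpcr out/qpcr.tsv --out out/profiles.tsv
colitype classify --profiles out/profiles.tsv --hosts out/hosts.tsv
colitype ca --indicator indicator.tsv
colitype vf-report                      # defaults to the packaged strain panel
```

On the default five-template cohort with `--seed 42`, the run log reports
a 13-axis correspondence analysis whose F1–F2 plane carries 47.0% of the
total inertia, and `vf_report.tsv` contains the per-gene prevalences,
pairwise exact/χ² p-values and the group mean scores (6.38 for the animal
panel).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete pipeline from scratch on a synthetic cohort (100
samples per enterocolitype) plus the reconstructed strain panel, checks
that every stage produced its output, and writes the results JSON.  The
scientific acceptance checks themselves (published worked example,
chi-square identity of the CA, quantification invariants, enterocolitype
recovery, exact-test enumeration, rank-test calibration) live in
`tests/test_acceptance.py`.

See `docs/methods.md` for the model, parameter defaults and limitations.
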