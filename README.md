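# mmclock

Molecular-clock timing and whole-genome profiling of myeloma precursor
conditions (MGUS / smoldering myeloma) versus multiple myeloma.

## The problem

Clinically, precursor plasma-cell conditions are graded by disease burden,
which predicts progression poorly in low-burden patients. Whole-genome
sequencing offers a different axis: *when* the founding chromosomal gains
were acquired and *which* myeloma-defining events (APOBEC mutagenesis,
chromothripsis, templated insertions, recurrent CNVs and SV hotspots) are
already present. `mmclock` implements that analysis chain for people who
have somatic calls in hand — SNVs with allelic depths (VCF), clonal
allele-specific copy-number segments (Battenberg-like TSV), SVs (BEDPE) —
and want per-patient timing estimates plus cohort-level comparisons. A
fully ground-truthed synthetic cohort generator is included, so every
estimator can be validated end to end.

## The model

A clonal SNV acquired before a single-allele gain is carried by both copies
of the duplicated allele (multiplicity m = 2); later mutations, or those on
the untouched allele, have m = 1. With purity ρ, cancer cell fraction `ccf`
and tumor/normal local copy numbers n_t / n_n, the expected VAF is

    E[VAF] = ρ · m · ccf / (ρ · n_t + (1 − ρ) · n_n)

(2/3 vs 1/3 for duplicated vs non-duplicated clonal mutations in a pure
trisomic region). Multiplicity is called per mutation by a binomial
likelihood test; clonal vs subclonal status by a binomial mixture over CCF
with BIC model selection. For a gain at relative molecular time t in (0,1]
of the clone's lifetime, counting duplicated (N2) and non-duplicated (N1)
clonal mutations gives

    trisomy-like (2,1):  t = 3·N2 / (N1 + 2·N2)
    CN-LOH       (2,0):  t = 2·N2 / (N1 + 2·N2)

with tetrasomies excluded as untimeable, segments filtered to > 1 Mb and
> 50 clonal mutations, and 95% CIs from a 1000× mutation bootstrap. Gains
whose CIs mutually overlap form one multi-gain event; restricting the
counts to the clock-like SBS1+SBS5 burden (weighting each mutation by its
signature posterior) converts the earliest event's molecular time to a
patient age: `age ≈ t_clock × age_at_sampling`.

Signature exposures are maximum-likelihood multinomial fits (EM) with
mmsig-style backward elimination (SBS1/SBS5 protected, SBS2/SBS13 moved
jointly); APOBEC activity is summarized by the SBS2+SBS13 fraction and the
APOBEC3A:3B-discriminating YTCA:RTCA ratio at tCa motifs. Chained SVs are
classified as chromothripsis / templated insertion / chromoplexy / single
by their copy-number footprints, and cohort contrasts use pairwise Wilcoxon
rank-sum tests with BH-FDR, two-sided Fisher's exact tests, and OLS
regression.

## Worked example

Run the default synthetic cohort (15 stable, 17 progressive, 20 MM) through
the full pipeline:

```bash
mmclock run-all --seed 0 --outdir cohort_run
```

which prints (abridged):

```json
{
  "median_burden":   {"stable": 3533.0, "progressive": 5652.0, "MM": 6036.0},
  "median_gain_age": {"stable": 51.8,   "progressive": 22.9,   "MM": 21.8},
  "apobec_detected": {"stable": 0,      "progressive": 17,     "MM": 20},
  "sv_event_counts": {"single": 194, "chromothripsis": 37,
                      "templated_insertion": 37, "chromoplexy": 20,
                      "complex_unclassified": 2},
  "filters": {"gains_excluded": {"segment_too_short": 125,
                                 "too_few_clonal_mutations": 7,
                                 "tetrasomy": 5}}
}
```

Reading this: the simulated stable precursors carry fewer SNVs, show no
APOBEC activity or complex SVs, and their founding multi-gain events are
timed to a median patient age of ~52 years versus ~22–23 in the progressive
and MM groups — the late-initiation pattern that separates stable from
progressive disease. Per-gain timing with CIs is in
`cohort_run/gain_timing.tsv`, per-patient age estimates in
`cohort_run/multigain_windows.tsv` (e.g. sample SIM001, stable: age
estimate 61.6 years, 95% CI [57.3, 65.6], sampled at 72), and all pairwise
group tests in `cohort_run/comparisons.tsv`.

Other subcommands (`simulate`, `clonality`, `fit-signatures`, `time-gains`,
`classify-sv`, `compare-groups`) expose single stages; `--config` accepts a
YAML file mirroring `RunConfig`.

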