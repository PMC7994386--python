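# Methods

## Scope and data model

`mmclock` consumes somatic calls, not reads: biallelic SNVs with per-sample
allelic depths (VCF), clonal allele-specific copy-number segments
(tab-separated, Battenberg-like; column mapping configurable), structural
variants (BEDPE) and per-sample metadata (purity ρ, age at sampling,
clinical group, optional bone-marrow plasma-cell %). Internally all
coordinates are 1-based inclusive; BED/BEDPE are converted at the boundary.
Trinucleotide contexts are collapsed to the pyrimidine strand into the
96-class catalog order used by COSMIC-style signature tables; a
pentanucleotide (the two 5′ bases) is retained for APOBEC context analysis.
Sex chromosomes are parsed but excluded from gain timing by default because
their copy-number baseline is ambiguous.

## Multiplicity and clonality

The expected VAF of a mutation on m of n_t tumor copies at cancer cell
fraction `ccf` is ρ·m·ccf / (ρ·n_t + (1−ρ)·n_n). Multiplicity in gained
segments (major copy number 2) is called by comparing binomial likelihoods
of the observed alt count under the clonal m = 1 and m = 2 expectations
with equal priors; exact ties go to m = 1, which can only understate the
duplicated count and therefore biases timing late rather than early.
Mutations outside any segment are flagged and excluded downstream, with
counts logged.

Clonal/subclonal separation uses a finite binomial mixture over CCF fitted
by EM for K = 1..4 with BIC selection. This is a deliberate, deterministic
simplification of Dirichlet-process clustering: the downstream timing and
signature steps only consume the clonal/subclonal split, not the cluster
posterior. The M-step solves the per-cluster CCF score equation exactly by
bisection, so the EM log-likelihood is monotone and non-convergence is a
hard error. A cluster is clonal when its center is ≥ 0.85 CCF — a declared
threshold chosen to tolerate binomial noise at ~40× coverage; it is
surfaced in `RunConfig`, not hard-coded into results. As a cross-check, the
purity implied by clonal diploid heterozygous mutations (2 × median VAF) is
compared with the supplied ρ and flagged when they differ by > 0.1, rather
than silently reconciled.

## Gain timing

For a single-allele gain at relative molecular time t with per-allele
mutation mass μ on the segment, the expected duplicated/non-duplicated
clonal counts are E[N2] = μt with E[N1] = μt + 3μ(1−t) (trisomy-like 2:1)
or E[N1] = 2μ(1−t) (copy-neutral LOH 2:0), inverting to t = 3N2/(N1+2N2)
and t = 2N2/(N1+2N2). Estimates are clamped to [0,1] with an audit flag
(sampling noise can push the ratio past 1) instead of being rejected.
Tetrasomies (2,2) are excluded: the order of the two gains is
unidentifiable. Segments must be > 1 Mb with > 50 clonal mutations (both
strict); every exclusion carries a recorded reason.

Confidence intervals are 2.5/97.5 percentiles over 1000 bootstrap
resamples of the segment's clonal mutations. For unweighted counts the
resampled duplicated count is drawn as Binomial(n, N2/n) — the exact
distribution of the count under index resampling — which keeps the
cohort-scale bootstrap cheap; weighted (clock) bootstraps resample indices
explicitly.

Gains are merged into multi-gain windows by a greedy ascending-t scan in
which a gain joins the current window only if its CI overlaps every
member's CI. The threshold-free overlap rule was chosen over k-means on t
because it is auditable; the window with the smallest mean t is the
earliest event. For absolute conversion, each member mutation is weighted
by its posterior of arising from SBS1 or SBS5 given the fitted exposures
(soft weighting has lower variance than hard assignment), the weighted
counts are pooled across members, and the clock time is converted as
age = t_clock × age_at_sampling — assuming a constant SBS1+SBS5 rate from
birth to sampling, with no in-utero/childhood rate correction. Windows
pooling mixed gain classes combine per-member clock times by a
(W2+W1)-weighted mean and are flagged. Windows with ≤ 50 weighted clock
mutations are never converted to ages. Absolute-age CIs bootstrap the
member mutations 1000×.

## Signature fitting and APOBEC

Per-sample 96-context catalogs are fitted against a signature reference by
multinomial EM (uniform initialization, tolerance 1e−8, cap 10 000
iterations; fully deterministic). The default model is {SBS1, SBS2, SBS5,
SBS8, SBS9, SBS13, SBS18}. Backward elimination removes, repeatedly, the
lowest-contributing removable signature whose removal costs < 0.01
reconstruction cosine similarity; SBS1/SBS5 are always retained and
SBS2/SBS13 are removed or kept jointly, since APOBEC is one biological
process. "Detectable APOBEC activity" is defined as a positive SBS2+SBS13
fraction after elimination — a declared gate, not a reconstruction of any
particular significance test. The APOBEC3A:3B ratio counts C>T and C>G
mutations at tCa motifs split by the 5′−2 base (YTCA vs RTCA) and is
undefined — not zero — when no RTCA mutations exist or APOBEC is
undetected.

The bundled signature reference is synthetic: deterministic 96-context
profiles reproducing each signature's identifying shape (CpG-deamination
peaks for SBS1, TpC peaks for SBS2/13, a flat clock-like SBS5, C>A-dominated
SBS8/18, T-substitution-rich SBS9). Real COSMIC-format TSVs are accepted
via `read_signatures` / `RunConfig.signature_file`.

## Structural variants

Breakpoints within 1 Mb on a chromosome, or sharing an SV, are chained into
components (union-find). Multi-SV components are classified in a fixed
cascade — chromothripsis (≥ 10 breakpoints on one chromosome, total-CN
states between breakpoints oscillating among ≤ 3 values with ≥ 6 switches),
then templated insertion (translocation chain/cycle across ≥ 2 chromosomes
with every bounded segment a focal gain < 5 Mb above its flanks), then
chromoplexy (≥ 2 chromosomes, junction-adjacent CN loss, no gains), else
`complex_unclassified`; the cascade order puts the most specific footprint
first so overlapping evidence resolves deterministically. All thresholds
are declared defaults calibrated on the synthetic benchmark — the
footprints themselves are qualitative — and are exposed in `SVThresholds`
and logged. Missing segment coverage at a junction marks the call
incomplete rather than failing it. Hotspot annotation takes a user-supplied
interval list (a 69-interval synthetic stand-in catalog, with the
field-standard locus names, ships for the simulator); breakpoint density
counts each patient at most once per 1 Mb bin.

## Cohort statistics

Pairwise Wilcoxon rank-sum tests use exact enumeration when both groups
have n ≤ 25 and no ties, else the tie-corrected normal approximation —
reproducing the default behavior of R's `pairwise.wilcox.test` — with
Benjamini–Hochberg adjustment across the pairs of one feature. Fisher's
exact test is two-sided by the point-probability convention (the R
convention, as implemented in `scipy.stats.fisher_exact`). CNV prevalence
contrasts call a sample gained/lost per interval from clonal total copy
number vs 2 (subclonal CNVs are out of scope) and BH-adjust across
intervals that show the aberration at least once; silent intervals are
flagged and excluded from the family. Burden regression is ordinary least
squares with the two-sided slope t-test.

## Synthetic cohort generator

The generator is first-class, tested code that emulates the statistical
structure the analyses assume, with full ground truth: whole-chromosome
gains placed at known molecular times with Poisson mutation counts from the
allele bookkeeping above; contexts drawn from exposure-weighted signature
profiles (APOBEC tCa mutations carry a configurable YTCA:RTCA generation
odds); one subclone at CCF 0.35 (default 25% of the clonal burden) to
exercise the clonal/subclonal split; depth ~ Poisson scaled by local copy
number and purity with binomial alt counts; and complex SVs injected as
minimal canonical footprints (oscillating-CN shattering, gained
translocation cycles, loss-flanked balanced chains) on chromosomes without
timed gains. Records are emitted on a random reference strand so strand
collapse is exercised. Output is bit-reproducible given the seed, and every
pipeline stage draws from a named substream of the run seed.

Default cohort conditions: 15 stable patients (gain time t ~ U(0.75, 0.95),
no APOBEC, 39 SBS1+SBS5 mutations/year/diploid genome), 17 progressive
(t ~ U(0.2, 0.6), APOBEC at ~1:1 YTCA:RTCA, clock yield 48) and 20 MM
(t ~ U(0.15, 0.5), clock yield 48, fuller SV menu). Clock yields were set
so that total burdens land near the observed group medians (~3.4k/5.5k
SNVs); ages are uniform on 45–75 years in all groups (age at sampling does
not separate the groups — the timing does); purity U(0.65, 0.95) and 40×
coverage reflect typical flow-sorted precursor genomes. The per-year
SBS1+SBS5 yield is otherwise a power parameter, not a biological estimate.

What the simulation does *not* model — and what passing tests therefore do
not show about real data: mutation-rate acceleration over life,
subclonal copy number, germline variation, caller artifacts, kataegis,
multi-sample phylogenies, or realistic SV breakpoint microhomology. The
generator validates the estimators under their own assumptions; it cannot
validate the assumptions.

## Problem sizes and numerics

The test suite validates estimator recovery at the scale the statistics
need rather than full genomes: the timing grid uses 50 replicates per
(gain class, t) with ≥ 1500–2000 segment mutations; absolute-age recovery
uses 50 replicate patients at 60× coverage with > 200 clock mutations per
window; group separation runs the full 52-sample default cohort; SV
recovery uses 50 patients with one injected event of each complex type.
Bootstraps are 1000× throughout, as in the analysis itself. EM tolerances:
1e−8 relative log-likelihood for both the signature fit and the clonality
mixture (the latter errors out rather than returning an unconverged model).
Degenerate inputs are defined behavior: empty catalogs, zero-mutation
segments and empty SV sets raise or return empty structures; Fisher tables
with degenerate margins return p = 1 with a flag.
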