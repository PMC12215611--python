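# Methods

`plantfit` reimplements, as a tested pipeline over synthetic data, the
computational analysis of a barcoded transposon (TnBarSeq) colonization
screen: a mutant library of a plant-colonizing bacterium is inoculated
into soil at sowing, plants grow for weeks, and barcode amplicon
sequencing of soil, root and shoot samples reveals which gene disruptions
change a mutant's relative abundance in each habitat. Downstream stages
cover efflux-pump ortholog clade calling across genomes, recombinant
inbred line (RIL) linkage mapping of a plant-derived antibacterial, a
combinatorial glucosinolate breakdown rule model, and dose-response /
expression assay computations.

## The generative model (synthetic_data)

The generator produces inputs with the statistical structure the analysis
assumes; it is the ground truth for every recovery test.

* **Library.** Each of `n_genes` genes receives a Poisson number of
  unique 20-mer barcodes (default mean 8.5 insertions per gene, matching
  the screen this emulates; recovery benchmarks use 5 to match their
  stated problem size), at positions uniform in the central 10–90% of the
  gene body. A 5% fraction of barcodes is intergenic (no locus tag).
  Inoculum abundances are lognormal with log2-sd 1.0 — the screen does
  not report an abundance distribution, so a one-decade spread typical of
  saturated transposon libraries is used.
* **Counts.** Soil samples are multinomial draws (depth
  `read_depth`, default 100,000) from the inoculum times
  `2**soil_effect`. Plant samples model the colonization founder
  bottleneck: `bottleneck_founders` barcodes are sampled without
  replacement weighted by inoculum, grown deterministically by
  `2**habitat_effect`, then sequenced multinomially. The bottleneck is
  the simplest mechanism that yields a different starting population on
  each plant sample; it is off (`None`) by default and in the recovery
  benchmarks, which quantify the no-bottleneck regime the regression is
  calibrated for.
* **Design.** Five habitats (soil, At_root, At_shoot, Bd_root,
  Bd_shoot), with auxiliary-community inoculation, harvest day (1/2) and
  growth flat as covariates. `make_design` alternates covariates within
  habitat so they are estimable in every contrast.
* **RILs.** Five chromosomes, Poisson(`recomb_per_chrom`, default 1.5)
  crossovers per chromosome at uniform positions, homozygous Col/Ler
  genotypes (residual heterozygosity ignored), 98 lines by default.
  Phenotypes are computed by the glucosinolate rule engine from the three
  causal loci (ESP-like on chromosome 1, AOP3-like on 4, MAM-like on 5).
* **Protein family.** All sequences mutate from one ancestral peptide
  (length 500 — real RND inner-membrane subunits run ~1000 residues;
  500 keeps pairwise alignment cheap while leaving per-branch
  substitution counts realistic). Background members diverge
  independently at rate 0.4; the designed clade descends from a clade
  ancestor (itself at background-level distance) and splits into two
  anchor-headed lineages, so the anchors' MRCA is the clade root — as
  for the two functionally tested genes, which come from different
  genera on opposite sides of the real clade. Within-clade divergence
  defaults to 0.05: each internal branch then carries enough
  substitutions (~12 over 500 aa) to be resolvable; with much shorter or
  shallower clades the designed topology is not identifiable by any
  distance method.
* **Dose-response.** OD(c) = top / (1 + (c/IC50)^hill) plus Gaussian
  noise (sd 0.02, four replicates, 1.5-fold dilution series), floored at
  zero.

What the generator does **not** emulate: PCR/sequencing error in barcodes
(counting is exact-match), chimeric reads, index hopping, compositional
interactions between samples, real genome sequence, selection during the
8-hour enrichment culture, and 16S community structure. Passing recovery
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to those artifacts.

## Barcode quantification

Extraction takes, per read, the 20 bases after the first exact occurrence
of a 6-nt anchor (configurable; no mismatch tolerance, since the upstream
protocol defines the anchor exactly); reads without a complete barcode
are counted as discarded. Counting is exact matching against the mapping
table. The usability filter keeps barcodes that map within a gene,
centrally (10–90% of the gene body), with mean raw soil count ≥ 3 —
the conventions of established barcode-fitness pipelines.

## Fitness scores

Soil is the T0-like reference: the reference profile is the mean of
depth-normalized soil counts. Strain fitness is
`log2((n + 1) / (depth * ref + 1))` (pseudocount configurable). Gene
fitness is an inverse-variance weighted mean over member strains with
Poisson-motivated weights `w = 1 / (1/(1+n) + 1/(1+depth*ref))`, followed
by per-sample median centering (exactly zero median by construction).
Median centering replaces chromosome-position smoothing: the simulated
genome is a single replicon and position effects are out of scope. Soil
samples score near zero but keep their between-sample variance, which the
regression uses. The reference is the global soil mean; a per-flat
reference is a documented option of the design, not implemented here.

## Differential fitness

Per gene and per plant habitat:

    Fitness ~ Sample_type + Auxiliary_community + Harvest_day + (1 | flat)

fit by maximum likelihood (statsmodels MixedLM, Powell optimizer — chosen
for speed and convergence robustness on small per-gene datasets). The
Sample_type coefficient is the log2 fold change. The p-value is a
likelihood-ratio test against the model without Sample_type (χ², 1 df),
avoiding denominator-df approximations; when the estimated flat variance
is at the zero boundary (≤ 1e-8) the model degrades to OLS and the
coefficient t-test, which for balanced two-group data without covariates
equals the pooled t-test. Constant covariates are dropped with a log
entry; genes with fewer than two samples per group are skipped, not
silently dropped.

Genes whose residuals reject Shapiro–Wilk normality (p < 0.05) in **any**
contrast are omitted globally (`omitted_nonnormal`). Note the gate's
cost: with four contrasts at level 0.05 it removes roughly 15–18% of
genes even under perfectly Gaussian noise; this bounds the achievable
end-to-end sensitivity of the pipeline at about 0.82–0.85 regardless of
effect size.

Benjamini–Hochberg adjustment is applied within each contrast across
retained genes. Classification: `association` (q < 0.05, log2FC < −1;
mutant depleted in planta, i.e. the intact gene benefits association),
`negative_association` (q < 0.05, log2FC > 1), else `indifferent`.
Fitting is per contrast (habitat vs soil), matching per-contrast
volcano-style reporting.

## Specificity and enrichment

From the four contrasts, each gene gets an association habitat set and a
negative set, each classified as: `general` (all four), `host_specific`
(both organs of one host), `organ_specific` (one organ in both hosts),
`single_habitat`, `mixed` (any other multi-habitat pattern — needed for a
total classification), or `none`. Upset counts partition genes by exact
intersection pattern per direction. COG-category enrichment uses the
two-sided Fisher exact test per category against the annotated genome
background with BH adjustment across categories; Fisher was chosen
because the comparison is a descriptive 2×2 contrast and no test is
prescribed by the upstream analysis.

## Efflux-pump clade calling

Family selection by functional tag (default COG0841, the RND efflux pump
inner-membrane subunit, which determines substrate specificity). Pairwise
global alignment (Biopython PairwiseAligner) with BLOSUM50 and affine
gaps (open 10, extend 1 — conventional defaults, configurable) gives
scores `S_ij`; dissimilarity `d = 1 − S_ij / min(S_ii, S_jj)` is 0 for
identical sequences and scale-free; it can exceed 1 for very dissimilar
pairs and is not clipped. Neighbor joining is implemented in-package for
determinism: Q-criterion ties break on the lexicographically smallest
cluster-id pair (a cluster is named after its smallest leaf) and negative
limb lengths truncate to zero; additive matrices are reproduced exactly
(path lengths to 1e-9). The unrooted tree is midpoint-rooted (no rooting
method is prescribed upstream; midpoint is the assumption-free default),
and the clade is all leaves under the MRCA of the anchor genes. Prevalence
is the fraction of genomes per taxonomic class with ≥ 1 member; copy
number is members per genome.

## Host genetics

The glucosinolate rule engine maps the 2×2×2 allelic states of ESP
(breakdown moiety), MAM (chain length) and AOP3 (side-chain
hydroxylation) to eight breakdown products. Hydroxyl isothiocyanates are
reported as their spontaneous cyclization products (3C →
1,3-Oxazinane-2-thione; 4C → 1,3-Oxazepane-2-thione). Toxicity classes:
all four nitriles non-toxic; 4MSO-ITC (sulforaphane), 3MSO-ITC (iberin)
and 1,3-Oxazepane-2-thione toxic to the efflux-pump deletion mutant only
(`d90_toxic`); 1,3-Oxazinane-2-thione toxic to wild type as well
(`WT_toxic`). Parental genotypes reproduce the parental chemotypes
(Col-0 → 4MSO-ITC, Ler-1 → 3OHP-Nitrile).

The RIL scan computes, per phenotype group and marker, the Ler-allele
fraction among non-missing lines (missing calls are excluded) with a
two-sided exact binomial test against 0.5. Candidate intervals are
maximal within-chromosome runs of ≥ 2 consecutive markers deviating from
0.5 by ≥ 0.25; the run-based caller and the binomial test are supplied as
documented plumbing — the upstream analysis plots fractions without a
stated significance procedure.

## Assay models

The Hill fit fixes the lower asymptote at zero (full inhibition);
initialization: top = max OD, IC50 = dose nearest half-max, Hill slope 1,
parameters bounded positive; 95% confidence intervals are Wald intervals
from the coefficient covariance; MIC is defined as the fitted IC50. A fit
with no decrease from lowest to highest dose is flagged non-identifiable.
−ΔΔCt is exact arithmetic. The growth endpoint is the first time the
no-plant control reaches 90% of its maximum OD (step-function lookup, no
interpolation); a well's background is its fifth-smallest OD (plant
material absorbance decays, so the first reading would over-subtract),
and final OD is the endpoint reading minus background.

## Benchmarks and problem sizes

`plantfit.benchmarks` packages the recovery experiments used by the test
suite and `scripts/acceptance.py`:

* differential-fitness recovery: 500 genes × ~5 barcodes, 4 habitats × 6
  samples + 6 soil, 30 genes at effect −2 in At_shoot, pooled over 8
  independent replicate simulations (~8 min on one core);
* global-null calibration on the same design (one replicate);
* 50 random additive trees (≤ 8 taxa) for the NJ oracle;
* 20 protein-family seeds for clade recovery;
* 100 RIL populations for causal-locus localization, plus a 200-line
  neutral population;
* 100 noisy dose-response fits for IC50 recovery;
* an exact FASTQ → extract → count round trip (60 genes, 3 samples).

These sizes keep a full run within minutes on one core while leaving the
binomial standard errors of the reported rates a few percent.

## Known limitations

* Exact-match barcode counting will undercount if reads contain
  sequencing errors; no error correction is attempted.
* The mixed model treats soil both as fitness reference and as regression
  comparison group, so soil residual variance enters twice in spirit;
  this mirrors the upstream design but slightly couples the contrasts.
* Shapiro–Wilk on ≤ 12 conditional residuals has limited power against
  mild non-normality and, as noted, a fixed false-omission cost.
* Wald confidence intervals for the Hill IC50 can undercover when the
  dose grid poorly brackets the transition; profile likelihood is not
  implemented.
* The NJ implementation is O(n³) in pure numpy loops — fine for hundreds
  of sequences, not for tens of thousands.
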