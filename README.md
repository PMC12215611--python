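# plantfit

Analysis pipeline for barcoded transposon (TnBarSeq) colonization screens
of plant-associated bacteria, plus the downstream genetics of one of their
fitness factors: an antimicrobial-exporting efflux pump.

## The problem

A randomly barcoded transposon mutant library of a plant-colonizing
bacterium is inoculated into soil at sowing; after weeks of growth, soil,
root and shoot samples of two host plants (*Arabidopsis thaliana* and
*Brachypodium distachyon*) are sequenced for barcode abundance. Genes
whose mutants are depleted in a plant habitat relative to soil are
*plant-association genes* (the intact gene benefits colonization); genes
whose mutants are enriched are *negative* association genes. Most such
genes turn out to be host- and organ-specific, and among them are RND
efflux pumps that detoxify host defense chemistry — in *Arabidopsis*
shoots, glucosinolate breakdown products such as sulforaphane.

`plantfit` implements the full computational chain for this kind of
study, with a synthetic-data generator standing in for raw sequencing
data:

1. **barcode_quant** — anchor-based barcode extraction from FASTQ,
   exact-match counting against a mapping table, usability filtering.
2. **fitness_scores** — strain fitness `log2((n+1)/(depth·ref+1))`
   against the mean depth-normalized soil reference; gene fitness as an
   inverse-variance weighted mean over strains, median-centered per
   sample.
3. **differential_fitness** — per gene and habitat, the mixed model
   `Fitness ~ Sample_type + Auxiliary_community + Harvest_day + (1|flat)`
   with a likelihood-ratio test for the Sample_type coefficient
   (log₂FC), a Shapiro–Wilk residual-normality gate, Benjamini–Hochberg
   FDR per contrast, and classification at q < 0.05 and |log₂FC| > 1.
4. **specificity_enrichment** — cross-habitat specificity classes
   (general / host-specific / organ-specific / single-habitat / mixed),
   upset intersection counts, Fisher-exact COG enrichment.
5. **pump_clade** — protein family selection by functional tag
   (COG0841), BLOSUM50 global-alignment dissimilarity
   `d = 1 − S_ij/min(S_ii,S_jj)`, deterministic neighbor joining,
   midpoint rooting, MRCA-of-anchors clade calling, per-class prevalence
   and per-genome copy number.
6. **host_genetics** — the combinatorial glucosinolate rule engine
   (ESP × MAM × AOP3 → 8 breakdown products → 3 toxicity classes) and a
   RIL Ler-allele-fraction linkage scan with exact binomial tests and a
   run-based interval caller.
7. **assay_models** — decreasing Hill dose-response fits (MIC ≡ IC50,
   Wald 95% CIs), −ΔΔCt relative expression, growth-curve endpoint and
   background rules.
8. **synthetic_data** — generators for all of the above: Poisson
   insertions per gene, lognormal inoculum, per-plant founder
   bottlenecks, multinomial sequencing, five-chromosome RIL populations,
   protein families with a designed clade, and Hill-shaped dose-response
   tables.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Simulate a small screen, score fitness, and test one contrast:

```sh
plantfit simulate barseq --seed 3 --out-dir demo --n-genes 80 \
    --read-depth 40000 --n-per-habitat 4 --n-soil 4
plantfit fitness --counts demo/counts.tsv --map demo/mapping.tsv \
    --design demo/design.csv --out demo/fitness.tsv
plantfit test --fitness demo/fitness.tsv --design demo/design.csv \
    --contrasts At_shoot --out demo/results.tsv
```

The `test` command prints a run summary like:

```json
{
  "genes_tested": 80,
  "genes_omitted_nonnormal": 8,
  "genes_skipped": 0,
  "calls": {
    "At_shoot": {
      "indifferent": 72,
      "omitted_nonnormal": 8
    }
  }
}
```

Every tested gene is `indifferent` here because the simulation planted no
fitness effects; eight genes were omitted by the residual-normality gate
(its expected false-omission cost at α = 0.05 per contrast). Planting effects via
`plantfit.synthetic_data.TrueEffects` and re-running yields `association`
calls at the planted genes — that recovery experiment is packaged in
`plantfit.benchmarks.recovery_benchmark`.

The glucosinolate rule engine, from the command line:

```sh
$ plantfit gsl --genotype esp=non_functional,mam=MAM1,aop3=inactive
{
  "name": "4MSO-ITC",
  "precursor_chain": "4C",
  "side_chain": "MSO",
  "moiety": "isothiocyanate",
  "cyclized_name": null,
  "toxicity": "d90_toxic"
}
```

i.e. the Col-0 parental genotype produces sulforaphane (4MSO-ITC), which
inhibits the efflux-pump deletion mutant but not the wild type.

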