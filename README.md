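# ssmdep — somatic synonymous mutation depletion at splicing-associated sequence

Tumour genomes are usually read under the assumption that synonymous
somatic mutations (SSMs) are selectively neutral, so their local density
is a fair proxy for the local mutation rate. That assumption fails if
synonymous changes that disrupt splicing are purged by selection inside
the tumour. `ssmdep` implements the analysis that tests this: it
partitions internal protein-coding exons (length L ≥ 160 bp) into two
20 bp terminal **flanks** — enriched for splice-regulatory sequence —
and a 40 bp central **core** anchored at M = ⌊L/2⌋, and asks whether the
SSM rate per bp per tumour is lower at flanks than cores. The same
battery runs on **exonic splice enhancer (ESE)** hexamer regions versus
distance-matched control ("non-ESE") hexamer regions within 69 bp of
exon ends, where non-ESE hexamers are the subset of all 4⁶ = 4096
hexamers at Hamming distance ≥ 2 from every ESE.

The headline estimand is the depletion fraction

```
depletion = 1 − rate(flank) / rate(core)
```

interpreted, when the core rate is taken as the true local mutation
rate, as the share of flank mutational events rendered unobservable by
purifying selection. Per cohort, paired per-tumour flank/core rates are
compared by a Wilcoxon signed-rank test; cohorts are combined by
Fisher's method (χ² = −2Σln pᵢ on 2k df) with a Cohen's *d* over
cohort-level mean rates; pooled densities carry B = 500 percentile
bootstrap CIs; the 5′- vs 3′-flank split uses an exact binomial sign
test. Confounding by mutational heterogeneity is addressed exactly as
in the study design: CpG-dinucleotide masking, six-class
(A>C, A>G, A>T, C>G, C>T, G>T, reverse-complement collapsed)
composition-normalized rates, 96 trinucleotide-context rates, and
covariate strata (nucleosome occupancy and replication-timing
quartiles, oncogene / tumour-suppressor / non-cancer and
essential / non-essential gene classes, MSI status).

Because the consortium call sets behind the original study are not
redistributable, the package ships a first-class synthetic cohort
simulator: multi-exon genes with planted ESE motifs, per-tumour SNVs at
rate μ with optional CpG hypermutability and substitution-signature
skew, and a region-dependent *purge* probability — the selection
coefficient the pipeline must recover. Every stage is validated by
parameter recovery and independent oracles (see `docs/methods.md`).

## Worked example

Simulate a small cohort with 25% flank purging and analyse it:

```
$ ssmdep simulate --out-dir study --seed 8 --n-genes 30 --exons-per-gene 5 \
      --n-tumours 40 --mu 0.006 --purge-flank 0.25 --ese-plant-rate 1.5
wrote study to study: 30 genes, 90 internal exons, 8327 retained mutations
(flank depletion truth: 0.250)

$ cat > config.yaml <<EOF
genome: study/genome.fa
transcripts: study/transcripts.genepred
mutations: study/mutations.maf
ese_hexamers: study/ese_hexamers.txt
out_dir: out
B: 200
seed: 8
EOF

$ ssmdep flank-core --config config.yaml
combined p = 0.00693, depletion = 0.297
```

The simulator purged 25.0% of flank mutations before "calling" them;
the pipeline re-estimates 0.297 from 40 tumours over 90 internal exons
(small-cohort sampling error; the acceptance-scale runs below recover
the planted value to within a percentage point) and the paired Wilcoxon
test rejects the uniform-rate null at p ≈ 0.007. `out/` holds tidy
per-cohort, combined and per-tumour TSVs plus a JSON run log recording
seed and parameters. `ssmdep ese`, `ssmdep strata`, `ssmdep intervals`
and `ssmdep ese-scan` expose the other analyses; the library entry
points live in `ssmdep.depletion`, `ssmdep.strata` and
`ssmdep.experiments`.

## Analysis scripts

The `analysis/` drivers rebuild the full study at scale (640 genes,
2,560 internal exons, 200 tumours per cohort) and write small summary
tables under `results/`:

1. `01_simulate_cohorts.py` — cohorts at purge 0 / 0.1 / 0.2 / 0.3 plus
   an ESE-purged cohort (bulky intermediates under `scratch/sim/`).
2. `02_flank_core_depletion.py` — flank/core battery per cohort.
3. `03_ese_depletion.py` — ESE vs non-ESE battery.
4. `04_covariate_strata.py` — covariate strata on the 0.2 cohort.
5. `05_calibration_and_nulls.py` — type-I calibration and the CpG /
   signature normalization nulls (self-contained).

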