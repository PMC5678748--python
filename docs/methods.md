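# Methods

## The question and the estimand

Internal protein-coding exons carry splice-regulatory information near
their ends: exonic splice enhancers (ESEs) and other splicing signals
concentrate within roughly 70 bp of the exon boundary. If synonymous
somatic mutations (SSMs) that disrupt these signals are deleterious to
the tumour cell, their *observed* density at exon ends will fall below
the local mutation rate. The package contrasts two generative accounts:

* **Selection model** — mutations arise uniformly across the exon; a
  fraction δ of those arising in splicing-associated sequence is purged
  (the cell dies or fails to expand) before variant calling.
* **Mutation model** — no purging; the rate itself varies along the
  exon through composition (CpG content, signature interactions,
  nucleosomes, replication timing, repair).

Under the selection model, with the exon-core rate standing in for the
true rate, the depletion fraction `1 − rate(flank)/rate(core)` is a
direct estimate of δ. The analysis battery exists to measure that
quantity and to exclude the mutation model's composition channels one
at a time.

## Spatial units

For each internal coding exon of length L ≥ 160 bp (inclusive
threshold, exposed as `min_exon`): flanks are the terminal 20 bp
intervals, the core is the 40 bp interval centred on M = ⌊L/2⌋ (integer
centring for odd L: core = [M−20, M+20)). At these defaults the flank
and core footprints are equal (40 bp each per exon), so the two region
classes are size-matched by construction. An `end_exclusion` of 3 bp
trims the terminal bases that carry the canonical splice sites, testing
that the signal is not merely splice-site damage. Flanks are oriented
by transcription direction (`flank5`/`flank3`). Disjointness of flanks
and core is guaranteed for L ≥ 80 and checked.

All internal coordinates are 0-based half-open; 1-based formats (MAF,
genePred-like tables) are converted at the I/O boundary.

## Region annotation by hexamers

The ESE catalogue is a plain hexamer list. Control ("non-ESE")
hexamers are all 4096 hexamers whose minimum Hamming distance to every
ESE is ≥ 2 (aligned positions, no indels; the threshold is a
parameter). Exon coding-strand sequence is scanned for perfect matches
whose start lies within 69 bp of either exon end (`end_window`, after
the observation that splice-affecting mutations concentrate within
~70 bp of exon ends); same-set matches that overlap or abut are merged
into maximal regions, and ESE regions overlapping non-ESE regions are
discarded from **both** sets by default. The symmetric discard is a
deliberate choice: dropping only the ESE side (the asymmetric variant
is available) would leave the contested bases inside the control set
and contaminate it with splice-relevant sequence.

A consequence of the distance construction worth knowing: in random
sequence, ~90% of hexamer windows belong to the control set, so an
*isolated* ESE match is essentially always flanked by overlapping
control matches and is removed by the discard rule. Surviving ESE
regions are therefore motif *clusters* whose overlapping windows are
themselves within distance 1 of the catalogue — which is exactly how
purine-rich ESE families behave in real exons. The synthetic generator
reproduces this by planting motifs inside guard contexts (below).

## Mutation processing

MAF or column-mapped TSV input; only single-nucleotide substitutions
are kept (indels/MNVs dropped and counted). Consequences are either
trusted from the input annotation (`Silent` → synonymous) or recomputed
from transcript models and genome under the standard genetic code,
reverse-complementing codons for minus-strand genes. Substitutions
collapse with their reverse complements into six classes
{A>C, A>G, A>T, C>G, C>T, G>T}; trinucleotide classes add the 5′/3′
reference context, reverse-complementing the whole triplet when the
centre substitution needs collapsing (96 labels). This six-class
convention (A- and C-centred plus G>T) is kept deliberately — the
composition denominators ("number of X plus complement(X) bases") must
match it, and it differs from the pyrimidine-centred convention used
by signature catalogues.

## Densities and normalizations

The density unit is mutations per bp per tumour:
`rate = count / (effective_bp × n_tumours)`. Tumours without any call
in a region contribute explicit zeros (they dilute the cohort mean, as
"per tumour" averaging requires). CpG masking removes every base of a
CG dinucleotide — reading one base of genome context beyond interval
edges, because hypermutability is context-driven, not interval-driven —
from both the numerator and the effective denominator.
Class-normalized rates divide class counts by eligible reference bases;
trinucleotide rates divide by reference-triplet occurrences counted on
both strands. Undefined denominators are reported as missing, never as
zero rates.

## Statistics

* Paired Wilcoxon signed-rank on per-tumour flank/core rates; zeros
  discarded (the R-default policy; Pratt available), exact null for
  ≤ 25 untied differences, tie-corrected normal approximation
  otherwise; all-zero differences give p = 1 by contract.
* Fisher's method across cohorts: χ² = −2Σln pᵢ on 2k df; p = 0 inputs
  are rejected rather than silently clamped.
* Percentile bootstrap CI of the mean per-tumour rate, B = 500,
  seeded generator, no global RNG state.
* Cohen's *d* over cohort-level mean rates (pooled unbiased variances)
  with Var(d) = (nₐ+n_b)/(nₐn_b) + d²/(2(nₐ+n_b)) and a t(nₐ+n_b−2)
  critical value — the convention of the compute.es-style toolchain,
  which yields deliberately wide intervals at small cohort counts.
* Exact binomial sign test for the 5′/3′ flank split (one-sided upper
  tail; two-sided = doubled smaller tail capped at 1).
* Mann–Whitney U for per-interval score comparisons (mappability-type
  covariates): exact tie-aware enumeration for pooled n ≤ 14 —
  written in-package because the common exact implementations assume
  no ties, and the identical-multisets case must return p = 1 —
  otherwise the tie-corrected normal approximation.

## The synthetic cohort generator

What it emulates: multi-exon coding genes (random strand, CDS padded to
codon multiples) separated by introns/intergenic spacers on one contig;
per-site per-tumour mutation probability μ shaped by a six-class
signature (a site's hazard is proportional to the signature mass
applicable to its reference base, normalized so the uniform signature
gives exactly μ everywhere); optional CpG multiplier on both bases of
CG dinucleotides; at most one mutation per site per tumour
(infinite-sites at desk scale); purging as independent thinning with
probability `purge_flank` / `purge_ese` by region (maximum, not
compounding, where both apply) and per-gene-class multipliers (e.g.
tumour suppressors exempt). Purging-by-thinning is exactly the quantity
the depletion fraction estimates, which is what makes planted values
recoverable ground truth.

Defaults are composition-neutral: uniform signature and CpG multiplier
1.0, so the null model has a uniform per-base rate and covariate
fixtures are null by construction. Mutational heterogeneity is opt-in
(the CpG null uses multiplier 10; the signature null uses a C>T-heavy
skew), so each confounder is tested in isolation. The default
μ = 10⁻³–10⁻² per bp per tumour is far above human somatic rates; it is
a desk-scale choice that buys counting resolution on a ~1 Mb genome,
and enters nothing but statistical precision.

Planted ESEs: the synthetic catalogue is the 64 purine hexamers (the
planting alphabet) plus 20 two-cytosine hexamers, 84 in total —
matching the size and purine bias of intersection-style ESE catalogues,
and labelled synthetic throughout. Each planted motif sits inside a
guard template (4 purines + 1 pyrimidine on each side), which makes
every window overlapping the match fall within Hamming distance 1 of
the catalogue; the scan therefore recovers planted motifs instead of
discarding them (see the clustering note above). The simulator's
functional-ESE ground truth for purging is *every* exact catalogue
match in the end zones — planted or arisen by chance — because an
accidental perfect motif is an ESE; the pipeline's resolved regions are
a subset of those bases, which keeps the region comparison unbiased.

What the generator does not model: exome-capture coverage bias,
sequencing error, clonal structure, realistic codon usage or
composition gradients along exons, correlated covariates. Passing
recovery tests therefore demonstrates that the *estimation machinery*
is unbiased and calibrated under the selection model, not that real
tumour data are free of the technical artefacts the original study
addresses with its covariate panels.

## Synonymous opportunity and the consequence filter

Comparing per-bp *synonymous* rates across region classes implicitly
assumes equal synonymous opportunity (the genetic-code probability that
a random substitution is silent) on both sides. Flanks and cores of
motif-free random sequence are opportunity-matched in expectation, so
the flank-recovery and calibration experiments run on synonymous calls
with planting off. Purine-rich ESE regions are not opportunity-matched
to their controls, so the ESE-recovery and signature-null experiments
run the same estimator on all substitutions — the estimator is
consequence-agnostic, and this cleanly separates selection from
code-structure artefacts. The same caveat applies to real data, where
it motivates the composition normalizations. For the same reason the
signature-recovery check tests the class mix of retained core mutations
of all consequences (the generator's invariant) rather than of the
synonymous subset, whose mix is reweighted by the code.

## Problem sizes and calibration results

Chosen once for statistical resolution: recovery runs use 640 genes ×
6 exons (2,560 internal exons, ~102 kb of flank and of core), 200
tumours, μ = 0.01 — about 50,000 retained synonymous core calls, which
puts both the counting error and the per-genome opportunity fluctuation
below one percentage point on the depletion estimate. Type-I
calibration uses 100 cohorts of 50 tumours over a shared
120-internal-exon genome. At these sizes the pipeline recovers planted
purge strengths 0/0.1/0.2/0.3 to within a point, the ESE purge 0.25 to
within half a point, and rejects the null in ~4–6% of null cohorts at
α = 0.05 — numbers recomputed on every run of `scripts/acceptance.py`
and asserted (with their tolerance bands) in `tests/test_acceptance.py`.

## Numerical conventions and degenerate inputs

Quantile strata use linear-interpolation quantiles with ≥/≤ boundary
rules (exons on both boundaries are dropped with a warning); all-equal
scores are an error rather than an arbitrary split. Genes annotated as
both oncogene and tumour suppressor are excluded from the cancer-class
split to avoid double counting. Overlapping region roles are a hard
error (region construction guarantees disjointness; counting refuses to
guess). Contig-edge trinucleotide contexts and N-containing windows are
excluded and logged. All stochastic components take explicit seeds;
identical seed and inputs give byte-identical outputs.

## Known limitations

Single canonical transcript per gene (overlapping isoforms are out of
scope); annotation-mode consequence filtering trusts the caller's
Silent flag; trinucleotide denominators count reference-triplet
occurrences (an alternative reading — plain bp — would rescale rates
class-uniformly); bigWig-style covariates must arrive as per-base or
per-exon TSV. The Fisher-combination of per-cohort Wilcoxon p-values
treats cohorts as independent, which the simulator satisfies by
construction and real cohorts only approximately.
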