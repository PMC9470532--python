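# Methods

This note documents the statistical models implemented in `stemvar`, the
defaults and why they were chosen, what the synthetic data emulate, and
the limits of what passing tests demonstrate.

## Paired somatic calling

At every candidate site the caller tests the 2×2 contingency table

```
              ref reads   alt reads
parent        p_ref       p_alt
derived       d_ref       d_alt
```

with a two-sided Fisher exact test (one-sided derived-enrichment is
available behind `CallerConfig.two_sided=False`).  The test is symmetric
in the two samples on purpose: unlike tumour–normal callers, it does not
assume the variant is absent from the "normal" — parental fibroblast
populations are oligoclonal and many derived-line mutations are present
at low frequency in the parent.  A consequence worth knowing: mutations
*lost* through the reprogramming bottleneck (parent subclone mutations
not inherited by the derived clone) are also significant allele-frequency
changes and appear in the call set; consumers interested only in
mutations the derived line carries should filter on `derived_vaf`
(the pipeline's sister-pair comparison filters at `derived_vaf ≥ 0.2`).

Prefilters: germline-flagged sites are dropped (the population-frequency
lookup of real pipelines is abstracted to a boolean input flag); depth
(ref+alt) must be ≥ 20 in both samples and alternate support ≥ 3 reads in
at least one sample.  Low-coverage sites could never reach significance,
and excluding them keeps the multiple-testing burden honest.

Multiple testing uses Benjamini–Hochberg step-up control at FDR 0.05 over
the whole tested batch (one genome-wide correction, not per sample).  The
reported threshold is the largest p(k) with p(k) ≤ (k/m)·fdr; ties at the
threshold are all called.

Postfilters: calls above 0.6 alternate allele fraction in either sample
are removed (enriched for germline leakage and artifacts), as are sites
flagged by low-mappability or copy-number masks.  VAF is computed as
alt/(ref+alt).  Note the postfilter trades a predictable amount of
sensitivity for specificity: at Poisson(60) depth about 5.8% of true
clonal heterozygous sites fluctuate above VAF 0.6 and are removed, which
is why the recovery suite measures detection sensitivity at the
significance stage and treats the VAF filter as a specificity device.

Runs of immediately adjacent calls are merged: length 2 becomes a DBS
record with concatenated alleles (CC>TT), length ≥ 3 a single MNV record
(a conservative extension of the dinucleotide rule; MNVs are excluded
from catalogs together with DBS).  A call is *shared* with the parent
when the parent sample has at least one alternate read at the site, else
*private*.  With a per-base error rate e and depth d, a fraction
1−(1−e)^d of truly private sites will draw a stray parent read and be
labelled shared (≈ 6% at e = 10⁻³, d = 60); this is inherent to the
read-level definition, not a defect.

## Mutational signatures

Catalogs are 96-channel single-base-substitution counts: six
pyrimidine-oriented substitution classes × 16 trinucleotide contexts,
channels ordered (C>A, C>G, C>T, T>A, T>C, T>G) × contexts in
lexicographic order.  Purine-reference mutations are reverse complemented
(mutation and context together) before binning; the orientation is an
involution, and the catalog total equals the oriented SNV count.

Exposures solve the non-negative least squares problem
min ‖c − M·e‖₂, e ≥ 0 with the reference matrix M column-stochastic.
Bootstrap stabilisation resamples the catalog multinomially (preserving
the total count) `n_boot = 100` times and refits; a signature is stable
when its exposure exceeds `min_fraction = 0.05` of the total in at least
95% of refits.  Unstable exposures are set to zero and the catalog refit
over the stable set, so the final exposures remain an NNLS optimum.
These defaults are stated, configurable stand-ins — reference fitting
packages defer to their own defaults, which are not asserted here.

The packaged reference set (`fallback_signatures()`) is synthetic: a
UV-like column (C>T concentrated at TCA/TCC/TCT, COSMIC-signature-7
style), an oxidative column (C>A at ACA/GCA/GCT, signature-18 style) and
a flat background.  It exists so tests and synthetic pipelines run
without downloads; real analyses should load a published signature
matrix via `read_signatures_tsv` and name the UV members to aggregate
(`uv_total` sums them).

## Clonality deconvolution

Sample VAFs are smoothed with a Gaussian kernel on a grid of step 0.002
over [0, 1].  Mass outside the interval is reflected at both boundaries
(density(x) = K(x) + K(−x) + K(2−x)), which removes the edge bias that
would otherwise depress the near-zero neutral-tail peak.  Bandwidth
defaults to Silverman's rule 0.9·min(sd, IQR/1.34)·n^(−1/5), floored at
10⁻³ so degenerate (all-equal) inputs remain well defined; fewer than 10
mutations are refused.

Every interior local maximum defines a cluster; membership is the set of
mutations between the flanking local minima (with 0 and 1 closing the
outer clusters), and clusters holding < 10% of mutations are dropped.
Under the diploid, copy-neutral, heterozygous model a cluster at mean
VAF v corresponds to a subclone occupying min(1, 2v) of the population —
VAF 0.25 means half the population; VAF 0.5 means clonal.

Classification excludes the neutral-tail cluster (mean VAF < 0.1, a
documented cutoff — the tail peak sits near zero but no published
boundary exists) and calls the sample clonal when the largest remaining
cluster lies within 0.1 of VAF 0.5, oligoclonal otherwise, indeterminate
when only tail clusters remain.  When smoothing merges a subclone peak
into the tail the cutoff decides; this is a limitation of any
single-sample KDE deconvolution.

## Strand bias by replication timing

Pyrimidine-oriented C>T and CC>TT events are mapped onto protein-coding
gene footprints.  Inside a footprint, an event whose pyrimidine lies on
the gene's own (coding) strand is *nontranscribed*; on the template
strand, *transcribed*.  Positions outside all footprints are intergenic;
positions covered by footprints of both orientations are ambiguous and
excluded but counted, so strand + intergenic + ambiguous always conserves
the C>T (and CC>TT) totals.  A CC>TT doublet is assigned by its first
base.  Counts are stratified by replication-timing bin (uncovered
positions go to an "unbinned" stratum) and per-bin asymmetry is reported
as nontranscribed/transcribed, missing when the denominator is zero.
All intervals are half-open [start, end) with 1-based starts.

## Cohort statistics

- Prevalence: exact binomial tests; default alternative "greater"
  (enrichment over a background rate).  For the reference case of 3 hits
  in 17 lines against a background of 11/452, "greater" and the
  two-sided minimum-likelihood convention agree to the fourth decimal
  (0.0076), so the result is sidedness-robust.
- Burden vs genotype: two-sided Mann–Whitney; exact enumeration when the
  combined n ≤ 12 with no ties, else normal approximation with tie
  correction.
- Passage correlation: Pearson r with the two-sided t transform; zero
  variance yields (nan, nan).
- Sister pairs: concordant ⟺ > 10 shared substitutions and catalog
  cosine > 0.9 (substitutions only).
- Census overlap: plain gene-label intersection against a user-supplied
  census list (consequence prediction and selection scans are out of
  scope); percentages round half away from zero.
- Subclone tracking: presence ⟺ ≥ 1 alternate read; a variant is
  recapitulated (parent and ≥ 1 subclone), new-in-subclone (zero parent
  reads, ≥ 1 subclone), absent (no subclone), or unclassified when parent
  counts are unavailable at the site.  Missing sample/site combinations
  are NA.

## Synthetic lineages

The simulator emulates the generative structure the analysis assumes:

- A parent population with shared-ancestor mutations (cell fraction 1),
  per-subclone private UV mutations at the subclone's fraction (star
  topology over the ancestor — marginal cell fractions are all the
  downstream analyses use), a neutral tail whose cell fractions follow a
  1/f² density truncated to [2/depth_mean, 0.1] (the standard
  neutral-growth form; the tail's exponent is otherwise unconstrained),
  and heterozygous germline-like sites to exercise the caller's
  exclusion flag.
- UV events drawn from the UV-like 96-channel profile, a configurable
  fraction emitted as CC>TT doublets (two adjacent records with equal
  cell fraction, so the caller's merge can reconstruct them exactly),
  placed with transcribed:nontranscribed odds 1:`strand_asymmetry`
  inside gene footprints.
- Derived lines pass through a single-cell bottleneck: they inherit the
  ancestor's and the chosen subclone's mutations at cell fraction 1 and
  acquire Poisson(`passages × culture_rate_per_passage`) oxidative
  culture mutations, also clonal.  The parent's neutral tail is not
  propagated (each tail mutation belongs to a vanishing fraction of
  cells) and derived lines carry no tail of their own.
- Read sampling: depth ~ Poisson(`depth_mean`, floor 1) per sample and
  site; alt reads ~ Binomial(depth, v(1−e) + (1−v)e) with v =
  cell_fraction/2 (diploid, copy-neutral, heterozygous) and e the
  per-base error rate; plus error-only null sites carried by neither
  sample.  Identical config and seed give byte-identical output.

Default scales (ancestral 300, UV 400 per subclone, culture 15 per
passage × 18 passages, tail 300, depth 41, error 10⁻³) give per-stage
event counts in the hundreds — large enough for stable recovery
statistics, small enough that the full pipeline runs in seconds.  The
in-vivo mutation-rate scale per fibroblast lineage is not an observable
this package models; defaults were chosen for test power, not realism.

Not emulated: alignment artifacts, indels, structural variants, copy
number (CNV handling is an input mask), contamination, nested subclone
phylogenies (available behind the star topology only as marginal
fractions), sequence-level reads.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to real-data artifacts upstream of read counts.

## Numerical choices

- Fisher p-values come from the exact hypergeometric distribution; the
  test suite verifies equality (relative 10⁻¹⁰) against exhaustive
  enumeration with exact rational arithmetic over all tables with
  margins ≤ 12 and a random sample with margins ≤ 60.
- All-zero contingency tables return p = 1 by convention; zero catalogs
  fit to all-zero exposures; all-zero vectors have cosine similarity 0.
- BH with no qualifying p-value reports threshold 0 and no calls.
- KDE grids are fixed-step, so densities and cluster boundaries are
  reproducible; cluster membership uses half-open VAF intervals except
  at the upper boundary.
- Serialization uses fixed column orders and `%.6g` floats; pipeline
  randomness flows from one seed through `numpy.random.SeedSequence`
  spawning, so reruns are byte-identical.

## Known limitations

- The symmetric Fisher test cannot distinguish true germline variants
  leaking through the exclusion flag when both samples sit at similar
  VAF — such sites simply fail to reject, and no extra rule is added.
- Detection power at the default 5% FDR depends on the batch
  composition: the BH threshold is data dependent, so sensitivity
  figures are only meaningful together with the simulated site mix.
- The bootstrap stability rule is a stand-in for whichever convention a
  published fitting package uses; equivalence is not claimed.
- Shared/private classification at the read level misclassifies ~1−(1−e)^d
  of private sites as shared under sequencing error; at high depth this
  grows and a count threshold above 1 read would be needed.
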