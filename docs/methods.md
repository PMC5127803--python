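# Methods

## Data model and site filtering

A locus is an aligned set of homozygous-inbred accessions over
`A C G T - N`. Gaps and `N` are *uncalled*. A column enters statistics only
when at least 90% of accessions are called there (mirroring the ~5%
ambiguity tolerance of resequencing panels); the number of retained
columns is the **effective length**. Coordinates are 0-based, half-open;
the distance from a column to an indel is the number of columns strictly
between it and the nearer span boundary, counted in callable columns where
a profile requires it.

Indel events are identically-placed maximal gap runs: two runs are the
same event only if they share both boundaries, so co-located indels of
different size remain distinct events. A sample is *absent* when gapped
across the full span, *present* when fully ungapped and N-free, otherwise
*unknown*. Events whose presence states are internally uniform within each
haplogroup but differ between them are fixed indel variation and are
masked to `N` before any divergence is computed; the effective length
drops by the masked columns. This masking is what reconciles a printed
fixed-substitution count with a per-site fixed divergence (e.g. 37 fixed
sites over a 600-bp region with 11 masked columns gives
37/589 = 0.0628/site).

## Diversity decomposition

All pairwise statistics count differences over retained columns with
pairwise deletion in the numerator and normalize by the common effective
length. On complete data this equals the usual per-pair normalization; its
advantage is that the decomposition

    pi_t = pi_h + pi_fixedxy + pi_nonfixedxy

holds *exactly* (to floating-point rounding) on every input, including
missing data, because the within-x, within-y and cross-group difference
counts partition the total count column by column. A per-pair-normalized
`pi` would break the identity whenever callable lengths differ between
pairs, which is why that variant is not used.

A site is *fixed* between haplogroups when all called x-members share one
base, all called y-members share another, and the bases differ; a column
where the groups are fixed for different members of a three-allele trio
also counts. Tajima's D uses the original 1989 variance coefficients and
is reported as NaN (never silently 0) for monomorphic input; no
small-sample correction is applied. Whether to compute it on nominal or
effective length is moot here because the statistic uses counts only.

## Haplogroups, linked SNPs and the dimorphism call

The minor haplogroup is x. Equal-sized splits tie-break to the
insertion-carrying side when the event kind is known, else to the side
holding the lexicographically smallest accession id — determinism over
biology, as the labeling carries no inferential weight.

SNP columns are grouped by their *canonical bipartition* of the called
samples (the side containing the smallest called id listed first);
biallelic columns only. Columns group together only when both the called
sample set and its split are identical. Comparing partially-missing
columns on their shared called subset was considered and rejected: that
relation is not transitive, so the resulting groups would depend on
column order.

A group of `k` linked SNPs with minor count `m` is scored by the neutral
probability of observing at least `k` linked SNPs at minor count at least
`m` — a quantity monotone in both arguments. Because a locus offers many
candidate (k, m) corners, comparing each marginal probability to `alpha`
alone inflates the per-locus error (measured at 0.17 under the default
null); the caller therefore additionally requires the marginal probability
to fall below the **family-wise threshold**, the alpha-quantile of the
per-replicate minimum marginal probability among qualifying groups. With
that correction the per-locus false-positive rate on neutral data is
held at `alpha` (measured 0.045 at `alpha` = 0.05 on 1,000 genealogy-exact
neutral loci). When qualifying groups are rare under the null, the
threshold equals the corner probability itself and the call reduces to the
simple combinatorial rule (at least 3 linked SNPs at the frequency floor);
`alpha=1` recovers that rule unconditionally.

## The coalescent null

The null is the standard n-coalescent: exponential waiting times at rate
C(i,2), infinite-sites mutations as a Poisson process of rate theta/2 per
unit branch length, each mutation carried by its branch's descendant set.
`theta` is *per locus* (the bundled survey conditions use theta = 4 per
600-bp region, the multi-locus Watterson estimate rescaled to 600 bp; the
CLI accepts any value). Mutations are mutually linked when they induce the
identical sample bipartition — complementary descendant sets (the two
root-adjacent branches) induce the same allele pattern and are merged,
matching the empirical definition.

Two null summaries are exposed, and they differ enormously:

- `probability(k, floor)` — P(>= k linked SNPs at minor count >= floor),
  the union over frequency classes. Under n = 96, theta = 4 this is ~0.65
  for k = 3, floor = 10: a no-recombination neutral locus very often
  carries three linked intermediate-frequency SNPs somewhere.
- `probability_at_frequency(k, m)` — the same event restricted to one
  minor-frequency class. Every class from 4/96 upward sits below 0.05
  (~0.031 at 10/96). This per-class probability is the calibration
  quantity behind the published "less than 5%" threshold for declaring
  dimorphisms at the 10/96 frequency, and is what the acceptance script
  reports.

The distinction matters: summarizing the union event by a per-class
probability understates chance linkage, which is why the caller described
above uses the union semantics plus a family-wise correction instead.

Multilocus theta estimation follows Watterson:
`theta = S_total / n_loci / a_{n-1} / mean_length * target_length`, with
constants supplied by the caller (pooled SNP+indel counts, locus counts
and lengths are dataset facts, not package constants).

## Decay profiles

Each fixed substitution contributes to the 100-bp bin of its
distance-to-junction (distances in callable columns); each locus
contributes fixed/callable per bin; bins are averaged across loci with
SEM where at least two loci contribute. The one-phase model
`y = (y0 - plateau) exp(-K x) + plateau` is fit by bounded nonlinear least
squares (K >= 0; initialization y0 = first-bin mean, plateau = last-bin
mean, K = 1/500 bp; parameter tolerance 1e-10; non-convergence is
reported, never silent). R-squared is computed against the bin means and
reported as 0 with a degenerate flag when the profile is constant
(SS_tot = 0). Fit uncertainty, where requested, comes from a seeded
residual bootstrap (default 1,000 resamples) rather than asymptotic
p-values. Control profiles re-anchor each locus on the SNP closest to the
midpoint of the dimorphism's extension and rebuild the same profile
around it.

Defaults: bin width 100 bp, maximum distance 2 kb, junction flank
300 bp per side (~600 bp junction regions). The junction region takes up
to 2x flank non-indel columns in total, borrowing the deficit from the
other side when the locus edge truncates one flank, and flags truncation.

## The synthetic generator

The generator emulates the statistical *signature* the pipeline measures,
not the generating mechanism: a deletion splits the accessions 10:11 (21
accessions, the genotyped-panel condition); fixed between-group
substitutions are planted by a per-column Bernoulli process with intensity
`A exp(-d / lambda)` at distance d from the junction (defaults A = 0.08
per site, lambda = 300 bp, matching observed peak fixed divergence of
~0.02-0.09 per site and ~1-kb dimorphism extensions); beyond a suppression
window w (default 1 kb) each fixed difference is converted with
probability 0.5 into a polymorphism shared across groups, emulating
recombination's erosion of dimorphism away from the indel; background
within-group mutations fall at 0.005 per site per group (genome-wide
*Arabidopsis* diversity levels) on proper subsets of one group. Planted
fixed sites, homogenized sites and background sites occupy distinct
columns (infinite-sites style), so the truth record is exact and is
verified against the emitted alignment at generation time.

Neutral control loci can instead be drawn genealogy-exactly: a coalescent
replicate's mutations are placed at unique uniform columns, so S follows
the Watterson expectation and linked groups have genuine genealogical
structure. Compound loci carry two disjoint indels with independent
presence patterns and independent planted sets.

What the generator does *not* emulate — and hence what passing tests do
not establish about field data: genealogical correlation between nearby
fixed sites in dimorphic loci (sites are planted independently),
recombination within haplogroups, gene conversion, indel-size and GC
heterogeneity, alignment error, and selection. Calibration and recovery
results transfer to real data only insofar as the decay-of-fixed-
divergence signature is the dominant structure.

## Numerical and interface choices

- Seeds are explicit everywhere randomness exists; identical seeds give
  byte-identical alignments and simulation output. Derived seeds stay
  below 2^31.
- Sites with more than 10% uncalled samples are excluded outright rather
  than imputed; pairwise statistics never mix denominators.
- Equality of floating identities is asserted at 1e-12, reflecting exact
  count arithmetic followed by a handful of float operations.
- TSV everywhere; no binary outputs. Every CLI output embeds version,
  seed and a config hash so a run is reproducible from its own header.
- Exit codes: 0 success, 1 usage error, 2 data error.

## Known limitations

- Linked-group formation with missing data is exact-signature only; a
  SNP column missing one call will not join an otherwise identical group.
- BLAST-style uniqueness screening is approximated by exact substring
  counting (both strands) in a supplied genome text; diverged repeats are
  not detected.
- The coalescent null ignores recombination by construction; for species
  or regions with substantial effective recombination it overstates
  chance linkage, making the dimorphism caller conservative.
- Decay fitting operates on bin means; per-locus heteroscedasticity is
  handled only through the residual bootstrap.
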