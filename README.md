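# indelpoly

Analysis of **indel-associated nucleotide polymorphism** in multi-accession
alignments of selfing plants such as *Arabidopsis thaliana*.

Large insertion/deletion polymorphisms (indels) locally suppress crossing
over and elevate mutation, so the accessions carrying and lacking an indel
can diverge into two long-lived haplotype classes — a *nucleotide
dimorphism* — with fixed differences concentrated around the deletion
junction. `indelpoly` provides the statistics and simulations needed to
detect and characterize this pattern:

- partition accessions into haplogroups by indel presence/absence;
- decompose nucleotide diversity into within-group, fixed and non-fixed
  between-group components;
- call dimorphic loci against a neutral coalescent null;
- fit the one-phase exponential decay of fixed divergence with distance
  from the indel;
- generate synthetic loci with exact truth records for validation.

It is aimed at population geneticists working with aligned FASTA loci
(Sanger panels, resequencing panels) who want these quantities reproducibly
and with calibrated error rates.

## The statistics

For a locus with `n = n1 + n2` accessions split into a minor haplogroup *x*
(`n1`) and major haplogroup *y* (`n2`), Nei's nucleotide diversity
decomposes exactly as

```
pi_t = n1(n1-1)/(n(n-1)) pi_x + n2(n2-1)/(n(n-1)) pi_y + 2 n1 n2/(n(n-1)) D_xy
     = pi_h + pi_fixedxy + pi_nonfixedxy
```

where `D_xy` is the mean pairwise between-group divergence per site and
`d_xy` — the *fixed* divergence — is the number of sites at which the two
haplogroups are internally fixed for different bases, divided by the
effective (callable, post-masking) length. Then
`pi_fixedxy = 2 n1 n2/(n(n-1)) d_xy`, and `pi_fixedxy / pi_t` measures how
much of the locus's variation the dimorphism carries. Indel variation fixed
within the haplogroups is masked before divergence is computed, so the
effective length shrinks accordingly.

Whether `k` mutually linked SNPs (SNPs inducing the identical sample
bipartition) could arise by chance is judged against a Hudson-style neutral
coalescent (constant population size, panmixia, no recombination, infinite
sites) at a per-locus `theta`, with a family-wise Monte-Carlo threshold so
the per-locus false-positive rate stays at `alpha`. The spatial signal is
summarized by binning `d_xy` against distance to the junction and fitting
`y(x) = (y0 - plateau) exp(-K x) + plateau`.

## Worked example

```python
import indelpoly as ip
from indelpoly import alignment_io as aio, coalescent as co

# a synthetic 21-accession locus with a 300-bp indel (10 carriers)
a, truth = ip.generate_dimorphic_locus(ip.SyntheticConfig(seed=42))

major = aio.extract_indels(a, min_size=100)[0]
part = ip.partition_by_indel(a, major)          # 10:11 haplogroups
jr = ip.junction_region(a, major, flank=300)    # ~600 bp around the junction
dec = ip.decompose_diversity(jr, part)

null = co.build_null_distribution(
    co.NullModelConfig(n=21, theta=4.0, replicates=10000, seed=1))
calls = ip.call_dimorphism(ip.find_linked_snp_groups(a), null)
```

which prints, via the fields of `dec` and `calls`:

```
locus synthetic: n=21 (10:11), indel 300 bp at (2000, 2300)
junction region: 600 callable bp, 29 fixed substitutions, 0 fixed indels
pi_t=0.0297  pi_h=0.0013  pi_fixed=0.0253  pi_nonfixed=0.0031
D_xy=0.0543  d_xy=0.0483  pi_fixed/pi_t=85.1%  Tajima's D=3.07
dimorphism: k=48 linked SNPs at 10/21, null P=0 -> dimorphic
```

Read: of the locus's total junction-region diversity (`pi_t = 0.0297`),
85% is carried by substitutions fixed between the indel-present and
indel-absent haplotypes; 48 SNPs across the locus share the indel's exact
10:11 presence pattern, far beyond what the neutral coalescent produces.

The same pipeline is scriptable from the shell:

```
indelpoly generate --out-dir loci --seed 3
indelpoly analyze loci --out-dir results --seed 5
indelpoly simulate-null --n 96 --theta 4 --reps 10000 --k 3 --minor-floor 10 --seed 1
indelpoly decay loci --out-dir decay --seed 1
```

All outputs are TSV with a header embedding the version, seed and config
hash.

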