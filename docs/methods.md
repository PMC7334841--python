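# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the `campina` package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and coordinates

All genotype data are biallelic SNPs stored as diploid alternate-allele
dosages (0/1/2, −1 for missing) in a sites × samples matrix. Positions are
VCF-native 1-based throughout. Windows are 1-based inclusive
`[k·L+1, (k+1)·L]`, tiling each chromosome from position 1, so a site at
position 10000 lies in the first 10-kb window and a site at 10001 in the
second. Empty windows are yielded because per-bp diversity normalises by
window length. Multi-allelic records, indels and symbolic alleles are
dropped on ingestion with a logged count; phased and unphased genotypes are
treated identically and half-calls (`./1`) become missing — the
conservative reading.

Genotype-quality masking (genotypes with GQ below the threshold set to
missing) is applied *before* site-level missingness and minor-allele-
frequency filters; the defaults mirror the common resequencing pipeline
(GQ < 10 masked, MAF > 5% retained) but every threshold is per-command
configuration, since different analyses legitimately use different filter
combinations.

## Windowed statistics

π and d_xy are per-site sums divided by the window length in bp, so
monomorphic and uncalled positions count as zero difference — the
convention of windowed VCF scan tools, which fixes the absolute scale of π.
A sites-with-data denominator can be obtained by passing `denominator_bp`
explicitly.

Tajima's D uses only sites at which every genotype in the focal population
is called, so the sample size n entering the constants is fixed; the
alternative (per-site n with modal-n constants) was rejected as ambiguous.
D is undefined (reported `NA`) when no site segregates.

Weir–Cockerham F_ST follows the 1984 two-population variance-components
algebra exactly (r = 2, individual sample sizes n_i, allele frequencies
p_i, heterozygote proportions h_i); the window/genome estimate is the
weighted ratio of sums Σa/Σ(a+b+c). Negative per-window values are reported
as-is; clamping to 0 happens only in the isolation-by-distance module,
where the source pipeline states it.

Frequency-based statistics (π, F_ST, d_xy, quartet frequencies) skip sites
with fewer than 4 called allele copies in a contributing population: the
sampling variance of p̂ below that is too high to be useful. The threshold
is configurable.

## Introgression statistics

Patterson's D and f_d use the frequency-weighted formulation: the outgroup
contributes weight (1 − p₄) rather than being forced to a fixed state, so
outgroup-polymorphic sites still inform the test. The f_d denominator
replaces both P2 and P3 per site by the donor proxy (the one with the
higher derived frequency). Negative f_d values — which arise when BABA
exceeds ABBA and carry no admixture-fraction interpretation — are set to 0;
f_d is reported per window only, never genome-wide aggregated.

Genome-wide D uses ratio-of-sums across sites (not a mean of window D
values), with a delete-one block jackknife over 20 contiguous equal-count
blocks, so each pseudo-replicate keeps 95% of the data; block boundaries
follow site order and therefore respect chromosome breaks. The jackknife SD
is √[((m−1)/m)·Σ(θ₍₋ⱼ₎ − θ̄)²] and is snapped to exactly 0 when all
leave-out estimates are equal.

Peak calling on a windowed statistic flags windows with robust z-score ≥ 4
(a documented default — the underlying scan procedure has no canonical
threshold) and merges flagged windows within a configurable gap. The scale
estimate is 1.4826·MAD; when the MAD degenerates to 0 because most values
tie (typical for clamped f_d tracks, where the median window is exactly 0),
the scale falls back to the normal-consistent mean absolute deviation about
the median, and only when *all* values tie does it fall back to mean/SD
(which then flags nothing). The straight mean/SD fallback was rejected for
the MAD-degenerate case because the peak itself inflates the SD and masks
detection.

Divergence-ratio dating assumes divergence accumulates linearly with time
at equal rates in both lineages: t_intro/t_div = d_focal/d_genomewide.
Selection, recombination or rate variation at the focal locus bias this
ratio; it is a rough estimate by construction.

## Mutation load

Ancestral alleles are assigned from designated outgroup samples only when
every outgroup sample is called and a strict majority of outgroup allele
copies agrees; ties and partial calls leave the site unpolarized. Effect
classification is exact, case-sensitive membership in the two label sets
(neutral: `synonymous_variant`, `intron_variant`, `NONE`; deleterious:
`missense_variant`, `start_lost`, `stop_gained`); everything else is
excluded. Labels come from a `chrom⇥pos⇥effect` TSV — the package consumes
annotations, it does not run an annotation engine.

The unfolded SFS is built at a fixed sample size: only sites with exactly
n called allele copies in the target population contribute. Projection /
hypergeometric downsampling was rejected to keep counts directly
interpretable under strict-call filters. ξ_n (fixed derived) is reported
separately from the polymorphic classes so either pooled or split
presentations can be produced.

"Fixed in a population" defaults to derived frequency 1 among called allele
copies — the standard substitution definition, consistent with contrasting
"fixed" against "polymorphic". The literal per-individual reading (≥ 1
derived copy in every called individual) is available behind
`per_individual=True`. χ² p-values are reported without multiple-testing
correction; correction is the caller's choice.

## Ne and isolation by distance

Ne = π/(4μ) assumes neutral mutation-drift equilibrium; the CI comes from
the mutation-rate CI with the order inverted (high μ → low Ne). Distances
are great-circle (haversine) on a sphere of radius 6371.0088 km rather
than an ellipsoidal geodesic; the difference is < 0.5% and cannot affect
slope comparisons. A population's location is the spherical 3-vector
midpoint of its members' coordinates — when all members share one sampling
locality this reduces to that point, which resolves the otherwise
ambiguous "segment midpoint" rule in a single consistent way. Negative
F_ST pairs are clamped to 0 and F_ST = 1 pairs excluded (infinite
linearised value) before ordinary least squares of F_ST/(1−F_ST) on km. No
Mantel permutation test is performed.

## mtDNA haplotypes

Columns containing a gap or `N` in any sequence are removed first
(complete deletion); pairwise deletion was rejected because it can make
distances non-metric. The network is the union of all minimum spanning
trees over haplotype Hamming distances, computed by rank-grouped Kruskal
with tie retention — the ε = 0 backbone of a median-joining network.
Median (Steiner) vertex inference is out of scope; on low-divergence
alignments the backbone reproduces the published topology class, but dense
reticulations requiring inferred intermediate haplotypes will not appear.

## The synthetic-data generator

A standard structured Kingman coalescent run backward in time: pairs in a
population of diploid size N coalesce at rate 1/(2N) per generation;
lineages migrate at backward per-lineage rates; at an admixture pulse
(forward-time fraction f from source into recipient) every lineage in the
recipient jumps to the source with probability f; at a split the derived
population's lineages merge into the ancestral one; sizes are
piecewise-constant. Mutations are infinite-sites: Poisson on total branch
length, placed uniformly on branches, each at a unique position. Each
window is one independent genealogy — no intra-window recombination, which
matches treating windows as loci and is a documented non-goal. Diploids
pair consecutive haplotypes within a population (random mating, no
inbreeding parameter). Time is in generations; any generations-per-year
conversion is presentation-layer only. A fixed seed makes the whole bundle
bit-identical between runs.

Reference scenarios encode the study conditions with Heliconius-like
values: Ne = 4×10⁵ diploids and μ = 2.9×10⁻⁹/site/generation (so
equilibrium π ≈ 0.0046/site, near the observed ~0.005); a constant-size
calibration population (θ·L = 10 per 10-kb window, 6 diploids = 12
chromosomes, 1000 windows); a recent 10× contraction at 0.1·2N generations
(the bottleneck signature); and a four-taxon tree (((P1,P2),P3),O) with
subspecies split 10⁶, donor split 2.5×10⁶ and outgroup split 6×10⁶
generations, pulsed from P3 into P2 at 5×10⁵ generations. At the simulated
mimicry locus the pulse fraction is 1.0: the introgressed haplotype is
fixed in the recipient, as selection for mimicry fixed it in nature.
Deleterious-site realism is approximated by frequency-spectrum distortion
(a weighted sampler over SFS classes), not forward simulation with
selection coefficients — sufficient to exercise the load pipeline's
recovery behaviour, not a model of selection.

What passing simulation tests does *not* show about real data: no
sequencing error, no missingness structure, no linked selection, no
recombination within windows, and no reference bias; the generator
validates the statistical machinery, not the upstream calling pipeline.

## Statistical checks and their nulls

Per-window sites share one genealogy, so pooled-SFS counts are clustered,
not multinomial; the neutral-SFS goodness-of-fit in the acceptance suite
therefore uses a window-clustered (cluster-robust) covariance for the
score statistic (χ² with n−2 df after dropping the redundant class) rather
than the plain Pearson χ², whose null does not hold under that
correlation. Stochastic calibration checks use 3-standard-error bands with
fixed seeds. Problem sizes (200–1000 windows, 10-kb windows, 4–6 diploids
per population) are the package's validation defaults: large enough for
the 3-SE bands to be informative, small enough to run routinely.

## Known limitations

- Single-nucleotide biallelic variation only; no indels, no haplotype
  statistics (EHH/iHS), no LD computation.
- The coalescent simulator has no recombination within loci and no
  explicit selection.
- Jackknife block boundaries are count-based; strongly heterogeneous
  per-block information content is not rebalanced.
- The ellipsoidal geodesic and median-vector network inference are listed
  extensions, not implemented.
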