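# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `selsig` pipeline.

## Divergence: NG86 dN/dS

Ortholog CDS pairs are aligned end to end with the Needleman–Wunsch
algorithm (Bio.Align.PairwiseAligner; affine gaps, end gaps penalised).
Default scoring mimics EMBOSS needle defaults — match +5, mismatch −4, gap
open 10, gap extend 0.5, a gap of length k costing open + (k−1)·extend —
and is configurable. "Reciprocal identity" is taken as
min(matches/len(a), matches/len(b)) × 100; the term has no single standard
definition, so this conservative minimum is used throughout.

dN/dS is the Nei–Gojobori (1986) counting estimator. Synonymous site
fractions per codon exclude changes to stop codons from the denominator;
observed codon differences are partitioned by averaging over all
mutational orderings, excluding orderings that pass through a stop codon
(codon pairs with no stop-free path are skipped, with a log entry). Site
counts are averaged over the two sequences, and the Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)p) is applied; p ≥ 3/4 leaves the
distance undefined with a `saturated` flag, and dS = 0 leaves ω undefined.
This counting estimator stands in for likelihood codon models (it ignores
transition/transversion bias and codon usage); downstream use is purely
threshold- and rank-based, so only ordering and rough scale matter, which
the recovery tests verify (ω = 1 recovered within ±15% at 300 codons; the
ordering of ω ∈ {0.2, 1, 5} preserved, with ω = 5 compressed by
saturation). Aligned pairs are chunked into consecutive column triplets;
any triplet containing a gap or N in either row is skipped, so frame is
preserved only for in-frame indels — the stated precondition for inputs,
and all the synthetic generator produces.

Ortholog retention keeps pairs with reciprocal identity ≥ 75% and
0.02 < dS < 2 and dN < 2, all bounds strict as conventionally printed;
extreme dS/dN indicate saturation and unreliable ratios.

## MK table, NI and DOS

Polymorphisms are classified per segregating site (not per allele copy).
A SNP is mapped to a codon in every transcript whose CDS contains it; if
the synonymous/nonsynonymous status conflicts across transcripts (the site
is read in different frames) the SNP is `ambiguous` and excluded — the
per-gene NI and DOS need one consistent status per site. Dn and Ds are
the NG86 fractional pathway sums rounded half away from zero, since MK
counts are contingency-table entries.

NI uses the natural log (Haldane's log-odds convention; base
configurable), with the +1/×2 pseudo-count correction making it finite
for every table. DOS is undefined when either table margin is zero; such
genes are excluded downstream. Heterozygous VCF genotypes are resolved to
the ALT allele (the organism modelled is highly selfing, so heterozygous
calls are rare); the count of resolved calls is logged.

## Frequency-spectrum statistics

Per-gene haplotype alignments (n ingroup rows plus one `outgroup` row) are
reduced to a site frequency spectrum: columns with a gap or N in any used
row are excluded (inputs are end-to-end CDS alignments, so complete-case
is appropriate), multiallelic ingroup columns are excluded everywhere, and
the ancestral state is the outgroup allele when it matches one ingroup
allele — otherwise the site stays unpolarized, is kept for D and D* and
excluded from the unfolded spectrum used by H and E. Both site counts are
reported.

Estimators: θ̂W = S/a₁, θ̂π = Σ 2i(n−i)Sᵢ/(n(n−1)), θ̂H = Σ 2i²Sᵢ/(n(n−1)),
θ̂L = Σ iSᵢ/(n−1), with a₁ = Σ₁ⁿ⁻¹ 1/i. The identity
θπ − θH = 2(θπ − θL) holds algebraically and is asserted to 1e−12.

- Tajima's D uses the 1989 constants and all biallelic ingroup segregating
  sites (no polarization needed).
- Fu & Li's D* uses the 1993 formulation with the Simonsen, Churchill &
  Aquadro (1995) corrected variance constants; singletons are sites where
  one allele is carried by exactly one sequence.
- Fay & Wu's H defaults to the unnormalized θπ − θH. This choice matches
  the magnitude of published genome-wide gene-level values (medians of
  several units); the normalized (θπ − θL)/√Var variant of Zeng et
  al. (2006) is available by option and used in the calibration tests.
- Zeng's E is (θL − θW)/√Var with the Zeng et al. (2006) variance.

Variance formulas take θ = S/a₁ and the standard unbiased plug-in
θ² = S(S−1)/(a₁² + a₂). Statistics require n ≥ 4 and at least one usable
site; zero variance yields an invalid (NaN) value. Profiles with fewer
than 50 biallelic segregating sites are flagged invalid and carry no
statistic values — at low mutation counts these tests are unreliable. The
filter is applied to the biallelic ingroup count (pre-polarization), the
more conservative of the two possible readings.

Neutral calibration (asserted in the test suite): at n = 25, θ = 10 over
1000 coalescent replicates, the means of D, D*, normalized H and E all lie
within ±0.25 of zero and their variances within [0.6, 1.4] — these
normalized statistics are approximately, not exactly, unit-variance.

## Randomisation test

For a focal gene set (e.g. essential genes) and one statistic, s subsets
of the focal size are drawn without replacement from all genes with a
defined value — drawn per statistic, since each statistic has its own
defined-gene domain. For a lower-tail test, r counts draws whose median is
≤ the focal median and p = (r+1)/(s+1); ties are counted into r, the
conservative choice (they enlarge p). q = s − r is the number of draws the
focal subset beats outright, so the extreme case q = s gives the floor
p = 1/(s+1) — 1.00×10⁻⁴ at the default s = 10,000. Direction conventions
for the essential-gene test: lower-tail for dN/dS, DOS and H; higher-tail
for NI, D, D* and E. Under a random focal set the p-values are uniform on
{k/(s+1)}, which the suite checks by Kolmogorov–Smirnov distance.

Selection-candidate classification uses the conventional strict
thresholds (dN/dS > 1, DOS > 0, NI < 0, D < 0, D* < 0, H < 0, E < 0) or a
top-5% outlier mode (empirical quantile with linear interpolation, ties at
the cutoff included, each statistic taken in its selection-indicating
direction). Genes with any undefined statistic are excluded from the
seven-way intersection.

## Fitness association

Relative fitness of one data point is KO fruit count / paired wild-type
fruit count within the same experimental replicate; zero-WT points are
dropped with a log entry. A gene's fitness w is the mean over its data
points, and genes with fewer than four usable observations ("more than
three") are excluded. The area-ratio filter drops genes whose line area
ratio (a PCR-brightness proxy for multiple T-DNA insertions) exceeds 1.5
strictly; a missing assay is retained, flagged, since absence of the assay
is not evidence of extra insertions. Chamber Z-scores standardise ratios
to mean 0, variance 1 (population SD) within each growth chamber before
gene-level averaging. Where several WT plants share a replicate, callers
should supply the replicate-mean WT count as the row's divisor; rows are
otherwise treated as independent KO/WT pairs.

Class comparisons use the two-group Kruskal–Wallis rank test between
candidate and non-candidate genes per statistic; correlations are
complete-case Spearman with both raw and Benjamini–Hochberg adjusted
p-values reported.

## Synthetic data

The generator provides every pipeline input with known ground truth.

- **Coalescent genes.** Standard n-coalescent (exponential coalescence
  times at rate C(k,2)) with infinite-sites mutation at rate θ/2 per
  lineage-time unit; every mutation occupies a distinct CDS position, and
  outgroup divergence mutations are placed on positions untouched by
  ingroup mutations, so outgroup polarization is exact by construction.
  Mispolarization, gaps and Ns are therefore exercised with hand-built
  fixtures rather than the simulator; calibration runs use outgroup
  divergence 0. A sequence-free fast path draws spectrum counts directly
  from the genealogy's branch-length classes and is cross-validated
  against the sequence path and against msprime (mean S = θ·a₁).
- **Spectrum skew.** Sweep-like (singleton-excess) and
  high-frequency-derived skews reassign each polarizable site's derived
  class with a given probability, preserving the site count — enough to
  drive each statistic's sign in the expected direction.
- **Ortholog pairs.** A random stop-free CDS evolves along a branch by
  acceptance-ratio thinning: candidate single-base changes accepted at
  relative rate 1 (synonymous) vs ω (nonsynonymous), stop codons rejected.
  This is not a full codon rate matrix; it suffices for NG86 recovery and
  ordering, which is all that is asserted.
- **MK tables.** Independent Poisson draws per cell.
- **Fitness tables.** WT fruit counts are Poisson around a
  chamber-specific mean (lognormal chamber multipliers, SD 0.1); KO counts
  are Poisson around the paired WT plant's realized count × (1 + gene
  effect) × mean-one lognormal gene noise. Conditioning on the paired WT
  count keeps E[w] equal to the intended scale exactly (plants in a
  replicate share growing conditions) and calibrates the null: at effect
  0, mean w ≈ 1.

Default full-dataset conditions are desk-scale stand-ins for the source
study's shape: 500 genes (for the genome-wide ortholog set), 24 ingroup
haplotypes plus outgroup, per-locus θ = 25 over 200 codons so most genes
clear the 50-site filter, ω ~ lognormal(median 0.2, σ = 1) putting ~5% of
genes above ω = 1 (matching the observed genome-wide fraction),
essential fraction 591/17,630 with essential ω reduced by 0.1, five
fitness replicates per line (≈1852/379 data points per gene in the source
data), 38% of lines with area ratio > 1.5 (matching the observed 379→236
filter attrition), and fitness effect 0 — the null regime is the default
because no fitness–selection association is the study-scale expectation.
All generators are pure functions of (config, seed); the manifest records
every true parameter.

What passing tests do and do not show: the generator has no
recombination, migration, demography, linkage between genes, or real
selfing genealogies (inbreeding-like spectra are emulated only via skew),
and within-species polymorphism is neutral regardless of ω — so synthetic
NI/DOS distributions are shifted relative to real data (excess
nonsynonymous polymorphism), and calibration results speak to estimator
correctness, not to demographic robustness on real populations.

## Pipeline

Stage order: align/filter orthologs → NG86 divergence → MK → SFS →
classify → randomise (when an essential list is present) → fitness
association. One top-level seed drives every stage; outputs are TSV with
headers, carry no timestamps, and are byte-identical across reruns of the
same (config, seed). Every exclusion is logged with its rule name and
count, and gene counts are non-increasing along the filter chain. In the
SFS stage, accession rows are checked against the reference row and
dropped below 75% identity; same-length rows are compared column-wise,
which equals alignment identity for the end-to-end CDS alignments this
stage consumes (the general global-alignment check is available in the IO
module). An optional accession subset recomputes the SFS statistics on a
restricted panel, mirroring geographically restricted control analyses.

## Known limitations

- NG86 is not numerically equivalent to likelihood codon models; filter
  bounds are applied to NG86 estimates as printed.
- Lineage-specific (branch-model) dN/dS with a third genome is out of
  scope, as are GO-term enrichment, variant calling and whole-genome
  alignment.
- The MK stage takes the first haplotype as the codon-context reference;
  sites where the reference row carries a gap/N are skipped.
- Heterozygous genotype handling (ALT allele) is a documented choice, not
  a published behaviour.
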