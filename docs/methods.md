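# Methods

`tigerwing` implements the computational core of a comparative mimicry-genomics
study design: given phased genotypes for two species that each comprise two
wing-pattern subspecies — with the similar-looking (co-mimetic) subspecies of
the two species living in the same locality — it asks whether the co-mimics
share unusually recent ancestry at a color-pattern locus (localized
introgression), whether allele sharing is elevated genome-wide (f4, fd/fdM),
whether color loci carry signatures of long-term balancing selection
(multispecies π, trans-species polymorphism), and how tightly individual SNPs
track the discrete wing phenotype (association post-processing).  All stages
run end to end on data from the built-in coalescent simulator.

## Windowed genealogies and topology weighting

The genome is cut into non-overlapping windows of exactly 100 SNPs (the
trailing remainder is dropped; window coordinates are the bp span from the
first SNP to one past the last).  Per window a neighbor-joining tree is built
over haplotypes from p-distances: d(i,j) = (# co-called sites with differing
alleles) / (# co-called sites).  The distance is the simplest defensible
choice for short windows; any allele mismatch counts one difference, so
multiallelic sites need no special handling.  Windows containing a haplotype
pair with no co-called site are dropped and logged rather than imputed.

NJ follows Saitou–Nei Q-matrix joins.  Two determinism rules are fixed: when
several Q entries tie at the minimum, the lexicographically smallest index
pair (in current working order) is joined; and negative branch-length
estimates are clamped to zero after estimation, keeping the topology.  NJ on
additive matrices recovers the generating topology exactly (tested for every
labeled 4- and 5-leaf topology and random 6- and 7-leaf trees, the latter
cross-checked against scikit-bio's implementation).

For a quartet of taxon groups with fixed roles — g1 = sspA1, g2 = sspA2,
g3 = sspB1, g4 = sspB2, with sspA1/sspB1 the co-mimics — each window tree is
summarized by the fraction of one-leaf-per-group tuples resolving to each of
the three unrooted group topologies: species (g1g2|g3g4), introgression
(g1g3|g2g4), third (g1g4|g2g3).  Enumeration is exhaustive up to 50,000
tuples, Monte Carlo (10,000 with-replacement draws, recorded seed) beyond.
The introgression-compatible topology is declared by the configuration and
never inferred from data, which would be circular.  Because NJ trees are
binary, zero-length internal branches still resolve; the stored resolution
counts.  A window is *intro95* when the introgression-topology weight is at
least 0.95.

## The block-permutation test

The observed statistic is the intro95 count among windows whose bp midpoint
falls in a fixed focal region (the association peak).  The null shuffles the
order of contiguous 100 kb blocks of the track: windows travel with their
block, preserving within-block order and hence the local autocorrelation of
the weights, and are re-addressed to the bp span their block occupies after
the shuffle; the focal region stays fixed in genomic coordinates and the
count is recomputed.  The trailing partial block participates in the shuffle
(dropping it would bias the span).  The p-value uses the add-one convention
p = (1 + #{null ≥ observed}) / (1 + n_perm), so p is never 0 and a track with
no introgression-compatible windows anywhere reports p = 1 with a degeneracy
flag.  The default is 50,000 permutations; the shuffling is fully vectorized,
so this costs well under a second per test.

Operating characteristics, measured with a synthetic exchangeable-flag
harness: the test is slightly conservative when intro95 windows are rare
(the discrete null puts visible mass on the observed value) and slightly
anticonservative when flag run lengths approach the block size (shuffling
splits clumps at block boundaries that the observed count keeps intact).  At
the simulator's default study conditions (flag runs of ~2 windows, ~40
windows per block) it is well calibrated: 10/200 rejections at α = 0.05 in
the null calibration test.

## f4, fd and fdM

f4 over populations arranged (A, B; C, D) is the mean over usable sites of
(p_A − p_B)(p_C − p_D), computed on allele frequencies; sites with any
population undefined are skipped, not imputed.  The test arrangement places
the two sympatric same-locality pairs as (A, C), so positive f4 means excess
sympatric allele sharing.  Standard errors come from a delete-one-block
weighted jackknife over non-overlapping 500 kb blocks (weights proportional
to usable sites per block, Busing–Meijer–van der Leeden formula); Z = f4/SE.

fd and fdM are windowed ABBA–BABA asymmetries on derived-allele frequencies
for a trio (P1, P2, P3) plus outgroup O.  The window numerator is
Σ[(1−p1)p2p3(1−pO) − p1(1−p2)p3(1−pO)]; the fd denominator substitutes
pD = max(p2, p3) for both p2 and p3.  fd is reported only where the
numerator is positive (the raw numerator is always retained); fdM
substitutes the P1-donor maximum when the numerator is negative and keeps
the sign, making it symmetric for the two possible recipients.  Windows
default to 20 kb with at least 20 informative sites (neither value is pinned
by the study design; both are configurable).  Ancestral states come from the
outgroup major allele, falling back to the most frequent allele across the
whole sample where the outgroup is uncalled; frequency ties resolve to the
reference allele.

## Diversity and trans-species polymorphism

Pooled nucleotide diversity uses the invariant-site-aware ratio-of-sums
estimator in 50 kb windows: per site, discordant called-allele pairs over
all called-allele pairs, summed per window before dividing (never a mean of
per-site ratios).  The input must include invariant sites; repeat masking is
an input concern.

A biallelic site is trans-species polymorphic when (i) at least four species
are polymorphic if more than three species have data at the site, (ii) all
species are polymorphic if three or fewer are present, and (iii) each allele
has at least six copies summed across all species.  "Polymorphic within a
species" requires one copy of each allele among that species' called alleles
(the weakest literal reading; no per-species floor beyond that).  The copy
rule counts across all species, not only polymorphic ones — the alternative
reading would only be stricter.  Counts are reported in 10 kb windows.

## Association post-processing

The association scan itself is plumbing: a Cochran–Armitage-style trend
test (N·r² against χ²₁, with r the dose–phenotype Pearson correlation),
which extends unchanged to the categorical 0/0.5/1 phenotype coding.  It
deliberately omits relatedness correction; mixed-model machinery is out of
scope, and the scan exists so the post-processing stages have realistic
input.  Its null p-values are calibrated in the tail but discrete, with an
atom at p = 1 from exactly balanced SNPs — a property of any exact discrete
test, checked by binomial bounds rather than a continuous-uniform KS test.

Sites enter at minor allele frequency ≥ 10% (boundary inclusive, computed on
called genotypes) and missingness < 25% (boundary exclusive).  Significance
is Bonferroni: α / n_tests over the filtered site count.  For significant
SNPs the strength of association is ρ², the squared Spearman rank
correlation (midrank ties) between genotype dose and phenotype code; a SNP
is *fully associated* when ρ² = 1 (within 1e−9) on its called samples.  The
fully-associated interval is the minimal 1-based inclusive [min, max]
position span of such SNPs; its length is end − start + 1, matching how
peak coordinates are conventionally printed.

The genotype-matrix export orders samples by average-linkage hierarchical
clustering on genotype Hamming distance; sample order is canonicalized
before clustering so the output is permutation-invariant.

The diagnostic motif scan enumerates k-mers (default k = 6–12) overlapping a
declared fixed-SNP position in any sequence of either homozygote group, and
scores presence by substring containment anywhere in a sequence (the
semantics of motif-discovery tools).  Strict mode requires 100% presence in
one group and 0% in the other; relaxed mode tolerates <5% in the other.  An
optional per-sequence occurrence filter (min, max) is exposed rather than
hard-coded, since tool conventions differ.

## The synthetic-data generator

Haplotypes are generated per non-recombining 5 kb segment from a structured
Kingman coalescent on the population tree ((sspA1, sspA2), (sspB1, sspB2)),
with subspecies merging at `split_time_subspecies` and species at
`split_time_species` (units of 2N generations).  Mutations are infinite-sites,
Poisson(θ_within × branch length) per branch with uniform positions, so the
expected pairwise within-population diversity is 2·θ_within per segment
(verified by regression across θ values).  Segment boundaries give window-
scale genealogical heterogeneity without the cost of within-segment
recombination.

Introgression is a migration pulse: each sspA1 haplotype independently
carries the donor tract with probability `introgression_fraction`.  Inside
tract-overlapping segments the migrant lineages occupy their own deme —
they can coalesce neither with non-migrant sspA1 lineages nor with sspB1
lineages more recently than the pulse — until `introgression_time`, when
they merge into sspB1 (or the ancestral B population if the pulse postdates
the subspecies merge).  A causal SNP at `causal_pos` carries the derived
allele on all sspB1 haplotypes plus the migrant sspA1 haplotypes; the binary
phenotype is noiseless given the causal genotype under the configured
dominance (recessive by default, matching the study system's yellow-band
allele).  The generator supports exactly the 2 species × 2 subspecies
quartet design; co-mimics share a locality in the emitted metadata.

The 4-population frequency generator is Balding–Nichols: ancestral
p ~ U(0.05, 0.95) per site, each population drawing
Beta(p(1−F)/F, (1−p)(1−F)/F) with drift F ∈ (0, 1); an optional admixture
edge replaces the recipient frequency with (1−m)·p_recipient + m·p_donor.
Population frequencies are exact (no binomial sampling noise), so the
no-drift and no-admixture identities hold exactly in expectation.

What the generator does not emulate: within-segment recombination,
selection at the causal site, demographic size change, genotyping error and
missingness (fields accept missing data; the simulator never emits it),
phenotype noise or intermediates, and chromosome rearrangements.  Passing
calibration and power tests therefore certify the statistics under clean
phasing and genotyping; they do not measure robustness to those artifacts.

## Frozen study conditions for the introgression test

Calibration and power tests (and the demo) use: 1 diploid per subspecies, a
3 Mb chromosome, θ_within = 25 per 5 kb segment (~120 SNPs per segment, so
one 100-SNP window spans roughly one genealogy), subspecies split 0.2 and
species split 0.4 (a recently radiated group with substantial incomplete
lineage sorting), quartet groups of one haplotype each, focal region
1.0–1.5 Mb (5 of 30 blocks).  Single-haplotype groups are the deliberate
design: the windowed-NJ quartet test is explicitly usable at small sample
size, and with one leaf per group the intro95 flag fires for ~20% of windows
under the null, giving the permutation null enough resolution to be
calibrated (with two haplotypes per group the all-tuple intro95 event has
probability ~0.02 and the discrete null is visibly conservative).  Power
runs add a fully introgressed tract equal to the focal region with pulse
time 0.02.  Calibration and power use 1,000 permutations per replicate for
speed; single tests default to 50,000.

The parameter-recovery experiment for association post-processing uses 15
diploids per subspecies on a 300 kb chromosome (θ_within = 10), cohort =
species A, with a fully introgressed tract so the two subspecies are fixed
for alternative causal alleles — the regime in which wild-caught samples
show fully associated SNPs (heterozygotes absent, ρ² = 1 at the causal
site).

## Numerical and degenerate-input conventions

* Internal coordinates 0-based half-open; VCF and reported tables 1-based.
* Missing code −1 throughout; missing genotypes are excluded from MAF and
  frequency denominators.
* Quartet resolution uses edge-count distances; in a binary tree the
  minimizing pairing is strict, so no tie-break is needed.
* −log10 p capped at 320 for export.
* θ_within = 0 yields zero segregating sites and an empty window track.
* All randomness flows through numpy Generators seeded from explicit seeds;
  module streams are separated by fixed seed offsets, and every output is
  bit-reproducible given the seed.

## Known limitations

* The trend-test scan ignores population structure; with structured cohorts
  its p-values are anticonservative.  Only the post-processing around it is
  meant to be production-grade.
* The block-permutation null assumes the weight track is exchangeable at the
  block scale; real chromosomes with megabase-scale heterogeneity (e.g.,
  inversions) violate this, which is why the focal region must be chosen
  a priori.
* fd/fdM window size and minimum informative-site count are conventions,
  not estimated quantities.
* The simulator's quartet design is fixed at 2 × 2; multi-species balancing
  selection scans accept arbitrary species maps from real data, but the
  simulator exercises them with two species only.
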