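# Methods

`hippogen` re-implements, as a single tested pipeline, the analysis stack
used to study introgression and diversity in the hippotragin antelopes —
the extinct blue antelope (*Hippotragus leucophaeus*), the sable
(*H. niger*) and the roan (*H. equinus*), with the scimitar-horned oryx as
outgroup. Every stage can be validated against simulation truth, so the
package ships a multispecies-coalescent + ancient-DNA-damage generator as
first-class, tested code.

## The generative model

**Species tree and coalescent.** Gene trees are drawn per window under the
structured coalescent on the species tree `(((blue, sable), roan), outgroup)`
with piecewise-constant diploid effective sizes per branch. Within a
population with `k` lineages and size `Ne`, coalescences occur at rate
`k(k-1)/(4Ne)` per generation. Split times are in generations; the default
anchors are the dated divergences (blue/sable 1.67 Ma, roan 2.86 Ma,
outgroup 4.0 Ma) converted with an 8-year generation time — a documentation
convention, not a biological claim. Windows are independent loci: free
recombination between windows, none within, matching the way sliding-window
trees treat loci.

**Introgression pulse.** An optional pulse `(donor, recipient, time, f)`
moves each recipient-population lineage alive at the pulse time into the
donor population independently with probability `f` (the standard
instantaneous-admixture convention). Leaves descending from migrated
lineages are recorded as truth.

**Mutation.** Finite-site two-parameter (Kimura) mutation: Poisson
mutations at rate `mu` per site per generation along each branch; each
mutation is a transition with probability `kappa/(kappa+1)`, otherwise a
uniformly chosen transversion. Sites can be hit repeatedly (saturation is
real, and tests account for it). The closed-form K2P divergence serves as
the oracle for this layer.

**Observation (aDNA) model.** Per site, sequencing depth is
Poisson(`coverage`); each observation picks a haplotype uniformly, a
fragment offset `p ~ Uniform{0..read_len-1}` from the nearer end, then
suffers, in order: C→T deamination with probability
`delta_ss * exp(-lambda * p)` (both fragment ends deaminate — the
single-stranded-library convention, chosen because the damaged specimens
show terminal C→T at both ends), position-independent G→T oxidation with
probability `delta_ox`, and uniform base error `eps`. Damage relabels
observations but never changes depth.

## Pseudohaploid calling

Two modes. *Consensify-style*: at each site draw up to three observations
without replacement and emit the base seen at least twice, else N — this
suppresses singleton damage/error at low coverage. *Random-read*: emit one
uniformly drawn observation. Sites below `min_depth` (default 2) or above
`max_depth` are masked; `max_depth` defaults to twice the individual's
empirical mean depth (pile-up removal). Calls use positionally indexed
randomness, so depth-gate changes can mask or unmask sites but never alter
the base called at a site that stays called (tested as a monotonicity
invariant). The site-call distribution is pinned against exhaustive
enumeration of all 3-subsets.

## Damage-aware site classification

Unordered base pairs partition into: identical; transitions (C/T, A/G),
which overlap cytosine-deamination artefacts; damage-like transversions
(G/T, C/A), which overlap oxidative damage; and clean transversions (A/T,
C/G). RY coding (A,G→R; C,T→Y) makes transitions invisible and underlies
all distance computations. The joint site filter drops sites with any
missing call or no variation across the cohort; its retained-site count is
the shared normalization denominator for diversity.

## D statistic

Transversions-only ABBA-BABA on pseudohaploid quartets (P1, P2, P3, O) =
(sable, blue, roan, oryx): sites with any N, not exactly two alleles, or a
transition allele pair are skipped; the outgroup allele is ancestral;
`D = (nABBA - nBABA)/(nABBA + nBABA)`. Standard errors come from a
Busing-style weighted delete-one-block jackknife over contiguous 1-Mb
blocks (weights `h_j = n/m_j` with `m_j` informative sites in block `j`);
with equal blocks this reduces exactly to the plain delete-1 jackknife,
which the tests exploit as an oracle. `|Z| > 3` is called significant.
Design choices the source pipeline leaves open: polarization strictly by
outgroup match, >2-allele sites excluded, blocks never span scaffolds,
empty blocks dropped.

## Window phylogenies

Windows tile each scaffold at stride `w + lw` (defaults 20 kb + 80 kb); a
window is dropped when any taxon exceeds 50% missing data (the per-taxon
reading of the threshold; the alternative — pooled missingness — is
stricter for no clear benefit). Pairwise transversion p-distances
(pairwise deletion) feed Saitou–Nei neighbor joining with negative branch
estimates clamped to zero and ties broken to the smallest taxon index
pair. For quartets the topology decision is distance-dominated, so NJ
replaces maximum-likelihood window trees; NJ is exact on additive input
and agrees with brute-force least-squares quartet selection, which the
tests verify. Window trees are classed BS (species topology), BR, RS by
the sister pair against the outgroup; an internal edge ≤ `tol` (default 0,
i.e. a strictly positive edge is required) is "other". Gene concordance
factors are class proportions; site concordance factors count decisive
2+2 transversion patterns.

## Direction and timing of gene flow

For each window tree the roan–sable path length, as a proportion of total
tree length, is extracted; values outside [0.0002, 0.9] are discarded
(bounds inclusive: the exclusion rule is written strictly, so the boundary
values stay). The BR-class distribution is compared with the BS-class
distribution: under roan→blue gene flow the introgressed windows still
coalesce roan and sable at the species-tree depth, so the two classes
match (unimodal, equal medians); under blue→roan the introgressed windows
carry roan–sable coalescences at the younger blue/sable depth, producing a
short mode and a depressed median. The published analysis judged this by
eye; here it is operationalized as (i) a permutation test on the median
difference and (ii) Hartigan's dip test on the BR distances, both at
alpha = 0.01, with calls: both non-significant → roan_to_blue;
significantly shorter BR median or significant dip → blue_to_roan;
otherwise indeterminate. The dip statistic is a direct port of the
classical algorithm, validated against an independent linear-programming
oracle (dip = the minimal sup-distance to a continuous unimodal CDF,
solvable exactly as one LP per candidate mode for small samples); its
p-value is Monte Carlo against the uniform null. With two roan
individuals, BR windows where blue attaches outside the roan pair indicate
gene flow predating the roan MRCA; blue nested between the roans indicates
younger flow.

Two caveats are worth stating. First, branch-length direction inference
has power only when coalescent-time variance (~2·Ne generations) is small
against the split-time gap; in the high-ILS regime implied by ~50% window
concordance the distributions overlap and calls go to the null. The
direction scenarios therefore use Ne = 25,000 throughout. Second,
tree-length normalization makes the proportion sensitive to total tree
length: a very recent pulse shortens introgressed trees and biases the
proportion upward in BR windows. The scenario pulse sits at 150 kgen,
where introgressed and resident blue lineages have comparable tip lengths.
Under f = 0 the BR (pure-ILS) distances are slightly deeper than BS ones
in expectation — the two classes are not exactly exchangeable — so the
null calibration of the permutation test is approximate, and the tests
assert rarity of false significance rather than exact uniformity.

## Diversity

Within-species pairwise differences over the jointly filtered site set,
counting only clean transversions, normalized by the single shared
denominator — the design that makes species comparable (one denominator
for the whole cohort, as in the source analysis). The simulation-truth
heterozygosity (fraction of sites where an individual's two haplotypes
differ) validates the statistic: across species with Ne spanning
10^3–10^5 the species-mean normalized diversity is strictly ordered and
rank-correlates with truth. Genotype-likelihood heterozygosity estimation
is intentionally not re-implemented; simulation truth replaces it as the
oracle.

The damage-robustness experiment observes the same truth twice: once
clean (8× coverage, eps = 0.002) and once with the designated ancient
individual read through heavy damage (delta_ss = 0.3, lambda = 0.3,
delta_ox = 0.1, read_len = 60). Robustness of the normalized statistic
requires the retained-site denominator to be dominated by genuine
polymorphism: majority-of-3 calling still flips ≈ 3·delta_ox² of G sites,
and those false polymorphisms enter everyone's denominator. The diversity
scenario therefore uses mu = 1.5e-7 on a 1.5-Mb genome — concentrating
genome-scale numbers of polymorphic sites into a desk-scale simulation —
and one damaged individual in a cohort of twelve, mirroring the single
heavily oxidized museum specimen in the real cohort. Under these
conditions the unaffected-species means move by well under 5% while raw
difference counts for pairs involving the damaged individual inflate
many-fold.

## Mitochondrial statistics

Aligned mitogenomes are filtered by dropping every column containing a
gap, N or IUPAC ambiguity in any sequence; segregating sites, nucleotide
diversity (mean pairwise difference per retained column, `n(n-1)/2` pairs,
no sample-size correction — the convention of haplotype-network software)
and the pairwise Hamming matrix are reported. Alignment construction is
upstream (MAFFT); synthetic alignments from the simulator are gap-free.

## Problem sizes and determinism

Scenario sizes (windows × length, replicate counts) are chosen so the full
validation bench runs on a single desktop core in minutes: discordance
calibration 10,000 gene trees; D-statistic 2,000 × 5 kb (pulse) and 50 ×
200 × 5 kb (null); direction 20 replicates per pulse direction at 200 ×
6 kb plus 12 null replicates; diversity 300 × 5 kb with 13 individuals.
Every stage takes an explicit seed; a single pipeline seed fans out to
stages via `numpy.random.SeedSequence.spawn`, and identical configs
reproduce byte-identical outputs (checksummed in the run manifest).

## Known limitations

- No recombination within windows, no selection, no indels; FASTQ-level
  read simulation is out of scope (base counts are the observation unit).
- The simulator's outgroup is a single haploid lineage used only for
  rooting/polarization.
- Pseudohaploid sequences mix an individual's two haplotypes, halving the
  branch-length signal of heterozygous introgressed loci; direction calls
  need correspondingly more windows than haplotype-resolved data would.
- Absolute diversity values from pseudohaploids are not estimates of pi;
  only relative comparisons across species sharing the denominator are
  meaningful.
- The dip-test null (uniform) is the conventional least-favourable choice;
  with small BR classes the test is conservative.
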