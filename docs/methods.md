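# Methods

This note documents the models and procedures implemented in `regevo`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions made where
the design was genuinely open.

## Coordinate model

All intervals are 0-based half-open (BED convention); GFF-style 1-based
inputs must be shifted at the reader boundary. Overlap fractions are
measured per interval: for intervals a, b the overlap length is
`max(0, min(ends) − max(starts))` and the fraction is taken of a's length,
of b's, or of both, selected by an overlap `mode`:

* `either` — ≥ `min_frac` of a **or** b. Default for replicate
  reproducibility, promoter calls, and tissue-specificity, mirroring
  reciprocal-overlap validation flags (`-f 0.5 -F 0.5 -e`) used with
  interval tools.
* `anchor` — ≥ `min_frac` of a only. Default for cross-species sharing,
  where the threshold is read as anchored on the query's projected interval.
* `reciprocal` — both.

Every call site exposes the mode; the defaults above are package policy, not
hard-coded behaviour. Merging treats touching intervals (end == start) as
one region, the common interval-tool default.

## Consensus peaks and RE classes

A replicate peak is *reproducible* if it overlaps peaks in at least
`min_replicates − 1` other replicates (default 2 replicates, i.e. one
supporter) at ≥ 50% of either peak's length; the consensus set is the merge
of all reproducible peaks across replicates. Reproducibility is counted as
pairwise support, not a k-way simultaneous intersection, matching the plain
reading of "detected in at least two biological replicates".

Consensus H3K27ac regions are then classified: *promoter* if some H3K4me3
consensus peak overlaps at ≥ 50% (either length); *enhancer* if H3K4me3
overlap is exactly zero; *ambiguous* otherwise (0 < overlap < threshold).
The ambiguous bin exists because the fate of sub-threshold overlaps is
otherwise undefined; keeping it explicit preserves the partition invariant
(the three outputs tile the H3K27ac input exactly), which the test suite
asserts on random inputs.

TSS proximity uses boundary-to-point distance on half-open intervals:
0 if a TSS lies inside the RE, else `TSS − end` (TSS right of the RE) or
`start − TSS` (left). An RE is proximal iff distance ≤ 5000 bp. Note the
boundary consequence: a TSS exactly 5000 bp past `end` is proximal.

## Cross-species conservation

The cross-species map is a table of anchor→target interval pairs with an
alignability flag (rows with `alignable = 0` carry `.` targets), standing in
for multi-genome alignments consumed as precomputed pairwise maps. An RE's
*projection* into a target species is the alignable record whose anchor
interval overlaps it most (ties → leftmost target); REs overlapping several
records are flagged (`n_blocks`) rather than split. Activity is *shared*
with species s iff the projection overlaps an RE of the same class in s at
≥ 50% of the projected interval (anchor mode). Class-matched sharing is the
default because conserved enhancers and promoters are tabulated separately
downstream; a class-agnostic mode is available.

Labels partition the anchor set: `all_conserved` (shared with every other
species), `clade_specific` (shared with exactly the anchor's clade),
`species_specific` (shared with none), `other` (any remaining pattern, kept
with its bitmask). Per-species counts satisfy, by construction and asserted
at run time:

    N_i = N_N + N_L + N_C        N_s = N_N + N_L

Re-running with a different anchor and clade partition yields
human-anchored categories (human-specific, human-pig, human-pig-mouse, …)
with no special-case code.

## Omics phylogenies

Distance between two species is `1 − ρ` with ρ Spearman's rank correlation
(Pearson on midranks; ties averaged) across orthologous features, giving
distances in [0, 2]. Trees are Saitou–Nei neighbor joining (via
scikit-bio), exact on additive matrices. NJ can produce small negative
branch lengths on non-additive input; these are clamped to zero with the
deficit moved to the sibling edge — a common practice that keeps total
branch length comparable and nonnegative — and the raw lengths are retained
on each node (`raw_length`).

Branch-length uncertainty: features are resampled with replacement B times
(default 1000), the tree rebuilt, and the total branch length recorded.
Replicates that draw a zero-variance species column are redrawn and counted.
Two bootstrap runs are compared by pairing replicates by index:

    p = 2 · min(#(a ≥ b) + 1, #(a ≤ b) + 1) / (B + 1), capped at 1

This paired empirical test is a documented substitute for an unspecified
significance procedure; an unpaired Mann–Whitney alternative is exposed.

Matrix preparation: CpG methylation level = methylated / total reads at
sites with coverage ≥ 5, averaged over retained CpGs per region (regions
with none are reported missing, not zero); expression features are kept iff
CPM > 1 (strict) in ≥ 20% of samples.

## RE-to-gene linking and gene comparisons

Basal regulatory domains span 5 kb upstream to 1 kb downstream of the TSS,
strand-aware, clipped to the chromosome. REs link to every gene whose domain
they overlap by ≥ 1 bp. Target assignment uses basal domains only; a
GREAT-style extension (up to 50 kb per side, stopping at the neighbouring
basal domain, never shrinking below basal) is available behind a flag
because extension belongs to the ontology-enrichment context, not to target
assignment.

Gene categories come from RE presence (Both / Promoter / Enhancer / None);
multiplicity groups use enhancers ≥ 3 or promoters ≥ 2 as "multiple"
(both thresholds configurable). Expression matching is greedy 1:1
nearest-neighbour without replacement with caliper 0.5 in pooled-SD units —
a direct-covariate replacement for propensity-based matching, which would be
overkill for a single matching variable. Rank tests are exact where the
null is enumerable (unpaired: combined n ≤ 20 without ties; paired: n ≤ 25
without zero differences) and normal-approximate with tie correction
otherwise; both variants (paired/unpaired) are exposed because published
usage is ambiguous for some comparisons. Cross-species transcriptional
stability is operationalized as the negative coefficient of variation of a
gene's expression across species — one reasonable choice among several, so
it is isolated in a single replaceable function.

## Enrichment tests

*Permutation enrichment*: the observed statistic (count of query intervals
overlapping the annotation, or overlapping bases) is compared with
`n_perm = 1000` random placements of the query. The null preserves each
interval's length and, by default, its chromosome (a genome-wide placement
mode is exposed, since published descriptions rarely state which null was
used); placed intervals may overlap each other. Fold =
observed / mean(permuted); empirical p uses the add-one rule with floor
1/(n_perm + 1).

*Count-based marker-set GWAS test*: membership is evaluated against the
region set grown by 50 kb per side and merged ("windows around REs" read as
per-side; a total-width mode is a flag). T_count counts member SNPs with
p strictly below t_o = 0.01 — each SNP's own p-value, resolving an index
ambiguity in the usual statement of the sum. Significance is the inclusive
hypergeometric upper tail P(X ≥ T_count) with population N (all SNPs),
successes K (genome-wide p < t_o), draws c (member SNPs); the enrichment
threshold is P < 1e−5. No multiple-testing correction is applied by the
test itself; Benjamini–Hochberg across traits is available as an explicit
post-step.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
sequencing data. Defaults describe a desk-scale six-mammal design: species
(cattle, sheep, goat | pig, human, mouse) in two clades with cattle the
anchor; 4 chromosomes × 10 Mb; 2000 anchor REs (~21% promoters, matching
the promoter share of published liver RE catalogues); 3 replicates per
mark; 500 private REs per non-anchor species.

*REs and peaks.* Anchor REs (500–2000 bp) occupy isolated slots; each gets a
planted conservation label from a configurable mix (defaults: 15% AC, 20%
clade-specific, 10% unalignable-specific, 15% alignable-specific, 40%
other), realized with largest-remainder rounding so planted counts are
exact. Orthologous intervals exist in exactly the species the label
dictates; per-species slot permutations scramble coordinates so projection
is non-trivial. Replicate peaks jitter each RE endpoint by up to 10% of its
length (≤ 20% total displacement), a cap chosen so that no planted
50%-overlap relation can be destroyed by noise — labels stay well-defined
under the default noise. Replicate dropout (probability a true peak is
missing from a replicate) defaults to 0 so that consensus calling and
conservation labelling are exactly recoverable; raising it trades recovery
for realism and is the knob for studying replicate irreproducibility.
H3K4me3 peaks are emitted only over promoter REs.

*Signal matrices.* Each feature draws an ancestral value ~ N(0, 1) at the
root of the species tree, then accumulates independent N(0, rate × branch
length) increments along branches. The ancestral spread is what makes the
rate identifiable from correlations: with pure rate-scaled increments the
interspecies correlation is scale-invariant and all rates would give the
same expected 1 − ρ, whereas with a fixed ancestral variance a larger rate
strictly lowers correlations and lengthens trees (rate → 0 collapses all
species onto identical columns). The default tree is ultrametric with the
two-clade topology; default per-omics rates order expression slowest and
methylation fastest.

*GWAS.* SNP positions are uniform; null p-values Uniform(0, 1); SNPs inside
the planted regions draw p ~ Beta(a, 1) with a = 1 + ln(effect)/ln(t_o), so
that P(p < t_o) = effect × t_o exactly while keeping p continuous — a point
mass at small p would make the strict inequality in T_count ambiguous.
Effect 1 recovers the null; effects < 1 (depletion) are rejected. SNP
p-values are independent given region membership; no LD structure is
simulated.

Every generator is a pure function of (config, seed); the global seed fans
out to fixed per-generator streams so regenerating one stage never perturbs
another.

What passing tests on this generator do **not** show: robustness to
correlated replicate noise, alignment errors or split orthology in real
whole-genome alignments, LD among SNPs, peak-width biases of real peak
callers, or non-Brownian (selective) signal evolution.

## Problem sizes used in the acceptance script

`scripts/acceptance.py` verifies: published-count arithmetic (means/sums of
the six per-species RE counts and conserved-class counts); the worked
hypergeometric tail (N = 10, K = 5, c = 4, T = 3 → 55/210); NJ on the
tabulated additive 4-taxon matrix (total length 11); type-I error of the
marker-set test at α = 0.05 over 500 random region sets on 10,000 uniform-p
SNPs (region sets cover ~30–70% of the genome so the discrete
hypergeometric null has rich support and the attained level sits near
nominal); detection of planted enrichment (effect 5, ~1000 in-region SNPs,
100 seeds, P < 1e−5); conservation-label recovery on 300 REs at zero
dropout; permutation-null fold with n_perm = 1000; topology recovery
(RF = 0) over 100 matrices of 2000 Brownian features; and the paired
bootstrap comparison of rates r vs 2r at B = 1000. These sizes are the
package's chosen desk-scale study conditions and run in about a minute.

## Known limitations

* Conservation projection takes the maximal-overlap map block; REs spanning
  many blocks are flagged but not split across them.
* The permutation null preserves interval lengths and (by default)
  chromosomes but not inter-region spacing or GC/mappability structure.
* The marker-set test inherits hypergeometric discreteness: for region sets
  containing few SNPs its attained size is below nominal.
* Greedy matching is order-dependent when many treated units compete for
  the same controls; optimal matching is out of scope.
* Bootstrap support values for individual branches are not computed, only
  total branch lengths.
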