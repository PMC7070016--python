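# Methods

`httscan` infers horizontal transfer of transposable elements (HTT) between
host lineages from pairwise TE–TE similarity hits, and ships a forward
simulator that generates every input the inference consumes, with ground
truth. This note describes the model behind each stage, the tunable
parameters, what the simulator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## The inference model

A TE copy transferred horizontally between two host lineages is younger
than the lineages' split, so its cross-lineage synonymous divergence (Ks)
falls below the divergence of vertically inherited sequence. The pipeline
operationalizes this in stages:

1. **Hit retention.** Pairwise nucleotide hits between TE copies of
   different species are kept when they span ≥ 300 bp at ≥ 75% identity
   with score ≥ 200, connect copies of the same superfamily, and involve
   species that diverged ≥ 120 My ago. The 120-My floor exists because, at
   the vertebrate synonymous rate (~3.1 × 10⁻⁹/site/year), slower-than-
   average vertical copies cannot be separated from transfer at shorter
   timescales. Reciprocal best-hit duplicates are collapsed to the
   higher-scoring record.

2. **Divergence filter.** For each species pair, the vertical null is the
   empirical distribution of core-gene (conserved single-copy ortholog) Ks
   between the two sister clades of the pair's most recent common
   ancestor (alignments ≥ 600 bp, longest per gene instance; for clade
   pairs older than 250 My, one genome per sub-30-My subclade). A hit
   survives iff `Ks + 2·sd(Ks) ≤ q0.005` of that null, `Ks < 0.5`, and the
   estimate rests on ≥ 100 codons. An identity pre-screen
   (`1 − pID/100 ≤ q0.005`) skips Ka/Ks computation for hopeless hits; it
   is a pure optimization (property-tested: it never removes a hit the Ks
   filter would keep).

3. **Ka/Ks.** Codon pairs are reconstructed from the nucleotide alignment
   plus per-copy protein-anchored frame maps (`codon_project`): a codon is
   kept only when both copies' within-codon phases agree at all three
   columns, no gap or ambiguity intersects it, and neither codon is a
   stop; phases are re-derived from each copy's own frame map after
   interruptions, never by continuation. Rates follow Li's (1993)
   degeneracy-class method. Conventions pinned here: site degeneracy from
   the count of synonymous single-base alternatives (1–2 → twofold);
   multi-substitution pathways weighted equally, stop-crossing pathways
   excluded when avoidable; difference counts attributed half to each
   flanking codon's site class; `sd(Ks)` by the delta method on the
   per-class transition/transversion proportions (multinomial variance).
   An independently written brute-force oracle agrees to 1 × 10⁻¹⁰; the
   classic R implementation agrees to 1 × 10⁻⁶ on codons free of the
   Leu/Arg/Ile special cases, which published implementations assign
   differently.

4. **Clustering.** Surviving hits are reduced to *hit groups*, one per
   (direct or indirect) transfer. Species are collapsed into clades
   younger than 40 My. Hits sharing a copy are pre-clustered
   (single-linkage) and thinned to ≤ 200 hits per cluster per species
   pair, preferring the longest coding regions. Within one (superfamily,
   clade-pair) set, two hits join when the copies they involve are more
   similar within at least one clade than between clades (**criterion
   1**, reference = the weaker hit's pID); communities are read off the
   criterion-1 graph by greedy modularity maximization with deterministic
   node order. Communities merge into groups when ≥ 5% of their
   cross-community hit pairs pass criterion 1 (or when their copy sets
   are non-overlapping fragments: no nucleotide homology and < 100 bp of
   shared protein-anchored region) **and** each community's mean hit Ks
   reaches the core-gene q0.005 of every within-side host divergence a
   common transfer would have to predate (**criterion 2**, a reconstruction of the
   transfer-chronology argument; isolated in one predicate). Groups
   are complete-linkage clusters of the community pass graph — every
   pair inside a group passes both criteria, re-checked exhaustively by a
   property test. Merge order: descending mean member pID, ties by id.

5. **Evaluation.** Copies of the member species that were thinned away
   earlier are *retrieved*: a candidate joins a clade when its mean
   identity to that clade's group copies (alignments ≥ 100 bp) exceeds
   the group's mean cross-clade hit identity (a both-sides candidate
   joins the side it resembles more). Groups need ≥ 5 copies per clade
   including retrieved ones and ≥ 2 hit copies per clade
   (anti-contamination), a modal Ks class exceeding the rightmost
   occupied class by ≥ 20 hits, and a maximum Ks at least 0.2 below the
   selection threshold `θ = min(0.5, q0.005)` (anti-truncation: a
   distribution cut off at the threshold is the left tail of a vertical
   distribution, not a transfer). Histogram classes follow the classic
   plotting default: Sturges' class count on nice (1/2/5 × 10ᵏ)
   boundaries, right-closed intervals; "rightmost class" is the rightmost
   occupied one and modal ties break leftward.

6. **Counting.** Groups are reduced to a minimal set of independent
   events by the greedy explanatory-transfer procedure: processing groups
   by increasing reliability (the lower of the two per-clade sums of each
   copy's best hit pID), a focal group is explained when every involved
   species has a copy more similar to a clade-compatible copy of another
   pooled group than to at least one of its own cross-clade partners,
   with ≥ 2 distinct explanatory groups overall (requirement 1);
   explanatory groups whose removal breaks requirement 1 are flagged
   required and are never themselves explained; explained groups leave
   the pool. The procedure is a greedy bound, not an exact set-cover
   minimum; tests check it against a literal independent implementation
   and against the best over all processing orders (within +1).

7. **Permutations.** Each independent transfer is reduced to the species
   pair of its highest-identity hit. Null distributions of per-clade
   transfer counts come from bijective species relabelings within each
   unit (superfamily; superfamilies with < 20 transfers pooled per TE
   class; units > 120 transfers split into seeded balanced subsets),
   rejecting relabelings that imply a transfer between species diverged
   < 120 My (the observed data cannot contain one). Habitat effects are
   tested by permuting aquatic/terrestrial labels over the tetrapod
   species involved in fish transfers.

8. **Selection regimes.** Per superfamily, Ka/Ks distributions are built
   for horizontally diverged pairs (the retained hits) and within-genome
   pairs (copies sharing a hit community and a genome, ≥ 300 coding bp),
   and each is tested against neutrality with a one-sided Wilcoxon
   signed-rank test of location 1 (the one-sample analogue of the
   Mann-Whitney test; values exactly 1 dropped; exact null to n = 25,
   normal approximation with continuity correction beyond). Ratios with
   Ks = 0 carry no signal and are excluded. No multiple-testing
   correction is applied by default (per-superfamily p-values are
   reported directly).

## The simulator

The generator's defaults are the reference conditions the tests assume;
they are not tuned per test.

**Sequence process.** Codon sequences evolve by proposal/rejection: point
mutations proposed uniformly over the three alternative bases at rate
`mu_s` per site per year; stop-creating proposals always rejected;
non-synonymous proposals accepted with probability ω. Expected pairwise
synonymous divergence for lineages split t years ago is `2·mu_s·t` on
Li's synonymous-site scale, and realized Ka/Ks ≈ ω. Because stop-avoiding
rejections are all non-synonymous, the realized neutral process is very
slightly purifying (median Ka/Ks ≈ 0.95 at ω = 1); the neutrality test's
measured type-I rate under ω = 1 (~1.3% at the 1% level, 25 pairs per
replicate) stays within the acceptance band.

**TE dynamics.** Each superfamily carries one or more families; families
share a protein anchor but no nucleotide homology. Within each lineage a
family keeps one immortal, always-active **master** copy; transposition
bursts (default 0.3/lineage/My) insert copies of the master, giving the
star-like within-genome divergence structure the clustering criteria
assume (the master-gene model of TE amplification). Non-master copies
deactivate after an exponential active span (mean 10 My, hard cap 15 My
— activity windows are finite under host silencing), then evolve
neutrally, lose their protein-anchored frames after 6 My inert
(frameshift accumulation leaves old relics alignable at the DNA level
but useless for codon-level rates — the reason the pipeline's 100-codon
rule exists), and are deleted or degraded beyond annotation at rate
0.04/My. A planted transfer copies the donor lineage's master — the
functional, replicating element is what invades — into the recipient
branch, where it founds a new master lineage, transposes `n_amplify`
times immediately and keeps transposing at `amplify_rate` (default
2.5/lineage/My, far below real invasion sizes) in all descendant
lineages. Optional per-copy lognormal rate multipliers (mean one, sd
`rate_lognorm_sd`, clamped to [0.1, 10] — synonymous rates vary
severalfold across lineages, not without bound) generate the
slow-vertical-tail scenario the truncation filter targets.

**Emissions.** Core genes (default 500 × 600 bp) evolve neutrally along
the tree; per-gene pairwise Ks feeds the vertical null. Hits mimic
reciprocal searches: for every ordered species pair in different
sub-40-My clades, each query copy reports its best positional alignment
per target species (score 2·matches − 3·mismatches, the default
nucleotide search weights), thresholded like real retention. Identity
tables are all-vs-all within families, dropping pairs below a 70%
detectability horizon. The default tree has two 450-My-diverged sides of
two three-species clades each (crowns 15 My, splits 90 My), so transfer
is only callable across the deep split; a three-lineage variant in the
test suite (150/450 My) exercises indirect transfers.

**What the simulator does not emulate** — and hence what green tests do
not certify about real data: indels and alignment error (copies are
gapless homologs; indel robustness is tested through synthetic gapped
fixtures of the codon projection), assembly artifacts, base-composition
non-stationarity, rate variation among core genes (the vertical null is
clock-like, so its 0.5% quantile is tighter than a real one), SINEs and
non-coding TEs, taxonomic misclassification, and genome-scale copy
numbers.

## Problem sizes

Tests run at desk scale: 60–120 core genes per dataset (for 450-My sides
the core quantile saturates far above the 0.5 Ks cap at any n, so
thresholds are unchanged), 10/8/6/6 replicate seeds for 1/3/5/8 planted
transfers with at most one failing seed allowed, 500 replicates for
estimator calibration, 200 replicates × 400 permutations for the
permutation type-I check. The acceptance script re-runs a five-transfer
screen with 1000 permutations per unit.

## Known limitations

- The truncation rule cannot reject a vertical pair whose lineage is slow
  enough to mimic a *recent* transfer outright; bounded rate variation
  (and, on real data, the 120-My rule) is what keeps this case rare, and
  one near-boundary group in ~30 does slip through the guard fixture.
- Criterion 2's exact inequality is a reconstruction of figure logic and
  lives behind a single predicate for easy revision.
- The explanatory-transfer count is order-dependent by design; reversing
  the order changes counts by ≲ 15% on datasets with indirect transfers.
- The published 307-species vertebrate timetree that the search-count
  reproduction check needs is not bundled; the check runs only when that
  file is supplied at `data/timetree_307.nwk`.
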