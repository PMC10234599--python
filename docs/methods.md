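# Methods

`strainshare` re-implements, as a desk-scale tested pipeline, the strain-level
mother-to-infant transmission analysis used in large mother-infant metagenomic
cohort studies: species-level genome binning of MAGs, selection of
species-specific marker genes, reconstruction of per-sample strain consensus
sequences, strain phylogenies with a data-driven identity threshold, and
cohort-level sharing and abundance statistics. Everything runs end-to-end on
synthetic cohorts with planted ground truth, so each stage's behavior is
verifiable without any sequence download.

## Genome binning (SGB/GGB/FGB)

MAGs passing the quality gate (completeness strictly above 50%, contamination
strictly below 5%) are sketched with a MinHash over canonical k-mers
(k = 21, sketch size s = 1000, fixed splitmix64 mixing function so sketches
are comparable across runs). Pairwise distances use the Mash point estimate
d = −ln(2j/(1+j))/k from the bottom-s Jaccard estimate j; a zero estimate is
capped at d = 1.0 to keep linkage finite.

Bins are formed assignment-first: a genome joins the closest existing
species-level bin when its mean sketch distance to the bin's members is
strictly below 5% (the mean-to-members rule keeps assignment consistent with
average linkage; the literature procedure specifies only "closest"). Leftover
genomes are clustered by average-linkage agglomeration; cutting one merge
schedule at 5%, 15% and 30% yields the species- (SGB), genus- (GGB) and
family-level (FGB) partitions and guarantees nesting. Merges at linkage
height exactly equal to the threshold are not applied, and ties merge the
pair with smallest member indices, making the partition deterministic. The
agglomeration is implemented directly (O(n³)) because these cut and
tie-break semantics are part of the contract; scipy's implementation serves
as an independent cross-check in the tests.

Taxonomy is a plurality vote over the reference genomes in the bin, falling
back one level at a time (SGB → GGB → FGB → up to 100 nearest references
genome-wide) when a bin has none; a tie backs off to the deepest rank where a
strict plurality of label prefixes exists. Unknown SGBs (no reference member)
with fewer than 5 MAGs are excluded from strain profiling; known SGBs are
kept at any size.

## Marker genes

Core genes (present in ≥ 80% of an SGB's members — the prevalence cutoff
defining "core" is a tool-side choice, exposed as `core_frac`) are split into
150-nt fragments (a terminal remainder is kept only at ≥ 50 nt; genes shorter
than one fragment are used whole). A gene is "present" in a genome when any
fragment occurs on either strand; mapping is exact containment by default,
with an optional seed-and-verify substitution tolerance (`max_mismatches`)
standing in for a sensitive short-read mapper at desk scale. A core gene
becomes a marker iff, for every other SGB, it is present in at most 1% of
that SGB's genomes (per-SGB fractions; a pooled-external variant is a config
switch). Selection is therefore monotone: adding external genomes can only
shrink a marker set.

## Consensus, MSA and trees

A single consensus engine serves the bacterial markers and the eukaryote
references. Reads are excluded before pileup when mapping quality < 30,
identity < 97%, or aligned length < 30 nt; a position is called to its
dominant base only with depth ≥ 5 and a dominant-allele fraction ≥ 80%
(both boundaries inclusive), else N. Per-sample marker consensi are
reference-coordinate aligned, so concatenation needs no realignment step.
Samples and markers are filtered in one pass (markers present in ≥ 5 samples
first, then samples with ≥ 10 surviving markers; a marker counts as present
when ≥ 80% of its positions are called, `min_called_frac`). MSA columns with
strictly more than 50% missing data ({N, -}) are dropped. Fewer than 4
surviving samples skips the SGB with a logged reason.

Pairwise distances are p-distances over co-called columns (pairs with fewer
than `min_overlap_cols` = 50 shared columns are flagged missing, never given
a fabricated 0). Trees are neighbor-joining (via scikit-bio) — the sharing
statistic depends on relative distances, which NJ preserves at this scale;
negative branch lengths are clamped to zero, and an externally computed
newick tree can be supplied through the newick reader for parity with
likelihood-based tooling. The sharing statistic consumes patristic distances
divided by the tree's total branch length, which bounds them in [0, 1].

## Sharing inference

Related pairs are same-subject (longitudinal) pairs and mother-infant pairs
within a family. Per SGB, the strain-identity threshold is the 1st percentile
(type-7 linear interpolation) of the unrelated-pair normalized distances,
estimated only when ≥ 50 unrelated distances exist (`min_unrelated_pairs`
keeps the 1st percentile estimable); related distances never enter the
estimate. A strain-sharing event is a related pair strictly below the
threshold. By construction the procedure has an implicit type-I calibration:
with no transmission, about 1% of related pairs fall below the threshold.

Per-infant summaries report 100 × (SGBs shared with the own mother) /
(profilable SGBs). The denominator restricts to SGBs where the mother is also
profiled — an SGB the mother does not carry cannot be shared — with an
infant-only denominator available as a switch, since published figure legends
do not fix this choice. For longitudinal subjects an SGB counts as shared if
any infant time point shares with any maternal time point. The
unrelated-mothers baseline computes the same percentage against every
same-cohort unrelated mother and summarizes per infant by the median. Cohort
contrasts report group medians, a two-sided Mann-Whitney U on per-infant
percentages, and a Fisher exact test on pooled shared/not-shared counts.

## Coverage-based typing

Eukaryote subtypes are detected by breadth of coverage against per-subtype
reference genomes: a sample is positive for a subtype iff strictly more than
10% of reference positions are covered by at least one aligned base, each
subtype independently (multi-mapping reads count for every reference). For
positive samples the shared consensus engine builds a per-subtype MSA (same
five filters, same >50% column rule); mother-infant subtype sharing uses the
percentile rule when enough unrelated pairs exist, else a fixed distance
ceiling (0.001, flagged in the output) — eukaryote positivity is typically
too sparse for the percentile. Reference ranking (the food-source
attribution logic) orders candidate references by descending breadth, ties
broken by id.

## Cohort statistics

Differential abundance between two groups: species prefiltered at > 0.05%
mean relative abundance and > 20% prevalence in at least one group; the
comparison group subsampled uniformly without replacement to the reference
group's infant age strata ([0, 6), [6, 12), [12, ∞) months); a two-sided
Wilcoxon rank-sum per species (exact for small tie-free samples, tie-corrected
normal approximation otherwise) with Benjamini-Hochberg correction across
species; the whole test repeated 10 times with different random pickings. The
per-species summary is the median across repeats (min and max also reported);
BH is applied within each repeat and the adjusted values median-combined,
with a switch to apply BH once to the median raw p instead — the repeats'
combination rule is not fixed by the published procedure. Prevalence
contrasts run a Mann-Whitney U on presence/absence; because the standard
exact method cannot handle the massive ties of binary data, small samples use
an exact hypergeometric enumeration over the success split (the U statistic
is a function of group-A successes at fixed margins). Bray-Curtis matrices
(scipy) are provided for downstream ordination; NMDS and PERMANOVA are
deliberately out of scope.

## Synthetic data: what it emulates, and what it does not

The generators plant complete ground truth:

* **Pangenomes** — per-SGB core and accessory gene repertoires (one contig
  per gene), per-genome gene copies diverging from the ancestral gene at half
  the stated within-SGB divergence so genome pairs differ by roughly the
  stated value; optionally, core genes copied verbatim into a chosen fraction
  of another SGB's genomes, exactly the homologs the 1% cross-mapping rule
  must reject.
* **Cohorts** — one mother and one infant per family; each mother strain sits
  at half the between-strain divergence from the SGB ancestor (so independent
  strains differ by the stated between-strain divergence, default 0.02);
  carriage is Bernoulli per sample and SGB, independent of transmission, so
  detectability and sharing can be separated; an infant-carried SGB is, with
  probability `p_transmit`, the mother's strain mutated at the within-strain
  divergence (default 0.001), else an independent strain. Strain genomes are
  gene-wise concatenations of the SGB's core genes (no intergenic sequence),
  sharing coordinates with marker selection and consensus calling.
* **Reads** — uniform start positions, Bernoulli strands, independent
  per-base substitution errors, read count = round(depth × genome length /
  read length); every read emits its true alignment record, so no mapper is
  needed. Defaults for the end-to-end experiments: depth 20, read length
  100 nt, error rate 0.005 — enough depth that the consensus filters
  (depth ≥ 5, dominant ≥ 80%) call nearly every position while leaving the
  filters with real work at coverage dips. For reference-ranking experiments,
  true alignments are *projected* onto coordinate-shared candidate references
  and dropped below a mapper-like identity floor (default 90%).
* **Abundance tables** — log-normal species means and log-normal sample
  draws renormalized to 1 (compositional, heavy-tailed); planted fold
  changes multiply the affected group's mean before renormalization, which
  slightly attenuates large folds, as in real relative-abundance data.

Not emulated: sequencing quality-score profiles, indels, chimeric reads and
assembly artifacts, real read mapping (alignments are true by construction or
projected), within-sample strain mixtures, and recombination. Passing tests
therefore demonstrate the correctness and calibration of the inference
machinery under its stated model — not robustness to mapper idiosyncrasies or
mixed-strain samples.

## Numerical choices and problem sizes

All generators and pipeline stages take explicit seeds; identical seed and
inputs give identical outputs. Percentiles use linear interpolation (type-7);
argmax ties in consensus resolve to the alphabetically first base (only
observable below a 50% dominance threshold); clustering and assignment ties
resolve lexicographically. The test and acceptance experiments use 50
families × 10 SGBs (10 marker genes of 300 nt each) for the read-level
recovery and null-calibration runs, 100 replicates of 25-family cohorts
(consensus-stage pipeline) for the transmission contrast, and 1,000 simulated
tables for the statistical calibration — sizes chosen so every planted
quantity is estimable with useful precision on a single CPU.

## Known limitations

* NJ replaces maximum-likelihood tree inference; bootstrap support is not
  computed.
* The exact sensitivity of a short-read mapper is not reproduced; fragment
  cross-mapping is containment-based (optionally with substitutions).
* Bin representatives are not recomputed as bins grow during assignment; the
  genome-to-bin distance is always the mean over current members.
* The eukaryote subtype sharing rule below the unrelated-pair minimum is a
  fixed ceiling, a stand-in where the source procedure is not specified.
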