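# strainshare

Strain-resolved mother-to-infant microbiome sharing analysis, implemented as a
tested, reusable pipeline that runs end-to-end on synthetic cohorts with
planted transmission events.

## The problem

Whether an infant's gut bacteria were acquired from the mother cannot be
decided at the species level: mother and infant sharing a species may carry
unrelated strains. Strain-level transmission inference therefore asks, for
each species-level genome bin (SGB), whether the phylogenetic distance between
the mother's and the infant's strain is small enough to call them *the same
strain* — and calibrates "small enough" from the data itself.

`strainshare` implements that workflow for researchers studying vertical
microbiome transmission:

1. **Genome binning** — MAGs with completeness >50% and contamination <5% are
   clustered by MinHash/Mash distance with average linkage into SGBs, GGBs and
   FGBs at 5%, 15% and 30% genetic distance; taxonomy by majority vote over
   reference genomes with level fallback; unknown SGBs with <5 MAGs excluded.
2. **Marker selection** — SGB core genes are cut into 150-nt fragments and
   cross-mapped; genes found in >1% of any other SGB's genomes are rejected.
3. **Strain profiling** — reads filtered on mapq ≥ 30, identity ≥ 97%, length
   ≥ 30 nt; consensus called at depth ≥ 5 and dominant-allele frequency
   ≥ 80%; samples/markers filtered StrainPhlAn-style (marker in ≥5 samples,
   sample with ≥10 markers); MSA columns with >50% missing dropped;
   neighbor-joining trees; patristic distances normalized by total branch
   length.
4. **Sharing inference** — per SGB, the strain-identity threshold *t* is the
   1st percentile of the unrelated-pair distance distribution; a related pair
   (mother-infant or same subject) at distance `d < t` is a strain-sharing
   event. Per-infant sharing percentages, per-SGB sharing rates and cohort
   contrasts (Mann-Whitney, Fisher) follow.
5. **Coverage typing** — eukaryote subtypes (e.g. *Blastocystis* ST1-ST9)
   called positive at breadth of coverage >10%; subtype consensus phylogenies
   with the same five filters; best-reference ranking by breadth of coverage
   for source attribution.
6. **Cohort statistics** — differential abundance with abundance/prevalence
   prefilters (>0.05% mean, >20% prevalence), age-matched random subsampling
   repeated 10 times, Wilcoxon rank-sum with Benjamini-Hochberg correction;
   exact presence/absence Mann-Whitney prevalence contrasts; Bray-Curtis
   matrices.

A first-class synthetic-data module generates pangenomes, mother-infant
cohorts with a controllable per-SGB transmission probability, shotgun reads
with true alignments, and abundance tables with planted effects — so every
stage is testable against known ground truth. See `docs/methods.md` for the
model details and design choices.

## Worked example

Simulate a 50-family cohort with 10 SGBs where each infant-carried SGB has a
30% chance of being the mother's strain (within-strain divergence 0.001,
between-strain 0.02), sequence every strain at 20x with 0.5% error, and run
the full pipeline:

```python
from strainshare import transmission_experiment

out = transmission_experiment(n_families=50, n_sgbs=10, p_transmit=0.3,
                              carriage_prob=1.0, within_strain_div=0.001,
                              between_strain_div=0.02, seed=7, use_reads=True)
print(f"precision {out['precision']:.3f}  recall {out['recall']:.3f}  "
      f"median infant sharing {out['median_infant_sharing_pct']:.1f}%")
```

```
precision 0.966  recall 0.986  median infant sharing 30.0%
```

The pipeline recovered 144 of the 146 planted transmission events (recall
0.986) while calling 5 spurious ones (precision 0.966 — the 1st-percentile
threshold concedes ~1% false positives among related pairs by construction),
and the median infant shares 30% of co-profiled SGBs with its mother,
matching the planted transmission probability.

The same machinery is available from the shell:

```bash
strainshare share --n-families 20 --n-sgbs 5 --p-transmit 0.3 --seed 0 --outdir run/
strainshare stats --abundance profiles.tsv --manifest manifest.tsv \
    --reference-group non_westernized --comparison-group westernized --out diff.tsv
```

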