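"""Pipeline configuration: every numeric threshold used downstream, in one place.

Defaults mirror the published strain-transmission workflow this package
re-implements: species/genus/family genome bins at 5/15/30% genetic distance,
MAG quality gates (completeness >50%, contamination <5%), 150-nt marker
fragments with a 1% cross-mapping ceiling, StrainPhlAn-style sample/marker
filters (marker in >=5 samples, sample with >=10 markers), a strain-identity
threshold at the 1st percentile of unrelated-pair distances, breadth-of-coverage
positivity above 10%, and the five consensus filters (mapq >=30, depth >=5,
read identity >=97%, aligned length >=30 nt, dominant allele >=80%).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # genome binning
    sgb_threshold: float = 0.05
    ggb_threshold: float = 0.15
    fgb_threshold: float = 0.30
    completeness_min_pct: float = 50.0
    contamination_max_pct: float = 5.0
    min_mags_per_usgb: int = 5
    # marker selection
    fragment_len_nt: int = 150
    min_fragment_tail_nt: int = 50
    cross_map_max_frac: float = 0.01
    cross_map_pooled: bool = False  # pool external genomes instead of per-SGB fractions
    max_mismatches: int = 0  # fragment-to-genome mapping tolerance
    core_frac: float = 0.8  # gene prevalence defining "core" (tool-side choice)
    # strain profiling
    marker_in_n_samples: int = 5
    sample_with_n_markers: int = 10
    min_called_frac: float = 0.8  # marker counts as present in a sample above this
    min_mapq: int = 30
    min_depth: int = 5
    min_read_identity_frac: float = 0.97
    min_aligned_len_nt: int = 30
    min_dominant_allele_frac: float = 0.80
    max_missing_col_frac: float = 0.50
    min_overlap_cols: int = 50  # pairwise p-distance needs this many co-called columns
    # sharing inference
    sharing_percentile: float = 1.0
    min_unrelated_pairs: int = 50
    infant_only_denominator: bool = False  # sharing pct over infant SGBs regardless of mother
    # coverage typing
    boc_positive_frac: float = 0.10
    st_fallback_ceiling: float = 0.001  # fixed distance ceiling when unrelated pairs are scarce
    # cohort statistics
    diff_min_mean_abundance_frac: float = 0.0005
    diff_min_prevalence_frac: float = 0.20
    diff_n_repeats: int = 10
    bh_within_repeat: bool = True  # BH per repeat then median; else BH on median raw p
    # sketching
    kmer_len: int = 21
    sketch_size: int = 1000
    # seed for stages that do not receive one explicitly
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "sgb_threshold": self.sgb_threshold,
            "ggb_threshold": self.ggb_threshold,
            "fgb_threshold": self.fgb_threshold,
            "cross_map_max_frac": self.cross_map_max_frac,
            "core_frac": self.core_frac,
            "min_called_frac": self.min_called_frac,
            "min_read_identity_frac": self.min_read_identity_frac,
            "min_dominant_allele_frac": self.min_dominant_allele_frac,
            "max_missing_col_frac": self.max_missing_col_frac,
            "boc_positive_frac": self.boc_positive_frac,
            "diff_min_mean_abundance_frac": self.diff_min_mean_abundance_frac,
            "diff_min_prevalence_frac": self.diff_min_prevalence_frac,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not self.sgb_threshold < self.ggb_threshold < self.fgb_threshold:
            raise ValueError("bin thresholds must be ordered sgb < ggb < fgb")
        counts = {
            "min_mags_per_usgb": self.min_mags_per_usgb,
            "fragment_len_nt": self.fragment_len_nt,
            "min_fragment_tail_nt": self.min_fragment_tail_nt,
            "marker_in_n_samples": self.marker_in_n_samples,
            "sample_with_n_markers": self.sample_with_n_markers,
            "min_depth": self.min_depth,
            "min_aligned_len_nt": self.min_aligned_len_nt,
            "min_overlap_cols": self.min_overlap_cols,
            "min_unrelated_pairs": self.min_unrelated_pairs,
            "diff_n_repeats": self.diff_n_repeats,
            "kmer_len": self.kmer_len,
            "sketch_size": self.sketch_size,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value}")
        if not 0.0 < self.sharing_percentile < 100.0:
            raise ValueError("sharing_percentile must be in (0, 100)")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML mapping; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
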