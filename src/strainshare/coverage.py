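"""Coverage-based organism detection and strain comparison.

Used for organisms outside the marker-gene machinery: eukaryote subtypes
(e.g. *Blastocystis* ST1-ST9) detected by breadth of coverage against per-ST
reference genomes (>10% of positions covered means positive), filtered
consensus MSAs for positive samples using the same five-filter consensus
engine as the bacterial path, and best-reference ranking by breadth of
coverage (the food-source attribution logic used for
*Fructilactobacillus sanfranciscensis*).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import AlignmentRecord, CohortManifest
from .profiling import (SGBSkipped, StrainMSA, build_msa, call_consensus,
                        pairwise_pdistance, pileup)
from .sharing import infer_threshold, related_pairs


@dataclass
class CoverageProfile:
    sample_id: str
    reference_id: str
    reference_length: int
    depth: np.ndarray  # per-position read depth
    breadth_of_coverage: float  # fraction of positions with depth >= 1


@dataclass
class STCall:
    sample_id: str
    st_id: str
    breadth: float
    positive: bool


def breadth_of_coverage(records: Sequence[AlignmentRecord], reference_id: str,
                        reference_length: int, sample_id: str = "") -> CoverageProfile:
    """Per-position depth and the fraction of reference positions covered by
    at least one aligned base. No quality filters: detection mirrors a raw
    genomecov-style pass, the consensus filters come later."""
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    depth = np.zeros(reference_length, dtype=np.int64)
    for r in records:
        if r.ref_id != reference_id:
            continue
        end = r.ref_start + r.aligned_len_nt
        if end > reference_length:
            raise ValueError("alignment extends past the reference end")
        depth[r.ref_start : end] += 1
    return CoverageProfile(
        sample_id=sample_id, reference_id=reference_id,
        reference_length=reference_length, depth=depth,
        breadth_of_coverage=float((depth >= 1).mean()),
    )


def call_subtypes(profiles: Sequence[CoverageProfile],
                  config: PipelineConfig | None = None) -> list[STCall]:
    """Independent per-ST positivity: breadth strictly above
    ``boc_positive_frac`` (default 10%). A sample may be positive for several
    subtypes."""
    config = config or PipelineConfig()
    return [
        STCall(sample_id=p.sample_id, st_id=p.reference_id,
               breadth=p.breadth_of_coverage,
               positive=p.breadth_of_coverage > config.boc_positive_frac)
        for p in profiles
    ]


def eukaryote_consensus_msa(alignments_by_sample: Mapping[str, Sequence[AlignmentRecord]],
                            st_id: str, reference_length: int,
                            config: PipelineConfig | None = None
                            ) -> tuple[StrainMSA, list[str]]:
    """Consensus MSA over one subtype's reference for its positive samples.

    Reuses the shared pileup/consensus engine (mapq >=30, depth >=5, identity
    >=97%, length >=30 nt, dominant allele >=80%); samples whose consensus is
    entirely N are dropped (returned separately); columns with more than 50%
    missing data are excluded.
    """
    config = config or PipelineConfig()
    consensus: dict[str, dict] = {}
    kept, dropped = [], []
    for sample_id in sorted(alignments_by_sample):
        pile = pileup(list(alignments_by_sample[sample_id]), reference_length,
                      config, ref_id=st_id)
        cons = call_consensus(pile.counts, sample_id=sample_id, marker_id=st_id,
                              config=config)
        if cons.called_frac == 0.0:
            dropped.append(sample_id)
            continue
        kept.append(sample_id)
        consensus[sample_id] = {st_id: cons}
    msa = build_msa(consensus, kept, [st_id], {st_id: reference_length},
                    sgb_id=st_id, config=config)
    return msa, dropped


def st_strain_sharing(msa: StrainMSA, manifest: CohortManifest,
                      config: PipelineConfig | None = None) -> pd.DataFrame:
    """Shared / not-shared per co-positive mother-infant pair.

    Uses the bacterial rule (1st percentile of unrelated-pair p-distances)
    when enough unrelated pairs exist; otherwise falls back to the fixed
    distance ceiling ``st_fallback_ceiling`` (flagged in the output) — typical
    for sparse eukaryote positivity.
    """
    config = config or PipelineConfig()
    D = pairwise_pdistance(msa, config)
    ids = msa.sample_ids
    related = related_pairs(manifest)
    try:
        threshold, _ = infer_threshold(D, ids, related, config)
        fallback = False
    except SGBSkipped:
        threshold, fallback = config.st_fallback_ceiling, True
    idx = {s: i for i, s in enumerate(ids)}
    rows = []
    for mother, infant in manifest.mother_infant_pairs():
        if mother not in idx or infant not in idx:
            continue
        d = D[idx[mother], idx[infant]]
        rows.append(dict(
            st_id=msa.sgb_id, mother_sample=mother, infant_sample=infant,
            distance=float(d) if not np.isnan(d) else np.nan,
            shared=bool(not np.isnan(d) and d < threshold),
            threshold=threshold, threshold_is_fallback=fallback,
        ))
    return pd.DataFrame(rows, columns=["st_id", "mother_sample", "infant_sample",
                                       "distance", "shared", "threshold",
                                       "threshold_is_fallback"])


def rank_references_by_boc(profiles: Sequence[CoverageProfile]) -> list[tuple[str, float]]:
    """References for one sample ordered by descending breadth of coverage;
    ties break lexicographically by reference id."""
    if not profiles:
        raise ValueError("no candidate references to rank")
    return sorted(
        ((p.reference_id, p.breadth_of_coverage) for p in profiles),
        key=lambda t: (-t[1], t[0]),
    )
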