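"""End-to-end orchestration on synthetic cohorts.

``run_sharing_pipeline`` executes the full chain for every SGB of a simulated
cohort: shotgun reads from each carried strain genome (or, optionally, the
strain genomes directly as perfect consensi), filtered pileup and consensus per
marker gene, StrainPhlAn-style sample/marker filters, MSA assembly and column
cleaning, pairwise p-distances, a neighbor-joining tree, patristic distances
normalized by total branch length, the 1st-percentile unrelated-pair threshold,
and strain-sharing events. ``evaluate_events`` scores the calls against the
planted transmission truth; the experiment helpers reproduce the cohort-level
contrasts and the null calibration of the threshold rule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .profiling import (ConsensusSequence, SGBSkipped, build_msa, call_consensus,
                        filter_profiles, nj_tree, normalized_patristic,
                        pairwise_pdistance, pileup)
from .sharing import (SharingResult, detect_events, infant_sharing_summary,
                      infer_threshold, related_pairs)
from .simulate import CohortSim, SyntheticSGBSpec, simulate_cohort, simulate_reads

logger = logging.getLogger("strainshare")


@dataclass
class PipelineResult:
    results: dict[str, SharingResult]
    profiled: dict[str, set[str]]  # sgb -> samples surviving filters
    skipped: dict[str, str] = field(default_factory=dict)  # sgb -> reason

    def summary(self, cohort: CohortSim, config: PipelineConfig | None = None,
                sgb_known: dict[str, bool] | None = None) -> pd.DataFrame:
        return infant_sharing_summary(self.results, self.profiled, cohort.manifest,
                                      sgb_known=sgb_known, config=config)


def run_sharing_pipeline(cohort: CohortSim, config: PipelineConfig | None = None,
                         seed: int = 0, mean_depth: float = 20.0, read_len: int = 100,
                         err_rate: float = 0.005, use_reads: bool = True,
                         markers: dict[str, list[str]] | None = None) -> PipelineResult:
    """Run reads -> consensus -> tree -> threshold -> events for every SGB.

    ``markers`` optionally restricts each SGB to a marker-gene subset (e.g.
    the output of marker selection); by default all simulated core genes are
    used. With ``use_reads=False`` the strain genomes stand in as perfect
    consensi and the pipeline starts at the filtering/MSA stage — the read,
    pileup and consensus stages are exercised wherever the experiment's
    question involves them.
    """
    config = config or PipelineConfig()
    related = related_pairs(cohort.manifest)
    results: dict[str, SharingResult] = {}
    profiled: dict[str, set[str]] = {}
    skipped: dict[str, str] = {}

    for sgb_index, sgb_id in enumerate(cohort.sgb_ids):
        offsets = cohort.gene_offsets[sgb_id]
        if markers is not None:
            wanted = set(markers.get(sgb_id, []))
            offsets = [o for o in offsets if o[0] in wanted]
        if not offsets:
            skipped[sgb_id] = "no markers available"
            continue
        marker_lengths = {gid: end - start for gid, start, end in offsets}
        carriers = cohort.carriers(sgb_id)
        consensus: dict[str, dict] = {}
        frac_rows = {}
        for sample_index, sample_id in enumerate(carriers):
            genome = cohort.strain_genomes[(sample_id, sgb_id)]
            if use_reads:
                rs = simulate_reads(
                    genome, mean_depth, read_len, err_rate,
                    np.random.default_rng([int(seed) % (2**31), sgb_index, sample_index]),
                    ref_id=f"{sample_id}:{sgb_id}")
                pile = pileup(rs.alignments, len(genome), config, ref_id=sgb_id)
                counts = pile.counts
            else:
                counts = None
            per_marker = {}
            fracs = {}
            for gid, start, end in offsets:
                if use_reads:
                    cons = call_consensus(counts[start:end], sample_id, gid, config)
                else:
                    cons = ConsensusSequence(sample_id=sample_id, marker_id=gid,
                                             sequence=genome[start:end], called_frac=1.0)
                per_marker[gid] = cons
                fracs[gid] = cons.called_frac
            consensus[sample_id] = per_marker
            frac_rows[sample_id] = fracs

        frac_table = pd.DataFrame.from_dict(frac_rows, orient="index").reindex(
            index=carriers, columns=[gid for gid, _, _ in offsets]).fillna(0.0)
        try:
            samples, kept_markers = filter_profiles(frac_table, config)
            msa = build_msa(consensus, samples, kept_markers, marker_lengths,
                            sgb_id=sgb_id, config=config)
            D = pairwise_pdistance(msa, config)
            if np.isnan(D).any():
                raise SGBSkipped("insufficient pairwise column overlap")
            tree = nj_tree(D, samples)
            ids, P = normalized_patristic(tree)
            threshold, n_unrel = infer_threshold(P, ids, related, config)
            results[sgb_id] = detect_events(P, ids, related, threshold,
                                            sgb_id=sgb_id, n_unrelated=n_unrel)
            profiled[sgb_id] = set(samples)
        except SGBSkipped as exc:
            logger.info("SGB %s skipped: %s", sgb_id, exc)
            skipped[sgb_id] = str(exc)
    return PipelineResult(results=results, profiled=profiled, skipped=skipped)


# ---------------------------------------------------------------------------
# Scoring against planted truth
# ---------------------------------------------------------------------------

def evaluate_events(result: PipelineResult, cohort: CohortSim) -> dict:
    """Precision/recall of mother-infant events against planted transmissions.

    Truth positives are co-carried inherited (family, SGB) pairs; predictions
    are the pipeline's mother-infant events mapped back to families.
    """
    df = cohort.manifest.frame
    family_of = dict(zip(df["sample_id"], df["family_id"]))
    predicted: set[tuple[str, str]] = set()
    for sgb_id, res in result.results.items():
        mi = res.events[res.events["relationship"] == "mother_infant"]
        for a, b in zip(mi["sample_a"], mi["sample_b"]):
            if family_of[a] == family_of[b]:
                predicted.add((family_of[a], sgb_id))
    truth = cohort.truth
    actual = {(r.family_id, r.sgb_id) for r in truth.itertuples() if r.transmitted}
    tp = len(predicted & actual)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(actual) if actual else float("nan")
    return dict(n_predicted=len(predicted), n_true=len(actual), n_tp=tp,
                precision=precision, recall=recall)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def default_sgb_specs(n_sgbs: int, n_core_genes: int = 10, gene_len: int = 300
                      ) -> list[SyntheticSGBSpec]:
    return [SyntheticSGBSpec(sgb_id=f"SGB{i:03d}", n_core_genes=n_core_genes,
                             gene_len_nt=gene_len) for i in range(n_sgbs)]


def transmission_experiment(n_families: int = 50, n_sgbs: int = 10,
                            p_transmit: float = 0.3, carriage_prob: float = 1.0,
                            within_strain_div: float = 0.001,
                            between_strain_div: float = 0.02, seed: int = 0,
                            use_reads: bool = True, mean_depth: float = 20.0,
                            read_len: int = 100, err_rate: float = 0.005,
                            n_core_genes: int = 10, gene_len: int = 300,
                            config: PipelineConfig | None = None) -> dict:
    """Simulate one cohort, run the pipeline, and score it against truth."""
    config = config or PipelineConfig()
    cohort = simulate_cohort(n_families, default_sgb_specs(n_sgbs, n_core_genes, gene_len),
                             p_transmit, carriage_prob, within_strain_div,
                             between_strain_div, seed)
    result = run_sharing_pipeline(cohort, config, seed=seed + 1, use_reads=use_reads,
                                  mean_depth=mean_depth, read_len=read_len,
                                  err_rate=err_rate)
    scores = evaluate_events(result, cohort)
    summary = result.summary(cohort, config)
    scores["median_infant_sharing_pct"] = float(summary["pct_shared_own_mother"].median())
    scores["summary"] = summary
    scores["result"] = result
    scores["cohort"] = cohort
    return scores


def null_calibration_experiment(n_families: int = 50, n_sgbs: int = 10, seed: int = 0,
                                use_reads: bool = True,
                                config: PipelineConfig | None = None, **kwargs) -> dict:
    """p_transmit = 0: the related-pair event rate should sit near the
    percentile level (~1%) within binomial error."""
    out = transmission_experiment(n_families=n_families, n_sgbs=n_sgbs,
                                  p_transmit=0.0, seed=seed, use_reads=use_reads,
                                  config=config, **kwargs)
    result: PipelineResult = out["result"]
    cohort: CohortSim = out["cohort"]
    related = related_pairs(cohort.manifest)
    n_pairs = n_events = 0
    for res in result.results.values():
        present = set(res.ids)
        idx = {s: i for i, s in enumerate(res.ids)}
        for (a, b) in related:
            if a in present and b in present and not np.isnan(res.distances[idx[a], idx[b]]):
                n_pairs += 1
        n_events += len(res.events)
    out["n_related_pairs"] = n_pairs
    out["n_false_events"] = n_events
    out["false_event_rate"] = (n_events / n_pairs) if n_pairs else float("nan")
    return out


def cohort_contrast_experiment(n_replicates: int = 100, p_low: float = 0.05,
                               p_high: float = 0.30, n_families: int = 25,
                               n_sgbs: int = 8, seed: int = 0,
                               config: PipelineConfig | None = None) -> dict:
    """Replicated two-cohort contrast (consensus-stage pipeline for speed).

    Returns how often the high-transmission cohort reports the strictly higher
    median per-infant sharing percentage, plus one replicate's medians.
    """
    config = config or PipelineConfig()
    wins = 0
    medians = []
    for r in range(n_replicates):
        meds = {}
        for tag, p in (("low", p_low), ("high", p_high)):
            out = transmission_experiment(
                n_families=n_families, n_sgbs=n_sgbs, p_transmit=p,
                seed=int(np.random.default_rng([seed, r, int(p * 1000)]).integers(2**31)),
                use_reads=False, config=config)
            meds[tag] = out["median_infant_sharing_pct"]
        medians.append(meds)
        wins += int(meds["high"] > meds["low"])
    return dict(n_replicates=n_replicates, n_high_wins=wins,
                win_fraction=wins / n_replicates, medians=medians)
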