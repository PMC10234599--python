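"""Strain-sharing inference and cohort-level sharing summaries.

Related sample pairs are same-subject (longitudinal) pairs and mother-infant
pairs within a family; every other pair is unrelated. Per SGB, the
strain-identity threshold is the 1st percentile (linear interpolation) of the
unrelated-pair normalized patristic distances, and a strain-sharing event is a
related pair strictly below it. Per-infant summaries report the percentage of
the infant's profilable SGBs shared with the own mother (by default restricted
to SGBs the mother is also profiled for), split by known/unknown SGB, plus an
unrelated-mothers baseline (median over same-cohort unrelated mothers).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import CohortManifest
from .profiling import SGBSkipped

MOTHER_INFANT = "mother_infant"
SAME_SUBJECT = "same_subject"


def related_pairs(manifest: CohortManifest) -> dict[tuple[str, str], str]:
    """All related sample pairs with labels; keys are sorted (a, b) tuples.

    Mother-infant relatedness wins over same-subject (the two cannot overlap
    for distinct subjects, so the label is unambiguous in practice).
    """
    pairs: dict[tuple[str, str], str] = {}
    df = manifest.frame
    for _, group in df.groupby("subject_id"):
        ids = sorted(group["sample_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs[(ids[i], ids[j])] = SAME_SUBJECT
    for mother, infant in manifest.mother_infant_pairs():
        pairs[tuple(sorted((mother, infant)))] = MOTHER_INFANT
    return pairs


def _unrelated_distances(D: np.ndarray, ids: list[str],
                         related: dict[tuple[str, str], str]) -> np.ndarray:
    vals = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if tuple(sorted((ids[i], ids[j]))) in related:
                continue
            if not np.isnan(D[i, j]):
                vals.append(D[i, j])
    return np.asarray(vals, dtype=float)


def infer_threshold(D: np.ndarray, ids: list[str],
                    related: dict[tuple[str, str], str],
                    config: PipelineConfig | None = None) -> tuple[float, int]:
    """Strain-identity threshold: the ``sharing_percentile``-th percentile
    (linear interpolation between order statistics) of unrelated-pair
    distances. Related-pair distances never enter the estimate."""
    config = config or PipelineConfig()
    vals = _unrelated_distances(D, ids, related)
    if len(vals) < config.min_unrelated_pairs:
        raise SGBSkipped(
            f"only {len(vals)} unrelated-pair distances "
            f"(need {config.min_unrelated_pairs} to estimate the percentile)")
    return float(np.percentile(vals, config.sharing_percentile)), len(vals)


@dataclass
class SharingResult:
    """Per-SGB sharing call: threshold, the distances it came from, events."""

    sgb_id: str
    threshold: float
    n_unrelated: int
    ids: list[str]
    distances: np.ndarray
    events: pd.DataFrame  # sample_a, sample_b, distance, relationship
    n_unrelated_below: int

    def event_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in zip(self.events["sample_a"],
                                                      self.events["sample_b"])}


def detect_events(D: np.ndarray, ids: list[str],
                  related: dict[tuple[str, str], str], threshold: float,
                  sgb_id: str = "", n_unrelated: int = 0) -> SharingResult:
    """Call an event for every related pair strictly below the threshold.

    Unrelated pairs below the threshold are counted (they feed the
    unrelated-mothers baseline) but never called events.
    """
    rows = []
    n_unrel_below = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = D[i, j]
            if np.isnan(d):
                continue
            key = tuple(sorted((ids[i], ids[j])))
            rel = related.get(key)
            if rel is None:
                n_unrel_below += int(d < threshold)
            elif d < threshold:
                rows.append(dict(sample_a=key[0], sample_b=key[1],
                                 distance=float(d), relationship=rel))
    events = pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance", "relationship"])
    return SharingResult(sgb_id=sgb_id, threshold=threshold, n_unrelated=n_unrelated,
                         ids=list(ids), distances=np.asarray(D), events=events,
                         n_unrelated_below=n_unrel_below)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _subject_samples(manifest: CohortManifest) -> pd.DataFrame:
    return manifest.frame[["sample_id", "subject_id", "family_id", "role", "cohort"]]


def infant_sharing_summary(results: dict[str, SharingResult],
                           profiled: dict[str, set[str]],
                           manifest: CohortManifest,
                           sgb_known: dict[str, bool] | None = None,
                           config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-infant sharing percentages across all profiled SGBs.

    An SGB is profilable for a subject if any of its samples survived that
    SGB's filters; it is shared if any infant sample forms an event with any
    maternal sample (longitudinal any-to-any rule). The denominator restricts
    to SGBs where the own mother is also profiled unless
    ``infant_only_denominator`` is set. The unrelated-mothers baseline uses
    same-cohort mothers of other families and the plain below-threshold rule,
    summarized per infant by the median.
    """
    config = config or PipelineConfig()
    sgb_known = sgb_known or {}
    df = manifest.frame
    rows = []
    infants = df[df["role"] == "infant"]
    mothers = df[df["role"] == "mother"]
    for subject_id, inf_group in infants.groupby("subject_id"):
        family_id = inf_group["family_id"].iloc[0]
        cohort = inf_group["cohort"].iloc[0]
        inf_samples = set(inf_group["sample_id"])
        own_mother_samples = set(
            mothers.loc[mothers["family_id"] == family_id, "sample_id"])
        n_prof = n_shared = 0
        n_prof_k = n_shared_k = n_prof_u = n_shared_u = 0
        unrelated_shared: dict[str, list[int]] = {}
        for sgb_id, res in results.items():
            prof = profiled.get(sgb_id, set())
            infant_prof = bool(inf_samples & prof)
            if not infant_prof:
                continue
            mother_prof = bool(own_mother_samples & prof)
            if config.infant_only_denominator or mother_prof:
                n_prof += 1
                events = res.event_pairs()
                shared = any(
                    tuple(sorted((i, m))) in events
                    for i in inf_samples & prof for m in own_mother_samples & prof
                )
                n_shared += int(shared)
                if sgb_known.get(sgb_id, False):
                    n_prof_k += 1
                    n_shared_k += int(shared)
                else:
                    n_prof_u += 1
                    n_shared_u += int(shared)
            # unrelated-mothers baseline (same cohort, other families)
            idx = {s: k for k, s in enumerate(res.ids)}
            other = mothers[(mothers["cohort"] == cohort) & (mothers["family_id"] != family_id)]
            for om_subject, om_group in other.groupby("subject_id"):
                om_samples = set(om_group["sample_id"]) & prof
                if not om_samples:
                    continue
                hit = 0
                for i in inf_samples & prof:
                    for m in om_samples:
                        if i in idx and m in idx:
                            d = res.distances[idx[i], idx[m]]
                            if not np.isnan(d) and d < res.threshold:
                                hit = 1
                unrelated_shared.setdefault(om_subject, []).append(hit)
        baseline = np.nan
        if unrelated_shared:
            pcts = [100.0 * np.mean(hits) for hits in unrelated_shared.values()]
            baseline = float(np.median(pcts))
        rows.append(dict(
            infant_subject_id=subject_id, family_id=family_id, cohort=cohort,
            n_profilable_sgbs=n_prof, n_shared_with_own_mother=n_shared,
            pct_shared_own_mother=(100.0 * n_shared / n_prof) if n_prof else np.nan,
            pct_shared_unrelated_mothers_median=baseline,
            n_profilable_ksgb=n_prof_k, n_shared_ksgb=n_shared_k,
            n_profilable_usgb=n_prof_u, n_shared_usgb=n_shared_u,
        ))
    return pd.DataFrame(rows)


def sgb_sharing_rate(results: dict[str, SharingResult],
                     profiled: dict[str, set[str]],
                     manifest: CohortManifest) -> pd.DataFrame:
    """Per SGB and cohort: infant prevalence and the mother-infant sharing
    rate (percentage of co-profiled pairs with an event; missing when no pair
    is co-profiled)."""
    df = manifest.frame
    infants = df[df["role"] == "infant"]
    rows = []
    for sgb_id, res in results.items():
        prof = profiled.get(sgb_id, set())
        events = res.event_pairs()
        for cohort, inf_group in infants.groupby("cohort"):
            subjects = inf_group.groupby("subject_id")["sample_id"].apply(set)
            n_inf = len(subjects)
            n_prof = sum(bool(samples & prof) for samples in subjects)
            n_pairs = n_events = 0
            for subject_id, samples in subjects.items():
                family_id = inf_group.loc[inf_group["subject_id"] == subject_id,
                                          "family_id"].iloc[0]
                mom = set(manifest.mother_samples_of_family(family_id)) & prof
                inf = samples & prof
                if mom and inf:
                    n_pairs += 1
                    if any(tuple(sorted((i, m))) in events for i in inf for m in mom):
                        n_events += 1
            rows.append(dict(
                sgb_id=sgb_id, cohort=cohort,
                infant_prevalence=(n_prof / n_inf) if n_inf else np.nan,
                n_co_profiled_pairs=n_pairs,
                sharing_rate_pct=(100.0 * n_events / n_pairs) if n_pairs else np.nan,
            ))
    return pd.DataFrame(rows)


def cohort_contrast(summary: pd.DataFrame, groups: pd.Series) -> dict:
    """Compare per-infant sharing percentages between two groups.

    ``groups`` maps infant_subject_id -> group label (exactly two labels).
    Returns group medians, a two-sided Mann-Whitney U on the per-infant
    percentages, and a Fisher exact test on the pooled shared / not-shared
    SGB counts.
    """
    merged = summary.set_index("infant_subject_id").join(groups.rename("group"), how="inner")
    merged = merged.dropna(subset=["pct_shared_own_mother"])
    labels = sorted(merged["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"cohort_contrast needs exactly 2 groups, got {labels}")
    a = merged[merged["group"] == labels[0]]
    b = merged[merged["group"] == labels[1]]
    out: dict = {"groups": labels,
                 "median_pct": {labels[0]: float(a["pct_shared_own_mother"].median()),
                                labels[1]: float(b["pct_shared_own_mother"].median())}}
    if len(a) >= 2 and len(b) >= 2:
        u = stats.mannwhitneyu(a["pct_shared_own_mother"], b["pct_shared_own_mother"],
                               alternative="two-sided")
        out["mannwhitney_p"] = float(u.pvalue)
    else:
        out["mannwhitney_p"] = None
    table = [[int(a["n_shared_with_own_mother"].sum()),
              int((a["n_profilable_sgbs"] - a["n_shared_with_own_mother"]).sum())],
             [int(b["n_shared_with_own_mother"].sum()),
              int((b["n_profilable_sgbs"] - b["n_shared_with_own_mother"]).sum())]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    out["fisher_table"] = table
    out["fisher_odds_ratio"] = float(odds)
    out["fisher_p"] = float(p)
    return out
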