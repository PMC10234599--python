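"""Species/genus/family-level genome binning.

Genomes (MAGs and references) are sketched with a MinHash over canonical
k-mers; Mash-style distances feed an average-linkage agglomeration cut at 5%,
15% and 30% genetic distance to form species-, genus- and family-level genome
bins (SGB/GGB/FGB). New genomes are first assigned to an existing catalog bin
when their mean distance to its members falls below the level threshold;
leftovers are clustered into new bins. Bins without reference genomes are
"unknown" (uSGB/uGGB/uFGB); taxonomy is decided by plurality vote over member
references, falling back one level at a time (SGB -> GGB -> FGB -> nearest
references) when a bin has none.

The agglomeration is written out directly (O(n^3), deterministic smallest-index
tie-break) rather than delegated, because the cut semantics — no merge at
linkage distance >= threshold is ever applied — and the tie-break are part of
the binning contract. scipy's implementation serves as a cross-check in the
test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dna import encode

LEVELS = ("sgb", "ggb", "fgb")
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_LEVEL_DEEPEST_RANK = {"sgb": "species", "ggb": "genus", "fgb": "family"}


@dataclass
class GenomeRecord:
    """One genome: a MAG with quality metadata or a reference with taxonomy."""

    genome_id: str
    sequences: list[str]
    source: str = "mag"  # "mag" | "reference"
    completeness_pct: float | None = None
    contamination_pct: float | None = None
    taxonomy: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.source not in {"mag", "reference"}:
            raise ValueError("source must be 'mag' or 'reference'")
        if self.source == "reference" and self.taxonomy is None:
            raise ValueError(f"reference genome {self.genome_id} must carry taxonomy")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


@dataclass
class MinHashSketch:
    genome_id: str
    k: int
    size: int
    hashes: np.ndarray  # sorted, strictly increasing uint64

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if len(self.hashes) > 1 and not np.all(np.diff(self.hashes.astype(np.int64)) > 0):
            raise ValueError("sketch hashes must be strictly increasing")


@dataclass
class GenomeBin:
    bin_id: str
    level: str
    member_genome_ids: list[str]
    known: bool = False
    taxonomy: tuple[str, ...] = ("",) * len(RANKS)
    deepest_rank: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if not self.member_genome_ids:
            raise ValueError("bin must have at least one member")


@dataclass
class BinHierarchy:
    """Nested SGB/GGB/FGB assignments plus the bin objects at each level."""

    assignments: pd.DataFrame  # genome_id, sgb_id, ggb_id, fgb_id
    bins: dict[str, dict[str, GenomeBin]]  # level -> bin_id -> bin
    sketches: dict[str, MinHashSketch] = field(default_factory=dict)

    def sgb_of(self, genome_id: str) -> str:
        df = self.assignments
        return df.loc[df["genome_id"] == genome_id, "sgb_id"].iloc[0]


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def filter_mag_quality(genome: GenomeRecord, config: PipelineConfig) -> bool:
    """Medium/high quality gate: completeness strictly above 50% and
    contamination strictly below 5% (defaults). References always pass."""
    if genome.source == "reference":
        return True
    if genome.completeness_pct is None or genome.contamination_pct is None:
        raise ValueError(f"MAG {genome.genome_id} lacks completeness/contamination values")
    return (
        genome.completeness_pct > config.completeness_min_pct
        and genome.contamination_pct < config.contamination_max_pct
    )


# ---------------------------------------------------------------------------
# MinHash sketching and Mash distance
# ---------------------------------------------------------------------------

def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit mixing function; seed-free so sketches compare across runs."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x = (x * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    x ^= x >> np.uint64(27)
    x = (x * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    x ^= x >> np.uint64(31)
    return x


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed canonical k-mer codes; windows containing N are dropped."""
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid_base = codes < 4
    # a window is valid iff all k bases are valid
    ok = np.ones(n, dtype=bool)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    comp = (np.uint64(3) - c64) & np.uint64(3)
    for j in range(k):
        window = slice(j, j + n)
        ok &= valid_base[window]
        fwd = (fwd << np.uint64(2)) | c64[window]
        rev |= comp[window] << np.uint64(2 * j)
    return np.minimum(fwd[ok], rev[ok])


def sketch_genome(genome: GenomeRecord | Sequence[str], k: int = 21, s: int = 1000,
                  genome_id: str | None = None) -> MinHashSketch:
    """MinHash sketch: the ``s`` smallest splitmix64 hashes over canonical k-mers."""
    if isinstance(genome, GenomeRecord):
        seqs = genome.sequences
        gid = genome.genome_id
    else:
        seqs = list(genome)
        gid = genome_id or "genome"
    if sum(len(x) for x in seqs) < k:
        raise ValueError(f"genome {gid} shorter than k={k}")
    kmers = [_canonical_kmer_codes(seq, k) for seq in seqs]
    allk = np.unique(np.concatenate(kmers)) if kmers else np.empty(0, dtype=np.uint64)
    if allk.size == 0:
        raise ValueError(f"genome {gid} contains no valid (N-free) {k}-mers")
    hashes = np.unique(_splitmix64(allk))
    return MinHashSketch(genome_id=gid, k=k, size=s, hashes=hashes[:s])


def estimate_jaccard(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash's bottom-s estimator: shared fraction among the s smallest of the union."""
    if a.k != b.k:
        raise ValueError("sketches built with different k cannot be compared")
    s = min(a.size, b.size)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if union.size == 0:
        return 0.0
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = np.isin(union, shared, assume_unique=True).sum()
    return float(n_shared) / float(union.size)


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance d = -ln(2j / (1+j)) / k; a zero Jaccard estimate caps at 1.0."""
    j = estimate_jaccard(a, b)
    if j <= 0.0:
        return 1.0
    d = -np.log(2.0 * j / (1.0 + j)) / a.k
    return float(min(max(d, 0.0), 1.0))


def pairwise_mash_matrix(sketches: Sequence[MinHashSketch]) -> np.ndarray:
    n = len(sketches)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mash_distance(sketches[i], sketches[j])
    return D


# ---------------------------------------------------------------------------
# Average-linkage clustering
# ---------------------------------------------------------------------------

def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return D


def average_linkage_merges(D: np.ndarray) -> list[tuple[float, frozenset[int], frozenset[int]]]:
    """Full average-linkage agglomeration schedule as (height, left, right) merges.

    Ties are broken by the lexicographically smallest (min member, min member)
    pair of cluster indices. Average linkage is reducible, so merge heights are
    non-decreasing and cutting the schedule at any height yields a partition.
    """
    D = _check_distance_matrix(D)
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    # linkage between current clusters, keyed by representative (min member)
    link = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    while len(clusters) > 1:
        best = min(link.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), height = best
        merged = sorted(clusters[a] + clusters[b])
        merges.append((height, frozenset(clusters[a]), frozenset(clusters[b])))
        del clusters[b]
        clusters[a] = merged
        for key in list(link):
            if a in key or b in key:
                del link[key]
        for c in clusters:
            if c == a:
                continue
            link[(min(a, c), max(a, c))] = _merged_linkage(D, clusters[c], merged)
    return merges


def _merged_linkage(D: np.ndarray, members_a: list[int], members_b: list[int]) -> float:
    return float(D[np.ix_(members_a, members_b)].mean())


def average_linkage_cluster(D: np.ndarray, threshold: float) -> list[int]:
    """Partition by average linkage: apply every merge at height strictly below
    ``threshold``. Returns a flat label per item; labels are the smallest member
    index of each cluster."""
    D = _check_distance_matrix(D)
    n = D.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for height, left, right in average_linkage_merges(D):
        if height >= threshold:
            break
        ra, rb = find(min(left)), find(min(right))
        parent[max(ra, rb)] = min(ra, rb)
    return [find(i) for i in range(n)]


# ---------------------------------------------------------------------------
# Assignment and hierarchy construction
# ---------------------------------------------------------------------------

def genome_bin_distance(sketch: MinHashSketch, bin_: GenomeBin,
                        sketches: Mapping[str, MinHashSketch]) -> float:
    """Mean sketch distance to all bin members (mirrors average linkage)."""
    ds = [mash_distance(sketch, sketches[m]) for m in bin_.member_genome_ids]
    return float(np.mean(ds))


def assign_genome(sketch: MinHashSketch, catalog: Iterable[GenomeBin],
                  sketches: Mapping[str, MinHashSketch], threshold: float) -> str | None:
    """Assign to the closest catalog bin if its distance is strictly below the
    level threshold; ties go to the lexicographically smallest bin_id."""
    best_id, best_d = None, np.inf
    for bin_ in catalog:
        d = genome_bin_distance(sketch, bin_, sketches)
        if d < best_d or (d == best_d and best_id is not None and bin_.bin_id < best_id):
            best_id, best_d = bin_.bin_id, d
    if best_id is not None and best_d < threshold:
        return best_id
    return None


def _cluster_ids(labels: Sequence[int], genome_ids: Sequence[str], prefix: str) -> dict[str, str]:
    """Deterministic bin ids: clusters ordered by their sorted member-id tuples."""
    groups: dict[int, list[str]] = {}
    for lab, gid in zip(labels, genome_ids):
        groups.setdefault(lab, []).append(gid)
    ordered = sorted(groups.values(), key=lambda members: sorted(members))
    mapping: dict[str, str] = {}
    for idx, members in enumerate(ordered, start=1):
        bin_id = f"{prefix}{idx:04d}"
        for gid in members:
            mapping[gid] = bin_id
    return mapping


def build_hierarchy(genomes: Sequence[GenomeRecord], config: PipelineConfig,
                    catalog: BinHierarchy | None = None) -> BinHierarchy:
    """Quality-filter MAGs, sketch, then bin at 5/15/30% genetic distance.

    Assignment-first: with a ``catalog``, each genome lands in the closest
    existing SGB below 5% (inheriting its GGB/FGB); remaining genomes are
    clustered into new bins from a single average-linkage schedule cut at the
    three thresholds, which guarantees SGB ⊆ GGB ⊆ FGB nesting.
    """
    kept = [g for g in genomes if filter_mag_quality(g, config)]
    if not kept:
        raise ValueError("no genomes pass the quality filter")
    sketches = {g.genome_id: sketch_genome(g, k=config.kmer_len, s=config.sketch_size)
                for g in kept}
    by_id = {g.genome_id: g for g in kept}

    rows: dict[str, dict[str, str]] = {}
    unassigned: list[GenomeRecord] = []
    if catalog is not None:
        for g in kept:
            sgb = assign_genome(sketches[g.genome_id], catalog.bins["sgb"].values(),
                                {**catalog.sketches, **sketches}, config.sgb_threshold)
            if sgb is None:
                unassigned.append(g)
                continue
            cat_row = catalog.assignments[catalog.assignments["sgb_id"] == sgb].iloc[0]
            rows[g.genome_id] = {"sgb_id": sgb, "ggb_id": cat_row["ggb_id"],
                                 "fgb_id": cat_row["fgb_id"]}
    else:
        unassigned = list(kept)

    if unassigned:
        ids = [g.genome_id for g in unassigned]
        D = pairwise_mash_matrix([sketches[i] for i in ids])
        merges = average_linkage_merges(D) if len(ids) > 1 else []
        for level, threshold, prefix in (
            ("sgb", config.sgb_threshold, "SGB"),
            ("ggb", config.ggb_threshold, "GGB"),
            ("fgb", config.fgb_threshold, "FGB"),
        ):
            labels = _cut_merges(merges, len(ids), threshold)
            mapping = _cluster_ids(labels, ids, prefix)
            for gid in ids:
                rows.setdefault(gid, {})[f"{level}_id"] = mapping[gid]

    assignments = pd.DataFrame(
        [{"genome_id": gid, **level_ids} for gid, level_ids in sorted(rows.items())]
    )
    bins: dict[str, dict[str, GenomeBin]] = {}
    for level in LEVELS:
        bins[level] = {}
        for bin_id, group in assignments.groupby(f"{level}_id"):
            members = sorted(group["genome_id"])
            known = any(by_id[m].source == "reference" for m in members if m in by_id)
            bins[level][bin_id] = GenomeBin(bin_id=bin_id, level=level,
                                            member_genome_ids=members, known=known)
    hierarchy = BinHierarchy(assignments=assignments, bins=bins, sketches=sketches)
    for level in LEVELS:
        for bin_ in hierarchy.bins[level].values():
            tax, deepest = vote_taxonomy(bin_, hierarchy, by_id)
            bin_.taxonomy, bin_.deepest_rank = tax, deepest
    return hierarchy


def _cut_merges(merges, n: int, threshold: float) -> list[int]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for height, left, right in merges:
        if height >= threshold:
            break
        ra, rb = find(min(left)), find(min(right))
        parent[max(ra, rb)] = min(ra, rb)
    return [find(i) for i in range(n)]


# ---------------------------------------------------------------------------
# Taxonomy voting
# ---------------------------------------------------------------------------

def _plurality_prefix(taxonomies: Sequence[tuple[str, ...]], max_rank_index: int
                      ) -> tuple[tuple[str, ...], str | None]:
    """Deepest rank (<= max_rank_index) with a strict plurality of label prefixes."""
    for depth in range(max_rank_index, -1, -1):
        counts: dict[tuple[str, ...], int] = {}
        for tax in taxonomies:
            prefix = tuple(tax[: depth + 1])
            if all(prefix):
                counts[prefix] = counts.get(prefix, 0) + 1
        if not counts:
            continue
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ordered) == 1 or ordered[0][1] > ordered[1][1]:
            prefix = ordered[0][0]
            tax = tuple(prefix) + ("",) * (len(RANKS) - len(prefix))
            return tax, RANKS[len(prefix) - 1]
    return ("",) * len(RANKS), None


def vote_taxonomy(bin_: GenomeBin, hierarchy: BinHierarchy,
                  genomes_by_id: Mapping[str, GenomeRecord]) -> tuple[tuple[str, ...], str | None]:
    """Plurality vote over member references, with level fallback.

    kSGBs vote at species level among their own references; uSGBs fall back to
    the genus-level vote over their GGB's references, uGGBs to the family-level
    vote over their FGB's, and uFGBs to a vote over the (up to) 100 nearest
    references genome-wide. A vote tie recurses to the deepest shallower rank
    with a strict plurality. With no references anywhere the bin is
    unclassified at all ranks.
    """
    assignments = hierarchy.assignments

    def refs_of(member_ids: Iterable[str]) -> list[tuple[str, ...]]:
        return [
            genomes_by_id[m].taxonomy
            for m in member_ids
            if m in genomes_by_id and genomes_by_id[m].source == "reference"
        ]

    parent_of = {"sgb": "ggb", "ggb": "fgb", "fgb": None}
    level = bin_.level
    current_id = bin_.bin_id
    members = bin_.member_genome_ids
    while True:
        refs = refs_of(members)
        if refs:
            max_idx = RANKS.index(_LEVEL_DEEPEST_RANK[level])
            return _plurality_prefix(refs, max_idx)
        parent_level = parent_of[level]
        if parent_level is None:
            break
        # widen to the parent bin's membership
        col_child, col_parent = f"{level}_id", f"{parent_level}_id"
        sel = assignments.loc[assignments[col_child] == current_id, col_parent]
        if sel.empty:
            break
        current_id = sel.iloc[0]
        members = list(assignments.loc[assignments[col_parent] == current_id, "genome_id"])
        level = parent_level

    # uFGB: up to 100 nearest references anywhere
    all_refs = [g for g in genomes_by_id.values() if g.source == "reference"]
    if not all_refs:
        return ("unclassified",) * len(RANKS), None
    member_sk = [hierarchy.sketches[m] for m in bin_.member_genome_ids
                 if m in hierarchy.sketches]
    scored = []
    for ref in all_refs:
        sk = hierarchy.sketches.get(ref.genome_id) or sketch_genome(ref)
        d = float(np.mean([mash_distance(sk, ms) for ms in member_sk])) if member_sk else 1.0
        scored.append((d, ref.genome_id, ref.taxonomy))
    scored.sort(key=lambda t: (t[0], t[1]))
    nearest = [tax for _, _, tax in scored[:100]]
    return _plurality_prefix(nearest, RANKS.index("family"))


def exclude_small_usgbs(sgb_bins: Mapping[str, GenomeBin], config: PipelineConfig
                        ) -> dict[str, GenomeBin]:
    """Drop unknown SGBs with fewer than ``min_mags_per_usgb`` members (default
    5); known SGBs are always retained regardless of size."""
    return {
        bin_id: b
        for bin_id, b in sgb_bins.items()
        if b.known or len(b.member_genome_ids) >= config.min_mags_per_usgb
    }
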