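"""Per-sample strain reconstruction and per-SGB phylogenies.

The consensus engine is shared with the eukaryote path: reads are filtered on
mapping quality (>=30), identity (>=97%) and aligned length (>=30 nt) before
pileup; a position is called to its dominant base only with depth >=5 and a
dominant-allele fraction >=80%, otherwise N. Per-sample marker consensi are
concatenated (reference-coordinate aligned, so no realignment step) into an
MSA; columns with more than 50% missing data are dropped; StrainPhlAn-style
filters (marker in >=5 samples, sample with >=10 markers) decide which samples
and markers survive. Trees are neighbor-joining on pairwise p-distances, and
the sharing statistic consumes patristic distances normalized by the tree's
total branch length.
"""
from __future__ import annotations

import io as _stdio
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .config import PipelineConfig
from .dna import GAP, N, decode, encode
from .io import AlignmentRecord


class SGBSkipped(Exception):
    """An SGB that cannot be profiled meaningfully; the reason is the message."""


# ---------------------------------------------------------------------------
# Pileup and consensus
# ---------------------------------------------------------------------------

@dataclass
class Pileup:
    ref_id: str
    counts: np.ndarray  # (ref_len, 4) int32 counts over A,C,G,T
    n_reads_used: int
    n_reads_filtered: int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def pileup(records: list[AlignmentRecord], ref_len: int,
           config: PipelineConfig | None = None, ref_id: str = "ref") -> Pileup:
    """Filtered per-position base counts.

    Reads with mapq below ``min_mapq``, identity below
    ``min_read_identity_frac`` or aligned length below ``min_aligned_len_nt``
    are excluded entirely. N and gap calls contribute to no base count.
    """
    config = config or PipelineConfig()
    counts = np.zeros((ref_len, 4), dtype=np.int32)
    positions, codes = [], []
    used = 0
    for r in records:
        if (r.mapq < config.min_mapq
                or r.identity_frac < config.min_read_identity_frac
                or r.aligned_len_nt < config.min_aligned_len_nt):
            continue
        used += 1
        c = encode(r.bases)
        keep = c < 4  # drop N and '-'
        if keep.any():
            positions.append(np.arange(r.ref_start, r.ref_start + r.aligned_len_nt)[keep])
            codes.append(c[keep])
    if positions:
        pos = np.concatenate(positions)
        cod = np.concatenate(codes)
        if pos.max() >= ref_len:
            raise ValueError("alignment extends past the reference end")
        np.add.at(counts, (pos, cod), 1)
    return Pileup(ref_id=ref_id, counts=counts, n_reads_used=used,
                  n_reads_filtered=len(records) - used)


@dataclass
class ConsensusSequence:
    sample_id: str
    marker_id: str
    sequence: str  # over {A,C,G,T,N}
    called_frac: float


def call_consensus(counts: np.ndarray, sample_id: str = "", marker_id: str = "",
                   config: PipelineConfig | None = None) -> ConsensusSequence:
    """Dominant-base consensus under the depth and allele-frequency filters.

    A position is called iff depth >= ``min_depth`` and the dominant base
    reaches ``min_dominant_allele_frac`` of the depth (both boundaries
    inclusive); otherwise N. Ties on the dominant base resolve to the
    alphabetically first base, which can only matter below a 50% threshold.
    """
    config = config or PipelineConfig()
    counts = np.asarray(counts)
    depth = counts.sum(axis=1)
    dominant = counts.argmax(axis=1).astype(np.uint8)  # argmax ties -> lowest code
    top = counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    called = (depth >= config.min_depth) & (frac >= config.min_dominant_allele_frac)
    seq_codes = np.where(called, dominant, np.uint8(N)).astype(np.uint8)
    called_frac = float(called.mean()) if len(called) else 0.0
    return ConsensusSequence(sample_id=sample_id, marker_id=marker_id,
                             sequence=decode(seq_codes), called_frac=called_frac)


# ---------------------------------------------------------------------------
# Sample/marker filtering and MSA assembly
# ---------------------------------------------------------------------------

def filter_profiles(called_frac: pd.DataFrame, config: PipelineConfig | None = None,
                    min_samples: int = 4) -> tuple[list[str], list[str]]:
    """Single-pass StrainPhlAn-style filter on a samples x markers table of
    called fractions: drop markers present (called_frac >= ``min_called_frac``)
    in fewer than ``marker_in_n_samples`` samples, then drop samples left with
    fewer than ``sample_with_n_markers`` markers. Raises :class:`SGBSkipped`
    when fewer than ``min_samples`` samples survive."""
    config = config or PipelineConfig()
    present = called_frac >= config.min_called_frac
    markers = [m for m in called_frac.columns
               if int(present[m].sum()) >= config.marker_in_n_samples]
    samples = [s for s in called_frac.index
               if int(present.loc[s, markers].sum()) >= config.sample_with_n_markers]
    if len(samples) < min_samples:
        raise SGBSkipped(
            f"only {len(samples)} samples survive marker/sample filters "
            f"(need {min_samples} for a meaningful tree)")
    return samples, markers


@dataclass
class StrainMSA:
    """Concatenated marker consensus matrix over {A,C,G,T,N,-}."""

    sgb_id: str
    sample_ids: list[str]
    matrix: np.ndarray  # (n_samples, n_cols) uint8 codes, all columns
    retained: np.ndarray  # bool per column (missingness filter)
    marker_offsets: list[tuple[str, int, int]]

    @property
    def retained_matrix(self) -> np.ndarray:
        return self.matrix[:, self.retained]

    def row(self, sample_id: str) -> str:
        return decode(self.matrix[self.sample_ids.index(sample_id)])


def build_msa(consensus: dict[str, dict[str, ConsensusSequence]],
              samples: list[str], markers: list[str], marker_lengths: dict[str, int],
              sgb_id: str = "", config: PipelineConfig | None = None) -> StrainMSA:
    """Concatenate marker consensi (missing markers padded with N) and flag
    columns with strictly more than ``max_missing_col_frac`` missing ({N,-})."""
    config = config or PipelineConfig()
    offsets, pos = [], 0
    for m in markers:
        offsets.append((m, pos, pos + marker_lengths[m]))
        pos += marker_lengths[m]
    matrix = np.full((len(samples), pos), np.uint8(N), dtype=np.uint8)
    for i, s in enumerate(samples):
        for m, start, end in offsets:
            cons = consensus.get(s, {}).get(m)
            if cons is not None:
                codes = encode(cons.sequence)
                if len(codes) != end - start:
                    raise ValueError(f"consensus length mismatch for {s}/{m}")
                matrix[i, start:end] = codes
    missing_frac = ((matrix == N) | (matrix == GAP)).mean(axis=0) if len(samples) else np.ones(pos)
    retained = missing_frac <= config.max_missing_col_frac
    return StrainMSA(sgb_id=sgb_id, sample_ids=list(samples), matrix=matrix,
                     retained=retained, marker_offsets=offsets)


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def pairwise_pdistance(msa: StrainMSA, config: PipelineConfig | None = None) -> np.ndarray:
    """Proportion of differing bases over columns where both rows are called
    (A/C/G/T). Pairs with fewer than ``min_overlap_cols`` co-called columns are
    flagged NaN rather than given a fabricated distance."""
    config = config or PipelineConfig()
    m = msa.retained_matrix
    n = m.shape[0]
    if n < 2:
        raise ValueError("p-distance needs at least 2 sequences")
    called = m < 4
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            overlap = int(both.sum())
            if overlap < config.min_overlap_cols:
                D[i, j] = D[j, i] = np.nan
            else:
                diff = int((m[i, both] != m[j, both]).sum())
                D[i, j] = D[j, i] = diff / overlap
    return D


def nj_tree(D: np.ndarray, ids: list[str]) -> TreeNode:
    """Neighbor-joining tree (negative branch lengths clamped to zero).

    ``D`` must be complete (no NaN). Two taxa degenerate to a single edge of
    length d split across the two leaf branches.
    """
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix is incomplete (NaN entries); cannot build tree")
    if len(ids) != D.shape[0]:
        raise ValueError("ids must match matrix size")
    if len(ids) < 2:
        raise ValueError("tree needs at least 2 leaves")
    if len(ids) == 2:
        half = D[0, 1] / 2.0
        return TreeNode.read(_stdio.StringIO(f"({ids[0]}:{half},{ids[1]}:{half});"))
    tree = _skbio_nj(DistanceMatrix(D, ids), neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(node.length or 0.0 for node in tree.traverse()))


def normalized_patristic(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths divided by the tree's total branch length.

    Entries live in [0, 1] because any leaf-to-leaf path uses a subset of the
    edges. Returns ``(leaf_ids, matrix)`` with a zero diagonal.
    """
    total = total_branch_length(tree)
    if total <= 0:
        raise ValueError("tree has zero total branch length; cannot normalize")
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data / total
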