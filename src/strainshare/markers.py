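"""SGB-specific marker gene selection.

Core genes (present in >= ``core_frac`` of an SGB's members) are cut into
150-nt fragments and tested for presence in every genome of every other SGB; a
gene "present" in a genome means at least one fragment maps. Core genes found
in more than 1% of any other SGB's genomes are rejected; the survivors are the
SGB's markers. Fragment mapping defaults to exact containment on either
strand, with an optional seed-and-verify mismatch tolerance standing in for a
sensitive short-read mapper at desk scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .binning import GenomeRecord
from .config import PipelineConfig
from .dna import encode, revcomp


@dataclass
class GeneFamily:
    """A gene within one SGB: representative sequence + member presence map."""

    gene_id: str
    sgb_id: str
    sequence: str
    presence: dict[str, bool]  # genome_id -> present

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"gene {self.gene_id} has an empty representative")


@dataclass
class MarkerSet:
    sgb_id: str
    markers: list[GeneFamily]
    cross_hit_fracs: dict[str, float]  # gene_id -> max fraction across other SGBs

    @property
    def marker_ids(self) -> list[str]:
        return [g.gene_id for g in self.markers]


def find_core_genes(sgb_id: str, gene_inventory: Mapping[str, Sequence[str]],
                    gene_sequences: Mapping[str, str],
                    core_frac: float = 0.8) -> list[GeneFamily]:
    """Genes present in at least ``core_frac`` of the SGB's genomes."""
    if not gene_inventory:
        raise ValueError(f"SGB {sgb_id} has no genomes")
    n = len(gene_inventory)
    counts: dict[str, int] = {}
    for genes in gene_inventory.values():
        for gid in set(genes):
            counts[gid] = counts.get(gid, 0) + 1
    core = []
    for gid in sorted(counts):
        if counts[gid] / n >= core_frac and gid in gene_sequences:
            presence = {gm: gid in set(genes) for gm, genes in gene_inventory.items()}
            core.append(GeneFamily(gene_id=gid, sgb_id=sgb_id,
                                   sequence=gene_sequences[gid], presence=presence))
    return core


def fragment_sequence(seq: str, fragment_len: int = 150, min_tail: int = 50) -> list[str]:
    """Consecutive non-overlapping ``fragment_len`` windows; a terminal
    remainder is kept only when >= ``min_tail`` nt; sequences shorter than one
    fragment yield themselves whole."""
    if len(seq) == 0:
        return []
    if len(seq) <= fragment_len:
        return [seq]
    fragments = [seq[i : i + fragment_len] for i in range(0, len(seq) - fragment_len + 1, fragment_len)]
    tail_start = len(fragments) * fragment_len
    tail = seq[tail_start:]
    if len(tail) >= min_tail:
        fragments.append(tail)
    return fragments


def _contains_with_mismatches(fragment: str, contig: str, max_mismatches: int) -> bool:
    """Seed-and-verify approximate containment (substitutions only)."""
    m = len(fragment)
    if m > len(contig):
        return False
    if max_mismatches == 0:
        return fragment in contig
    # pigeonhole: one of max_mismatches+1 seeds must match exactly
    n_seeds = max_mismatches + 1
    seed_len = m // n_seeds
    if seed_len == 0:
        return True  # fragment shorter than tolerance; trivially matches
    frag_codes = encode(fragment)
    contig_codes = encode(contig)
    checked: set[int] = set()
    for s in range(n_seeds):
        seed = fragment[s * seed_len : (s + 1) * seed_len]
        pos = contig.find(seed)
        while pos != -1:
            start = pos - s * seed_len
            if 0 <= start <= len(contig) - m and start not in checked:
                checked.add(start)
                mism = int((contig_codes[start : start + m] != frag_codes).sum())
                if mism <= max_mismatches:
                    return True
            pos = contig.find(seed, pos + 1)
    return False


def fragment_maps_to_genome(fragment: str, genome: GenomeRecord | Sequence[str],
                            max_mismatches: int = 0) -> bool:
    """True iff the fragment or its reverse complement occurs in any contig
    with at most ``max_mismatches`` substitutions."""
    contigs = genome.sequences if isinstance(genome, GenomeRecord) else list(genome)
    rc = revcomp(fragment)
    for contig in contigs:
        if _contains_with_mismatches(fragment, contig, max_mismatches):
            return True
        if _contains_with_mismatches(rc, contig, max_mismatches):
            return True
    return False


def gene_present_in_genome(gene: GeneFamily | str, genome: GenomeRecord | Sequence[str],
                           config: PipelineConfig | None = None) -> bool:
    """A gene is present in a genome if at least one of its fragments maps."""
    config = config or PipelineConfig()
    seq = gene.sequence if isinstance(gene, GeneFamily) else gene
    for fragment in fragment_sequence(seq, config.fragment_len_nt, config.min_fragment_tail_nt):
        if fragment_maps_to_genome(fragment, genome, config.max_mismatches):
            return True
    return False


def select_markers(core_genes: Sequence[GeneFamily],
                   genomes_by_sgb: Mapping[str, Sequence[GenomeRecord]],
                   sgb_id: str, config: PipelineConfig | None = None) -> MarkerSet:
    """Keep core genes never present in more than ``cross_map_max_frac`` of any
    other SGB's genomes (default: per-SGB fractions; ``cross_map_pooled``
    pools all external genomes instead)."""
    config = config or PipelineConfig()
    markers, fracs = [], {}
    external = {other: genomes for other, genomes in genomes_by_sgb.items() if other != sgb_id}
    for gene in core_genes:
        if config.cross_map_pooled:
            hits = total = 0
            for genomes in external.values():
                total += len(genomes)
                hits += sum(gene_present_in_genome(gene, g, config) for g in genomes)
            worst = hits / total if total else 0.0
        else:
            worst = 0.0
            for genomes in external.values():
                if not genomes:
                    continue
                frac = sum(gene_present_in_genome(gene, g, config) for g in genomes) / len(genomes)
                worst = max(worst, frac)
        fracs[gene.gene_id] = worst
        if worst <= config.cross_map_max_frac:
            markers.append(gene)
    return MarkerSet(sgb_id=sgb_id, markers=markers, cross_hit_fracs=fracs)
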