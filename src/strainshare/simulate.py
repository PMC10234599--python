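"""Synthetic data with planted ground truth.

Everything downstream of assembly is testable against these generators:

* pangenomes — per-SGB core/accessory gene repertoires with controlled
  within-SGB nucleotide divergence, optionally "leaky" core genes copied into
  another SGB's genomes (to exercise the 1% cross-mapping marker ceiling);
* cohorts — mother-infant families where each infant-carried SGB is, with a
  controllable probability, the mother's strain mutated at the within-strain
  divergence, or an independent strain at the between-strain divergence;
* shotgun reads — uniform-start, substitution-only error reads that emit their
  own true alignment records (so no external mapper is needed at desk scale);
* abundance tables — log-normal compositional profiles with planted fold
  changes between groups.

Strain genomes are built gene-wise (concatenated core genes, no intergenic
sequence) so marker selection and consensus calling share coordinates with the
truth manifests. All generators are deterministic given their seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import GenomeRecord
from .dna import decode, encode, revcomp_codes
from .io import AlignmentRecord, CohortManifest


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_sequence(length: int, rng) -> str:
    return decode(_rng(rng).integers(0, 4, size=length, dtype=np.uint8))


def mutate_sequence(seq: str, subst_rate: float, seed) -> str:
    """Substitute each position independently with probability ``subst_rate``
    to a uniformly chosen *different* base."""
    if len(seq) == 0:
        raise ValueError("cannot mutate an empty sequence")
    if not 0.0 <= subst_rate <= 1.0:
        raise ValueError("subst_rate must be in [0, 1]")
    rng = _rng(seed)
    codes = encode(seq)
    hit = rng.random(len(codes)) < subst_rate
    n_hit = int(hit.sum())
    if n_hit:
        # adding 1..3 mod 4 always lands on a different base
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=n_hit, dtype=np.uint8)) % 4
    return decode(codes)


# ---------------------------------------------------------------------------
# Pangenomes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSGBSpec:
    sgb_id: str
    n_genomes: int = 10
    n_core_genes: int = 20
    n_accessory_genes: int = 10
    gene_len_nt: int = 300
    within_sgb_divergence: float = 0.01
    n_reference_genomes: int = 0  # 0 -> unknown SGB
    taxonomy: tuple[str, ...] | None = None
    accessory_presence_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("a pangenome needs at least 2 genomes")
        if not 0.0 <= self.within_sgb_divergence < 0.05:
            raise ValueError("within-SGB divergence must stay below the 5% species boundary")
        if self.gene_len_nt < 1:
            raise ValueError("gene_len_nt must be positive")
        if self.n_reference_genomes > self.n_genomes:
            raise ValueError("n_reference_genomes cannot exceed n_genomes")


@dataclass
class PangenomeTruth:
    """One simulated SGB: genomes, ancestral gene sequences, and what is planted."""

    sgb_id: str
    genomes: list[GenomeRecord]
    gene_sequences: dict[str, str]  # gene_id -> ancestral sequence
    gene_inventory: dict[str, list[str]]  # genome_id -> gene ids present
    core_gene_ids: list[str]
    unique_gene_ids: list[str]  # core genes with no homolog planted elsewhere


def simulate_pangenome(spec: SyntheticSGBSpec, seed) -> PangenomeTruth:
    """Generate one SGB's pangenome.

    Core genes appear in every member; each accessory gene appears in a random
    subset. Per-genome gene copies diverge from the ancestral gene at
    ``within_sgb_divergence / 2`` so genome *pairs* differ by roughly the
    stated divergence. Each gene is one contig, keeping presence/absence and
    fragment mapping aligned with the truth.
    """
    rng = _rng(seed)
    core_ids = [f"{spec.sgb_id}_core{i:03d}" for i in range(spec.n_core_genes)]
    acc_ids = [f"{spec.sgb_id}_acc{i:03d}" for i in range(spec.n_accessory_genes)]
    gene_sequences = {gid: random_sequence(spec.gene_len_nt, rng) for gid in core_ids + acc_ids}

    genomes: list[GenomeRecord] = []
    inventory: dict[str, list[str]] = {}
    for g in range(spec.n_genomes):
        genome_id = f"{spec.sgb_id}_g{g:03d}"
        present = list(core_ids)
        for gid in acc_ids:
            if rng.random() < spec.accessory_presence_prob:
                present.append(gid)
        seqs = [mutate_sequence(gene_sequences[gid], spec.within_sgb_divergence / 2.0, rng)
                for gid in present]
        is_ref = g < spec.n_reference_genomes
        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                sequences=seqs,
                source="reference" if is_ref else "mag",
                completeness_pct=None if is_ref else float(rng.uniform(60, 99)),
                contamination_pct=None if is_ref else float(rng.uniform(0, 4.5)),
                taxonomy=spec.taxonomy if is_ref else None,
            )
        )
        inventory[genome_id] = present
    return PangenomeTruth(
        sgb_id=spec.sgb_id,
        genomes=genomes,
        gene_sequences=gene_sequences,
        gene_inventory=inventory,
        core_gene_ids=core_ids,
        unique_gene_ids=list(core_ids),
    )


def simulate_pangenome_set(specs: Sequence[SyntheticSGBSpec], seed,
                           n_leaky_core_genes: int = 0,
                           leak_frac: float = 0.2) -> dict[str, PangenomeTruth]:
    """Generate several SGBs with distinct gene pools, optionally planting
    cross-SGB homologs.

    For each SGB, the first ``n_leaky_core_genes`` core genes are copied
    verbatim as extra contigs into ``ceil(leak_frac * n)`` genomes of the next
    SGB (cyclically). Leaky genes are removed from ``unique_gene_ids``: they
    are exactly the genes the 1% cross-mapping rule must reject when
    ``leak_frac`` exceeds it.
    """
    rng = _rng(seed)
    truths = {spec.sgb_id: simulate_pangenome(spec, rng) for spec in specs}
    if n_leaky_core_genes:
        if len(specs) < 2:
            raise ValueError("cross-SGB leakage needs at least two SGBs")
        order = [spec.sgb_id for spec in specs]
        for idx, sgb_id in enumerate(order):
            src = truths[sgb_id]
            dst = truths[order[(idx + 1) % len(order)]]
            n_copy = max(1, math.ceil(leak_frac * len(dst.genomes)))
            leaky = src.core_gene_ids[:n_leaky_core_genes]
            targets = list(rng.choice(len(dst.genomes), size=n_copy, replace=False))
            for gid in leaky:
                for t in targets:
                    dst.genomes[t].sequences.append(src.gene_sequences[gid])
                    dst.gene_inventory[dst.genomes[t].genome_id].append(gid)
            src.unique_gene_ids = [g for g in src.core_gene_ids if g not in set(leaky)]
    return truths


# ---------------------------------------------------------------------------
# Cohorts with planted transmission
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    """A simulated mother-infant cohort and its complete ground truth."""

    manifest: CohortManifest
    strain_genomes: dict[tuple[str, str], str]  # (sample_id, sgb_id) -> genome
    gene_offsets: dict[str, list[tuple[str, int, int]]]  # sgb -> (gene_id, start, end)
    ancestors: dict[str, str]  # sgb -> ancestral genome
    truth: pd.DataFrame  # family_id, sgb_id, carriage, transmission decisions
    sgb_ids: list[str] = field(default_factory=list)

    def carriers(self, sgb_id: str) -> list[str]:
        return sorted(s for (s, g) in self.strain_genomes if g == sgb_id)


def simulate_cohort(n_families: int, sgb_specs: Sequence[SyntheticSGBSpec],
                    p_transmit: float, carriage_prob: float,
                    within_strain_div: float, between_strain_div: float, seed,
                    cohort: str = "synthetic", lifestyle: str = "westernized") -> CohortSim:
    """Simulate families with planted mother-to-infant strain transmission.

    Per (family, SGB): the mother's strain sits at ``between_strain_div / 2``
    from the SGB ancestor, so two independent strains differ by roughly
    ``between_strain_div``. Carriage is Bernoulli per sample and SGB,
    independent of transmission. An infant-carried SGB is, with probability
    ``p_transmit``, the mother's strain mutated at ``within_strain_div``;
    otherwise an independent strain. ``truth.transmitted`` is True only for
    inherited *and* co-carried triples — the events the pipeline can observe.
    """
    if not 0.0 <= p_transmit <= 1.0:
        raise ValueError("p_transmit must be in [0, 1]")
    if not 0.0 <= carriage_prob <= 1.0:
        raise ValueError("carriage_prob must be in [0, 1]")
    if within_strain_div >= between_strain_div:
        raise ValueError("within-strain divergence must be below between-strain divergence")
    rng = _rng(seed)

    gene_offsets: dict[str, list[tuple[str, int, int]]] = {}
    ancestors: dict[str, str] = {}
    for spec in sgb_specs:
        genes = [(f"{spec.sgb_id}_core{i:03d}", random_sequence(spec.gene_len_nt, rng))
                 for i in range(spec.n_core_genes)]
        offsets, pos, parts = [], 0, []
        for gid, seq in genes:
            offsets.append((gid, pos, pos + len(seq)))
            pos += len(seq)
            parts.append(seq)
        gene_offsets[spec.sgb_id] = offsets
        ancestors[spec.sgb_id] = "".join(parts)

    rows = []
    strain_genomes: dict[tuple[str, str], str] = {}
    truth_rows = []
    for f in range(n_families):
        family_id = f"F{f:03d}"
        mother_sample, infant_sample = f"{family_id}_M", f"{family_id}_I"
        rows.append(dict(sample_id=mother_sample, subject_id=f"{family_id}_mom",
                         family_id=family_id, role="mother",
                         age_months=float(rng.integers(240, 480)), cohort=cohort,
                         lifestyle=lifestyle, delivery_mode="unknown"))
        rows.append(dict(sample_id=infant_sample, subject_id=f"{family_id}_inf",
                         family_id=family_id, role="infant",
                         age_months=float(rng.uniform(0.5, 12.0)), cohort=cohort,
                         lifestyle=lifestyle,
                         delivery_mode="vaginal" if rng.random() < 0.8 else "c_section"))
        for spec in sgb_specs:
            sgb = spec.sgb_id
            mother_strain = mutate_sequence(ancestors[sgb], between_strain_div / 2.0, rng)
            mother_carries = bool(rng.random() < carriage_prob)
            infant_carries = bool(rng.random() < carriage_prob)
            inherited = bool(rng.random() < p_transmit)
            if inherited:
                infant_strain = mutate_sequence(mother_strain, within_strain_div, rng)
                planted_div = within_strain_div
            else:
                infant_strain = mutate_sequence(ancestors[sgb], between_strain_div / 2.0, rng)
                planted_div = between_strain_div
            if mother_carries:
                strain_genomes[(mother_sample, sgb)] = mother_strain
            if infant_carries:
                strain_genomes[(infant_sample, sgb)] = infant_strain
            truth_rows.append(dict(
                family_id=family_id, sgb_id=sgb,
                mother_carries=mother_carries, infant_carries=infant_carries,
                inherited=inherited,
                transmitted=inherited and mother_carries and infant_carries,
                mother_strain_id=f"{family_id}:{sgb}:M",
                infant_strain_id=f"{family_id}:{sgb}:I",
                planted_divergence=planted_div,
            ))
    manifest = CohortManifest.from_frame(pd.DataFrame(rows))
    return CohortSim(
        manifest=manifest,
        strain_genomes=strain_genomes,
        gene_offsets=gene_offsets,
        ancestors=ancestors,
        truth=pd.DataFrame(truth_rows),
        sgb_ids=[spec.sgb_id for spec in sgb_specs],
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSim:
    reads: list[tuple[str, str]]  # (read_id, sequence as sequenced)
    alignments: list[AlignmentRecord]  # the true alignment of every read


def simulate_reads(genome: str, mean_depth: float, read_len: int, err_rate: float,
                   seed, ref_id: str = "ref", read_prefix: str = "r") -> ReadSim:
    """Uniform-start substitution-error shotgun reads plus their true alignments.

    Read count is ``round(mean_depth * genome_len / read_len)``; strands are
    Bernoulli(0.5); each base is substituted independently at ``err_rate``.
    The emitted AlignmentRecord carries the read's base calls in reference
    orientation with the true mapq (60) and realized identity.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if len(genome) == 0 or read_len > len(genome):
        raise ValueError("read_len must not exceed genome length")
    rng = _rng(seed)
    n_reads = int(round(mean_depth * len(genome) / read_len))
    genome_codes = encode(genome)
    starts = rng.integers(0, len(genome) - read_len + 1, size=n_reads)
    minus = rng.random(n_reads) < 0.5
    reads, alignments = [], []
    for i in range(n_reads):
        start = int(starts[i])
        codes = genome_codes[start : start + read_len].copy()
        hit = rng.random(read_len) < err_rate
        n_hit = int(hit.sum())
        if n_hit:
            codes[hit] = (codes[hit] + rng.integers(1, 4, size=n_hit, dtype=np.uint8)) % 4
        identity = 1.0 - n_hit / read_len
        ref_oriented = decode(codes)
        read_seq = decode(revcomp_codes(codes)) if minus[i] else ref_oriented
        read_id = f"{read_prefix}{i:06d}"
        reads.append((read_id, read_seq))
        alignments.append(AlignmentRecord(
            read_id=read_id, ref_id=ref_id, ref_start=start, aligned_len_nt=read_len,
            mapq=60, identity_frac=identity, strand="-" if minus[i] else "+",
            bases=ref_oriented,
        ))
    return ReadSim(reads=reads, alignments=alignments)


def project_alignments(alignments: Sequence[AlignmentRecord], target_genome: str,
                       target_ref_id: str, min_identity: float = 0.90
                       ) -> list[AlignmentRecord]:
    """Re-map true alignments onto a coordinate-shared candidate reference.

    Synthetic genomes derived by substitution share coordinates, so a read's
    gapless alignment carries over position-for-position; only its identity
    against the new reference changes. Reads falling below ``min_identity``
    are dropped, emulating a sensitive mapper's alignment threshold. This is
    the desk-scale stand-in for re-mapping reads against each candidate in a
    reference-ranking analysis.
    """
    target_codes = encode(target_genome)
    out = []
    for r in alignments:
        codes = encode(r.bases)
        ref_slice = target_codes[r.ref_start : r.ref_start + r.aligned_len_nt]
        comparable = (codes < 4) & (ref_slice < 4)
        n_comp = int(comparable.sum())
        if n_comp == 0:
            continue
        identity = 1.0 - int((codes[comparable] != ref_slice[comparable]).sum()) / n_comp
        if identity < min_identity:
            continue
        out.append(AlignmentRecord(
            read_id=r.read_id, ref_id=target_ref_id, ref_start=r.ref_start,
            aligned_len_nt=r.aligned_len_nt, mapq=r.mapq,
            identity_frac=identity, strand=r.strand, bases=r.bases))
    return out


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceSim:
    table: pd.DataFrame  # samples x species, rows sum to 1
    groups: pd.Series  # sample -> group label
    planted_effects: dict[str, float]  # species -> fold change in group B


def simulate_abundance_table(n_samples_per_group: int, n_species: int,
                             planted_effects: Mapping[str, float] | Mapping[int, float],
                             seed, sigma: float = 1.0,
                             group_labels: tuple[str, str] = ("A", "B")) -> AbundanceSim:
    """Compositional log-normal abundance table with planted group effects.

    Species base means are themselves log-normal (heavy-tailed, like real
    profiles); planted species have their group-B mean multiplied by the fold
    change before row renormalization. Renormalization slightly attenuates
    large planted folds, as it does in real relative-abundance data.
    """
    rng = _rng(seed)
    species = [f"s{i:03d}" for i in range(n_species)]
    effects: dict[str, float] = {}
    for key, fold in dict(planted_effects).items():
        name = species[key] if isinstance(key, (int, np.integer)) else str(key)
        if name not in species:
            raise ValueError(f"unknown species {name!r}")
        if fold <= 0:
            raise ValueError("fold change must be positive")
        effects[name] = float(fold)

    base_mu = rng.normal(0.0, 1.5, size=n_species)
    n = n_samples_per_group
    raw = np.exp(rng.normal(base_mu, sigma, size=(2 * n, n_species)))
    for name, fold in effects.items():
        raw[n:, species.index(name)] *= fold
    table = raw / raw.sum(axis=1, keepdims=True)
    sample_ids = [f"{group_labels[0]}_{i:03d}" for i in range(n)] + [
        f"{group_labels[1]}_{i:03d}" for i in range(n)
    ]
    groups = pd.Series([group_labels[0]] * n + [group_labels[1]] * n, index=sample_ids)
    return AbundanceSim(
        table=pd.DataFrame(table, index=sample_ids, columns=species),
        groups=groups,
        planted_effects=effects,
    )
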