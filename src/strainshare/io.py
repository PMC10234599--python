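"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ and the internal tabular alignment format are plain text; trees go
through scikit-bio's newick support; SAM/BAM alignments are adapted to
:class:`AlignmentRecord` via pysam; manifests, distance matrices and abundance
tables are tab-separated tables handled with pandas.

Coordinates are 0-based half-open everywhere; SAM's 1-based coordinates are
converted at this boundary. Sequences are upper-cased on read and characters
outside {A,C,G,T} become N.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from skbio import TreeNode

from .dna import normalize

FASTA_WIDTH = 80

ROLES = {"mother", "infant"}
LIFESTYLES = {"westernized", "non_westernized"}
DELIVERY_MODES = {"vaginal", "c_section", "unknown"}

MANIFEST_COLUMNS = [
    "sample_id",
    "subject_id",
    "family_id",
    "role",
    "age_months",
    "cohort",
    "lifestyle",
    "delivery_mode",
]


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line number."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``[(id, sequence), ...]``.

    Sequences are normalized (upper case, non-ACGT -> N). Malformed headers,
    empty identifiers and empty sequences raise :class:`FastaParseError`
    naming the line number. The hand parser exists because these line-level
    diagnostics and the normalization contract are part of the format surface.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks or not any(chunks):
            raise FastaParseError(f"line {header_line}: record '{header}' has an empty sequence")
        records.append((header, normalize("".join(chunks))))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"line {lineno}: sequence data before any '>' header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = FASTA_WIDTH) -> None:
    """Write ``(id, sequence)`` records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTQ into ``[(id, sequence), ...]``; qualities are discarded."""
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - 3, 4):
        if not lines[i].startswith("@"):
            raise ValueError(f"line {i + 1}: expected '@' FASTQ header")
        records.append((lines[i][1:].split()[0], normalize(lines[i + 1])))
    return records


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with flat maximum qualities (synthetic reads carry none)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Validated sample metadata: families, roles, ages, cohorts, lifestyles.

    ``frame`` carries one row per sample plus a derived boolean ``unpaired``
    column flagging infants whose family has no mother sample (kept, not
    dropped). Infants are defined by role; age strata used downstream apply to
    infants only.
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortManifest":
        df = frame.copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        df = df[MANIFEST_COLUMNS].astype(
            {"sample_id": str, "subject_id": str, "family_id": str, "role": str,
             "cohort": str, "lifestyle": str, "delivery_mode": str}
        )
        df["age_months"] = pd.to_numeric(df["age_months"])
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id: {sorted(set(dup))}")
        bad_role = set(df["role"]) - ROLES
        if bad_role:
            raise ValueError(f"unknown role value(s): {sorted(bad_role)}")
        bad_ls = set(df["lifestyle"]) - LIFESTYLES
        if bad_ls:
            raise ValueError(f"unknown lifestyle value(s): {sorted(bad_ls)}")
        bad_dm = set(df["delivery_mode"]) - DELIVERY_MODES
        if bad_dm:
            raise ValueError(f"unknown delivery_mode value(s): {sorted(bad_dm)}")
        if (df["age_months"] < 0).any():
            raise ValueError("age_months must be >= 0")
        mother_subjects = df[df["role"] == "mother"].groupby("family_id")["subject_id"].nunique()
        multi = mother_subjects[mother_subjects > 1]
        if len(multi):
            raise ValueError(f"families with more than one mother subject: {list(multi.index)}")
        mother_families = set(df.loc[df["role"] == "mother", "family_id"])
        df["unpaired"] = (df["role"] == "infant") & ~df["family_id"].isin(mother_families)
        return cls(df.reset_index(drop=True))

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_of_subject(self, subject_id: str) -> list[str]:
        df = self.frame
        return list(df.loc[df["subject_id"] == subject_id, "sample_id"])

    def infants(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "infant"]

    def mothers(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "mother"]

    def mother_samples_of_family(self, family_id: str) -> list[str]:
        df = self.frame
        sel = (df["family_id"] == family_id) & (df["role"] == "mother")
        return list(df.loc[sel, "sample_id"])

    def mother_infant_pairs(self) -> list[tuple[str, str]]:
        """All (mother sample, infant sample) pairs within each family."""
        pairs = []
        for family_id, group in self.frame.groupby("family_id"):
            mothers = group.loc[group["role"] == "mother", "sample_id"]
            infants = group.loc[group["role"] == "infant", "sample_id"]
            pairs.extend((m, i) for m in mothers for i in infants)
        return pairs

    def row(self, sample_id: str) -> pd.Series:
        df = self.frame
        return df.loc[df["sample_id"] == sample_id].iloc[0]


def read_manifest(path: str | Path) -> CohortManifest:
    return CohortManifest.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.frame.drop(columns=["unpaired"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees (newick)
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as newick; every leaf must be named."""
    for tip in tree.tips():
        if not tip.name:
            raise ValueError("tree has unnamed leaves; cannot serialize to newick")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One read-to-reference alignment, normalized to internal conventions.

    ``ref_start`` is 0-based; ``bases`` holds the per-reference-position base
    calls (over {A,C,G,T,-}) in reference orientation, so ``len(bases) ==
    aligned_len_nt`` and the record covers ``[ref_start, ref_start +
    aligned_len_nt)``.
    """

    read_id: str
    ref_id: str
    ref_start: int
    aligned_len_nt: int
    mapq: int
    identity_frac: float
    strand: str
    bases: str

    def __post_init__(self) -> None:
        if self.aligned_len_nt <= 0:
            raise ValueError("aligned_len_nt must be positive")
        if len(self.bases) != self.aligned_len_nt:
            raise ValueError("bases length must equal aligned_len_nt")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        if not 0.0 <= self.identity_frac <= 1.0:
            raise ValueError("identity_frac must be in [0, 1]")


ALIGNMENT_COLUMNS = [
    "read_id", "ref_id", "ref_start", "aligned_len_nt",
    "mapq", "identity_frac", "strand", "bases",
]


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.ref_id}\t{r.ref_start}\t{r.aligned_len_nt}\t"
                f"{r.mapq}\t{r.identity_frac:.6f}\t{r.strand}\t{r.bases}\n"
            )


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    return [
        AlignmentRecord(
            read_id=row.read_id,
            ref_id=row.ref_id,
            ref_start=int(row.ref_start),
            aligned_len_nt=int(row.aligned_len_nt),
            mapq=int(row.mapq),
            identity_frac=float(row.identity_frac),
            strand=row.strand,
            bases=row.bases,
        )
        for row in df.itertuples()
    ]


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Thin SAM/BAM adapter: mapped reads become AlignmentRecords.

    Base calls are projected onto reference coordinates (deletions become
    '-'; insertions are dropped, as they occupy no reference position).
    Identity is taken from the NM tag when present, otherwise 1.0.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            start = aln.reference_start
            span = aln.reference_end - start
            calls = ["-"] * span
            query = aln.query_sequence
            for qpos, rpos in aln.get_aligned_pairs():
                if rpos is None or qpos is None:
                    continue
                calls[rpos - start] = query[qpos].upper()
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            identity = max(0.0, 1.0 - nm / max(span, 1))
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name,
                    ref_start=start,
                    aligned_len_nt=span,
                    mapq=aln.mapping_quality,
                    identity_frac=identity,
                    strand="-" if aln.is_reverse else "+",
                    bases="".join(c if c in "ACGT-" else "N" for c in calls),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Matrices and tables
# ---------------------------------------------------------------------------

def write_distance_matrix(ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Samples x species relative abundance table (rows should sum to ~1)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_abundance_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
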