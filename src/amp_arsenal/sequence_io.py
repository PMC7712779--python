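"""Readers and writers for the external formats used across the pipeline.

All parsing of FASTA, FASTQ, the 9-column gene table, domain-hit tables and
Newick trees goes through this module so the rest of the package never touches
raw files.  Coordinates are 1-based inclusive throughout the public surface.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from skbio import TreeNode

DNA_ALPHABET = set("ACGTN")
#: minimum run of N considered an assembly gap (shorter runs = ambiguous bases)
MIN_GAP_RUN = 10

FASTA_WRAP = 70

GENE_TABLE_COLUMNS = [
    "no",
    "gene",
    "product",
    "cds_len",
    "prot_len",
    "pfam_code",
    "pfam_name",
    "scaffold",
    "equivalent_cds",
]

UNPLACED = "Unplaced"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaffoldSeq:
    """A genome scaffold plus the 1-based inclusive intervals of its N-gaps."""

    id: str
    seq: str
    gaps: tuple = field(default=())

    @staticmethod
    def from_seq(sid: str, seq: str, min_gap_run: int = MIN_GAP_RUN) -> "ScaffoldSeq":
        seq = seq.upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(f"scaffold {sid!r}: non-DNA characters {sorted(bad)}")
        gaps = tuple(
            (m.start() + 1, m.end())
            for m in re.finditer(r"N+", seq)
            if m.end() - m.start() >= min_gap_run
        )
        return ScaffoldSeq(sid, seq, gaps)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    qual: tuple

    def __post_init__(self):
        if len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: {len(self.seq)} bases but {len(self.qual)} quality values"
            )

    @property
    def mean_qual(self) -> float:
        return sum(self.qual) / len(self.qual) if self.qual else 0.0

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneTableRow:
    """One row of the curated AMP gene table (the printed catalogue row)."""

    no: int
    gene: str
    product: str
    cds_len: int
    prot_len: int
    pfam_code: str
    pfam_name: str
    scaffold: str
    equivalent_cds: str = ""

    def check_lengths(self) -> None:
        if self.cds_len % 3 != 0:
            raise FormatError(f"{self.gene}: CDS length {self.cds_len} not divisible by 3")
        expected = self.cds_len // 3 - 1
        if self.prot_len != expected:
            raise FormatError(
                f"{self.gene}: protein length {self.prot_len} != CDS/3 - 1 = {expected}"
            )


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain: str
    start: int
    end: int
    score: float


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _iter_fasta(handle) -> Iterable[tuple]:
    rid, chunks = None, []
    for lineno, raw in enumerate(handle, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if rid is not None:
                yield rid, "".join(chunks)
            rid = line[1:].split()[0] if line[1:].strip() else ""
            if not rid:
                raise FormatError(f"line {lineno}: empty FASTA record id")
            chunks = []
        else:
            if rid is None:
                raise FormatError(f"line {lineno}: sequence before first header")
            chunks.append(line.strip().upper())
    if rid is not None:
        yield rid, "".join(chunks)


def read_fasta(path, alphabet: set | None = None) -> list:
    """Read FASTA into an ordered list of (id, uppercased sequence) pairs."""
    with _open_text(path) as fh:
        records = list(_iter_fasta(fh))
    if alphabet is not None:
        for rid, seq in records:
            bad = set(seq) - alphabet
            if bad:
                raise FormatError(f"record {rid!r}: characters outside alphabet: {sorted(bad)}")
    return records


def read_fasta_str(text: str) -> list:
    return list(_iter_fasta(io.StringIO(text)))


def write_fasta(records: Iterable, path, wrap: int = FASTA_WRAP) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path, offset: int = 33) -> list:
    """Read a 4-line-per-record FASTQ file (Phred+33 unless offset=64)."""
    reads = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"FASTQ record truncated: {len(lines)} lines is not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"line {i + 1}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"line {i + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise FormatError(f"record {head[1:]!r}: sequence/quality length mismatch")
        reads.append(
            ReadRecord(head[1:].split()[0], seq.upper(), tuple(ord(c) - offset for c in qual))
        )
    return reads


def write_fastq(reads: Iterable, path, offset: int = 33) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + offset) for q in r.qual) + "\n")


# ---------------------------------------------------------------------------
# gene table (9-column TSV)
# ---------------------------------------------------------------------------


def read_gene_table(path, check: bool = True) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table missing columns: {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        row = GeneTableRow(
            no=int(rec.no),
            gene=rec.gene,
            product=rec.product,
            cds_len=int(rec.cds_len),
            prot_len=int(rec.prot_len),
            pfam_code=rec.pfam_code,
            pfam_name=rec.pfam_name,
            scaffold=rec.scaffold,
            equivalent_cds=rec.equivalent_cds,
        )
        if check:
            row.check_lengths()
        rows.append(row)
    return rows


def write_gene_table(rows: Sequence, path) -> None:
    df = pd.DataFrame(
        [[getattr(r, c) for c in GENE_TABLE_COLUMNS] for r in rows],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# domain-hit table
# ---------------------------------------------------------------------------


def read_domain_hits(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = ["protein_id", "domain", "start", "end", "score"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"domain-hit table missing columns: {missing}")
    return [
        DomainHit(r.protein_id, r.domain, int(r.start), int(r.end), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_domain_hits(hits: Iterable, path) -> None:
    df = pd.DataFrame(
        [[h.protein_id, h.domain, h.start, h.end, h.score] for h in hits],
        columns=["protein_id", "domain", "start", "end", "score"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
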