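"""Sequence I/O, alphabet normalization, codon iteration and stop-codon logic.

Coordinates are 1-based and inclusive throughout the package; BED export
(in :mod:`prfcub.prf_signal`) converts to 0-based half-open.  The internal
canonical alphabet is DNA: RNA input is accepted and U is mapped to T.
Ambiguity codes (N, R, Y, ...) are rejected rather than skipped, because
every downstream statistic assumes unambiguous codons.

The genetic code is the standard nuclear code; the stop set is fixed to
{TAA, TAG, TGA}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("prfcub")

#: Stop codons of the standard nuclear genetic code (DNA alphabet).
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Canonical nucleotide alphabet after normalization.
DNA_ALPHABET = frozenset("ACGT")

_NORMALIZE = str.maketrans("acgtuU", "ACGTTT")


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, duplicate ids...)."""


@dataclass(frozen=True)
class Gene:
    """A coding sequence with identity and length bookkeeping.

    Attributes
    ----------
    id : str
        Non-empty identifier, unique within a gene set.
    seq : str
        Nucleotide string over {A, C, G, T} after normalization.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("gene id must be non-empty")
        bad = next((i for i, ch in enumerate(self.seq) if ch not in DNA_ALPHABET), None)
        if bad is not None:
            raise SequenceError(
                f"gene {self.id!r}: invalid nucleotide {self.seq[bad]!r} "
                f"at position {bad + 1} (only A/C/G/T/U accepted)"
            )

    @classmethod
    def from_raw(cls, gene_id: str, raw_seq: str) -> "Gene":
        """Build a Gene from raw (possibly RNA, mixed-case) sequence text."""
        return cls(id=gene_id, seq=raw_seq.translate(_NORMALIZE))

    @property
    def length_nt(self) -> int:
        """Length in nucleotides."""
        return len(self.seq)

    @property
    def length_codons(self) -> int:
        """Number of complete codons in frame 0 (floor of length_nt / 3)."""
        return len(self.seq) // 3


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression: protein molecules per cell P, optional mRNA level."""

    gene_id: str
    protein_per_cell: float
    mrna_per_cell: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.protein_per_cell > 0:
            raise SequenceError(
                f"gene {self.gene_id!r}: protein_per_cell must be > 0"
            )


def read_fasta(path: str | Path) -> list[Gene]:
    """Read a FASTA file into a list of :class:`Gene`, order preserved.

    Records may be line-wrapped, DNA or RNA, mixed case.  Duplicate ids and
    non-ACGTU characters raise :class:`SequenceError`; an empty file returns
    an empty list with a warning.
    """
    path = Path(path)
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in ">;\n":
            raise SequenceError(f"{path}: sequence data before first FASTA header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise SequenceError(f"{path}: duplicate gene id {rec.id!r}")
            seen.add(rec.id)
            genes.append(Gene.from_raw(rec.id, str(rec.seq)))
    if not genes:
        logger.warning("%s: no FASTA records found", path)
    return genes


def write_fasta(genes: Iterable[Gene], path: str | Path, width: int = 70) -> None:
    """Write Genes to FASTA (wrapped at `width` columns)."""
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def codons(gene: Gene, start_nt: int = 1) -> tuple[list[str], str]:
    """Consecutive non-overlapping codons of `gene` from 1-based `start_nt`.

    Returns ``(codon_list, remainder)`` where `remainder` is the trailing
    1-2 nt that do not fill a codon.
    """
    if not 1 <= start_nt <= gene.length_nt:
        raise SequenceError(
            f"start_nt={start_nt} out of range 1..{gene.length_nt} for gene {gene.id!r}"
        )
    tail = gene.seq[start_nt - 1 :]
    n_full = len(tail) // 3
    codon_list = [tail[3 * i : 3 * i + 3] for i in range(n_full)]
    return codon_list, tail[3 * n_full :]


def first_stop(codon_list: Sequence[str]) -> Optional[int]:
    """1-based index of the first stop codon in `codon_list`, or None."""
    for i, c in enumerate(codon_list):
        if len(c) != 3:
            raise SequenceError(f"element {i + 1} is not a 3-mer: {c!r}")
        if c in STOP_CODONS:
            return i + 1
    return None


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read the expression TSV: gene_id, protein_per_cell[, mrna_per_cell].

    Rows with missing or nonpositive protein_per_cell are dropped; the drop
    count is logged.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "protein_per_cell"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceError(f"{path}: missing columns {sorted(missing)}")
    has_mrna = "mrna_per_cell" in df.columns
    records: list[ExpressionRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        p = getattr(row, "protein_per_cell")
        if pd.isna(p) or p <= 0:
            dropped += 1
            continue
        m = getattr(row, "mrna_per_cell", None) if has_mrna else None
        if m is not None and pd.isna(m):
            m = None
        records.append(
            ExpressionRecord(
                gene_id=str(getattr(row, "gene_id")),
                protein_per_cell=float(p),
                mrna_per_cell=None if m is None else float(m),
            )
        )
    if dropped:
        logger.info("dropped %d expression rows with missing/nonpositive P", dropped)
    return records


def write_expression(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    """Write expression records as TSV (mrna_per_cell blank when absent)."""
    records = list(records)
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "protein_per_cell": [r.protein_per_cell for r in records],
            "mrna_per_cell": [r.mrna_per_cell for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
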