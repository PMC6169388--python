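"""Relative adaptiveness and the codon adaptation index (CAI).

The relative adaptiveness of a codon c decoding amino acid a is its
frequency within the synonymous family, measured on a reference set of
highly expressed genes (by convention the concatenated ribosomal coding
sequences):

    omega_ac = o_ac / sum_{c' in C_a} o_ac'

Note this is frequency / family *sum*; the classical variant that divides
by the family *maximum* is available via ``omega_mode="max"``.

The index of a gene is the mean log relative adaptiveness over its scored
codons,

    log CAI = (1/L) * sum_a sum_c o_ac * ln(omega_ac^ref),

with o_ac counted on the gene in frame 0, stop codons and a trailing
partial codon skipped, and L the number of codons actually scored.  The
headline value reported is CAI = exp(log CAI), which lies in (0, 1]; both
forms are emitted.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .sequence_core import Gene, SequenceError, STOP_CODONS, codons

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons of the standard code.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: amino acid -> sorted tuple of its synonymous codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))


@dataclass(frozen=True)
class AdaptivenessTable:
    """Per-codon relative adaptiveness learned from a reference gene set."""

    omega: Mapping[str, float]
    counts: Mapping[str, float]
    source_ids: tuple[str, ...]
    omega_mode: str = "sum"

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.omega)
        if missing:
            raise SequenceError(f"omega table incomplete: missing {sorted(missing)[:4]}...")

    def log_omega(self, codon: str) -> float:
        return math.log(self.omega[codon])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: codon, amino_acid, count, omega."""
        rows = [
            (c, CODON_TO_AA[c], self.counts[c], self.omega[c])
            for c in SENSE_CODONS
        ]
        return pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "omega"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CaiValue:
    """CAI of one gene: log form (<= 0), exp form in (0, 1], codons scored."""

    gene_id: str
    log_cai: float
    cai: float
    codons_used: int


def build_reference(
    ref_genes: Sequence[Gene],
    pseudocount: float = 0.5,
    omega_mode: Literal["sum", "max"] = "sum",
) -> AdaptivenessTable:
    """Pool codon counts over the concatenated reference genes and normalize.

    `pseudocount` is added to every sense codon's count before the
    within-family normalization, so omega > 0 even for codons absent from
    the reference.  Stop codons are excluded from counting.  With
    ``pseudocount=0`` a family left entirely uncounted raises an error.
    """
    if not ref_genes:
        raise SequenceError("empty reference gene set")
    if pseudocount < 0:
        raise SequenceError("pseudocount must be nonnegative")

    raw: Counter[str] = Counter()
    for g in ref_genes:
        codon_list, remainder = codons(g, 1)
        if remainder:
            logging.getLogger("prfcub").warning(
                "reference gene %s: dropping %d-nt trailing remainder", g.id, len(remainder)
            )
        raw.update(c for c in codon_list if c not in STOP_CODONS)

    counts = {c: raw.get(c, 0) + pseudocount for c in SENSE_CODONS}
    omega: dict[str, float] = {}
    for aa, family in AA_TO_CODONS.items():
        if omega_mode == "sum":
            denom = sum(counts[c] for c in family)
        elif omega_mode == "max":
            denom = max(counts[c] for c in family)
        else:
            raise ValueError(f"unknown omega_mode {omega_mode!r}")
        if denom == 0:
            raise SequenceError(
                f"amino acid family {aa!r} has zero reference count and pseudocount 0"
            )
        for c in family:
            omega[c] = counts[c] / denom

    return AdaptivenessTable(
        omega=omega,
        counts=counts,
        source_ids=tuple(g.id for g in ref_genes),
        omega_mode=omega_mode,
    )


def cai(gene: Gene, table: AdaptivenessTable) -> CaiValue:
    """Codon adaptation index of `gene` under `table` (frame 0).

    Stop codons and any trailing partial codon are skipped and excluded
    from the normalizer; a gene with no scorable sense codon is an error.
    """
    if gene.length_nt < 3:
        raise SequenceError(f"gene {gene.id!r}: too short for any codon")
    codon_list, _ = codons(gene, 1)
    total = 0.0
    used = 0
    for c in codon_list:
        if c in STOP_CODONS:
            continue
        total += table.log_omega(c)
        used += 1
    if used == 0:
        raise SequenceError(f"gene {gene.id!r}: no usable sense codons")
    log_cai = total / used
    return CaiValue(gene_id=gene.id, log_cai=log_cai, cai=math.exp(log_cai), codons_used=used)


def cai_of_sequence(seq: str, table: AdaptivenessTable, gene_id: str = "<seq>") -> CaiValue:
    """CAI of a bare nucleotide string (frame 0), e.g. a hybrid sequence x'."""
    return cai(Gene(id=gene_id, seq=seq), table)


def cai_table(genes: Iterable[Gene], table: AdaptivenessTable) -> pd.DataFrame:
    """CAI for many genes: columns gene_id, log_cai, cai, codons_used."""
    vals = [cai(g, table) for g in genes]
    return pd.DataFrame(
        {
            "gene_id": [v.gene_id for v in vals],
            "log_cai": [v.log_cai for v in vals],
            "cai": [v.cai for v in vals],
            "codons_used": [v.codons_used for v in vals],
        }
    )
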