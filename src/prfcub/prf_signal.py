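"""Slippery-site detection and -1 frameshifted hybrid sequence construction.

A -1 PRF slippery site is the heptamer X XXY YYZ: three identical X (any
base), three identical Y with Y in {A, T}, and Z in {A, C, T}.  There are
4 x 2 x 3 = 24 legal heptamers.  With the frame constraint on (default),
the heptamer must start at a 1-based position l with l % 3 == 0, so that
the lone X is the last base of a frame-0 codon and the in-frame codons
read XXY | YYZ.

When the ribosome slips it re-reads the base at l: translation continues
in the -1 frame with codons starting at l, l+3, ... (the first two -1
codons are XXX and YYY) until a premature termination codon (PTC).  The
hybrid sequence is

    x' = seq[1..l] ++ seq[l..l+lambda]         (1-based inclusive slices)

where lambda is the distance in nt from l to the last base of the first
-1-frame stop codon, so |x'| = l + lambda + 1 and is divisible by 3.

Pseudoknot / secondary-structure prediction is out of scope: the spacer
rule only requires >= min_spacer nt downstream of the heptamer, and
externally computed structure annotations can be used to filter sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .sequence_core import Gene, SequenceError, STOP_CODONS

#: Lookahead regex for overlapping matches of the slippery heptamer.
_HEPTAMER_RE = re.compile(r"(?=(([ACGT])\2{2}([AT])\3{2}[ACT]))")

#: All 24 heptamers matching the slippery-site pattern.
LEGAL_HEPTAMERS: tuple[str, ...] = tuple(
    sorted(
        x * 3 + y * 3 + z
        for x in "ACGT"
        for y in "AT"
        for z in "ACT"
    )
)


def is_slippery_heptamer(heptamer: str) -> bool:
    """Predicate form of the X XXY YYZ pattern rule for a single 7-mer."""
    if len(heptamer) != 7:
        return False
    x, y, z = heptamer[0], heptamer[3], heptamer[6]
    return (
        heptamer[1] == x
        and heptamer[2] == x
        and y in "AT"
        and heptamer[4] == y
        and heptamer[5] == y
        and z in "ACT"
    )


@dataclass(frozen=True)
class SlipperySite:
    """A detected slippery heptamer and (optionally) its frameshift outcome.

    `l` is the 1-based position of the heptamer's first base (the lone X).
    `lambda_nt` / `ptc_found` / `x_prime` are filled in by :func:`frameshift`.
    """

    gene_id: str
    l: int
    heptamer: str
    rel_pos: float
    spacer_ok: bool
    lambda_nt: Optional[int] = None
    ptc_found: Optional[bool] = None
    x_prime: Optional[str] = None

    @property
    def completed(self) -> bool:
        return self.lambda_nt is not None


def scan_slippery_sites(
    gene: Gene,
    min_spacer: int = 8,
    frame_constrained: bool = True,
) -> list[SlipperySite]:
    """All heptamer matches in `gene`, overlapping matches included.

    Sites failing the spacer rule (fewer than `min_spacer` nt downstream
    of the heptamer) are returned with ``spacer_ok=False``; downstream
    analyses exclude them by default.  With `frame_constrained`, only
    positions with l % 3 == 0 (1-based) are reported.
    """
    sites: list[SlipperySite] = []
    L = gene.length_nt
    for m in _HEPTAMER_RE.finditer(gene.seq):
        l = m.start() + 1
        if frame_constrained and l % 3 != 0:
            continue
        sites.append(
            SlipperySite(
                gene_id=gene.id,
                l=l,
                heptamer=m.group(1),
                rel_pos=l / L,
                spacer_ok=(L - (l + 6)) >= min_spacer,
            )
        )
    return sites


def frameshift(gene: Gene, site: SlipperySite) -> SlipperySite:
    """Complete `site` with the -1-frame PTC distance and hybrid sequence.

    Reads -1-frame codons from position l (codon starts l, l+3, ...).  If a
    stop codon is found, ``lambda_nt`` is the distance from l to its last
    base and ``x_prime = seq[1..l] ++ seq[l..l+lambda_nt]``.  If no stop
    occurs before the sequence end, ``ptc_found=False`` and the hybrid is
    built to the sequence end (lambda_nt = length_nt - l).
    """
    if site.gene_id != gene.id:
        raise SequenceError(f"site gene {site.gene_id!r} does not match gene {gene.id!r}")
    if gene.seq[site.l - 1 : site.l + 6] != site.heptamer:
        raise SequenceError(f"gene {gene.id!r}: heptamer mismatch at l={site.l}")
    seq = gene.seq
    L = gene.length_nt
    lam: Optional[int] = None
    # -1-frame codons start at 0-based offsets l-1, l+2, l+5, ...
    for start in range(site.l - 1, L - 2, 3):
        codon = seq[start : start + 3]
        if codon in STOP_CODONS:
            lam = (start + 3) - site.l  # 1-based last stop base minus l
            break
    if lam is not None:
        x_prime = seq[: site.l] + seq[site.l - 1 : site.l - 1 + lam + 1]
        return replace(site, lambda_nt=lam, ptc_found=True, x_prime=x_prime)
    x_prime = seq[: site.l] + seq[site.l - 1 :]
    return replace(site, lambda_nt=L - site.l, ptc_found=False, x_prime=x_prime)


def scan_and_frameshift(
    genes: Sequence[Gene],
    min_spacer: int = 8,
    frame_constrained: bool = True,
) -> list[SlipperySite]:
    """Scan every gene and complete every site; sites in gene order, 5'->3'."""
    out: list[SlipperySite] = []
    for g in genes:
        for s in scan_slippery_sites(g, min_spacer, frame_constrained):
            out.append(frameshift(g, s))
    return out


def select_primary_site(
    sites: Iterable[SlipperySite],
    selector: str = "five_prime",
) -> dict[str, SlipperySite]:
    """One site per gene for the corrections: default the 5'-most (smallest l).

    ``selector="max_r"`` is approximated by the largest l + lambda (the
    R numerator at fixed pi and L), flagged experimental.
    """
    chosen: dict[str, SlipperySite] = {}
    for s in sites:
        cur = chosen.get(s.gene_id)
        if cur is None:
            chosen[s.gene_id] = s
        elif selector == "five_prime":
            if s.l < cur.l:
                chosen[s.gene_id] = s
        elif selector == "max_r":
            if (s.l + (s.lambda_nt or 0)) > (cur.l + (cur.lambda_nt or 0)):
                chosen[s.gene_id] = s
        else:
            raise ValueError(f"unknown selector {selector!r}")
    return chosen


# ---------------------------------------------------------------------------
# Tabular I/O

_SITE_COLUMNS = ["gene_id", "l", "heptamer", "rel_pos", "spacer_ok", "lambda_nt", "ptc_found"]


def sites_to_frame(sites: Iterable[SlipperySite]) -> pd.DataFrame:
    """Sites as a DataFrame (l is 1-based; x_prime omitted for compactness)."""
    rows = [
        (s.gene_id, s.l, s.heptamer, s.rel_pos, s.spacer_ok, s.lambda_nt, s.ptc_found)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


def sites_to_tsv(sites: Iterable[SlipperySite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def sites_from_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SITE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise SequenceError(f"{path}: missing site columns {sorted(missing)}")
    return df


def sites_to_bed(sites: Iterable[SlipperySite], path: str | Path) -> None:
    """BED export of heptamer intervals (0-based half-open, per BED convention)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.gene_id}\t{s.l - 1}\t{s.l + 6}\t{s.heptamer}\n")
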