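"""Corrections of codon usage bias indices for -1 PRF signals.

Two corrections for an index I of a gene x carrying a slippery site at
position l with shifted-frame PTC distance lambda, gene length L (nt),
-1 PRF efficiency p and per-event NMD cost pi (nt-equivalents):

* Translation-efficiency lower bound.  The extra energy spent translating
  the hybrid x' relative to x is approximated by

      R(x, x') = ((l + lambda + pi) / L) * (p / (1 - p)),

  giving the corrected lower bound

      Ic^ = (1 + R)^(-1) * I(x).

* Averaging.  The expected index over productive and frameshifted
  translation events:

      Ia = (1 - p) * I(x) + p * I(x'),

  where I(x') is the index of the hybrid sequence; Ia is well defined at
  p = 1, unlike Ic^.

In the expression-dependent mode the efficiency declines with protein
abundance P as p(P) = pb / log10(P) (clamped to [0, p_cap]); substituting
p(P) into the formulas above yields the expression-dependent variants.

Both corrections operate on the positive (exponential) CAI scale, since
the multiplicative factor of Ic^ and the convex combination of Ia
presuppose a ratio-scale index; the log form of each index is emitted
alongside.  Default pi = 0, a conservative choice for the NMD cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .cub_index import AdaptivenessTable, cai, cai_of_sequence
from .prf_signal import SlipperySite, select_primary_site
from .sequence_core import Gene, SequenceError


@dataclass(frozen=True)
class CorrectionParams:
    """Efficiency / cost parameters for the corrections.

    `p` is the uniform -1 PRF efficiency; `pb` the baseline efficiency of
    the expression-dependent model p(P) = pb / log10(P); `pi` the per-event
    NMD cost in nucleotide-equivalents; `p_cap` clamps derived p(P).
    """

    p: float = 0.0
    pb: float = 0.0
    pi: float = 0.0
    mode: Literal["uniform", "expression_dependent"] = "uniform"
    p_cap: float = 0.99

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "expression_dependent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.pb < 0:
            raise ValueError("pb must be nonnegative")
        if self.pi < 0:
            raise ValueError("pi must be nonnegative")
        if not 0.0 < self.p_cap < 1.0:
            raise ValueError("p_cap must lie in (0, 1)")


@dataclass(frozen=True)
class CorrectedIndex:
    """Raw and corrected index values for one gene."""

    gene_id: str
    i_raw: float
    i_c_hat: Optional[float]
    i_a: Optional[float]
    i_xprime: Optional[float]
    p_used: float
    r_ratio: Optional[float]
    ptc_found: bool = True
    p_clamped: bool = False


def energy_ratio(l: int, lambda_nt: int, pi: float, L: int, p: float) -> float:
    """R(x, x') = ((l + lambda + pi) / L) * (p / (1 - p)).

    The relative energy overhead of frameshifted translation.  Undefined at
    p = 1 (use the averaging correction there).
    """
    if L <= 0:
        raise SequenceError("L must be positive")
    if not 0 < l <= L:
        raise SequenceError(f"l={l} out of range 1..{L}")
    if lambda_nt < 0:
        raise SequenceError("lambda_nt must be nonnegative")
    if not 0.0 <= p < 1.0:
        raise SequenceError("energy_ratio requires 0 <= p < 1")
    return (l + lambda_nt + pi) / L * (p / (1.0 - p))


def ic_hat(i_raw: float, R: float) -> float:
    """Lower-bound corrected index Ic^ = (1 + R)^(-1) * I(x)."""
    if R < 0:
        raise SequenceError("R must be nonnegative")
    return i_raw / (1.0 + R)


def i_a(i_raw: float, i_xprime: float, p: float) -> float:
    """Averaged corrected index Ia = (1 - p) I(x) + p I(x')."""
    if not 0.0 <= p <= 1.0:
        raise SequenceError("p must lie in [0, 1]")
    return (1.0 - p) * i_raw + p * i_xprime


def p_of_expression(P: float, pb: float, p_cap: float = 0.99) -> tuple[float, bool]:
    """Expression-dependent efficiency p(P) = pb / log10(P), clamped.

    Returns ``(p, clamped)``.  Genes with P <= 10 (log10(P) <= 1) receive
    the clamp whenever the raw value exceeds it, flagged in the second
    element.
    """
    if P <= 0:
        raise SequenceError("protein_per_cell must be positive")
    if pb < 0:
        raise SequenceError("pb must be nonnegative")
    log10P = math.log10(P)
    if log10P <= 0:
        return p_cap, True
    raw = pb / log10P
    if raw > p_cap:
        return p_cap, True
    if raw < 0:
        return 0.0, True
    return raw, False


def _strip_terminal_stop(x_prime: str) -> str:
    """Drop the trailing PTC so the hybrid index scores sense codons only.

    Stop codons are skipped during scoring anyway; this keeps the hybrid's
    codon count consistent with its translated portion.
    """
    return x_prime[:-3] if len(x_prime) >= 3 else x_prime


def correct_gene(
    gene: Gene,
    site: SlipperySite,
    table: AdaptivenessTable,
    params: CorrectionParams,
    P: Optional[float] = None,
) -> CorrectedIndex:
    """Both corrections for one gene with one (completed) slippery site.

    In uniform mode p = params.p; with p = 1, Ic^ is omitted (None) and Ia
    is still computed.  In expression-dependent mode p = p(P) requires the
    gene's protein abundance P.
    """
    if not site.completed:
        raise SequenceError(f"site at l={site.l} of {gene.id!r} not completed (no lambda)")
    if params.mode == "expression_dependent":
        if P is None:
            raise SequenceError("expression-dependent mode requires protein abundance P")
        p_used, clamped = p_of_expression(P, params.pb, params.p_cap)
    else:
        p_used, clamped = params.p, False

    i_raw = cai(gene, table).cai
    xp = _strip_terminal_stop(site.x_prime) if site.ptc_found else site.x_prime
    i_xp = cai_of_sequence(xp, table, gene_id=f"{gene.id}:xprime").cai

    if p_used < 1.0:
        R = energy_ratio(site.l, site.lambda_nt, params.pi, gene.length_nt, p_used)
        ic = ic_hat(i_raw, R)
    else:
        R, ic = None, None
    ia = i_a(i_raw, i_xp, p_used)

    return CorrectedIndex(
        gene_id=gene.id,
        i_raw=i_raw,
        i_c_hat=ic,
        i_a=ia,
        i_xprime=i_xp,
        p_used=p_used,
        r_ratio=R,
        ptc_found=bool(site.ptc_found),
        p_clamped=clamped,
    )


def correct_genes(
    genes: Sequence[Gene],
    sites: Iterable[SlipperySite],
    table: AdaptivenessTable,
    params: CorrectionParams,
    expression: Optional[Mapping[str, float]] = None,
    selector: str = "five_prime",
    require_ptc: bool = True,
    require_spacer: bool = True,
) -> list[CorrectedIndex]:
    """Corrections for every gene possessing a usable slippery site.

    Multi-site genes contribute via one site chosen by `selector`
    (default 5'-most).  Sites failing the spacer rule and, by default,
    sites whose shifted frame reaches the sequence end without a PTC are
    excluded.
    """
    usable = [
        s
        for s in sites
        if s.completed and (s.spacer_ok or not require_spacer) and (s.ptc_found or not require_ptc)
    ]
    primary = select_primary_site(usable, selector=selector)
    by_id = {g.id: g for g in genes}
    out: list[CorrectedIndex] = []
    for gene_id, site in primary.items():
        gene = by_id.get(gene_id)
        if gene is None:
            continue
        P = expression.get(gene_id) if expression is not None else None
        if params.mode == "expression_dependent" and P is None:
            continue
        out.append(correct_gene(gene, site, table, params, P=P))
    return out


def corrected_to_frame(values: Iterable[CorrectedIndex]) -> pd.DataFrame:
    """Long table: gene_id, i_raw, i_xprime, p_used, r_ratio, i_c_hat, i_a."""
    rows = [
        (v.gene_id, v.i_raw, v.i_xprime, v.p_used, v.r_ratio, v.i_c_hat, v.i_a, v.ptc_found)
        for v in values
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "i_raw", "i_xprime", "p_used", "r_ratio", "i_c_hat", "i_a", "ptc_found"],
    )
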