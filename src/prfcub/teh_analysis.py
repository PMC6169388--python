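"""Hypothesis tests for the cost of -1 PRF maintenance and the
corrected-index vs protein-expression correlation sweep.

Three hypotheses, each a signature of an intrinsic maintenance cost of
-1 PRF signals under the translation efficiency hypothesis (TEH):

* H1 — slippery sites become rarer with translation demand: per-gene,
  per-nucleotide site density declines with log10(protein / mRNA).
* H2 — sites sit 5' of the midpoint: the mean relative position l/L is
  below 0.5, the no-selection expectation.
* H3 — the 5' skew strengthens with expression: mean l/L declines with
  log10(protein per cell), summarized in 20 equal-log-width bins with
  +-1.96 SEM.

The sweep recomputes the Pearson and Spearman correlation between each
corrected index (Ic^, Ia, on the positive CAI scale) and log10 P over a
grid of (p, pi) — or (pb, pi) in the expression-dependent mode — using
only genes that possess a completed slippery site.  In the default grid
the averaging correction is evaluated at p = 1 in place of p = 0.9,
where it remains well defined and Ic^ does not.

Raw p-values are reported; no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corrections import CorrectionParams, correct_genes, corrected_to_frame
from .cub_index import AdaptivenessTable
from .prf_signal import SlipperySite
from .sequence_core import ExpressionRecord, Gene, SequenceError

DEFAULT_P_GRID: tuple[float, ...] = (0.01, 0.05, 0.1, 0.3, 0.5, 0.9)
DEFAULT_PI_GRID: tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass(frozen=True)
class AssociationResult:
    """Correlation / regression summary on stated axes."""

    n: int
    pearson_r: float
    spearman_r: float
    slope: float
    slope_p: float
    corr_p: float
    intercept: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class BinnedTrend:
    """Binned means with uncertainty over equal-width log10-expression bins.

    Bins with n < 2 have NaN sem/ci and are flagged in `low_n`; empty bins
    have NaN means.
    """

    bin_edges: np.ndarray
    bin_means: np.ndarray
    bin_sem: np.ndarray
    bin_n: np.ndarray
    ci_halfwidth: np.ndarray
    low_n: np.ndarray


def associate(x: np.ndarray, y: np.ndarray) -> AssociationResult:
    """Pearson + Spearman + OLS slope of y on x with their p-values.

    Zero-variance input yields a degenerate result (NaN statistics,
    flagged) rather than NaN propagation from the underlying routines.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise SequenceError(f"need >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = float("nan")
        return AssociationResult(n, nan, nan, nan, nan, nan, degenerate=True)
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    ols = stats.linregress(x, y)
    return AssociationResult(
        n=n,
        pearson_r=float(pearson.statistic),
        spearman_r=float(spearman.statistic),
        slope=float(ols.slope),
        slope_p=float(ols.pvalue),
        corr_p=float(spearman.pvalue),
        intercept=float(ols.intercept),
    )


def _expression_map(expression: Iterable[ExpressionRecord]) -> dict[str, ExpressionRecord]:
    return {r.gene_id: r for r in expression}


def _usable_sites(sites: Iterable[SlipperySite], require_spacer: bool = True) -> list[SlipperySite]:
    return [s for s in sites if s.spacer_ok or not require_spacer]


# ---------------------------------------------------------------------------
# H1: site density vs translation demand


@dataclass(frozen=True)
class SiteDensityResult:
    association: AssociationResult
    mean_sites_per_gene: float
    densities: np.ndarray
    predictor: np.ndarray


def h1_site_density(
    genes: Sequence[Gene],
    sites: Iterable[SlipperySite],
    expression: Iterable[ExpressionRecord],
) -> SiteDensityResult:
    """Per-gene, per-nucleotide slippery-site density vs log10(P / mRNA).

    Genes without sites count as zero sites; only genes with both protein
    and mRNA levels enter.  Also reports the global mean sites-per-gene.
    """
    expr = _expression_map(expression)
    counts: dict[str, int] = {g.id: 0 for g in genes}
    for s in _usable_sites(sites):
        if s.gene_id in counts:
            counts[s.gene_id] += 1
    dens, pred, n_sites = [], [], []
    for g in genes:
        rec = expr.get(g.id)
        if rec is None or rec.mrna_per_cell is None or rec.mrna_per_cell <= 0:
            continue
        dens.append(counts[g.id] / g.length_nt)
        pred.append(math.log10(rec.protein_per_cell / rec.mrna_per_cell))
        n_sites.append(counts[g.id])
    if len(dens) < 3:
        raise SequenceError("fewer than 3 genes with protein and mRNA levels")
    return SiteDensityResult(
        association=associate(np.array(pred), np.array(dens)),
        mean_sites_per_gene=float(np.mean(n_sites)),
        densities=np.array(dens),
        predictor=np.array(pred),
    )


# ---------------------------------------------------------------------------
# H2: 5' skew of relative site positions


@dataclass(frozen=True)
class PositionSkewResult:
    n: int
    mean_rel_pos: float
    sem: float
    ci_low: float
    ci_high: float
    ci_excludes_half: bool
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def h2_position_skew(
    sites: Iterable[SlipperySite],
    n_bins: int = 20,
) -> PositionSkewResult:
    """Mean relative position l/L with normal 95% CI and histogram on [0, 1].

    A CI upper bound below 0.5 indicates the 5' skew expected under a
    maintenance cost; sites failing the spacer rule are excluded.
    """
    rel = np.array([s.rel_pos for s in _usable_sites(sites)], dtype=float)
    if len(rel) < 3:
        raise SequenceError(f"need >= 3 sites, got {len(rel)}")
    mean = float(np.mean(rel))
    sem = float(np.std(rel, ddof=1) / math.sqrt(len(rel)))
    half = 1.96 * sem
    counts, edges = np.histogram(rel, bins=n_bins, range=(0.0, 1.0))
    return PositionSkewResult(
        n=len(rel),
        mean_rel_pos=mean,
        sem=sem,
        ci_low=mean - half,
        ci_high=mean + half,
        ci_excludes_half=(mean + half) < 0.5,
        hist_counts=counts,
        hist_edges=edges,
    )


# ---------------------------------------------------------------------------
# H3: relative position vs expression


def binned_trend(x: np.ndarray, y: np.ndarray, n_bins: int = 20) -> BinnedTrend:
    """Mean of y in `n_bins` equal-width bins over the observed range of x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    sems = np.full(n_bins, np.nan)
    ns = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        vals = y[idx == b]
        ns[b] = len(vals)
        if len(vals) >= 1:
            means[b] = np.mean(vals)
        if len(vals) >= 2:
            sems[b] = np.std(vals, ddof=1) / math.sqrt(len(vals))
    return BinnedTrend(
        bin_edges=edges,
        bin_means=means,
        bin_sem=sems,
        bin_n=ns,
        ci_halfwidth=1.96 * sems,
        low_n=ns < 2,
    )


def h3_position_vs_expression(
    sites: Iterable[SlipperySite],
    expression: Iterable[ExpressionRecord],
    n_bins: int = 20,
) -> tuple[AssociationResult, BinnedTrend]:
    """Relative site position l/L regressed on log10(protein per cell).

    All spacer-passing sites of a gene contribute; binned means use 20
    equal-width bins in log10 expression with +-1.96 SEM.
    """
    expr = _expression_map(expression)
    xs, ys = [], []
    for s in _usable_sites(sites):
        rec = expr.get(s.gene_id)
        if rec is None:
            continue
        xs.append(math.log10(rec.protein_per_cell))
        ys.append(s.rel_pos)
    if len(xs) < 3:
        raise SequenceError("fewer than 3 sites with expression")
    x = np.array(xs)
    y = np.array(ys)
    return associate(x, y), binned_trend(x, y, n_bins=n_bins)


# ---------------------------------------------------------------------------
# Correlation sweep (corrected index vs protein expression)


def correlation_sweep(
    genes: Sequence[Gene],
    sites: Sequence[SlipperySite],
    table: AdaptivenessTable,
    expression: Iterable[ExpressionRecord],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    pi_grid: Sequence[float] = DEFAULT_PI_GRID,
    mode: Literal["uniform", "expression_dependent"] = "uniform",
    ia_p_one_at: Optional[float] = 0.9,
) -> pd.DataFrame:
    """Correlations of Ic^ and Ia with log10 P over the (p, pi) grid.

    Only genes with a completed, spacer-passing, PTC-bearing site and
    known expression enter; n is constant across cells within a mode.
    Returns a long-format frame: mode, p_or_pb, pi, index_kind, n,
    pearson_r, pearson_p, spearman_r, spearman_p.  For the averaging
    correction the grid value `ia_p_one_at` is evaluated at p = 1
    (where Ia is still defined); pi does not enter Ia, so its Ia rows
    are computed at pi = pi_grid[0] only.
    """
    expr = {r.gene_id: r.protein_per_cell for r in _expression_map(expression).values()}
    if not genes:
        raise SequenceError("empty gene set")

    rows: list[dict] = []
    for p_val in p_grid:
        for pi_val in pi_grid:
            params = _make_params(mode, p_val, pi_val)
            corrected = correct_genes(genes, sites, table, params, expression=expr)
            df = corrected_to_frame(corrected)
            df = df[df["gene_id"].isin(expr)]
            logP = np.log10([expr[g] for g in df["gene_id"]])
            for kind in ("i_c_hat", "i_a"):
                if kind == "i_a":
                    if pi_val != pi_grid[0]:
                        continue  # pi does not enter Ia
                    p_eff = 1.0 if (ia_p_one_at is not None and p_val == ia_p_one_at) else p_val
                    if p_eff != p_val:
                        params2 = _make_params(mode, p_eff, pi_val)
                        corrected2 = correct_genes(genes, sites, table, params2, expression=expr)
                        df2 = corrected_to_frame(corrected2)
                        df2 = df2[df2["gene_id"].isin(expr)]
                        vals = df2[kind].to_numpy(dtype=float)
                        logP_k = np.log10([expr[g] for g in df2["gene_id"]])
                    else:
                        vals = df[kind].to_numpy(dtype=float)
                        logP_k = logP
                    p_report = p_eff
                else:
                    if mode == "uniform" and p_val >= 1.0:
                        continue  # Ic^ undefined at p = 1
                    vals = df[kind].to_numpy(dtype=float)
                    logP_k = logP
                    p_report = p_val
                finite = np.isfinite(vals)
                if finite.sum() < 3:
                    continue
                res = associate(logP_k[finite], vals[finite])
                rows.append(
                    {
                        "mode": mode,
                        "p_or_pb": p_report,
                        "pi": pi_val,
                        "index_kind": kind,
                        "n": res.n,
                        "pearson_r": res.pearson_r,
                        "pearson_p": _pearson_p(logP_k[finite], vals[finite]),
                        "spearman_r": res.spearman_r,
                        "spearman_p": res.corr_p,
                    }
                )
    return pd.DataFrame(rows)


def _make_params(mode: str, p_val: float, pi_val: float) -> CorrectionParams:
    if mode == "uniform":
        return CorrectionParams(p=p_val, pi=pi_val, mode="uniform")
    return CorrectionParams(pb=p_val, pi=pi_val, mode="expression_dependent")


def _pearson_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).pvalue)


def uncorrected_association(
    genes: Sequence[Gene],
    sites: Sequence[SlipperySite],
    table: AdaptivenessTable,
    expression: Iterable[ExpressionRecord],
) -> AssociationResult:
    """Uncorrected CAI vs log10 P on the site-bearing gene set (p = 0 limit)."""
    params = CorrectionParams(p=0.0, mode="uniform")
    expr = {r.gene_id: r.protein_per_cell for r in _expression_map(expression).values()}
    corrected = correct_genes(genes, sites, table, params, expression=expr)
    df = corrected_to_frame(corrected)
    df = df[df["gene_id"].isin(expr)]
    logP = np.log10([expr[g] for g in df["gene_id"]])
    return associate(logP, df["i_raw"].to_numpy(dtype=float))
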