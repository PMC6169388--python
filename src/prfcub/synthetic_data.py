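"""Synthetic genomes with planted -1 PRF signals and expression structure.

The generator emulates the statistical structure of a yeast-like coding
genome joined to a curated expression table:

* gene lengths are lognormal (in codons) and expression is lognormal
  (log10 protein molecules per cell, normal within a stated range);
* codon usage is biased toward a "ribosomal-like" reference profile, with
  the mixture weight increasing in standardized log10 expression — this
  plants the CUB-expression association at the heart of the translation
  efficiency hypothesis;
* each gene carries a Poisson number of slippery sites whose rate is
  log-linear in log10 expression (negative slope plants the H1 signal);
* site positions l/L follow a Beta law (a < b plants the 5' skew of H2)
  whose mean is shifted per expression decade (negative shift plants H3);
* every planted site is a legal heptamer snapped to a frame-0-compatible
  position (l % 3 == 0, ties toward 5'), with >= 8 nt of downstream
  spacer, and a -1-frame stop codon is spliced downstream when none
  occurs naturally.

Amino-acid sequences are drawn uniformly over the 20 amino acids before
codon assignment, isolating codon-level bias from composition effects.
mRNA levels are generated as a noisy power law of protein abundance, so
the protein-per-mRNA ratio used by the H1 test increases with expression.
Background (unplanted) heptamer matches are left in place; truth-based
evaluation therefore compares positions, not counts.

Same config and seed produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cub_index import AA_TO_CODONS, build_reference
from .prf_signal import LEGAL_HEPTAMERS, STOP_CODONS
from .sequence_core import ExpressionRecord, Gene, write_expression, write_fasta

_AA_LIST = tuple(sorted(AA_TO_CODONS))
_MIN_SPACER = 8


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic genome; defaults are the study conditions."""

    n_genes: int = 2000
    seed: int = 1
    # lognormal gene length, natural-log scale, in codons (median ~400)
    len_log_mean: float = 6.0
    len_log_sd: float = 0.35
    # log10 protein molecules per cell, normal clipped to this range
    expr_log10_range: tuple[float, float] = (0.0, 5.0)
    # codon-bias mixture weight w = clamp(bias_base + bias_slope * z), z standardized
    bias_base: float = 0.5
    bias_slope: float = 0.18
    # per-gene Poisson site rate = site_rate_base * exp(site_rate_slope * d), d in decades
    site_rate_base: float = 0.5
    site_rate_slope: float = -0.4
    # Beta(a, b) relative positions; mean shifted by pos_slope per decade
    pos_beta_a: float = 2.0
    pos_beta_b: float = 4.0
    pos_slope: float = -0.05
    # mRNA model: mrna = P^mrna_exponent * 10^N(0, mrna_log10_sd)
    mrna_exponent: float = 0.7
    mrna_log10_sd: float = 0.2
    # reference set emitted alongside the genome
    n_ref_genes: int = 60
    ref_len_codons: int = 300
    ref_bias: float = 0.95


def default_config(seed: int = 1, n_genes: int = 2000) -> GeneratorConfig:
    """The default study conditions: all three cost signals planted."""
    return GeneratorConfig(n_genes=n_genes, seed=seed)


def null_config(seed: int = 1, n_genes: int = 500) -> GeneratorConfig:
    """Negative control: no H1-H3 signal, symmetric positions, flat bias."""
    return GeneratorConfig(
        n_genes=n_genes,
        seed=seed,
        bias_slope=0.0,
        site_rate_slope=0.0,
        pos_beta_a=2.0,
        pos_beta_b=2.0,
        pos_slope=0.0,
    )


@dataclass
class SyntheticDataset:
    """Generator output: genome, reference set, expression and ground truth."""

    genes: list[Gene]
    reference: list[Gene]
    expression: list[ExpressionRecord]
    truth: pd.DataFrame  # gene_id, l, heptamer, lambda_nt, stop_spliced
    config: GeneratorConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": out / "genes.fa",
            "reference": out / "reference.fa",
            "expression": out / "expression.tsv",
            "truth": out / "truth_sites.tsv",
            "config": out / "config.json",
        }
        write_fasta(self.genes, paths["genes"])
        write_fasta(self.reference, paths["reference"])
        write_expression(self.expression, paths["expression"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _reference_profile(rng: np.random.Generator, decay: float = 0.35) -> dict[str, np.ndarray]:
    """Per-family codon frequencies of the ribosomal-like reference.

    Each family gets geometric weights decay^k permuted at random, so one
    codon dominates — the generator's notion of a preferred codon.
    """
    profile: dict[str, np.ndarray] = {}
    for aa in _AA_LIST:
        k = len(AA_TO_CODONS[aa])
        w = decay ** np.arange(k)
        rng.shuffle(w)
        profile[aa] = w / w.sum()
    return profile


def _draw_codon_seq(
    rng: np.random.Generator,
    n_codons: int,
    profile: dict[str, np.ndarray],
    w: float,
) -> list[str]:
    """Codon string for `n_codons` uniform amino acids under mixture weight w."""
    aa_idx = rng.integers(0, len(_AA_LIST), size=n_codons)
    out = [""] * n_codons
    for a, aa in enumerate(_AA_LIST):
        positions = np.nonzero(aa_idx == a)[0]
        if len(positions) == 0:
            continue
        fam = AA_TO_CODONS[aa]
        probs = w * profile[aa] + (1.0 - w) / len(fam)
        probs = probs / probs.sum()
        picks = rng.choice(len(fam), size=len(positions), p=probs)
        for pos, pick in zip(positions, picks):
            out[pos] = fam[pick]
    return out


def _first_minus1_stop(seq: str, l: int) -> Optional[int]:
    """lambda for the -1 frame from 1-based l (codon starts l, l+3, ...)."""
    for start in range(l - 1, len(seq) - 2, 3):
        if seq[start : start + 3] in STOP_CODONS:
            return (start + 3) - l
    return None


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset under `config` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    profile = _reference_profile(rng)

    # --- reference set (high-bias draws; ribosomal-like) -------------------
    reference = [
        Gene(
            id=f"ref{i+1:03d}",
            seq="".join(_draw_codon_seq(rng, config.ref_len_codons, profile, config.ref_bias))
            + "TAA",
        )
        for i in range(config.n_ref_genes)
    ]

    lo, hi = config.expr_log10_range
    mid = 0.5 * (lo + hi)
    spread = max(hi - lo, 1e-9) / 4.0  # nominal sd: range covers ~4 sd

    genes: list[Gene] = []
    expr: list[ExpressionRecord] = []
    truth_rows: list[dict] = []

    for i in range(config.n_genes):
        gene_id = f"g{i+1:05d}"
        # expression and its standardized / decade forms
        log10P = float(np.clip(rng.normal(mid, spread), lo, hi))
        d = log10P - mid
        z = d / spread
        P = 10.0 ** log10P
        log10m = config.mrna_exponent * log10P + rng.normal(0.0, config.mrna_log10_sd)
        mrna = 10.0 ** log10m

        # body of sense codons + terminal stop
        n_codons = max(50, int(round(float(rng.lognormal(config.len_log_mean, config.len_log_sd)))))
        w = float(np.clip(config.bias_base + config.bias_slope * z, 0.0, 1.0))
        body = _draw_codon_seq(rng, n_codons, profile, w)
        seq = bytearray(("".join(body) + "TAA").encode())
        L_nt = len(seq)

        # --- plant slippery sites ------------------------------------------
        rate = max(config.site_rate_base * float(np.exp(config.site_rate_slope * d)), 0.0)
        n_sites = int(rng.poisson(rate))
        planted: list[dict] = []
        occupied: list[tuple[int, int]] = []  # 0-based [start, end) heptamer intervals
        for _ in range(n_sites):
            mean_shift = config.pos_slope * d
            rel = float(rng.beta(config.pos_beta_a, config.pos_beta_b)) + mean_shift
            rel = float(np.clip(rel, 1e-6, 1.0))
            # snap to l % 3 == 0 (1-based), ties toward 5'
            l = 3 * int(np.floor(rel * L_nt / 3.0 + 0.5))
            l_max = 3 * ((L_nt - 6 - _MIN_SPACER) // 3)
            l = min(max(l, 3), l_max)
            if l < 3 or l > l_max:
                truth_rows.append(
                    {"gene_id": gene_id, "l": -1, "heptamer": "", "lambda_nt": -1,
                     "stop_spliced": False, "note": "dropped:no_valid_position"}
                )
                continue
            if any(l - 1 < e and l + 6 > s for s, e in occupied):
                truth_rows.append(
                    {"gene_id": gene_id, "l": -1, "heptamer": "", "lambda_nt": -1,
                     "stop_spliced": False, "note": "dropped:overlap"}
                )
                continue
            heptamer = LEGAL_HEPTAMERS[int(rng.integers(0, len(LEGAL_HEPTAMERS)))]
            seq[l - 1 : l + 6] = heptamer.encode()
            occupied.append((l - 1, l + 6))
            planted.append({"gene_id": gene_id, "l": l, "heptamer": heptamer})

        # --- ensure a -1-frame stop downstream of each planted site --------
        final = seq.decode()
        for site in planted:
            l = site["l"]
            lam = _first_minus1_stop(final, l)
            spliced = False
            if lam is None:
                k_max = (L_nt - l - 2) // 3
                candidates = [k for k in range(2, k_max + 1)]
                rng.shuffle(candidates)
                for k in candidates:
                    start = l - 1 + 3 * k  # 0-based splice start
                    if any(start < e and start + 3 > s for s, e in occupied):
                        continue
                    seq[start : start + 3] = b"TAA"
                    spliced = True
                    break
                final = seq.decode()
                lam = _first_minus1_stop(final, l)
            site["lambda_nt"] = -1 if lam is None else lam
            site["stop_spliced"] = spliced
            site["note"] = "" if lam is not None else "no_stop_placed"
        # splices may shorten an earlier site's lambda: recompute all
        final = seq.decode()
        for site in planted:
            lam = _first_minus1_stop(final, site["l"])
            site["lambda_nt"] = -1 if lam is None else lam
            truth_rows.append(site)

        genes.append(Gene(id=gene_id, seq=final))
        expr.append(ExpressionRecord(gene_id=gene_id, protein_per_cell=P, mrna_per_cell=mrna))

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "l", "heptamer", "lambda_nt", "stop_spliced", "note"],
    )
    return SyntheticDataset(
        genes=genes, reference=reference, expression=expr, truth=truth, config=config
    )


def reference_table(dataset: SyntheticDataset, pseudocount: float = 0.5):
    """Adaptiveness table learned from the dataset's own reference set."""
    return build_reference(dataset.reference, pseudocount=pseudocount)
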