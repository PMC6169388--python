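# Methods

## Scope and model

`prfcub` treats a gene as a CDS-level nucleotide string (no genome
coordinates, no UTRs); coordinates are 1-based inclusive everywhere
except BED export (0-based half-open). The internal alphabet is DNA;
RNA input is mapped U→T on read. Ambiguity codes are rejected rather
than skipped, because every downstream count assumes unambiguous
codons. The genetic code is fixed to the standard nuclear code with
stop set {TAA, TAG, TGA}; alternative codes are out of scope (the
intended organisms are yeast-like nuclear genes).

## Codon adaptation index

Relative adaptiveness is frequency over the *family sum*,
ω_ac = o_ac / Σ o_ac′, not the classical frequency-over-family-maximum;
the classical variant is available as `omega_mode="max"` for
comparison. The reference is the concatenation of a ribosomal(-like)
gene set; a pseudocount (default 0.5 per sense codon, added before
normalization) guarantees ln ω is finite for codons absent from the
reference. The gene-level index is the mean of ln ω over scored codons;
the normalizer is the number of codons actually scored (sense codons in
frame 0), not raw length/3, so the index is a true mean over
contributing terms — stop codons and a trailing partial codon are
excluded from both numerator and denominator. Single-codon families
(ATG, TGG) contribute ln 1 = 0 under the sum convention and are kept
for count bookkeeping. Because the mean-of-logs form is non-positive,
the package emits both `log_cai` (≤ 0) and `cai = exp(log_cai)` ∈
(0, 1]; exp is monotone, so rankings and rank correlations are
unaffected by the choice of scale.

## Slippery sites and the frameshifted hybrid

The heptamer grammar is three identical X (any base), three identical
Y ∈ {A, T}, Z ∈ {A, C, T} — 24 legal heptamers. Detection is
frame-constrained by default (heptamer start l with l ≡ 0 mod 3, so
the in-frame codons read XXY | YYZ and the lone X is the last base of
the preceding codon); a flag disables the constraint for exploratory
scans. Overlapping matches are all reported. With secondary-structure
prediction out of scope, the spacer rule is operationalized as
"≥ `min_spacer` (default 8) nt exist downstream of the heptamer";
spacer-failing sites are returned flagged and excluded from analyses
by default, and externally computed structure annotations can filter
further.

The slip convention: the ribosome re-reads the base at l (codons
XXY YYZ → XXX YYY), so the hybrid duplicates one nucleotide:
x′ = x[1..l] ++ x[l..l+λ], with λ measured from l to the last base of
the first −1-frame stop. Then |x′| = l + λ + 1 ≡ 0 (mod 3) and l + λ
approximates the translated stretch whose energy is wasted per slip.
If no −1-frame stop exists before the sequence end, the site is
completed with λ = L − l and flagged `ptc_found=False`; such sites are
excluded from the correction analyses by default. When a gene carries
several sites, the corrections use the 5′-most site by default
(`selector="five_prime"`); a max-overhead selector exists but is
experimental. The hybrid's index is computed in frame 0 of x′ with its
terminal PTC stripped (stops are skipped during scoring regardless).

## Corrections

The energy-overhead ratio R = ((l + λ + π)/L) · (p/(1 − p)) with π the
per-event NMD cost in nucleotide-equivalents (default 0, a conservative
choice; π is assumed uniform across genes). The lower bound is
Î_c = (1 + R)^(−1) I(x) — undefined at p = 1, where only the averaging
correction I_a = (1 − p) I(x) + p I(x′) applies. Both operate on the
positive (exponential) CAI scale: the multiplicative factor of Î_c and
the convex combination of I_a presuppose a ratio-scale index; the log
form is emitted alongside for transparency.

Expression-dependent efficiency: p(P) = p_b / log₁₀(P), clamped to
[0, p_cap] (default cap 0.99); genes with P ≤ 10 whose raw value
exceeds the cap are clamped and flagged. The expression-dependent
corrections substitute p(P) directly into the two formulas above. (An
alternative printed linearization of the averaging form,
I(x) − (p_b − log₁₀ P)(I(x) − I(x′)), is inconsistent with that
substitution — it can leave [0, 1] — so the direct-substitution form is
used; it reproduces the fixed-p formula exactly when p(P) is constant.)

## Hypothesis tests and sweep

H1 regresses per-gene site density (spacer-passing sites per
nucleotide, genes without sites counted as zero) on
log₁₀(protein/mRNA); H2 reports the mean relative position l/L with a
normal-approximation 95% CI (mean ± 1.96 · sem) and a histogram; H3
regresses l/L on log₁₀ P, summarized in 20 equal-width bins of the
observed log₁₀ range with ±1.96 sem, low-occupancy bins flagged rather
than fabricated. Genes contribute one observation to H1, all their
sites to H2/H3, and one corrected index (5′-most site) to the sweep.
Pearson on the log₁₀ expression axis is the headline statistic;
Spearman (average ranks for ties) is reported alongside, since it is
invariant to the log-vs-raw choice. Zero-variance inputs return a
flagged degenerate result instead of NaN propagation. Raw p-values; no
multiple-testing correction.

The sweep evaluates both corrections over p ∈ {0.01, 0.05, 0.1, 0.3,
0.5, 0.9} × π ∈ {0, 10, 100, 1000, 10000} (uniform mode) or the same
values as p_b (expression-dependent mode), on exactly the genes with a
completed, spacer-passing, PTC-bearing site and known expression — n is
conserved across cells within a mode. I_a does not depend on π and at
the 0.9 grid point is evaluated at p = 1, where it remains defined.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed
once. Per gene: length lognormal in codons (ln-mean 6.0, ln-sd 0.35,
median ≈ 400 codons, floor 50 — a yeast-like CDS length scale);
expression log₁₀ P normal at the center of [0, 5] decades with sd =
span/4, clipped to the range; mRNA = P^0.7 · 10^N(0, 0.2), so
protein-per-mRNA grows with expression. Amino acids are uniform over
the 20 (isolating codon-level bias from composition); codons are drawn
from w · (reference profile) + (1 − w) · (uniform in family) with
w = clamp(0.5 + 0.18 z), z the standardized log₁₀ expression — this
plants the CUB–expression association. The reference profile gives
each family geometric weights (ratio 0.35) in a seeded random order,
and the emitted reference set is 60 genes of 300 codons drawn at
w = 0.95, so no external reference is needed.

Site counts are Poisson with rate 0.5 · exp(−0.4 d), d the expression
offset in decades (negative slope plants H1, mean ≈ 0.55 sites/gene);
positions are Beta(2, 4) (mean 1/3, plants H2) shifted by −0.05 per
decade (plants H3), snapped to the nearest l ≡ 0 (mod 3) with ties
toward 5′ and confined so the heptamer keeps an 8-nt spacer. Planted
heptamers are sampled uniformly from the 24 legal ones; overlapping
placements are dropped with a truth-file note. If no −1-frame stop
occurs downstream of a planted site, a TAA is spliced at a random
−1-frame codon position that avoids every heptamer interval; truth-file
λ is recomputed from the final sequence, so it agrees with the
frameshift operation by construction. Background heptamer matches are
left in place — they are realistic scanner behavior — so truth-based
evaluation compares positions, not counts. The null configuration
zeroes all three slopes and uses symmetric Beta(2, 2) positions.

What the generator does **not** emulate: realistic yeast base/amino-acid
composition, tRNA pools, secondary structure (so the spacer is a length
rule only), NMD kinetics, or any dependence of the true slip efficiency
p on sequence — p is purely an analysis parameter. Passing tests
therefore show that the machinery recovers signals of the planted
statistical form at these sample sizes, not that real genomes contain
them.

## Numerical and design choices

* Problem sizes: the default genome is 2000 genes (the hypothesis-test
  and sweep analyses), the null calibration uses 20 seeds at 500 genes,
  and oracle-equivalence checks use 200 random genes (index) and 1000
  random sequences (scanner). Exact-arithmetic comparisons use a 1e−12
  absolute tolerance; the p → 0 sweep continuity check uses 1e−6 on
  correlation values.
* Determinism: one `numpy` PCG64 generator seeded from the config; the
  same config and seed give byte-identical output files.
* Degenerate inputs: genes with no scorable sense codon, empty
  references, fewer than 3 observations for any association, and
  zero-count families at zero pseudocount all raise typed errors;
  nonpositive expression rows are dropped with a logged count.

## Known limitations

Î_c inherits the lower-bound character of its derivation: downward
corrections can be exaggerated, and as p → 1 or π → ∞ it decays to 0
rather than to a floor index value. I_a can exceed I(x) when the hybrid
happens to score higher — the averaging construction permits it. The
spacer rule without structure prediction over-calls candidate sites
relative to a pseudoknot-filtered catalog; ingesting external structure
annotations is the supported remedy. Only the CAI is implemented as the
underlying index; the correction formulas accept any ratio-scale index
value but no other index is computed.
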