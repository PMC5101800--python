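# Methods

## Codon counting and frequency vectors

A CDS is read as consecutive triplets from a 5' offset of 0, +1 or +2
nucleotides; a trailing partial triplet is dropped, so a sequence of length
L shifted by k yields ⌊(L−k)/3⌋ triplets. Frequencies are defined over the
61 sense codons with denominator equal to the number of sense triplets:
stop triplets — which appear at CDS ends and are common in frameshifted
readings — are counted but excluded from the frequency vector. This keeps
frame-0 and frameshift-control analyses on the same 61-codon support; the
alternative denominator (all triplets including stops) differs by at most
one codon per gene in frame 0 and is not offered. The start codon is
counted like any other sense codon. Strict parsing requires triplet length
and no internal frame-0 stop; lenient parsing warns and keeps the record,
leaving dubious ORFs to upstream gene filters.

## tAI weights

Absolute adaptiveness of codon *i* is
W_i = Σ_j (1 − s_class(i,j)) · tGCN_j over the anticodons *j* able to
decode it, where tGCN is the genomic tRNA copy number (a proxy for tRNA
concentration). Each codon has one Watson–Crick reader and one wobble
reader determined by its third base (··U: G34, class G:U; ··C: A34 read as
inosine, I:C; ··A: A34, I:A; ··G: U34, U:G). AUG is reserved for the
elongator Met tRNA; an optional bacterial rule decodes AUA by
lysidine-modified CAU (L:A). Default penalties are the standard published
set — s(G:U)=0.41, s(I:C)=0.28, s(I:A)=0.9999, s(U:G)=0.68, s(L:A)=0.89 —
exposed as `WobblePenalties` and fully overridable; loading a published
per-codon weight table directly is the primary path and bypasses these
constants entirely. Relative weights are w_i = W_i / max W; codons with
W_i = 0 receive the geometric mean of the nonzero w values so that the
gene-level geometric mean remains defined.

Gene-level tAI_g is exp(Σ_c n_c ln w_c / Σ_c n_c) over the gene's sense
codons — the count-weighted geometric mean. Percent optimal codon content
is 100 × (optimal sense codons)/(sense codons). Binary cTE/nTE
classifications are *inputs*: they are never derived from a weight cutoff
here. A demand-normalised weight (nTE-style) is provided as a convenience:
codon demand d_i = Σ_g n_{g,i} m_g (abundance-weighted usage; a
transcript-frequency variant is selectable because the normalisation
convention differs between sources), both d and w/d rescaled to max 1.

## Steady-state kinetics

Units are minutes, molecules·cell⁻¹ and molecules·min⁻¹·cell⁻¹ throughout.
λ = ln2/hl and μ = m(α + λ); the "ln2" is the natural logarithm of 2, the
only reading for which λ·hl = ln 2 is dimensionally consistent. α is 0 for
transcription-shutoff datasets (growth halted) and ln2/ccl for labeling
datasets with a known cell-cycle length (150 min is the conventional
budding-yeast value in minimal medium). Relative abundances are scaled to
60,000 (S. cerevisiae) or 41,000 (S. pombe) total mRNAs per cell. Missing
inputs propagate to missing outputs; nothing is imputed. μ/m ≤ α is
non-physical under steady state and yields a missing half-life with a
warning. All downstream correlation statistics are rank-based, so
harmonisation (unit conversion, abundance scaling) cannot change them.

## Association statistics

Spearman correlations use average ranks and a two-sided p from the t
approximation on n−2 degrees of freedom (the default behaviour of standard
statistical software for tied data); exhaustive permutation is available
for n ≤ 9. CSC/CPC are these correlations applied per codon column against
half-life or synthesis rate with pairwise-complete deletion; codons with
constant frequency (e.g. absent everywhere) get missing entries and are
dropped, with the contingency support reduced accordingly.

The sign-partition test assigns exact zeros to the non-positive group (a
measure-zero event that must still be deterministic) and applies a
2×2 chi-square with Yates continuity correction, df = 1. Yates correction
is the default because it exactly reproduces the printed p-values of the
published summary tables from their marginals (the uncorrected statistic
is distinctly larger, e.g. ≈27.4 vs ≈24.7 on the (22,4,6,29) table); an
uncorrected mode is a flag. No multiple-testing correction is applied
across dataset rows, matching how such tables are conventionally reported.

First-order partial Spearman correlations rank-transform all three
variables and use
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) with a t statistic on
n−3 degrees of freedom. Perfectly correlated or constant controls are
errors, not NaNs.

**Calibration caveat.** Codon-level statistics (the CSC-vs-w correlation
and the sign-partition chi-square) treat the 61 codons as sampling units,
but the 61 coefficients share a single half-life vector and a
compositional constraint (frequencies sum to 1 within genes), so they are
mutually dependent and their nominal null distributions are overdispersed.
These statistics are meaningful comparatively (frame 0 vs frameshifts,
coupled vs uncoupled simulations) but their p-values should not be read as
calibrated under the null; the gene-level tests (tAI_g vs kinetics, genes
as independent units) are calibrated, and the null-uniformity checks in
the test suite use those.

Motif tests are one-sided Wilcoxon rank-sum comparisons
(normal approximation with tie and continuity corrections; exact method
for small samples) of motif-bearing (instance count ≥ 1) vs motif-free
genes within an explicit background set, with Bonferroni correction whose
family size m must be supplied (default: motifs × 2 directions per score
metric) because the appropriate family depends on how a motif table is
assembled. Near-identical motif variants can be merged by summing
instance counts before testing.

Cross-dataset comparison uses pairwise-complete Spearman matrices (gene
coverage differs per dataset, so listwise deletion would waste most
genes), five-number summaries with linear-interpolation quartiles, and
complete-linkage agglomerative clustering on Euclidean distances between
correlation-matrix rows (linkage configurable; clustering the displayed
correlation profiles rather than raw values matches how such heatmaps are
ordered).

## Synthetic data

Each gene gets a latent optimality score u_g ~ Uniform(0,1). Codons are
drawn within synonymous families with probability ∝ exp(tilt·u_g·w_c), so
amino-acid composition is identical in expectation across genes and only
synonymous choice carries signal — the exact contrast the codon statistics
are meant to isolate. Emitted CDSs are strict-valid ORFs (ATG + body +
TAA). Kinetics are log-normal around a 20-min half-life and
0.5 molecules·min⁻¹·cell⁻¹ synthesis rate (yeast-like medians, giving
~10 molecules·cell⁻¹ abundance at the ~5000-gene scale), with defaults
n_genes = 500, gene lengths 100–400 codons, 28/61 optimal codons,
tilt = 3, coupling_beta = synthesis_coupling = 1 and noise_sd = 0.4 —
chosen once as a clearly-coupled, realistically noisy regime.

Two regimes exercise the interpretation of partial correlations. In the
*direct* regime half-life and synthesis rate are each coupled to u and
abundance is derived (m = μ/(α+λ), steady-state exact). In the
*abundance-mediated* regime abundance is coupled to u and half-life
depends on abundance (log hl = κ·Δlog m + noise), so conditioning on
abundance should remove the optimality–stability association. One
cancellation is worth knowing about: because log m = log μ + log hl −
log ln2 exactly, a direct regime with *equal* stability and synthesis
couplings makes abundance absorb the entire latent signal (the hl-on-m
regression coefficient is ½·2 = 1 in the latent direction) and the partial
correlation vanishes even though the coupling is direct. The regime
contrast therefore isolates the stability coupling (synthesis_coupling
= 0) when the partial correlation is the quantity of interest. An
`abundance_noise_sd` knob adds log-normal measurement error to the
reported abundance (real abundance estimates come from independent
studies); with it at 0 the emitted triple satisfies μ = m(α+λ) to
floating-point exactness.

Motif assignment gives "stabilising" motifs a presence probability
logistic-increasing in u (slope motif_effect_delta) and "destabilising"
motifs a constant rate, mirroring the typical pattern of positive
promoter/5'UTR associations and null 3'UTR results.

What the generator does **not** emulate: real codon-usage covariation with
amino-acid composition and GC content, 5'/3' positional codon effects, RNA
structure, dataset-specific measurement error models, or annotation
artifacts. Passing tests on synthetic data therefore demonstrate that the
statistics recover the coupling they define, not that any particular
biological dataset carries such a coupling.

## Problem sizes and numerical choices

Routine runs and the reproduction script use 500-gene genomes (the
replicate-based calibrations use 100–200 replicates at that size), which
is ample for the effect sizes simulated. Frequencies use exact rational
arithmetic per gene before division; correlation identities hold to 1e-12
and the steady-state inversion to better than 1e-9 relative. Ties are
average-ranked everywhere; the chi-square requires all four marginals
non-zero and errors otherwise rather than returning a degenerate value.

## Known limitations

- Reproducing the published per-dataset CSC/CPC vectors and Total/Observed
  counts requires the original external kinetic datasets and
  annotation-version-matched gene sets; this package reproduces the full
  arithmetic and test statistics of those tables from their printed
  marginals, and everything else on synthetic data.
- The nTE weight construction follows the usual demand-normalised recipe,
  but published classifications should be loaded as inputs when available;
  the reconstruction is a convenience, not a reference implementation.
- The exact Bonferroni family behind published motif tables is generally
  not recoverable; m is explicit for that reason.
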