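# Methods

This note records the models, numerical choices and study conditions behind
`molspikes`, and what the synthetic tests do and do not demonstrate about
real data.

## Spike designs and extraction

Two spike layouts are supported. The *simple* design embeds an 18-nt random
spUMI between known flanking sequences; the *complex* design places a 7-nt
expression barcode directly upstream of a 14-nt spUMI followed by a 25-nt
constant region, with 24 barcodes per sequence arranged as a twofold,
12-level duplicate titration (11 sequences × 24 barcodes = 264 species).

Extraction is substitution-only. Anchors are located by a sliding-window
Hamming search within ±5 positions of the offset implied by the alignment
coordinate; the best (fewest-mismatch) window wins, with ties broken by
proximity to the expected offset. The default anchor mismatch budget is 2
for the simple design; the complex design uses the fixed thresholds of its
validation rule (barcode ≤ 1 with a unique best hit, constant region ≤ 3).
Reads whose indels change the spUMI length are rejected rather than
realigned, because both designs require an exact spUMI length anyway; each
rejected read is tallied under exactly one reason code (`anchor`, `length`,
`barcode`, `ambiguous-barcode`, `constant`, `truncated`, `low-quality-umi`,
`off-target`). SAM input relies on the convention that SEQ is stored in
reference orientation, so no re-orientation is applied when loading;
programmatic reads tagged with strand `-` are reverse-complemented first.

The library-UMI quality filter discards reads with more than three UMI bases
below Phred 20 (strictly more: three low bases pass). It is idempotent and
preserves order.

## UMI collapse

All four algorithms share a greedy frame: repeatedly take the most abundant
unassigned UMI as representative and absorb neighbours within Hamming
distance *d*. They differ in the absorption rule — adjacency absorbs all;
directional only neighbours with strictly less than 0.5× the
representative's reads (the alternative ≥ 2·b − 1 convention used by some
tools is deliberately not used); singleton only single-read neighbours;
cluster follows chains of distance-≤ *d* links with non-increasing
abundance, so nodes beyond *d* from the representative can still be
absorbed. Two conventions make results deterministic and testable:
abundance ties are broken by lexicographically smallest UMI, and the
"most abundant" ordering always uses original (pre-aggregation) counts.
N bases count as mismatches.

Neighbour search uses a position-mask partition on 2-bit-packed codes: two
length-L sequences are within distance *d* iff they agree outside some
subset of *d* positions, so bucketing by each of the C(L, d) masked patterns
enumerates exactly the qualifying pairs in O(C(L, d)·n log n) — quadratic
all-pairs work only arises inside buckets of identical masked patterns.
A naive oracle (full distance matrix, explicit network, recursive
absorption, ≤ 15 nodes) exists solely to cross-check the implementation.

spUMI correction applies adjacency at *d* = 2 within each
(cell, spike, barcode) group: 4¹⁸ ≈ 6.9 × 10¹⁰ codes make chance collisions
at distance ≤ 2 negligible, while PCR error clouds concentrate at 1–2
substitutions.

## Saturation model

Distinct-molecule counts versus sequencing effort are fitted with the
asymptotic regression y(x) = b0 + b1(1 − exp(−eᶜx)); the asymptote b0 + b1
estimates total complexity. Initialisation is b0 = min(y),
b1 = max(y) − min(y), c = log(1/median(x)), with five deterministically
jittered restarts on failure; a constant response short-circuits to
b1 = 0. The asymptote's standard error is propagated from the curve-fit
covariance and a fit whose asymptote SE exceeds 50% of the estimate is
flagged as unsaturated. Per-well estimation subsamples reads without
replacement on a 15-point linear depth grid from 10,000 to 150,000 reads
(truncated with a warning when the well has fewer reads), corrects spUMIs at
Hamming 2 at each depth, and fits the depth–molecule curve; the subsampling
seed is recorded on the fit. Wells are called empty when endogenous mapped
reads are < 20% and spike reads > 80% (both strict).

Uniform sampling of M codes follows the closed forms
E[distinct] = M(1 − (1 − 1/M)^m) and
Var = M(1 − 1/M)^m + M(M − 1)(1 − 2/M)^m − M²(1 − 1/M)^{2m},
used as independent oracles in the tests.

## Counting evaluation

Expression-level designs follow the two standard grids: 20 linear levels
from 1 to 100 molecules and 60 log-spaced levels from 1 to 1,000, with 100
in-silico cells per level. Per-cell molecule numbers are a single normal
draw with s.d. = √mean, rounded and clamped at zero — the simplest reading
of "normal with added Poisson noise"; a second additive noise term was
considered and rejected as double-counting the variance. Molecules are
sampled without replacement within a cell and are reusable across cells.
Counting a cell trims its library UMIs to the requested length, collapses
with the requested algorithm/distance, and reports observed/truth × 100;
the inflation null reads/truth × 100 describes total counting failure.

## Poisson-lognormal machinery and quasi-UMI rescue

The poilog pmf P(k) = ∫ Pois(k; λ) LN(λ; μ, σ) dλ is computed on the
standard-normal scale, where the log-integrand
g(z) = k(μ + σz) − e^{μ+σz} − z²/2 is strictly log-concave. For each count
the mode of g is found by Newton iteration and a 61-node trapezoid grid
spans ±8 Laplace widths (1/√(σ²λ* + 1)) around it. A fixed global grid was
tried first and rejected: at large counts the Poisson kernel is far narrower
than any practical fixed spacing, which made the likelihood surface noisy
enough to break MLE recovery. The adaptive rule keeps relative accuracy
high for every k (validated against direct quadrature and the normalization
invariant, which holds to 1e-6).

The MLE optimises (μ, log σ) by Nelder–Mead from a method-of-moments start,
requires ≥ 30 not-all-equal counts, and reports a convergence flag; σ pinned
at its 1e-3 floor marks a Poisson-like input (the poilog nests the Poisson
as σ → 0).

Quantile normalization maps zeros to zero and assigns each nonzero read
count the smallest k ≥ 1 whose zero-truncated poilog CDF reaches the count's
empirical quantile, taken at the midpoint of the count's empirical CDF
interval (the discrete quantile match; an upper-edge rule was tried first
and rejected because whole tied-value blocks flipped to the next quantile on
sampling noise). By default the location μ is re-anchored per cell so the
poilog zero probability equals the observed zero-gene fraction, and the
supplied shape contributes σ (plus the fallback μ for cells without zeros);
this mirrors the original quantile-normalization procedure and makes the
rescue robust to location noise in the spike-derived fit
(`anchor_zeros=False` restores the literal fixed-μ behaviour). Shape tuning
evaluates a 21-point σ grid over ±10% of the estimate, holding the anchoring
rule, and returns the result whose total is closest to the expected per-cell
total, ties going to the σ nearest the starting estimate. Rescued totals
are monotone non-decreasing in σ over the grid.

Total-RNA inference assumes reads sample spike and endogenous molecules
proportionally: total = spike_molecules × endogenous_reads / spike_reads,
invariant to common rescaling of the read counts. The expected spike amount
per well can be adjusted by the ratio of observed to empty-well-predicted
molecules at the cell's spike depth.

Expected molecules per dispensed mass use standard ssRNA residue masses
(A 329.2, C 305.2, G 345.2, U 306.2 g/mol, + 159 for the 5′ triphosphate),
a 30-nt poly-A tail, and a complexity-weighted mean molecular weight over
the pool's species (A/U and G/C assumed equimolar within their class).

## Simulator

Each molecule receives a uniform random spUMI and library UMI. PCR is
modelled as a binary amplification tree truncated at `pcr_cycles` with
per-base, per-cycle substitution; the tree is never materialised — each read
samples a random leaf and per-edge mutations are derived from deterministic
per-edge seeds, so reads sharing ancestry share mutations, reproducing the
within-cell enrichment of spUMIs one or two errors from a true sequence.
Sequencing errors are independent per-base substitutions per read, targets
drawn uniformly from the three alternative bases. Inflation modes stamp a
fresh library UMI on every read (`new_umi_per_read`, modelling oligo-dT
carry-over in direct-PCR protocols) or on a fraction of reads
(`tso_priming`, modelling residual template-switching oligo). Base
qualities are two-level (Phred 37, with an optional per-base probability of
Phred 10). Indels, quality realism beyond two levels and ambient RNA are
out of scope. Everything is seeded; fixture output (tagged SAM + TSV +
truth tables) is byte-identical for a fixed seed.

For the rescue study conditions, `expression_profile` draws a fixed per-gene
lognormal rate profile shared by all simulated cells of a type, and
`simulate_inflated_well` realises per-cell Poisson counts, inflated reads
and titration-distributed spike counts (twofold series scaled to ~33,378
molecules per well). The profile scale σ = 2.55 is design-derived: it is
the Poisson-lognormal shape that the twofold 12-level titration itself fits
to, i.e. the spread the spike set is built to span. Earlier variants that
redrew heavy-tailed gene rates independently per cell were rejected as
unrealistic — they let a single gene dominate a cell's total, which no
rank-based rescue can reproduce, and real cells of one type share a profile.

## Problem sizes and limitations

Tests run at desk scale by design: wells of up to 30,000 molecules, pools of
50,000 spUMIs, 3,000-gene cells, 10–100 in-silico cells — sizes at which the
statistical behaviour of every estimator is already visible. Passing tests
show that each algorithm implements its stated rule exactly (oracle
agreement), that estimators recover known simulation parameters within
stated bands, and that the rescue restores molecule-scale totals and ranks
under the generator's assumptions. They do not certify performance on real
libraries, where error processes are read-position dependent, amplification
is neither uniform nor independent of sequence, cell barcodes can collide,
and spike capture efficiency varies between wells beyond the Poisson level
modelled here. The genome-uniqueness screen for new spike sequences is an
exact k-mer membership test (k = 50, both strands) against a user-supplied
host k-mer set; it is stricter in spirit but not equivalent to read
simulation plus alignment against a full genome index.
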