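# Methods

## Substitution model

The simulator implements reversible continuous-time Markov substitution on
the DNA alphabet, pinned in the order A, C, G, T, with exchangeabilities in
the order AC, AG, AT, CG, CT, GT. A GTR model is assembled as
`Q_ij = s_ij π_j` (i ≠ j), diagonals set to minus the row sum, and the
matrix globally rescaled so the expected number of substitutions per site
and unit time, `−Σ_i π_i Q_ii`, equals exactly 1. Branch lengths therefore
mean expected substitutions per site averaged over all sites, including
invariant ones.

Transition probabilities `P(t) = exp(Qt)` are computed by spectral
decomposition of the π^{1/2}-symmetrized matrix
`A = diag(√π) Q diag(1/√π)`; reversibility guarantees `A` is symmetric, so
the spectrum is real and the decomposition is numerically stable. Entries
are clamped to [0, 1] and rows renormalized; a row-sum drift of 1e-9 or more
(which would indicate a genuine numerical failure, not float dust) raises
instead of being papered over. `P(0)` is returned as the exact identity so
zero-length branches and invariant sites copy parent states verbatim.

Sampling uses the inverse-CDF rule `state = Σ_k [u ≥ cum_k]` with
`u ∈ [0, 1)`, which maps `u = 0` to the first state of positive probability;
with an exact identity matrix this reproduces the parent state even at
`u = 0.0`.

## Among-site rate variation

+I+Γ: each site is invariant (rate 0) with probability `p_inv`, otherwise
it draws one of `k` discrete Gamma categories with equal weights. The
category rates are the *means* of the `k` equal-probability bins of
Gamma(α, mean 1) — the mean variant rather than the median variant, which
is the convention of the software family this simulator follows; the bin
means are computed from the incomplete-Gamma identity
`∫_a^b x f_α(x) dx = F_{α+1}(b) − F_{α+1}(a)` (no quadrature), and the test
suite checks them against direct numerical integration. Because the bin
means telescope, the weighted mean rate is exactly 1; non-invariant rates
are additionally rescaled by `1/(1 − p_inv)` so the mixture mean over all
sites stays 1 and branch lengths keep their meaning. Defaults follow the
benchmark configuration used throughout the tests: `p_inv = 0.2`, `α = 0.5`,
`k = 4`.

Per-site rates are drawn **once per alignment** (at the root) and shared by
every branch. This site-homogeneity is what makes disjoint site blocks
fully independent, which the parallel algorithms rely on; per-branch rate
redraws would break block decomposability.

## Sequential engine and the memory contract

The root sequence is drawn i.i.d. from π; a preorder walk then samples each
node from its parent using one 4×4 matrix per rate category per branch
(k + 1 matrix exponentials per branch rather than L). Tip sequences are
emitted in preorder-encounter order — the traversal order is also the tip
output order, matching the reference 7-tip example whose preorder is
7, 8, 9, 10, 0, 1, 2, 11, 3, 4, 12, 5, 6 (note that topology has depth 4).

A node's sequence is freed as soon as its last child has been simulated, so
the set of live sequences is always a subset of the current root-to-node
path: at most `D + 1` full-length sequences coexist, the `O(N) + O(D·L)`
footprint. `ResidencyMeter` counts acquisitions/releases exactly and is
asserted against `D + 1` on star, caterpillar, balanced, and random trees.

Draw order per (block) run is pinned for reproducibility: site categories,
then root states, then one uniform vector per non-root node in preorder.

## Parallel algorithms

`partition_sites(L, B)` produces contiguous blocks whose lengths differ by
at most one, remainder to the lowest-indexed blocks; `partition_tips`
applies the same rule to tip ranges. (A remainder-to-highest rule would be
equally valid; one had to be pinned, and all paths use the same one.)

**External memory.** Phase 1 runs the sequential engine per block in
separate OS processes, each writing a temporary single-block alignment
file; phase 2 splits tips into ranges, reads each tip's subsequences from
every temporary file at computed offsets, and writes the concatenated
sequence at its absolute position in the final file. Because every byte's
position is precomputed, the final file is independent of worker
scheduling — stronger than serializing writes through a critical section,
which would leave record order timing-dependent. Temporary files hold
exactly one extra copy of the `N·L` sequence payload (plus per-block
headers), and are deleted on success. A pre-flight check requires free disk
for twice the final file.

**Internal memory.** `K − 1` simulating threads each run one block with a
sink that stages `(offset, subsequence)` entries in a `BoundedBlockBuffer`
of capacity `⌈N·λ⌉`, blocking while full; the writer thread visits buffers
round-robin (`i → i mod (K−1) + 1`), drains whatever is available, and
writes each entry at its precomputed position. When all buffers are empty
and producers are still running, the writer sleeps briefly (default 1 ms,
configurable). Occupancy accounting is exact and asserted against the
capacity. The default `λ = min(2(K−1)/N, 1)` gives each buffer room for two
subsequences per simulating worker — with more workers each subsequence is
shorter and arrives faster, so staging room grows with K; the constant 2 is
an argument, not a magic number.

**Byte equivalence.** Each block's random stream is
`default_rng(base_seed + block_index)`, a function of the task's seed and
the block index only. Consequently the serial per-block reference, EM with
`K = B` workers, and IM with `K = B + 1` workers produce byte-identical
files, and this is asserted at N=100, L=12000, B=4 as well as on small
fuzzed instances with injected producer delays. Different block counts give
different (equally valid) alignments, since the stream layout differs.

## Batches and seeds

`H` alignments over `P` executors follow `w = (z mod P) + 1`. The seed
contract is `derive_seed(r, p, k) = r + 1000p + k`, rejecting `k ≥ 1000`
(which would collide with executor `p + 1`). Alignment `z`'s base seed is
`r + z·10⁶` regardless of the executor that runs it, which makes the batch
output an invariant of `P` — the per-(process, thread) formula alone cannot
deliver that, since the same alignment may land on different executors as
`P` changes. Executors are plain OS processes with no shared state; a
launcher-compatible CLI mode lets externally started executors compute
their own assignment from `(rank, P)`. An unset seed defaults to the
current microsecond and is logged so the run remains reproducible after
the fact.

## Output formats

Single-line FASTA (`>name`, sequence on one line) and relaxed sequential
PHYLIP (`N L` header, 10-character space-padded name field, sequence on one
line). Line wrapping is disabled in all direct-position paths so offsets are
affine in the site index; `rewrap` post-processes files for tools that
require wrapped lines. PHYLIP rejects names longer than the field.

## Synthetic data

Test fixtures are Yule–Harding trees: grown from two tips by uniformly
splitting a random current tip, labels assigned to tips by a random
permutation (labels are exchangeable under the model; any deterministic
naming would skew the labeled-topology distribution), branch lengths i.i.d.
exponential with mean 0.1. These trees are ultrametric-free, bifurcating,
and have depth ~O(log N); they exercise the algorithms' contracts but do
not emulate real-data features such as rate heterogeneity among lineages,
base-composition drift, alignment gaps, or model misspecification — passing
tests demonstrate correctness of the simulator under its own model, not
realism of any particular data set.

## Problem sizes and known limitations

The test suite validates statistical properties at L up to 10⁵ sites and
structural/memory contracts at up to 2048 tips (10⁵ for tree generation);
the cross-path equivalence check runs at N=100, L=12000 and the scaling
smoke test at N=2000, L=200000. The acceptance script uses N=500, L=50000
for its timing ratio. These sizes were chosen to exercise every contract at
scales where the statistics are decisive.

Insertions/deletions are not modelled: the site-independence argument
underlying both intra-alignment parallel algorithms fails under indels.
Codon models, empirical amino-acid matrices, non-reversible models,
partitioned or lineage-heterogeneous (heterotachous) models are out of
scope. The internal-memory writer is a single thread; on systems where
simulation is much faster than I/O it becomes the bottleneck by design,
which is the trade-off the external-memory variant exists for.
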