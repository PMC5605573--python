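# Methods

## Model

`wfage` analyses a biallelic diploid Wright-Fisher population of `Ne`
individuals as a finite absorbing Markov chain on mutant copy counts
`0 .. 2Ne`, with copy counts 0 (extinction) and `2Ne` (fixation) absorbing.
One chain step is one generation, composed of

1. **selection** on genotype fitnesses `1 : 1+sh : 1+s` (wild-type
   homozygote, heterozygote, mutant homozygote) under Hardy-Weinberg
   proportions,
2. **mutation** in both directions (`u`: wild-type → mutant, `v`: mutant →
   wild-type) applied to the post-selection gamete frequency,
3. **binomial resampling** of `2Ne` gametes.

So a row of the transition matrix at frequency `q = i/2Ne` is
`Binomial(2Ne, psi(q))` with

    psi = psi* (1-v) + (1-psi*) u,
    psi* = [(1+s) q^2 + (1+sh) q(1-q)] / [(1+s) q^2 + 2(1+sh) q(1-q) + (1-q)^2].

The selection-then-mutation life-cycle order is a modelling choice (the
alternative order differs at O(u·s)); it is pinned by the regression suite,
which reproduces published exact allele ages to the printed 0.01
generations across a selection/dominance/mutation grid.

Binomial rows are evaluated in log space (`gammaln`) over an adaptively
widened window around the mean and thresholded at `cutoff` (default
1e-12). Dropped entries are **not** renormalized — the row-sum deficit is
bounded by `(2Ne+1)·cutoff`, the discrete analogue of treating
sub-machine-precision probabilities as zero. The age moments computed at
cutoff 1e-12 and 1e-14 agree to well over 6 significant digits at
`Ne = 1000`; 1e-12 is the speed/fill compromise used everywhere.

Both boundaries are absorbing. Fixation-as-return-to-zero relabelling is
interpretive only; no quantity in the package needs the return process
materialized.

## Allele age

An allele founded at `p` copies and observed segregating at `x` copies has
age `t` with probability `f(t) = [Q^t]_{p,x} / N_{p,x}`, where `Q` is the
transient block and `N = (I-Q)^{-1}` the fundamental matrix. `t = 0` is
included (only `p = x` contributes): age counts generations since the
founding mutation. Raw moments factor through the negative-order
polylogarithm,

    mu_k = [Q A_k(Q) (I-Q)^{-(k+1)}]_{p,x} / N_{p,x},

with `A_k` the k-th Eulerian polynomial (`A_1 = 1`, `A_2 = 1+z`,
`A_3 = 1+4z+z^2`, `A_4 = 1+11z+11z^2+z^3`, generated by the Eulerian
triangle recurrence). Everything reduces to one sparse LU factorization of
`(I-Q)^T` (SuperLU through `scipy.sparse.linalg.splu`) plus `k+1`
triangular solves and sparse matrix-vector products assembling the x-th
column of `Q A_k(Q)` — no matrix-matrix product appears anywhere in the
package, which is what makes `Ne = 10^4` routine on one core (seconds to
~1 minute) and `Ne = 10^5` feasible.

Moments up to `k = 4` are exposed; the coefficient generator plus the
iterated-solve primitive document the extension path for higher k.

**Numerics.** Every solve verifies the residual
`‖(I-Q)^T m - b‖∞ ≤ 1e-8 · max(1, ‖b‖∞)`, applying one step of iterative
refinement when exceeded and failing hard otherwise. The bound scales with
the right-hand side because iterated solves feed back vectors whose entries
are expected visit counts (10^4 and beyond at strong mutation). Fill-in
ordering is delegated to SuperLU's default (COLAMD); the contract is the
residual, not the pivoting.

**Founding-copy prior.** At large population-scaled mutation rates
(`theta = 4 Ne u` approaching 1) the founding event can inject several
copies in one generation. The founding count is modelled as
`p ~ Poisson(theta/2)` conditioned on `p >= 1` (a p = 0 start has no allele
to observe), truncated to counts with raw pmf ≥ `epsilon` (default 1e-5)
and renormalized. Because the factorization does not depend on `p`,
integration costs one extra solve. At `theta <= 0.1` the integrated mean
differs from the `p = 1` mean by < 1e-3 relative; only near `theta ≈ 1`
does the difference become visible (third decimal place).

## Absorption and sojourn analyses

Classical absorbing-chain summaries use the same factorization:
absorption probabilities `B = N R` via one transposed solve
(`M1^T R`), and endpoint-conditioned sojourn times
`N_{p,j} B_{j,end} / B_{p,end}` via one *untransposed* solve per endpoint
(SuperLU exposes both orientations of one factorization). The
extinction/fixation-conditioned expected times are the sums of the
conditional sojourn vectors; the mixture identity
`t_uncond = pE·tE + pF·tF` is verified in the tests.

Conditional-time curves over a scaled-selection grid (the stochastic-
slowdown analysis) default to **starting at the founding copy count
p = 1**. This choice is empirical: with `theta = 0.96` the maximal
extinction-time excess over neutral computed from p = 1 converges with
increasing `Ne` toward the published ~67% (h = 0) and ~23% (h = 0.5),
while starting from the observed count x = 10 gives materially smaller
excesses (~53%/~14%). The observed-count start remains available via the
`start` argument. The located critical point (the `2Ne·s` maximizing the
extinction time at `theta = 0.96`, `h = 0`) is ≈ −2.44 from p = 1,
essentially `Ne`-invariant between `Ne = 1000` and `10^4`; note the curve
is extremely flat there (≲0.1% variation over ±0.1 in `2Ne·s`), so
third-digit estimates of this argmax are intrinsically fragile.

## Reversed-chain simulation

The Monte-Carlo validator samples exact allele ages by time reversal: with
`D = diag(N_{p,·})`, the reversed transient matrix is
`Q' = D^{-1} Q^T D`, and the only exit is a "stop" transition from `p`
with probability `1/N_{p,p}` (rows of `Q'` plus stop sum to 1 by the
fundamental-matrix identity `N = I + NQ`). A walker starts at `x`; the
number of transitions before stop is an exact age draw. States with
`N_{p,j} = 0` are pruned before the transform. Construction needs only
the single `p`-row of `N` — one solve.

Sampling is vectorized: each row's transition cdf is offset by its row
index, so the concatenation over rows is globally sorted and a single
`searchsorted` advances every active walker per generation. One
`numpy.random.Generator(PCG64(seed))` stream drives all replicates in
lock-step, so a run is reproducible given the seed and independent of any
batching. `max_steps` (default 1e9) only guards corrupted inputs;
truncated replicates are counted and excluded from moments, never silently
dropped. Histogram binning follows `numpy.histogram` (default `auto`);
the published long-tail plots accumulate the tail in the final bin, which
is a display choice the summary object leaves to the caller.

10^5 replicates reproduce exact means within Monte-Carlo error (the test
suite asserts 3 standard errors with a pre-registered single fresh-seed
retry); the exact solver is orders of magnitude faster than simulation at
equal precision, which is the point of the package.

## Diffusion baseline

The neutral no-mutation diffusion approximation to the expected age of an
allele at frequency `q`,

    E[T | q] = -4 Ne (q/(1-q)) ln q,

is included as an independent cross-check: it exceeds the exact
Markov-chain value in every tested configuration, by under 5% (a few
generations at low frequency), and is exactly linear in `Ne` at fixed
frequency.

## What the tests do and do not show

Unit and property tests validate every solver path against independent
dense oracles (`numpy.linalg.inv` fundamental matrices, brute-force pmf
summation by dense matrix powers) at `Ne ≤ 20`, closed forms on a scalar
chain, and hypothesis-fuzzed conservation/symmetry invariants of the
transition matrix. Regression tests then compare the full pipeline to
published exact values at `Ne = 1000..10^4`. Problem sizes in the default
suite — `Ne ≤ 10^4` exact, 10^5-replicate simulations at `theta ≤ 0.1`,
and the critical-point grid search at `Ne = 2000` — were chosen so the
whole suite runs in minutes on one core; they are regression scales, not
limits of the method.

All of this concerns the *model*: a constant-size, panmictic, biallelic
Wright-Fisher population at a single locus with known true frequency.
Agreement with the oracles says nothing about demographic change, linkage,
sampling error in the observed frequency, or multi-allelic sites — all out
of scope. The generic MatrixMarket entry point accepts any finite
absorbing chain, so non-Wright-Fisher models can be analysed, with the
caveat that state labels are then opaque integers `1..n`.

## Known limitations

- Equilibrium demography only; no time-varying `Ne`.
- Moments above `k = 4` require (documented, simple) extension.
- The full pmf path propagates one vector per generation and is
  restricted to `2Ne-1 ≤ 2001` transient states by default; moments are
  the supported route at scale.
- Conditional times are undefined (reported as `None`) when the
  conditioning absorption event has probability 0 — impossible for a valid
  Wright-Fisher chain started at a transient state, but possible for
  user-supplied chains whose R column is structurally zero.
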