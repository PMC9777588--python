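# Methods

## Model

The object of study is a finite driven (time-inhomogeneous) Markov chain
`X = (X_0, ..., X_N)` on a state set `S`, given by an initial distribution
`p0` and transition matrices `M_1, ..., M_N`, together with an inverse
temperature `β > 0`. Matrices are column-stochastic with entry
`(M_n)_{xy} = P(X_n = x | X_{n-1} = y)`, so distributions evolve by plain
matrix–vector products. The standing hypotheses everywhere are that `p0` is
strictly positive and every `M_n` is irreducible; irreducibility guarantees a
unique, strictly positive stationary distribution `p_n` per matrix, and these
`p_0, p_1, ..., p_N` are the *reference distributions* from which everything
else is built. Aperiodicity is never required — only stationarity is used,
never convergence — so periodic matrices (permutation cycles) are first-class
inputs.

Each strictly positive `p_n` determines an energy function up to an additive
constant (the *gauge*): `E_n(x) = -(1/β) log p_n(x) + c_n`, with partition
function `Z_n = Σ_x e^{-β E_n(x)}` and free energy `F_n = -(1/β) log Z_n`.
Along a realization `x = (x_0..x_N)`:

- work `W(x) = Σ_{n=0}^{N-1} E_{n+1}(x_n) - E_n(x_n)` (the external switch of
  the energy function at the occupied state),
- heat `Q(x) = Σ_{n=1}^{N} E_n(x_n) - E_n(x_{n-1})` (internal transitions
  under a fixed energy function),
- dissipated work `W^d = W - ΔF` with `ΔF = F_N - F_0`.

`W` and `ΔF` each shift by `c_N - c_0` under re-gauging; `Q` and `W^d` are
gauge-invariant; `W + Q = E_N(x_N) - E_0(x_0)` holds term-by-term (first
law). The package's default is the *zero-gauge* convention
(`E_n = -(1/β) log p_n` exactly), which makes every `Z_n = 1`, `F_n = 0`,
`ΔF = 0`. Since every identity checked here is gauge-covariant, this loses no
generality and removes an arbitrary constant from every test oracle;
non-zero-gauge families are first-class (energies are stored explicitly, not
recomputed from distributions).

## Reversed processes and fluctuation identities

The *auxiliary reversed chain* `Y` starts at `p_N` and uses the conjugated
matrices `(M̂_{n+1})_{xy} = p_{N-n}(x)/p_{N-n}(y) (M_{N-n})_{yx}`; column
stochasticity follows from stationarity and is re-verified at 1e-12 on
construction. The *time reversal* starts at `p_N` and runs `(M_N, ..., M_1)`.
The two coincide entrywise exactly when every `M_n` satisfies detailed
balance with respect to `p_n` (*microscopic reversibility*);
`is_microscopically_reversible` computes both criteria and demands they
agree, treating a disagreement as a numerical fault rather than a result.

Because every expectation over a finite chain is a finite sum, the
fluctuation identities are checked *exactly*, by enumerating all `|S|^(N+1)`
trajectories, rather than statistically:

- Jarzynski: `⟨e^{-β(W - ΔF)}⟩ = 1` for any valid chain, any gauge.
- Per-trajectory ratio: `P(X=x) = P(Y=x^R) e^{β(W(x)-ΔF)}` with `Y` the
  auxiliary chain; conditionally, the path-probability ratio equals
  `e^{-βQ}`.
- Work reversal: with the reversed energies `Ê_n = E_{N-(n-1)}` (`Ê_0 = Ê_1`),
  `W_Y(x^R) = -W_X(x) + E_1(x_0) - E_0(x_0) + k`, where `k` collects gauge
  offsets and is zero for re-used energies. The state-dependent term is the
  protocol asymmetry of discrete time; it collapses to a constant exactly
  when `p_0 = p_1`, making work odd under time reversal.
- Crooks: `P_F(W=w)/P_B(W=-w+k) = e^{β(w-ΔF)}` at every atom of the forward
  work distribution — guaranteed only when `p_0 = p_1`. When that hypothesis
  fails, `crooks_report` still produces the full atom table (missing
  backward atoms flagged undefined, `holds=False`): the breakdown is a
  first-class behavior. The three-state counterexample fixture
  (`counterexample_chain`, states {A,B,C}, `p0=(a,b,c)`, one reversible
  matrix with stationary `(a,c,b)`, `b < c`) exhibits it in pure form: the
  reversed process does no work at all, so the ratio is undefined at
  `w_B, w_C` and equals `a ≠ 1` at `w_A = 0`.
- Second law: `⟨W⟩ - ΔF ≥ 0` by Jensen on Jarzynski; equality iff `W` is
  almost surely `ΔF`.

Work values are floats; atoms of the work distribution are formed by
single-linkage grouping at `tol_group = 1e-9` so roundoff cannot split an
atom. Ratio identities are compared in the log domain with relative
tolerances; trajectories with probability zero on both sides are skipped and
one-sided zeros are reported as violations (the identities degenerate at
zeros). Monte Carlo estimators (`jarzynski_mc`, sampling) are explicitly
separate from the exact sums, seeded, and never silently substituted.

## Decision-making layer

Utilities act as negative energies (`U = -E`). The max-entropy policy under
an expected-utility constraint is the Boltzmann distribution
`p ∝ e^{βU}`, computed in the log domain. A learner facing a schedule of
environments is modelled by one transition matrix per environment with the
environment's policy as stationary distribution, built by the Metropolis
rule from a symmetric proposal (off-diagonal `(x,y)`:
`proposal(x,y) · min(1, p(x)/p(y))`; diagonal absorbs the rest). Any
stochastic matrix with the right stationary law would serve the theory; the
Metropolis rule is the simplest constructive choice, and asymmetric
proposals (which would need the Hastings correction) are refused rather than
silently accepted. `run_adaptation` repeats each environment's matrix for
its dwell time, starts the learner (by default) equilibrated to the first
environment — so `p_0 = p_1` and the Crooks hypothesis holds by construction,
with a flag to start uniform instead and reproduce the stationarity-failure
regime — and reports the Jarzynski expectation, the second-law gap (the
bound on expected surprise), and the Crooks report. Per-step surprises
`E_{n+1}(x_n) - E_n(x_n)` sum exactly to the work, which is the sense in
which dissipated work quantifies hysteresis between a schedule of
environments and its reversal.

## Numerical choices

- Tolerances: stochasticity 1e-9; stationary-solve residual 1e-10; exact
  identities asserted at 1e-12 (per-trajectory) or 1e-9/1e-10 (relative,
  aggregated); Monte Carlo assertions use fixed seeds and 5-standard-error
  bands.
- Stationary distributions come from the SVD null space of `M - I`
  (`rcond = 1e-10` — the zero singular value can sit a few ulps above the
  machine-eps threshold for near-symmetric matrices) and are always
  re-verified by the residual `‖Mp - p‖_∞ ≤ 1e-10`. Reducible matrices are
  refused: without uniqueness the reference distributions, hence all
  energies, are ill-defined.
- Irreducibility is strong connectivity of the transition graph, computed on
  the sparsity pattern.
- Partition sums use log-sum-exp; Boltzmann policies use a log-domain
  softmax.
- Chains with zero transitions are rejected at construction (work and heat
  would be empty sums).

## Synthetic chains

The random-chain generator emulates the study conditions, not real data:
`generic` mode draws column-stochastic matrices with every entry ≥ 1e-3
(positivity ⇒ irreducibility) and a random interior initial distribution;
`detailed_balance` mode builds Metropolis matrices against random positive
targets (reversible by construction, with an `equilibrated` flag setting
`p_0 = p_1`); `permutation` mode produces single-cycle deterministic
matrices (periodic, maximally non-reversible). All draws are seeded and
reproducible. Property suites run on small chains (2–5 states, 1–4 steps, at
most 3 125 trajectories each), where full enumeration is exact; nothing
about the identities depends on size, so these scales demonstrate them
without loss. What the generator does not emulate: structured state spaces,
estimated (noisy) transition matrices, or empirical decision data — passing
tests show the identities and counterexamples hold exactly for chains in
these classes, not that any particular real system is well modelled by one.

## Known limitations

- Finite state spaces and discrete time only; no rate matrices, kernels, or
  continuous trajectories, where work becomes an integral and the `p_0 = p_1`
  hypothesis could be dropped.
- One `β` per chain; no temperature schedules.
- Exact mode is exponential in `N` (it enumerates `|S|^(N+1)` paths); the
  enumeration cap refuses rather than degrades, and callers choose Monte
  Carlo explicitly.
- The uniqueness half of the auxiliary-chain characterization is not
  searched over competing chains; only the constructive direction (existence
  with the stated properties) is verified.
- Work-atom grouping is float-based; an exact-rational mode is not provided.
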