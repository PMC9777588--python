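# chainthermo

Stochastic thermodynamics for finite driven Markov chains — and for
bounded-rational decision-makers modelled as such.

A driven chain `X = (X_0, ..., X_N)` is a finite-state process with an
initial distribution `p0` and one transition matrix per step,
`M_1, ..., M_N`, at inverse temperature `β`. When `p0` is strictly positive
and every matrix is irreducible, each step carries a unique stationary
distribution `p_n`, and hence an energy function
`E_n = -(1/β) log p_n + c_n` (defined up to the gauge `c_n`). Along a
trajectory `x`, the work `W(x) = Σ E_{n+1}(x_n) - E_n(x_n)` is the energy
injected by switching the energy landscape, the heat
`Q(x) = Σ E_n(x_n) - E_n(x_{n-1})` the energy moved by the dynamics, and
their sum telescopes to `E_N(x_N) - E_0(x_0)` (the first law).

Because the state space is finite, the fluctuation theorems are not
statistical claims here — they are finite sums the package evaluates
exactly:

- **Jarzynski's equality** `⟨e^{-β(W-ΔF)}⟩ = 1` for every valid chain and
  gauge, and its Jensen corollary `ΔF ≤ ⟨W⟩` (the second law; in the
  decision-making reading, a bound on expected surprise).
- **Crooks' relation** `P_F(W=w)/P_B(W=-w) = e^{β(w-ΔF)}` atom by atom,
  which in discrete time with the symmetric work definition *additionally*
  requires `p_0 = p_1` (the initial distribution stationary for the first
  matrix). The package ships the three-state counterexample chain where
  that hypothesis fails and the relation is undefined or false at every
  work value — produced as a report, not an error.
- **Time reversal**: the reversed process, microscopic reversibility
  (equivalent to detailed balance of every matrix), the oddness of work
  under reversal when `p_0 = p_1`, and dissipated work
  `βW^d = log P(X=x) - log P(Y=x^R)` as a quantitative hysteresis measure.

The decision layer maps utilities to negative energies: max-entropy
(Boltzmann) policies, Metropolis matrices with a prescribed policy as
stationary distribution, per-step surprise as the driving signal, and an
adaptation runner that pushes a learner through a schedule of environments
and summarizes its thermodynamics.

## Worked example

```python
import chainthermo as ct

chain, family = ct.db2_chain()     # 2 states, 2 steps, detailed balance, p0 = p1
print(ct.jarzynski_exact(chain, family))
print(ct.second_law_gap(chain, family))
rep = ct.crooks_report(chain, family)
print(rep.table.to_string(index=False), "\nholds:", rep.holds)
```

```
1.0
0.05663301226513254
     work  prob_forward  prob_backward  observed_ratio  predicted_ratio  defined
-0.405465      0.333333            0.5        0.666667         0.666667     True
 0.287682      0.666667            0.5        1.333333         1.333333     True
holds: True
```

The forward work distribution has two atoms, `log(2/3) ≈ -0.405` and
`log(4/3) ≈ 0.288`; each forward/backward probability ratio matches
`e^{β(w-ΔF)}` exactly (here `ΔF = 0`), so the Crooks relation holds. The
mean work exceeds `ΔF` by `0.0566` — the dissipation bound of the second
law. On the counterexample chain the same call shows the breakdown:

```python
chain, family = ct.counterexample_chain(0.5, 0.2, 0.3)
print(ct.crooks_report(chain, family).table.to_string(index=False))
```

```
     work  prob_forward  prob_backward  observed_ratio  predicted_ratio  defined
-0.405465           0.2            0.0             NaN         0.666667    False
 0.000000           0.5            1.0             0.5         1.000000     True
 0.405465           0.3            0.0             NaN         1.500000    False
```

The reversed process does no work at all (its energy protocol never
changes), so the backward atoms at `±0.405` are missing and the ratio at
`w = 0` is `0.5 ≠ 1`: with `p_0 ≠ p_1`, Crooks fails everywhere.

A command-line interface mirrors the library
(`chainthermo validate|stationary|reverse|work-dist|jarzynski|crooks|second-law|counterexample|simulate`),
reading chain/energy JSON and trajectory CSV files; exit code 0 means the
queried identity holds, 1 that it fails, 2 that a precondition was violated.

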