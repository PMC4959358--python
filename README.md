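# smacglore

Secure multi-party logistic regression over horizontally partitioned
clinical data, built from secret-sharing boolean circuits.

## The problem

Hospitals and research networks often hold complementary patient cohorts —
the same variables, disjoint patients — and want a pooled logistic
regression without moving records or even summary statistics between
institutions.  Classical distributed fitting exchanges per-site
information matrices and score vectors, which are themselves disclosive.
Here *everything* after the parties' local preprocessing happens inside a
jointly evaluated boolean circuit under XOR secret sharing (GMW-style,
semi-honest parties, AND gates via 1-out-of-4 oblivious transfer): partial
Hessians, gradients and every intermediate coefficient iterate exist only
as random-looking shares.  The single decoded output is the fitted
coefficient vector β.

## The model and algorithm

For pooled design X (n × m, last column an all-ones intercept) and binary
outcomes y, the model is P(yᵢ = 1 | xᵢ, β) = 1/(1 + e^{−βᵀxᵢ}).  The
Newton–Raphson Hessian XᵀW⁽ᵗ⁾X is replaced by Böhning's constant bound, so
each party j feeds its local piece of

    H̃ = −¼ Σⱼ (Xʲ)ᵀXʲ,

the circuit aggregates, inverts A = −H̃ once with the division-free
Newton–Schulz iteration N_{t+1} = 2N_t − N_t M_t (N₀ = c⁻¹I, c = trace A),
and then iterates

    β ← β + A⁻¹ Σᵢ (yᵢ − P(xᵢ, β)) xᵢ

for a fixed number of steps.  Inside the circuit all reals are 28-bit
two's-complement fixed-point words with 11 fractional bits; exponentials
are an order-15 Taylor series in Horner form on exponents clamped to
[−5, 5], divisions are Newton–Schulz reciprocals, and matrix products use
one-level Strassen block decomposition (7 block multiplications).

Two interchangeable backends run the arithmetic: a plaintext fixed-point
*emulation* (fast, bit-exact to the circuits by construction and by test)
and an actual secret-sharing *MPC* evaluation with in-process parties and
a simulated OT backend.  The test suite pins their bit-level agreement on
every primitive and on a complete small fit.

## Worked example

Simulate a 60-record, 3-binary-feature study split across two parties,
then fit securely:

```
$ smacglore datagen --n 60 --features 3 --parties 2 --seed 42 --out-prefix party
wrote party1.csv (30 records)
wrote party2.csv (30 records)
$ smacglore fit --party party1.csv --party party2.csv --newton-iters 50 --out result.json
beta: [ 2.5952  1.2422 -1.5098 -0.4204]
AND gates: 1,195,587,306  OT invocations: 2,391,174,612
wrote result.json
```

The four numbers are the fitted log-odds coefficients for the three
binary features and the intercept: e.g. feature 1 multiplies the odds of
a positive outcome by e^2.5952 ≈ 13.4.  The counters say what the run
costs under secret sharing — only AND gates need interaction, two OT
invocations each for two parties.  The ordinary (plaintext) fit of the
pooled data, `smacglore oracle fit`, gives (2.5952, 1.2422, −1.5088,
−0.4219): the secure pipeline agrees to ~10⁻³, the price of fixed-point
truncation and the Taylor/reciprocal approximations.

Library use mirrors the CLI:

```python
from smacglore import SimSpec, simulate_parties, fit, GloreConfig
parties = simulate_parties(SimSpec(n=60, m_features=3, h=2, seed=42))
result = fit(parties, GloreConfig(newton_iters=50))   # backend="mpc" for real sharing
print(result.beta)
```

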