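# Methods

## Setting and threat model

h ≥ 2 institutions hold horizontally partitioned data: identical
covariates, disjoint patients.  Parties are semi-honest — they follow the
protocol but may inspect everything they receive.  The deliverable of a
joint computation is the fitted logistic-regression coefficient vector β
and nothing else: no record, partial Hessian, gradient, or intermediate
iterate β⁽ᵗ⁾ is ever decoded.  Differential privacy on the released β
itself is out of scope, as is malicious-adversary security and real
network transport (parties are in-process actors; the oblivious-transfer
backend is a correctness-only simulation behind an interface a
cryptographic 1-of-4 OT could implement).

## Fixed-point representation

All circuit values are 28-bit two's-complement words with 11 fractional
bits: range [−2¹⁶, 2¹⁶ − 2⁻¹¹], resolution 2⁻¹¹.  Encoding floors toward
negative infinity; arithmetic wraps silently mod 2²⁸ (circuit semantics).
Products are computed on sign-extended words and truncated once by an
arithmetic 11-bit right shift.

A printed statement of the format's lower bound as −(2²⁸−1)·2⁻¹¹ is
inconsistent with two's complement; the standard range with minimum
−2²⁷·2⁻¹¹ is used.

**Wide internal format.**  The contraction loops (Taylor exponential,
Newton–Schulz reciprocal and matrix inversion) run in a widened variant:
56-bit words with 22 fractional bits, reached by an exact shift and
truncated back to 28/11 at the boundary.  This is a deliberate design
choice, for a quantifiable reason: a reciprocal seeded with c⁻¹ for a
bound like c = 150 starts at m₀ = a/c ≈ 7·10⁻³, which an 11-fractional-bit
grid resolves to only ~8% relative error — the iteration then converges
to the reciprocal of the *misquantised* operand, and the logistic
response inherits errors up to ~10⁻¹.  At 22 fractional bits the seeding
error is ~4·10⁻⁵ and the end-to-end response error stays below 10⁻².
The widening is the same device already used for products (28→56 bits);
it roughly doubles AND-gate cost in those loops only.

## Circuits and gate accounting

Gate basis {XOR, AND, NOT}; only AND is nonlinear, so AND count is the
complexity measure.  Constructions are fixed so counts are reproducible:

- **Adder**: ripple carry, c′ = c ⊕ ((a⊕c) ∧ (b⊕c)), no final carry-out —
  exactly w−1 ANDs per w-bit addition, hence 27·n² for an n×n matrix
  addition (27, 108, 432, 2700 for n = 1, 2, 4, 10).
- **Subtraction**: two's complement — invert the subtrahend, add with
  carry-in 1 (w−1 ANDs).
- **Multiplier**: schoolbook low-half product on sign-extended operands;
  AND count is logged, not asserted (many multiplier constructions exist
  and none is canonical for this accounting).
- **Clamp**: signed comparison by subtraction sign at width w+1 (no
  overflow corner case), then a bitwise multiplexer m = (s ∧ (a⊕b)) ⊕ b.
- **Inner products** accumulate raw 56-bit products and truncate once,
  which both tightens error (one floor per entry, not per term) and
  matches the matrix-product circuits.

## Secret-sharing evaluation

GMW-style XOR sharing: share_bits draws h−1 uniform share vectors, the
last is fixed by the XOR constraint.  XOR gates are share-local; NOT is a
designated party's complement; an AND gate computes
a·b = ⊕ᵢaᵢbᵢ ⊕ ⊕_{i≠j} aᵢbⱼ with each cross term obtained through one
1-of-4 OT per ordered pair — h(h−1) OTs per AND.  Evaluation is batched
(bit-packed big integers, one machine op per gate per party across the
whole batch), which is what makes a complete fit under real sharing
runnable in tests.  The load-bearing invariant, enforced across the
suite, is *engine equivalence*: reconstruct(MPC evaluation) equals the
plaintext evaluator bit for bit, exhaustively for small circuits and
randomised at width 28.  The plaintext emulation backend is in turn
bit-exact to the circuits (int64 wraparound preserves the low word bits),
so accuracy numbers computed in emulation are the numbers the MPC path
produces.

## Matrix inversion and reciprocals

Newton–Schulz: N_{t+1} = 2N_t − N_tM_t, M_{t+1} = 2M_t − M_t²,
N₀ = c⁻¹I, M₀ = c⁻¹A.  For symmetric positive definite A and c = trace(A)
(computed in-circuit from the shared matrix) the spectrum of M₀ lies in
(0, 1) and the residual squares every step.  The reciprocal of the trace
needs a *public* upper bound for its own seeding constant; for all-binary
designs trace(¼XᵀX) ≤ nm/4, which the pipeline uses by default (n, m are
public).  Defaults: 15 iterations for both inversion and reciprocals —
the worst contraction in the pipeline (denominator ≈ 1 against bound 150)
needs ~12 doublings to pass 2⁻²², so 15 is convergence with margin.
Internally the iteration runs wide (56/22) and truncates at the end;
measured elementwise MSE against double-precision inverses on ¼XᵀX
matrices of sizes 2–10 is ~10⁻⁷.

The Hessian bound H̃ = −¼XᵀX is negative definite; the circuit inverts
A = −H̃ and *adds* A⁻¹·gradient, algebraically identical to the textbook
update but with a positive spectrum for the iteration.

One-level Strassen (7 block products of sums/differences of blocks) is
used inside the inversion; odd sizes are zero-padded and cropped.  Block
sums, products and the recombination all stay in the 56-bit container
with a single truncation at the end, so Strassen agrees with the standard
product bit-exactly absent container overflow — a stronger property than
the tolerance one would get truncating per block.  Multi-level recursion
is not implemented.

## Logistic response

Per record, t = −βᵀx is clamped to [−5, 5]; outside, the response is
below 1/(1+e⁵) ≈ 6.7·10⁻³, so the clamp costs little accuracy.  e^t is
the order-15 Taylor series in Horner form,
1 + t(1 + t/2(… (1 + t/15))), with 1/1 … 1/15 stored as plaintext
constants rounded to the nearest grid point; the division by 1 + e^t is
the 1×1 Newton–Schulz reciprocal with public bound 150 > 1 + e⁵.
Whether the clamp nominally applies to βᵀx or −βᵀx is immaterial — it is
symmetric.  Measured worst-case response error over the clamped range is
5.3·10⁻³ (Taylor truncation ~7·10⁻³ at the boundary plus fixed-point
noise, partially cancelling); response symmetry P(t) + P(−t) = 1 holds to
the same ~5·10⁻³, set by the approximation error rather than by single-
truncation 2⁻¹¹ arithmetic.

## The fit

Fixed number of Newton steps (default 10, configurable) rather than an
in-circuit convergence test, which would leak progress.  The fixed
Hessian dominates the true information matrix, so steps are conservative
and the oracle log-likelihood is monotone along the iterate path until
the quantisation floor.  Convergence is linear; on the 60-record
evaluation shape the fixed-point update is exactly zero by ~iteration 20,
and the accuracy evaluations run 50 steps ("until convergence") to
measure the converged gap, which is 4·10⁻⁴–2·10⁻³ against ordinary IRLS
across generator seeds.  Because fixed-point addition is exact and
order-independent mod 2²⁸, any split of the same pooled records across
2/3/4 parties yields a bit-identical β.

On the emulation path the fit checks the inversion residual
‖A⁻¹A − I‖∞ and raises a diagnostic failure above 0.05 (singular or
ill-conditioned pooled design); under MPC this check is skipped — it
would require decoding — and the caller sees divergence only in the
released β.

## Synthetic data

The generator emulates the evaluation condition of the study design:
n = 60 records, 3 iid Bernoulli(½) binary features plus intercept,
outcomes drawn from the logistic model, split across 2–4 parties in
contiguous blocks.  The generating coefficients are not published
anywhere to copy, so the package fixes β_true = (1, 0.5, −0.5, 0) —
moderate, mixed-sign effects with a null intercept, chosen once as a
realistic effect-size profile; feature_prob defaults to ½.  Draws with a
constant feature column are rejected and redrawn from a derived sub-seed
with a warning.  What passing tests show is therefore agreement and
invariance properties on well-behaved binary designs of the evaluation
shape; they do not exercise continuous covariates, separation, rare
outcomes, or ill-conditioned real cohorts (the residual diagnostic exists
for the latter).  Absolute coefficient values from any particular
external study are not reproduction targets, since their datasets'
generating processes are not available; the reproducible quantities are
the structural counts, approximation bounds, and secure-vs-ordinary gaps
the acceptance script computes.

## Numerical/problem sizes used

Tests and the acceptance script use: the 60×(3+1) evaluation shape for
end-to-end runs (50 Newton steps); Hessian sizes 2–10 at 60 records for
inversion MSE; a 1/128-step grid over [−5, 5] for response error;
n = 5000 for oracle parameter recovery (100 replicates); and a reduced
8-record, 1-feature configuration for the full fit under actual secret
sharing, where the MPC and emulation paths must agree bit for bit.

## Known limitations

- Range [−2¹⁶, 2¹⁶) and resolution 2⁻¹¹ are fixed; values outside wrap
  silently, as in the circuits.  No floating-point format.
- Semi-honest model only; the OT backend is a simulation (pluggable
  interface for a cryptographic one).
- Fixed iteration counts; no secure convergence or model diagnostics.
- One-level Strassen only; no pivoted or non-SPD inversion.
- Standard errors and p-values are oracle-side (plaintext, pooled-data)
  computations; the secure computation releases β only.
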