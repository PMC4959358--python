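"""Distributed fixed-Hessian Newton fitting of logistic regression.

The model: h institutions hold horizontally partitioned patient data —
the same covariates, disjoint patients.  Party j has the n_j x m design
block X^j (last column an all-ones intercept) and binary outcomes y^j.
The pooled logistic regression

    P(y_i = 1 | x_i, beta) = 1 / (1 + exp(-beta' x_i))

is fitted jointly without any party revealing records or intermediate
statistics; the only value ever decoded is the final coefficient vector.

The algorithm replaces the iteration-varying Hessian X'WX with Böhning's
constant bound X'X/4, which each party can decompose locally: party j
computes its partial -X^j' X^j / 4 and feeds it as private circuit input.
Inside the computation the partials are summed, A = X'X/4 is inverted
once by the division-free Newton–Schulz iteration, and beta is updated

    beta <- beta + A^{-1} * sum_i (y_i - P(x_i, beta)) x_i

for a fixed number of steps (a secure convergence test would leak
progress).  A is the negated Hessian bound, so the update adds rather
than subtracts; since A dominates the true information matrix the steps
never overshoot, at the price of a linear (not quadratic) rate.

Per-record logits t_i = -beta' x_i are clamped to [-5, 5] before the
exponential (the logistic response is below 6.7e-3 outside, so little
accuracy is lost), e^t is an order-15 Taylor series evaluated in Horner
form with a plaintext lookup table of 1/1..1/15, and the final division
is the 1x1 Newton–Schulz reciprocal with public bound 150 > 1 + e^5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import fixedpoint as fx
from . import linalg as la
from .linalg import EmulationBackend, MpcBackend, SecureMatrix

CLAMP_BOUND = 5.0
TAYLOR_ORDER = 15
#: public bound for the logit denominator 1 + e^t, t in [-5, 5]
LOGIT_RECIP_BOUND = 150.0

#: reciprocals of 1..15 as wide fixed-point constants (nearest 2^-22),
#: the lookup table that turns the Horner divisions into multiplications
RECIP_TABLE = {k: round((1 << fx.WIDE_FRAC) / k) / (1 << fx.WIDE_FRAC)
               for k in range(1, TAYLOR_ORDER + 1)}


class SingularHessianError(RuntimeError):
    """Raised when the Newton–Schulz residual shows the pooled Hessian
    bound was not usefully inverted (rank-deficient or ill-conditioned)."""

    def __init__(self, residual: float):
        super().__init__(f"Hessian inversion residual {residual:.3g}; the "
                         "pooled X'X/4 appears singular or ill-conditioned")
        self.residual = residual


@dataclass
class PartyDataset:
    """One institution's horizontal slice: X (n_j x m, last column all ones)
    and binary outcomes y (length n_j)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be n x m with one y per row")
        if self.X.shape[0] == 0:
            raise ValueError("party dataset is empty")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("outcomes must be binary 0/1")
        if not np.all(self.X[:, -1] == 1.0):
            raise ValueError("last column of X must be the all-ones intercept")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class GloreConfig:
    """Fitting configuration; defaults reproduce the reference settings
    (28/11-bit encoding, order-15 Taylor, clamp at 5, 15 inversion steps)."""

    newton_iters: int = 10
    inv_iters: int = 15
    recip_iters: int = 15
    taylor_order: int = TAYLOR_ORDER
    clamp_bound: float = CLAMP_BOUND
    backend: str = "emulation"
    seed: int = 0
    trace_bound: Optional[float] = None
    check_residual: bool = True
    record_history: bool = False

    def __post_init__(self) -> None:
        for name in ("newton_iters", "inv_iters", "recip_iters", "taylor_order"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clamp_bound <= 0:
            raise ValueError("clamp_bound must be positive")
        if self.backend not in ("emulation", "mpc"):
            raise ValueError("backend must be 'emulation' or 'mpc'")


@dataclass
class FitResult:
    """Outcome of a secure fit.  ``beta`` is the only model quantity that
    leaves the secure computation."""

    beta: np.ndarray
    iterations: int
    counters: dict = field(default_factory=dict)
    history: Optional[list] = None


# ---------------------------------------------------------------------------
# algorithm pieces
# ---------------------------------------------------------------------------

def local_partial_hessian(X_j: np.ndarray) -> np.ndarray:
    """Party-local share of the fixed Hessian bound: -X_j' X_j / 4."""
    X_j = np.asarray(X_j, dtype=float)
    if X_j.size == 0:
        return np.zeros((X_j.shape[1], X_j.shape[1]))
    return -0.25 * (X_j.T @ X_j)


def aggregate_fixed_hessian(partials: List[SecureMatrix]) -> SecureMatrix:
    """Secure sum of the per-party partial Hessians."""
    if not partials:
        raise ValueError("no partial Hessians")
    acc = partials[0]
    for p in partials[1:]:
        acc = la.mat_add(acc, p)
    return acc


def clamp_exponent(t: SecureMatrix, bound: float = CLAMP_BOUND) -> SecureMatrix:
    """min(max(t, -bound), bound) on every entry."""
    return t.backend.clamp(t, -bound, bound)


def taylor_exp(u, order: int = TAYLOR_ORDER):
    """Order-``order`` Taylor approximation of e^u in Horner form:

        e^u ~= 1 + u(1 + u/2(1 + ... u/(order-1)(1 + u/order))),

    with the divisions taken from the plaintext reciprocal table.  Accepts
    a 28/11 :class:`SecureMatrix` (clamped entries) or a FixedWord/real;
    internally evaluates wide and truncates back.
    """
    if not isinstance(u, SecureMatrix):
        be = EmulationBackend(count_gates=False)
        word = u if isinstance(u, fx.FixedWord) else fx.encode(float(u))
        M = be.from_words(np.array([[word.bits]]))
        return fx.FixedWord(int(be.demote(_taylor_exp_wide(be.promote(M),
                                                           order)).data[0, 0]))
    be = u.backend
    return be.demote(_taylor_exp_wide(be.promote(u), order))


def _taylor_exp_wide(U: SecureMatrix, order: int) -> SecureMatrix:
    be = U.backend
    one = be.const(1.0, U.shape, fx.WIDE_WIDTH, fx.WIDE_FRAC)
    v = one
    for k in range(order, 0, -1):
        inv_k = be.const(RECIP_TABLE[k], U.shape, fx.WIDE_WIDTH, fx.WIDE_FRAC)
        v = be.add(one, be.mul_elem(be.mul_elem(U, inv_k), v))
    return v


def secure_logit(t, recip_iters: int = 15, order: int = TAYLOR_ORDER):
    """1 / (1 + e^t) for pre-clamped t (the logistic response is
    secure_logit(-beta'x)).  Same input conventions as :func:`taylor_exp`."""
    if not isinstance(t, SecureMatrix):
        be = EmulationBackend(count_gates=False)
        word = t if isinstance(t, fx.FixedWord) else fx.encode(float(t))
        M = be.from_words(np.array([[word.bits]]))
        return fx.FixedWord(int(_logit_mat(M, recip_iters, order).data[0, 0]))
    return _logit_mat(t, recip_iters, order)


def _logit_mat(t: SecureMatrix, recip_iters: int, order: int) -> SecureMatrix:
    be = t.backend
    U = be.promote(t)
    denom = be.add(be.const(1.0, t.shape, fx.WIDE_WIDTH, fx.WIDE_FRAC),
                   _taylor_exp_wide(U, order))
    return be.demote(la.reciprocal_wide(denom, recip_iters, LOGIT_RECIP_BOUND))


def secure_gradient(X: SecureMatrix, y: SecureMatrix, beta: SecureMatrix,
                    cfg: GloreConfig) -> SecureMatrix:
    """X' (y - P) with P = logit(-X beta), evaluated entirely in-circuit."""
    if X.cols != beta.rows or X.rows != y.rows:
        raise la.DimensionError(
            f"X is {X.shape}, y is {y.shape}, beta is {beta.shape}")
    be = X.backend
    t = be.neg(la.mat_mul_standard(X, beta))
    t = clamp_exponent(t, cfg.clamp_bound)
    P = _logit_mat(t, cfg.recip_iters, cfg.taylor_order)
    resid = la.mat_sub(y, P)
    return la.mat_mul_standard(be.transpose(X), resid)


def fit(parties: List[PartyDataset], cfg: Optional[GloreConfig] = None) -> FitResult:
    """Run the full secure fitting procedure and release only beta.

    Steps: each party locally forms its partial Hessian bound and feeds it
    (and its data block) as private input; the partials are aggregated and
    A = X'X/4 inverted once; then ``newton_iters`` fixed-Hessian updates of
    beta run with the secure gradient.  The decoded coefficient vector is
    the single reveal.
    """
    cfg = cfg if cfg is not None else GloreConfig()
    if len(parties) < 2:
        raise ValueError("need at least 2 parties")
    m = parties[0].m
    if any(p.m != m for p in parties):
        raise ValueError("parties disagree on the number of covariates")
    n_total = sum(p.n for p in parties)

    if cfg.backend == "mpc":
        be = MpcBackend(parties=len(parties), seed=cfg.seed)
    else:
        be = EmulationBackend(parties=len(parties))

    # line 1: local partial Hessians, fed as private inputs and aggregated
    partials = [be.input_matrix(-local_partial_hessian(p.X), owner=j)
                for j, p in enumerate(parties)]  # negated: A_j = +X_j'X_j/4
    A = aggregate_fixed_hessian(partials)

    # public bound on trace(A) = sum x_ij^2 / 4 for designs with |x| <= 1
    trace_bound = cfg.trace_bound
    if trace_bound is None:
        trace_bound = n_total * m / 4.0

    # line 2: secure inversion
    A_inv = la.mat_inverse(A, iters=cfg.inv_iters, c_bound=trace_bound,
                           recip_iters=cfg.recip_iters)
    if cfg.check_residual and isinstance(be, EmulationBackend):
        resid = np.max(np.abs(be._peek(A_inv) @ be._peek(A) - np.eye(m)))
        if resid > 0.05:
            raise SingularHessianError(float(resid))

    # lines 4-7: fixed-Hessian Newton updates
    X = be.concat_rows([be.input_matrix(p.X, owner=j)
                        for j, p in enumerate(parties)])
    y = be.concat_rows([be.input_matrix(p.y.reshape(-1, 1), owner=j)
                        for j, p in enumerate(parties)])
    beta = be.const(0.0, (m, 1))
    history = [] if cfg.record_history else None
    for _ in range(cfg.newton_iters):
        g = secure_gradient(X, y, beta, cfg)
        beta = la.mat_add(beta, la.mat_mul_standard(A_inv, g))
        if history is not None and isinstance(be, EmulationBackend):
            history.append(be._peek(beta).ravel().copy())

    released = be.reveal(beta).ravel()
    counters = {
        "and_gates": be.transcript.and_gates,
        "ot_invocations": be.transcript.ot_invocations,
        "reveals": be.transcript.reveals,
    }
    return FitResult(beta=released, iterations=cfg.newton_iters,
                     counters=counters, history=history)
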