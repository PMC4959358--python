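"""Secure matrix primitives: addition, Strassen multiplication, and the
division-free Newton-Schulz inversion, in emulation and under MPC."""

import numpy as np
import pytest

from smacglore import fixedpoint as fx
from smacglore import linalg as la


@pytest.fixture
def be():
    return la.EmulationBackend()


def test_mat_add_gate_accounting(be, rng):
    A = be.input_matrix(rng.uniform(-3, 3, (2, 2)))
    before = be.transcript.and_gates
    la.mat_add(A, A)
    assert be.transcript.and_gates - before == 108  # 2x2: 4 adders x 27


def test_mat_add_identity_and_oracle(be, rng):
    vals = rng.uniform(-100, 100, (4, 4))
    A = be.input_matrix(vals)
    Z = be.input_matrix(np.zeros((4, 4)))
    np.testing.assert_array_equal(la.mat_add(A, Z).data, A.data)
    # encoded sum is exact when both operands are on the 2^-11 grid
    got = be._peek(la.mat_add(A, A))
    np.testing.assert_array_equal(got, 2 * be._peek(A))


def test_mat_sub(be, rng):
    A = be.input_matrix(rng.uniform(-50, 50, (3, 3)))
    B = be.input_matrix(rng.uniform(-50, 50, (3, 3)))
    np.testing.assert_array_equal(la.mat_sub(A, A).data, 0)
    np.testing.assert_array_equal(
        la.mat_sub(la.mat_add(A, B), B).data, A.data)


def test_scalar_case_matches_word_ops(be, rng):
    a, b = 3.25, -1.75
    A, B = be.input_matrix([[a]]), be.input_matrix([[b]])
    assert be._peek(la.mat_sub(A, B))[0, 0] == a - b
    got = be._peek(be.mul_elem(A, B))[0, 0]
    assert got == fx.decode(fx.multiply(fx.encode(a), fx.encode(b)))


def test_dimension_mismatch_errors(be):
    A = be.input_matrix(np.zeros((2, 3)))
    B = be.input_matrix(np.zeros((3, 3)))
    with pytest.raises(la.DimensionError):
        la.mat_add(A, B)
    with pytest.raises(la.DimensionError):
        la.mat_mul_standard(B, A)
    with pytest.raises(la.DimensionError):
        la.mat_mul_strassen(A, B)


def test_matmul_identity_exact(be, rng):
    A = be.input_matrix(rng.uniform(-5, 5, (4, 4)))
    I = be.input_matrix(np.eye(4))
    np.testing.assert_array_equal(la.mat_mul_standard(I, A).data, A.data)
    np.testing.assert_array_equal(la.mat_mul_strassen(I, A).data, A.data)


def test_matmul_error_bound_vs_real(be, rng):
    A = rng.uniform(-3, 3, (3, 3))
    B = rng.uniform(-3, 3, (3, 3))
    got = be._peek(la.mat_mul_standard(be.input_matrix(A), be.input_matrix(B)))
    # operands are floored to the grid, then one truncation per entry
    Aq = fx.decode_array(fx.encode_array(A))
    Bq = fx.decode_array(fx.encode_array(B))
    assert np.max(np.abs(got - Aq @ Bq)) <= 3 * 2**-11


def test_strassen_block_count_and_agreement(be, rng):
    A = be.input_matrix(rng.uniform(-3, 3, (4, 4)))
    B = be.input_matrix(rng.uniform(-3, 3, (4, 4)))
    stats = {}
    got = la.mat_mul_strassen(A, B, stats)
    assert stats["block_multiplications"] == 7
    np.testing.assert_array_equal(got.data, la.mat_mul_standard(A, B).data)


@pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
def test_strassen_standard_agreement_sizes(be, rng, n):
    for _ in range(3):
        A = be.input_matrix(rng.uniform(-4, 4, (n, n)))
        B = be.input_matrix(rng.uniform(-4, 4, (n, n)))
        np.testing.assert_array_equal(la.mat_mul_strassen(A, B).data,
                                      la.mat_mul_standard(A, B).data)


@pytest.mark.parametrize("a, want", [(1.0, 1.0), (2.0, 0.5)])
def test_scalar_reciprocal_simple(a, want):
    assert abs(la.scalar_reciprocal(a).value - want) <= 2**-11


def test_scalar_reciprocal_logit_boundary():
    # 1/(1 + e^5): the denominator at the clamp boundary
    got = la.scalar_reciprocal(149.4130859375)
    assert abs(got.value - 0.006693) <= 2**-11


def test_inverse_identity_fixed_point(be):
    inv = la.mat_inverse(be.input_matrix(np.eye(3)), c_bound=4.0)
    assert np.max(np.abs(be._peek(inv) - np.eye(3))) <= 2**-11


def test_inverse_diagonal_closed_form(be):
    inv = la.mat_inverse(be.input_matrix(np.diag([2.0, 2.0])), c_bound=4.0)
    assert np.max(np.abs(be._peek(inv) - np.diag([0.5, 0.5]))) <= 2**-11


def test_inverse_uses_seven_block_products_per_multiplication(be):
    stats = {}
    la.mat_inverse(be.input_matrix(np.diag([2.0, 3.0])), iters=4,
                   c_bound=8.0, stats=stats)
    # two Strassen multiplications per iteration
    assert stats["block_multiplications"] == 7 * 2 * 4


def test_inverse_explicit_constant(be):
    inv = la.mat_inverse(be.input_matrix(np.diag([2.0, 2.0])), c=4.0)
    assert np.max(np.abs(be._peek(inv) - np.diag([0.5, 0.5]))) <= 2**-11


def test_residual_decay_monotone(be, rng):
    """|| N_t A - I ||_F decreases monotonically until the quantisation
    floor (double-precision shadow of the fixed-point iterates)."""
    X = rng.integers(0, 2, (60, 4)).astype(float)
    X[:, -1] = 1.0
    Aq = 0.25 * X.T @ X
    A = be.input_matrix(Aq)
    Adec = be._peek(A)
    prev = np.inf
    floor_hit = False
    for iters in range(1, 13):
        N = be._peek(la.mat_inverse(A, iters=iters, c_bound=60.0))
        r = np.linalg.norm(N @ Adec - np.eye(4))
        if floor_hit or r < 0.05:  # quantisation floor ~ m * 2^-11 * ||A||
            floor_hit = True
        else:
            assert r <= prev + 1e-12
        prev = r
    assert prev < 0.05  # converged to the floor


def test_inversion_mse_on_synthetic_hessians(be, rng):
    for m in (2, 5, 8):
        X = rng.integers(0, 2, (60, m)).astype(float)
        X[:, -1] = 1.0
        Aq = 0.25 * X.T @ X
        A = be.input_matrix(Aq)
        inv = be._peek(la.mat_inverse(A, c_bound=60 * m / 4))
        exact = np.linalg.inv(be._peek(A))
        assert np.mean((inv - exact) ** 2) <= 1e-5


def test_nonsquare_inverse_rejected(be):
    with pytest.raises(la.DimensionError):
        la.mat_inverse(be.input_matrix(np.zeros((2, 3))))


def test_trace(be):
    A = be.input_matrix(np.diag([1.5, 2.5, 3.0]))
    assert be._peek(la.trace(A))[0, 0] == 7.0


# ---------------------------------------------------------------------------
# MPC backend: every primitive agrees with emulation bit for bit
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("h", [2, 3])
def test_mpc_primitives_match_emulation(h, rng):
    em = la.EmulationBackend(count_gates=False)
    mp = la.MpcBackend(parties=h, seed=h)
    A = rng.uniform(-2, 2, (2, 2))
    B = rng.uniform(-2, 2, (2, 2))
    EA, EB = em.input_matrix(A), em.input_matrix(B)
    SA, SB = mp.input_matrix(A), mp.input_matrix(B)
    pairs = [
        (la.mat_add(EA, EB), la.mat_add(SA, SB)),
        (la.mat_sub(EA, EB), la.mat_sub(SA, SB)),
        (em.mul_elem(EA, EB), mp.mul_elem(SA, SB)),
        (la.mat_mul_standard(EA, EB), la.mat_mul_standard(SA, SB)),
        (la.mat_mul_strassen(EA, EB), la.mat_mul_strassen(SA, SB)),
        (em.clamp(EA, -1.0, 1.0), mp.clamp(SA, -1.0, 1.0)),
        (em.neg(EA), mp.neg(SA)),
    ]
    for expected, got in pairs:
        np.testing.assert_array_equal(mp.reveal(got), em._peek(expected))


def test_mpc_inversion_matches_emulation(rng):
    X = rng.integers(0, 2, (20, 2)).astype(float)
    X[:, -1] = 1.0
    Aq = 0.25 * X.T @ X
    em = la.EmulationBackend(count_gates=False)
    mp = la.MpcBackend(parties=2, seed=9)
    want = em._peek(la.mat_inverse(em.input_matrix(Aq), iters=6,
                                   c_bound=16.0, recip_iters=10))
    got = mp.reveal(la.mat_inverse(mp.input_matrix(Aq), iters=6,
                                   c_bound=16.0, recip_iters=10))
    np.testing.assert_array_equal(got, want)


def test_mpc_requires_public_trace_bound(rng):
    mp = la.MpcBackend(parties=2, seed=0)
    A = mp.input_matrix(np.diag([2.0, 2.0]))
    with pytest.raises(ValueError, match="c_bound"):
        la.mat_inverse(A, iters=2)
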