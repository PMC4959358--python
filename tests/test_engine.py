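"""Secret-sharing engine: share algebra, oblivious transfer, and the
engine-equivalence oracle (MPC reconstruction == plaintext evaluation)."""

import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from smacglore import circuits as cc
from smacglore import engine as eng
from smacglore import fixedpoint as fx

MOD = 1 << 28


def _single_and_circuit():
    c = cc.Circuit(n_wires=3, gates=[("AND", 0, 1, 2)],
                   input_groups={"a": [0], "b": [1]},
                   output_groups={"out": [2]})
    return c


@pytest.mark.parametrize("h", [2, 3, 4])
def test_share_reconstruct_round_trip(h, rng):
    bits = rng.integers(0, 2, 256, dtype=np.uint8)
    st_ = eng.share_bits(bits, h, rng)
    np.testing.assert_array_equal(eng.reconstruct(st_), bits)
    assert st_.party_shares.shape == (h, 256)


def test_share_requires_two_parties(rng):
    with pytest.raises(ValueError):
        eng.share_bits(np.array([1]), 1, rng)


def test_reconstruct_all_zero_shares():
    assert eng.reconstruct(eng.ShareTensor(np.zeros((3, 5), np.uint8))).sum() == 0


def test_flipped_share_flips_plaintext(rng):
    bits = rng.integers(0, 2, 64, dtype=np.uint8)
    st_ = eng.share_bits(bits, 3, rng)
    st_.party_shares[1, 10] ^= 1
    rec = eng.reconstruct(st_)
    assert rec[10] == bits[10] ^ 1
    np.testing.assert_array_equal(np.delete(rec, 10), np.delete(bits, 10))


def test_all_share_assignments_occur_h3():
    """For h=3 the first two shares of a single bit are free: all 4
    combinations must appear across seeds."""
    seen = set()
    for seed in range(1000):
        rng = np.random.default_rng(seed)
        s = eng.share_bits(np.array([1], np.uint8), 3, rng).party_shares
        seen.add((int(s[0, 0]), int(s[1, 0])))
        if len(seen) == 4:
            break
    assert seen == {(0, 0), (0, 1), (1, 0), (1, 1)}


def test_ot4_contract():
    ot = eng.SimulatedOT()
    msgs = [b"m0", b"m1", b"m2", b"m3"]
    assert ot.ot4(msgs, 2) == b"m2"
    assert [ot.ot4(msgs, i) for i in range(4)] == msgs
    assert ot.calls == 5
    with pytest.raises(ValueError):
        ot.ot4(msgs, 4)
    with pytest.raises(ValueError):
        ot.ot4(msgs[:3], 0)
    with pytest.raises(ValueError):
        ot.ot4([b"x", b"yy", b"x", b"x"], 0)


def test_and_gate_exhaustive_all_sharings_h2():
    """AND under MPC equals its truth table for all 4 plaintext pairs and
    many share randomisations."""
    circ = _single_and_circuit()
    for a in (0, 1):
        for b in (0, 1):
            for seed in range(16):
                out = eng.eval_circuit_mpc(
                    circ, {"a": (0, a), "b": (1, b)}, 2,
                    rng=random.Random(seed))
                assert out["out"] == (a & b), (a, b, seed)


def test_and_cross_terms_match_direct_products():
    """Cross terms through 1-of-4 OT reproduce a_i * b_j exhaustively."""
    ot = eng.SimulatedOT()
    mask = 1
    for ai in (0, 1):
        for bj in (0, 1):
            for aj in (0, 1):  # receiver's own a-share must not matter
                r = 1
                t = ot.ot4_packed(r, r, r ^ ai, r ^ ai, bj, aj, mask, 1)
                assert r ^ t == (ai & bj)


@pytest.mark.parametrize("h", [2, 3, 4])
def test_adder_mpc_matches_plaintext(h, rng):
    add = cc.build_adder(28)
    a = rng.integers(0, MOD, 16)
    b = rng.integers(0, MOD, 16)
    plain = cc.eval_plain(add, {"a": a, "b": b})["sum"]
    res = eng.eval_circuit_mpc(add, {"a": (0, a), "b": (h - 1, b)}, h,
                               rng=random.Random(7))
    np.testing.assert_array_equal(res["sum"], plain)


def test_small_adder_mpc_exhaustive():
    """Engine equivalence, exhaustive over all inputs of a 4-bit adder."""
    add = cc.build_adder(4)
    a = np.repeat(np.arange(16), 16)
    b = np.tile(np.arange(16), 16)
    res = eng.eval_circuit_mpc(add, {"a": (0, a), "b": (1, b)}, 2,
                               rng=random.Random(3))
    np.testing.assert_array_equal(res["sum"], (a + b) % 16)


def test_fixed_multiplier_mpc_randomised(rng):
    """28-bit fixed-point multiplication under MPC: randomized engine
    equivalence against both the plaintext evaluator and word semantics."""
    fm = cc.build_fixed_multiplier(28, 11)
    a = rng.integers(0, MOD, 8)
    b = rng.integers(0, MOD, 8)
    plain = np.asarray(cc.eval_plain(fm, {"a": a, "b": b})["prod"])
    for h in (2, 3):
        res = eng.eval_circuit_mpc(fm, {"a": (0, a), "b": (1, b)}, h,
                                   rng=random.Random(h))
        np.testing.assert_array_equal(res["prod"], plain)
    np.testing.assert_array_equal(plain, fx.mul_words(a, b))


def test_clamp_mpc(rng):
    cl = cc.build_clamp(28, -5.0, 5.0)
    x = rng.integers(0, MOD, 32)
    plain = cc.eval_plain(cl, {"x": x})["clamped"]
    res = eng.eval_circuit_mpc(cl, {"x": (0, x)}, 2, rng=random.Random(1))
    np.testing.assert_array_equal(res["clamped"], plain)


def test_determinism_under_fixed_seeds(rng):
    add = cc.build_adder(28)
    a = rng.integers(0, MOD, 4)
    b = rng.integers(0, MOD, 4)
    runs = []
    for _ in range(2):
        ot = eng.SimulatedOT()
        tr = eng.Transcript()
        res = eng.eval_circuit_mpc(add, {"a": (0, a), "b": (1, b)}, 2,
                                   ot=ot, rng=random.Random(99), transcript=tr)
        runs.append((tuple(res["sum"]), ot.calls, tr.and_gates,
                     tr.ot_invocations))
    assert runs[0] == runs[1]
    assert runs[0][2] == 27  # one AND per carry
    assert runs[0][3] == 27 * 2  # h(h-1) OTs per AND


def test_share_marginals_indistinguishable():
    """A single party's share is ~Bernoulli(1/2) whether the secret bit is
    0 or 1 (chi-square over 10^4 seeded sharings)."""
    counts = {}
    for bit in (0, 1):
        rng = np.random.default_rng(777 + bit)
        shares = eng.share_bits(np.full(10_000, bit, np.uint8), 2, rng)
        counts[bit] = int(shares.party_shares[1].sum())
    table = np.array([[counts[0], 10_000 - counts[0]],
                      [counts[1], 10_000 - counts[1]]])
    _, p, _, _ = sps.chi2_contingency(table)
    assert p > 1e-3


def test_unassigned_input_group_rejected():
    add = cc.build_adder(4)
    with pytest.raises(ValueError, match="unassigned"):
        eng.eval_circuit_mpc(add, {"a": (0, 1)}, 2, rng=random.Random(0))
    with pytest.raises(ValueError, match="owner"):
        eng.eval_circuit_mpc(add, {"a": (0, 1), "b": (5, 1)}, 2,
                             rng=random.Random(0))


@given(st.integers(0, MOD - 1), st.integers(0, MOD - 1),
       st.integers(0, 2**32 - 1))
def test_xor_linearity_of_sharing(a, b, seed):
    """share(a) XOR share(b) reconstructs to a XOR b (XOR-linearity)."""
    rng = np.random.default_rng(seed)
    bits_a = np.array([(a >> k) & 1 for k in range(28)], np.uint8)
    bits_b = np.array([(b >> k) & 1 for k in range(28)], np.uint8)
    sa = eng.share_bits(bits_a, 3, rng).party_shares
    sb = eng.share_bits(bits_b, 3, rng).party_shares
    rec = eng.reconstruct(eng.ShareTensor(sa ^ sb))
    np.testing.assert_array_equal(rec, bits_a ^ bits_b)
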