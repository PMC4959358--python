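"""Secure matrix primitives composed from fixed-point arithmetic circuits.

A :class:`SecureMatrix` holds the raw fixed-point words of a matrix under
one of two interchangeable backends:

* :class:`EmulationBackend` — plaintext fixed-point emulation.  Words are
  int64 arrays and every operation reproduces the corresponding circuit's
  output bit for bit (int64 wraps mod 2^64 and the low ``width`` bits of
  sums/products survive the wrap).  This is the fast path; it is what the
  published accuracy numbers are computed with.
* :class:`MpcBackend` — words exist only as per-party XOR share bits, and
  every arithmetic operation is an actual circuit evaluation through
  :mod:`smacglore.engine`.  Structural operations (transpose, slicing,
  sign extension, shifts by the fractional width) rearrange share planes
  and are free, like XOR gates.

The two backends are exchangeable by construction; the test suite pins
their bit-exact agreement on every primitive, which is what licenses
running the full pipeline in emulation.

Matrix multiplication follows the widen-accumulate-truncate discipline:
entry products are formed on sign-extended words, accumulated at 56 bits,
and truncated once.  One-level Strassen splits a (padded) even-sized
matrix into 2x2 blocks, forms the seven block products M1..M7 from sums
and differences of blocks, and recombines — the block sums, products and
recombination all stay in the 56-bit container with a single truncation
at the very end, so Strassen agrees with the standard product bit-exactly
whenever nothing overflows the container.

Matrix inversion is the division-free Newton–Schulz iteration

    N_{t+1} = 2 N_t - N_t M_t,   N_0 = c^{-1} I,
    M_{t+1} = 2 M_t - M_t^2,     M_0 = c^{-1} A,

which converges to A^{-1} for symmetric positive definite A once the
spectrum of M_0 lies in (0, 1); the constant c defaults to trace(A),
computed inside the computation, which guarantees that.  The iteration
(and the 1x1 specialisation used for reciprocals) runs in the wide
56-bit / 22-fractional-bit format and truncates to 28/11 on the way out:
at 11 fractional bits the initial step c^{-1} quantises too coarsely for
the contraction to reach the published accuracy.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import circuits as cc
from . import fixedpoint as fx
from .engine import SimulatedOT, Transcript, evaluate_shares

WIDTH, FRAC = fx.WIDTH, fx.FRAC
WIDE, WFRAC = fx.WIDE_WIDTH, fx.WIDE_FRAC


class DimensionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# shared circuit cache (also used for gate accounting)
# ---------------------------------------------------------------------------

_CIRCUITS: dict = {}


def get_circuit(key) -> cc.Circuit:
    if key not in _CIRCUITS:
        kind = key[0]
        if kind == "adder":
            _CIRCUITS[key] = cc.build_adder(key[1])
        elif kind == "sub":
            _CIRCUITS[key] = cc.build_subtractor(key[1])
        elif kind == "neg":
            _CIRCUITS[key] = cc.build_negator(key[1])
        elif kind == "fixedmul":
            _CIRCUITS[key] = cc.build_fixed_multiplier(key[1], key[2])
        elif kind == "dot":
            _, k, w, f, acc, raw = key
            _CIRCUITS[key] = cc.build_dot(k, w, f, acc, raw)
        elif kind == "clamp":
            _, w, lo_bits, hi_bits, f = key
            _CIRCUITS[key] = cc.build_clamp(
                w, fx.FixedWord(lo_bits, w, f), fx.FixedWord(hi_bits, w, f), f)
        else:
            raise KeyError(key)
    return _CIRCUITS[key]


def _mul_ands(ext: int) -> int:
    # schoolbook low-half: ext(ext+1)/2 partial-product ANDs plus the
    # ripple accumulation's (ext-1)(ext-2)/2
    return ext * (ext + 1) // 2 + (ext - 1) * (ext - 2) // 2


def and_count(key) -> int:
    """Closed-form AND count of :func:`get_circuit`'s output (used for gate
    accounting without building the circuit; pinned against the built
    circuits in the test suite)."""
    kind = key[0]
    if kind in ("adder", "sub"):
        return key[1] - 1
    if kind == "neg":
        return key[1] - 2
    if kind == "fixedmul":
        return _mul_ands(key[1] + key[2])
    if kind == "dot":
        _, k, w, f, acc, raw = key
        return k * _mul_ands(acc) + (k - 1) * (acc - 1)
    if kind == "clamp":
        return 4 * key[1]
    raise KeyError(key)


@dataclass
class SecureMatrix:
    """Fixed-point matrix whose entries live inside a secure computation.

    ``data`` is backend-specific: an int64 word array (rows, cols) under
    emulation, a uint8 share-bit array (h, rows, cols, width) under MPC.
    """

    rows: int
    cols: int
    width: int
    frac: int
    backend: "EmulationBackend | MpcBackend"
    data: np.ndarray

    @property
    def shape(self):
        return (self.rows, self.cols)

    def _like(self, data, width=None, frac=None, rows=None, cols=None):
        return SecureMatrix(
            rows if rows is not None else self.rows,
            cols if cols is not None else self.cols,
            width if width is not None else self.width,
            frac if frac is not None else self.frac,
            self.backend, data)


def _conform(A: SecureMatrix, B: SecureMatrix) -> None:
    if A.shape != B.shape or A.width != B.width:
        raise DimensionError(f"shape/width mismatch: {A.shape}/{A.width} "
                             f"vs {B.shape}/{B.width}")
    if A.backend is not B.backend:
        raise DimensionError("operands belong to different backends")


class EmulationBackend:
    """Plaintext fixed-point emulation, bit-exact to the circuits.

    Gate accounting mirrors what the secret-sharing engine would execute:
    each arithmetic call adds the AND count of the corresponding circuit
    (times the batch size) to ``transcript.and_gates``.
    """

    name = "emulation"

    def __init__(self, count_gates: bool = True, parties: int = 2) -> None:
        self.count_gates = count_gates
        self.parties = parties
        self.transcript = Transcript()

    # -- bookkeeping -------------------------------------------------------
    def _account(self, key, batch: int) -> None:
        if self.count_gates:
            n_and = and_count(key) * batch
            self.transcript.and_gates += n_and
            self.transcript.ot_invocations += n_and * self.parties * (self.parties - 1)

    # -- I/O ---------------------------------------------------------------
    def input_matrix(self, values, width: int = WIDTH, frac: int = FRAC,
                     owner: int = 0) -> SecureMatrix:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        words = fx.encode_array(values, width, frac)
        return SecureMatrix(values.shape[0], values.shape[1], width, frac,
                            self, words)

    def from_words(self, words, width: int = WIDTH, frac: int = FRAC) -> SecureMatrix:
        words = np.atleast_2d(np.asarray(words, dtype=np.int64))
        return SecureMatrix(words.shape[0], words.shape[1], width, frac,
                            self, words)

    def const(self, values, shape, width: int = WIDTH, frac: int = FRAC) -> SecureMatrix:
        vals = np.broadcast_to(np.asarray(values, dtype=float), shape)
        return self.input_matrix(vals, width, frac)

    def reveal(self, M: SecureMatrix) -> np.ndarray:
        """Decode to reals.  The only sanctioned exit from the computation."""
        self.transcript.reveals += 1
        return fx.decode_array(M.data, M.width, M.frac)

    def _peek(self, M: SecureMatrix) -> np.ndarray:
        """Diagnostic decode that is NOT available under MPC; used only for
        convergence checks on the emulation path."""
        return fx.decode_array(M.data, M.width, M.frac)

    # -- arithmetic --------------------------------------------------------
    def add(self, A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
        _conform(A, B)
        self._account(("adder", A.width), A.rows * A.cols)
        return A._like(fx.add_words(A.data, B.data, A.width))

    def sub(self, A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
        _conform(A, B)
        self._account(("sub", A.width), A.rows * A.cols)
        return A._like(fx.sub_words(A.data, B.data, A.width))

    def neg(self, A: SecureMatrix) -> SecureMatrix:
        self._account(("neg", A.width), A.rows * A.cols)
        return A._like(fx.neg_words(A.data, A.width))

    def mul_elem(self, A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
        _conform(A, B)
        self._account(("fixedmul", A.width, A.frac), A.rows * A.cols)
        return A._like(fx.mul_words(A.data, B.data, A.width, A.frac))

    def matmul(self, A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
        if A.cols != B.rows:
            raise DimensionError(f"inner dimensions {A.cols} != {B.rows}")
        if A.width != WIDTH:
            raise DimensionError("matmul operates on 28-bit matrices")
        self._account(("dot", A.cols, WIDTH, FRAC, WIDE, False),
                      A.rows * B.cols)
        acc = np.einsum("ik,kj->ij", fx.to_signed(A.data, WIDTH),
                        fx.to_signed(B.data, WIDTH)) % (np.int64(1) << WIDE)
        out = (fx.to_signed(acc, WIDE) >> FRAC) % (np.int64(1) << WIDTH)
        return A._like(out, rows=A.rows, cols=B.cols)

    def raw_matmul(self, A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
        """Wide block product without truncation (Strassen internal)."""
        if A.cols != B.rows or A.width != WIDE:
            raise DimensionError("raw_matmul expects conforming wide matrices")
        self._account(("dot", A.cols, WIDE, 0, WIDE, True), A.rows * B.cols)
        acc = np.einsum("ik,kj->ij", fx.to_signed(A.data, WIDE),
                        fx.to_signed(B.data, WIDE)) % (np.int64(1) << WIDE)
        return A._like(acc, rows=A.rows, cols=B.cols)

    def clamp(self, A: SecureMatrix, lo: float, hi: float) -> SecureMatrix:
        lo_b = fx.encode(lo, A.width, A.frac).bits
        hi_b = fx.encode(hi, A.width, A.frac).bits
        self._account(("clamp", A.width, lo_b, hi_b, A.frac), A.rows * A.cols)
        return A._like(fx.clamp_words(A.data, lo, hi, A.width, A.frac))

    # -- structural (free) -------------------------------------------------
    def transpose(self, A: SecureMatrix) -> SecureMatrix:
        return A._like(A.data.T.copy(), rows=A.cols, cols=A.rows)

    def submatrix(self, A: SecureMatrix, r0, r1, c0, c1) -> SecureMatrix:
        return A._like(A.data[r0:r1, c0:c1].copy(), rows=r1 - r0, cols=c1 - c0)

    def pad(self, A: SecureMatrix, rows: int, cols: int) -> SecureMatrix:
        out = np.zeros((rows, cols), dtype=np.int64)
        out[:A.rows, :A.cols] = A.data
        return A._like(out, rows=rows, cols=cols)

    def concat_rows(self, mats) -> SecureMatrix:
        top = mats[0]
        data = np.concatenate([m.data for m in mats], axis=0)
        return top._like(data, rows=data.shape[0])

    def diag_embed(self, s: SecureMatrix, m: int) -> SecureMatrix:
        """m x m matrix with the 1x1 entry of ``s`` on the diagonal."""
        out = np.zeros((m, m), dtype=np.int64)
        out[np.arange(m), np.arange(m)] = s.data[0, 0]
        return s._like(out, rows=m, cols=m)

    def broadcast_scalar(self, s: SecureMatrix, shape) -> SecureMatrix:
        out = np.full(shape, s.data[0, 0], dtype=np.int64)
        return s._like(out, rows=shape[0], cols=shape[1])

    def ext_to_wide(self, A: SecureMatrix) -> SecureMatrix:
        """Sign-extend 28-bit words into the 56-bit container (value kept)."""
        return A._like(fx.to_signed(A.data, A.width) % (np.int64(1) << WIDE),
                       width=WIDE)

    def promote(self, A: SecureMatrix) -> SecureMatrix:
        """28/11 -> 56/22 (exact left shift by 11)."""
        return A._like(fx.promote_words(A.data), width=WIDE, frac=WFRAC)

    def demote(self, A: SecureMatrix) -> SecureMatrix:
        """56/22 -> 28/11 (arithmetic right shift by 11)."""
        return A._like(fx.demote_words(A.data), width=WIDTH, frac=FRAC)

    def shift_trunc(self, A: SecureMatrix, shift: int, out_width: int,
                    out_frac: int) -> SecureMatrix:
        """Arithmetic right shift then keep the low ``out_width`` bits."""
        out = (fx.to_signed(A.data, A.width) >> shift) % (np.int64(1) << out_width)
        return A._like(out, width=out_width, frac=out_frac)


class MpcBackend:
    """Backend in which every word exists only as per-party XOR share bits.

    ``data`` layout: uint8 array of shape (h, rows, cols, width).  All
    arithmetic routes through :func:`smacglore.engine.evaluate_shares`;
    nothing is reconstructed except through :meth:`reveal`, which is
    counted on the transcript (the privacy surface of a fit is exactly
    one reveal: the final coefficient vector).
    """

    name = "mpc"

    def __init__(self, parties: int = 2, seed: int = 0,
                 ot: Optional[SimulatedOT] = None) -> None:
        if parties < 2:
            raise ValueError("need at least 2 parties")
        self.parties = parties
        self.rng = random.Random(seed)
        self.ot = ot if ot is not None else SimulatedOT()
        self.transcript = Transcript()

    # -- share packing -----------------------------------------------------
    def _pack_group(self, data: np.ndarray):
        """(h, batch, width) share bits -> engine layout (per wire, per party)."""
        h, batch, width = data.shape
        out = []
        for k in range(width):
            per_party = []
            for p in range(h):
                per_party.append(int.from_bytes(
                    np.packbits(data[p, :, k], bitorder="little").tobytes(),
                    "little"))
            out.append(per_party)
        return out

    def _unpack_group(self, layout, batch: int) -> np.ndarray:
        width = len(layout)
        h = len(layout[0])
        nbytes = (batch + 7) // 8
        out = np.zeros((h, batch, width), dtype=np.uint8)
        for k in range(width):
            for p in range(h):
                raw = np.frombuffer(layout[k][p].to_bytes(nbytes, "little"),
                                    dtype=np.uint8)
                out[p, :, k] = np.unpackbits(raw, bitorder="little")[:batch]
        return out

    def _run(self, key, groups: dict, batch: int, out_name: str,
             out_width: int) -> np.ndarray:
        circ = get_circuit(key)
        shares = {name: self._pack_group(arr) for name, arr in groups.items()}
        res = evaluate_shares(circ, shares, self.parties, self.ot, self.rng,
                              batch, self.transcript)
        return self._unpack_group(res[out_name], batch)

    def _flat(self, A: SecureMatrix) -> np.ndarray:
        return A.data.reshape(self.parties, A.rows * A.cols, A.width)

    def _unflat(self, arr: np.ndarray, like: SecureMatrix, rows=None, cols=None,
                width=None, frac=None) -> SecureMatrix:
        rows = rows if rows is not None else like.rows
        cols = cols if cols is not None else like.cols
        width = width if width is not None else like.width
        return SecureMatrix(rows, cols, width,
                            frac if frac is not None else like.frac,
                            self, arr.reshape(self.parties, rows, cols, width))

    # -- I/O ---------------------------------------------------------------
    def input_matrix(self, values, width: int = WIDTH, frac: int = FRAC,
                     owner: int = 0) -> SecureMatrix:
        """Encode a party's plaintext and share every bit to all parties."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        words = fx.encode_array(values, width, frac)
        h = self.parties
        bits = ((words[..., None] >> np.arange(width)) & 1).astype(np.uint8)
        data = np.zeros((h,) + bits.shape, dtype=np.uint8)
        acc = np.zeros_like(bits)
        for p in range(h - 1):
            r = np.frombuffer(
                bytes(self.rng.getrandbits(8) for _ in range(bits.size)),
                dtype=np.uint8).reshape(bits.shape) & 1
            data[p] = r
            acc ^= r
        data[h - 1] = acc ^ bits
        return SecureMatrix(values.shape[0], values.shape[1], width, frac,
                            self, data)

    def const(self, values, shape, width: int = WIDTH, frac: int = FRAC) -> SecureMatrix:
        """Public constant: party 0 holds the bits, other shares are zero."""
        vals = np.broadcast_to(np.asarray(values, dtype=float), shape)
        words = fx.encode_array(vals, width, frac)
        bits = ((words[..., None] >> np.arange(width)) & 1).astype(np.uint8)
        data = np.zeros((self.parties,) + bits.shape, dtype=np.uint8)
        data[0] = bits
        return SecureMatrix(shape[0], shape[1], width, frac, self, data)

    def reveal(self, M: SecureMatrix) -> np.ndarray:
        self.transcript.reveals += 1
        bits = np.bitwise_xor.reduce(M.data, axis=0).astype(np.int64)
        words = (bits << np.arange(M.width)).sum(axis=-1)
        return fx.decode_array(words, M.width, M.frac)

    # -- arithmetic (circuit evaluations) ------------------------------------
    def _binop(self, key, A: SecureMatrix, B: SecureMatrix, out_name: str,
               ga: str = "a", gb: str = "b") -> SecureMatrix:
        _conform(A, B)
        batch = A.rows * A.cols
        out = self._run(key, {ga: self._flat(A), gb: self._flat(B)}, batch,
                        out_name, A.width)
        return self._unflat(out, A)

    def add(self, A, B):
        return self._binop(("adder", A.width), A, B, "sum")

    def sub(self, A, B):
        return self._binop(("sub", A.width), A, B, "diff")

    def neg(self, A: SecureMatrix) -> SecureMatrix:
        batch = A.rows * A.cols
        out = self._run(("neg", A.width), {"a": self._flat(A)}, batch,
                        "neg", A.width)
        return self._unflat(out, A)

    def mul_elem(self, A, B):
        return self._binop(("fixedmul", A.width, A.frac), A, B, "prod")

    def _matmul(self, A: SecureMatrix, B: SecureMatrix, key,
                out_width: int) -> np.ndarray:
        if A.cols != B.rows:
            raise DimensionError(f"inner dimensions {A.cols} != {B.rows}")
        k = A.cols
        ii, jj = np.meshgrid(np.arange(A.rows), np.arange(B.cols), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
        groups = {}
        for t in range(k):
            groups[f"a{t}"] = A.data[:, ii, t, :]
            groups[f"b{t}"] = B.data[:, t, jj, :]
        return self._run(key, groups, ii.size, "dot", out_width)

    def matmul(self, A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
        if A.width != WIDTH:
            raise DimensionError("matmul operates on 28-bit matrices")
        out = self._matmul(A, B, ("dot", A.cols, WIDTH, FRAC, WIDE, False), WIDTH)
        return self._unflat(out, A, rows=A.rows, cols=B.cols)

    def raw_matmul(self, A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
        if A.width != WIDE:
            raise DimensionError("raw_matmul expects wide matrices")
        out = self._matmul(A, B, ("dot", A.cols, WIDE, 0, WIDE, True), WIDE)
        return self._unflat(out, A, rows=A.rows, cols=B.cols)

    def clamp(self, A: SecureMatrix, lo: float, hi: float) -> SecureMatrix:
        lo_b = fx.encode(lo, A.width, A.frac).bits
        hi_b = fx.encode(hi, A.width, A.frac).bits
        batch = A.rows * A.cols
        out = self._run(("clamp", A.width, lo_b, hi_b, A.frac),
                        {"x": self._flat(A)}, batch, "clamped", A.width)
        return self._unflat(out, A)

    # -- structural (share-plane rearrangements, no interaction) -------------
    def transpose(self, A: SecureMatrix) -> SecureMatrix:
        return A._like(np.transpose(A.data, (0, 2, 1, 3)).copy(),
                       rows=A.cols, cols=A.rows)

    def submatrix(self, A, r0, r1, c0, c1):
        return A._like(A.data[:, r0:r1, c0:c1, :].copy(),
                       rows=r1 - r0, cols=c1 - c0)

    def pad(self, A: SecureMatrix, rows: int, cols: int) -> SecureMatrix:
        out = np.zeros((self.parties, rows, cols, A.width), dtype=np.uint8)
        out[:, :A.rows, :A.cols, :] = A.data
        return A._like(out, rows=rows, cols=cols)

    def concat_rows(self, mats) -> SecureMatrix:
        top = mats[0]
        data = np.concatenate([m.data for m in mats], axis=1)
        return top._like(data, rows=data.shape[1])

    def diag_embed(self, s: SecureMatrix, m: int) -> SecureMatrix:
        out = np.zeros((self.parties, m, m, s.width), dtype=np.uint8)
        out[:, np.arange(m), np.arange(m), :] = s.data[:, 0, 0, :][:, None, :]
        return s._like(out, rows=m, cols=m)

    def broadcast_scalar(self, s: SecureMatrix, shape) -> SecureMatrix:
        entry = s.data[:, 0, 0, :]
        out = np.broadcast_to(entry[:, None, None, :],
                              (self.parties,) + tuple(shape) + (s.width,)).copy()
        return s._like(out, rows=shape[0], cols=shape[1])

    def ext_to_wide(self, A: SecureMatrix) -> SecureMatrix:
        sign = A.data[..., -1:]
        ext = np.concatenate([A.data] + [sign] * (WIDE - A.width), axis=-1)
        return A._like(ext, width=WIDE)

    def promote(self, A: SecureMatrix) -> SecureMatrix:
        zeros = np.zeros(A.data.shape[:-1] + (FRAC,), dtype=np.uint8)
        sign = A.data[..., -1:]
        ext = np.concatenate([zeros, A.data]
                             + [sign] * (WIDE - FRAC - A.width), axis=-1)
        return A._like(ext, width=WIDE, frac=WFRAC)

    def demote(self, A: SecureMatrix) -> SecureMatrix:
        return self.shift_trunc(A, FRAC, WIDTH, FRAC)

    def shift_trunc(self, A: SecureMatrix, shift: int, out_width: int,
                    out_frac: int) -> SecureMatrix:
        hi = shift + out_width
        if hi <= A.width:
            out = A.data[..., shift:hi]
        else:  # arithmetic shift: sign-extend past the top plane
            sign = A.data[..., -1:]
            out = np.concatenate([A.data[..., shift:]]
                                 + [sign] * (hi - A.width), axis=-1)
        return A._like(out.copy(), width=out_width, frac=out_frac)


# ---------------------------------------------------------------------------
# matrix operations (backend-generic)
# ---------------------------------------------------------------------------

def mat_add(A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
    """Elementwise fixed-point sum; rows*cols*(width-1) AND gates."""
    return A.backend.add(A, B)


def mat_sub(A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
    return A.backend.sub(A, B)


def mat_mul_standard(A: SecureMatrix, B: SecureMatrix) -> SecureMatrix:
    """Schoolbook product with 56-bit accumulation and one truncation."""
    return A.backend.matmul(A, B)


def mat_mul_strassen(A: SecureMatrix, B: SecureMatrix,
                     stats: Optional[dict] = None) -> SecureMatrix:
    """One-level Strassen product of square matrices.

    Odd dimensions are zero-padded to even and cropped afterwards.  All
    intermediate sums and the seven block products stay in the 56-bit
    container; a single truncation restores the input format, so the
    result matches :func:`mat_mul_standard` bit-exactly in the absence of
    container overflow.  ``stats["block_multiplications"]`` is incremented
    by 7 when a dict is supplied.
    """
    if A.rows != A.cols or B.rows != B.cols or A.rows != B.rows:
        raise DimensionError("Strassen requires equal square matrices")
    be = A.backend
    n0 = A.rows
    w, f = A.width, A.frac
    Aw = be.ext_to_wide(A) if w != WIDE else A
    Bw = be.ext_to_wide(B) if w != WIDE else B
    n = n0 + (n0 % 2)
    if n != n0:
        Aw, Bw = be.pad(Aw, n, n), be.pad(Bw, n, n)
    k = n // 2

    def blk(M, i, j):
        return be.submatrix(M, i * k, (i + 1) * k, j * k, (j + 1) * k)

    A11, A12, A21, A22 = (blk(Aw, 0, 0), blk(Aw, 0, 1),
                          blk(Aw, 1, 0), blk(Aw, 1, 1))
    B11, B12, B21, B22 = (blk(Bw, 0, 0), blk(Bw, 0, 1),
                          blk(Bw, 1, 0), blk(Bw, 1, 1))
    M1 = be.raw_matmul(A11, be.sub(B12, B22))
    M2 = be.raw_matmul(be.add(A11, A12), B22)
    M3 = be.raw_matmul(be.add(A21, A22), B11)
    M4 = be.raw_matmul(A22, be.sub(B21, B11))
    M5 = be.raw_matmul(be.add(A11, A22), be.add(B11, B22))
    M6 = be.raw_matmul(be.sub(A12, A22), be.add(B21, B22))
    M7 = be.raw_matmul(be.sub(A11, A21), be.add(B11, B12))
    if stats is not None:
        stats["block_multiplications"] = stats.get("block_multiplications", 0) + 7
    C11 = be.add(be.sub(be.add(M5, M4), M2), M6)
    C12 = be.add(M1, M2)
    C21 = be.add(M3, M4)
    C22 = be.sub(be.sub(be.add(M5, M1), M3), M7)

    C = _place(be, C11, n, 0, 0)
    for block, (i, j) in ((C12, (0, 1)), (C21, (1, 0)), (C22, (1, 1))):
        C = _assemble(be, C, block, i * k, j * k)
    out = be.shift_trunc(C, f, w, f)
    if n != n0:
        out = be.submatrix(out, 0, n0, 0, n0)
    return out


def _place(be, block: SecureMatrix, n: int, r: int, c: int) -> SecureMatrix:
    """Zero matrix of size n with ``block`` at (r, c) — structural."""
    if isinstance(be, EmulationBackend):
        out = np.zeros((n, n), dtype=np.int64)
        out[r:r + block.rows, c:c + block.cols] = block.data
    else:
        out = np.zeros((be.parties, n, n, block.width), dtype=np.uint8)
        out[:, r:r + block.rows, c:c + block.cols, :] = block.data
    return block._like(out, rows=n, cols=n)


def _assemble(be, C: SecureMatrix, block: SecureMatrix, r: int,
              c: int) -> SecureMatrix:
    """Write ``block`` into the (so far zero) region of C at (r, c)."""
    if isinstance(be, EmulationBackend):
        data = C.data.copy()
        data[r:r + block.rows, c:c + block.cols] = block.data
    else:
        data = C.data.copy()
        data[:, r:r + block.rows, c:c + block.cols, :] = block.data
    return C._like(data)


def _wide_double(be, M: SecureMatrix) -> SecureMatrix:
    return be.add(M, M)


def reciprocal_wide(a: SecureMatrix, iters: int, bound: float) -> SecureMatrix:
    """Elementwise Newton–Schulz reciprocal in the wide 56/22 format.

    Requires ``0 < value <= bound`` elementwise; ``bound`` is a public
    constant (the iteration constant c), so ``1/bound`` enters as a
    plaintext circuit constant.
    """
    if a.width != WIDE:
        raise DimensionError("reciprocal_wide expects wide words")
    if bound <= 0:
        raise ValueError("bound must be positive")
    be = a.backend
    inv_c = be.const(1.0 / bound, a.shape, WIDE, WFRAC)
    n = inv_c
    m = be.mul_elem(inv_c, a)
    for _ in range(iters):
        n = be.sub(_wide_double(be, n), be.mul_elem(n, m))
        m = be.sub(_wide_double(be, m), be.mul_elem(m, m))
    return n


def scalar_reciprocal(a, iters: int = 15, c: float = 150.0,
                      backend: Optional[EmulationBackend] = None):
    """Approximate 1/a for a 28/11 word via the 1x1 matrix iteration.

    ``a`` may be a :class:`~smacglore.fixedpoint.FixedWord`, a real, or a
    1x1 :class:`SecureMatrix`; the result matches the input kind.  ``c``
    bounds ``a`` from above (0 < a <= c).
    """
    if isinstance(a, SecureMatrix):
        be = a.backend
        wide = a if a.width == WIDE else be.promote(a)
        return be.demote(reciprocal_wide(wide, iters, c))
    be = backend if backend is not None else EmulationBackend(count_gates=False)
    word = a if isinstance(a, fx.FixedWord) else fx.encode(float(a))
    M = be.from_words(np.array([[word.bits]]))
    out = be.demote(reciprocal_wide(be.promote(M), iters, c))
    return fx.FixedWord(int(out.data[0, 0]))


def trace(A: SecureMatrix) -> SecureMatrix:
    """Sum of diagonal entries as a 1x1 matrix (width preserved)."""
    be = A.backend
    acc = be.submatrix(A, 0, 1, 0, 1)
    for i in range(1, min(A.rows, A.cols)):
        acc = be.add(acc, be.submatrix(A, i, i + 1, i, i + 1))
    return acc


def mat_inverse(A: SecureMatrix, iters: int = 15,
                c: Optional[float] = None, c_bound: Optional[float] = None,
                recip_iters: int = 15,
                stats: Optional[dict] = None) -> SecureMatrix:
    """Newton–Schulz inverse of a symmetric positive definite 28/11 matrix.

    The constant defaults to trace(A), computed inside the computation; its
    reciprocal needs a public upper bound ``c_bound`` (for the binary-design
    pipeline this is n*m/4).  When ``c`` is given explicitly it is used as a
    plaintext constant instead.  Strassen multiplication is used for the
    internal products; the whole iteration runs wide and truncates at the
    end.  Convergence is not tested in-circuit (a flag would leak progress);
    the caller checks the residual where it legitimately can.
    """
    if A.rows != A.cols:
        raise DimensionError("inverse requires a square matrix")
    be = A.backend
    m = A.rows
    Aw = be.promote(A)
    if c is not None:
        inv_c = be.const(1.0 / float(c), (1, 1), WIDE, WFRAC)
    else:
        tr = trace(Aw)
        if c_bound is None:
            if isinstance(be, EmulationBackend):
                tval = float(be._peek(tr)[0, 0])
                c_bound = float(2 ** math.ceil(math.log2(max(tval, 1e-9))))
            else:
                raise ValueError("c_bound (public trace bound) is required "
                                 "under the MPC backend")
        inv_c = reciprocal_wide(tr, recip_iters, c_bound)
    N = be.diag_embed(inv_c, m)
    M = be.mul_elem(Aw, be.broadcast_scalar(inv_c, (m, m)))
    for _ in range(iters):
        N = be.sub(_wide_double(be, N), mat_mul_strassen(N, M, stats))
        M = be.sub(_wide_double(be, M), mat_mul_strassen(M, M, stats))
    return be.demote(N)
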