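"""Boolean circuits over the {XOR, AND, NOT} basis for fixed-point arithmetic.

Circuits are immutable DAGs of gates over numbered wires, built by the
``build_*`` functions and evaluated either in plaintext (`eval_plain`) or
under secret sharing (:mod:`smacglore.engine`).  Only AND gates are
nonlinear: under the secret-sharing evaluator XOR and NOT are local
("free"), so the AND count is the complexity measure that matters and is
tracked exactly.  OR, when needed, is expressed as (a AND b) XOR a XOR b.

Construction choices are fixed so gate counts are reproducible:

* adders are ripple-carry with the carry recurrence
  ``c' = c XOR ((a XOR c) AND (b XOR c))`` and no final carry-out, giving
  exactly ``width - 1`` AND gates per addition;
* subtraction is two's complement: invert the subtrahend, add with an
  initial carry of 1;
* multipliers are schoolbook low-half products (partial-product rows ANDed
  and ripple-accumulated);
* the clamp is a signed comparator (subtraction sign at width+1, so no
  overflow corner cases) followed by a bitwise multiplexer
  ``m = (s AND (a XOR b)) XOR b``.

Evaluation is batch-oriented: a group's value for a batch of words is
bit-packed into Python integers (bit *i* of the packed wire value is
instance *i*), so every gate is a single big-int operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

XOR, AND, NOT = "XOR", "AND", "NOT"


@dataclass
class Circuit:
    """A topologically ordered gate list with named input/output wire groups.

    ``input_groups`` / ``output_groups`` map a name to a list of wire ids,
    least-significant bit first.  Output groups may reference input wires
    or repeat a wire (free sign extension); every *gate output* wire is
    written exactly once.  ``const_wires`` maps wire id -> fixed bit.
    """

    n_wires: int = 0
    gates: list = field(default_factory=list)  # (kind, in1, in2 | None, out)
    input_groups: dict = field(default_factory=dict)
    output_groups: dict = field(default_factory=dict)
    const_wires: dict = field(default_factory=dict)

    def count_gates(self, kind: str) -> int:
        if kind not in (XOR, AND, NOT):
            raise ValueError(f"unknown gate kind {kind!r}")
        return sum(1 for g in self.gates if g[0] == kind)

    @property
    def and_count(self) -> int:
        return self.count_gates(AND)

    def to_netlist(self) -> str:
        """One gate per line: ``KIND in1[,in2] -> out``, for audits."""
        lines = [f"# wires={self.n_wires} gates={len(self.gates)} and={self.and_count}"]
        for name, ws in self.input_groups.items():
            lines.append(f"# input {name}: {','.join(map(str, ws))}")
        for kind, a, b, out in self.gates:
            ins = f"{a}" if b is None else f"{a},{b}"
            lines.append(f"{kind} {ins} -> {out}")
        for name, ws in self.output_groups.items():
            lines.append(f"# output {name}: {','.join(map(str, ws))}")
        return "\n".join(lines)


class _Builder:
    """Mutable helper used by the build_* functions."""

    def __init__(self) -> None:
        self.c = Circuit()
        self._const = {}

    def wire(self) -> int:
        w = self.c.n_wires
        self.c.n_wires += 1
        return w

    def group(self, name: str, width: int) -> list:
        ws = [self.wire() for _ in range(width)]
        self.c.input_groups[name] = ws
        return ws

    def const(self, bit: int) -> int:
        if bit not in self._const:
            w = self.wire()
            self.c.const_wires[w] = bit
            self._const[bit] = w
        return self._const[bit]

    def xor(self, a: int, b: int) -> int:
        w = self.wire()
        self.c.gates.append((XOR, a, b, w))
        return w

    def and_(self, a: int, b: int) -> int:
        w = self.wire()
        self.c.gates.append((AND, a, b, w))
        return w

    def not_(self, a: int) -> int:
        w = self.wire()
        self.c.gates.append((NOT, a, None, w))
        return w

    # ---- compound blocks -------------------------------------------------
    def add_bits(self, a: list, b: list, cin: int | None = None) -> list:
        """Ripple-carry sum of equal-length bit vectors, final carry dropped."""
        assert len(a) == len(b)
        w = len(a)
        out = []
        carry = cin
        for i in range(w):
            if carry is None:
                out.append(self.xor(a[i], b[i]))
                if i < w - 1:
                    carry = self.and_(a[i], b[i])
            else:
                axc = self.xor(a[i], carry)
                out.append(self.xor(axc, b[i]))
                if i < w - 1:
                    bxc = self.xor(b[i], carry)
                    carry = self.xor(carry, self.and_(axc, bxc))
        return out

    def sub_bits(self, a: list, b: list) -> list:
        """a - b as a + NOT(b) + 1."""
        nb = [self.not_(x) for x in b]
        return self.add_bits(a, nb, cin=self.const(1))

    def mul_low_bits(self, a: list, b: list) -> list:
        """Low ``len(a)`` bits of the integer product (schoolbook)."""
        w = len(a)
        assert len(b) == w
        acc = [self.and_(a[j], b[0]) for j in range(w)]
        for i in range(1, w):
            row = [self.and_(a[j], b[i]) for j in range(w - i)]
            acc[i:] = self.add_bits(acc[i:], row)
        return acc

    def mux_bits(self, s: int, a: list, b: list) -> list:
        """Bitwise ``s ? a : b`` via m = (s AND (a XOR b)) XOR b."""
        return [self.xor(self.and_(s, self.xor(ai, bi)), bi)
                for ai, bi in zip(a, b)]

    def signed_lt(self, a: list, b: list) -> int:
        """Sign bit of (a - b) computed at width+1: 1 iff a < b (signed)."""
        ae = a + [a[-1]]
        be = b + [b[-1]]
        return self.sub_bits(ae, be)[-1]


def _finish(bld: _Builder, name: str, wires: list) -> Circuit:
    bld.c.output_groups[name] = wires
    return bld.c


def build_adder(width: int) -> Circuit:
    """(a + b) mod 2^width; exactly ``width - 1`` AND gates."""
    if width < 2:
        raise ValueError("width must be >= 2")
    b = _Builder()
    return _finish(b, "sum", b.add_bits(b.group("a", width), b.group("b", width)))


def build_negator(width: int) -> Circuit:
    """Two's-complement negation: flip all bits, then add one."""
    if width < 2:
        raise ValueError("width must be >= 2")
    b = _Builder()
    a = b.group("a", width)
    n = [b.not_(x) for x in a]
    out = [a[0]]  # n0 XOR 1 == a0
    carry = n[0]
    for i in range(1, width):
        out.append(b.xor(n[i], carry))
        if i < width - 1:
            carry = b.and_(n[i], carry)
    return _finish(b, "neg", out)


def build_subtractor(width: int) -> Circuit:
    """(a - b) mod 2^width via addition of the two's complement."""
    if width < 2:
        raise ValueError("width must be >= 2")
    b = _Builder()
    return _finish(b, "diff", b.sub_bits(b.group("a", width), b.group("b", width)))


def build_multiplier(width: int) -> Circuit:
    """Low ``width`` bits of the integer product (valid for signed words too,
    since the low half of a two's-complement product equals the unsigned one)."""
    if width < 2:
        raise ValueError("width must be >= 2")
    b = _Builder()
    return _finish(b, "prod", b.mul_low_bits(b.group("a", width), b.group("b", width)))


def build_fixed_multiplier(width: int = 28, frac: int = 11) -> Circuit:
    """Fixed-point product: sign-extend, multiply, arithmetic-shift by ``frac``.

    The extension width ``width + frac`` is the smallest that makes the kept
    bits exact; the result decodes to ``floor(a * b * 2^frac) / 2^frac``
    whenever it is representable, and wraps otherwise.
    """
    b = _Builder()
    a = b.group("a", width)
    bb = b.group("b", width)
    ext = width + frac
    ae = a + [a[-1]] * (ext - width)
    be = bb + [bb[-1]] * (ext - width)
    prod = b.mul_low_bits(ae, be)
    return _finish(b, "prod", prod[frac:frac + width])


def build_dot(k: int, width: int = 28, frac: int = 11,
              acc_width: int = 56, raw: bool = False) -> Circuit:
    """Inner product of two k-vectors: widened raw products accumulated at
    ``acc_width`` bits, then one truncation (or none if ``raw``).

    Input groups are ``a0..a{k-1}`` and ``b0..b{k-1}``; output ``dot`` has
    ``width`` wires (``acc_width`` when raw).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    b = _Builder()
    acc = None
    for i in range(k):
        a = b.group(f"a{i}", width)
        bb = b.group(f"b{i}", width)
        ae = a + [a[-1]] * (acc_width - width)
        be = bb + [bb[-1]] * (acc_width - width)
        p = b.mul_low_bits(ae, be)
        acc = p if acc is None else b.add_bits(acc, p)
    out = acc if raw else acc[frac:frac + width]
    return _finish(b, "dot", out)


def build_clamp(width: int, lo, hi, frac: int = 11) -> Circuit:
    """min(max(x, lo), hi) with signed comparison; lo/hi are circuit constants.

    ``lo`` and ``hi`` may be reals or :class:`~smacglore.fixedpoint.FixedWord`.
    """
    from . import fixedpoint as fx

    def as_bits(v):
        w = v if isinstance(v, fx.FixedWord) else fx.encode(float(v), width, frac)
        return w.bits

    lo_bits, hi_bits = as_bits(lo), as_bits(hi)
    if fx.to_signed(np.int64(lo_bits), width) >= fx.to_signed(np.int64(hi_bits), width):
        raise ValueError("lo must be < hi as signed values")
    b = _Builder()
    x = b.group("x", width)
    lo_w = [b.const((lo_bits >> i) & 1) for i in range(width)]
    hi_w = [b.const((hi_bits >> i) & 1) for i in range(width)]
    gt = b.signed_lt(hi_w, x)          # hi < x  ->  clamp to hi
    y = b.mux_bits(gt, hi_w, x)
    lt = b.signed_lt(y, lo_w)          # y < lo  ->  clamp to lo
    return _finish(b, "clamped", b.mux_bits(lt, lo_w, y))


def build_matrix_add(rows: int, cols: int, width: int = 28) -> Circuit:
    """Elementwise matrix addition: one ripple-carry adder per entry, hence
    ``rows * cols * (width - 1)`` AND gates."""
    b = _Builder()
    a = b.group("a", rows * cols * width)
    bb = b.group("b", rows * cols * width)
    out = []
    for e in range(rows * cols):
        sl = slice(e * width, (e + 1) * width)
        out.extend(b.add_bits(a[sl], bb[sl]))
    return _finish(b, "sum", out)


# ---------------------------------------------------------------------------
# plaintext evaluation (reference semantics for the secret-sharing engine)
# ---------------------------------------------------------------------------

def pack_words(words, wires_width: int) -> list:
    """Bit-pack a batch of words: element k of the result is the packed
    value of bit k across the batch (bit i = instance i)."""
    arr = np.atleast_1d(np.asarray(words, dtype=np.int64))
    packed = []
    for k in range(wires_width):
        bits = ((arr >> k) & 1).astype(np.uint8)
        packed.append(int.from_bytes(np.packbits(bits, bitorder="little").tobytes(),
                                     "little"))
    return packed


def unpack_words(packed: list, batch: int) -> np.ndarray:
    """Inverse of :func:`pack_words`."""
    nbytes = (batch + 7) // 8
    out = np.zeros(batch, dtype=np.int64)
    for k, pv in enumerate(packed):
        raw = np.frombuffer(pv.to_bytes(nbytes, "little"), dtype=np.uint8)
        bits = np.unpackbits(raw, bitorder="little")[:batch]
        out |= bits.astype(np.int64) << k
    return out


def eval_packed(circuit: Circuit, packed_inputs: dict, batch: int) -> dict:
    """Evaluate on bit-packed inputs; returns packed output groups."""
    mask = (1 << batch) - 1
    wires = [0] * circuit.n_wires
    for name, ws in circuit.input_groups.items():
        if name not in packed_inputs:
            raise ValueError(f"missing input group {name!r}")
        vals = packed_inputs[name]
        if len(vals) != len(ws):
            raise ValueError(f"input group {name!r}: expected {len(ws)} wires, "
                             f"got {len(vals)}")
        for w, v in zip(ws, vals):
            wires[w] = v & mask
    for w, bit in circuit.const_wires.items():
        wires[w] = mask if bit else 0
    for kind, a, b, out in circuit.gates:
        if kind == XOR:
            wires[out] = wires[a] ^ wires[b]
        elif kind == AND:
            wires[out] = wires[a] & wires[b]
        else:
            wires[out] = ~wires[a] & mask
    return {name: [wires[w] for w in ws]
            for name, ws in circuit.output_groups.items()}


def eval_plain(circuit: Circuit, inputs: dict) -> dict:
    """Evaluate the circuit on plaintext words.

    ``inputs`` maps each input group name to an int or an array of words
    (a batch); outputs come back in the same shape.
    """
    scalar = all(np.isscalar(v) or np.ndim(v) == 0 for v in inputs.values())
    sizes = {np.atleast_1d(np.asarray(v)).size for v in inputs.values()}
    if len(sizes) > 1:
        raise ValueError(f"inconsistent batch sizes across input groups: {sizes}")
    batch = 1 if scalar else sizes.pop()
    missing = set(circuit.input_groups) - set(inputs)
    if missing:
        raise ValueError(f"missing input group {sorted(missing)[0]!r}")
    packed = {name: pack_words(vals, len(circuit.input_groups[name]))
              for name, vals in inputs.items()}
    out = eval_packed(circuit, packed, batch)
    res = {name: unpack_words(pv, batch) for name, pv in out.items()}
    if scalar:
        res = {name: int(v[0]) for name, v in res.items()}
    return res
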