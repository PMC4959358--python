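"""GMW-style evaluation of boolean circuits under XOR secret sharing.

Every wire value is split into h random-looking bits, one per party, whose
XOR is the plaintext bit.  Linear gates are free: XOR is evaluated share-
locally by every party, NOT by flipping a designated party's share (party
0).  AND gates are interactive: with shares a_i, b_i,

    a AND b = XOR_i (a_i b_i)  XOR  XOR_{i != j} (a_i b_j),

and each cross term a_i b_j is obtained through a 1-out-of-4 oblivious
transfer between the ordered pair (i, j): the sender masks its share with
a random bit r, the receiver selects the message indexed by its own two
share bits and learns r XOR a_i b_j without the sender learning the
choice.  That is h(h-1) OT invocations per AND gate.

Parties here are in-process actors; the OT backend is a correctness-only
simulation with seeded masks (the interface takes 4 equal-length messages
and a choice in 0..3, so a cryptographic 1-of-4 OT can be substituted).
Evaluation is batched: many independent instances of the circuit run at
once, bit-packed into Python integers, with per-gate truth-table semantics
preserved instance by instance.

The load-bearing correctness property of the whole package is that for
every circuit and input, reconstructing the shares produced here equals
:func:`smacglore.circuits.eval_plain` bit for bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .circuits import AND, NOT, XOR, Circuit, pack_words, unpack_words


@dataclass
class ShareTensor:
    """Per-party XOR shares of a bit array (one bit per wire instance)."""

    party_shares: np.ndarray  # shape (h, n), uint8 in {0, 1}

    @property
    def h(self) -> int:
        return self.party_shares.shape[0]


def share_bits(bits, h: int, rng) -> ShareTensor:
    """Split a bit array into h uniformly random XOR shares.

    The first h-1 share arrays are drawn from ``rng``; the last is fixed by
    the constraint that all h XOR back to the input.
    """
    if h < 2:
        raise ValueError("need at least 2 parties")
    bits = np.asarray(bits, dtype=np.uint8) & 1
    shares = np.empty((h, bits.size), dtype=np.uint8)
    acc = np.zeros(bits.size, dtype=np.uint8)
    for i in range(h - 1):
        shares[i] = rng.integers(0, 2, size=bits.size, dtype=np.uint8)
        acc ^= shares[i]
    shares[h - 1] = acc ^ bits
    return ShareTensor(shares)


def reconstruct(shares: ShareTensor) -> np.ndarray:
    """XOR over parties; inverts :func:`share_bits`."""
    ps = shares.party_shares
    if ps.ndim != 2:
        raise ValueError("party_shares must be 2-D (h, n)")
    return np.bitwise_xor.reduce(ps, axis=0)


class SimulatedOT:
    """In-process 1-out-of-4 oblivious transfer (correctness only).

    The receiver obtains exactly the message at its choice index; the public
    API keeps no record linking a choice to the sender's state.  ``calls``
    counts protocol invocations (one per AND gate per ordered party pair;
    a batched call counts its batch size).
    """

    def __init__(self) -> None:
        self.calls = 0

    def ot4(self, messages, choice: int):
        """Scalar transfer: 4 equal-length messages, choice in 0..3."""
        if len(messages) != 4:
            raise ValueError("ot4 requires exactly 4 messages")
        lengths = {len(m) if hasattr(m, "__len__") else -1 for m in messages}
        if len(lengths) != 1:
            raise ValueError("ot4 messages must have equal length")
        if choice not in (0, 1, 2, 3):
            raise ValueError("choice must be in {0, 1, 2, 3}")
        self.calls += 1
        return messages[choice]

    def ot4_packed(self, m0: int, m1: int, m2: int, m3: int,
                   hi: int, lo: int, mask: int, batch: int) -> int:
        """Vectorised transfer: per bit position, select m[2*hi + lo].

        ``hi``/``lo`` are the packed high/low choice bits of the receiver.
        """
        self.calls += batch
        nhi, nlo = ~hi & mask, ~lo & mask
        return ((nhi & nlo & m0) | (nhi & lo & m1)
                | (hi & nlo & m2) | (hi & lo & m3))


@dataclass
class Transcript:
    """Public accounting of an MPC evaluation (no wire values)."""

    and_gates: int = 0
    ot_invocations: int = 0
    gate_events: int = 0
    reveals: int = 0
    message_counts: list = field(default_factory=list)


def _shared_const(bit_packed: int, h: int) -> list:
    return [bit_packed] + [0] * (h - 1)


def evaluate_shares(circuit: Circuit, input_shares: dict, h: int,
                    ot: SimulatedOT, rng: random.Random, batch: int,
                    transcript: Transcript | None = None) -> dict:
    """Evaluate on already-shared, bit-packed inputs; return output shares.

    ``input_shares`` maps group name -> list over wires of per-party packed
    ints ``[s_0, ..., s_{h-1}]``.  Outputs come back in the same layout.
    """
    mask = (1 << batch) - 1
    wires = [None] * circuit.n_wires
    for name, ws in circuit.input_groups.items():
        vals = input_shares[name]
        if len(vals) != len(ws):
            raise ValueError(f"input group {name!r}: wire count mismatch")
        for w, sv in zip(ws, vals):
            wires[w] = list(sv)
    for w, bit in circuit.const_wires.items():
        wires[w] = _shared_const(mask if bit else 0, h)

    for kind, a, b, out in circuit.gates:
        if transcript is not None:
            transcript.gate_events += 1
        if kind == XOR:
            wires[out] = [wires[a][i] ^ wires[b][i] for i in range(h)]
        elif kind == NOT:
            v = list(wires[a])
            v[0] = ~v[0] & mask
            wires[out] = v
        else:  # AND via pairwise cross-term OT
            av, bv = wires[a], wires[b]
            c = [av[i] & bv[i] for i in range(h)]
            for i in range(h):
                for j in range(h):
                    if i == j:
                        continue
                    r = rng.getrandbits(batch)
                    t = ot.ot4_packed(r, r, r ^ av[i], r ^ av[i],
                                      bv[j], av[j], mask, batch)
                    c[i] ^= r
                    c[j] ^= t
            wires[out] = c
            if transcript is not None:
                transcript.and_gates += 1
                transcript.ot_invocations += h * (h - 1)
    for w in (w for ws in circuit.output_groups.values() for w in ws):
        if wires[w] is None:
            raise ValueError(f"output wire {w} never assigned")
    return {name: [wires[w] for w in ws]
            for name, ws in circuit.output_groups.items()}


def share_words(words, width: int, h: int, rng: random.Random,
                batch: int) -> list:
    """Share a batch of words into the packed per-wire layout."""
    packed = pack_words(words, width)
    out = []
    for pv in packed:
        shares = []
        acc = 0
        for _ in range(h - 1):
            s = rng.getrandbits(batch)
            shares.append(s)
            acc ^= s
        shares.append(acc ^ pv)
        out.append(shares)
    return out


def reconstruct_words(share_layout: list, batch: int) -> np.ndarray:
    """XOR party shares per wire and unpack to words."""
    packed = []
    for per_wire in share_layout:
        v = 0
        for s in per_wire:
            v ^= s
        packed.append(v)
    return unpack_words(packed, batch)


def eval_circuit_mpc(circuit: Circuit, party_inputs: dict, h: int,
                     ot: SimulatedOT | None = None,
                     rng: random.Random | None = None,
                     transcript: Transcript | None = None) -> dict:
    """Share each party's inputs, evaluate under MPC, reconstruct outputs.

    ``party_inputs`` maps an input group name to ``(owner, words)`` where
    ``owner`` is the party index holding that plaintext and ``words`` is an
    int or array of words (the batch).  Returns plaintext output words,
    which must equal :func:`~smacglore.circuits.eval_plain` bit-exactly.
    """
    if h < 2:
        raise ValueError("need at least 2 parties")
    ot = ot if ot is not None else SimulatedOT()
    rng = rng if rng is not None else random.Random(0)
    missing = set(circuit.input_groups) - set(party_inputs)
    if missing:
        raise ValueError(f"unassigned input groups: {sorted(missing)}")
    scalar = all(np.isscalar(v) or np.ndim(v) == 0
                 for _, v in party_inputs.values())
    batch = 1 if scalar else len(np.atleast_1d(next(iter(party_inputs.values()))[1]))
    shared = {}
    for name, (owner, words) in party_inputs.items():
        if not 0 <= owner < h:
            raise ValueError(f"input {name!r}: owner {owner} out of range")
        shared[name] = share_words(words, len(circuit.input_groups[name]),
                                   h, rng, batch)
    out_shares = evaluate_shares(circuit, shared, h, ot, rng, batch, transcript)
    if transcript is not None:
        transcript.reveals += len(out_shares)
    res = {name: reconstruct_words(layout, batch)
           for name, layout in out_shares.items()}
    if scalar:
        res = {name: int(v[0]) for name, v in res.items()}
    return res
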