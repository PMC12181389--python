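"""Exact statevector simulation of small qubit registers.

The simulator keeps the full complex amplitude vector of an ``n``-qubit
register and applies unitary gates to it, either as dense matrices or as
tensor contractions on selected wires.  Basis ordering convention: qubit 0
is the *most significant* bit of the computational-basis index, i.e. the
basis state ``|q0 q1 ... q_{n-1}>`` has index ``q0*2^(n-1) + ... + q_{n-1}``.

Two evaluation modes are supported downstream: "exact" (probabilities read
directly off the statevector) and "sampled" (a seeded multinomial draw with
a finite shot count, 1024 by default).  All randomness flows through
explicit integer seeds; there is no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Statevector",
    "ShotCounts",
    "hadamard_gate",
    "rx_gate",
    "ry_gate",
    "ising_xx_gate",
    "ising_zz_gate",
    "pauli_x",
    "pauli_z",
    "embed_gate",
    "apply",
    "apply_gate",
    "basis_probabilities",
    "marginal_one_probabilities",
    "sample_counts",
    "zero_state",
]

_SQRT2 = math.sqrt(2.0)


def _check_angle(theta: float) -> float:
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError(f"gate angle must be finite, got {theta!r}")
    return theta


@dataclass
class Statevector:
    """Pure state of an ``n_qubits`` register (qubit 0 = MSB of the index)."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex).ravel()
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be a positive integer")
        if self.amplitudes.size != 2**self.n_qubits:
            raise ValueError(
                f"amplitude vector of length {self.amplitudes.size} does not match "
                f"2**{self.n_qubits} basis states"
            )

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


@dataclass
class ShotCounts:
    """Multinomial measurement record: ``counts`` per basis outcome."""

    counts: np.ndarray
    shots: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.shots:
            raise ValueError("counts must sum to the shot total")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / float(self.shots)


def zero_state(n_qubits: int) -> Statevector:
    """The all-zeros basis state ``|00...0>``."""
    amps = np.zeros(2**n_qubits, dtype=complex)
    amps[0] = 1.0
    return Statevector(n_qubits, amps)


def hadamard_gate() -> np.ndarray:
    """H = (1/sqrt 2) [[1, 1], [1, -1]]."""
    return np.array([[1.0, 1.0], [1.0, -1.0]], dtype=complex) / _SQRT2


def rx_gate(theta: float) -> np.ndarray:
    """Rotation about the X axis: [[cos t/2, -i sin t/2], [-i sin t/2, cos t/2]]."""
    theta = _check_angle(theta)
    c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)


def ry_gate(theta: float) -> np.ndarray:
    """Rotation about the Y axis: real rotation matrix by theta/2."""
    theta = _check_angle(theta)
    c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def pauli_x() -> np.ndarray:
    return np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)


def pauli_z() -> np.ndarray:
    return np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)


def ising_xx_gate(theta: float) -> np.ndarray:
    """XX(theta) = exp(-i theta/2 X(x)X) = cos(t/2) I - i sin(t/2) X(x)X."""
    theta = _check_angle(theta)
    c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
    xx = np.kron(pauli_x(), pauli_x())
    return c * np.eye(4, dtype=complex) - 1j * s * xx


def ising_zz_gate(theta: float) -> np.ndarray:
    """ZZ(theta) = diag(e^{-it/2}, e^{+it/2}, e^{+it/2}, e^{-it/2})."""
    theta = _check_angle(theta)
    lo = np.exp(-1j * theta / 2.0)
    hi = np.exp(+1j * theta / 2.0)
    return np.diag([lo, hi, hi, lo]).astype(complex)


def embed_gate(gate: np.ndarray, wires: list[int] | tuple[int, ...], n_qubits: int) -> np.ndarray:
    """Dense ``2^n x 2^n`` unitary acting as ``gate`` on ``wires``, identity elsewhere.

    Consistent with the MSB-first basis ordering of :class:`Statevector`.
    """
    gate = np.asarray(gate, dtype=complex)
    wires = list(wires)
    k = len(wires)
    if len(set(wires)) != k:
        raise ValueError(f"wires must be distinct, got {wires}")
    if any(w < 0 or w >= n_qubits for w in wires):
        raise ValueError(f"wire index out of range for {n_qubits} qubits: {wires}")
    if gate.shape != (2**k, 2**k):
        raise ValueError(f"gate of shape {gate.shape} does not act on {k} wires")
    dim = 2**n_qubits
    # Build by transporting gate axes onto the wire axes of the rank-2n tensor.
    op = np.kron(gate, np.eye(2 ** (n_qubits - k), dtype=complex))
    op = op.reshape([2] * (2 * n_qubits))
    rest = [w for w in range(n_qubits) if w not in wires]
    perm = wires + rest
    inv = np.argsort(perm)
    op = op.transpose(list(inv) + [n_qubits + i for i in inv])
    return op.reshape(dim, dim)


def apply(state: Statevector, unitary: np.ndarray) -> Statevector:
    """Apply a dense unitary to the full register: amplitudes -> U @ amplitudes."""
    unitary = np.asarray(unitary, dtype=complex)
    dim = state.amplitudes.size
    if unitary.shape != (dim, dim):
        raise ValueError(f"unitary shape {unitary.shape} does not match state dim {dim}")
    return Statevector(state.n_qubits, unitary @ state.amplitudes)


def apply_gate(state: Statevector, gate: np.ndarray, wires: list[int] | tuple[int, ...]) -> Statevector:
    """Apply a small gate to selected wires by tensor contraction.

    Equivalent to ``apply(state, embed_gate(gate, wires, n))`` but without
    materialising the dense embedded matrix, so it stays cheap for the
    16-qubit register of the 4x4 filter.
    """
    wires = list(wires)
    n = state.n_qubits
    k = len(wires)
    gate = np.asarray(gate, dtype=complex).reshape([2] * (2 * k))
    psi = state.amplitudes.reshape([2] * n)
    psi = np.tensordot(gate, psi, axes=(list(range(k, 2 * k)), wires))
    # tensordot moved the wire axes to the front, in `wires` order; restore.
    psi = np.moveaxis(psi, list(range(k)), wires)
    return Statevector(n, psi.ravel())


def basis_probabilities(state: Statevector) -> np.ndarray:
    """Computational-basis outcome probabilities |amplitude_b|^2."""
    return np.abs(state.amplitudes) ** 2


def marginal_one_probabilities(probabilities: np.ndarray, n_qubits: int) -> np.ndarray:
    """Per-qubit marginal P(qubit = 1) from a joint basis distribution."""
    p = np.asarray(probabilities, dtype=float).reshape([2] * n_qubits)
    out = np.empty(n_qubits)
    for q in range(n_qubits):
        out[q] = np.take(p, 1, axis=q).sum()
    return out


def sample_counts(probabilities: np.ndarray, shots: int = 1024, seed: int = 0) -> ShotCounts:
    """Seeded multinomial draw of ``shots`` measurements from a distribution."""
    p = np.asarray(probabilities, dtype=float)
    if shots < 1:
        raise ValueError("shots must be >= 1")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(shots, np.clip(p, 0.0, None) / p.sum())
    return ShotCounts(counts=counts, shots=shots, seed=seed)
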