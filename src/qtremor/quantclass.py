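"""QuantClass: a two-qubit decision head whose four basis-measurement
outcomes serve as class scores, trained with the parameter-shift rule.

The printed circuit is U(theta) = (H (x) H) . (RX(theta) (x) RX(theta))
applied to |00>, measured in the computational basis.  That circuit is
provably *flat*: RX(theta)|0> has equal-magnitude amplitudes on |0> and
|1>, the Hadamard keeps the magnitudes equal, so every basis probability is
exactly 1/4 for every theta and the parameter-shift gradient vanishes
identically.  This "literal" mode is kept for fidelity tests.

The default "functional" mode makes the minimal change that restores
theta-sensitivity: Hadamard first, then RY(theta), giving the per-qubit
marginal P(1) = (1 + sin theta)/2.  A second degeneracy remains whenever
both qubits share one angle: the two qubits then carry identical states, so
p01 = p10 for every theta and the |10> class can never win the argmax.  The
trainable head therefore supports one angle per qubit (the default in the
network module); the shared-angle form is what the single-theta functions
here compute.

Gradients flow through the head by the parameter-shift rule,
(f(theta+s) - f(theta-s)) / (2 sin s) with s = pi/2, evaluated by running
the same circuit at the shifted angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import qcore

__all__ = [
    "QuantClassConfig",
    "ThetaEncoding",
    "encode_theta",
    "quantclass_unitary",
    "quantclass_forward",
    "parameter_shift_grad",
    "hybrid_backward",
    "QuantClassHead",
]

OUTCOME_CLASSES = ("00", "01", "10", "11")  # outcome index -> class 0..3


@dataclass
class QuantClassConfig:
    """mode: 'functional' (default, trainable) or 'literal' (printed circuit).
    shift: parameter-shift offset s in (0, pi).  jitter_sigma: std-dev of the
    seeded random shift added to the angle(s) before evaluation (0 = off).
    eval: 'exact' or 'sampled' (multinomial with ``shots`` draws)."""

    mode: str = "functional"
    shift: float = math.pi / 2.0
    jitter_sigma: float = 0.0
    shots: int = 1024
    eval: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("functional", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.shift < math.pi:
            raise ValueError("shift must lie in (0, pi)")
        if self.jitter_sigma < 0.0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.eval not in ("exact", "sampled"):
            raise ValueError(f"unknown eval {self.eval!r}")


@dataclass
class ThetaEncoding:
    """Affine-plus-squash angle encoding theta = scale * tanh(w1 x1 + w2 x2 + b)."""

    w1: float = 1.0
    w2: float = 1.0
    b: float = 0.0
    scale: float = math.pi


def encode_theta(x1: float, x2: float, enc: ThetaEncoding | None = None) -> float:
    """Differentiable angle encoding; |theta| < scale (= pi by default)."""
    enc = enc or ThetaEncoding()
    return enc.scale * math.tanh(enc.w1 * float(x1) + enc.w2 * float(x2) + enc.b)


def quantclass_unitary(theta: float, mode: str = "functional") -> np.ndarray:
    """Dense 4x4 circuit unitary.

    literal:    (H (x) H) . (RX(theta) (x) RX(theta))  -- as printed
    functional: (RY(theta) (x) RY(theta)) . (H (x) H)  -- H first, then RY
    """
    h2 = np.kron(qcore.hadamard_gate(), qcore.hadamard_gate())
    if mode == "literal":
        rx = qcore.rx_gate(theta)
        return h2 @ np.kron(rx, rx)
    if mode == "functional":
        ry = qcore.ry_gate(theta)
        return np.kron(ry, ry) @ h2
    raise ValueError(f"unknown mode {mode!r}")


def _single_qubit_amplitudes(theta: np.ndarray, mode: str) -> np.ndarray:
    """Per-qubit state after the circuit, for an array of angles: shape (..., 2)."""
    theta = np.asarray(theta, dtype=float)
    c = np.cos(theta / 2.0)
    s = np.sin(theta / 2.0)
    inv = 1.0 / math.sqrt(2.0)
    if mode == "literal":
        # H . RX(theta) |0> = ((c - i s), (c + i s)) / sqrt(2)
        a0 = (c - 1j * s) * inv
        a1 = (c + 1j * s) * inv
    elif mode == "functional":
        # RY(theta) . H |0> = ((c - s), (c + s)) / sqrt(2)
        a0 = (c - s) * inv
        a1 = (c + s) * inv
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.stack([a0, a1], axis=-1)


def _probs_from_angles(theta0: np.ndarray, theta1: np.ndarray, mode: str) -> np.ndarray:
    """Joint outcome probabilities (..., 4) over (00, 01, 10, 11)."""
    aq0 = _single_qubit_amplitudes(theta0, mode)
    aq1 = _single_qubit_amplitudes(theta1, mode)
    joint = aq0[..., :, None] * aq1[..., None, :]
    p = np.abs(joint) ** 2
    return p.reshape(p.shape[:-2] + (4,))


def quantclass_forward(theta, cfg: QuantClassConfig | None = None) -> np.ndarray:
    """Outcome probabilities over {00, 01, 10, 11} of the head circuit.

    ``theta`` is a single shared angle (both qubits) or a pair of per-qubit
    angles.  With ``jitter_sigma > 0`` a seeded normal shift is added to the
    angle(s) before evaluation; in 'sampled' mode the probabilities are shot
    frequencies.
    """
    cfg = cfg or QuantClassConfig()
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if th.shape not in ((1,), (2,)):
        raise ValueError("theta must be a scalar or a pair of angles")
    if cfg.jitter_sigma > 0.0:
        rng = np.random.default_rng(cfg.seed)
        th = th + rng.normal(0.0, cfg.jitter_sigma, size=th.shape)
    t0, t1 = (th[0], th[0]) if th.shape == (1,) else (th[0], th[1])
    p = _probs_from_angles(np.asarray(t0), np.asarray(t1), cfg.mode)
    if cfg.eval == "sampled":
        counts = qcore.sample_counts(p, shots=cfg.shots, seed=cfg.seed)
        p = counts.frequencies
    return p


def parameter_shift_grad(circuit, theta: float, s: float = math.pi / 2.0) -> np.ndarray:
    """(circuit(theta + s) - circuit(theta - s)) / (2 sin s).

    Exact derivative for any single-frequency angle dependence; with
    s = pi/2 the denominator is 2.
    """
    s = float(s)
    if abs(math.sin(s)) < 1e-12:
        raise ValueError("shift s must satisfy sin(s) != 0")
    hi = np.asarray(circuit(theta + s), dtype=float)
    lo = np.asarray(circuit(theta - s), dtype=float)
    return (hi - lo) / (2.0 * math.sin(s))


class QuantClassHead:
    """Batched forward/backward interface of the head.

    forward: angles (B,) or (B, n_angles) -> probabilities (B, 4), caching
    the probabilities at theta +/- s for the backward pass.
    backward: upstream dL/dp (B, 4) -> dL/dtheta with the same shape as the
    input angles, via the parameter-shift rule.
    """

    def __init__(self, cfg: QuantClassConfig | None = None):
        self.cfg = cfg or QuantClassConfig()
        self._cache = None
        self._jitter_calls = 0

    def _eval(self, t0: np.ndarray, t1: np.ndarray) -> np.ndarray:
        p = _probs_from_angles(t0, t1, self.cfg.mode)
        if self.cfg.eval == "sampled":
            out = np.empty_like(p)
            base = self.cfg.seed + 7919 * self._jitter_calls
            for i in range(p.shape[0]):
                out[i] = qcore.sample_counts(p[i], shots=self.cfg.shots,
                                             seed=base + i).frequencies
            self._jitter_calls += 1
            return out
        return p

    def forward(self, thetas: np.ndarray) -> np.ndarray:
        th = np.asarray(thetas, dtype=float)
        squeeze = th.ndim == 1
        if squeeze:
            th = th[:, None]
        if th.shape[1] not in (1, 2):
            raise ValueError("expected 1 or 2 angles per sample")
        if self.cfg.jitter_sigma > 0.0:
            rng = np.random.default_rng(self.cfg.seed + self._jitter_calls)
            self._jitter_calls += 1
            th = th + rng.normal(0.0, self.cfg.jitter_sigma, size=th.shape)
        cols = (th[:, 0], th[:, 0]) if th.shape[1] == 1 else (th[:, 0], th[:, 1])
        probs = self._eval(*cols)
        s = self.cfg.shift
        shifted = []
        for a in range(th.shape[1]):
            pl_cols = list(cols)
            mi_cols = list(cols)
            if th.shape[1] == 1:
                pl_cols = [cols[0] + s, cols[1] + s]
                mi_cols = [cols[0] - s, cols[1] - s]
            else:
                pl_cols[a] = cols[a] + s
                mi_cols[a] = cols[a] - s
            shifted.append((self._eval(*pl_cols), self._eval(*mi_cols)))
        self._cache = {"thetas": th, "squeeze": squeeze, "shifted": shifted}
        return probs

    def backward(self, upstream: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward (no cached pass)")
        upstream = np.asarray(upstream, dtype=float)
        th = self._cache["thetas"]
        denom = 2.0 * math.sin(self.cfg.shift)
        grads = np.empty_like(th)
        for a, (p_plus, p_minus) in enumerate(self._cache["shifted"]):
            dprob = (p_plus - p_minus) / denom  # (B, 4)
            grads[:, a] = (upstream * dprob).sum(axis=1)
        return grads[:, 0] if self._cache["squeeze"] else grads


def hybrid_backward(upstream_grad: np.ndarray, theta, cfg: QuantClassConfig | None = None):
    """dLoss/dtheta for one sample: parameter-shift gradient of the outcome
    probabilities contracted with the upstream dLoss/dp vector."""
    cfg = cfg or QuantClassConfig()
    head = QuantClassHead(cfg)
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    out = head.forward(th[None, :] if th.size > 1 else th[:1][None, :])
    del out
    g = head.backward(np.asarray(upstream_grad, dtype=float)[None, :])
    g = np.asarray(g).ravel()
    return float(g[0]) if th.size == 1 else g
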