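"""Quantvolution: a quantum-circuit analogue of a convolutional filter.

Each non-overlapping ``k x k`` pixel window of a grayscale image is mapped
onto a ring graph over its ``k**2`` pixels (row-major node order); one qubit
is assigned to each *edge* of the ring.  For edge ``(j, k)`` the circuit
applies, in order, Hadamards on qubits ``j`` and ``k``, then an IsingXX and
an IsingZZ coupling on the pair, both with angle ``pi * theta[j]`` where
``theta[j] = arccos(p_j)`` and ``p_j`` is the window pixel (normalised to
[0, 1]) at the edge's first node.  The filter output is one channel per
qubit, carrying the marginal probability of measuring that qubit in |1>.

The filter is fixed preprocessing: it has no trainable parameters.  Exact
mode reads marginals off the statevector and is bitwise deterministic;
sampled mode estimates them from a seeded multinomial draw (1024 shots by
default).

Two evaluation paths exist: :func:`quantvolve_window` is a direct,
gate-by-gate reference on a single window, and :func:`quantvolve_image`
runs a vectorised engine over all windows at once.  The two are asserted
equal in the test suite.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np

from . import qcore

__all__ = [
    "WindowGraph",
    "QuantvolutionConfig",
    "window_graph",
    "pixel_to_theta",
    "edge_unitary",
    "quantvolve_window",
    "quantvolve_image",
    "write_feature_map",
]


@dataclass(frozen=True)
class WindowGraph:
    """Ring graph over the ``k*k`` row-major pixels of a window."""

    k: int
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]

    @property
    def n_qubits(self) -> int:
        return len(self.edges)


@dataclass
class QuantvolutionConfig:
    """Configuration of the filter.

    k            window side length (2 or 4)
    stride       tiling stride; defaults to ``k`` (non-overlapping)
    theta_mode   'arccos' (theta = arccos(pixel), the default reading) or
                 'direct' (theta = pixel)
    theta_source 'first' (pixel at the edge's first node) or 'mean'
                 (mean of the two endpoint pixels)
    mode         'exact' or 'sampled'
    """

    k: int = 2
    stride: int | None = None
    theta_mode: str = "arccos"
    theta_source: str = "first"
    mode: str = "exact"
    shots: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k not in (2, 4):
            raise ValueError(f"window size k must be 2 or 4, got {self.k}")
        if self.stride is None:
            self.stride = self.k
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.theta_mode not in ("arccos", "direct"):
            raise ValueError(f"unknown theta_mode {self.theta_mode!r}")
        if self.theta_source not in ("first", "mean"):
            raise ValueError(f"unknown theta_source {self.theta_source!r}")
        if self.mode not in ("exact", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")


def window_graph(k: int) -> WindowGraph:
    """Ring over the row-major nodes ``0..k*k-1``; for k=2 the edge list is
    exactly ((0,1), (1,2), (2,3), (3,0))."""
    if k not in (2, 4):
        raise ValueError(f"window size k must be 2 or 4, got {k}")
    m = k * k
    edges = tuple((j, (j + 1) % m) for j in range(m))
    return WindowGraph(k=k, nodes=tuple(range(m)), edges=edges)


def pixel_to_theta(p: float) -> float:
    """theta = arccos(p) for a pixel value normalised to [0, 1]."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"normalised pixel value must lie in [0, 1], got {p}")
    return math.acos(p)


def edge_unitary(edge: tuple[int, int], theta_j: float, n_qubits: int) -> np.ndarray:
    """Dense n-qubit unitary for one edge: H_j, H_k, then XX and ZZ at angle
    ``pi * theta_j`` on the pair (circuit order; matrices multiply right to
    left)."""
    j, k = edge
    if not (0 <= j < n_qubits and 0 <= k < n_qubits) or j == k:
        raise ValueError(f"invalid edge {edge} for {n_qubits} qubits")
    alpha = math.pi * float(theta_j)
    h = qcore.hadamard_gate()
    u = qcore.embed_gate(h, [j], n_qubits)
    u = qcore.embed_gate(h, [k], n_qubits) @ u
    u = qcore.embed_gate(qcore.ising_xx_gate(alpha), [j, k], n_qubits) @ u
    u = qcore.embed_gate(qcore.ising_zz_gate(alpha), [j, k], n_qubits) @ u
    return u


def _window_thetas(pixels: np.ndarray, graph: WindowGraph, cfg: QuantvolutionConfig) -> np.ndarray:
    """Per-edge angles theta[j] for flattened window pixel rows (..., k*k)."""
    js = np.array([e[0] for e in graph.edges])
    ks = np.array([e[1] for e in graph.edges])
    if cfg.theta_source == "first":
        src = pixels[..., js]
    else:
        src = 0.5 * (pixels[..., js] + pixels[..., ks])
    if cfg.theta_mode == "arccos":
        return np.arccos(np.clip(src, 0.0, 1.0))
    return src.astype(float)


def quantvolve_window(window: np.ndarray, cfg: QuantvolutionConfig | None = None) -> np.ndarray:
    """Run the circuit on one ``k x k`` window; returns the length-``k**2``
    vector of per-qubit P(1) marginals.

    Reference implementation: sequential gate application on a statevector.
    """
    cfg = cfg or QuantvolutionConfig()
    window = np.asarray(window, dtype=float)
    if window.shape != (cfg.k, cfg.k):
        raise ValueError(f"expected a {cfg.k}x{cfg.k} window, got shape {window.shape}")
    if window.min() < 0.0 or window.max() > 1.0:
        raise ValueError("window values must lie in [0, 1]")
    graph = window_graph(cfg.k)
    n = graph.n_qubits
    thetas = _window_thetas(window.ravel(), graph, cfg)
    state = qcore.zero_state(n)
    h = qcore.hadamard_gate()
    for (j, k), th in zip(graph.edges, thetas):
        alpha = math.pi * th
        state = qcore.apply_gate(state, h, [j])
        state = qcore.apply_gate(state, h, [k])
        state = qcore.apply_gate(state, qcore.ising_xx_gate(alpha), [j, k])
        state = qcore.apply_gate(state, qcore.ising_zz_gate(alpha), [j, k])
    probs = qcore.basis_probabilities(state)
    if cfg.mode == "sampled":
        counts = qcore.sample_counts(probs, shots=cfg.shots, seed=cfg.seed)
        probs = counts.frequencies
    return qcore.marginal_one_probabilities(probs, n)


# ---------------------------------------------------------------------------
# vectorised engine: all windows of an image at once
# ---------------------------------------------------------------------------

_INV_SQRT2 = 1.0 / math.sqrt(2.0)


def _h_on_qubit(state: np.ndarray, q: int, n: int) -> None:
    """In-place Hadamard on qubit ``q`` of a flat (B, 2**n) state stack."""
    b = state.shape[0]
    v = state.reshape(b, 2**q, 2, -1)
    s0 = v[:, :, 0, :]
    s1 = v[:, :, 1, :]
    t0 = (s0 + s1) * _INV_SQRT2
    t1 = (s0 - s1) * _INV_SQRT2
    v[:, :, 0, :] = t0
    v[:, :, 1, :] = t1


def _batched_circuit_states(thetas: np.ndarray, n_qubits: int,
                            edges: tuple[tuple[int, int], ...],
                            dtype: np.dtype) -> np.ndarray:
    """Flat states (B, 2**n) after the full edge circuit for a batch of
    per-edge angle rows ``thetas`` of shape (B, n_edges).

    MSB-first bit convention matches :class:`qcore.Statevector`; the flat
    index is contiguous, so axis (q) of the bit tensor is the reshape block
    of size 2**(n-1-q)."""
    b = thetas.shape[0]
    n = n_qubits
    state = np.zeros((b, 2**n), dtype=dtype)
    state[:, 0] = 1.0
    hh = np.kron([[1, 1], [1, -1]], [[1, 1], [1, -1]]).astype(complex) / 2.0
    hh_rows_flipped = hh[::-1].copy()  # (X (x) X) . (H (x) H)
    for m, (j, k) in enumerate(edges):
        lo, hi = (j, k) if j < k else (k, j)
        alpha = math.pi * thetas[:, m]
        # fused per-edge two-qubit gate ZZ(a) . XX(a) . (H (x) H); every
        # factor is symmetric under qubit swap, so (lo, hi) ordering is safe
        c = np.cos(alpha / 2.0)[:, None, None]
        s = np.sin(alpha / 2.0)[:, None, None]
        half = np.exp(-0.5j * alpha)
        zz_diag = np.stack([half, half.conj(), half.conj(), half], axis=1)
        gate = zz_diag[:, :, None] * (c * hh - 1j * s * hh_rows_flipped)
        # gather the two coupled qubits into a trailing length-4 axis
        v = state.reshape(b, 2**lo, 2, 2 ** (hi - lo - 1), 2, -1)
        w = np.ascontiguousarray(v.transpose(0, 1, 3, 5, 2, 4)).reshape(b, -1, 4)
        w = np.matmul(w, gate.astype(dtype).transpose(0, 2, 1))
        w = w.reshape(b, 2**lo, 2 ** (hi - lo - 1), -1, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        state = np.ascontiguousarray(w).reshape(b, 2**n)
    return state


def _marginals_from_states(state: np.ndarray, n_qubits: int) -> np.ndarray:
    p = (np.abs(state) ** 2).astype(np.float64)
    b = p.shape[0]
    out = np.empty((b, n_qubits))
    for q in range(n_qubits):
        out[:, q] = p.reshape(b, 2**q, 2, -1)[:, :, 1, :].sum(axis=(1, 2))
    return out


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Bring an image to float values in [0, 1] (8-bit inputs divide by 255)."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(float) / 255.0
    else:
        image = image.astype(float)
        if image.size and image.max() > 1.0 + 1e-9:
            image = image / 255.0
    if image.size and (image.min() < -1e-9 or image.max() > 1.0 + 1e-9):
        raise ValueError("image values are not normalisable to [0, 1]")
    return np.clip(image, 0.0, 1.0)


def quantvolve_image(image: np.ndarray, cfg: QuantvolutionConfig | None = None) -> np.ndarray:
    """Apply the filter to a full image; returns a feature map of shape
    ``(floor((H-k)/stride)+1, floor((W-k)/stride)+1, k**2)`` with values in
    [0, 1] (per-qubit P(1) channels).  Remainder rows/columns are dropped.
    """
    cfg = cfg or QuantvolutionConfig()
    image = normalize_image(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    hh, ww = image.shape
    k, stride = cfg.k, cfg.stride
    if hh < k or ww < k:
        raise ValueError(f"image {image.shape} is smaller than the {k}x{k} window")
    out_h = (hh - k) // stride + 1
    out_w = (ww - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(image, (k, k))[::stride, ::stride]
    pixels = win.reshape(out_h * out_w, k * k)

    graph = window_graph(k)
    n = graph.n_qubits
    thetas = _window_thetas(pixels, graph, cfg)
    dtype = np.complex128 if n <= 8 else np.complex64
    if n > 8:
        # 16-qubit register: process windows in chunks to bound memory
        chunks = []
        step = 64
        for i in range(0, pixels.shape[0], step):
            st = _batched_circuit_states(thetas[i:i + step], n, graph.edges, dtype)
            chunks.append(_finalize(st, n, cfg, offset=i))
        marg = np.concatenate(chunks, axis=0)
    else:
        st = _batched_circuit_states(thetas, n, graph.edges, dtype)
        marg = _finalize(st, n, cfg, offset=0)
    return marg.reshape(out_h, out_w, n)


def _finalize(state: np.ndarray, n: int, cfg: QuantvolutionConfig, offset: int) -> np.ndarray:
    if cfg.mode == "exact":
        return _marginals_from_states(state, n)
    b = state.shape[0]
    joint = (np.abs(state) ** 2).astype(np.float64)
    joint /= joint.sum(axis=1, keepdims=True)
    out = np.empty((b, n))
    for i in range(b):
        counts = qcore.sample_counts(joint[i], shots=cfg.shots, seed=cfg.seed + offset + i)
        out[i] = qcore.marginal_one_probabilities(counts.frequencies, n)
    return out


def write_feature_map(feature_map: np.ndarray, directory: str, cfg: QuantvolutionConfig | None = None,
                      prefix: str = "channel") -> str:
    """Write one 8-bit grayscale PNG per channel plus a JSON sidecar with the
    shape and configuration; returns the sidecar path."""
    from PIL import Image

    os.makedirs(directory, exist_ok=True)
    fm = np.asarray(feature_map)
    for c in range(fm.shape[2]):
        arr = np.rint(np.clip(fm[:, :, c], 0.0, 1.0) * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(os.path.join(directory, f"{prefix}_{c:02d}.png"))
    sidecar = os.path.join(directory, f"{prefix}_meta.json")
    meta = {"shape": list(fm.shape)}
    if cfg is not None:
        meta["config"] = {k: getattr(cfg, k) for k in
                          ("k", "stride", "theta_mode", "theta_source", "mode", "shots", "seed")}
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return sidecar
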