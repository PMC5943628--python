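"""Functional forms of the network's building blocks.

These single-example, loop-free-of-batching functions state the math of one
LSTM step, global attention, and the MLP + softmax composition exactly as
the model computes them; the batched training code in :mod:`.model` is an
equivalent vectorization.  They are the reference surface that unit tests
compare against independently coded oracles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class LSTMStepParams:
    """The eight weight matrices and four biases of one LSTM cell.

    (W1,W2,b1) -> input gate, (W3,W4,b2) -> candidate, (W5,W6,b3) -> forget
    gate, (W7,W8,b4) -> output gate; odd-numbered matrices multiply the
    input, even-numbered the previous hidden state.
    """

    W1: np.ndarray
    W2: np.ndarray
    b1: np.ndarray
    W3: np.ndarray
    W4: np.ndarray
    b2: np.ndarray
    W5: np.ndarray
    W6: np.ndarray
    b3: np.ndarray
    W7: np.ndarray
    W8: np.ndarray
    b4: np.ndarray


def lstm_step(
    p: LSTMStepParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update: gates, memory write, gated output."""
    k = p.b1.shape[0]
    for name, arr in (("x_t", x_t), ("h_prev", h_prev), ("c_prev", c_prev)):
        if arr.shape != (k,):
            raise ValueError(f"{name} has shape {arr.shape}, expected ({k},)")
    i = sigmoid(p.W1 @ x_t + p.W2 @ h_prev + p.b1)
    g = np.tanh(p.W3 @ x_t + p.W4 @ h_prev + p.b2)
    f = sigmoid(p.W5 @ x_t + p.W6 @ h_prev + p.b3)
    o = sigmoid(p.W7 @ x_t + p.W8 @ h_prev + p.b4)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def run_lstm(
    p: LSTMStepParams, xs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Run a window of inputs (L, k) from zero state; returns (H, h_last)."""
    k = p.b1.shape[0]
    h = np.zeros(k)
    c = np.zeros(k)
    outputs = []
    for t in range(xs.shape[0]):
        h, c = lstm_step(p, xs[t], h, c)
        outputs.append(h)
    H = np.stack(outputs)
    return H, h


@dataclass
class AttentionParams:
    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    W4: np.ndarray
    w: np.ndarray


def attend(p: AttentionParams, S: np.ndarray, h_last: np.ndarray) -> np.ndarray:
    """Global attention over encoder outputs.

    ``S`` has the output vectors as its columns (shape (H, L)).  Computes
    M = tanh(W1 S + (W2 h_last) ⊕ 1_L), a = softmax(wᵀM), z = S aᵀ and the
    refined representation h' = tanh(W3 z + W4 h_last).
    """
    H, L = S.shape
    if h_last.shape != (H,):
        raise ValueError(f"h_last has shape {h_last.shape}, expected ({H},)")
    if p.W1.shape != (H, H):
        raise ValueError(f"W1 has shape {p.W1.shape}, expected ({H}, {H})")
    M = np.tanh(p.W1 @ S + np.outer(p.W2 @ h_last, np.ones(L)))
    a = softmax(p.w @ M)
    z = S @ a
    return np.tanh(p.W3 @ z + p.W4 @ h_last)


def attention_weights(p: AttentionParams, S: np.ndarray, h_last: np.ndarray) -> np.ndarray:
    """The softmax-normalized attention vector ``a`` alone."""
    L = S.shape[1]
    M = np.tanh(p.W1 @ S + np.outer(p.W2 @ h_last, np.ones(L)))
    return softmax(p.w @ M)


def compose_and_classify(
    W_mlp: np.ndarray,
    b_mlp: np.ndarray,
    h_left: np.ndarray,
    h_right: np.ndarray,
    augmented: np.ndarray | None = None,
) -> np.ndarray:
    """MLP composition of the two entity representations, then softmax.

    Optionally concatenates embedded distance/type features before the MLP.
    Returns the probability vector over relation types.
    """
    parts = [h_left, h_right] + ([augmented] if augmented is not None else [])
    u = np.concatenate(parts)
    if W_mlp.shape[1] != u.shape[0]:
        raise ValueError(
            f"W_mlp expects input width {W_mlp.shape[1]}, got {u.shape[0]}"
        )
    r = np.tanh(W_mlp @ u + b_mlp)
    return softmax(r)
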