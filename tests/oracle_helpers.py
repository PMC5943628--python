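"""Independent scalar-arithmetic oracles shared by unit and acceptance tests.

Deliberately written with python loops and ``math`` functions only, so they
share no code path with the numpy implementations they check.
"""
from __future__ import annotations

import math

from aderex.types import NONE_LABEL


def sig(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def oracle_lstm_step(p, x, h, c):
    k = len(x)

    def affine(Wa, Wb, b):
        return [
            sum(Wa[i][j] * x[j] for j in range(k))
            + sum(Wb[i][j] * h[j] for j in range(k))
            + b[i]
            for i in range(k)
        ]

    i_g = [sig(v) for v in affine(p.W1, p.W2, p.b1)]
    cand = [math.tanh(v) for v in affine(p.W3, p.W4, p.b2)]
    f_g = [sig(v) for v in affine(p.W5, p.W6, p.b3)]
    o_g = [sig(v) for v in affine(p.W7, p.W8, p.b4)]
    c_new = [f_g[i] * c[i] + i_g[i] * cand[i] for i in range(k)]
    h_new = [o_g[i] * math.tanh(c_new[i]) for i in range(k)]
    return h_new, c_new


def oracle_attend(p, S, h_last):
    k, L = len(S), len(S[0])
    W2h = [sum(p.W2[i][j] * h_last[j] for j in range(k)) for i in range(k)]
    M = [
        [math.tanh(sum(p.W1[i][j] * S[j][t] for j in range(k)) + W2h[i]) for t in range(L)]
        for i in range(k)
    ]
    scores = [sum(p.w[i] * M[i][t] for i in range(k)) for t in range(L)]
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    a = [e / sum(exps) for e in exps]
    z = [sum(S[i][t] * a[t] for t in range(L)) for i in range(k)]
    out = [
        math.tanh(
            sum(p.W3[i][j] * z[j] for j in range(k))
            + sum(p.W4[i][j] * h_last[j] for j in range(k))
        )
        for i in range(k)
    ]
    return out, a


def oracle_compose(W, b, hl, hr, aug=None):
    u = list(hl) + list(hr) + (list(aug) if aug is not None else [])
    r = [math.tanh(sum(W[i][j] * u[j] for j in range(len(u))) + b[i]) for i in range(len(b))]
    mx = max(r)
    exps = [math.exp(v - mx) for v in r]
    return [e / sum(exps) for e in exps]


def oracle_bin_label(bins, distance):
    """Interval-scan bin membership: (lower, upper], first bin includes 0."""
    lower = -1.0
    for bound, label in bins:
        if distance > lower and distance <= bound:
            return label
        lower = bound
    return NONE_LABEL


def oracle_prf(gold, pred, label):
    tp = sum(1 for g, p in zip(gold, pred) if g == p == label)
    fp = sum(1 for g, p in zip(gold, pred) if p == label and g != label)
    fn = sum(1 for g, p in zip(gold, pred) if g == label and p != label)
    prec = 100 * tp / (tp + fp) if tp + fp else 0.0
    rec = 100 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1
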