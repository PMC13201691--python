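"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles — explicit loops and
direct formula evaluation — and deliberately shares no code with the
package.
"""

import numpy as np


def conv2d_oracle(x, w, b=None, stride=1, padding=0):
    """Element-by-element direct-arithmetic 2-D convolution."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, C, H, W = x.shape
    Cout, Cin, k, _ = w.shape
    assert C == Cin
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    out = np.zeros((B, Cout, Ho, Wo))
    for bi in range(B):
        for co in range(Cout):
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[bi, :, i * stride:i * stride + k,
                               j * stride:j * stride + k]
                    out[bi, co, i, j] = (patch * w[co]).sum()
            if b is not None:
                out[bi, co] += b[co]
    return out


def auroc_pairs_oracle(scores, labels):
    """AUROC by exhaustive positive/negative pair counting, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def attention_oracle(Q, K, V):
    """Scaled dot-product attention by per-row explicit softmax arithmetic."""
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    d_k = Q.shape[-1]
    out = np.zeros((Q.shape[0], V.shape[1]))
    for i in range(Q.shape[0]):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(K.shape[0])])
        e = np.exp(scores - scores.max())
        weights = e / e.sum()
        out[i] = sum(weights[j] * V[j] for j in range(V.shape[0]))
    return out


def fire_params_closed_form(c_in, c_out):
    """Learnable scalars of a Fire module from the three conv closed forms."""
    c_s = max(1, c_in // 2)
    n = c_out // 2
    squeeze = c_in * c_s * 1 * 1 + c_s
    e1 = c_s * n * 1 * 1 + n
    e3 = c_s * n * 3 * 3 + n
    return squeeze + e1 + e3


def numeric_grad(f, x, eps=1e-5):
    """Central finite differences of scalar-valued f at x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
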