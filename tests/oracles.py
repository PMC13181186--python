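"""Independent oracles shared by the unit and acceptance tests.

Everything here is deliberately written against the mathematical definition
(dense attention, literal per-pixel counting) rather than reusing the
package's vectorised implementations.
"""

import numpy as np


def dense_attention_oracle(wa, tokens: np.ndarray) -> np.ndarray:
    """Brute-force multi-head softmax attention over one window's tokens.

    ``wa`` is a WindowAttention module whose weights are read; ``tokens`` is
    (N, C) in row-major window order.
    """
    N, C = tokens.shape
    H, hd = wa.num_heads, C // wa.num_heads
    flat = tokens @ wa.qkv.weight.data + wa.qkv.bias.data
    qkv = flat.reshape(N, 3, H, hd)
    out = np.zeros((N, H, hd))
    bias = wa.rel_bias.data[wa._rel_index.reshape(-1)].reshape(N, N, H)
    for h in range(H):
        q, k, v = qkv[:, 0, h], qkv[:, 1, h], qkv[:, 2, h]
        logits = q @ k.T * wa.scale + bias[:, :, h]
        logits -= logits.max(axis=-1, keepdims=True)
        w = np.exp(logits)
        w /= w.sum(axis=-1, keepdims=True)
        out[:, h] = w @ v
    return out.reshape(N, C) @ wa.proj.weight.data + wa.proj.bias.data


def brute_force_report(pred: np.ndarray, gt: np.ndarray):
    """Literal per-pixel recount and metric arithmetic.

    Returns ((recall, specificity, precision, f1, f2, acc, miou),
    (tp, fp, fn, tn)).
    """
    tp = fp = fn = tn = 0
    for p, g in zip(pred.reshape(-1), gt.reshape(-1)):
        if p == 1 and g == 1:
            tp += 1
        elif p == 1 and g == 0:
            fp += 1
        elif p == 0 and g == 1:
            fn += 1
        else:
            tn += 1

    def ratio(n, d):
        return 1.0 if d == 0 else n / d

    rec = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    f2 = 0.0 if prec + rec == 0 else 5 * prec * rec / (4 * prec + rec)
    acc = (tp + tn) / (tp + fp + fn + tn)
    miou = 0.5 * (ratio(tp, tp + fp + fn) + ratio(tn, tn + fp + fn))
    return (rec, spec, prec, f1, f2, acc, miou), (tp, fp, fn, tn)
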