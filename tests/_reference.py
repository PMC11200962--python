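"""Independent reference implementations used as oracles by the tests.

Everything here is written directly in numpy against the textbook
definitions (explicit loops where that is clearest) and deliberately does
not import the package's model or evaluation code, so agreement between
the two routes is meaningful evidence of correctness.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# rank-statistic and enumeration oracles for the metric suite
# ---------------------------------------------------------------------------

def auc_rank_oracle(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the probability of correct ranking, ties credited 1/2."""
    pos = scores[np.asarray(y_true) == 1]
    neg = scores[np.asarray(y_true) == 0]
    total = 0.0
    for p in pos:
        total += float((p > neg).sum()) + 0.5 * float((p == neg).sum())
    return total / (len(pos) * len(neg))


def ap_enumeration_oracle(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise average precision by explicit threshold enumeration."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(s), reverse=True):
        calls = s >= t
        tp = int((calls & (y == 1)).sum())
        fp = int((calls & (y == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def confusion_enumeration(y_true, y_prob, threshold):
    """Confusion counts by a plain loop."""
    tp = fp = fn = tn = 0
    for y, p in zip(y_true, y_prob):
        call = p >= threshold
        if y == 1 and call:
            tp += 1
        elif y == 1:
            fn += 1
        elif call:
            fp += 1
        else:
            tn += 1
    return tp, fp, fn, tn


# ---------------------------------------------------------------------------
# scalar neural-network oracles
# ---------------------------------------------------------------------------

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def softmax_rows(m: np.ndarray) -> np.ndarray:
    e = np.exp(m - m.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def attention_oracle(Q, K, V, d_k):
    """softmax(Q K^T / sqrt(d_k)) V by direct arithmetic."""
    scores = np.asarray(Q) @ np.asarray(K).swapaxes(-1, -2) / np.sqrt(d_k)
    return softmax_rows(scores) @ np.asarray(V)


def layer_norm_oracle(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def block_forward_oracle(X: np.ndarray, w: dict, n_heads: int,
                         gated: bool = False,
                         gate_source: str = "layer_input") -> np.ndarray:
    """Post-norm transformer block, optionally with sigmoid gates.

    ``w`` maps plain names (Wq, bq, ..., ln2_b) to numpy arrays with the
    same layout the package's model uses.  Written head-by-head with
    explicit slicing as an independent route.
    """
    B, S, D = X.shape
    d_k = D // n_heads
    Q_all = X @ w["Wq"] + w["bq"]
    K_all = X @ w["Wk"] + w["bk"]
    V_all = X @ w["Wv"] + w["bv"]
    ctx = np.zeros_like(X)
    for h in range(n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        ctx[:, :, sl] = attention_oracle(Q_all[:, :, sl], K_all[:, :, sl],
                                         V_all[:, :, sl], d_k)
    A = ctx @ w["Wo"] + w["bo"]
    if gated:
        src = X if gate_source == "layer_input" else A
        G = sigmoid(src @ w["Wg"] + w["bg"])
        A = G * A
    X1 = layer_norm_oracle(X + A, w["ln1_g"], w["ln1_b"])
    F = np.maximum(X1 @ w["F1"] + w["b1"], 0.0)
    if gated:
        G_F = sigmoid(X1 @ w["Fg"] + w["bgF"])
        F = F * G_F
    out = F @ w["F2"] + w["b2"]
    return layer_norm_oracle(X1 + out, w["ln2_g"], w["ln2_b"])


def model_forward_oracle(model, cat_codes: np.ndarray,
                         cont_values: np.ndarray) -> np.ndarray:
    """Full eval-mode forward pass rebuilt from the checkpoint arrays.

    Uses only the parameter arrays and configuration, not the package's
    forward code, mirroring the documented architecture layer by layer.
    """
    arrays = model.state_arrays()
    cfg = model.config
    n_cat = len(model.cat_cardinalities)
    B = cat_codes.shape[0]
    D = cfg.embed_dim
    X = np.stack([arrays[f"emb_{j}"][cat_codes[:, j]] for j in range(n_cat)],
                 axis=1) + arrays["col_id"]
    for b in range(cfg.n_blocks):
        w = {k.split(".", 1)[1]: v for k, v in arrays.items()
             if k.startswith(f"block{b}.")}
        X = block_forward_oracle(X, w, cfg.n_heads, gated=cfg.gate_enabled,
                                 gate_source=cfg.gate_input_source)
    flat = X.reshape(B, n_cat * D)
    if cont_values.shape[1]:
        flat = np.concatenate([flat, cont_values], axis=1)
    z = np.maximum(flat @ arrays["head.W1"] + arrays["head.b1"], 0.0)
    z = np.maximum(z @ arrays["head.W2"] + arrays["head.b2"], 0.0)
    return z @ arrays["head.W3"] + arrays["head.b3"]
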