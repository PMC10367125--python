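"""A small NumPy transformer encoder with exact manual backpropagation.

This is the computational engine behind all five model families: token +
position embeddings, pre-LayerNorm encoder blocks with multi-head scaled
dot-product self-attention

    MultiHead(Q, K, V) = Concat(head_1, ..., head_h) W^O
    head_i = Attention(Q W_i^Q, K W_i^K, V W_i^V)
    Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V

(with row-softmax over keys, padding keys masked out), a GELU feed-forward
sublayer, and task heads for masked-language-model prediction, per-token
replaced-token detection, and [CLS] sequence classification.  Gradients
are derived by hand for every operation, and parameters are updated with
Adam under a linear-warmup learning-rate schedule.

Everything runs in float64 on a single CPU and is bit-reproducible for a
fixed seed: there is no dropout and no non-deterministic kernel.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np

NEG_INF = -1e9
IGNORE_INDEX = -100


# ---------------------------------------------------------------------------
# primitive ops

def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm_forward(x, g, b, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu_forward(x):
    u = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(u)
    return 0.5 * x * (1.0 + t), (x, t)


def gelu_backward(dy, cache):
    x, t = cache
    du = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du)


def _split_heads(x, n_heads):
    B, T, d = x.shape
    dk = d // n_heads
    return x.reshape(B, T, n_heads, dk).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, h, T, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)


def _linear_grads(x, dy):
    """Weight/bias grads for y = x @ W + b with x (..., din), dy (..., dout)."""
    xf = x.reshape(-1, x.shape[-1])
    dyf = dy.reshape(-1, dy.shape[-1])
    return xf.T @ dyf, dyf.sum(axis=0)


# ---------------------------------------------------------------------------
# encoder

class TransformerEncoder:
    """Pre-LN transformer encoder plus task heads, parameters in a flat dict."""

    def __init__(self, config, seed: int = 0, params: Optional[Dict[str, np.ndarray]] = None):
        self.config = config
        if params is not None:
            self.params = params
        else:
            self.params = self._init_params(np.random.default_rng(seed))

    # -- initialisation -----------------------------------------------------
    def _init_params(self, rng) -> Dict[str, np.ndarray]:
        c = self.config
        d, f, V, P = c.hidden_size, c.ffn_size, c.vocab_size, c.max_positions
        std = c.initializer_range

        def W(*shape):
            return rng.normal(0.0, std, size=shape)

        p: Dict[str, np.ndarray] = {
            "emb_tok": W(V, d),
            "emb_pos": W(P, d),
            "emb_ln_g": np.ones(d),
            "emb_ln_b": np.zeros(d),
            "ln_f_g": np.ones(d),
            "ln_f_b": np.zeros(d),
            # task heads
            "mlm_W": W(d, V),
            "mlm_b": np.zeros(V),
            "cls_W": W(d, 2),
            "cls_b": np.zeros(2),
            "disc_W": W(d, 1),
            "disc_b": np.zeros(1),
        }
        for i in range(c.n_layers):
            p.update(
                {
                    f"l{i}_ln1_g": np.ones(d),
                    f"l{i}_ln1_b": np.zeros(d),
                    f"l{i}_Wq": W(d, d),
                    f"l{i}_bq": np.zeros(d),
                    f"l{i}_Wk": W(d, d),
                    f"l{i}_bk": np.zeros(d),
                    f"l{i}_Wv": W(d, d),
                    f"l{i}_bv": np.zeros(d),
                    f"l{i}_Wo": W(d, d),
                    f"l{i}_bo": np.zeros(d),
                    f"l{i}_ln2_g": np.ones(d),
                    f"l{i}_ln2_b": np.zeros(d),
                    f"l{i}_W1": W(d, f),
                    f"l{i}_b1": np.zeros(f),
                    f"l{i}_W2": W(f, d),
                    f"l{i}_b2": np.zeros(d),
                }
            )
        return p

    def clone(self) -> "TransformerEncoder":
        return TransformerEncoder(
            self.config, params={k: v.copy() for k, v in self.params.items()}
        )

    # -- forward ------------------------------------------------------------
    def forward(
        self, ids: np.ndarray, mask: np.ndarray, store_attn: bool = False
    ):
        """Run the backbone.

        Returns (hidden (B,T,d), attentions, cache).  ``attentions`` is a
        list of (B, h, T, T) row-stochastic arrays, one per layer, when
        ``store_attn`` is set (always stored; the flag is kept for API
        symmetry and costs nothing at this scale).
        """
        p, c = self.params, self.config
        ids = np.asarray(ids, dtype=np.int64)
        mask = np.asarray(mask, dtype=np.float64)
        B, T = ids.shape
        dk = c.hidden_size // c.n_heads
        scale = 1.0 / math.sqrt(dk)

        x_e = p["emb_tok"][ids] + p["emb_pos"][:T][None, :, :]
        x, c_emb = layer_norm_forward(x_e, p["emb_ln_g"], p["emb_ln_b"])

        # additive bias: NEG_INF on padded key positions, 0 elsewhere
        key_bias = (1.0 - mask[:, None, None, :]) * NEG_INF

        attns: List[np.ndarray] = []
        layer_caches = []
        for i in range(c.n_layers):
            y, c_ln1 = layer_norm_forward(x, p[f"l{i}_ln1_g"], p[f"l{i}_ln1_b"])
            Q = y @ p[f"l{i}_Wq"] + p[f"l{i}_bq"]
            K = y @ p[f"l{i}_Wk"] + p[f"l{i}_bk"]
            V = y @ p[f"l{i}_Wv"] + p[f"l{i}_bv"]
            Qh, Kh, Vh = (_split_heads(t, c.n_heads) for t in (Q, K, V))
            S = np.matmul(Qh, Kh.transpose(0, 1, 3, 2)) * scale + key_bias
            A = softmax(S)
            ctx_h = np.matmul(A, Vh)
            ctx = _merge_heads(ctx_h)
            o = ctx @ p[f"l{i}_Wo"] + p[f"l{i}_bo"]
            x1 = x + o
            z, c_ln2 = layer_norm_forward(x1, p[f"l{i}_ln2_g"], p[f"l{i}_ln2_b"])
            a = z @ p[f"l{i}_W1"] + p[f"l{i}_b1"]
            g, c_g = gelu_forward(a)
            fout = g @ p[f"l{i}_W2"] + p[f"l{i}_b2"]
            x2 = x1 + fout

            attns.append(A)
            layer_caches.append(
                dict(y=y, c_ln1=c_ln1, Qh=Qh, Kh=Kh, Vh=Vh, A=A, ctx=ctx,
                     c_ln2=c_ln2, z=z, c_g=c_g, g=g)
            )
            x = x2

        hidden, c_lnf = layer_norm_forward(x, p["ln_f_g"], p["ln_f_b"])
        cache = dict(ids=ids, T=T, c_emb=c_emb, layers=layer_caches,
                     c_lnf=c_lnf, scale=scale)
        return hidden, attns, cache

    # -- backward -----------------------------------------------------------
    def backward(self, cache, dhidden: np.ndarray) -> Dict[str, np.ndarray]:
        p, c = self.params, self.config
        grads: Dict[str, np.ndarray] = {}

        dx, grads["ln_f_g"], grads["ln_f_b"] = layer_norm_backward(
            dhidden, cache["c_lnf"]
        )

        for i in reversed(range(c.n_layers)):
            lc = cache["layers"][i]
            # x2 = x1 + FFN(LN2(x1))
            df = dx
            grads[f"l{i}_W2"], grads[f"l{i}_b2"] = _linear_grads(lc["g"], df)
            dg = df @ p[f"l{i}_W2"].T
            da = gelu_backward(dg, lc["c_g"])
            grads[f"l{i}_W1"], grads[f"l{i}_b1"] = _linear_grads(lc["z"], da)
            dz = da @ p[f"l{i}_W1"].T
            dz_x, grads[f"l{i}_ln2_g"], grads[f"l{i}_ln2_b"] = layer_norm_backward(
                dz, lc["c_ln2"]
            )
            dx1 = dx + dz_x

            # x1 = x + MHSA(LN1(x))
            do = dx1
            grads[f"l{i}_Wo"], grads[f"l{i}_bo"] = _linear_grads(lc["ctx"], do)
            dctx = do @ p[f"l{i}_Wo"].T
            dctx_h = _split_heads(dctx, c.n_heads)
            A, Qh, Kh, Vh = lc["A"], lc["Qh"], lc["Kh"], lc["Vh"]
            dA = np.matmul(dctx_h, Vh.transpose(0, 1, 3, 2))
            dVh = np.matmul(A.transpose(0, 1, 3, 2), dctx_h)
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dQh = np.matmul(dS, Kh) * cache["scale"]
            dKh = np.matmul(dS.transpose(0, 1, 3, 2), Qh) * cache["scale"]
            dQ, dK, dV = (_merge_heads(t) for t in (dQh, dKh, dVh))
            y = lc["y"]
            grads[f"l{i}_Wq"], grads[f"l{i}_bq"] = _linear_grads(y, dQ)
            grads[f"l{i}_Wk"], grads[f"l{i}_bk"] = _linear_grads(y, dK)
            grads[f"l{i}_Wv"], grads[f"l{i}_bv"] = _linear_grads(y, dV)
            dy = dQ @ p[f"l{i}_Wq"].T + dK @ p[f"l{i}_Wk"].T + dV @ p[f"l{i}_Wv"].T
            dy_x, grads[f"l{i}_ln1_g"], grads[f"l{i}_ln1_b"] = layer_norm_backward(
                dy, lc["c_ln1"]
            )
            dx = dx1 + dy_x

        dx_e, grads["emb_ln_g"], grads["emb_ln_b"] = layer_norm_backward(
            dx, cache["c_emb"]
        )
        ids, T = cache["ids"], cache["T"]
        demb_tok = np.zeros_like(p["emb_tok"])
        np.add.at(demb_tok, ids.reshape(-1), dx_e.reshape(-1, dx_e.shape[-1]))
        grads["emb_tok"] = demb_tok
        demb_pos = np.zeros_like(p["emb_pos"])
        demb_pos[:T] = dx_e.sum(axis=0)
        grads["emb_pos"] = demb_pos
        return grads

    # -- task heads ---------------------------------------------------------
    def mlm_loss(self, hidden: np.ndarray, labels: np.ndarray):
        """Mean cross-entropy over positions where labels != IGNORE_INDEX.

        Returns (loss, dhidden, head_grads).
        """
        p = self.params
        sel = labels != IGNORE_INDEX
        n = int(sel.sum())
        dhidden = np.zeros_like(hidden)
        if n == 0:
            return 0.0, dhidden, {"mlm_W": np.zeros_like(p["mlm_W"]),
                                  "mlm_b": np.zeros_like(p["mlm_b"])}
        hf = hidden[sel]                     # (n, d)
        logits = hf @ p["mlm_W"] + p["mlm_b"]
        probs = softmax(logits)
        tgt = labels[sel]
        loss = -np.mean(np.log(probs[np.arange(n), tgt] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(n), tgt] -= 1.0
        dlogits /= n
        head_grads = {"mlm_W": hf.T @ dlogits, "mlm_b": dlogits.sum(axis=0)}
        dhidden[sel] = dlogits @ p["mlm_W"].T
        return float(loss), dhidden, head_grads

    def cls_logits(self, hidden: np.ndarray) -> np.ndarray:
        return hidden[:, 0, :] @ self.params["cls_W"] + self.params["cls_b"]

    def cls_loss(self, hidden: np.ndarray, y: np.ndarray):
        """Mean 2-class cross-entropy on the [CLS] representation."""
        p = self.params
        B = hidden.shape[0]
        logits = self.cls_logits(hidden)
        probs = softmax(logits)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        head_grads = {
            "cls_W": hidden[:, 0, :].T @ dlogits,
            "cls_b": dlogits.sum(axis=0),
        }
        dhidden = np.zeros_like(hidden)
        dhidden[:, 0, :] = dlogits @ p["cls_W"].T
        return float(loss), dhidden, head_grads

    def disc_loss(self, hidden: np.ndarray, labels: np.ndarray, positions: np.ndarray):
        """Per-token sigmoid BCE for replaced-token detection.

        ``labels`` in {0,1}, evaluated only where ``positions`` is True.
        """
        p = self.params
        logits = (hidden @ p["disc_W"])[..., 0] + p["disc_b"][0]
        n = int(positions.sum())
        if n == 0:
            z = np.zeros_like(hidden)
            return 0.0, z, {"disc_W": np.zeros_like(p["disc_W"]),
                            "disc_b": np.zeros_like(p["disc_b"])}
        sig = 1.0 / (1.0 + np.exp(-logits))
        y = labels.astype(np.float64)
        eps = 1e-12
        loss = -np.mean(
            y[positions] * np.log(sig[positions] + eps)
            + (1 - y[positions]) * np.log(1 - sig[positions] + eps)
        )
        dlogits = np.zeros_like(logits)
        dlogits[positions] = (sig[positions] - y[positions]) / n
        head_grads = {
            "disc_W": (hidden.reshape(-1, hidden.shape[-1]).T @ dlogits.reshape(-1, 1)),
            "disc_b": np.array([dlogits.sum()]),
        }
        dhidden = dlogits[..., None] * p["disc_W"][None, None, :, 0]
        return float(loss), dhidden, head_grads


# ---------------------------------------------------------------------------
# optimiser

class Adam:
    """Adam with linear learning-rate warmup then a constant rate."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 warmup_steps: int = 0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.warmup = warmup_steps
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def current_lr(self) -> float:
        if self.warmup > 0 and self.t < self.warmup:
            return self.lr * (self.t + 1) / self.warmup
        return self.lr

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        lr = self.current_lr()
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
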