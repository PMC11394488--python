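"""The dual-attention aggregator.

Pipeline for one bag: three linear maps embed the key set and the bag
(queries/values); cross-attention lets every key slot take a convex
combination of the bag's value vectors (softmax over instances, scaled
by 1/sqrt(Dh)); gated attention — a tanh/sigmoid product gate — weighs
the tau cross-attention outputs into a single slide representation z;
an affine head maps z to two class logits.

Implemented in NumPy with hand-derived gradients (`loss_and_grads`);
`forward_loop` is an intentionally naive scalar-loop reference used to
cross-check the vectorized path.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field, fields
from io import BytesIO
from pathlib import Path

import numpy as np

from damil.bags import EmbeddingBag
from damil.keyset import KeySet


@dataclass
class DamilConfig:
    dim: int = 768  # D: input embedding dimension
    hidden_dim: int = 512  # Dh
    gate_dim: int = 256  # L
    n_classes: int = 2
    seed: int = 0
    bias_in_embeddings: bool = True
    bias_in_gate: bool = False

    def __post_init__(self) -> None:
        if min(self.dim, self.hidden_dim, self.gate_dim) < 1:
            raise ValueError("dim, hidden_dim and gate_dim must be >= 1")
        if self.n_classes != 2:
            raise ValueError("this aggregator is a binary (RC/NRC) classifier")


@dataclass
class DamilParams:
    """Named weight arrays; gate maps carry no bias by default."""

    W_k: np.ndarray  # (Dh, D)
    W_q: np.ndarray  # (Dh, D)
    W_v: np.ndarray  # (Dh, D)
    V: np.ndarray  # (L, Dh) gate tanh branch
    U: np.ndarray  # (L, Dh) gate sigmoid branch
    w: np.ndarray  # (1, L) gate scorer
    head_W: np.ndarray  # (n_classes, Dh)
    head_b: np.ndarray | None  # (n_classes,)
    b_k: np.ndarray | None = None
    b_q: np.ndarray | None = None
    b_v: np.ndarray | None = None
    b_V: np.ndarray | None = None
    b_U: np.ndarray | None = None
    b_w: np.ndarray | None = None

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.arrays().values()))

    def copy(self) -> "DamilParams":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        return DamilParams(
            **{k: (v.copy() if v is not None else None) for k, v in kwargs.items()}
        )


@dataclass
class AttentionOutput:
    H: np.ndarray  # (tau, Dh) cross-attention output
    attn: np.ndarray  # (tau, n) row-stochastic cross-attention weights
    a: np.ndarray  # (tau,) gated-attention weights, sums to 1
    z: np.ndarray  # (Dh,) slide representation
    logits: np.ndarray  # (n_classes,)
    probs: np.ndarray  # (n_classes,) sums to 1

    @property
    def p_rc(self) -> float:
        """Probability of the positive (RC) class, index 1."""
        return float(self.probs[1])


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    scale = np.sqrt(2.0 / sum(shape))
    return rng.normal(0.0, scale, size=shape)


def init_params(config: DamilConfig) -> DamilParams:
    """Glorot-normal weights, zero biases; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    D, Dh, L, C = config.dim, config.hidden_dim, config.gate_dim, config.n_classes
    eb = config.bias_in_embeddings
    gb = config.bias_in_gate
    return DamilParams(
        W_k=_glorot(rng, (Dh, D)),
        W_q=_glorot(rng, (Dh, D)),
        W_v=_glorot(rng, (Dh, D)),
        V=_glorot(rng, (L, Dh)),
        U=_glorot(rng, (L, Dh)),
        w=_glorot(rng, (1, L)),
        head_W=_glorot(rng, (C, Dh)),
        head_b=np.zeros(C) if eb else None,
        b_k=np.zeros(Dh) if eb else None,
        b_q=np.zeros(Dh) if eb else None,
        b_v=np.zeros(Dh) if eb else None,
        b_V=np.zeros(L) if gb else None,
        b_U=np.zeros(L) if gb else None,
        b_w=np.zeros(1) if gb else None,
    )


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _affine(W: np.ndarray, X: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    out = W @ X
    if b is not None:
        out = out + b[:, None]
    return out


def cross_attention(
    K: np.ndarray, Q: np.ndarray, params: DamilParams
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-attend the embedded key set against the bag.

    K is (D, tau), Q is (D, n). Scores K~^T Q~ / sqrt(Dh) are softmaxed
    over the instance axis, so each of the tau rows of the returned
    attention matrix is a distribution over patches; H = A V~^T.
    Returns (H (tau, Dh), A (tau, n)).
    """
    if K.shape[0] != Q.shape[0]:
        raise ValueError(f"K and Q disagree on D: {K.shape[0]} vs {Q.shape[0]}")
    if K.shape[1] < 1 or Q.shape[1] < 1:
        raise ValueError("need at least one key and one instance")
    Dh = params.W_k.shape[0]
    Kt = _affine(params.W_k, K, params.b_k)  # (Dh, tau)
    Qt = _affine(params.W_q, Q, params.b_q)  # (Dh, n)
    Vt = _affine(params.W_v, Q, params.b_v)  # (Dh, n)
    S = (Kt.T @ Qt) / np.sqrt(Dh)  # (tau, n)
    A = _softmax(S, axis=1)
    return A @ Vt.T, A


def gated_attention(
    H: np.ndarray, params: DamilParams
) -> tuple[np.ndarray, np.ndarray]:
    """Tanh/sigmoid product gate over the tau rows of H.

    a_i ~ exp(w (tanh(V h_i) * sigm(U h_i))) normalized over i;
    z = sum_i a_i h_i. Returns (a (tau,), z (Dh,)).
    """
    H = np.asarray(H)
    if not np.isfinite(H).all():
        raise ValueError("non-finite cross-attention output")
    T = np.tanh(_affine(params.V, H.T, params.b_V).T)  # (tau, L)
    G = _sigmoid(_affine(params.U, H.T, params.b_U).T)  # (tau, L)
    e = _affine(params.w, (T * G).T, params.b_w).ravel()  # (tau,)
    a = _softmax(e)
    return a, a @ H


def forward(
    bag: EmbeddingBag | np.ndarray, keyset: KeySet, params: DamilParams
) -> AttentionOutput:
    """Full aggregator pass for one bag; invariant to instance order."""
    E = bag.embeddings if isinstance(bag, EmbeddingBag) else np.asarray(bag)
    if E.shape[0] == 0:
        raise ValueError("empty bag")
    if E.shape[1] != keyset.dim:
        raise ValueError(
            f"bag dimension {E.shape[1]} != key-set dimension {keyset.dim}"
        )
    H, A = cross_attention(keyset.K, E.T.astype(np.float64), params)
    a, z = gated_attention(H, params)
    logits = params.head_W @ z
    if params.head_b is not None:
        logits = logits + params.head_b
    return AttentionOutput(H=H, attn=A, a=a, z=z, logits=logits, probs=_softmax(logits))


def forward_loop(
    bag: EmbeddingBag | np.ndarray, keyset: KeySet, params: DamilParams
) -> AttentionOutput:
    """Pure-loop scalar reference of `forward`; for cross-checking only."""
    E = bag.embeddings if isinstance(bag, EmbeddingBag) else np.asarray(bag)
    K = keyset.K
    D, tau = K.shape
    n = E.shape[0]
    Dh = params.W_k.shape[0]
    L = params.V.shape[0]

    def aff(W, b, x):
        out = [sum(W[i][j] * x[j] for j in range(len(x))) for i in range(W.shape[0])]
        if b is not None:
            out = [o + b[i] for i, o in enumerate(out)]
        return out

    Kt = [aff(params.W_k, params.b_k, K[:, t]) for t in range(tau)]
    Qt = [aff(params.W_q, params.b_q, E[i]) for i in range(n)]
    Vt = [aff(params.W_v, params.b_v, E[i]) for i in range(n)]

    H = np.zeros((tau, Dh))
    A = np.zeros((tau, n))
    for t in range(tau):
        scores = [
            sum(Kt[t][d] * Qt[i][d] for d in range(Dh)) / np.sqrt(Dh) for i in range(n)
        ]
        mx = max(scores)
        exps = [np.exp(s - mx) for s in scores]
        tot = sum(exps)
        for i in range(n):
            A[t, i] = exps[i] / tot
            for d in range(Dh):
                H[t, d] += A[t, i] * Vt[i][d]

    e = []
    for t in range(tau):
        tanh_part = aff(params.V, params.b_V, H[t])
        sig_part = aff(params.U, params.b_U, H[t])
        gated = [
            np.tanh(tanh_part[l]) * (1.0 / (1.0 + np.exp(-sig_part[l])))
            for l in range(L)
        ]
        val = sum(params.w[0][l] * gated[l] for l in range(L))
        if params.b_w is not None:
            val += params.b_w[0]
        e.append(val)
    mx = max(e)
    exps = [np.exp(v - mx) for v in e]
    a = np.array([v / sum(exps) for v in exps])
    z = np.array([sum(a[t] * H[t, d] for t in range(tau)) for d in range(Dh)])
    logits = np.array(aff(params.head_W, params.head_b, z))
    probs = np.exp(logits - logits.max())
    probs = probs / probs.sum()
    return AttentionOutput(H=H, attn=A, a=a, z=z, logits=logits, probs=probs)


def loss_and_grads(
    bag: EmbeddingBag | np.ndarray,
    keyset: KeySet,
    params: DamilParams,
    y: int,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy loss for class y and gradients for every parameter.

    Manual backward pass through head, gated attention, cross-attention
    and the three embedding maps; verified against finite differences.
    """
    E = bag.embeddings if isinstance(bag, EmbeddingBag) else np.asarray(bag)
    if E.shape[0] == 0:
        raise ValueError("empty bag")
    K = keyset.K
    Q = E.T.astype(np.float64)  # (D, n)
    Dh = params.W_k.shape[0]

    # --- forward (cached intermediates) ---
    Kt = _affine(params.W_k, K, params.b_k)
    Qt = _affine(params.W_q, Q, params.b_q)
    Vt = _affine(params.W_v, Q, params.b_v)
    S = (Kt.T @ Qt) / np.sqrt(Dh)
    A = _softmax(S, axis=1)  # (tau, n)
    H = A @ Vt.T  # (tau, Dh)
    preT = _affine(params.V, H.T, params.b_V).T  # (tau, L)
    preG = _affine(params.U, H.T, params.b_U).T
    T = np.tanh(preT)
    G = _sigmoid(preG)
    e = _affine(params.w, (T * G).T, params.b_w).ravel()
    a = _softmax(e)
    z = a @ H
    logits = params.head_W @ z
    if params.head_b is not None:
        logits = logits + params.head_b
    p = _softmax(logits)
    loss = -float(np.log(max(p[y], 1e-300)))

    # --- backward ---
    g: dict[str, np.ndarray] = {}
    dlogits = p.copy()
    dlogits[y] -= 1.0
    g["head_W"] = np.outer(dlogits, z)
    if params.head_b is not None:
        g["head_b"] = dlogits
    dz = params.head_W.T @ dlogits  # (Dh,)
    da = H @ dz  # (tau,)
    dH = np.outer(a, dz)  # from z = a @ H
    de = a * (da - a @ da)  # softmax backward over keys
    dGate = np.outer(de, params.w.ravel())  # (tau, L); d(T*G)
    g["w"] = (de[None, :] @ (T * G))
    if params.b_w is not None:
        g["b_w"] = np.array([de.sum()])
    dpreT = dGate * G * (1.0 - T**2)
    dpreG = dGate * T * G * (1.0 - G)
    g["V"] = dpreT.T @ H
    g["U"] = dpreG.T @ H
    if params.b_V is not None:
        g["b_V"] = dpreT.sum(axis=0)
    if params.b_U is not None:
        g["b_U"] = dpreG.sum(axis=0)
    dH = dH + dpreT @ params.V + dpreG @ params.U  # (tau, Dh)

    dA = dH @ Vt  # (tau, n)
    dVt = dH.T @ A  # (Dh, n)
    dS = A * (dA - (A * dA).sum(axis=1, keepdims=True))  # row softmax backward
    dKt = (Qt @ dS.T) / np.sqrt(Dh)  # (Dh, tau)
    dQt = (Kt @ dS) / np.sqrt(Dh)  # (Dh, n)

    g["W_k"] = dKt @ K.T
    g["W_q"] = dQt @ Q.T
    g["W_v"] = dVt @ Q.T
    if params.b_k is not None:
        g["b_k"] = dKt.sum(axis=1)
        g["b_q"] = dQt.sum(axis=1)
        g["b_v"] = dVt.sum(axis=1)
    return loss, g


def count_params_flops(
    config: DamilConfig, n: int, tau: int
) -> tuple[int, int]:
    """Trainable-parameter count and multiply-accumulate count.

    Parameters are enumerated from the actual arrays produced by
    `init_params`. MACs cover one evaluation forward pass: the three
    linear embeddings, the tau x n x Dh attention products (scores and
    value mixing), the gate, the weighted sum and the head — linear in
    n at fixed tau, never quadratic in n.
    """
    params = init_params(config)
    n_params = params.n_parameters()
    D, Dh, L, C = config.dim, config.hidden_dim, config.gate_dim, config.n_classes
    macs = 0
    macs += Dh * D * tau  # key embedding
    macs += Dh * D * n * 2  # query + value embeddings
    macs += tau * n * Dh  # attention scores K~^T Q~
    macs += tau * n * Dh  # H = A V~^T
    macs += tau * L * Dh * 2  # gate tanh + sigmoid branches
    macs += tau * L  # gate scorer
    macs += tau * Dh  # z = sum a_i h_i
    macs += C * Dh  # head
    return n_params, macs


def save_checkpoint(
    params: DamilParams, config: DamilConfig, path: str | Path
) -> None:
    """Single-file archive: named parameter arrays + JSON config."""
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(config)))
        buf = BytesIO()
        np.savez(buf, **params.arrays())
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[DamilParams, DamilConfig]:
    with zipfile.ZipFile(path, "r") as zf:
        config = DamilConfig(**json.loads(zf.read("config.json")))
        with np.load(BytesIO(zf.read("params.npz"))) as data:
            arrays = {k: data[k] for k in data.files}
    template = init_params(config)
    kwargs = {
        f.name: arrays.get(f.name) for f in fields(DamilParams)
    }
    # restore None for absent biases
    for f in fields(DamilParams):
        if kwargs[f.name] is None and getattr(template, f.name) is not None:
            raise ValueError(f"checkpoint missing parameter {f.name}")
    return DamilParams(**kwargs), config
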