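"""Echo State Network decoder with online RLS and reinforcement updates.

The reservoir state evolves by leaky integration of a fixed random
recurrent pool,

    R(t) = (1 - a) R(t-1) + a tanh(W_in in(t) + W_res R(t-1)),

with spectral_radius(W_res) < 1 so the network forgets its initial
condition (the echo-state property).  Each output head is a linear map of
the concatenated reservoir-and-input vector,

    out(t) = W_out [R(t); in(t)],

trained online: recursive least squares on labelled windows, and a
satisfaction-gated reinforcement rule with an eligibility trace

    E   <- delta E + (1 - delta) out (x)T      (x = [R; in])
    W   <- W - alpha (1 - satisfaction) E

which pushes the readout away from recently produced outputs whenever the
user signals dissatisfaction, and leaves it untouched while satisfied.

Heads: ``state`` (movement class, argmax-decoded), ``trajectory`` (raw 3D
coordinates per hand, pure regression) and ``satisfaction`` (binary,
argmax-decoded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

__all__ = [
    "ReadoutHead",
    "ESNModel",
    "esn_init",
    "esn_step",
    "esn_output",
    "rls_update",
    "rl_update",
    "decode_state",
    "decode_satisfaction",
    "save_model",
    "load_model",
]


@dataclass
class ReadoutHead:
    """One linear readout with its RLS state and eligibility trace."""

    W_out: np.ndarray               # (n_outputs, N+K)
    rls_P: np.ndarray               # (N+K, N+K) inverse correlation matrix
    forgetting: float = 1.0
    E: np.ndarray = None            # eligibility trace, same shape as W_out
    alpha: float = 1e-4             # reinforcement learning rate
    delta: float = 0.9              # eligibility trace decay rate

    def __post_init__(self) -> None:
        if not 0 < self.forgetting <= 1:
            raise ValueError("forgetting factor must be in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if self.E is None:
            self.E = np.zeros_like(self.W_out)


@dataclass
class ESNModel:
    W_in: np.ndarray                # (N, K)
    W_res: sp.csr_matrix            # (N, N), spectral radius < 1
    a: float                        # leaking rate
    R: np.ndarray                   # (N,) reservoir state
    heads: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.W_in.shape[0]

    @property
    def K(self) -> int:
        return self.W_in.shape[1]


def _spectral_radius(W: sp.spmatrix) -> float:
    n = W.shape[0]
    if n < 6:
        return float(np.max(np.abs(np.linalg.eigvals(W.toarray()))))
    # fixed ARPACK start vector: the estimate (hence the rescale) must be
    # bit-reproducible across calls
    v0 = np.full(n, 1.0 / np.sqrt(n))
    val = scipy.sparse.linalg.eigs(
        W.astype(float), k=1, which="LM", return_eigenvectors=False,
        maxiter=10000, tol=0, v0=v0,
    )
    return float(np.abs(val[0]))


def esn_init(
    N: int,
    K: int,
    a: float = 0.5,
    sparsity: float = 0.5,
    rho: float = 0.95,
    input_scale: float = 1.0,
    seed: int = 0,
    heads: dict | None = None,
    eps: float = 1e-2,
    forgetting: float = 1.0,
    alpha: float = 1e-4,
    delta: float = 0.9,
) -> ESNModel:
    """Build a reservoir with exactly ``floor(sparsity * N**2)`` nonzero
    recurrent weights, rescaled to spectral radius ``rho``.

    ``heads`` maps head name -> output dimension; readout weights start at
    zero, RLS inverse-correlation at I/eps. Reproducible under ``seed``.
    """
    if N < 1 or K < 1:
        raise ValueError("N and K must be >= 1")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    if not 0 < a <= 1:
        raise ValueError("leaking rate must be in (0, 1]")
    if rho >= 1:
        raise ValueError("spectral radius target must be < 1")
    rng = np.random.default_rng(seed)
    W_in = rng.uniform(-input_scale, input_scale, size=(N, K))
    nnz = int(sparsity * N * N)
    flat = rng.choice(N * N, size=nnz, replace=False)
    vals = rng.uniform(-1.0, 1.0, size=nnz)
    W_res = sp.csr_matrix(
        (vals, (flat // N, flat % N)), shape=(N, N), dtype=float
    )
    sr = _spectral_radius(W_res)
    if sr > 0:
        W_res = W_res * (rho / sr)
    model = ESNModel(W_in=W_in, W_res=W_res, a=a, R=np.zeros(N))
    d = N + K
    for name, n_out in (heads or {}).items():
        model.heads[name] = ReadoutHead(
            W_out=np.zeros((n_out, d)),
            rls_P=np.eye(d) / eps,
            forgetting=forgetting,
            alpha=alpha,
            delta=delta,
        )
    return model


def esn_step(model: ESNModel, in_t: np.ndarray) -> np.ndarray:
    """Advance the reservoir one step; returns (and stores) the new state."""
    in_t = np.asarray(in_t, dtype=float)
    if in_t.shape != (model.K,):
        raise ValueError(f"input length {in_t.shape} != K={model.K}")
    pre = model.W_in @ in_t + model.W_res @ model.R
    model.R = (1.0 - model.a) * model.R + model.a * np.tanh(pre)
    return model.R


def concat_state(model: ESNModel, in_t: np.ndarray) -> np.ndarray:
    """The readout regressor x = [R; in] (reservoir first)."""
    return np.concatenate([model.R, np.asarray(in_t, dtype=float)])


def esn_output(model: ESNModel, head: str, in_t: np.ndarray) -> np.ndarray:
    """Linear readout of the named head on the current reservoir state."""
    if head not in model.heads:
        raise KeyError(f"unknown head {head!r}")
    return model.heads[head].W_out @ concat_state(model, in_t)


def rls_update(head: ReadoutHead, x: np.ndarray, target: np.ndarray) -> ReadoutHead:
    """One recursive-least-squares step on an (x, target) pair.

    Shares the inverse correlation matrix P across the head's output rows
    (they see the same regressor), so with forgetting 1 and P0 = I/eps the
    trajectory lands exactly on the ridge solution with penalty eps.
    """
    x = np.asarray(x, dtype=float)
    target = np.atleast_1d(np.asarray(target, dtype=float))
    if not (np.isfinite(x).all() and np.isfinite(target).all()):
        raise ValueError("non-finite values in RLS update")
    lam = head.forgetting
    Px = head.rls_P @ x
    g = Px / (lam + x @ Px)
    head.rls_P = (head.rls_P - np.outer(g, Px)) / lam
    err = target - head.W_out @ x
    head.W_out = head.W_out + np.outer(err, g)
    return head


def rl_update(
    head: ReadoutHead, x: np.ndarray, out: np.ndarray, satisfaction: int
) -> ReadoutHead:
    """Satisfaction-gated reinforcement step.

    The eligibility trace always integrates the current output/regressor
    outer product; the weights only move (away from the traced outputs)
    when the reinforcement signal reports dissatisfaction.
    """
    if satisfaction not in (0, 1):
        raise ValueError("satisfaction must be 0 or 1")
    x = np.asarray(x, dtype=float)
    out = np.atleast_1d(np.asarray(out, dtype=float))
    head.E = head.delta * head.E + (1.0 - head.delta) * np.outer(out, x)
    head.W_out = head.W_out - head.alpha * (1 - satisfaction) * head.E
    return head


def decode_state(scores: np.ndarray) -> int:
    """Argmax decoding with lowest-index tie-break."""
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty score vector")
    return int(np.argmax(scores))


def decode_satisfaction(scores: np.ndarray) -> int:
    """Binary argmax decoding (1 = satisfied)."""
    scores = np.asarray(scores)
    if scores.size != 2:
        raise ValueError("satisfaction scores must have length 2")
    return decode_state(scores)


def save_model(model: ESNModel, path) -> None:
    """Portable JSON checkpoint (all matrices, rates, heads)."""
    coo = model.W_res.tocoo()
    payload = {
        "a": model.a,
        "W_in": model.W_in.tolist(),
        "R": model.R.tolist(),
        "W_res": {
            "shape": list(coo.shape),
            "row": coo.row.tolist(),
            "col": coo.col.tolist(),
            "data": coo.data.tolist(),
        },
        "heads": {
            name: {
                "W_out": h.W_out.tolist(),
                "rls_P": h.rls_P.tolist(),
                "forgetting": h.forgetting,
                "E": h.E.tolist(),
                "alpha": h.alpha,
                "delta": h.delta,
            }
            for name, h in model.heads.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> ESNModel:
    with open(path) as fh:
        payload = json.load(fh)
    w = payload["W_res"]
    W_res = sp.csr_matrix(
        (w["data"], (w["row"], w["col"])), shape=tuple(w["shape"]), dtype=float
    )
    model = ESNModel(
        W_in=np.asarray(payload["W_in"], dtype=float),
        W_res=W_res,
        a=payload["a"],
        R=np.asarray(payload["R"], dtype=float),
    )
    for name, h in payload["heads"].items():
        model.heads[name] = ReadoutHead(
            W_out=np.asarray(h["W_out"], dtype=float),
            rls_P=np.asarray(h["rls_P"], dtype=float),
            forgetting=h["forgetting"],
            E=np.asarray(h["E"], dtype=float),
            alpha=h["alpha"],
            delta=h["delta"],
        )
    return model
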