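"""Sequence-regression architectures on the numpy autodiff engine.

All networks are single-output regressors over short DNA inputs: a
multilayer perceptron on flattened one-hot input, a (stacked) bidirectional
GRU, a 1D convolutional network, and a transformer encoder with learned
token + position embeddings — each optionally consuming integer codon
tokens instead of nucleotides. Weight initialization is Glorot-style and
fully seeded.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, embedding, layer_norm


class Network:
    """Base: a named parameter dict + a forward pass building a Tensor graph."""

    def __init__(self, seed: int):
        self.params: dict[str, Tensor] = {}
        self.rng = np.random.default_rng(seed)
        self.l2 = 0.0

    def add_param(self, name: str, shape: tuple, fan_in: int | None = None) -> Tensor:
        fan_in = fan_in if fan_in is not None else shape[0]
        scale = np.sqrt(1.0 / max(fan_in, 1))
        t = Tensor(self.rng.normal(0.0, scale, size=shape), requires_grad=True)
        self.params[name] = t
        return t

    def add_bias(self, name: str, size: int) -> Tensor:
        t = Tensor(np.zeros(size), requires_grad=True)
        self.params[name] = t
        return t

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False).data

    def l2_penalty(self) -> Tensor | float:
        if self.l2 == 0.0:
            return 0.0
        total = None
        for name, p in self.params.items():
            if name.endswith("_b") or name.startswith("ln"):
                continue  # biases and layer-norm scales are not regularized
            term = (p * p).sum()
            total = term if total is None else total + term
        return total * self.l2

    def _dropout(self, x: Tensor, rate: float, train: bool) -> Tensor:
        if not train or rate <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(mask)


class MLPNet(Network):
    """Multilayer perceptron on flattened one-hot input."""

    def __init__(
        self,
        input_dim: int,
        hidden_units: tuple = (64, 64),
        dropout: float = 0.0,
        l2: float = 0.0,
        seed: int = 0,
    ):
        super().__init__(seed)
        self.hidden_units = tuple(hidden_units)
        self.dropout = dropout
        self.l2 = l2
        prev = input_dim
        for i, h in enumerate(self.hidden_units):
            self.add_param(f"W{i}", (prev, h))
            self.add_bias(f"W{i}_b", h)
            prev = h
        self.add_param("Wout", (prev, 1))
        self.add_bias("Wout_b", 1)

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        h = Tensor(X)
        for i in range(len(self.hidden_units)):
            h = (h @ self.params[f"W{i}"] + self.params[f"W{i}_b"]).relu()
            h = self._dropout(h, self.dropout, train)
        out = h @ self.params["Wout"] + self.params["Wout_b"]
        return out.reshape(-1)


class _GRULayer:
    """One GRU direction; weights live in the owning network's param dict."""

    def __init__(self, net: Network, prefix: str, input_dim: int, units: int):
        self.units = units
        self.Wz = net.add_param(f"{prefix}_Wz", (input_dim, units))
        self.Uz = net.add_param(f"{prefix}_Uz", (units, units))
        self.bz = net.add_bias(f"{prefix}_Wz_b", units)
        self.Wr = net.add_param(f"{prefix}_Wr", (input_dim, units))
        self.Ur = net.add_param(f"{prefix}_Ur", (units, units))
        self.br = net.add_bias(f"{prefix}_Wr_b", units)
        self.Wh = net.add_param(f"{prefix}_Wh", (input_dim, units))
        self.Uh = net.add_param(f"{prefix}_Uh", (units, units))
        self.bh = net.add_bias(f"{prefix}_Wh_b", units)

    def run(self, steps: list, h_mask=None) -> list:
        """Run over a list of (B, D) tensors; returns per-step hidden states."""
        B = steps[0].shape[0]
        h = Tensor(np.zeros((B, self.units)))
        states = []
        for x in steps:
            hd = h if h_mask is None else h * h_mask
            z = (x @ self.Wz + hd @ self.Uz + self.bz).sigmoid()
            r = (x @ self.Wr + hd @ self.Ur + self.br).sigmoid()
            cand = (x @ self.Wh + (r * hd) @ self.Uh + self.bh).tanh()
            h = (1.0 - z) * h + z * cand
            states.append(h)
        return states


class BiRNNNet(Network):
    """Stacked bidirectional GRU; final forward/backward states -> dense."""

    def __init__(
        self,
        seq_len: int,
        input_dim: int,
        units: tuple = (32,),
        recurrent_dropout: float = 0.0,
        l2: float = 0.0,
        vocab: int | None = None,
        embed_dim: int | None = None,
        seed: int = 0,
    ):
        super().__init__(seed)
        self.seq_len = seq_len
        self.units = tuple(units)
        self.recurrent_dropout = recurrent_dropout
        self.l2 = l2
        self.vocab = vocab
        if vocab is not None:
            embed_dim = embed_dim or 8
            self.add_param("embed", (vocab, embed_dim), fan_in=embed_dim)
            self.add_param("pos_embed", (seq_len, embed_dim), fan_in=embed_dim)
            input_dim = embed_dim
        self.layers = []
        prev = input_dim
        for i, u in enumerate(self.units):
            fwd = _GRULayer(self, f"gru{i}f", prev, u)
            bwd = _GRULayer(self, f"gru{i}b", prev, u)
            self.layers.append((fwd, bwd))
            prev = 2 * u
        self.add_param("Wout", (prev, 1))
        self.add_bias("Wout_b", 1)

    def _input_steps(self, X: np.ndarray) -> list:
        if self.vocab is not None:
            emb = embedding(self.params["embed"], X) + self.params["pos_embed"]
            return [emb[:, t, :] for t in range(X.shape[1])]
        xt = Tensor(X)
        return [xt[:, t, :] for t in range(X.shape[1])]

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        steps = self._input_steps(X)
        B = X.shape[0]
        for i, (fwd, bwd) in enumerate(self.layers):
            mask = None
            if train and self.recurrent_dropout > 0.0:
                keep = (
                    self.rng.random((B, fwd.units)) >= self.recurrent_dropout
                ) / (1.0 - self.recurrent_dropout)
                mask = Tensor(keep)
            f_states = fwd.run(steps, h_mask=mask)
            b_states = bwd.run(steps[::-1], h_mask=mask)
            if i < len(self.layers) - 1:
                steps = [
                    concat([f, b], axis=-1)
                    for f, b in zip(f_states, b_states[::-1])
                ]
            else:
                final = concat([f_states[-1], b_states[-1]], axis=-1)
        out = final @ self.params["Wout"] + self.params["Wout_b"]
        return out.reshape(-1)


class CNNNet(Network):
    """1D convolutional network (valid padding, kernel 3) + dense head."""

    def __init__(
        self,
        seq_len: int,
        input_dim: int = 4,
        channels: tuple = (32,),
        kernel_size: int = 3,
        dense_units: tuple = (32,),
        l2: float = 0.0,
        seed: int = 0,
    ):
        super().__init__(seed)
        self.seq_len = seq_len
        self.channels = tuple(channels)
        self.kernel_size = kernel_size
        self.dense_units = tuple(dense_units)
        self.l2 = l2
        prev, length = input_dim, seq_len
        for i, ch in enumerate(self.channels):
            self.add_param(f"conv{i}", (kernel_size, prev, ch), fan_in=kernel_size * prev)
            self.add_bias(f"conv{i}_b", ch)
            prev, length = ch, length - kernel_size + 1
            if length < 1:
                raise ValueError("sequence too short for this conv stack")
        flat = prev * length
        prev = flat
        for i, u in enumerate(self.dense_units):
            self.add_param(f"dense{i}", (prev, u))
            self.add_bias(f"dense{i}_b", u)
            prev = u
        self.add_param("Wout", (prev, 1))
        self.add_bias("Wout_b", 1)

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        h = Tensor(X)  # (B, L, C)
        for i in range(len(self.channels)):
            W = self.params[f"conv{i}"]
            Lout = h.shape[1] - self.kernel_size + 1
            acc = None
            for k in range(self.kernel_size):
                term = h[:, k : k + Lout, :] @ W[k]
                acc = term if acc is None else acc + term
            h = (acc + self.params[f"conv{i}_b"]).relu()
        B = h.shape[0]
        h = h.reshape(B, -1)
        for i in range(len(self.dense_units)):
            h = (h @ self.params[f"dense{i}"] + self.params[f"dense{i}_b"]).relu()
        out = h @ self.params["Wout"] + self.params["Wout_b"]
        return out.reshape(-1)


class TransformerNet(Network):
    """Transformer encoder over integer tokens with learned position embedding."""

    def __init__(
        self,
        seq_len: int,
        vocab: int,
        embed_dim: int = 16,
        heads: int = 2,
        head_size: int | None = None,
        ff_units: int = 32,
        blocks: int = 1,
        dropout: float = 0.0,
        l2: float = 0.0,
        seed: int = 0,
    ):
        super().__init__(seed)
        if blocks < 1:
            raise ValueError("a transformer needs at least one stacked module")
        self.seq_len = seq_len
        self.heads = heads
        self.head_size = head_size or max(embed_dim // heads, 1)
        self.embed_dim = embed_dim
        self.blocks = blocks
        self.dropout = dropout
        self.l2 = l2
        self.add_param("embed", (vocab, embed_dim), fan_in=embed_dim)
        self.add_param("pos_embed", (seq_len, embed_dim), fan_in=embed_dim)
        hd = self.heads * self.head_size
        for b in range(blocks):
            for nm in ("q", "k", "v"):
                self.add_param(f"blk{b}_W{nm}", (embed_dim, hd))
            self.add_param(f"blk{b}_Wo", (hd, embed_dim))
            self.add_param(f"blk{b}_ff1", (embed_dim, ff_units))
            self.add_bias(f"blk{b}_ff1_b", ff_units)
            self.add_param(f"blk{b}_ff2", (ff_units, embed_dim))
            self.add_bias(f"blk{b}_ff2_b", embed_dim)
            for ln in ("ln1", "ln2"):
                g = Tensor(np.ones(embed_dim), requires_grad=True)
                self.params[f"ln_{b}_{ln}_g"] = g
                self.params[f"ln_{b}_{ln}_b"] = Tensor(
                    np.zeros(embed_dim), requires_grad=True
                )
        self.add_param("Wout", (embed_dim, 1))
        self.add_bias("Wout_b", 1)

    def _attention(self, x: Tensor, b: int) -> Tensor:
        B, L = x.shape[0], x.shape[1]
        H, dh = self.heads, self.head_size

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dh).transpose((0, 2, 1, 3))

        q = split(x @ self.params[f"blk{b}_Wq"])
        k = split(x @ self.params[f"blk{b}_Wk"])
        v = split(x @ self.params[f"blk{b}_Wv"])
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, L, H * dh)
        return ctx @ self.params[f"blk{b}_Wo"]

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        x = embedding(self.params["embed"], X) + self.params["pos_embed"]
        for b in range(self.blocks):
            attn_out = self._dropout(self._attention(x, b), self.dropout, train)
            x = layer_norm(
                x + attn_out,
                self.params[f"ln_{b}_ln1_g"],
                self.params[f"ln_{b}_ln1_b"],
            )
            h = (x @ self.params[f"blk{b}_ff1"] + self.params[f"blk{b}_ff1_b"]).relu()
            h = self._dropout(h @ self.params[f"blk{b}_ff2"] + self.params[f"blk{b}_ff2_b"], self.dropout, train)
            x = layer_norm(
                x + h,
                self.params[f"ln_{b}_ln2_g"],
                self.params[f"ln_{b}_ln2_b"],
            )
        pooled = x.mean(axis=1)
        out = pooled @ self.params["Wout"] + self.params["Wout_b"]
        return out.reshape(-1)


class RMSProp:
    """Root-mean-square propagation with the standard moving-average cache."""

    def __init__(self, params: list, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, c in zip(self.params, self.cache):
            if p.grad is None:
                continue
            c *= self.rho
            c += (1.0 - self.rho) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)
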