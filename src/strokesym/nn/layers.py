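"""Neural network layers for the stroke model, built on the autodiff core."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat, log_softmax, relu, softmax

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "BatchNorm",
    "Dropout",
    "GCNLayer",
    "CausalDilatedConv1d",
    "TCN",
    "CrossModalAttention",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self) -> None:
        self._training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, flag: bool = True) -> "Module":
        self._training = flag
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        out: dict[str, np.ndarray] = {}

        def visit(obj: "Module", prefix: str) -> None:
            for name, value in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{key}.{i}"] = item.data

        visit(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        current = self.state_arrays()
        missing = set(current) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing arrays: {sorted(missing)[:5]}")
        for key, arr in current.items():
            src = np.asarray(state[key])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: {src.shape} vs {arr.shape}")
            arr[...] = src


class Linear(Module):
    """Affine map with fan-in-scaled (He) initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Stack of Linear + ReLU layers (ReLU after every layer but the last
    when ``final_activation`` is False)."""

    def __init__(
        self,
        dims: Sequence[int],
        rng: np.random.Generator,
        final_activation: bool = True,
    ) -> None:
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if self.final_activation or i < len(self.layers) - 1:
                x = relu(x)
        return x


class BatchNorm(Module):
    """Batch normalization over all axes except the trailing channel axis."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self._training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self._training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class GCNLayer(Module):
    """One graph-convolution layer: sigma(A_norm @ H @ W).

    ``A_norm`` is the symmetrically normalized weighted adjacency (constant,
    possibly batched as (B, 1, J, J) to honour per-sample handedness).
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.linear = Linear(n_in, n_out, rng)

    def __call__(self, h: Tensor, a_norm: Tensor, activation: bool = True) -> Tensor:
        out = a_norm @ self.linear(h)
        return relu(out) if activation else out


class CausalDilatedConv1d(Module):
    """Causal 1-D convolution with dilation; output[t] sees inputs <= t only.

    Input and output are (B, T, C); the sequence length is preserved by
    left-padding with (kernel - 1) * dilation zeros.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        kernel: int,
        dilation: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (n_in * kernel))
        self.weight = Tensor(rng.normal(0.0, scale, size=(kernel, n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.kernel = kernel
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.weight.shape[1]:
            raise ValueError(
                f"channel mismatch: got {x.shape[-1]}, expected {self.weight.shape[1]}"
            )
        b, t, _ = x.shape
        pad = (self.kernel - 1) * self.dilation
        if pad:
            zeros = Tensor(np.zeros((b, pad, x.shape[-1])))
            xp = concat([zeros, x], axis=1)
        else:
            xp = x
        out = None
        for j in range(self.kernel):
            # tap j reaches back j * dilation frames
            start = pad - j * self.dilation
            term = xp[:, start:start + t, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias


class TCN(Module):
    """Causal dilated temporal stack with exponentially growing dilations."""

    def __init__(
        self,
        n_channels: int,
        n_layers: int,
        kernel: int,
        rng: np.random.Generator,
        dilations: Optional[Sequence[int]] = None,
    ) -> None:
        super().__init__()
        dil = list(dilations) if dilations is not None else [2**i for i in range(n_layers)]
        if len(dil) != n_layers:
            raise ValueError("need one dilation per layer")
        self.convs = [
            CausalDilatedConv1d(n_channels, n_channels, kernel, d, rng) for d in dil
        ]
        self.dilations = tuple(dil)
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = relu(conv(x))
        return x

    @property
    def receptive_field(self) -> int:
        return 1 + (self.kernel - 1) * sum(self.dilations)


class CrossModalAttention(Module):
    """Scaled dot-product attention across the three modality summaries.

    Each modality vector is projected into a shared query/key space; the
    3 x 3 attention matrix is row-softmaxed over the key modality, and the
    fused vector is the average over query rows of the attention-weighted
    values, projected to the fusion dimension.
    """

    def __init__(
        self,
        d_model: int,
        d_k: int,
        fusion_dim: int,
        rng: np.random.Generator,
        row_softmax: bool = True,
    ) -> None:
        super().__init__()
        self.wq = Linear(d_model, d_k, rng)
        self.wk = Linear(d_model, d_k, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.proj = Linear(d_model, fusion_dim, rng)
        self.d_k = d_k
        self.row_softmax = row_softmax

    def attention_weights(self, modalities: Sequence[Tensor]) -> Tensor:
        if len(modalities) != 3:
            raise ValueError(f"cross-modal attention expects 3 modalities, got {len(modalities)}")
        stacked = concat([m.reshape(m.shape[0], 1, m.shape[1]) for m in modalities], axis=1)
        q = self.wq(stacked)                      # (B, 3, d_k)
        k = self.wk(stacked)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_k))
        axis = -1 if self.row_softmax else -2
        return softmax(scores, axis=axis)         # (B, 3, 3)

    def __call__(self, modalities: Sequence[Tensor]) -> Tensor:
        a = self.attention_weights(modalities)
        stacked = concat(
            [m.reshape(m.shape[0], 1, m.shape[1]) for m in modalities], axis=1
        )
        v = self.wv(stacked)                      # (B, 3, d_model)
        fused = (a @ v).mean(axis=1)              # (1/3) sum_i sum_j A_ij V_j
        return relu(self.proj(fused))             # (B, fusion_dim)
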