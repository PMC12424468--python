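"""Eight fusion operators combining the image embedding x and clinical
embedding y into one representation for the classifier.

Dimension contracts at the default widths (|x| = 512, |y| = 256):

    concat / wconcat            -> 768
    hadamard / bilinear / gated -> 256
    tensor                      -> outer 512 x 256, flattened + projected
    selfattn                    -> 2 * d_m (per-modality pooled, concatenated)
    crossattn                   -> d_m (image queries over clinical keys/values)

For the attention variants the embeddings are reshaped into token grids
(defaults: image 8 tokens x 64, clinical 8 tokens x 32) and projected to a
shared model width d_m before scaled dot-product attention; a literal
single-token configuration is available, under which cross-attention
degenerates to y W^V (the softmax over one key is identically 1).
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat
from .nn import Linear, Module

__all__ = ["build_fusion", "FUSION_METHODS", "ConcatFusion",
           "WeightedConcatFusion", "HadamardFusion", "TensorFusion",
           "BilinearFusion", "GatedFusion", "SelfAttentionFusion",
           "CrossAttentionFusion"]


class FusionConfigError(ValueError):
    pass


def _check_batch(x: Tensor, y: Tensor):
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError(
            f"fusion expects batched 1-D embeddings (B x d); got shapes "
            f"{x.shape} and {y.shape}")


class FusionBase(Module):
    method: str = ""
    out_dim: int = 0

    def __init__(self, x_dim: int, y_dim: int):
        super().__init__()
        self.x_dim = x_dim
        self.y_dim = y_dim


class ConcatFusion(FusionBase):
    """z = [x; y]"""
    method = "concat"

    def __init__(self, x_dim: int, y_dim: int, rng=None):
        super().__init__(x_dim, y_dim)
        self.out_dim = x_dim + y_dim

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_batch(x, y)
        return concat([x, y], axis=1)


class WeightedConcatFusion(FusionBase):
    """z = [w1 x; w2 y] with learnable scalars, initialized at 1."""
    method = "wconcat"

    def __init__(self, x_dim: int, y_dim: int, rng=None):
        super().__init__(x_dim, y_dim)
        self.out_dim = x_dim + y_dim
        self.w1 = Tensor(np.array(1.0, dtype=np.float32), requires_grad=True)
        self.w2 = Tensor(np.array(1.0, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_batch(x, y)
        return concat([x * self.w1, y * self.w2], axis=1)


class HadamardFusion(FusionBase):
    """z = (P x) . y element-wise, after projecting x into y's space."""
    method = "hadamard"

    def __init__(self, x_dim: int, y_dim: int, rng: np.random.Generator):
        super().__init__(x_dim, y_dim)
        self.out_dim = y_dim
        self.proj = Linear(x_dim, y_dim, rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_batch(x, y)
        return self.proj(x) * y


class TensorFusion(FusionBase):
    """Z = x (outer) y; flattened and affinely projected for the classifier."""
    method = "tensor"

    def __init__(self, x_dim: int, y_dim: int, rng: np.random.Generator,
                 proj_dim: int = 512):
        super().__init__(x_dim, y_dim)
        self.out_dim = proj_dim
        self.proj = Linear(x_dim * y_dim, proj_dim, rng)

    @staticmethod
    def outer(x: Tensor, y: Tensor) -> Tensor:
        """The raw interaction matrix Z[b, i, j] = x[b, i] * y[b, j]."""
        _check_batch(x, y)
        b, dx = x.shape
        dy = y.shape[1]
        return x.reshape(b, dx, 1) * y.reshape(b, 1, dy)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        z = self.outer(x, y)
        return self.proj(z.reshape(x.shape[0], self.x_dim * self.y_dim))


class BilinearFusion(FusionBase):
    """z_i = x^T W_i y for each output index i."""
    method = "bilinear"

    def __init__(self, x_dim: int, y_dim: int, rng: np.random.Generator,
                 out_dim: int = 256):
        super().__init__(x_dim, y_dim)
        self.out_dim = out_dim
        scale = 1.0 / np.sqrt(x_dim * y_dim)
        self.W = Tensor(rng.uniform(-scale, scale,
                                    size=(out_dim, x_dim, y_dim)),
                        requires_grad=True)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_batch(x, y)
        b = x.shape[0]
        o, dx, dy = self.W.shape
        if x.shape[1] != dx or y.shape[1] != dy:
            raise ValueError(
                f"bilinear weights expect ({dx}, {dy}) inputs; got "
                f"({x.shape[1]}, {y.shape[1]})")
        # x^T W_i y for all i, via one matmul: (B, dx) @ (dx, O*dy)
        wmat = self.W.transpose(1, 0, 2).reshape(dx, o * dy)
        xw = (x @ wmat).reshape(b, o, dy)
        return (xw * y.reshape(b, 1, dy)).sum(axis=2)


class GatedFusion(FusionBase):
    """g = sigmoid(W_x x' + W_y y + b); z = g . x' + (1 - g) . y."""
    method = "gated"

    def __init__(self, x_dim: int, y_dim: int, rng: np.random.Generator):
        super().__init__(x_dim, y_dim)
        self.out_dim = y_dim
        self.proj = Linear(x_dim, y_dim, rng)
        self.Wx = Linear(y_dim, y_dim, rng, bias=False)
        self.Wy = Linear(y_dim, y_dim, rng, bias=False)
        self.b = Tensor(np.zeros(y_dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_batch(x, y)
        xp = self.proj(x)
        g = (self.Wx(xp) + self.Wy(y) + self.b).sigmoid()
        one = Tensor(np.float32(1.0))
        return g * xp + (one - g) * y


def _tokenize(v: Tensor, n_tokens: int, dim: int) -> Tensor:
    if dim % n_tokens != 0:
        raise FusionConfigError(
            f"embedding dim {dim} not divisible into {n_tokens} tokens")
    return v.reshape(v.shape[0], n_tokens, dim // n_tokens)


def _attention(q: Tensor, k: Tensor, v: Tensor, d: int) -> Tensor:
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
    return scores.softmax(axis=-1) @ v


class SelfAttentionFusion(FusionBase):
    """Scaled dot-product self-attention within each modality's token
    sequence; attended tokens are mean-pooled per modality and concatenated."""
    method = "selfattn"

    def __init__(self, x_dim: int, y_dim: int, rng: np.random.Generator,
                 x_tokens: int = 8, y_tokens: int = 8, d_model: int = 64):
        super().__init__(x_dim, y_dim)
        if x_dim % x_tokens or y_dim % y_tokens:
            raise FusionConfigError(
                f"token counts ({x_tokens}, {y_tokens}) must divide the "
                f"embedding dims ({x_dim}, {y_dim})")
        self.x_tokens, self.y_tokens, self.d_model = x_tokens, y_tokens, d_model
        self.out_dim = 2 * d_model
        xw, yw = x_dim // x_tokens, y_dim // y_tokens
        self.xq = Linear(xw, d_model, rng, bias=False)
        self.xk = Linear(xw, d_model, rng, bias=False)
        self.xv = Linear(xw, d_model, rng, bias=False)
        self.yq = Linear(yw, d_model, rng, bias=False)
        self.yk = Linear(yw, d_model, rng, bias=False)
        self.yv = Linear(yw, d_model, rng, bias=False)

    def attend_x(self, x: Tensor) -> Tensor:
        t = _tokenize(x, self.x_tokens, self.x_dim)
        return _attention(self.xq(t), self.xk(t), self.xv(t), self.d_model)

    def attend_y(self, y: Tensor) -> Tensor:
        t = _tokenize(y, self.y_tokens, self.y_dim)
        return _attention(self.yq(t), self.yk(t), self.yv(t), self.d_model)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_batch(x, y)
        px = self.attend_x(x).mean(axis=1)
        py = self.attend_y(y).mean(axis=1)
        return concat([px, py], axis=1)


class CrossAttentionFusion(FusionBase):
    """Image tokens supply queries; clinical tokens supply keys and values:
    z = softmax(Q_x K_y^T / sqrt(d)) V_y.

    The per-query attended outputs are concatenated (flattened) into the
    fused vector, so the classifier sees each query token's own
    attention-weighted combination of clinical values; with a single query
    and a single clinical token this reduces exactly to y W^V."""
    method = "crossattn"

    def __init__(self, x_dim: int, y_dim: int, rng: np.random.Generator,
                 x_tokens: int = 8, y_tokens: int = 8, d_model: int = 64):
        super().__init__(x_dim, y_dim)
        if x_dim % x_tokens or y_dim % y_tokens:
            raise FusionConfigError(
                f"token counts ({x_tokens}, {y_tokens}) must divide the "
                f"embedding dims ({x_dim}, {y_dim})")
        self.x_tokens, self.y_tokens, self.d_model = x_tokens, y_tokens, d_model
        self.out_dim = x_tokens * d_model
        self.Wq = Linear(x_dim // x_tokens, d_model, rng, bias=False)
        self.Wk = Linear(y_dim // y_tokens, d_model, rng, bias=False)
        self.Wv = Linear(y_dim // y_tokens, d_model, rng, bias=False)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_batch(x, y)
        q = self.Wq(_tokenize(x, self.x_tokens, self.x_dim))
        kt = _tokenize(y, self.y_tokens, self.y_dim)
        attended = _attention(q, self.Wk(kt), self.Wv(kt), self.d_model)
        return attended.reshape(x.shape[0], self.out_dim)


FUSION_METHODS = {
    "concat": ConcatFusion,
    "wconcat": WeightedConcatFusion,
    "hadamard": HadamardFusion,
    "tensor": TensorFusion,
    "bilinear": BilinearFusion,
    "gated": GatedFusion,
    "selfattn": SelfAttentionFusion,
    "crossattn": CrossAttentionFusion,
}


def build_fusion(method: str, x_dim: int, y_dim: int,
                 rng: np.random.Generator, **hyper) -> FusionBase:
    """Instantiate a fusion operator by name."""
    if method not in FUSION_METHODS:
        raise FusionConfigError(
            f"unknown fusion method {method!r}; valid names: "
            f"{sorted(FUSION_METHODS)}")
    return FUSION_METHODS[method](x_dim, y_dim, rng, **hyper)
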