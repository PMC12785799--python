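"""The lightweight residual attention classifier (Light-ResAttNet).

Architecture: a 5x5/stride-2 stem convolution (bias on) with BN+ReLU, three
pre-activation residual stages widening 32->64->128->256 (strides 1, 2, 2),
a spatial attention gate after the third stage, then global average pooling,
dropout 0.5 and a softmax dense head.  For a 128x128x3 input the feature
maps run (64,64,32) -> (64,64,64) -> (32,32,128) -> (16,16,256).

Parameter accounting counts four terms per batch-norm channel (scale,
offset and the two running statistics); on that convention the stem
convolution holds 2432 parameters, the stem BN 128, the first residual
block 57,728, the attention gate 99 and the dense head 2570, for a model
total of ~1.21 million.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    DTYPE,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    GlobalAveragePool,
    PreActResBlock,
    ReLU,
    SpatialAttention,
)


@dataclass(frozen=True)
class ArchitectureSpec:
    input_shape: tuple[int, int, int] = (128, 128, 3)
    stem_kernel: int = 5
    stem_stride: int = 2
    stem_filters: int = 32
    stage_filters: tuple[int, ...] = (64, 128, 256)
    stage_strides: tuple[int, ...] = (1, 2, 2)
    attention_kernel: int = 7
    dropout_rate: float = 0.5
    n_classes: int = 10
    post_add_relu: bool = False

    def validate(self) -> None:
        h, w, _ = self.input_shape
        total_stride = self.stem_stride * int(np.prod(self.stage_strides))
        if h % total_stride or w % total_stride:
            raise ValueError(
                f"input {h}x{w} not divisible through the stride plan (x{total_stride})"
            )
        if len(self.stage_filters) != len(self.stage_strides):
            raise ValueError("stage_filters and stage_strides must align")


class LightResAttNet:
    """Queryable model: per-component parameter counts, shapes, fwd/bwd."""

    def __init__(self, spec: ArchitectureSpec = ArchitectureSpec(), seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        h, w, c = spec.input_shape
        self.stem_conv = Conv2D(c, spec.stem_filters, spec.stem_kernel,
                                stride=spec.stem_stride, bias=True, name="stem_conv", rng=rng)
        self.stem_bn = BatchNorm(spec.stem_filters, name="stem_bn")
        self.stem_relu = ReLU()
        self.blocks = []
        in_ch = spec.stem_filters
        for i, (f, s) in enumerate(zip(spec.stage_filters, spec.stage_strides), start=1):
            self.blocks.append(PreActResBlock(in_ch, f, stride=s,
                                              post_add_relu=spec.post_add_relu,
                                              name=f"stage{i}_block", rng=rng))
            in_ch = f
        self.attention = SpatialAttention(kernel=spec.attention_kernel, rng=rng)
        self.gap = GlobalAveragePool()
        self.dropout = Dropout(spec.dropout_rate, rng=np.random.default_rng(seed + 1))
        self.dense = Dense(in_ch, spec.n_classes, name="dense", rng=rng)
        self._components = [
            ("stem_conv", self.stem_conv),
            ("stem_bn", self.stem_bn),
            *[(b.name, b) for b in self.blocks],
            ("spatial_attention", self.attention),
            ("dense", self.dense),
        ]

    # -- parameter bookkeeping ------------------------------------------------

    def component_param_counts(self) -> dict[str, int]:
        return {name: comp.n_params() for name, comp in self._components}

    def total_params(self) -> int:
        return sum(self.component_param_counts().values())

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for _, comp in self._components:
            out.update(comp.params())
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for _, comp in self._components:
            out.update(comp.grads())
        return out

    def get_state(self):
        return copy.deepcopy({k: v for k, v in self.params().items()}), copy.deepcopy(
            [(b.bn1.running_mean.copy(), b.bn1.running_var.copy(),
              b.bn2.running_mean.copy(), b.bn2.running_var.copy()) for b in self.blocks]
            + [(self.stem_bn.running_mean.copy(), self.stem_bn.running_var.copy())]
        )

    def set_state(self, state) -> None:
        params, bn_stats = state
        live = self.params()
        for k, v in params.items():
            live[k][...] = v
        for b, (m1, v1, m2, v2) in zip(self.blocks, bn_stats):
            b.bn1.running_mean[...] = m1
            b.bn1.running_var[...] = v1
            b.bn2.running_mean[...] = m2
            b.bn2.running_var[...] = v2
        self.stem_bn.running_mean[...] = bn_stats[-1][0]
        self.stem_bn.running_var[...] = bn_stats[-1][1]

    def _bn_layers(self):
        return [self.stem_bn] + [bn for b in self.blocks for bn in (b.bn1, b.bn2)]

    def save(self, path) -> None:
        """Checkpoint all weights and batch-norm statistics to an .npz."""
        arrays = dict(self.params())
        for bn in self._bn_layers():
            arrays[f"{bn.name}.running_mean"] = bn.running_mean
            arrays[f"{bn.name}.running_var"] = bn.running_var
        np.savez(path, **arrays)

    def load(self, path) -> None:
        data = np.load(path)
        live = self.params()
        for k, v in live.items():
            v[...] = data[k]
        for bn in self._bn_layers():
            bn.running_mean[...] = data[f"{bn.name}.running_mean"]
            bn.running_var[...] = data[f"{bn.name}.running_var"]

    # -- execution ------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of NHWC images."""
        x = np.asarray(x, dtype=DTYPE)
        h = self.stem_conv.forward(x, training)
        h = self.stem_bn.forward(h, training)
        h = self.stem_relu.forward(h, training)
        for b in self.blocks:
            h = b.forward(h, training)
        h = self.attention.forward(h, training)
        h = self.gap.forward(h, training)
        h = self.dropout.forward(h, training)
        return self.dense.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense.backward(dlogits.astype(DTYPE))
        d = self.dropout.backward(d)
        d = self.gap.backward(d)
        d = self.attention.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem_conv.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> list[dict]:
        h, w, c = self.spec.input_shape
        sh, sw = h // self.spec.stem_stride, w // self.spec.stem_stride
        rows = [
            {"layer": "Input", "output_shape": (h, w, c), "params": 0},
            {"layer": f"Conv2D ({self.spec.stem_kernel}x{self.spec.stem_kernel}, stride "
                      f"{self.spec.stem_stride})", "output_shape": (sh, sw, self.spec.stem_filters),
             "params": self.stem_conv.n_params()},
            {"layer": "BatchNormalization, ReLU", "output_shape": (sh, sw, self.spec.stem_filters),
             "params": self.stem_bn.n_params()},
        ]
        for b in self.blocks:
            sh, sw = sh // b.stride, sw // b.stride
            rows.append({"layer": f"Pre-Activation Res-Block ({b.name})",
                         "output_shape": (sh, sw, b.out_ch), "params": b.n_params()})
        rows += [
            {"layer": "Spatial Attention", "output_shape": (sh, sw, self.blocks[-1].out_ch),
             "params": self.attention.n_params()},
            {"layer": "Global Average Pooling 2D", "output_shape": (self.blocks[-1].out_ch,),
             "params": 0},
            {"layer": f"Dropout ({self.spec.dropout_rate})",
             "output_shape": (self.blocks[-1].out_ch,), "params": 0},
            {"layer": "Dense (Softmax)", "output_shape": (self.spec.n_classes,),
             "params": self.dense.n_params()},
        ]
        return rows


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(spec: ArchitectureSpec = ArchitectureSpec(), seed: int = 0) -> LightResAttNet:
    return LightResAttNet(spec, seed=seed)
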