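"""3D classifier architecture: encoder, class-wise attention, GAP classifier.

The model is a small, fully differentiable 3D convolutional network written
directly on numpy (float64 throughout):

* an encoder of ``conv3x3x3 -> ReLU -> 2x average-pool`` stages whose
  channel widths are configurable — the feature extractor F;
* an attention module of two parallel 3D convolutions mapping the C
  encoder channels to K class channels: F' (the projected features) and M
  (the attention maps, linear activation so attention can be signed and
  compared against signed saliency priors in [-1, 1]);
* a classifier that multiplies F' and M elementwise and applies global
  average pooling — the spatial mean of class channel k is logit k — then
  softmax.

Forward passes cache intermediates so :meth:`CNNClassifier.backward` can
return exact gradients with respect to every parameter and the input
volume; the latter is what the Shapley attribution backend consumes.
All randomness (He-style initialization) is seeded through the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Dim3

__all__ = [
    "FeatureStack",
    "AttentionStack",
    "ClassProbabilities",
    "ModelConfig",
    "CNNClassifier",
    "extract_features",
    "attention_forward",
    "classify",
    "softmax",
]


@dataclass
class FeatureStack:
    """C-channel feature grid at (possibly reduced) spatial resolution."""

    values: np.ndarray  # (C, D', H', W')

    def __post_init__(self) -> None:
        if np.asarray(self.values).ndim != 4:
            raise ValueError("FeatureStack requires a 4D (C, D, H, W) array")
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_dims(self) -> tuple[int, int, int]:
        return self.values.shape[1:]


@dataclass
class AttentionStack:
    """Learnt class-wise attention maps M_k, one channel per class."""

    maps: np.ndarray  # (K, D', H', W')

    def __post_init__(self) -> None:
        if np.asarray(self.maps).ndim != 4:
            raise ValueError("AttentionStack requires a 4D (K, D, H, W) array")
        self.maps = np.asarray(self.maps, dtype=np.float64)

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]


@dataclass
class ClassProbabilities:
    logits: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=np.float64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if abs(self.probs.sum() - 1.0) > 1e-6 or (self.probs < -1e-12).any():
            raise ValueError("probs must be non-negative and sum to 1")

    @property
    def predicted(self) -> int:
        # argmax breaks ties toward the lowest class index
        return int(np.argmax(self.probs))


@dataclass
class ModelConfig:
    n_classes: int
    input_dims: Dim3
    encoder_widths: list[int] = field(default_factory=lambda: [8, 16])
    attention_kernel: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.encoder_widths:
            raise ValueError("encoder_widths must be nonempty")
        if self.encoder_widths[-1] < self.n_classes:
            raise ValueError(
                "final encoder width must be >= n_classes so the attention "
                "convolution can emit one channel per class"
            )
        if self.attention_kernel % 2 != 1 or self.attention_kernel < 1:
            raise ValueError("attention_kernel must be odd and positive")
        factor = 2 ** len(self.encoder_widths)
        for name, v in zip(("depth", "height", "width"), self.input_dims.shape):
            if v % factor != 0:
                raise ValueError(
                    f"input {name}={v} must be divisible by {factor} "
                    f"(one 2x pool per encoder stage)"
                )

    @property
    def feature_dims(self) -> tuple[int, int, int]:
        f = 2 ** len(self.encoder_widths)
        d, h, w = self.input_dims.shape
        return (d // f, h // f, w // f)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "input_dims": list(self.input_dims.shape),
            "encoder_widths": list(self.encoder_widths),
            "attention_kernel": self.attention_kernel,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            n_classes=int(d["n_classes"]),
            input_dims=Dim3(*[int(v) for v in d["input_dims"]]),
            encoder_widths=[int(v) for v in d["encoder_widths"]],
            attention_kernel=int(d["attention_kernel"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# conv/pool primitives (stride 1, 'same' zero padding, odd kernels)
#
# The convolution is decomposed into k^3 shifted slab matmuls: for each
# kernel offset the padded input slab (Cin, D*H*W) is multiplied by the
# (Cout, Cin) weight slice.  Slab copies are contiguous, which keeps this
# memory-bandwidth friendly at the volume sizes the package targets.


def conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded stride-1 3D convolution. Returns (out, cache)."""
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    if x.shape[0] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.shape[0]} channels, "
            f"kernel expects {cin}"
        )
    p = k // 2
    d, h, w = x.shape[1:]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
    acc = np.repeat(b[:, None], d * h * w, axis=1)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[:, i : i + d, j : j + h, l : l + w].reshape(cin, -1)
                acc += W[:, :, i, j, l] @ xs
    return acc.reshape(cout, d, h, w), (x.shape, xp, W)


def conv3d_backward(dout: np.ndarray, cache):
    """Gradients of conv3d_forward: returns (dx, dW, db)."""
    x_shape, xp, W = cache
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    p = k // 2
    d, h, w = x_shape[1:]
    dmat = dout.reshape(cout, -1)
    dW = np.empty_like(W)
    db = dmat.sum(axis=1)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[:, i : i + d, j : j + h, l : l + w].reshape(cin, -1)
                dW[:, :, i, j, l] = dmat @ xs.T
                dxp[:, i : i + d, j : j + h, l : l + w] += (
                    W[:, :, i, j, l].T @ dmat
                ).reshape(cin, d, h, w)
    dx = dxp[:, p : p + d, p : p + h, p : p + w] if p else dxp
    return np.ascontiguousarray(dx), dW, db


def avgpool2_forward(x: np.ndarray) -> np.ndarray:
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))


def avgpool2_backward(dout: np.ndarray) -> np.ndarray:
    return np.repeat(
        np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2), 2, axis=3
    ) / 8.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# the model


class CNNClassifier:
    """Encoder + class-wise attention + GAP softmax classifier.

    Parameters live in ``self.params`` (name -> float64 array) and are
    He-initialized from ``config.seed``.  ``forward`` returns all
    intermediate stacks; ``backward`` consumes the upstream gradients of
    the logits and (optionally) an extra gradient on the attention maps —
    the path through which the prior-alignment loss supervises M — and
    returns parameter gradients plus the gradient on the input volume.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(config.seed)
        cin = 1
        for i, cout in enumerate(config.encoder_widths):
            fan_in = cin * 27
            self.params[f"enc{i}.W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3, 3)
            )
            self.params[f"enc{i}.b"] = np.zeros(cout)
            cin = cout
        k = config.attention_kernel
        fan_in = cin * k**3
        for name in ("attn_f", "attn_m"):
            self.params[f"{name}.W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(config.n_classes, cin, k, k, k)
            )
            self.params[f"{name}.b"] = np.zeros(config.n_classes)
        # identity-initialized modulation: M starts near 1 so early logits
        # follow F' and gradients flow through the product from step one
        self.params["attn_m.b"][:] = 1.0

    # -- forward -----------------------------------------------------------

    def _check_input(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume, dtype=np.float64)
        if volume.shape != self.config.input_dims.shape:
            raise ValueError(
                f"input shape {volume.shape} does not match model input "
                f"dims {self.config.input_dims.shape}"
            )
        return volume

    def forward(self, volume: np.ndarray) -> dict:
        """Full forward pass; returns a dict with features, attention,
        modulated features, probabilities, and the backward cache."""
        volume = self._check_input(volume)
        x = volume[None]  # add channel axis
        caches = []
        for i in range(len(self.config.encoder_widths)):
            z, ccache = conv3d_forward(
                x, self.params[f"enc{i}.W"], self.params[f"enc{i}.b"]
            )
            a = np.maximum(z, 0.0)
            x = avgpool2_forward(a)
            caches.append((ccache, z > 0))
        features = x  # (C, D', H', W')
        f_prime, cache_f = conv3d_forward(
            features, self.params["attn_f.W"], self.params["attn_f.b"]
        )
        m, cache_m = conv3d_forward(
            features, self.params["attn_m.W"], self.params["attn_m.b"]
        )
        modulated = f_prime * m
        logits = modulated.mean(axis=(1, 2, 3))
        probs = softmax(logits)
        return {
            "features": FeatureStack(features),
            "f_prime": FeatureStack(f_prime),
            "attention": AttentionStack(m),
            "modulated": FeatureStack(modulated),
            "output": ClassProbabilities(logits=logits, probs=probs),
            "_cache": (caches, cache_f, cache_m, f_prime, m),
        }

    def logits(self, volume: np.ndarray) -> np.ndarray:
        return self.forward(volume)["output"].logits

    def predict(self, volume: np.ndarray) -> int:
        return self.forward(volume)["output"].predicted

    # -- backward ----------------------------------------------------------

    def backward(
        self,
        fwd: dict,
        dlogits: np.ndarray,
        dattention: np.ndarray | None = None,
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backpropagate.  ``dlogits`` is dL/dlogits (length K);
        ``dattention`` is an optional extra dL/dM (K, D', H', W') added at
        the attention maps.  Returns (param gradients, input gradient)."""
        caches, cache_f, cache_m, f_prime, m = fwd["_cache"]
        grads: dict[str, np.ndarray] = {}
        n_vox = np.prod(f_prime.shape[1:])
        dmod = (np.asarray(dlogits, dtype=np.float64)[:, None, None, None]
                / n_vox) * np.ones_like(f_prime)
        df_prime = dmod * m
        dm = dmod * f_prime
        if dattention is not None:
            dm = dm + dattention
        dfeat_f, grads["attn_f.W"], grads["attn_f.b"] = conv3d_backward(
            df_prime, cache_f
        )
        dfeat_m, grads["attn_m.W"], grads["attn_m.b"] = conv3d_backward(dm, cache_m)
        dx = dfeat_f + dfeat_m
        for i in reversed(range(len(self.config.encoder_widths))):
            ccache, relu_mask = caches[i]
            da = avgpool2_backward(dx)
            dz = da * relu_mask
            dx, grads[f"enc{i}.W"], grads[f"enc{i}.b"] = conv3d_backward(dz, ccache)
        return grads, dx[0]

    def input_gradient(self, volume: np.ndarray, target_class: int) -> np.ndarray:
        """d logit_target / d volume — the primitive the attribution
        backend integrates along the reference-to-input path."""
        fwd = self.forward(volume)
        onehot = np.zeros(self.config.n_classes)
        onehot[target_class] = 1.0
        _, dvol = self.backward(fwd, onehot)
        return dvol

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k}")
            if self.params[k].shape != v.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {self.params[k].shape} vs {v.shape}"
                )
            self.params[k] = np.asarray(v, dtype=np.float64).copy()

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


# ---------------------------------------------------------------------------
# functional views matching the module contract


def extract_features(volume: np.ndarray, model: CNNClassifier) -> FeatureStack:
    """Run only the encoder and return the feature stack."""
    return model.forward(volume)["features"]


def attention_forward(
    features: FeatureStack, model: CNNClassifier
) -> tuple[AttentionStack, FeatureStack]:
    """Apply the attention module to precomputed features: returns the
    attention maps M and the modulated features F' ⊙ M."""
    f = features.values
    f_prime, _ = conv3d_forward(f, model.params["attn_f.W"], model.params["attn_f.b"])
    m, _ = conv3d_forward(f, model.params["attn_m.W"], model.params["attn_m.b"])
    return AttentionStack(m), FeatureStack(f_prime * m)


def classify(modulated: FeatureStack, n_classes: int) -> ClassProbabilities:
    """GAP classifier: logit_k = spatial mean of channel k, then softmax."""
    if modulated.n_channels != n_classes:
        raise ValueError(
            f"modulated stack has {modulated.n_channels} channels, "
            f"expected {n_classes} (one per class)"
        )
    logits = modulated.values.mean(axis=(1, 2, 3))
    return ClassProbabilities(logits=logits, probs=softmax(logits))
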