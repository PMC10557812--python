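"""Two-stage training orchestration.

Stage 1 trains a baseline classifier with class-weighted cross-entropy;
its Shapley priors are computed offline (``priors`` module); stage 2
trains a *freshly initialized* model whose class-wise attention maps are
additionally pulled toward those frozen priors by the alignment loss.

Mechanics shared by both stages: a seeded shuffled cycling sampler (a
fixed number of weight updates per epoch implies sampling beyond one pass
of a finite dataset), gradient accumulation (each update averages
gradients over ``accumulation_steps`` micro-batches, numerically identical
to one large batch), Adam with a constant learning rate, optional
augmentation and Mixup, and best-checkpoint selection by validation
macro F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from . import losses
from .evalmetrics import confusion, macro_f1
from .losses import LossConfig, WeightVector, class_weights
from .netcore import CNNClassifier, ModelConfig, softmax
from .phantom import Dim3, VolumeSample, _minmax, _smooth_field
from .priors import PriorSet

__all__ = [
    "TrainConfig",
    "AugmentPolicy",
    "FoldAssignment",
    "TrainResult",
    "stratified_folds",
    "augment",
    "mixup_batch",
    "train_baseline",
    "train_guided",
]


@dataclass
class AugmentPolicy:
    """Training-time augmentation: gamma contrast, smooth multiplicative
    bias field, random crop + upsample back, then min-max intensity
    scaling to [0, 1].  Each geometric/intensity transform fires with
    ``per_transform_probability``; the final scaling is deterministic."""

    contrast_range: tuple[float, float] = (0.7, 1.5)
    bias_field_amplitude: float = 0.3
    crop_fraction: float = 0.9
    upsample_to: Dim3 | None = None
    intensity_scale_to_unit: bool = True
    per_transform_probability: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.crop_fraction <= 1:
            raise ValueError("crop_fraction must be in (0, 1]")
        if not 0 <= self.per_transform_probability <= 1:
            raise ValueError("per_transform_probability must be in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 60
    steps_per_epoch: int = 200
    micro_batch: int = 2
    accumulation_steps: int = 8
    learning_rate: float = 1e-3
    k_folds: int = 5
    split_ratio: tuple[float, float, float] = (3.0, 1.0, 1.0)
    loss: LossConfig = field(default_factory=LossConfig)
    augmentation: AugmentPolicy | None = None
    mixup_alpha: float | None = None  # None disables Mixup; paper setting 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if min(self.split_ratio) <= 0:
            raise ValueError("split_ratio entries must be positive")
        if self.mixup_alpha is not None and self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be positive")

    @property
    def effective_batch(self) -> int:
        return self.micro_batch * self.accumulation_steps

    @property
    def normalized_split(self) -> tuple[float, float, float]:
        s = sum(self.split_ratio)
        return tuple(r / s for r in self.split_ratio)


@dataclass
class FoldAssignment:
    """Stratified partition of subjects into k folds with per-fold
    train/val/test roles realized by rotating held-out fold blocks."""

    fold_of_subject: dict[str, int]
    roles: dict[int, dict[str, str]]  # fold -> subject_id -> role
    k: int

    def subjects_with_role(self, fold: int, role: str) -> list[str]:
        return sorted(s for s, r in self.roles[fold].items() if r == role)


def stratified_folds(
    labels: dict[str, int],
    k: int,
    split_ratio: tuple[float, float, float] = (3.0, 1.0, 1.0),
    seed: int = 0,
) -> FoldAssignment:
    """Seeded class-stratified k-fold split with rotating role blocks.

    Fold blocks are stratified so each block's class proportions match the
    global ones within one subject per class.  For run ``f`` the test
    block(s) start at fold f, the validation block(s) follow, and the rest
    train; with k = 5 and ratio 3:1:1 that is 3 train, 1 val, 1 test.
    """
    subjects = sorted(labels)
    y = np.array([labels[s] for s in subjects])
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if len(small):
        raise ValueError(
            f"classes {small.tolist()} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = {}
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            fold_of[subjects[i]] = f

    shares = np.asarray(split_ratio, dtype=np.float64)
    shares /= shares.sum()
    n_test = max(1, round(k * shares[2]))
    n_val = max(1, round(k * shares[1]))
    if n_test + n_val >= k:
        raise ValueError("split_ratio leaves no folds for training")
    roles: dict[int, dict[str, str]] = {}
    for f in range(k):
        test_blocks = {(f + j) % k for j in range(n_test)}
        val_blocks = {(f + n_test + j) % k for j in range(n_val)}
        roles[f] = {
            s: ("test" if fold_of[s] in test_blocks
                else "val" if fold_of[s] in val_blocks
                else "train")
            for s in subjects
        }
    return FoldAssignment(fold_of_subject=fold_of, roles=roles, k=k)


# ---------------------------------------------------------------------------
# augmentation


def augment(sample: VolumeSample, policy: AugmentPolicy, seed: int) -> VolumeSample:
    """Apply the augmentation policy (seeded, label-preserving)."""
    rng = np.random.default_rng(seed)
    v = sample.volume.copy()
    shape = v.shape

    if rng.uniform() < policy.per_transform_probability:
        gamma = rng.uniform(*policy.contrast_range)
        v = np.clip(v, 0.0, None) ** gamma
    if rng.uniform() < policy.per_transform_probability:
        fieldv = _smooth_field(shape, 4.0, rng)
        v = v * (1.0 + policy.bias_field_amplitude * fieldv)
    if rng.uniform() < policy.per_transform_probability and policy.crop_fraction < 1:
        sizes = [max(1, int(round(policy.crop_fraction * s))) for s in shape]
        if min(sizes) < 2:
            raise ValueError("crop_fraction leaves fewer than 2 voxels per axis")
        origins = [int(rng.integers(0, s - c + 1)) for s, c in zip(shape, sizes)]
        v = v[tuple(slice(o, o + c) for o, c in zip(origins, sizes))]
        target = policy.upsample_to.shape if policy.upsample_to else shape
        v = ndimage.zoom(v, [t / c for t, c in zip(target, v.shape)], order=1)
        if v.shape != tuple(target):  # zoom rounding
            v = np.pad(v, [(0, t - s) for t, s in zip(target, v.shape)], mode="edge")

    if policy.intensity_scale_to_unit:
        v = _minmax(v)
    return VolumeSample(
        volume=v,
        label=sample.label,
        domain=sample.domain,
        subject_id=sample.subject_id,
        severity=sample.severity,
    )


def mixup_batch(
    volumes: np.ndarray,
    onehot: np.ndarray,
    alpha: float = 0.2,
    seed: int = 0,
    lam: float | None = None,
):
    """Convex combinations of example pairs and their one-hot labels,
    Beta(alpha, alpha) mixing weights; ``lam`` overrides the draw."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    volumes = np.asarray(volumes, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    n = volumes.shape[0]
    if n < 2:
        raise ValueError("mixup needs a batch of >= 2 samples")
    rng = np.random.default_rng(seed)
    # random single-cycle pairing: no sample is ever mixed with itself
    order = rng.permutation(n)
    perm = np.empty(n, dtype=int)
    perm[order] = np.roll(order, 1)
    lams = np.full(n, lam) if lam is not None else rng.beta(alpha, alpha, size=n)
    lv = lams.reshape((n,) + (1,) * (volumes.ndim - 1))
    mixed_x = lv * volumes + (1 - lv) * volumes[perm]
    mixed_y = lams[:, None] * onehot + (1 - lams[:, None]) * onehot[perm]
    return mixed_x, mixed_y


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainResult:
    model: CNNClassifier
    log: pd.DataFrame
    best_val_f1: float | None = None


class _CyclingSampler:
    """Seeded shuffled cycling over dataset indices (with reshuffle per
    pass), so a fixed step count per epoch can exceed the dataset size."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n, self.rng = n, rng
        self._order = rng.permutation(n)
        self._pos = 0

    def take(self, count: int) -> list[int]:
        out = []
        while len(out) < count:
            if self._pos >= self.n:
                self._order = self.rng.permutation(self.n)
                self._pos = 0
            out.append(int(self._order[self._pos]))
            self._pos += 1
        return out


def _soft_wce_and_grad(logits: np.ndarray, target: np.ndarray,
                       w: WeightVector) -> tuple[float, np.ndarray]:
    """Weighted CE with a soft (possibly mixed) target distribution.

    loss = -sum_k w_k y_k log p_k;  dloss/dlogit_j = p_j * sum_k w_k y_k
    - w_j y_j.  For a one-hot target this reduces to w_y (p - e_y)."""
    p = softmax(logits)
    loss = -float((w.weights * target * np.log(np.maximum(p, losses.LOG_FLOOR))).sum())
    coeff = float((w.weights * target).sum())
    grad = p * coeff - w.weights * target
    return loss, grad


def _run_training(
    data: list[VolumeSample],
    config: TrainConfig,
    model_config: ModelConfig,
    priors: PriorSet | None,
    val_data: list[VolumeSample] | None,
) -> TrainResult:
    if not data:
        raise ValueError("training split is empty")
    model = CNNClassifier(model_config)
    n_classes = model_config.n_classes
    counts = np.bincount([s.label for s in data], minlength=n_classes)
    # weights from the train split only; mean-1 normalization keeps the
    # gradient scale (hence the learning rate) independent of dataset size
    w = class_weights(np.maximum(counts, 1), normalize=True)
    lam = config.loss.lambda_ if priors is not None else 0.0

    prior_grids = None
    if priors is not None:
        prior_grids = priors.resampled(model_config.feature_dims).priors

    rng = np.random.default_rng(config.seed)
    sampler = _CyclingSampler(len(data), rng)
    opt = Adam(model.params, lr=config.learning_rate)
    records = []
    best_state = model.state_dict()
    best_f1: float | None = None
    step = 0

    for epoch in range(config.epochs):
        for _ in range(config.steps_per_epoch):
            grad_sums = {k: np.zeros_like(v) for k, v in model.params.items()}
            wce_sum = sim_sum = 0.0
            n_seen = 0
            for _ in range(config.accumulation_steps):
                idx = sampler.take(config.micro_batch)
                batch = [data[i] for i in idx]
                if config.augmentation is not None:
                    batch = [
                        augment(s, config.augmentation,
                                int(rng.integers(0, 2**31 - 1)))
                        for s in batch
                    ]
                vols = np.stack([s.volume for s in batch])
                targets = np.eye(n_classes)[[s.label for s in batch]]
                if config.mixup_alpha is not None and len(batch) >= 2:
                    vols, targets = mixup_batch(
                        vols, targets, config.mixup_alpha,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                for x, t in zip(vols, targets):
                    fwd = model.forward(x)
                    wce_i, dlogits = _soft_wce_and_grad(
                        fwd["output"].logits, t, w
                    )
                    datt = None
                    if prior_grids is not None:
                        m_i = fwd["attention"].maps[None]
                        sim_cfg = replace(config.loss, reduction="sum")
                        sim_i = losses.similarity_loss(m_i, prior_grids, sim_cfg)
                        datt = lam * losses.similarity_loss_grad(
                            m_i, prior_grids, sim_cfg
                        )[0]
                        sim_sum += sim_i
                    grads, _ = model.backward(fwd, dlogits, datt)
                    for k in grad_sums:
                        grad_sums[k] += grads[k]
                    wce_sum += wce_i
                    n_seen += 1
            mean_grads = {k: g / n_seen for k, g in grad_sums.items()}
            wce_mean = wce_sum / n_seen
            sim_mean = sim_sum / n_seen
            total = wce_mean + lam * sim_mean
            if not np.isfinite(total):
                warnings.warn(
                    "non-finite loss encountered; aborting with the last "
                    "good checkpoint", RuntimeWarning, stacklevel=2,
                )
                model.load_state_dict(best_state)
                return TrainResult(
                    model=model, log=pd.DataFrame(records), best_val_f1=best_f1
                )
            opt.step(model.params, mean_grads)
            records.append({
                "step": step, "epoch": epoch, "wce": wce_mean,
                "sim": sim_mean, "total": total, "lr": config.learning_rate,
            })
            step += 1
        if val_data:
            true = [s.label for s in val_data]
            pred = [model.predict(s.volume) for s in val_data]
            f1 = macro_f1(confusion(true, pred, n_classes))
            if best_f1 is None or f1 >= best_f1:
                best_f1, best_state = f1, model.state_dict()
        else:
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainResult(model=model, log=pd.DataFrame(records), best_val_f1=best_f1)


def train_baseline(
    data: list[VolumeSample],
    config: TrainConfig,
    model_config: ModelConfig,
    val_data: list[VolumeSample] | None = None,
) -> TrainResult:
    """Stage 1: weighted cross-entropy only (no prior supervision)."""
    return _run_training(data, config, model_config, priors=None,
                         val_data=val_data)


def train_guided(
    data: list[VolumeSample],
    priors: PriorSet,
    config: TrainConfig,
    model_config: ModelConfig,
    val_data: list[VolumeSample] | None = None,
) -> TrainResult:
    """Stage 2: fresh model trained with WCE + lambda * prior alignment.

    The model is initialized from ``model_config.seed``; pass a different
    seed than the baseline's to keep the two initializations independent.
    """
    if priors.n_classes != model_config.n_classes:
        raise ValueError(
            f"priors cover {priors.n_classes} classes, model expects "
            f"{model_config.n_classes}"
        )
    return _run_training(data, config, model_config, priors=priors,
                         val_data=val_data)
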