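"""Class-wise saliency priors from Shapley-value attribution.

Stage 1 of the pipeline trains a baseline classifier; this module then
attributes each *correctly predicted* training volume to its true class
with a Shapley-style method, averages the signed attributions per class,
and scales each class average by its maximum absolute value so priors live
in [-1, 1].  The frozen priors supervise the attention maps of the stage-2
model.

Two attribution backends share one interface:

``expected_gradients``
    The default.  Integrates the input gradient of the target-class logit
    along the straight path from a reference volume to the input,
    approximated by stratified jittered Monte-Carlo sampling of the path
    position (seeded).  Exact for linear models at any sample count;
    satisfies the Shapley completeness axiom in the sampling limit for
    piecewise-linear networks.

``exact``
    Exhaustive subset enumeration of the classical Shapley value over the
    voxels that differ from the reference, feasible only for tiny inputs
    (<= ``max_exact_players`` players).  Serves as the independent oracle.

Models consumed here need two methods: ``logits(volume) -> (K,) array``
and, for the gradient backend, ``input_gradient(volume, target_class)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import VolumeSample

__all__ = [
    "AttributionConfig",
    "SaliencyVolume",
    "PriorSet",
    "attribute_sample",
    "build_class_priors",
    "resample_prior",
    "save_prior_set",
    "load_prior_set",
]


@dataclass
class AttributionConfig:
    method: str = "expected_gradients"
    n_samples: int = 64
    seed: int = 0
    max_exact_players: int = 14

    def __post_init__(self) -> None:
        if self.method not in ("expected_gradients", "exact"):
            raise ValueError(f"unknown attribution method {self.method!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SaliencyVolume:
    """Per-voxel attribution of one subject toward one class logit."""

    values: np.ndarray
    target_class: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            n_bad = int((~np.isfinite(self.values)).sum())
            raise ValueError(f"attribution contains {n_bad} non-finite voxels")


@dataclass
class PriorSet:
    """K class-averaged saliency volumes plus bookkeeping."""

    priors: np.ndarray  # (K, D, H, W)
    scale_mode: str = "maxabs"
    n_samples_used: np.ndarray = field(default_factory=lambda: np.array([]))
    source_model_id: str = ""

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if self.priors.ndim != 4:
            raise ValueError("priors must be (K, D, H, W)")
        self.n_samples_used = np.asarray(self.n_samples_used, dtype=np.int64)

    @property
    def n_classes(self) -> int:
        return self.priors.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.priors.shape[1:]

    def resampled(self, target_dims: tuple[int, int, int]) -> "PriorSet":
        """Return a copy with every class prior trilinearly resampled."""
        out = np.stack([resample_prior(p, target_dims) for p in self.priors])
        return PriorSet(
            priors=out,
            scale_mode=self.scale_mode,
            n_samples_used=self.n_samples_used.copy(),
            source_model_id=self.source_model_id,
        )


# ---------------------------------------------------------------------------
# attribution backends


def _expected_gradients(
    model, x: np.ndarray, ref: np.ndarray, target: int, cfg: AttributionConfig
) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    delta = x - ref
    grad_sum = np.zeros_like(x)
    # stratified jitter: one uniform draw per stratum of the path integral
    u = rng.uniform(size=cfg.n_samples)
    alphas = (np.arange(cfg.n_samples) + u) / cfg.n_samples
    for a in alphas:
        grad_sum += model.input_gradient(ref + a * delta, target)
    return delta * grad_sum / cfg.n_samples


def _exact_shapley(
    model, x: np.ndarray, ref: np.ndarray, target: int, cfg: AttributionConfig
) -> np.ndarray:
    players = np.argwhere(~np.isclose(x, ref))
    n = len(players)
    if n > cfg.max_exact_players:
        raise ValueError(
            f"exact Shapley enumeration supports at most "
            f"{cfg.max_exact_players} differing voxels, got {n}"
        )
    attr = np.zeros_like(x)
    if n == 0:
        return attr
    # value of every coalition: voxels in S take the input value, rest the
    # reference; one forward pass per subset
    values = np.empty(1 << n)
    for s in range(1 << n):
        v = ref.copy()
        for j in range(n):
            if s >> j & 1:
                idx = tuple(players[j])
                v[idx] = x[idx]
        values[s] = model.logits(v)[target]
    fact = [math.factorial(i) for i in range(n + 1)]
    for j in range(n):
        phi = 0.0
        for s in range(1 << n):
            if s >> j & 1:
                continue
            size = bin(s).count("1")
            w = fact[size] * fact[n - size - 1] / fact[n]
            phi += w * (values[s | (1 << j)] - values[s])
        attr[tuple(players[j])] = phi
    return attr


def attribute_sample(
    model,
    sample: "VolumeSample | np.ndarray",
    reference: np.ndarray,
    target_class: int,
    config: AttributionConfig | None = None,
) -> SaliencyVolume:
    """Per-voxel Shapley-style attribution of the target-class logit
    relative to ``reference``."""
    config = config or AttributionConfig()
    if isinstance(sample, VolumeSample):
        x, sid = sample.volume, sample.subject_id
    else:
        x, sid = np.asarray(sample, dtype=np.float64), ""
    ref = np.asarray(reference, dtype=np.float64)
    if ref.shape != x.shape:
        raise ValueError(
            f"reference shape {ref.shape} does not match input {x.shape}"
        )
    if config.method == "exact":
        vals = _exact_shapley(model, x, ref, target_class, config)
    else:
        vals = _expected_gradients(model, x, ref, target_class, config)
    return SaliencyVolume(values=vals, target_class=target_class, subject_id=sid)


# ---------------------------------------------------------------------------
# class priors


def _maxabs(v: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(v))
    return v / m if m > 0 else v


def build_class_priors(
    model,
    dataset: list[VolumeSample],
    config: AttributionConfig | None = None,
    reference: np.ndarray | None = None,
    scale_mode: str = "maxabs",
    fall_back_to_all: bool = False,
    source_model_id: str = "",
) -> PriorSet:
    """Average signed attributions of correctly predicted samples per class.

    Steps: run inference over ``dataset``; keep samples whose predicted
    class (argmax, ties toward the lowest index) equals the true label;
    attribute each kept sample toward its true class; average per class;
    scale each class prior by its maximum absolute value (``maxabs``) or
    leave raw (``none``).  A class with zero correct predictions raises
    unless ``fall_back_to_all`` admits all its samples instead.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    if scale_mode not in ("maxabs", "none"):
        raise ValueError("scale_mode must be 'maxabs' or 'none'")
    config = config or AttributionConfig()
    n_classes = model.config.n_classes if hasattr(model, "config") else (
        int(max(s.label for s in dataset)) + 1
    )
    if reference is None:
        reference = np.zeros_like(dataset[0].volume)

    by_class: dict[int, list[VolumeSample]] = {k: [] for k in range(n_classes)}
    present: set[int] = set()
    for s in dataset:
        present.add(s.label)
        pred = int(np.argmax(model.logits(s.volume)))
        if pred == s.label:
            by_class[s.label].append(s)

    missing = [k for k in sorted(present) if not by_class[k]]
    if missing and not fall_back_to_all:
        raise ValueError(
            f"classes {missing} have zero correct predictions; pass "
            f"fall_back_to_all=True to average over all their samples"
        )
    for k in missing:
        by_class[k] = [s for s in dataset if s.label == k]

    shape = dataset[0].volume.shape
    priors = np.zeros((n_classes,) + shape)
    n_used = np.zeros(n_classes, dtype=np.int64)
    for k in range(n_classes):
        for i, s in enumerate(by_class[k]):
            sub_cfg = AttributionConfig(
                method=config.method,
                n_samples=config.n_samples,
                seed=int((config.seed * 100003 + k * 1009 + i) % (2**31 - 1)),
                max_exact_players=config.max_exact_players,
            )
            priors[k] += attribute_sample(model, s, reference, k, sub_cfg).values
        n_used[k] = len(by_class[k])
        if n_used[k] > 0:
            priors[k] /= n_used[k]
        if scale_mode == "maxabs":
            priors[k] = _maxabs(priors[k])
    return PriorSet(
        priors=priors,
        scale_mode=scale_mode,
        n_samples_used=n_used,
        source_model_id=source_model_id,
    )


def resample_prior(prior: np.ndarray, target) -> np.ndarray:
    """Trilinear (corner-aligned) resampling onto ``target`` dims."""
    prior = np.asarray(prior, dtype=np.float64)
    tgt = tuple(int(t) for t in (target.shape if hasattr(target, "shape") else target))
    if any(t < 1 for t in tgt):
        raise ValueError("target dims must be >= 1")
    if tgt == prior.shape:
        return prior.copy()
    axes = []
    for ax in range(3):
        s, t = prior.shape[ax], tgt[ax]
        if t == 1:
            axes.append(np.full(1, (s - 1) / 2.0))
        else:
            axes.append(np.arange(t) * (s - 1) / (t - 1))
    grid = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(
        prior, np.stack([g.ravel() for g in grid]), order=1, mode="nearest"
    ).reshape(tgt)


# ---------------------------------------------------------------------------
# persistence: one NIfTI per class + JSON sidecar


def save_prior_set(priors: PriorSet, out_dir: str | Path, seed: int | None = None
                   ) -> Path:
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k in range(priors.n_classes):
        nib.save(
            nib.Nifti1Image(priors.priors[k].astype(np.float32), np.eye(4)),
            out / f"prior_class{k}.nii.gz",
        )
    meta = {
        "n_classes": priors.n_classes,
        "grid": list(priors.grid),
        "scale_mode": priors.scale_mode,
        "n_samples_used": priors.n_samples_used.tolist(),
        "source_model_id": priors.source_model_id,
        "seed": seed,
    }
    (out / "priors.json").write_text(json.dumps(meta, indent=2))
    return out


def load_prior_set(in_dir: str | Path) -> PriorSet:
    import nibabel as nib

    src = Path(in_dir)
    meta = json.loads((src / "priors.json").read_text())
    vols = [
        np.asarray(
            nib.load(src / f"prior_class{k}.nii.gz").get_fdata(), dtype=np.float64
        )
        for k in range(meta["n_classes"])
    ]
    return PriorSet(
        priors=np.stack(vols),
        scale_mode=meta["scale_mode"],
        n_samples_used=np.asarray(meta["n_samples_used"], dtype=np.int64),
        source_model_id=meta.get("source_model_id", ""),
    )
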