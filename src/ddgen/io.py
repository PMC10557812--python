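"""Package-level I/O: NIfTI volumes, CSV tables, run configuration,
checkpoints, seed fan-out, and embedding export.

Volumes are stored as single-channel 3D NIfTI (.nii/.nii.gz) indexed
(depth, height, width) with the affine preserved for round-trips;
synthetic cohorts are written with an identity affine.  All CSVs are
comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .netcore import CNNClassifier, ModelConfig
from .phantom import AtlasVolume, PathologyGrades, VolumeSample
from .trainer import TrainConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "write_cohort",
    "read_cohort",
    "write_grades",
    "read_grades",
    "RunConfig",
    "load_run_config",
    "stage_seed",
    "save_checkpoint",
    "load_checkpoint",
    "export_embeddings",
]

STAGES = ("simulate", "baseline", "priors", "guided", "evaluate", "pathology")


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a single 3D NIfTI volume -> (grid, affine)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume file: {p}")
    img = nib.load(p)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{p} is {data.ndim}D (shape {data.shape}); expected a single "
            f"3D volume"
        )
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine)


def write_volume(grid: np.ndarray, path: str | Path,
                 affine: np.ndarray | None = None) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float64), affine), p)
    return p


def write_atlas(atlas: AtlasVolume, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4)), p)
    return p


def read_atlas(path: str | Path) -> AtlasVolume:
    grid, _ = read_volume(path)
    labels = np.rint(grid).astype(np.int32)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return AtlasVolume(
        labels=labels,
        region_volumes={int(i): int(c) for i, c in zip(ids, counts)},
    )


# ---------------------------------------------------------------------------
# cohorts


def write_cohort(samples: list[VolumeSample], out_dir: str | Path) -> Path:
    """Volumes as NIfTI plus a subjects.csv with labels/domains/severity."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        write_volume(s.volume, out / f"{s.subject_id}.nii.gz")
        rows.append({
            "subject_id": s.subject_id, "label": s.label,
            "domain": s.domain, "severity": s.severity,
        })
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    return out


def read_cohort(in_dir: str | Path) -> list[VolumeSample]:
    src = Path(in_dir)
    table = pd.read_csv(src / "subjects.csv")
    samples = []
    for row in table.itertuples():
        vol, _ = read_volume(src / f"{row.subject_id}.nii.gz")
        sev = None if pd.isna(row.severity) else float(row.severity)
        samples.append(VolumeSample(
            volume=vol, label=int(row.label), domain=str(row.domain),
            subject_id=str(row.subject_id), severity=sev,
        ))
    return samples


def write_grades(grades: list[PathologyGrades], path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"subject_id": g.subject_id, "region_id": r, "grade": v}
        for g in grades for r, v in sorted(g.grades.items())
    ]
    pd.DataFrame(rows).to_csv(p, index=False)
    return p


def read_grades(path: str | Path) -> list[PathologyGrades]:
    table = pd.read_csv(path)
    out: dict[str, dict[int, int]] = {}
    for row in table.itertuples():
        out.setdefault(str(row.subject_id), {})[int(row.region_id)] = int(row.grade)
    return [PathologyGrades(subject_id=s, grades=g) for s, g in out.items()]


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated run settings with the study defaults filled in:
    lambda = 5e-5, k = 5 folds, 60 epochs x 200 steps, micro-batch 2 with
    8-step gradient accumulation, Mixup alpha 0.2 when enabled."""

    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    attribution: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    seed: int = 0
    stage: str = "simulate"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")

    def train_config(self) -> TrainConfig:
        from .losses import LossConfig

        t = dict(self.train)
        loss = LossConfig(lambda_=float(t.pop("lambda", 5e-5)))
        ratio = t.pop("split_ratio", (3.0, 1.0, 1.0))
        return TrainConfig(
            epochs=int(t.pop("epochs", 60)),
            steps_per_epoch=int(t.pop("steps_per_epoch", 200)),
            micro_batch=int(t.pop("micro_batch", 2)),
            accumulation_steps=int(t.pop("accumulation_steps", 8)),
            learning_rate=float(t.pop("learning_rate", 1e-3)),
            k_folds=int(t.pop("k_folds", 5)),
            split_ratio=tuple(float(r) for r in ratio),
            loss=loss,
            mixup_alpha=t.pop("mixup_alpha", None),
            seed=self.seed,
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_KNOWN_KEYS = {"model", "train", "attribution", "paths", "seed", "stage"}


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON run config, rejecting unknown top-level keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Fan one global seed out to a stable per-stage stream (< 2**31)."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: CNNClassifier, path: str | Path,
                    extra: dict | None = None) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({"model": model.config.to_dict(),
                    "extra": extra or {}}).encode(), dtype=np.uint8
    )
    np.savez(p, **payload)
    return p


def load_checkpoint(path: str | Path) -> CNNClassifier:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["config_json"].tobytes()).decode())
        state = {
            k.removeprefix("param/"): data[k]
            for k in data.files if k.startswith("param/")
        }
    model = CNNClassifier(ModelConfig.from_dict(meta["model"]))
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# embedding export (attention-module level representations)


def export_embeddings(model: CNNClassifier, samples: list[VolumeSample],
                      pooled: bool = False) -> pd.DataFrame:
    """Per-sample attention-level representation with metadata columns.

    ``pooled`` reduces each class channel to its spatial mean (length K);
    otherwise the full modulated feature stack is flattened.
    """
    rows = []
    for s in samples:
        fwd = model.forward(s.volume)
        mod = fwd["modulated"].values
        emb = mod.mean(axis=(1, 2, 3)) if pooled else mod.ravel()
        row = {"subject_id": s.subject_id, "domain": s.domain, "label": s.label}
        row.update({f"e{i}": float(v) for i, v in enumerate(emb)})
        rows.append(row)
    return pd.DataFrame(rows)
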