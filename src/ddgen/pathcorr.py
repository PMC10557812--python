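"""Region-level validation of model attention against pathology grades.

The disease-class attention map is aggregated per parcellation region
(sum of voxel attention divided by region volume), and the resulting
region scores are rank-correlated (Spearman) across subjects with ordinal
0-3 pathology grades.  A positive correlation in disease-involved regions
means the model's attention tracks the regional disease burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .phantom import AtlasVolume, PathologyGrades
from .priors import resample_prior

__all__ = [
    "RegionScoreTable",
    "CorrelationTable",
    "region_attention_scores",
    "spearman_rho",
    "correlate_with_pathology",
]

log = logging.getLogger(__name__)


@dataclass
class RegionScoreTable:
    """Volume-normalized attention score per region for one subject."""

    subject_id: str
    scores: dict[int, float]
    target_class: int
    flagged: set[int] | None = None  # regions empty after resampling

    def __post_init__(self) -> None:
        bad = {r: s for r, s in self.scores.items() if not np.isfinite(s)}
        if bad:
            raise ValueError(f"non-finite region scores: {bad}")


@dataclass
class CorrelationTable:
    """(region, stain) -> (rho, n); rho may be None when undefined."""

    entries: dict[tuple[int, str], tuple[float | None, int]]

    def rho(self, region: int, stain: str) -> float | None:
        return self.entries[(region, stain)][0]


def _nearest_downsample(labels: np.ndarray, target: tuple[int, int, int]
                        ) -> np.ndarray:
    axes = []
    for ax in range(3):
        s, t = labels.shape[ax], target[ax]
        if t == 1:
            axes.append(np.full(1, (s - 1) / 2.0))
        else:
            axes.append(np.arange(t) * (s - 1) / (t - 1))
    grid = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(
        labels, np.stack([g.ravel() for g in grid]), order=0, mode="nearest"
    ).reshape(target)


def region_attention_scores(
    attention,
    target_class: int,
    atlas: AtlasVolume,
    subject_id: str = "",
    resample: str = "atlas_to_attention",
) -> RegionScoreTable:
    """score_r = (sum of target-class attention over region r) / |r|.

    When the attention grid differs from the atlas grid, either the atlas
    is downsampled to the attention grid by nearest neighbour (default —
    preserves label identity) or the attention map is trilinearly
    upsampled to the atlas grid (``resample='attention_to_atlas'``).
    Regions that vanish under resampling are flagged and omitted.
    """
    maps = attention.maps if hasattr(attention, "maps") else np.asarray(attention)
    if not 0 <= target_class < maps.shape[0]:
        raise ValueError(f"target_class {target_class} out of range")
    att = np.asarray(maps[target_class], dtype=np.float64)
    labels = atlas.labels
    if att.shape != labels.shape:
        if resample == "atlas_to_attention":
            labels = _nearest_downsample(labels, att.shape)
        elif resample == "attention_to_atlas":
            att = resample_prior(att, labels.shape)
        else:
            raise ValueError(f"unknown resample direction {resample!r}")

    scores: dict[int, float] = {}
    flagged: set[int] = set()
    flat_labels = labels.ravel()
    sums = np.bincount(flat_labels, weights=att.ravel(),
                       minlength=max(atlas.region_ids) + 1)
    counts = np.bincount(flat_labels, minlength=max(atlas.region_ids) + 1)
    for r in atlas.region_ids:
        if counts[r] == 0:
            flagged.add(r)
            continue
        scores[r] = float(sums[r] / counts[r])
    return RegionScoreTable(
        subject_id=subject_id,
        scores=scores,
        target_class=target_class,
        flagged=flagged or None,
    )


def spearman_rho(x, y) -> float | None:
    """Spearman rank correlation (average ranks for ties).

    Returns None — reported as missing, never coerced to 0 — when either
    vector is constant, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need 1D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else None


def correlate_with_pathology(
    score_tables: list[RegionScoreTable],
    grades: list[PathologyGrades],
    stain: str = "pathology",
    min_n: int = 3,
) -> CorrelationTable:
    """Per-region Spearman correlation, across subjects, between attention
    score and pathology grade.  Regions with fewer than ``min_n``
    overlapping subjects are omitted (logged); constant-grade regions are
    reported with rho = None.
    """
    grade_by_subject = {g.subject_id: g.grades for g in grades}
    shared = [t for t in score_tables if t.subject_id in grade_by_subject]
    if not shared:
        raise ValueError("no overlapping subjects between scores and grades")

    regions = sorted({r for t in shared for r in t.scores})
    entries: dict[tuple[int, str], tuple[float | None, int]] = {}
    for r in regions:
        xs, ys = [], []
        for t in shared:
            g = grade_by_subject[t.subject_id]
            if r in t.scores and r in g:
                xs.append(t.scores[r])
                ys.append(g[r])
        if len(xs) < min_n:
            log.info("region %d omitted: only %d overlapping subjects", r, len(xs))
            continue
        entries[(r, stain)] = (spearman_rho(xs, ys), len(xs))
    return CorrelationTable(entries=entries)
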