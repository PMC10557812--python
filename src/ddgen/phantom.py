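"""Synthetic domain-shifted 3D phantom cohorts.

This module generates seeded, fully reproducible stand-ins for multi-cohort
structural brain MRI studies: an ellipsoidal "brain" mask partitioned into
atlas regions, per-subject volumes in which disease classes manifest as
hypointense signal in designated regions, per-cohort acquisition shifts
(global intensity scaling, smooth multiplicative bias fields, additive
noise), and per-region ordinal pathology grades driven by the same latent
severity that drives the class label.  Every downstream stage of the
package (training, attribution, evaluation, pathology correlation) is
testable end to end on these phantoms without any real scans.

Conventions: voxel arrays are indexed (depth, height, width); atlas label 0
is background everywhere in the package; class 0 is the control class and
carries no disease regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Dim3",
    "AtlasVolume",
    "DomainSpec",
    "CohortSpec",
    "VolumeSample",
    "PathologyGrades",
    "make_atlas",
    "sample_subject",
    "generate_cohort",
]

#: hard ceiling on voxel counts; phantoms are desk-scale by design
DEFAULT_VOXEL_CAP = 64 ** 3


@dataclass(frozen=True)
class Dim3:
    """Spatial grid dimensions (depth, height, width) in voxels."""

    depth: int
    height: int
    width: int
    voxel_cap: int = DEFAULT_VOXEL_CAP

    def __post_init__(self) -> None:
        for name in ("depth", "height", "width"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 8:
                raise ValueError(f"{name} must be an integer >= 8, got {v!r}")
        if self.n_voxels > self.voxel_cap:
            raise ValueError(
                f"grid {self.shape} has {self.n_voxels} voxels, "
                f"exceeding the cap of {self.voxel_cap}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.depth, self.height, self.width)

    @property
    def n_voxels(self) -> int:
        return self.depth * self.height * self.width


@dataclass
class AtlasVolume:
    """Integer-labelled parcellation: 0 = background, 1..R = regions."""

    labels: np.ndarray
    region_volumes: dict[int, int]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D integer grid")
        present = set(np.unique(labels)) - {0}
        if set(self.region_volumes) != present:
            raise ValueError(
                "region_volumes keys must match the nonzero labels present"
            )
        if sum(self.region_volumes.values()) != int(np.count_nonzero(labels)):
            raise ValueError("region_volumes must sum to the nonzero voxel count")
        self.labels = labels

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_volumes)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def dims(self) -> Dim3:
        d, h, w = self.labels.shape
        return Dim3(d, h, w)


@dataclass(frozen=True)
class DomainSpec:
    """One acquisition domain (cohort/scanner) and its intensity shifts.

    intensity_scale multiplies the whole volume; bias_field_amplitude sets
    the peak relative deviation of a smooth multiplicative field (Gaussian
    length-scale ``bias_field_smoothness`` voxels); noise_sigma is the std
    of additive Gaussian noise, on the pre-rescaling intensity scale.
    """

    name: str
    intensity_scale: float = 1.0
    bias_field_amplitude: float = 0.0
    bias_field_smoothness: float = 4.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if self.bias_field_amplitude < 0:
            raise ValueError("bias_field_amplitude must be >= 0")
        if self.bias_field_smoothness <= 0:
            raise ValueError("bias_field_smoothness must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class CohortSpec:
    """Full specification of a synthetic multi-domain cohort."""

    dims: Dim3
    n_classes: int
    disease_regions: dict[int, set[int]]
    effect_size: float
    domains: list[DomainSpec]
    n_per_class_per_domain: int
    seed: int
    grade_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        bad = [k for k in self.disease_regions if not 0 <= k < self.n_classes]
        if bad:
            raise ValueError(f"disease_regions keys outside 0..K-1: {bad}")
        if 0 in self.disease_regions and self.disease_regions[0]:
            raise ValueError("class 0 is the control class and has no disease regions")
        names = [d.name for d in self.domains]
        if len(names) != len(set(names)):
            raise ValueError("domain names must be unique")
        if not 0.0 <= self.grade_noise <= 1.0:
            raise ValueError("grade_noise must be in [0, 1]")

    def validate_against(self, atlas: AtlasVolume) -> None:
        known = set(atlas.region_volumes)
        for k, regions in self.disease_regions.items():
            missing = set(regions) - known
            if missing:
                raise ValueError(
                    f"class {k} references atlas regions {sorted(missing)} "
                    f"that do not exist"
                )


@dataclass
class VolumeSample:
    """One subject's scan plus its labels.

    ``severity`` is the latent disease burden in [0, 1] for synthetic
    subjects; it may be None for real data.
    """

    volume: np.ndarray
    label: int
    domain: str
    subject_id: str
    severity: float | None = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.label < 0:
            raise ValueError("label must be a non-negative class index")


@dataclass
class PathologyGrades:
    """Ordinal 0-3 pathology grades per atlas region for one subject.

    0 = none, 1 = mild, 2 = moderate, 3 = severe.
    """

    subject_id: str
    grades: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r: g for r, g in self.grades.items() if g not in (0, 1, 2, 3)}
        if bad:
            raise ValueError(f"grades must be in {{0,1,2,3}}, got {bad}")


# ---------------------------------------------------------------------------
# atlas construction


def _ellipsoid_mask(dims: Dim3) -> np.ndarray:
    """Axis-aligned ellipsoid filling ~84% of each axis, centred."""
    shape = dims.shape
    coords = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    r2 = np.zeros(shape)
    for ax in range(3):
        c = (shape[ax] - 1) / 2.0
        semi = 0.42 * shape[ax]
        r2 = r2 + ((coords[ax] - c) / semi) ** 2
    return r2 <= 1.0


def make_atlas(dims: Dim3, n_regions: int, seed: int) -> AtlasVolume:
    """Partition an ellipsoidal brain mask into ``n_regions`` Voronoi regions.

    Seed points are drawn uniformly from the in-mask voxels; every in-mask
    voxel is assigned to its nearest seed point (Euclidean distance, ties
    to the lowest region id), yielding contiguous compact regions.
    Deterministic for fixed (dims, n_regions, seed).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask = _ellipsoid_mask(dims)
    in_mask = np.argwhere(mask)
    if n_regions > len(in_mask):
        raise ValueError(
            f"cannot fit {n_regions} nonempty regions in a mask of "
            f"{len(in_mask)} voxels; enlarge dims"
        )
    rng = np.random.default_rng(seed)
    # sample without replacement so no two regions share a seed voxel
    idx = rng.choice(len(in_mask), size=n_regions, replace=False)
    seeds = in_mask[idx].astype(np.float64)

    d2 = ((in_mask[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1) + 1  # region ids 1..R; argmin = lowest id on tie

    labels = np.zeros(dims.shape, dtype=np.int32)
    labels[tuple(in_mask.T)] = assign
    ids, counts = np.unique(assign, return_counts=True)
    region_volumes = {int(i): int(c) for i, c in zip(ids, counts)}
    if len(region_volumes) != n_regions:
        raise ValueError(
            "degenerate Voronoi partition: some regions captured no voxels; "
            "enlarge dims or reduce n_regions"
        )
    return AtlasVolume(labels=labels, region_volumes=region_volumes)


# ---------------------------------------------------------------------------
# subject synthesis


def _smooth_field(shape: tuple[int, int, int], smoothness: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-max-abs smooth random field (Gaussian-filtered noise)."""
    raw = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(raw, sigma=smoothness)
    f -= f.mean()
    m = np.max(np.abs(f))
    if m > 0:
        f /= m
    return f


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def sample_subject(
    atlas: AtlasVolume,
    spec: CohortSpec,
    label: int,
    domain: DomainSpec,
    severity: float,
    seed: int,
    subject_id: str = "",
) -> VolumeSample:
    """Synthesize one subject volume.

    Pipeline: smooth seeded base anatomy on the brain mask; subtract
    ``effect_size * severity`` inside the class's disease regions
    (hypointensity, mimicking atrophy); then the domain transform in
    order — multiply by ``intensity_scale``, multiply by a smooth bias
    field, add Gaussian noise — and finally min-max scale to [0, 1].

    The base anatomy, bias field, and noise derive from ``seed`` alone, so
    two domains differing only in intensity_scale produce (with zero noise)
    volumes identical after the final rescaling.
    """
    if not 0 <= label < spec.n_classes:
        raise ValueError(f"label {label} outside 0..{spec.n_classes - 1}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    if label != 0 and label not in spec.disease_regions:
        raise ValueError(
            f"class {label} has no disease_regions entry; only the control "
            f"class 0 may omit one"
        )
    spec.validate_against(atlas)

    shape = atlas.labels.shape
    rng = np.random.default_rng(seed)
    # base anatomy: smooth field mapped to [0.3, 0.8] inside the mask
    base = 0.55 + 0.25 * _smooth_field(shape, smoothness=3.0, rng=rng)
    vol = np.where(atlas.mask, base, 0.0)

    regions = spec.disease_regions.get(label, set())
    if regions and severity > 0:
        lesion = np.isin(atlas.labels, sorted(regions))
        vol = vol - spec.effect_size * severity * lesion

    vol = vol * domain.intensity_scale
    bias = _smooth_field(shape, domain.bias_field_smoothness, rng)
    vol = vol * (1.0 + domain.bias_field_amplitude * bias)
    vol = vol + domain.noise_sigma * rng.standard_normal(shape)
    vol = _minmax(vol)

    return VolumeSample(
        volume=vol,
        label=label,
        domain=domain.name,
        subject_id=subject_id or f"sub-{seed}",
        severity=float(severity),
    )


# ---------------------------------------------------------------------------
# cohort generation


def _class_severity(label: int, n_classes: int, rng: np.random.Generator) -> float:
    """Severity stratified upward by class: control 0; diseased classes draw
    from adjacent upward bands of [0, 1]."""
    if label == 0:
        return 0.0
    n_dis = n_classes - 1
    lo = (2 * label - 1) / (2.0 * n_dis)
    hi = min(1.0, (2 * label + 1) / (2.0 * n_dis))
    return float(rng.uniform(lo, hi))


def severity_to_grade(severity: float, involved: bool, noise: float,
                      rng: np.random.Generator | None = None) -> int:
    """Equal-width quartile binning of severity*involvement into {0,1,2,3},
    with optional +/-1 ordinal noise applied with probability ``noise``."""
    v = severity if involved else 0.0
    grade = min(3, int(np.floor(4.0 * v)))
    if noise > 0:
        if rng is None:
            raise ValueError("ordinal noise requires an rng")
        if rng.uniform() < noise:
            grade = int(np.clip(grade + rng.choice([-1, 1]), 0, 3))
    return grade


def generate_cohort(
    spec: CohortSpec, atlas: AtlasVolume
) -> tuple[list[VolumeSample], list[PathologyGrades]]:
    """Generate the full cohort: ``n_per_class_per_domain`` subjects per
    (class, domain), with severities drawn class-conditionally and grades a
    monotone binning of severity restricted to involved regions.

    Fully reproducible from ``spec.seed``.
    """
    if not spec.domains:
        raise ValueError("cohort needs at least one domain")
    spec.validate_against(atlas)
    master = np.random.default_rng(spec.seed)
    samples: list[VolumeSample] = []
    grades: list[PathologyGrades] = []
    counter = 0
    for domain in spec.domains:
        for label in range(spec.n_classes):
            involved = spec.disease_regions.get(label, set())
            for _ in range(spec.n_per_class_per_domain):
                sev = _class_severity(label, spec.n_classes, master)
                sub_seed = int(master.integers(0, 2**31 - 1))
                sid = f"{domain.name}-c{label}-{counter:04d}"
                samples.append(
                    sample_subject(
                        atlas, spec, label, domain, sev, sub_seed, subject_id=sid
                    )
                )
                grng = np.random.default_rng(sub_seed + 1)
                g = {
                    r: severity_to_grade(sev, r in involved, spec.grade_noise, grng)
                    for r in atlas.region_ids
                }
                grades.append(PathologyGrades(subject_id=sid, grades=g))
                counter += 1
    return samples, grades
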