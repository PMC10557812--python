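"""The frozen phantom study protocol.

This module pins the desk-scale experimental conditions used to exercise
the full two-stage pipeline end to end: a 16^3 phantom with one clean
training domain and two acquisition-shifted target domains (a global
intensity scaling and a strong, very smooth multiplicative bias field),
training with micro-batch 2 and 8-step gradient accumulation (effective
batch 16), augmentation, validation-selected checkpoints, mean-referenced
Shapley priors, and an alignment weight of 1e-3 chosen so the alignment
term contributes a small fraction of the total loss (see docs/methods.md).

`run_study_seed` executes baseline -> priors -> guided for one seed;
`prior_recovery_run` is the larger 24^3 single-domain experiment that
checks the disease-class prior concentrates inside the lesion;
`study_pathology_rho` correlates the guided model's disease-class region
evidence with the phantom's noise-free pathology grades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evalmetrics import TARGET_MEAN, evaluate_model
from .losses import LossConfig
from .netcore import ModelConfig
from .pathcorr import correlate_with_pathology, region_attention_scores
from .phantom import CohortSpec, Dim3, DomainSpec, generate_cohort, make_atlas
from .priors import AttributionConfig, build_class_priors
from .trainer import (
    AugmentPolicy,
    TrainConfig,
    stratified_folds,
    train_baseline,
    train_guided,
)

__all__ = ["StudyRun", "run_study_seed", "prior_recovery_run",
           "study_pathology_rho"]


@dataclass
class StudyRun:
    seed: int
    atlas: object
    spec: CohortSpec
    samples: list
    grades: list
    disease_regions: dict
    baseline: object
    guided: object
    guided_log: object
    priors: object
    base_target_acc: float
    guided_target_acc: float


def _disease_regions(atlas) -> dict[int, set[int]]:
    """Classes 1 and 2 affect the two largest atlas regions."""
    big = sorted(atlas.region_volumes, key=atlas.region_volumes.get,
                 reverse=True)
    return {1: {big[1]}, 2: {big[0]}}


def run_study_seed(seed: int, *, lambda_: float = 1e-3, epochs: int = 12,
                   augment: bool = True) -> StudyRun:
    """Baseline -> mean-referenced priors -> guided model for one seed."""
    dims = Dim3(16, 16, 16)
    atlas = make_atlas(dims, 6, seed=100 + seed)
    dr = _disease_regions(atlas)
    domains = [
        DomainSpec("src", 1.0, 0.0, 4.0, 0.02),
        DomainSpec("tgt_scale", 1.6, 0.3, 8.0, 0.03),
        DomainSpec("tgt_bias", 0.8, 0.8, 8.0, 0.03),
    ]
    spec = CohortSpec(dims=dims, n_classes=3, disease_regions=dr,
                      effect_size=0.5, domains=domains,
                      n_per_class_per_domain=12, seed=200 + seed)
    samples, grades = generate_cohort(spec, atlas)
    src = [s for s in samples if s.domain == "src"]
    targets = {
        d.name: [s for s in samples if s.domain == d.name]
        for d in domains[1:]
    }
    folds = stratified_folds({s.subject_id: s.label for s in src}, k=5,
                             seed=700 + seed)
    roles = folds.roles[0]
    train = [s for s in src if roles[s.subject_id] == "train"]
    val = [s for s in src if roles[s.subject_id] == "val"]
    policy = AugmentPolicy() if augment else None

    mc_base = ModelConfig(n_classes=3, input_dims=dims, encoder_widths=[8],
                          seed=300 + seed)
    tc = TrainConfig(epochs=epochs, steps_per_epoch=20, micro_batch=2,
                     accumulation_steps=8, learning_rate=1e-2,
                     seed=400 + seed, augmentation=policy)
    rb = train_baseline(train, tc, mc_base, val_data=val)

    mean_volume = np.mean([s.volume for s in train], axis=0)
    priors = build_class_priors(
        rb.model, train, AttributionConfig(n_samples=8, seed=500 + seed),
        reference=mean_volume, fall_back_to_all=True,
    )

    mc_guided = ModelConfig(n_classes=3, input_dims=dims, encoder_widths=[8],
                            seed=600 + seed)
    tc_guided = TrainConfig(epochs=epochs, steps_per_epoch=20, micro_batch=2,
                            accumulation_steps=8, learning_rate=1e-2,
                            seed=400 + seed, augmentation=policy,
                            loss=LossConfig(lambda_=lambda_))
    rg = train_guided(train, priors, tc_guided, mc_guided, val_data=val)

    def target_acc(model):
        rows = evaluate_model(model, targets)
        return next(r.accuracy for r in rows if r.domain == TARGET_MEAN)

    return StudyRun(
        seed=seed, atlas=atlas, spec=spec, samples=samples, grades=grades,
        disease_regions=dr, baseline=rb.model, guided=rg.model,
        guided_log=rg.log, priors=priors,
        base_target_acc=target_acc(rb.model),
        guided_target_acc=target_acc(rg.model),
    )


def prior_recovery_run(seed: int) -> tuple[float, float]:
    """Train a baseline on a 24^3 single-domain phantom and build
    mean-referenced class priors; returns (train accuracy, ratio of mean
    |disease-class prior| inside vs outside the lesion region)."""
    dims = Dim3(24, 24, 24)
    atlas = make_atlas(dims, 6, seed=100 + seed)
    dr = _disease_regions(atlas)
    spec = CohortSpec(dims=dims, n_classes=3, disease_regions=dr,
                      effect_size=0.5,
                      domains=[DomainSpec("src", 1.0, 0.0, 4.0, 0.02)],
                      n_per_class_per_domain=8, seed=200 + seed)
    samples, _ = generate_cohort(spec, atlas)
    mc = ModelConfig(n_classes=3, input_dims=dims, encoder_widths=[4, 8],
                     seed=300 + seed)
    tc = TrainConfig(epochs=12, steps_per_epoch=20, micro_batch=2,
                     accumulation_steps=4, learning_rate=1e-2,
                     seed=400 + seed)
    result = train_baseline(samples, tc, mc)
    acc = float(np.mean([result.model.predict(s.volume) == s.label
                         for s in samples]))
    mean_volume = np.mean([s.volume for s in samples], axis=0)
    priors = build_class_priors(
        result.model, samples,
        AttributionConfig(n_samples=8, seed=500 + seed),
        reference=mean_volume, fall_back_to_all=True,
    )
    lesion = np.isin(atlas.labels, sorted(dr[2]))
    disease_prior = np.abs(priors.priors[2])
    ratio = float(disease_prior[lesion].mean()
                  / disease_prior[~lesion].mean())
    return acc, ratio


def study_pathology_rho(run: StudyRun) -> float:
    """Mean Spearman rho between the guided model's disease-class region
    evidence (the attention module's output channel for the disease
    class, volume-normalized per region) and the phantom's noise-free
    grades, over the involved regions."""
    involved = sorted(run.disease_regions[2])
    tables = [
        region_attention_scores(
            run.guided.forward(s.volume)["modulated"].values, 2, run.atlas,
            subject_id=s.subject_id,
        )
        for s in run.samples
    ]
    corr = correlate_with_pathology(tables, run.grades)
    rhos = [corr.entries[(r, "pathology")][0] for r in involved
            if (r, "pathology") in corr.entries]
    return float(np.mean(rhos))
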